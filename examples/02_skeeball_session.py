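"""Play a simulated ball-throwing training session scored by extensor ratio.

Simulates a participant who extends with moderate flexor co-contraction
(extensor ratio ~0.75), runs the full simulate → calibrate → process →
score chain, and prints per-trial results.  Higher individuation (ER
closer to 1) earns more points in expectation.
"""

import myofeedback as mf

protocol = mf.TrainingProtocol(blocks=1, reps_per_block=10, inter_trial_rest_s=1.0,
                               inter_block_rest_s=0.0)
pairs = [(0.6, 0.2)] * protocol.n_trials  # extensor-dominant activation
sess = mf.run_training_session(individuation=pairs, protocol=protocol, seed=7)

print("trial  ER     ext    flex   bin  points")
for t in sess.log.trials:
    print(f"{t.index:>5}  {t.er:.3f}  {t.ext_mean:.3f}  {t.flex_mean:.3f}  "
          f"{t.bin:>3}  {t.points:>5}")
print(f"final score: {sess.log.final_score}")
print(f"session mean ER: {sess.summary.er_mean:.3f} "
      "(1 = pure extension, 0.5 = full co-contraction)")
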