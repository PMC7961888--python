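"""Recover a training effect across simulated sessions.

Simulates a participant whose extension individuation drifts from ER 0.5
(full co-contraction) toward 0.8 over 15 sessions, then tests for a
change over time with Pearson correlations of the per-session means —
the same analysis a therapist would run over weeks of real training logs.
"""

import myofeedback as mf

protocol = mf.TrainingProtocol(blocks=1, reps_per_block=8, inter_trial_rest_s=1.0,
                               inter_block_rest_s=0.0)
summaries = mf.run_longitudinal_study(n_sessions=15, er_start=0.5, er_end=0.8,
                                      protocol=protocol, seed=11)
print("session  er_mean  ext_mean  flex_mean  score")
for s in summaries:
    print(f"{s.session_index:>7}  {s.er_mean:.3f}    {s.ext_mean:.3f}     "
          f"{s.flex_mean:.3f}    {s.score:.0f}")
for field in ("er_mean", "ext_mean", "flex_mean", "score"):
    tr = mf.longitudinal_trend(summaries, field)
    print(f"trend in {field:<9}: rho = {tr.rho:+.3f}, p = {tr.p:.2g} (n = {tr.n})")
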