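"""Compare two simulated sensors on the isometric ramp-hold task.

Each 'device' records the same protocol: 12 trials of 5-s ramp to 25% of
maximum grip force, 5-s hold, 7-s rest, with EMG and force coupled.  The
per-trial hold-phase extensor ratios are compared with a paired t-test
(equivalent devices should not differ) and per-muscle EMG-force
regressions quantify how much force variance the envelopes explain.
"""

import numpy as np

import myofeedback as mf

report = mf.run_validation_study(seed=5)
print(f"hold-phase ER, device A: {np.mean(report.er_means_a):.3f} "
      f"+/- {np.std(report.er_means_a):.3f} over {len(report.er_means_a)} holds")
print(f"hold-phase ER, device B: {np.mean(report.er_means_b):.3f} "
      f"+/- {np.std(report.er_means_b):.3f}")
print(f"paired t-test: t = {report.t:.3f}, p = {report.p:.3f} "
      "(p > 0.05: no evidence the devices differ)")
for dev, regs in (("A", report.regressions_a), ("B", report.regressions_b)):
    for muscle, r in regs.items():
        print(f"device {dev} {muscle:<9} slope = {r.slope:.2f}, R^2 = {r.r2:.3f}")
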