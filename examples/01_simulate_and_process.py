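"""Synthesize a grip recording and extract its normalized envelope.

Builds a 3-s co-activated grip flanked by rest, passes it through the
simulated low-cost front-end (500 V/V, 1.65 V mid-supply offset, 12-bit
ADC at 2000 Hz), calibrates on the grip, and processes the same recording
back through the envelope chain.
"""

import numpy as np

import myofeedback as mf

model = mf.SensorModel()
rec = mf.simulate_grip_recording(model, grip_level=1.0, seed=42)
volts = mf.counts_to_volts(rec, model)
print(f"raw counts range: [{rec.samples.min()}, {rec.samples.max()}] "
      f"(midpoint code {round((2**model.adc_bits - 1) / 2)})")
print(f"mean level: {volts.samples.mean():.4f} V (front-end offset {model.midpoint_v} V)")

profile = mf.calibrate_grip(rec)
print("calibration amplitudes (counts):",
      {k: round(v, 1) for k, v in profile.amplitudes.items()})

env = mf.process(rec, profile)
rest = env.values[:, : int(0.5 * env.fs_hz)].mean()
print(f"envelope peak per channel: {np.round(env.values.max(axis=1), 3)} "
      "(~1.0 = as active as the calibration grip)")
print(f"envelope rest level: {rest:.4f} (~0 = no volitional activity)")

disp = mf.downsample_for_display(env, fps=60.0)
print(f"display stream: {disp.values.shape[1]} frames at 60 fps, "
      f"color index range [{disp.color_index.min():.2f}, {disp.color_index.max():.2f}]")
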