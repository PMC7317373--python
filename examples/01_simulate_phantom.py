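"""Simulate one synthetic perfusion subject and inspect its ground truth.

Generates three short-axis slices at rest and stress (desk-scale: 128 px,
32 frames), then prints the first-pass timing and geometry labels for each
series.  The printed ordering (RV pool peak before LV pool peak before
myocardial peak) is the fingerprint of first-pass contrast transit.
"""

import numpy as np

from perfusionkit.phantom import desk_phantom_config, generate_series

config = desk_phantom_config(noise_sd=0.02)
pairs = generate_series(config, seed=42, subject_id="demo")

print(f"subject 'demo': {len(pairs)} series "
      f"({config.n_slices} slices x {len(config.conditions)} conditions)\n")
for series, truth in pairs:
    rv_peak = int(np.argmax(series.frames[:, truth.rv_mask].mean(axis=1)))
    myo_peak = int(np.argmax(series.frames[:, truth.myo_mask].mean(axis=1)))
    r0, r1, c0, c1 = truth.bbox.bounds(series.shape)
    print(
        f"{series.slice_level:>6}/{series.condition:<6} "
        f"RV peak t={rv_peak:2d}  LV peak t={truth.peak_frame:2d}  myo peak t={myo_peak:2d}  "
        f"box [{r0}:{r1}, {c0}:{c1}]  myo {int(truth.myo_mask.sum())} px  "
        f"mean Fp {truth.param_maps.Fp[truth.myo_mask].mean():.2f} mL/min/mL"
    )

print("\nLV peak follows the RV peak by ~3 frames (bolus transit through the "
      "lungs); myocardial enhancement peaks last and is ~5x weaker than the pool.")
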