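"""Train and evaluate the whole pipeline on a miniature phantom cohort.

A shrunken version of the desk-scale study (6/2/2 subjects, short training)
that still exercises every stage: simulate, train the four networks, run
the automated pipeline on held-out subjects, and score it against ground
truth.  Takes a few minutes on one CPU; the full-size study (40/5/10) is
what `scripts/acceptance.py` and the acceptance tests run.
"""

import time

from perfusionkit.experiment import DeskExperimentConfig, run_desk_experiment

config = DeskExperimentConfig(
    n_train=6, n_val=2, n_test=2,
    peak_iterations=200, bbox_iterations=300, seg_iterations=120, action_iterations=150,
)

t0 = time.time()
metrics, models = run_desk_experiment(seed=3, cfg=config)
print(f"\nfinished in {time.time() - t0:.0f} s\n")
for key in (
    "peak_frame_mae", "box_dsc_mean", "myo_dsc_mean", "insertion_error_px_mean",
    "pipeline_completions", "mbf_rest_mean", "mbf_stress_mean", "segment_mbf_icc",
):
    print(f"  {key}: {metrics[key]}")
print("\nWith this little training the detection metrics are rougher than the "
      "full desk-scale study's; they tighten with 40 training subjects.")
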