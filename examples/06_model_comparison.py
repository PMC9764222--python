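"""Compare the habituation (h1) and prediction-error (h2) models per voxel.

Each model yields one task regressor (its amplitude vector,
z-standardised per run); the conjugate linear-model log-evidence is
combined across subjects into fixed-effects Bayes factors K_{h2/h1} and
random-effects posterior probability maps.
"""

import numpy as np

from oddball_fmri import bms, design, simulate

grid = simulate.make_roi_grid(
    {"shape": (5, 5, 2), "rois": {"AC": ((0, 5), (0, 5), (0, 2))}})

runs_data, schedules = [], []
for subject in range(10):
    data_row, sched_row = [], []
    for r in range(4):
        schedule = design.build_run(seed=100 * subject + r, run_index=r)
        run = simulate.simulate_run(schedule, grid,
                                    {"AC": simulate.h2_profile()},
                                    simulate.NoiseSpec(tsnr=50.0),
                                    tr=1.6, seed=7000 + 10 * subject + r)
        data_row.append(run.data)
        sched_row.append(schedule)
    runs_data.append(data_row)
    schedules.append(sched_row)

evidence = bms.evidence_for_cohort(runs_data, schedules, tr=1.6, grid=grid)
posterior = bms.group_maps(evidence)

lnk = posterior.log_bayes_factor
frac = (posterior.expected_posterior[:, 1] > 0.5).mean()
print(f"Cohort generated under h2 ({grid.n_labeled} voxels, 10 subjects, "
      f"4 runs):")
print(f"  fixed-effects ln K_h2/h1: median {np.median(lnk):.1f} "
      f"(K > 1 favours prediction error)")
print(f"  voxels with RFX posterior > 0.5 for h2: {100 * frac:.1f}%")
print(posterior.roi_summary("h2").to_string(index=False,
                                            float_format="%.2f"))
print("\nK grows multiplicatively with subjects (log-evidences add), so")
print("even modest per-subject evidence yields decisive group maps.")
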