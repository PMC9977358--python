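"""Generate condition-coded beta volumes and map decodable regions.

A searchlight decode of "conscious stimulus vs absent" over the
visuospatial search mask defines a subject ROI (top gray-matter voxels
above chance), which later analyses reuse for orthogonal contrasts.

Run:  python examples/04_synthetic_betas_and_searchlight.py
"""

import numpy as np

from cfswm import build_design, build_schedule, mvpa
from cfswm import synthetic_fmri as sf

design = build_design(3)
grid = sf.default_grid((16, 16, 10))  # desk-scale grid for a quick demo
effects = sf.default_effects(grid)
schedule = build_schedule(design, seed=1)
images = sf.generate_betas(schedule, effects, grid, seed=11, phases=("delay",))
print(f"Generated {len(images)} delay-phase beta volumes on grid {grid.shape}")

# ROI-defining contrast: conscious vs absent (balanced by down-sampling)
data, labels = mvpa.stack_images(images, phase="delay")
mask = labels["condition"].isin(["conscious", "absent"]).to_numpy()
y = labels.loc[mask, "condition"].to_numpy()
onsets = (labels["onset_s"] + 4000.0 * labels["block"]).to_numpy()[mask]
rng = np.random.default_rng(0)
conscious = np.flatnonzero(y == "conscious")
absent = np.flatnonzero(y == "absent")
keep = np.sort(np.concatenate([rng.choice(conscious, absent.size, replace=False), absent]))
folds = mvpa.build_folds(onsets[keep], n_folds=10, min_gap_s=30.0, seed=0, labels=y[keep])
print(f"Folds: {folds.n_folds}, dropped at boundaries: {folds.n_dropped}, "
      f"gap violations: {len(mvpa.audit_fold_gaps(folds))}")

accuracy_map = mvpa.run_searchlight(
    data[mask][keep], y[keep], folds, grid.brain_mask, grid.visuospatial_mask,
    mvpa.SearchlightSpec(radius_voxels=2.0),
)
print(f"Searchlight mean accuracy {100 * np.nanmean(accuracy_map):.1f}% "
      f"(max {100 * np.nanmax(accuracy_map):.1f}%)")

roi = mvpa.select_roi(accuracy_map, grid.gray_mask, max_voxels=200,
                      source_contrast="conscious-vs-absent-delay")
print(f"ROI: {roi.n_voxels} voxels from contrast {roi.source_contrast!r}")
# Accuracy well above 50% where the stimulus-evoked pattern lives marks the
# voxels worth decoding; the ROI keeps the best of them (capped, above chance).
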