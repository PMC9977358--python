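"""Balanced ROI decoding across subjects with permutation group inference.

Decodes the target's side (left vs right) from conscious delay-phase
activity in a lateralized ROI, balancing distractor presence across the
two sides, then tests the group-mean accuracy against an empirical null
built by within-fold label shuffling with full classifier refits.

Run:  python examples/05_roi_decoding_and_group_inference.py
"""

import numpy as np

from cfswm import build_design, build_schedule, mvpa
from cfswm import synthetic_fmri as sf

design = build_design(3)
grid = sf.default_grid()
effects = sf.default_effects(grid)

subjects = []
for s in range(6):
    schedule = [t for t in build_schedule(design, seed=100 + s) if t.condition == "conscious"]
    images = sf.generate_betas(schedule, effects, grid, seed=200 + s, phases=("delay",))
    data, labels = mvpa.stack_images(images, phase="delay")
    y = labels["target_side"].to_numpy()
    onsets = (labels["onset_s"] + 4000.0 * labels["block"]).to_numpy()
    folds = mvpa.build_folds(onsets, n_folds=10, min_gap_s=30.0, seed=s, labels=y)
    X = mvpa.mask_features(data, grid.visuospatial_mask)
    res = mvpa.decode_roi_balanced(
        X, y, folds, n_iter=50, seed=s,
        balance_by=labels["distractor_present"].to_numpy(),
        contrast_name="conscious-target-side-delay",
    )
    print(f"subject {s}: accuracy {100 * res.accuracy:.1f}% "
          f"({res.n_trials_used} trials/iteration)")
    subjects.append(mvpa.SubjectDecodeData(X=X, labels=y, folds=folds))

group = mvpa.group_permutation_test(subjects, n_perm=200, seed=0)
print(f"\nGroup mean accuracy {100 * group.observed_group_accuracy:.1f}% "
      f"vs null mean {100 * group.null_distribution.mean():.1f}%; "
      f"one-tailed p = {group.p_value:.4f} ({group.n_perm} permutations)")
# Accuracy near the calibrated ~63% regime with p at the add-one floor shows
# the lateralized working-memory signal is recovered by the full procedure.
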