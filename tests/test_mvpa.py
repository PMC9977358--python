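"""Decoding engine: folds, searchlight, ROI selection, balancing, inference."""

import numpy as np
import pytest

from cfswm import design, mvpa, synthetic_fmri as sf
from cfswm.classifier import LinearMaxMargin, cv_accuracy


def _noise_features(rng, n, d):
    return rng.normal(size=(n, d))


def _alternating(n, a="A", b="B"):
    return np.array([a, b] * (n // 2))


def _simple_folds(n, n_folds, spacing=40.0):
    onsets = np.arange(n) * spacing
    return mvpa.build_folds(onsets, n_folds=n_folds, min_gap_s=30.0)


def brute_force_gap_violations(plan):
    """Independent oracle: scan all retained cross-fold temporally adjacent pairs."""
    idx = plan.retained
    order = idx[np.argsort(plan.onsets[idx])]
    bad = []
    for a, b in zip(order[:-1], order[1:]):
        if plan.fold_of[a] != plan.fold_of[b] and plan.onsets[b] - plan.onsets[a] < plan.min_gap_s:
            bad.append((a, b))
    return bad


class TestFolds:
    def test_wide_spacing_drops_nothing(self):
        plan = _simple_folds(50, 10, spacing=40.0)
        assert plan.n_dropped == 0
        assert brute_force_gap_violations(plan) == []

    def test_close_spacing_drops_only_boundary_trials(self):
        onsets = np.arange(0, 1000, 10.0)
        plan = mvpa.build_folds(onsets, n_folds=5, min_gap_s=30.0)
        assert brute_force_gap_violations(plan) == []
        # 10 s spacing needs two trials sacrificed per boundary
        assert plan.n_dropped == 2 * 4
        # dropped trials all sit adjacent to a fold transition
        dropped = np.flatnonzero(plan.fold_of < 0)
        kept_folds = plan.fold_of[plan.fold_of >= 0]
        assert len(np.unique(kept_folds)) == 5

    def test_too_few_trials_is_infeasible(self):
        with pytest.raises(mvpa.InfeasibleFoldsError):
            mvpa.build_folds(np.arange(5) * 40.0, n_folds=10)

    def test_every_fold_contains_both_classes_or_infeasible(self, rng):
        onsets = np.arange(40) * 40.0
        labels = _alternating(40)
        plan = mvpa.build_folds(onsets, n_folds=4, min_gap_s=30.0, seed=0, labels=labels)
        for f in range(4):
            assert np.unique(labels[plan.fold_of == f]).size == 2
        # fully blocked labels cannot be mixed by contiguous-in-time chunks
        blocked = np.array(["A"] * 20 + ["B"] * 20)
        with pytest.raises(mvpa.InfeasibleFoldsError):
            mvpa.build_folds(onsets, n_folds=4, min_gap_s=30.0, seed=0, labels=blocked)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_gap_audit_clean_on_seeded_experiment_schedules(self, exp3, seed):
        sched = design.build_schedule(exp3, seed)
        onsets = np.array([t.onset_s + 1000.0 * t.block for t in sched])
        plan = mvpa.build_folds(onsets, n_folds=10, min_gap_s=30.0, seed=seed)
        assert mvpa.audit_fold_gaps(plan) == []
        assert brute_force_gap_violations(plan) == []


class TestSphereOffsets:
    @pytest.mark.parametrize("radius,count", [(0, 1), (3, 123), (4.2, 305)])
    def test_lattice_counts_match_brute_force(self, radius, count):
        offs = mvpa.sphere_offsets(radius)
        assert len(offs) == count
        # independent enumeration
        r = int(np.floor(radius))
        brute = sum(
            1
            for x in range(-r, r + 1)
            for y in range(-r, r + 1)
            for z in range(-r, r + 1)
            if x * x + y * y + z * z <= radius * radius
        )
        assert len(offs) == brute

    def test_default_radius_near_300_voxels(self):
        spec = mvpa.SearchlightSpec()
        n = len(mvpa.sphere_offsets(spec.radius_voxels))
        assert abs(n - spec.target_sphere_size) / spec.target_sphere_size <= 0.10


class TestClassifier:
    def test_deterministic_and_separates_separable_data(self, rng):
        X = _noise_features(rng, 40, 10)
        y = _alternating(40)
        X[y == "A", 0] += 5.0
        m1 = LinearMaxMargin().fit(X, y)
        m2 = LinearMaxMargin().fit(X, y)
        assert np.array_equal(m1.coef_, m2.coef_)
        assert m1.score(X, y) == 1.0

    def test_agreement_with_reference_svm(self, rng):
        SVC = pytest.importorskip("sklearn.svm").SVC
        agree = []
        for rep in range(10):
            X = _noise_features(rng, 60, 30)
            y = _alternating(60)
            X[y == "A", :5] += 0.8
            Xt = _noise_features(rng, 40, 30)
            yt = _alternating(40)
            Xt[yt == "A", :5] += 0.8
            ref = SVC(kernel="linear", C=1.0).fit(X, y)
            ours = LinearMaxMargin().fit(X, y)
            agree.append(np.mean(ours.predict(Xt) == ref.predict(Xt)))
        assert np.mean(agree) > 0.9


class TestSearchlight:
    def test_shuffled_labels_give_chance_map(self, small_grid, rng):
        n = 60
        data = rng.normal(size=(n, *small_grid.shape))
        y = _alternating(n)
        folds = _simple_folds(n, 6)
        search = np.zeros(small_grid.shape, dtype=bool)
        centers = np.argwhere(small_grid.visuospatial_mask)[::12]
        search[tuple(centers.T)] = True
        amap = mvpa.run_searchlight(
            data, y, folds, small_grid.brain_mask, search,
            mvpa.SearchlightSpec(radius_voxels=2.0),
        )
        mean_acc = np.nanmean(amap)
        assert abs(mean_acc - 0.5) < 0.05

    def test_signal_patch_localized(self, small_grid, rng):
        n = 60
        data = rng.normal(size=(n, *small_grid.shape))
        y = _alternating(n)
        patch = np.argwhere(small_grid.visuospatial_mask)[0]
        px, py, pz = patch
        data[y == "A", px, py, pz] += 4.0  # strong separable signal in one voxel
        folds = _simple_folds(n, 6)
        search = np.zeros(small_grid.shape, dtype=bool)
        search[px, py, pz] = True
        far = np.argwhere(small_grid.brain_mask)[-1]
        search[tuple(far)] = True
        amap = mvpa.run_searchlight(
            data, y, folds, small_grid.brain_mask, search,
            mvpa.SearchlightSpec(radius_voxels=1.0, accuracy_smooth_fwhm_mm=0.0),
        )
        assert amap[px, py, pz] > 0.9
        assert abs(amap[tuple(far)] - 0.5) < 0.25

    def test_unbalanced_input_rejected(self, small_grid, rng):
        data = rng.normal(size=(30, *small_grid.shape))
        y = np.array(["A"] * 20 + ["B"] * 10)
        folds = _simple_folds(30, 3)
        with pytest.raises(ValueError, match="balance"):
            mvpa.run_searchlight(
                data, y, folds, small_grid.brain_mask, small_grid.visuospatial_mask
            )

    def test_contradictory_duplicates_force_chance(self, small_grid, rng):
        # every trial duplicated with the opposite label: no classifier can
        # beat chance, however strong the underlying pattern
        n = 30
        base = rng.normal(size=(n, *small_grid.shape))
        y = _alternating(n)
        base[y == "A"] += 2.0
        data = np.repeat(base, 2, axis=0)  # interleave originals and copies
        y2 = np.empty(2 * n, dtype=y.dtype)
        y2[0::2] = y
        y2[1::2] = np.where(y == "A", "B", "A")
        folds = _simple_folds(2 * n, 6)
        center = np.argwhere(small_grid.visuospatial_mask)[0]
        search = np.zeros(small_grid.shape, dtype=bool)
        search[tuple(center)] = True
        amap = mvpa.run_searchlight(
            data, y2, folds, small_grid.brain_mask, search,
            mvpa.SearchlightSpec(radius_voxels=2.0, accuracy_smooth_fwhm_mm=0.0),
        )
        assert abs(np.nanmean(amap) - 0.5) <= 0.1


class TestSelectROI:
    def test_under_cap_takes_all_above_chance(self, small_grid, rng):
        amap = np.full(small_grid.shape, 0.4)
        idx = np.argwhere(small_grid.gray_mask)[:100]
        amap[tuple(idx.T)] = 0.8
        roi = mvpa.select_roi(amap, small_grid.gray_mask, max_voxels=5000)
        assert roi.n_voxels == 100

    def test_rank_order_respected_at_cap(self, small_grid, rng):
        amap = np.full(small_grid.shape, np.nan)
        gray = np.argwhere(small_grid.gray_mask)
        vals = np.linspace(0.51, 0.99, len(gray))
        rng.shuffle(vals)
        amap[tuple(gray.T)] = vals
        roi = mvpa.select_roi(amap, small_grid.gray_mask, max_voxels=200)
        assert roi.n_voxels == 200
        selected = amap[roi.mask]
        rejected = amap[small_grid.gray_mask & ~roi.mask]
        assert selected.min() >= rejected.max()

    def test_chance_map_yields_empty_roi_error(self, small_grid):
        amap = np.full(small_grid.shape, 0.5)
        with pytest.raises(mvpa.EmptyROIError):
            mvpa.select_roi(amap, small_grid.gray_mask)

    def test_tie_break_is_seeded_and_counted(self, small_grid):
        amap = np.full(small_grid.shape, np.nan)
        gray = np.argwhere(small_grid.gray_mask)
        amap[tuple(gray.T)] = 0.7  # all tied above chance
        roi1 = mvpa.select_roi(amap, small_grid.gray_mask, max_voxels=50, seed=1)
        roi2 = mvpa.select_roi(amap, small_grid.gray_mask, max_voxels=50, seed=1)
        roi3 = mvpa.select_roi(amap, small_grid.gray_mask, max_voxels=50, seed=2)
        assert np.array_equal(roi1.mask, roi2.mask)
        assert not np.array_equal(roi1.mask, roi3.mask)
        assert roi1.n_tied_at_cutoff == len(gray)


class TestBalancedDecoding:
    def test_balanced_input_gives_identical_iterations(self, rng):
        X = _noise_features(rng, 40, 12)
        y = _alternating(40)
        folds = _simple_folds(40, 4)
        res = mvpa.decode_roi_balanced(X, y, folds, n_iter=50, seed=0)
        assert np.unique(res.iteration_accuracies).size == 1
        assert res.accuracy == res.iteration_accuracies[0]

    def test_label_independent_data_decodes_at_chance(self, rng):
        accs = []
        for seed in range(10):
            r = np.random.default_rng(seed)
            X = _noise_features(r, 80, 30)
            y = _alternating(80)
            folds = _simple_folds(80, 8)
            accs.append(mvpa.decode_roi_balanced(X, y, folds, n_iter=5, seed=seed).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.04

    def test_unbalanced_classes_are_downsampled_every_iteration(self, rng):
        X = _noise_features(rng, 60, 10)
        y = np.array(["A", "A", "B"] * 20)  # 40 vs 20, interleaved in time
        folds = mvpa.build_folds(np.arange(60) * 40.0, n_folds=4, labels=y, seed=0)
        res = mvpa.decode_roi_balanced(X, y, folds, n_iter=20, seed=0)
        for audit in res.balance_audits:
            assert audit["A"] == audit["B"]

    def test_nested_factor_balancing_audited(self, rng):
        # decoding y while balancing a nested factor across classes:
        # every iteration's class x factor cross-tab must be balanced
        n = 80
        X = _noise_features(rng, n, 10)
        y = np.array(["L", "R"] * (n // 2))
        factor = rng.choice(["with", "without"], p=[0.7, 0.3], size=n)
        # ensure every label x factor cell occurs
        assert all(
            np.any((y == c) & (factor == f)) for c in ("L", "R") for f in ("with", "without")
        )
        folds = _simple_folds(n, 4)
        res = mvpa.decode_roi_balanced(
            X, y, folds, n_iter=20, seed=0, balance_by=factor
        )
        for audit in res.balance_audits:
            for level in ("with", "without"):
                assert audit[("L", level)] == audit[("R", level)]

    def test_single_class_rejected(self, rng):
        X = _noise_features(rng, 20, 5)
        y = np.array(["A"] * 20)
        folds = _simple_folds(20, 2)
        with pytest.raises(ValueError):
            mvpa.decode_roi_balanced(X, y, folds)

    def test_accuracy_nondecreasing_in_amplitude(self, small_grid):
        # planted-effect monotonicity over a 5-point amplitude grid
        accs = []
        for amp in [0.0, 0.05, 0.1, 0.2, 0.4]:
            r = np.random.default_rng(7)
            n = 60
            y = _alternating(n, "left", "right")
            lp = sf._hemisphere_patch(small_grid, "left").ravel() > 0
            X = r.normal(size=(n, int(lp.sum())))
            X[y == "left"] += amp
            folds = _simple_folds(n, 6)
            accs.append(mvpa.decode_roi_balanced(X, y, folds, n_iter=5, seed=0).accuracy)
        assert all(b >= a - 0.02 for a, b in zip(accs, accs[1:]))
        assert accs[-1] > accs[0]


class TestGroupPermutation:
    def _subjects(self, rng, n_sub=4, n=24, d=8, shift=0.0):
        subs = []
        for s in range(n_sub):
            X = rng.normal(size=(n, d))
            y = _alternating(n)
            X[y == "A"] += shift
            folds = _simple_folds(n, 3)
            subs.append(mvpa.SubjectDecodeData(X=X, labels=y, folds=folds))
        return subs

    def test_add_one_convention_when_observed_beats_every_permutation(self, rng):
        subs = self._subjects(rng, shift=3.0)
        res = mvpa.group_permutation_test(subs, n_perm=50, seed=0)
        assert res.p_value == pytest.approx(1.0 / 51.0)
        assert res.observed_group_accuracy > 0.9

    def test_null_distribution_centers_on_chance(self, rng):
        subs = self._subjects(rng, n_sub=4, n=32)
        res = mvpa.group_permutation_test(subs, n_perm=100, seed=1)
        assert abs(res.null_distribution.mean() - 0.5) < 0.05
        assert res.null_distribution.shape == (100,)

    def test_invalid_arguments_rejected(self, rng):
        subs = self._subjects(rng)
        with pytest.raises(ValueError):
            mvpa.group_permutation_test(subs, n_perm=0)
        with pytest.raises(ValueError):
            mvpa.group_permutation_test(subs[:1], n_perm=10)

    def test_permutation_shuffles_within_folds(self, rng):
        labels = np.array(["A", "B"] * 10)
        fold_of = np.repeat([0, 1], 10)
        perms = mvpa.permute_labels_within_folds(labels, fold_of, rng, 50)
        for p in perms:
            for f in (0, 1):
                orig = np.sort(labels[fold_of == f])
                assert np.array_equal(np.sort(p[fold_of == f]), orig)


class TestControls:
    def test_zero_contamination_is_indistinguishable(self, rng):
        accs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            absent = r.normal(size=(40, 20))
            conscious = r.normal(loc=1.0, size=(30, 20))
            accs.append(
                mvpa.contamination_control(
                    absent, np.arange(40) * 40.0, conscious, 2000 + np.arange(30) * 40.0,
                    contamination_rate=0.0, n_folds=4, n_iter=10, seed=seed,
                ).accuracy
            )
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_heavy_contamination_with_strong_signal_detected(self):
        accs = []
        for seed in range(4):
            r = np.random.default_rng(seed)
            absent = r.normal(size=(40, 20))
            conscious = r.normal(loc=2.0, size=(40, 20))
            accs.append(
                mvpa.contamination_control(
                    absent, np.arange(40) * 80.0, conscious, np.arange(40) * 80.0 + 40.0,
                    contamination_rate=0.5, n_folds=4, n_iter=10, seed=seed,
                ).accuracy
            )
        assert np.mean(accs) > 0.55

    def test_bin_sizes_differ_by_at_most_one(self, rng):
        for n_abs in (40, 41):
            absent = rng.normal(size=(n_abs, 10))
            conscious = rng.normal(size=(20, 10))
            res = mvpa.contamination_control(
                absent, np.arange(n_abs) * 40.0, conscious, 5000 + np.arange(20) * 40.0,
                contamination_rate=0.0, n_folds=4, n_iter=5, seed=0,
            )
            # with zero contamination the decode set is exactly the split
            assert res.n_trials_used in (n_abs, n_abs - 1)

    def test_invalid_contamination_rate(self, rng):
        with pytest.raises(ValueError):
            mvpa.contamination_control(
                rng.normal(size=(40, 5)), np.arange(40.0), rng.normal(size=(5, 5)),
                np.arange(5.0), contamination_rate=1.0,
            )

    def test_nuisance_factor_without_signal_decodes_at_chance(self, rng):
        accs = []
        for seed in range(6):
            r = np.random.default_rng(seed)
            n = 64
            X = r.normal(size=(n, 16))
            y = _alternating(n)
            factor = np.array(["left", "right"] * (n // 2))
            folds = _simple_folds(n, 4)
            accs.append(
                mvpa.relabel_control(
                    X, y, factor, folds, n_iter=5, seed=seed, mode="decode_factor"
                ).accuracy
            )
        assert abs(np.mean(accs) - 0.5) < 0.06

    def test_counterbalancing_removes_confound_driven_accuracy(self):
        # signal carried only by the nuisance factor, which is skewed across
        # classes: the naive decode succeeds, the counterbalanced one cannot
        naive_accs, bal_accs = [], []
        for seed in range(3):
            r = np.random.default_rng(seed)
            n = 160
            y = np.array(["A"] * (n // 2) + ["B"] * (n // 2))
            factor = np.concatenate(
                [
                    np.array(["left"] * 60 + ["right"] * 20),  # A: 75% left
                    np.array(["left"] * 20 + ["right"] * 60),  # B: 25% left
                ]
            )
            X = r.normal(size=(n, 20))
            X[factor == "left", :8] += 1.5  # only the factor drives the pattern
            perm = r.permutation(n)
            X, y, factor = X[perm], y[perm], factor[perm]
            folds = _simple_folds(n, 4)
            naive_accs.append(mvpa.decode_roi_balanced(X, y, folds, n_iter=10, seed=0).accuracy)
            balanced = mvpa.relabel_control(X, y, factor, folds, n_iter=20, seed=0)
            bal_accs.append(balanced.accuracy)
            for audit in balanced.balance_audits:
                assert len(set(audit.values())) == 1  # exactly uniform cross-tab
        assert np.mean(naive_accs) > 0.6
        assert abs(np.mean(bal_accs) - 0.5) < 0.06

    def test_roi_selection_orthogonal_to_decoded_contrast(self, small_grid):
        # double-dipping guard: selecting an ROI on one contrast must not
        # inflate accuracy for an independent contrast on null data
        r = np.random.default_rng(3)
        accs = []
        for rep in range(5):
            n = 60
            data = r.normal(size=(n, *small_grid.shape))
            y_select = _alternating(n, "stim", "absent")
            data[y_select == "stim"] += 0.3  # ROI-defining signal only
            y_decode = _alternating(n, "left", "right")[r.permutation(n)]
            folds = _simple_folds(n, 6)
            search = np.zeros(small_grid.shape, dtype=bool)
            centers = np.argwhere(small_grid.visuospatial_mask)[::15]
            search[tuple(centers.T)] = True
            amap = mvpa.run_searchlight(
                data, y_select, folds, small_grid.brain_mask, search,
                mvpa.SearchlightSpec(radius_voxels=2.0),
            )
            roi = mvpa.select_roi(amap, small_grid.gray_mask, max_voxels=100, seed=rep)
            X = mvpa.mask_features(data, roi.mask)
            accs.append(mvpa.decode_roi_balanced(X, y_decode, folds, n_iter=5, seed=rep).accuracy)
        assert abs(np.mean(accs) - 0.5) < 0.05
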