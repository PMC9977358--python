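"""Multivoxel decoding: gapped cross-validation, searchlight, ROI inference.

The decoding procedure mirrors the event-related working-memory analysis it
was built for:

1. trials are chunked in time into cross-validation folds such that any two
   temporally adjacent trials in *different* folds are at least 30 s apart
   (so slow hemodynamic carry-over cannot leak between training and test);
2. a sphere searchlight (~300 voxels at radius 4.2) maps where a contrast of
   interest is decodable, the accuracy map is smoothed (8 mm FWHM) and the
   up-to-5,000 best gray-matter voxels above chance define a subject ROI;
3. ROI decoding balances class counts by repeated random down-sampling
   (50 iterations, mean accuracy reported), optionally balancing a nested
   nuisance factor's counts across classes;
4. group inference compares the across-subject mean accuracy against an
   empirical null built by re-running the decoder under within-fold label
   shuffling (one-tailed, add-one p);
5. control analyses: clean-vs-contaminated absent bins, decoding a nuisance
   factor directly, and counterbalanced relabeling.

All stochastic steps draw from named substreams of a caller-provided seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classifier import cv_accuracy, cv_accuracy_batch
from .synthetic_fmri import BetaImage, smooth_volume


class InfeasibleFoldsError(RuntimeError):
    """Fold construction cannot satisfy its contract; message names why."""


class EmptyROIError(RuntimeError):
    """No voxel exceeded chance level during ROI selection."""


# ---------------------------------------------------------------------------
# fold construction
# ---------------------------------------------------------------------------

@dataclass
class FoldPlan:
    """Assignment of trials to temporally-gapped cross-validation folds."""

    n_folds: int
    fold_of: np.ndarray  # per trial; -1 means dropped at a fold boundary
    onsets: np.ndarray
    min_gap_s: float

    @property
    def retained(self) -> np.ndarray:
        return np.flatnonzero(self.fold_of >= 0)

    @property
    def n_dropped(self) -> int:
        return int(np.sum(self.fold_of < 0))


def _chunk_sizes(n: int, n_folds: int, rng: np.random.Generator | None) -> np.ndarray:
    base = np.full(n_folds, n // n_folds)
    base[: n % n_folds] += 1
    if rng is not None:  # jitter: move a few trials between adjacent folds
        for _ in range(n_folds):
            i, j = rng.integers(0, n_folds, size=2)
            if base[i] > 2:
                base[i] -= 1
                base[j] += 1
    return base


def _drop_boundary_trials(
    order: np.ndarray, onsets: np.ndarray, bounds: np.ndarray, min_gap_s: float
) -> np.ndarray:
    """Fold labels in temporal order, with boundary-adjacent trials dropped.

    Greedily removes, at each fold boundary, whichever neighboring trial
    sits in the currently larger fold until the closest retained cross-fold
    pair is at least ``min_gap_s`` apart.
    """
    n = order.size
    fold_idx = np.empty(n, dtype=int)
    start = 0
    for k, size in enumerate(bounds):
        fold_idx[start : start + size] = k
        start += size
    keep = np.ones(n, dtype=bool)
    for k in range(len(bounds) - 1):
        while True:
            left = np.flatnonzero(keep & (fold_idx == k))
            right = np.flatnonzero(keep & (fold_idx == k + 1))
            if left.size == 0 or right.size == 0:
                break
            i, j = left[-1], right[0]
            gap = onsets[order[j]] - onsets[order[i]]
            if gap >= min_gap_s:
                break
            if left.size >= right.size:
                keep[i] = False
            else:
                keep[j] = False
    labels = np.where(keep, fold_idx, -1)
    return labels


def build_folds(
    onsets,
    n_folds: int = 10,
    min_gap_s: float = 30.0,
    seed: int = 0,
    labels=None,
    max_retries: int = 40,
) -> FoldPlan:
    """Contiguous-in-time chunking into folds with a temporal guard band.

    Trials are sorted by onset and cut into ``n_folds`` contiguous chunks;
    trials too close to a chunk boundary are dropped until every temporally
    adjacent cross-fold pair is at least ``min_gap_s`` apart.  If ``labels``
    is given, chunk boundaries are re-jittered (seeded) until every fold
    retains both classes, up to ``max_retries``.
    """
    onsets = np.asarray(onsets, dtype=float)
    n = onsets.size
    if n < n_folds:
        raise InfeasibleFoldsError(
            f"{n} trials cannot fill {n_folds} folds (need at least one per fold)"
        )
    order = np.argsort(onsets, kind="stable")
    rng = np.random.default_rng(seed)
    labels = None if labels is None else np.asarray(labels)
    jitter = None
    for attempt in range(max_retries):
        sizes = _chunk_sizes(n, n_folds, jitter)
        fold_in_order = _drop_boundary_trials(order, onsets, sizes, min_gap_s)
        fold_of = np.full(n, -1, dtype=int)
        fold_of[order] = fold_in_order
        counts = np.bincount(fold_of[fold_of >= 0], minlength=n_folds)
        ok = (counts > 0).all()
        if ok and labels is not None:
            for k in range(n_folds):
                in_fold = labels[fold_of == k]
                if np.unique(in_fold).size < 2:
                    ok = False
                    break
        if ok:
            return FoldPlan(
                n_folds=n_folds, fold_of=fold_of, onsets=onsets, min_gap_s=min_gap_s
            )
        jitter = rng  # retry with jittered chunk boundaries
    reason = "an empty fold" if labels is None else "a single-class or empty fold"
    raise InfeasibleFoldsError(
        f"could not build {n_folds} folds without {reason} after "
        f"{max_retries} attempts ({n} trials, min_gap_s={min_gap_s})"
    )


def audit_fold_gaps(plan: FoldPlan) -> list[tuple[int, int, float]]:
    """Violations of the temporal-gap contract (empty list when clean).

    Checks every temporally adjacent retained pair in different folds.
    """
    idx = plan.retained
    order = idx[np.argsort(plan.onsets[idx], kind="stable")]
    violations = []
    for a, b in zip(order[:-1], order[1:]):
        if plan.fold_of[a] != plan.fold_of[b]:
            gap = float(plan.onsets[b] - plan.onsets[a])
            if gap < plan.min_gap_s:
                violations.append((int(a), int(b), gap))
    return violations


# ---------------------------------------------------------------------------
# searchlight
# ---------------------------------------------------------------------------

def sphere_offsets(radius_voxels: float) -> np.ndarray:
    """All integer voxel offsets within Euclidean distance ``radius_voxels``."""
    if radius_voxels < 0:
        raise ValueError("radius must be nonnegative")
    r = int(np.floor(radius_voxels))
    axis = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(axis, axis, axis, indexing="ij")
    inside = dx**2 + dy**2 + dz**2 <= radius_voxels**2
    return np.stack([dx[inside], dy[inside], dz[inside]], axis=1)


@dataclass(frozen=True)
class SearchlightSpec:
    radius_voxels: float = 4.2  # ~300-voxel spheres
    target_sphere_size: int = 300
    accuracy_smooth_fwhm_mm: float = 8.0


def _require_balanced(labels: np.ndarray) -> None:
    vals, counts = np.unique(labels, return_counts=True)
    if vals.size != 2:
        raise ValueError(f"labels must be binary, got {vals.size} classes")
    if counts[0] != counts[1]:
        raise ValueError(
            "searchlight input must be class-balanced "
            f"(got {dict(zip(vals.tolist(), counts.tolist()))}); balance explicitly first"
        )


def stack_images(
    images: list[BetaImage], phase: str | None = None, where: dict | None = None
) -> tuple[np.ndarray, pd.DataFrame]:
    """Stack beta images (optionally filtered) into (n, x, y, z) + labels."""
    selected = []
    for img in images:
        if phase is not None and img.phase != phase:
            continue
        if where and any(img.labels.get(k) != v for k, v in where.items()):
            continue
        selected.append(img)
    if not selected:
        raise ValueError("no beta images match the requested phase/labels")
    data = np.stack([img.values for img in selected])
    labels = pd.DataFrame([img.labels for img in selected]).reset_index(drop=True)
    return data, labels


def mask_features(data: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(n, x, y, z) volumes -> (n, n_mask_voxels) feature matrix."""
    n = data.shape[0]
    return data.reshape(n, -1)[:, np.asarray(mask, dtype=bool).ravel()]


def run_searchlight(
    data: np.ndarray,
    labels,
    folds: FoldPlan,
    brain_mask: np.ndarray,
    search_mask: np.ndarray,
    spec: SearchlightSpec = SearchlightSpec(),
    voxel_size_mm: float = 2.0,
) -> np.ndarray:
    """Accuracy map of a sphere-searchlight decode over ``search_mask``.

    ``data`` is (n_trials, x, y, z).  For each center voxel, features are the
    sphere voxels intersected with the brain mask; accuracy is the pooled
    cross-validated fraction correct under ``folds``.  The map is smoothed
    with ``accuracy_smooth_fwhm_mm`` (renormalized within the search mask)
    and is NaN outside it.  Inputs must be class-balanced.
    """
    labels = np.asarray(labels)
    _require_balanced(labels)  # balance is on the supplied trial set;
    # boundary dropping may leave slightly uneven retained counts
    shape = data.shape[1:]
    flat = data.reshape(data.shape[0], -1)
    brain_flat = np.asarray(brain_mask, dtype=bool).ravel()
    offsets = sphere_offsets(spec.radius_voxels)
    centers = np.argwhere(search_mask)
    acc_map = np.full(shape, np.nan)
    for cx, cy, cz in centers:
        coords = offsets + np.array([cx, cy, cz])
        ok = (
            (coords >= 0).all(axis=1)
            & (coords[:, 0] < shape[0])
            & (coords[:, 1] < shape[1])
            & (coords[:, 2] < shape[2])
        )
        coords = coords[ok]
        lin = np.ravel_multi_index(coords.T, shape)
        lin = lin[brain_flat[lin]]
        X = flat[:, lin]
        acc_map[cx, cy, cz] = cv_accuracy(X, labels, folds.fold_of)
    if spec.accuracy_smooth_fwhm_mm > 0:
        defined = np.isfinite(acc_map)
        num = smooth_volume(
            np.where(defined, acc_map, 0.0), spec.accuracy_smooth_fwhm_mm, voxel_size_mm
        )
        den = smooth_volume(
            defined.astype(float), spec.accuracy_smooth_fwhm_mm, voxel_size_mm
        )
        with np.errstate(invalid="ignore"):
            acc_map = np.where(defined, num / den, np.nan)
    return acc_map


# ---------------------------------------------------------------------------
# ROI selection
# ---------------------------------------------------------------------------

@dataclass
class ROISpec:
    mask: np.ndarray
    source_contrast: str = ""
    max_voxels: int = 5000
    n_tied_at_cutoff: int = 0

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def select_roi(
    accuracy_map: np.ndarray,
    gray_mask: np.ndarray,
    max_voxels: int = 5000,
    chance: float = 0.5,
    seed: int = 0,
    source_contrast: str = "",
) -> ROISpec:
    """Top gray-matter voxels of a (smoothed) accuracy map, above chance.

    Voxels with accuracy strictly above ``chance`` are ranked descending and
    truncated at ``max_voxels``; ties at the cutoff are resolved by a seeded
    draw and their count recorded.
    """
    gray = np.asarray(gray_mask, dtype=bool)
    candidate = gray & np.isfinite(accuracy_map) & (accuracy_map > chance)
    idx = np.flatnonzero(candidate.ravel())
    if idx.size == 0:
        raise EmptyROIError(
            "no gray-matter voxel exceeds chance; consider an orthogonal ROI"
        )
    mask = np.zeros(accuracy_map.shape, dtype=bool)
    n_tied = 0
    if idx.size <= max_voxels:
        mask.ravel()[idx] = True
    else:
        vals = accuracy_map.ravel()[idx]
        order = np.argsort(-vals, kind="stable")
        cutoff = vals[order[max_voxels - 1]]
        above = idx[vals > cutoff]
        tied = idx[vals == cutoff]
        n_needed = max_voxels - above.size
        n_tied = tied.size
        rng = np.random.default_rng(seed)
        chosen_ties = rng.choice(tied, size=n_needed, replace=False)
        mask.ravel()[above] = True
        mask.ravel()[chosen_ties] = True
    return ROISpec(
        mask=mask,
        source_contrast=source_contrast,
        max_voxels=max_voxels,
        n_tied_at_cutoff=n_tied,
    )


# ---------------------------------------------------------------------------
# balanced ROI decoding
# ---------------------------------------------------------------------------

@dataclass
class DecodingResult:
    accuracy: float
    iteration_accuracies: np.ndarray
    n_iterations: int
    n_trials_used: int
    contrast_name: str = ""
    chance: float = 0.5
    balance_audits: list[dict] = field(default_factory=list)


def _crosstab(labels: np.ndarray, factor: np.ndarray | None) -> dict:
    if factor is None:
        vals, counts = np.unique(labels, return_counts=True)
        return {str(v): int(c) for v, c in zip(vals, counts)}
    tab: dict = {}
    for lv, fv in zip(labels, factor):
        tab[(str(lv), str(fv))] = tab.get((str(lv), str(fv)), 0) + 1
    return tab


def _balanced_subsample(
    rng: np.random.Generator,
    candidates: np.ndarray,
    labels: np.ndarray,
    factor: np.ndarray | None,
    uniform_cells: bool,
) -> np.ndarray:
    """Indices (subset of ``candidates``) with balanced classes.

    Without a factor, the larger class is down-sampled to the smaller.
    With a factor, each factor level's count is equalized across classes
    (per-level minimum); with ``uniform_cells`` every label x factor cell is
    down-sampled to the global minimum cell count (exactly uniform cross-tab).
    """
    lab = labels[candidates]
    classes = np.unique(lab)
    if classes.size != 2:
        raise ValueError("need exactly two classes to balance")
    if factor is None:
        take = []
        n_min = min(int(np.sum(lab == c)) for c in classes)
        for c in classes:
            pool = candidates[lab == c]
            take.append(rng.choice(pool, size=n_min, replace=False))
        return np.sort(np.concatenate(take))
    fac = factor[candidates]
    levels = np.unique(fac)
    cell_counts = {
        (c, lv): int(np.sum((lab == c) & (fac == lv))) for c in classes for lv in levels
    }
    if uniform_cells:
        m = min(cell_counts.values())
        if m == 0:
            raise InfeasibleFoldsError(
                "factor cannot be counterbalanced: an empty label x factor cell"
            )
        targets = {key: m for key in cell_counts}
    else:
        targets = {}
        for lv in levels:
            m = min(cell_counts[(c, lv)] for c in classes)
            for c in classes:
                targets[(c, lv)] = m
    take = []
    for (c, lv), m in targets.items():
        if m == 0:
            continue
        pool = candidates[(lab == c) & (fac == lv)]
        take.append(rng.choice(pool, size=m, replace=False))
    if not take:
        raise InfeasibleFoldsError("balancing removed every trial")
    return np.sort(np.concatenate(take))


def decode_roi_balanced(
    X: np.ndarray,
    labels,
    folds: FoldPlan,
    n_iter: int = 50,
    seed: int = 0,
    balance_by=None,
    uniform_cells: bool = False,
    contrast_name: str = "",
) -> DecodingResult:
    """Balanced-resampling ROI decode: mean accuracy over ``n_iter`` draws.

    Each iteration randomly down-samples to exactly balanced classes (and,
    when ``balance_by`` is given, equalizes that factor's counts across
    classes), then scores a fold-wise linear decode on the ROI features.
    Already-balanced input with no factor skips resampling entirely, so all
    iterations are identical (the classifier is deterministic).  Every
    iteration's label/factor cross-tab is recorded for auditing.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must be (n_trials, n_voxels) with a nonempty ROI")
    labels = np.asarray(labels)
    factor = None if balance_by is None else np.asarray(balance_by)
    retained = folds.retained
    lab_ret = labels[retained]
    classes, counts = np.unique(lab_ret, return_counts=True)
    if classes.size != 2 or counts.min() < 2:
        raise ValueError("need two classes with at least two retained trials each")
    rng = np.random.default_rng(seed)
    already_balanced = counts[0] == counts[1] and factor is None
    if already_balanced:
        acc = cv_accuracy(X, labels, folds.fold_of)
        iters = np.full(n_iter, acc)
        audits = [_crosstab(lab_ret, None)]
        n_used = retained.size
    else:
        audits = []
        n_used = 0
        include = np.zeros((n_iter, labels.shape[0]), dtype=bool)
        for i in range(n_iter):
            sub = _balanced_subsample(rng, retained, labels, factor, uniform_cells)
            include[i, sub] = True
            audits.append(
                _crosstab(labels[sub], None if factor is None else factor[sub])
            )
            n_used = sub.size
        Y = np.tile(labels, (n_iter, 1))
        iters = cv_accuracy_batch(X, Y, folds.fold_of, include=include)
    return DecodingResult(
        accuracy=float(iters.mean()),
        iteration_accuracies=iters,
        n_iterations=n_iter,
        n_trials_used=int(n_used),
        contrast_name=contrast_name,
        balance_audits=audits,
    )


# ---------------------------------------------------------------------------
# group permutation inference
# ---------------------------------------------------------------------------

@dataclass
class SubjectDecodeData:
    """One subject's ROI features, labels, and fold plan."""

    X: np.ndarray
    labels: np.ndarray
    folds: FoldPlan


@dataclass
class GroupPermutationResult:
    observed_group_accuracy: float
    null_distribution: np.ndarray
    p_value: float
    n_perm: int
    per_subject_observed: np.ndarray


def permute_labels_within_folds(
    labels: np.ndarray, fold_of: np.ndarray, rng: np.random.Generator, n_perm: int
) -> np.ndarray:
    """(n_perm, n) label matrix, independently shuffled within each fold."""
    n = labels.shape[0]
    out = np.tile(labels, (n_perm, 1))
    for f in np.unique(fold_of[fold_of >= 0]):
        idx = np.flatnonzero(fold_of == f)
        block = out[:, idx]
        perm = np.argsort(rng.random((n_perm, idx.size)), axis=1)
        out[:, idx] = np.take_along_axis(block, perm, axis=1)
    return out


def group_permutation_test(
    subjects: list[SubjectDecodeData],
    n_perm: int = 10000,
    seed: int = 0,
    n_iter_balance: int = 50,
) -> GroupPermutationResult:
    """Two-step permutation test of group-mean decoding accuracy.

    Step 1 estimates each subject's accuracy under ``n_perm`` within-fold
    label shufflings, with the classifier literally refit per shuffle
    (batched).  Step 2 compares the observed across-subject mean against the
    across-subject means of the shuffled accuracies (one-tailed), with the
    add-one convention p = (1 + #{null >= observed}) / (1 + n_perm).

    Subjects with unbalanced classes are reduced once, by a seeded balanced
    subsample, before both the observed and the permuted decodes; the
    observed accuracy for such subjects is the usual ``n_iter_balance``-draw
    mean on the full data.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be at least 1")
    if len(subjects) < 2:
        raise ValueError("need at least two subjects")
    rng = np.random.default_rng(seed)
    observed = np.empty(len(subjects))
    null = np.zeros((len(subjects), n_perm))
    for s, subj in enumerate(subjects):
        sub_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
        labels = np.asarray(subj.labels)
        retained = subj.folds.retained
        _, counts = np.unique(labels[retained], return_counts=True)
        if counts[0] == counts[1]:
            fold_of = subj.folds.fold_of
            observed[s] = cv_accuracy(subj.X, labels, fold_of)
        else:
            observed[s] = decode_roi_balanced(
                subj.X,
                labels,
                subj.folds,
                n_iter=n_iter_balance,
                seed=int(sub_rng.integers(0, 2**31 - 1)),
            ).accuracy
            sub = _balanced_subsample(sub_rng, retained, labels, None, False)
            fold_of = np.full(labels.shape[0], -1, dtype=int)
            fold_of[sub] = subj.folds.fold_of[sub]
        Y = permute_labels_within_folds(labels, fold_of, sub_rng, n_perm)
        null[s] = cv_accuracy_batch(subj.X, Y, fold_of)
    group_null = null.mean(axis=0)
    obs = float(observed.mean())
    p = (1.0 + int(np.sum(group_null >= obs - 1e-12))) / (1.0 + n_perm)
    return GroupPermutationResult(
        observed_group_accuracy=obs,
        null_distribution=group_null,
        p_value=float(p),
        n_perm=n_perm,
        per_subject_observed=observed,
    )


# ---------------------------------------------------------------------------
# control analyses
# ---------------------------------------------------------------------------

def contamination_control(
    absent_X: np.ndarray,
    absent_onsets,
    conscious_X: np.ndarray,
    conscious_onsets,
    contamination_rate: float = 0.063,
    n_folds: int = 10,
    min_gap_s: float = 30.0,
    n_iter: int = 50,
    seed: int = 0,
) -> DecodingResult:
    """Decode a clean vs a deliberately contaminated half of the absent trials.

    The absent trials are split into two bins whose sizes differ by at most
    one; one bin is spiked with conscious trials so that they make up
    ``contamination_rate`` of it (the estimated rate of erroneous visibility
    ratings).  If the spiked bin is genuinely distinguishable, mislabeled
    conscious trials could masquerade as nonconscious signal; chance-level
    accuracy rules that out.
    """
    if not 0.0 <= contamination_rate < 1.0:
        raise ValueError("contamination_rate must be in [0, 1)")
    absent_X = np.asarray(absent_X, dtype=float)
    conscious_X = np.asarray(conscious_X, dtype=float)
    n_abs = absent_X.shape[0]
    if n_abs < 2 * n_folds:
        raise InfeasibleFoldsError("too few absent trials to split into folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_abs)
    half = n_abs // 2
    clean_idx, contam_idx = order[:half], order[half:]
    n_bin = contam_idx.size
    n_add = int(round(contamination_rate * n_bin / (1.0 - contamination_rate)))
    n_add = min(n_add, conscious_X.shape[0])
    add_idx = rng.choice(conscious_X.shape[0], size=n_add, replace=False)
    X = np.vstack([absent_X[clean_idx], absent_X[contam_idx], conscious_X[add_idx]])
    onsets = np.concatenate(
        [
            np.asarray(absent_onsets, dtype=float)[clean_idx],
            np.asarray(absent_onsets, dtype=float)[contam_idx],
            np.asarray(conscious_onsets, dtype=float)[add_idx],
        ]
    )
    labels = np.array(
        ["clean"] * clean_idx.size + ["contaminated"] * (n_bin + n_add)
    )
    folds = build_folds(
        onsets,
        n_folds=n_folds,
        min_gap_s=min_gap_s,
        seed=int(rng.integers(0, 2**31 - 1)),
        labels=labels,
    )
    return decode_roi_balanced(
        X,
        labels,
        folds,
        n_iter=n_iter,
        seed=int(rng.integers(0, 2**31 - 1)),
        contrast_name="clean-vs-contaminated-absent",
    )


def relabel_control(
    X: np.ndarray,
    labels,
    counterbalance_on,
    folds: FoldPlan,
    n_iter: int = 50,
    seed: int = 0,
    mode: str = "counterbalance",
    contrast_name: str = "",
) -> DecodingResult:
    """Nuisance-factor controls for a decoding contrast.

    ``mode="counterbalance"`` re-runs the decode on subsets whose
    label x factor cross-tab is exactly uniform, so any accuracy left cannot
    come from the factor's distribution differing between classes.
    ``mode="decode_factor"`` instead decodes the factor itself (balanced),
    testing whether the factor alone carries signal.
    """
    factor = np.asarray(counterbalance_on)
    if mode == "decode_factor":
        return decode_roi_balanced(
            X,
            factor,
            folds,
            n_iter=n_iter,
            seed=seed,
            contrast_name=contrast_name or "nuisance-factor-decode",
        )
    if mode != "counterbalance":
        raise ValueError("mode must be 'counterbalance' or 'decode_factor'")
    return decode_roi_balanced(
        X,
        labels,
        folds,
        n_iter=n_iter,
        seed=seed,
        balance_by=factor,
        uniform_cells=True,
        contrast_name=contrast_name or "counterbalanced-relabel",
    )
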