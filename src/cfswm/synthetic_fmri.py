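"""Synthetic per-trial beta volumes for the decoding pipeline.

The first-level GLM of a real experiment is not simulated; instead its
outputs — one 3-D coefficient ("beta") image per trial and task phase — are
drawn directly as *pattern x amplitude + Gaussian noise*, lightly smoothed,
on a small voxel grid with the mask structure the decoding stages expect
(brain, gray matter, a lateralized "visuospatial" search mask, and an
extended search mask for the probe phase).  Condition-coded effects are
declared as sparse voxel patterns gated by trial labels, e.g. a left/right
target-side pattern on conscious trials, a distractor-presence pattern, or
a probe-status pattern.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy import ndimage

from .design import TrialSpec, quadrant_side

PHASES = ("sample", "delay", "probe")

FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth_volume(
    values: np.ndarray, fwhm_mm: float, voxel_size_mm: float = 2.0
) -> np.ndarray:
    """Separable Gaussian smoothing with a renormalized truncated kernel.

    sigma = FWHM / (2 sqrt(2 ln 2)) per axis, in voxel units.  Boundaries
    use a zero-padded kernel renormalized by the smoothed all-ones volume,
    so constant images are exactly preserved and there is no wraparound.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be nonnegative")
    if fwhm_mm == 0:
        return np.asarray(values, dtype=float).copy()
    sigma = fwhm_mm * FWHM_TO_SIGMA / voxel_size_mm
    v = np.asarray(values, dtype=float)
    num = ndimage.gaussian_filter(v, sigma, mode="constant", cval=0.0)
    den = ndimage.gaussian_filter(np.ones_like(v), sigma, mode="constant", cval=0.0)
    return num / den


def _ellipsoid(shape: tuple[int, int, int], semiaxes: tuple[float, float, float]) -> np.ndarray:
    grid = np.indices(shape).astype(float)
    center = [(s - 1) / 2.0 for s in shape]
    r2 = sum(
        ((grid[i] - center[i]) / semiaxes[i]) ** 2 for i in range(3)
    )
    return r2 <= 1.0


@dataclass
class VolumeGrid:
    """Voxel grid and mask hierarchy for the synthetic volumes."""

    shape: tuple[int, int, int]
    voxel_size_mm: float
    brain_mask: np.ndarray
    gray_mask: np.ndarray
    visuospatial_mask: np.ndarray
    extended_mask: np.ndarray

    def validate(self) -> None:
        for name in ("brain_mask", "gray_mask", "visuospatial_mask", "extended_mask"):
            mask = getattr(self, name)
            if mask.shape != self.shape:
                raise ValueError(f"{name} shape mismatch")
            if not mask.any():
                raise ValueError(f"{name} is empty")
        if (self.gray_mask & ~self.brain_mask).any():
            raise ValueError("gray_mask must be inside brain_mask")
        for name in ("visuospatial_mask", "extended_mask"):
            if (getattr(self, name) & ~self.brain_mask).any():
                raise ValueError(f"{name} must be inside brain_mask")

    @property
    def affine(self) -> np.ndarray:
        return np.diag([self.voxel_size_mm] * 3 + [1.0])


def default_grid(shape: tuple[int, int, int] = (24, 24, 16), voxel_size_mm: float = 2.0) -> VolumeGrid:
    """Desk-scale grid: ellipsoidal brain with lateral posterior patches.

    The first axis is left-right; the visuospatial mask is two posterior
    lateral slabs (one per hemisphere) so lateralized effects have somewhere
    anatomically sensible to live, and the extended mask adds an anterior
    slab standing in for frontal cortex.
    """
    nx, ny, nz = shape
    semi = (nx * 0.46, ny * 0.46, nz * 0.44)
    brain = _ellipsoid(shape, semi)
    gray = _ellipsoid(shape, (semi[0] * 0.92, semi[1] * 0.92, semi[2] * 0.92)) & brain
    vis = np.zeros(shape, dtype=bool)
    # posterior third of the volume, lateral halves of each hemisphere
    post = slice(0, max(2, ny // 3))
    vis[: nx // 2, post, :] = True
    vis[nx - nx // 2 :, post, :] = True
    vis &= gray
    ext = vis.copy()
    ant = slice(ny - max(2, ny // 4), ny)
    frontal = np.zeros(shape, dtype=bool)
    frontal[:, ant, :] = True
    ext |= frontal & gray
    grid = VolumeGrid(
        shape=shape,
        voxel_size_mm=voxel_size_mm,
        brain_mask=brain,
        gray_mask=gray,
        visuospatial_mask=vis,
        extended_mask=ext,
    )
    grid.validate()
    return grid


@dataclass(frozen=True)
class Effect:
    """One condition-coded multivoxel pattern.

    The pattern is added (times ``amplitude``) to every trial whose labels
    match all key/value pairs in ``when`` on the given phase.
    """

    name: str
    phase: str
    when: dict
    pattern: np.ndarray
    amplitude: float

    def matches(self, labels: dict) -> bool:
        return all(labels.get(k) == v for k, v in self.when.items())


@dataclass
class EffectSpec:
    """Collection of effects plus the noise/smoothing model."""

    effects: list[Effect] = field(default_factory=list)
    noise_sd: float = 1.0
    smooth_fwhm_mm: float = 2.0

    def validate(self, grid: VolumeGrid) -> None:
        for e in self.effects:
            if e.amplitude < 0:
                raise ValueError(f"effect {e.name!r} has negative amplitude")
            if e.phase not in PHASES:
                raise ValueError(f"effect {e.name!r} has unknown phase {e.phase!r}")
            if e.pattern.shape != grid.shape:
                raise ValueError(f"effect {e.name!r} pattern shape mismatch")
            if (np.abs(e.pattern) > 0)[~grid.brain_mask].any():
                raise ValueError(f"effect {e.name!r} pattern leaves the brain mask")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _hemisphere_patch(grid: VolumeGrid, side: str) -> np.ndarray:
    """Unit pattern on the posterior patch of one hemisphere."""
    nx = grid.shape[0]
    patch = grid.visuospatial_mask.copy()
    if side == "left":
        patch[nx // 2 :, :, :] = False
    else:
        patch[: nx // 2, :, :] = False
    return patch.astype(float)


def default_effects(
    grid: VolumeGrid,
    amplitude_conscious_side: float = 0.08,
    amplitude_nonconscious: float = 0.05,
    amplitude_probe_status: float = 0.05,
    amplitude_stimulus: float = 0.10,
    noise_sd: float = 1.0,
) -> EffectSpec:
    """The planted effects the decoding stages are meant to recover.

    Attention to a left-field target drives the contralateral (right)
    posterior patch and vice versa; distractor presence adds a bilateral
    pattern; any stimulus (vs absent) adds a broad visuospatial response
    used by the ROI-defining contrast; probe status perturbs a dedicated
    pattern during the probe phase.  Default amplitudes were calibrated
    once against the decoding module so that, at experiment-3 trial counts
    and unit noise, conscious target-side accuracy lands in the ~63% regime
    and nonconscious effects in the ~52-56% regime.
    """
    left_patch = _hemisphere_patch(grid, "left")
    right_patch = _hemisphere_patch(grid, "right")
    both = grid.visuospatial_mask.astype(float)
    rng = np.random.default_rng(202206)  # fixed: the sign patterns define the effects
    distractor_pattern = both * rng.choice([-1.0, 1.0], size=grid.shape)
    probe_pattern = both * rng.choice([-1.0, 1.0], size=grid.shape)
    effects = []
    for phase in ("sample", "delay"):
        for cond in ("conscious", "nonconscious"):
            amp = amplitude_conscious_side if cond == "conscious" else amplitude_nonconscious
            effects.append(
                Effect(
                    name=f"{cond}-target-left-{phase}",
                    phase=phase,
                    when={"condition": cond, "target_side": "left"},
                    pattern=right_patch,
                    amplitude=amp,
                )
            )
            effects.append(
                Effect(
                    name=f"{cond}-target-right-{phase}",
                    phase=phase,
                    when={"condition": cond, "target_side": "right"},
                    pattern=left_patch,
                    amplitude=amp,
                )
            )
            effects.append(
                Effect(
                    name=f"{cond}-distractor-{phase}",
                    phase=phase,
                    when={"condition": cond, "distractor_present": True},
                    pattern=distractor_pattern,
                    amplitude=amplitude_nonconscious,
                )
            )
            effects.append(
                Effect(
                    name=f"{cond}-stimulus-{phase}",
                    phase=phase,
                    when={"condition": cond},
                    pattern=both,
                    amplitude=amplitude_stimulus,
                )
            )
    for cond in ("conscious", "nonconscious"):
        effects.append(
            Effect(
                name=f"{cond}-probe-status",
                phase="probe",
                when={"condition": cond, "probe_type": "target-match"},
                pattern=probe_pattern,
                amplitude=amplitude_probe_status,
            )
        )
    return EffectSpec(effects=effects, noise_sd=noise_sd)


def trial_labels(trial: TrialSpec) -> dict:
    """Decoding-relevant labels of one scheduled trial."""
    return {
        "trial_index": trial.trial_index,
        "condition": trial.condition,
        "distractor_present": trial.distractor_present,
        "target_side": trial.target_side,
        "probe_type": trial.probe_type,
        "probe_side": quadrant_side(trial.probe_quadrant),
        "onset_s": trial.onset_s,
        "block": trial.block,
    }


@dataclass
class BetaImage:
    """One trial x phase coefficient volume."""

    trial_index: int
    phase: str
    values: np.ndarray
    labels: dict


def generate_betas(
    schedule: list[TrialSpec],
    effects: EffectSpec,
    grid: VolumeGrid,
    seed: int,
    phases: tuple[str, ...] = PHASES,
) -> list[BetaImage]:
    """Per-trial beta volumes: matching patterns x amplitude + smoothed noise.

    Absent trials match no lateralized/stimulus effect and therefore come out
    as pure noise.  Voxels outside the brain mask are zeroed.
    """
    effects.validate(grid)
    rng = np.random.default_rng(seed)
    images: list[BetaImage] = []
    brain = grid.brain_mask
    for trial in schedule:
        labels = trial_labels(trial)
        for phase in phases:
            vol = rng.normal(0.0, effects.noise_sd, size=grid.shape)
            for e in effects.effects:
                if e.phase == phase and e.matches(labels):
                    vol += e.amplitude * e.pattern
            if effects.smooth_fwhm_mm > 0:
                vol = smooth_volume(vol, effects.smooth_fwhm_mm, grid.voxel_size_mm)
            vol[~brain] = 0.0
            images.append(
                BetaImage(
                    trial_index=trial.trial_index,
                    phase=phase,
                    values=vol,
                    labels=labels,
                )
            )
    return images


# ---------------------------------------------------------------------------
# NIfTI round trip
# ---------------------------------------------------------------------------

def save_volume(path, values: np.ndarray, grid: VolumeGrid) -> None:
    nib.save(nib.Nifti1Image(np.asarray(values, dtype=np.float32), grid.affine), str(path))


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata(), dtype=float)
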