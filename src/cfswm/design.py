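"""Trial-schedule generation for the delayed match-to-sample experiments.

Three experiments share one trial skeleton: a cue (circle or diamond) defines
which of two shapes is the target, the sample shows target (and usually a
distractor) in screen quadrants under continuous flash suppression, a 5-15 s
delay follows, and a "clock pointer" probe asks whether it points at the
target's quadrant (yes/no).  Visibility of the suppressed sample is titrated
online by a staircase on the shapes' gray level (RGB points against a
background of 210): every ten nonconscious trials, too many breakthrough
reports (PAS > 1) push the gray level toward the background (less contrast,
harder to see), otherwise away from it.

This module produces the printed designs (trial/probe counts, timing bounds,
staircase parameters), seeded trial schedules honoring those counts, and the
staircase update rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONSCIOUS = "conscious"
NONCONSCIOUS = "nonconscious"
ABSENT = "absent"
CONDITIONS = (CONSCIOUS, NONCONSCIOUS, ABSENT)

TARGET_MATCH = "target-match"
DISTRACTOR_MATCH = "distractor-match"
NON_MATCH = "non-match"
PROBE_TYPES = (TARGET_MATCH, DISTRACTOR_MATCH, NON_MATCH)

QUADRANTS = ("UL", "UR", "LL", "LR")
LEFT_QUADRANTS = ("UL", "LL")
RIGHT_QUADRANTS = ("UR", "LR")

BACKGROUND_RGB = 210


def quadrant_side(quadrant: str) -> str:
    """Screen side ('left'/'right') of a quadrant label."""
    return "left" if quadrant in LEFT_QUADRANTS else "right"


@dataclass(frozen=True)
class StaircaseConfig:
    """Parameters of the visibility staircase.

    ``bounds`` are (lowest, highest) admissible shape RGB values; the highest
    value (206) is the *least* contrasted (closest to the 210 background) and
    the lowest (182 or 174) the most visible.
    """

    step: int = 2
    bounds: tuple[int, int] = (182, 206)
    start: int = 196
    window: int = 10
    threshold: int = 3  # update rule: count(PAS > 1) > threshold -> less contrast


@dataclass(frozen=True)
class ExperimentDesign:
    """The printed parameters of one experiment.

    ``condition_counts`` maps condition name to trial count.
    ``probe_counts`` maps (condition, distractor_present, probe_type) to
    trial count; its values partition each condition's trials.
    """

    experiment_id: int
    n_trials_total: int
    condition_counts: dict[str, int]
    probe_counts: dict[tuple[str, bool, str], int]
    n_blocks_or_runs: int
    trials_per_block: int
    cue_duration_s: float = 1.75
    cue_sample_gap_s: float = 0.25
    sample_duration_s: float = 1.0
    mondrian_duration_s: float = 1.0
    delay_range_s: tuple[float, float] = (5.0, 15.0)
    iti_range_s: tuple[float, float] = (3.0, 3.0)
    response_deadline_s: float = 5.0
    pas_deadline_s: float = 5.0
    mondrian_rate_hz: float = 10.0  # metadata only
    staircase: StaircaseConfig = field(default_factory=StaircaseConfig)
    pas_scale: tuple[int, ...] = (1, 2, 3)
    pas1_target: float = 0.70  # advertised floor of PAS=1 nonconscious trials

    def validate(self) -> None:
        if sum(self.condition_counts.values()) != self.n_trials_total:
            raise ValueError("condition_counts do not sum to n_trials_total")
        for cond, n in self.condition_counts.items():
            n_probe = sum(
                v for (c, _, _), v in self.probe_counts.items() if c == cond
            )
            if n_probe != n:
                raise ValueError(f"probe_counts for {cond!r} sum to {n_probe}, expected {n}")
        lo, hi = self.staircase.bounds
        if not lo <= self.staircase.start <= hi:
            raise ValueError("staircase start outside bounds")
        if hi >= BACKGROUND_RGB:
            raise ValueError("shape RGB must stay below the background RGB")
        if self.n_blocks_or_runs * self.trials_per_block != self.n_trials_total:
            raise ValueError("blocks do not partition the trial count")


@dataclass(frozen=True)
class TrialSpec:
    """One scheduled trial (no behavior attached yet)."""

    trial_index: int
    block: int
    condition: str
    distractor_present: bool
    cue_shape: str
    target_quadrant: str | None
    distractor_quadrant: str | None
    probe_type: str
    probe_quadrant: str
    delay_s: float
    iti_s: float
    onset_s: float

    @property
    def target_side(self) -> str | None:
        if self.target_quadrant is None:
            return None
        return quadrant_side(self.target_quadrant)

    def duration_s(self, design: ExperimentDesign) -> float:
        """Scheduled envelope of the trial (full response/PAS windows)."""
        return (
            design.cue_duration_s
            + design.cue_sample_gap_s
            + design.sample_duration_s
            + self.delay_s
            + design.response_deadline_s
            + design.pas_deadline_s
        )


@dataclass
class StaircaseState:
    """Mutable staircase bookkeeping carried across blocks.

    ``window_buffer`` holds the PAS responses of the nonconscious trials seen
    since the last update; it is cleared after every update.
    """

    current_rgb: int
    window_buffer: list[int] = field(default_factory=list)
    history: list[tuple[int, int]] = field(default_factory=list)

    def observe(self, trial_index: int, pas: int, config: StaircaseConfig) -> bool:
        """Record one nonconscious-trial PAS; update when the window fills.

        Returns True when an update was triggered.
        """
        self.window_buffer.append(pas)
        if len(self.window_buffer) < config.window:
            return False
        window = self.window_buffer
        self.window_buffer = []
        new = update_staircase(
            self,
            window,
            config.bounds,
            config.step,
            threshold=config.threshold,
            window_size=config.window,
        )
        self.current_rgb = new.current_rgb
        self.history.append((trial_index, self.current_rgb))
        return True


def update_staircase(
    state: StaircaseState,
    pas_window: list[int],
    bounds: tuple[int, int],
    step: int,
    threshold: int = 3,
    window_size: int = 10,
) -> StaircaseState:
    """Apply one staircase decision to a full PAS window.

    More than ``threshold`` breakthrough reports (PAS > 1) in the window move
    the shape gray level ``step`` points *toward* the background (higher RGB,
    lower contrast, harder to see); otherwise ``step`` points away from it.
    The result is clamped to ``bounds``.
    """
    window = list(pas_window)
    if len(window) != window_size:
        raise ValueError(
            f"pas_window has {len(window)} values, expected {window_size}"
        )
    if any(p not in (1, 2, 3) for p in window):
        raise ValueError("PAS values must be in {1, 2, 3}")
    n_seen = sum(1 for p in window if p > 1)
    lo, hi = bounds
    if n_seen > threshold:
        rgb = state.current_rgb + step  # toward background: lower contrast
    else:
        rgb = state.current_rgb - step  # away from background: higher contrast
    rgb = int(min(hi, max(lo, rgb)))
    return StaircaseState(
        current_rgb=rgb,
        window_buffer=[],
        history=state.history + [(len(state.history), rgb)],
    )


def build_design(experiment_id: int) -> ExperimentDesign:
    """Return the printed design of experiment 1, 2, or 3."""
    if experiment_id in (1, 2):
        design = ExperimentDesign(
            experiment_id=experiment_id,
            n_trials_total=312,
            condition_counts={CONSCIOUS: 64, NONCONSCIOUS: 224, ABSENT: 24},
            probe_counts={
                (CONSCIOUS, True, TARGET_MATCH): 32,
                (CONSCIOUS, True, NON_MATCH): 16,
                (CONSCIOUS, True, DISTRACTOR_MATCH): 16,
                (NONCONSCIOUS, True, TARGET_MATCH): 112,
                (NONCONSCIOUS, True, DISTRACTOR_MATCH): 112,
                (ABSENT, False, NON_MATCH): 24,
            },
            n_blocks_or_runs=4,
            trials_per_block=78,
            cue_duration_s=1.75 if experiment_id == 1 else 1.8,
        )
    elif experiment_id == 3:
        design = ExperimentDesign(
            experiment_id=3,
            n_trials_total=222,
            condition_counts={CONSCIOUS: 60, NONCONSCIOUS: 120, ABSENT: 42},
            probe_counts={
                (CONSCIOUS, True, TARGET_MATCH): 18,
                (CONSCIOUS, True, NON_MATCH): 9,
                (CONSCIOUS, True, DISTRACTOR_MATCH): 9,
                (CONSCIOUS, False, TARGET_MATCH): 12,
                (CONSCIOUS, False, NON_MATCH): 12,
                (NONCONSCIOUS, True, TARGET_MATCH): 36,
                (NONCONSCIOUS, True, DISTRACTOR_MATCH): 36,
                (NONCONSCIOUS, False, TARGET_MATCH): 24,
                (NONCONSCIOUS, False, NON_MATCH): 24,
                (ABSENT, False, NON_MATCH): 42,
            },
            n_blocks_or_runs=3,
            trials_per_block=74,
            iti_range_s=(3.0, 9.0),
            staircase=StaircaseConfig(bounds=(174, 206)),
            pas1_target=0.80,
        )
    else:
        raise ValueError(f"unknown experiment_id: {experiment_id!r}")
    design.validate()
    return design


def _balanced_quadrants(n: int, rng: np.random.Generator) -> list[str]:
    """n quadrant labels, as equal as possible across the 4 quadrants.

    The remainder (n mod 4) is assigned by a seeded draw without replacement.
    """
    base = n // 4
    labels = [q for q in QUADRANTS for _ in range(base)]
    extra = rng.choice(4, size=n % 4, replace=False)
    labels.extend(QUADRANTS[i] for i in extra)
    rng.shuffle(labels)
    return labels


def _draw_discrete(rng: np.random.Generator, low: float, high: float, step: float = 0.5) -> float:
    n_steps = int(round((high - low) / step))
    return float(low + step * rng.integers(0, n_steps + 1))


def build_schedule(design: ExperimentDesign, seed: int) -> list[TrialSpec]:
    """Seeded random schedule reproducing the printed counts exactly.

    Target quadrants are balanced across the four quadrants within each
    condition cell; the distractor lands on the opposite screen side
    (experiments 1/2) or in any of the three free quadrants (experiment 3);
    trial order is a seeded permutation partitioned into the printed
    blocks/runs; delays (and experiment-3 ITIs) are drawn uniformly on a
    0.5 s lattice; onsets restart at 0 within each block/run.
    """
    design.validate()
    rng = np.random.default_rng(seed)
    proto: list[dict] = []
    for cond in CONDITIONS:
        cells = [(k, v) for k, v in design.probe_counts.items() if k[0] == cond]
        n_cond = design.condition_counts.get(cond, 0)
        if cond == ABSENT:
            for (_, _, probe), count in cells:
                for _ in range(count):
                    proto.append(
                        dict(
                            condition=cond,
                            distractor_present=False,
                            target_quadrant=None,
                            distractor_quadrant=None,
                            probe_type=probe,
                        )
                    )
            continue
        quadrants = _balanced_quadrants(n_cond, rng)
        qi = 0
        for (_, dp, probe), count in cells:
            for _ in range(count):
                tq = quadrants[qi]
                qi += 1
                if dp:
                    if design.experiment_id in (1, 2):
                        opposite = (
                            RIGHT_QUADRANTS if tq in LEFT_QUADRANTS else LEFT_QUADRANTS
                        )
                        dq = opposite[rng.integers(0, 2)]
                    else:
                        free = [q for q in QUADRANTS if q != tq]
                        dq = free[rng.integers(0, 3)]
                else:
                    dq = None
                proto.append(
                    dict(
                        condition=cond,
                        distractor_present=dp,
                        target_quadrant=tq,
                        distractor_quadrant=dq,
                        probe_type=probe,
                    )
                )
    order = rng.permutation(len(proto))
    trials: list[TrialSpec] = []
    onset = 0.0
    for idx, j in enumerate(order):
        p = proto[j]
        block = idx // design.trials_per_block
        if idx % design.trials_per_block == 0:
            onset = 0.0
        tq, dq = p["target_quadrant"], p["distractor_quadrant"]
        if p["probe_type"] == TARGET_MATCH:
            pq = tq
        elif p["probe_type"] == DISTRACTOR_MATCH:
            pq = dq
        else:
            free = [q for q in QUADRANTS if q not in (tq, dq)]
            pq = free[rng.integers(0, len(free))]
        delay = _draw_discrete(rng, *design.delay_range_s)
        iti = _draw_discrete(rng, *design.iti_range_s)
        onset_trial = onset + iti  # ITI precedes the cue
        trial = TrialSpec(
            trial_index=idx,
            block=block,
            condition=p["condition"],
            distractor_present=p["distractor_present"],
            cue_shape=("circle", "diamond")[rng.integers(0, 2)],
            target_quadrant=tq,
            distractor_quadrant=dq,
            probe_type=p["probe_type"],
            probe_quadrant=pq,
            delay_s=delay,
            iti_s=iti,
            onset_s=onset_trial,
        )
        trials.append(trial)
        onset = onset_trial + trial.duration_s(design)
    return trials


def schedule_tally(trials: list[TrialSpec]) -> dict[tuple[str, bool, str], int]:
    """Exhaustive (condition, distractor_present, probe_type) tally."""
    tally: dict[tuple[str, bool, str], int] = {}
    for t in trials:
        key = (t.condition, t.distractor_present, t.probe_type)
        tally[key] = tally.get(key, 0) + 1
    return tally
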