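"""Generative observer models for the delayed match-to-sample task.

An observer stochastically encodes the sample items (target, distractor) into
a small memory store, optionally with role tags, and answers the probe from
that store.  The three presets map onto the competing hypotheses the task was
built to separate:

* ``tagged_observer`` — items are stored *with* their target/distractor role
  (possible when the cue is consciously perceived): probes matching a stored
  distractor are rejected, so hits exceed distractor-match false alarms.
* ``untagged_observer`` — both items are stored but without role labels
  (nonconscious cue): any probe matching a stored location draws a "yes",
  so hits and distractor-match false alarms are equal in expectation.
* ``guessing_observer`` — nothing is stored; "yes" responses occur at the
  baseline bias, identical across probe types.

Trial-wise visibility (PAS) on nonconscious trials follows a logistic
psychometric function of the staircased shape gray level, which closes the
loop with the design module's staircase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .design import (
    ABSENT,
    CONSCIOUS,
    NONCONSCIOUS,
    StaircaseConfig,
    StaircaseState,
    TrialSpec,
)


@dataclass(frozen=True)
class ObserverParams:
    """Parameters of one simulated observer.

    Encoding probabilities ``p_enc_target``/``p_enc_distractor`` apply to
    nonconscious trials; conscious trials encode with ``p_enc_conscious``
    (and are always role-tagged, the cue being visible).  ``visibility_mid``
    is the shape RGB at which breakthrough probability reaches 50% and
    ``visibility_slope`` its steepness per RGB point (breakthrough falls as
    the gray level approaches the 210 background).
    """

    p_enc_target: float = 0.08
    p_enc_distractor: float = 0.10
    tagging: str = "tagged"  # {"tagged", "untagged"}
    p_yes_guess: float = 0.35
    p_yes_distractor_match: float = 0.08
    lapse: float = 0.02
    p_enc_conscious: float = 0.97
    visibility_mid: float = 178.0
    visibility_slope: float = 0.35
    erroneous_pas_rate: float = 0.063  # conscious trials rated PAS < 3
    p_false_experience: float = 0.10  # absent trials rated PAS > 1
    pas3_given_break: float = 0.25  # clear (vs vague) experience on breakthrough
    rt_median_ms: float = 800.0
    rt_sigma: float = 0.5
    p_no_response: float = 0.01

    def validate(self) -> None:
        probs = {
            "p_enc_target": self.p_enc_target,
            "p_enc_distractor": self.p_enc_distractor,
            "p_yes_guess": self.p_yes_guess,
            "p_yes_distractor_match": self.p_yes_distractor_match,
            "lapse": self.lapse,
            "p_enc_conscious": self.p_enc_conscious,
            "erroneous_pas_rate": self.erroneous_pas_rate,
            "p_false_experience": self.p_false_experience,
            "pas3_given_break": self.pas3_given_break,
            "p_no_response": self.p_no_response,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p}")
        if self.tagging not in ("tagged", "untagged"):
            raise ValueError("tagging must be 'tagged' or 'untagged'")
        if self.visibility_slope < 0:
            raise ValueError("visibility_slope must be nonnegative")


def tagged_observer(**overrides) -> ObserverParams:
    """Observer that stores items with their task role (conscious cue)."""
    return replace(ObserverParams(tagging="tagged"), **overrides)


def untagged_observer(**overrides) -> ObserverParams:
    """Observer that stores both items without role labels (nonconscious cue)."""
    params = ObserverParams(
        tagging="untagged", p_enc_target=0.10, p_enc_distractor=0.10
    )
    return replace(params, **overrides)


def guessing_observer(**overrides) -> ObserverParams:
    """Observer with no memory: pure response bias."""
    params = ObserverParams(p_enc_target=0.0, p_enc_distractor=0.0, p_enc_conscious=0.0)
    return replace(params, **overrides)


def visibility_probability(contrast_rgb: float, params: ObserverParams) -> float:
    """P(PAS > 1) on a nonconscious trial, logistic and decreasing in RGB."""
    x = params.visibility_slope * (contrast_rgb - params.visibility_mid)
    return 1.0 / (1.0 + math.exp(x))


@dataclass(frozen=True)
class BehavioralRecord:
    """One trial's simulated outcome."""

    trial_index: int
    condition: str
    distractor_present: bool
    probe_type: str
    response: str  # {"yes", "no", "none"}
    rt_ms: float  # NaN when response == "none"
    pas: int
    contrast_rgb: float  # NaN on absent trials


def _draw_rt(params: ObserverParams, rng: np.random.Generator) -> float:
    return float(np.exp(rng.normal(math.log(params.rt_median_ms), params.rt_sigma)))


def respond_to_probe(
    trial: TrialSpec,
    memory_state: list[tuple[str, str | None]],
    params: ObserverParams,
    rng: np.random.Generator,
) -> tuple[str, float]:
    """Yes/no decision (plus RT) from the stored locations.

    ``memory_state`` lists (quadrant, role) pairs; role is "target",
    "distractor", or None for untagged storage.  A probe matching a stored
    target or untagged item elicits "yes" with 1 - lapse; a stored,
    distractor-tagged match with ``p_yes_distractor_match`` (goal-directed
    rejection when that is below the guess bias); no match falls back on the
    baseline bias ``p_yes_guess``.
    """
    match_roles = [role for q, role in memory_state if q == trial.probe_quadrant]
    if any(role in ("target", None) for role in match_roles):
        p_yes = 1.0 - params.lapse
    elif match_roles:  # stored item(s) all tagged as distractor
        p_yes = params.p_yes_distractor_match
    else:
        p_yes = params.p_yes_guess
    response = "yes" if rng.random() < p_yes else "no"
    return response, _draw_rt(params, rng)


def _simulate_pas(
    trial: TrialSpec,
    contrast_rgb: float,
    params: ObserverParams,
    rng: np.random.Generator,
) -> int:
    if trial.condition == CONSCIOUS:
        if rng.random() < params.erroneous_pas_rate:
            return 2 if rng.random() < 0.8 else 1
        return 3
    if trial.condition == ABSENT:
        broke = rng.random() < params.p_false_experience
    else:
        broke = rng.random() < visibility_probability(contrast_rgb, params)
    if not broke:
        return 1
    return 3 if rng.random() < params.pas3_given_break else 2


def _encode(
    trial: TrialSpec, params: ObserverParams, rng: np.random.Generator
) -> list[tuple[str, str | None]]:
    memory: list[tuple[str, str | None]] = []
    if trial.condition == ABSENT:
        return memory
    if trial.condition == CONSCIOUS:
        p_t, p_d, tag = params.p_enc_conscious, params.p_enc_conscious, True
    else:
        p_t, p_d = params.p_enc_target, params.p_enc_distractor
        tag = params.tagging == "tagged"
    if trial.target_quadrant is not None and rng.random() < p_t:
        memory.append((trial.target_quadrant, "target" if tag else None))
    if (
        trial.distractor_present
        and trial.distractor_quadrant is not None
        and rng.random() < p_d
    ):
        memory.append((trial.distractor_quadrant, "distractor" if tag else None))
    return memory


def run_session(
    schedule: list[TrialSpec],
    params: ObserverParams,
    staircase: StaircaseState,
    seed: int,
    staircase_config: StaircaseConfig | None = None,
) -> list[BehavioralRecord]:
    """Simulate one observer through a full schedule.

    The staircase state is advanced in place: every ``staircase_config.window``
    nonconscious trials the shape gray level is re-titrated from the simulated
    PAS stream, and the final value carries over to whatever session is run
    next with the same state (block-to-block carry-over).
    """
    params.validate()
    config = staircase_config or StaircaseConfig()
    rng = np.random.default_rng(seed)
    records: list[BehavioralRecord] = []
    for trial in schedule:
        if trial.condition == NONCONSCIOUS:
            contrast = float(staircase.current_rgb)
        elif trial.condition == CONSCIOUS:
            contrast = 198.0  # fixed, fully visible presentation level
        else:
            contrast = float("nan")
        pas = _simulate_pas(trial, contrast, params, rng)
        memory = _encode(trial, params, rng)
        if rng.random() < params.p_no_response:
            response, rt = "none", float("nan")
        else:
            response, rt = respond_to_probe(trial, memory, params, rng)
        records.append(
            BehavioralRecord(
                trial_index=trial.trial_index,
                condition=trial.condition,
                distractor_present=trial.distractor_present,
                probe_type=trial.probe_type,
                response=response,
                rt_ms=rt,
                pas=pas,
                contrast_rgb=contrast,
            )
        )
        if trial.condition == NONCONSCIOUS:
            staircase.observe(trial.trial_index, pas, config)
    return records
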