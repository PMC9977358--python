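"""Exclusion rules, guessing-adjusted rates, and the behavioral inference suite.

Scoring follows the standard logic of the task: a "yes" to a target-match
probe is a hit; a "yes" to a distractor-match or non-match probe is a false
alarm; the "yes" rate on stimulus-absent trials estimates each subject's
information-free guessing rate and is subtracted from hit/false-alarm rates
to remove response bias.  Inference is random-effects across subjects:
Wilcoxon matched-pairs for paired rate comparisons, one-sample t against
zero for adjusted rates, and a default (JZS, Cauchy-prior) Bayes factor
BF01 to quantify evidence for null results.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

from .design import (
    ABSENT,
    CONSCIOUS,
    DISTRACTOR_MATCH,
    NON_MATCH,
    NONCONSCIOUS,
    TARGET_MATCH,
)
from .observers import BehavioralRecord


class DegenerateInputError(ValueError):
    """Raised when a test statistic is undefined for the given sample."""


RT_MIN_MS = 250.0

BF_BANDS: tuple[tuple[float, str], ...] = (
    (1.0, "no"),
    (3.0, "anecdotal"),
    (10.0, "substantial"),
    (30.0, "strong"),
    (100.0, "very strong"),
    (math.inf, "decisive"),
)


def bf_band(bf01: float) -> str:
    """Evidence band for a BF01 value (cutpoints 1, 3, 10, 30, 100)."""
    for cut, name in BF_BANDS:
        if bf01 < cut or cut == math.inf:
            return name
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# exclusions and rates
# ---------------------------------------------------------------------------

def apply_exclusions(
    records: list[BehavioralRecord],
    include_pas2: bool = False,
    rt_min_ms: float = RT_MIN_MS,
) -> tuple[list[BehavioralRecord], list[tuple[int, str]]]:
    """Drop trials failing the RT, response, and visibility-rating rules.

    Retained trials must have a response, RT >= ``rt_min_ms``, and the
    condition-appropriate PAS: 1 for absent and nonconscious trials, 3 for
    conscious trials (relaxed to >= 2 when ``include_pas2``).  Returns the
    retained records and an exclusion log of (trial_index, reason).
    """
    retained: list[BehavioralRecord] = []
    log: list[tuple[int, str]] = []
    for r in records:
        if r.response == "none" or not np.isfinite(r.rt_ms):
            log.append((r.trial_index, "no-response"))
            continue
        if r.rt_ms < rt_min_ms:
            log.append((r.trial_index, "fast-rt"))
            continue
        if r.condition in (ABSENT, NONCONSCIOUS):
            if r.pas != 1:
                log.append((r.trial_index, "pas"))
                continue
        elif r.condition == CONSCIOUS:
            floor = 2 if include_pas2 else 3
            if r.pas < floor:
                log.append((r.trial_index, "pas"))
                continue
        retained.append(r)
    return retained, log


@dataclass
class ConditionRates:
    """Percent rates for one (condition, distractor_present) cell."""

    hit_rate: float | None = None
    fa_distractor_rate: float | None = None
    fa_nonmatch_rate: float | None = None
    fa_rate: float | None = None  # pooled over distractor-match and non-match
    performance: float | None = None  # hit_rate - fa_rate
    hits_minus_guess: float | None = None
    fa_minus_guess: float | None = None
    n_trials: int = 0


@dataclass
class RateSummary:
    """Per-condition rates for one subject, plus the guessing rate."""

    yes_absent_rate: float | None
    conditions: dict[tuple[str, bool], ConditionRates] = field(default_factory=dict)
    n_retained: int = 0
    n_excluded: int = 0

    def cell(self, condition: str, distractor_present: bool) -> ConditionRates:
        return self.conditions[(condition, distractor_present)]


def _rate(n_yes: int, n: int) -> float | None:
    return None if n == 0 else 100.0 * n_yes / n


def compute_rates(
    retained: list[BehavioralRecord], n_excluded: int = 0
) -> RateSummary:
    """Percent hit/false-alarm/guessing rates from retained trials.

    Rates with an empty denominator are recorded as None (missing), never
    as zero.  Cells are keyed by (condition, distractor_present) so that
    the experiment-3 with/without-distractor split falls out naturally.
    """
    absent = [r for r in retained if r.condition == ABSENT]
    n_yes_absent = sum(1 for r in absent if r.response == "yes")
    guess = _rate(n_yes_absent, len(absent))
    summary = RateSummary(
        yes_absent_rate=guess,
        n_retained=len(retained),
        n_excluded=n_excluded,
    )
    keys = sorted(
        {(r.condition, r.distractor_present) for r in retained if r.condition != ABSENT}
    )
    for key in keys:
        cell_records = [
            r for r in retained if (r.condition, r.distractor_present) == key
        ]
        by_probe = {p: [r for r in cell_records if r.probe_type == p] for p in (
            TARGET_MATCH, DISTRACTOR_MATCH, NON_MATCH)}
        n_yes = {
            p: sum(1 for r in rs if r.response == "yes") for p, rs in by_probe.items()
        }
        cell = ConditionRates(n_trials=len(cell_records))
        cell.hit_rate = _rate(n_yes[TARGET_MATCH], len(by_probe[TARGET_MATCH]))
        cell.fa_distractor_rate = _rate(
            n_yes[DISTRACTOR_MATCH], len(by_probe[DISTRACTOR_MATCH])
        )
        cell.fa_nonmatch_rate = _rate(n_yes[NON_MATCH], len(by_probe[NON_MATCH]))
        n_fa_trials = len(by_probe[DISTRACTOR_MATCH]) + len(by_probe[NON_MATCH])
        cell.fa_rate = _rate(n_yes[DISTRACTOR_MATCH] + n_yes[NON_MATCH], n_fa_trials)
        if cell.hit_rate is not None and cell.fa_rate is not None:
            cell.performance = cell.hit_rate - cell.fa_rate
        if cell.hit_rate is not None and guess is not None:
            cell.hits_minus_guess = cell.hit_rate - guess
        if cell.fa_distractor_rate is not None and guess is not None:
            cell.fa_minus_guess = cell.fa_distractor_rate - guess
        summary.conditions[key] = cell
    return summary


# ---------------------------------------------------------------------------
# inferential statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_two_tailed: float
    n: int
    df: int | None = None
    bf01: float | None = None
    bf_band: str | None = None
    method: str = ""


def normal_p_from_z(z: float) -> float:
    """Two-tailed p for a standard-normal statistic."""
    return 2.0 * stats.norm.sf(abs(z))


def t_p_value(t: float, df: int) -> float:
    """Two-tailed p for a t statistic with ``df`` degrees of freedom."""
    return 2.0 * stats.t.sf(abs(t), df)


def wilcoxon_matched_pairs(
    x, y=None, exact_max_n: int = 25
) -> TestResult:
    """Wilcoxon signed-rank test on paired samples (or differences).

    Zero differences are dropped ("wilcox" convention), ties get midranks,
    and the reported statistic is the continuity-corrected normal
    approximation Z; the p-value comes from exact enumeration when the
    number of nonzero differences is at most ``exact_max_n``, otherwise
    from the normal approximation.
    """
    d = np.asarray(x, dtype=float)
    if y is not None:
        d = d - np.asarray(y, dtype=float)
    nz = d[d != 0]
    n = nz.size
    if n == 0:
        raise DegenerateInputError("all pairwise differences are zero")
    has_ties = np.unique(np.abs(nz)).size < n
    use_exact = n <= exact_max_n and not has_ties
    method = "exact" if use_exact else "approx"
    res = stats.wilcoxon(
        nz, zero_method="wilcox", correction=True, method=method
    )
    if use_exact:
        approx = stats.wilcoxon(nz, zero_method="wilcox", correction=True, method="approx")
        z = float(approx.zstatistic)
    else:
        z = float(res.zstatistic)
    return TestResult(
        statistic=abs(z),
        p_two_tailed=float(res.pvalue),
        n=n,
        method=f"wilcoxon-{method}",
    )


def one_sample_t(values, mu0: float = 0.0) -> TestResult:
    """One-sample t-test of the mean against ``mu0`` (two-tailed)."""
    v = np.asarray(values, dtype=float)
    n = v.size
    if n < 2:
        raise DegenerateInputError("need at least two observations")
    sd = v.std(ddof=1)
    if sd == 0:
        raise DegenerateInputError("zero sample variance")
    t = (v.mean() - mu0) / (sd / math.sqrt(n))
    df = n - 1
    return TestResult(
        statistic=float(t),
        p_two_tailed=t_p_value(t, df),
        n=n,
        df=df,
        method="one-sample-t",
    )


DEFAULT_PRIOR_SCALE = math.sqrt(2.0) / 2.0


def bayes_factor_null(
    t: float, n: int, prior_scale: float = DEFAULT_PRIOR_SCALE
) -> TestResult:
    """BF01 for a two-sided one-sample t-test with a JZS (Cauchy) prior.

    The alternative places a Cauchy(0, ``prior_scale``) prior on the
    standardized effect; the marginal likelihood is evaluated by adaptive
    quadrature over the inverse-gamma mixture representation.  BF01 > 1
    favors the null.
    """
    if n < 2:
        raise DegenerateInputError("need n >= 2")
    nu = n - 1
    r2 = prior_scale**2

    def integrand(g: float) -> float:
        a = 1.0 + n * g * r2
        return (
            a**-0.5
            * (1.0 + t * t / (a * nu)) ** (-(nu + 1) / 2.0)
            * (2.0 * math.pi) ** -0.5
            * g**-1.5
            * math.exp(-1.0 / (2.0 * g))
        )

    marginal_alt, err = integrate.quad(integrand, 0.0, np.inf, limit=200)
    if not np.isfinite(marginal_alt) or marginal_alt <= 0 or err > 1e-6 * marginal_alt + 1e-12:
        raise ArithmeticError(
            f"BF01 quadrature did not converge (value={marginal_alt}, abserr={err})"
        )
    marginal_null = (1.0 + t * t / nu) ** (-(nu + 1) / 2.0)
    bf01 = marginal_null / marginal_alt
    return TestResult(
        statistic=float(t),
        p_two_tailed=t_p_value(t, nu),
        n=n,
        df=nu,
        bf01=float(bf01),
        bf_band=bf_band(bf01),
        method="jzs-bf01",
    )
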