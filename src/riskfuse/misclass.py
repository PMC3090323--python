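"""Monte-Carlo adjustment of a case-referent RR for non-differential
exposure misclassification.

The case-referent study is recast as a closed cohort of ``n_total``
individuals split into exposed/unexposed groups by an assumed exposure
prevalence ``P_E``.  Each trial draws binomial case counts at incidence
``I_0·RR_true`` (exposed) and ``I_0`` (unexposed), computes the trial's true
RR from the drawn counts, then reclassifies exposure non-differentially —
within cases and within non-cases separately, exposed→unexposed moves are
Binomial(count, 1−Se) and unexposed→exposed moves Binomial(count, 1−Sp) —
and computes the misclassified RR from the reclassified table.  The per-trial
adjustment factor ``f_t = RR_true_t / RR_misclassified_t`` multiplies the
observed estimate; the scenario result is the median and 2.5/97.5 percentile
of the adjusted values over non-degenerate trials.

The classification probabilities are identical for cases and non-cases, so
the error is non-differential and biases the RR toward the null; the
adjustment therefore moves estimates away from the null as Se or Sp falls.
A deterministic expected-count mode replaces every draw by its expectation
and must agree with the closed-form misclassification-matrix correction
(:func:`matrix_correct`) exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "MisclassStudyConfig",
    "MisclassScenario",
    "MisclassResult",
    "TwoByTwo",
    "GUSTAVSSON_CONFIG",
    "simulate_trial",
    "expected_trial",
    "run_scenario",
    "run_grid",
    "matrix_correct",
    "expected_misclassified_table",
]


@dataclass(frozen=True)
class MisclassStudyConfig:
    """Cohort-equivalent constants of the study being bias-adjusted."""

    n_total: int
    incidence_unexposed: float  # I_0, probability over the study period
    rr_observed: float
    ci_observed: tuple[float, float]
    rr_true_assumed: float | None = None  # defaults to rr_observed

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if not (0 < self.incidence_unexposed < 1):
            raise ValueError("incidence_unexposed must be in (0, 1)")
        if self.rr_observed <= 0:
            raise ValueError("rr_observed must be positive")
        if self.rr_true_assumed is not None and self.rr_true_assumed <= 0:
            raise ValueError("rr_true_assumed must be positive")

    @property
    def rr_seed(self) -> float:
        """True RR used to seed trials (defaults to the observed RR)."""
        return self.rr_true_assumed if self.rr_true_assumed is not None else self.rr_observed


#: Constants of the Stockholm case-referent study: 1,042 cases + 2,364
#: referents; unexposed incidence proportion 842/(37.5·2,833) over an average
#: 37.5-year study period; observed top-quartile RR 1.63 (1.14–2.33).
GUSTAVSSON_CONFIG = MisclassStudyConfig(
    n_total=3406,
    incidence_unexposed=842.0 / (37.5 * 2833.0),
    rr_observed=1.63,
    ci_observed=(1.14, 2.33),
)


@dataclass(frozen=True)
class MisclassScenario:
    """One (exposure prevalence, sensitivity, specificity) cell."""

    p_exposed: float
    sensitivity: float
    specificity: float

    def __post_init__(self) -> None:
        if not (0 < self.p_exposed < 1):
            raise ValueError("p_exposed must be in (0, 1)")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class MisclassResult:
    """Median-adjusted RR with its 2.5–97.5 percentile interval."""

    scenario: MisclassScenario
    adjusted_rr: float
    interval: tuple[float, float]
    n_trials_used: int
    n_trials_discarded: int


@dataclass(frozen=True)
class TwoByTwo:
    """Exposure-by-case counts with fixed exposure-group denominators."""

    cases_exposed: float
    cases_unexposed: float
    n_exposed: float
    n_unexposed: float

    @property
    def rr(self) -> float:
        return (self.cases_exposed / self.n_exposed) / (
            self.cases_unexposed / self.n_unexposed
        )

    @property
    def degenerate(self) -> bool:
        return (
            self.cases_exposed <= 0
            or self.cases_unexposed <= 0
            or self.n_exposed <= 0
            or self.n_unexposed <= 0
        )


def _group_sizes(config: MisclassStudyConfig, scenario: MisclassScenario) -> tuple[int, int]:
    n1 = int(round(config.n_total * scenario.p_exposed))
    return n1, config.n_total - n1


def _reclassify(
    cases_exp, cases_unexp, nonc_exp, nonc_unexp, se: float, sp: float, rng=None
):
    """Move counts between exposure groups, separately for cases and non-cases.

    With ``rng`` the moves are binomial draws; without, expectations.
    Returns the misclassified (cases_exp*, cases_unexp*, n_exp*, n_unexp*).
    """
    if rng is None:
        fn_case = cases_exp * (1 - se)
        fp_case = cases_unexp * (1 - sp)
        fn_nonc = nonc_exp * (1 - se)
        fp_nonc = nonc_unexp * (1 - sp)
    else:
        fn_case = rng.binomial(cases_exp, 1 - se)
        fp_case = rng.binomial(cases_unexp, 1 - sp)
        fn_nonc = rng.binomial(nonc_exp, 1 - se)
        fp_nonc = rng.binomial(nonc_unexp, 1 - sp)
    mc_cases_exp = cases_exp - fn_case + fp_case
    mc_cases_unexp = cases_unexp - fp_case + fn_case
    mc_nonc_exp = nonc_exp - fn_nonc + fp_nonc
    mc_nonc_unexp = nonc_unexp - fp_nonc + fn_nonc
    return (
        mc_cases_exp,
        mc_cases_unexp,
        mc_cases_exp + mc_nonc_exp,
        mc_cases_unexp + mc_nonc_unexp,
    )


def simulate_trial(
    config: MisclassStudyConfig,
    scenario: MisclassScenario,
    rng: np.random.Generator,
) -> tuple[float, float] | None:
    """One Monte-Carlo trial: (true RR, misclassified RR), or None if degenerate.

    A trial is degenerate when either RR has a zero cell; such trials are
    flagged for discard, never raised.
    """
    n1, n0 = _group_sizes(config, scenario)
    p1 = min(config.incidence_unexposed * config.rr_seed, 1.0)
    cases_exp = rng.binomial(n1, p1)
    cases_unexp = rng.binomial(n0, config.incidence_unexposed)
    if cases_exp == 0 or cases_unexp == 0:
        return None
    rr_true = (cases_exp / n1) / (cases_unexp / n0)
    mc = TwoByTwo(
        *_reclassify(
            cases_exp,
            cases_unexp,
            n1 - cases_exp,
            n0 - cases_unexp,
            scenario.sensitivity,
            scenario.specificity,
            rng,
        )
    )
    if mc.degenerate:
        return None
    return rr_true, mc.rr


def expected_trial(
    config: MisclassStudyConfig, scenario: MisclassScenario
) -> tuple[float, float]:
    """Noise-free trial: every binomial draw replaced by its expectation."""
    n1, n0 = _group_sizes(config, scenario)
    cases_exp = n1 * min(config.incidence_unexposed * config.rr_seed, 1.0)
    cases_unexp = n0 * config.incidence_unexposed
    rr_true = (cases_exp / n1) / (cases_unexp / n0)
    mc = TwoByTwo(
        *_reclassify(
            cases_exp,
            cases_unexp,
            n1 - cases_exp,
            n0 - cases_unexp,
            scenario.sensitivity,
            scenario.specificity,
        )
    )
    return rr_true, mc.rr


def run_scenario(
    config: MisclassStudyConfig,
    scenario: MisclassScenario,
    n_trials: int,
    seed,
) -> MisclassResult:
    """Run ``n_trials`` seeded trials and summarize the adjusted estimates.

    Per trial, ``adjusted_t = rr_observed · (rr_true_t / rr_misclassified_t)``;
    the result reports the median and the 2.5/97.5 percentiles over
    non-degenerate trials.  Deterministic given the seed.  Draws are
    vectorized over trials in the same order as :func:`simulate_trial`
    (case counts first, then the four reclassification moves).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be at least 1")
    rng = np.random.default_rng(seed)
    n1, n0 = _group_sizes(config, scenario)
    p1 = min(config.incidence_unexposed * config.rr_seed, 1.0)

    cases_exp = rng.binomial(n1, p1, size=n_trials)
    cases_unexp = rng.binomial(n0, config.incidence_unexposed, size=n_trials)
    mc_ce, mc_cu, mc_n1, mc_n0 = _reclassify(
        cases_exp,
        cases_unexp,
        n1 - cases_exp,
        n0 - cases_unexp,
        scenario.sensitivity,
        scenario.specificity,
        rng,
    )
    ok = (
        (cases_exp > 0)
        & (cases_unexp > 0)
        & (mc_ce > 0)
        & (mc_cu > 0)
        & (mc_n1 > 0)
        & (mc_n0 > 0)
    )
    n_used = int(ok.sum())
    if n_used == 0:
        raise RuntimeError(
            f"all {n_trials} trials degenerate for scenario "
            f"(P_E={scenario.p_exposed}, Se={scenario.sensitivity}, "
            f"Sp={scenario.specificity})"
        )
    with np.errstate(divide="ignore", invalid="ignore"):
        rr_true = (cases_exp / n1) / (cases_unexp / n0)
        rr_mis = (mc_ce / mc_n1) / (mc_cu / mc_n0)
    adjusted = config.rr_observed * rr_true[ok] / rr_mis[ok]
    return MisclassResult(
        scenario=scenario,
        adjusted_rr=float(np.median(adjusted)),
        interval=(
            float(np.percentile(adjusted, 2.5)),
            float(np.percentile(adjusted, 97.5)),
        ),
        n_trials_used=n_used,
        n_trials_discarded=n_trials - n_used,
    )


def run_grid(
    config: MisclassStudyConfig,
    scenarios: Sequence[MisclassScenario],
    n_trials: int,
    seed: int,
) -> list[MisclassResult]:
    """Run every scenario with a stream derived from (master seed, index).

    Per-scenario seeding makes the grid reproducible and order-independent:
    removing or reordering rows does not change any other row's result.
    """
    if not scenarios:
        raise ValueError("scenario grid must be non-empty")
    results = []
    for i, sc in enumerate(scenarios):
        try:
            results.append(
                run_scenario(config, sc, n_trials, np.random.SeedSequence([seed, i]))
            )
        except RuntimeError as exc:
            raise RuntimeError(f"scenario {i} failed: {exc}") from exc
    return results


def expected_misclassified_table(
    config: MisclassStudyConfig, scenario: MisclassScenario
) -> TwoByTwo:
    """Expected 2×2 table after misclassification, at the seeded true RR."""
    n1, n0 = _group_sizes(config, scenario)
    cases_exp = n1 * min(config.incidence_unexposed * config.rr_seed, 1.0)
    cases_unexp = n0 * config.incidence_unexposed
    return TwoByTwo(
        *_reclassify(
            cases_exp,
            cases_unexp,
            n1 - cases_exp,
            n0 - cases_unexp,
            scenario.sensitivity,
            scenario.specificity,
        )
    )


def matrix_correct(
    cases_exposed: float,
    cases_unexposed: float,
    n_exposed: float,
    n_unexposed: float,
    se: float,
    sp: float,
) -> float:
    """Closed-form misclassification-matrix correction of an observed RR.

    Inverts the classification matrix within cases and within non-cases:
    ``true_exposed = (observed_exposed − (1 − Sp)·total) / (Se + Sp − 1)``.
    Requires Se + Sp > 1 (identifiability) and feasible (non-negative)
    reconstructed counts.
    """
    denom = se + sp - 1.0
    if denom <= 0:
        raise ValueError(
            f"matrix correction requires Se + Sp > 1, got Se + Sp − 1 = {denom:g}"
        )
    total_cases = cases_exposed + cases_unexposed
    total = n_exposed + n_unexposed
    nonc_exposed = n_exposed - cases_exposed
    total_nonc = total - total_cases

    true_cases_exp = (cases_exposed - (1 - sp) * total_cases) / denom
    true_nonc_exp = (nonc_exposed - (1 - sp) * total_nonc) / denom
    true_cases_unexp = total_cases - true_cases_exp
    true_nonc_unexp = total_nonc - true_nonc_exp
    cells = (true_cases_exp, true_nonc_exp, true_cases_unexp, true_nonc_unexp)
    if any(c < 0 for c in cells):
        raise ValueError(
            "infeasible (Se, Sp) for the observed table: reconstructed count "
            f"negative ({cells})"
        )
    true_n_exp = true_cases_exp + true_nonc_exp
    true_n_unexp = true_cases_unexp + true_nonc_unexp
    return (true_cases_exp / true_n_exp) / (true_cases_unexp / true_n_unexp)
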