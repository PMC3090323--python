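"""Ordinary sensitivity analysis for an unmeasured binary confounder.

The occupational cohorts lack individual smoking data, so the observed
RR/SMR may be inflated by the different smoking prevalence in the cohort
versus the external reference population.  For a binary confounder with
outcome rate ratio ``R`` and prevalence ``p``, the population-averaged
incidence is ``I_0·(p·R + 1 − p)`` where ``I_0`` is the incidence in
confounder-negative individuals.  The bias factor is the ratio of the
cohort's multiplier to the reference population's; dividing the observed
estimate (and its CI limits, the factor being treated as known) by the bias
factor yields the confounding-adjusted estimate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .fixtures_io import StudyEstimate

__all__ = [
    "ConfoundingScenario",
    "BiasFactorRow",
    "AdjustedEstimate",
    "incidence_multiplier",
    "bias_factor",
    "adjust_estimate",
    "scenario_grid",
]


@dataclass(frozen=True)
class ConfoundingScenario:
    """One sensitivity-analysis cell: confounder rate ratio and prevalences."""

    rr_confounder: float  # outcome rate ratio, confounder-positive vs -negative
    prev_cohort: float  # confounder prevalence in the exposed cohort
    prev_reference: float  # confounder prevalence in the reference population

    def __post_init__(self) -> None:
        if self.rr_confounder <= 0:
            raise ValueError("rr_confounder must be positive")
        for name in ("prev_cohort", "prev_reference"):
            p = getattr(self, name)
            if not (0 <= p <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class BiasFactorRow:
    """Incidence multipliers (as multiples of I_0) and the resulting bias factor."""

    scenario: ConfoundingScenario
    i_nonexp_multiplier: float  # reference-population incidence / I_0
    i_exp_multiplier: float  # cohort incidence / I_0
    bias_factor: float


@dataclass(frozen=True)
class AdjustedEstimate:
    """A study estimate divided by a bias factor, CI limits included."""

    source: StudyEstimate
    bias_factor: float
    estimate_adj: float
    ci_low_adj: float
    ci_high_adj: float


def incidence_multiplier(prev: float, rr_confounder: float) -> float:
    """Population-averaged incidence as a multiple of the confounder-negative
    incidence I_0: ``prev·R + (1 − prev)``."""
    if not (0 <= prev <= 1):
        raise ValueError(f"prevalence must be in [0, 1], got {prev}")
    if rr_confounder <= 0:
        raise ValueError("rr_confounder must be positive")
    return prev * rr_confounder + (1.0 - prev)


def bias_factor(scenario: ConfoundingScenario) -> float:
    """Ratio of the cohort incidence multiplier to the reference multiplier."""
    return incidence_multiplier(
        scenario.prev_cohort, scenario.rr_confounder
    ) / incidence_multiplier(scenario.prev_reference, scenario.rr_confounder)


def adjust_estimate(study: StudyEstimate, bf: float) -> AdjustedEstimate:
    """Divide the estimate and both CI limits by the bias factor ``bf``.

    The bias factor is treated as known without error, so the CI width ratio
    ``ci_high/ci_low`` is preserved.
    """
    if bf <= 0:
        raise ValueError("bias factor must be positive")
    return AdjustedEstimate(
        source=study,
        bias_factor=bf,
        estimate_adj=study.estimate / bf,
        ci_low_adj=study.ci_low / bf,
        ci_high_adj=study.ci_high / bf,
    )


def scenario_grid(
    study: StudyEstimate, scenarios: Sequence[ConfoundingScenario]
) -> list[tuple[BiasFactorRow, AdjustedEstimate]]:
    """Evaluate the sensitivity analysis over a scenario grid, in given order."""
    if not scenarios:
        raise ValueError("scenario grid must be non-empty")
    rows = []
    for sc in scenarios:
        m_ref = incidence_multiplier(sc.prev_reference, sc.rr_confounder)
        m_coh = incidence_multiplier(sc.prev_cohort, sc.rr_confounder)
        bf = m_coh / m_ref
        rows.append(
            (
                BiasFactorRow(sc, m_ref, m_coh, bf),
                adjust_estimate(study, bf),
            )
        )
    return rows
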