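"""Seeded generators producing inputs with the statistical structure each
pipeline stage assumes.

Every generator is a pure function of its spec (the mandatory seed
included), so identical specs give identical output and cross-module
pipelines are reproducible end to end.  Study effects for meta-analysis
tests are drawn on the *linear* ratio scale, consistent with the pipeline's
linear-scale pooling.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .bmd import multistage_prob
from .fixtures_io import BioassayDataset, BioassayGroup, StudyEstimate
from .meta import Z_95, MetaInput
from .misclass import TwoByTwo, _reclassify

__all__ = [
    "CohortSpec",
    "BioassaySpec",
    "CohortTables",
    "gen_cohort",
    "gen_bioassay",
    "gen_study_set",
]


@dataclass(frozen=True)
class CohortSpec:
    """A closed cohort with binary exposure and misclassified assessment."""

    n_total: int
    p_exposed: float
    incidence_unexposed: float
    rr_true: float
    sensitivity: float
    specificity: float
    seed: int

    def __post_init__(self) -> None:
        if self.n_total < 2:
            raise ValueError("n_total must be at least 2")
        if not (0 < self.p_exposed < 1):
            raise ValueError("p_exposed must be in (0, 1)")
        if not (0 < self.incidence_unexposed < 1):
            raise ValueError("incidence_unexposed must be in (0, 1)")
        if self.rr_true <= 0:
            raise ValueError("rr_true must be positive")
        for name in ("sensitivity", "specificity"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must be in (0, 1]")


@dataclass(frozen=True)
class BioassaySpec:
    """A quantal bioassay generated from known multistage parameters."""

    gamma: float
    betas: tuple[float, ...]
    doses: tuple[float, ...]
    n_per_group: int
    seed: int

    def __post_init__(self) -> None:
        if not (0 <= self.gamma < 1):
            raise ValueError("gamma must be in [0, 1)")
        if any(b < 0 for b in self.betas):
            raise ValueError("betas must be non-negative")
        if self.doses[0] != 0:
            raise ValueError("first dose must be 0 (control)")
        if any(b <= a for a, b in zip(self.doses, self.doses[1:])):
            raise ValueError("doses must be strictly increasing")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be at least 1")


@dataclass(frozen=True)
class CohortTables:
    """True and misclassified 2×2 tables from one generated cohort."""

    true: TwoByTwo
    observed: TwoByTwo
    small_cell_warning: bool  # an expected cell fell below 1


def gen_cohort(spec: CohortSpec) -> CohortTables:
    """Generate one cohort: binomial case counts, then non-differential
    exposure misclassification at (Se, Sp).  Both tables are returned so
    correction methods can be scored against the known truth."""
    rng = np.random.default_rng(spec.seed)
    n1 = int(round(spec.n_total * spec.p_exposed))
    n0 = spec.n_total - n1
    p1 = min(spec.incidence_unexposed * spec.rr_true, 1.0)
    cases_exp = int(rng.binomial(n1, p1))
    cases_unexp = int(rng.binomial(n0, spec.incidence_unexposed))
    true = TwoByTwo(cases_exp, cases_unexp, n1, n0)
    observed = TwoByTwo(
        *_reclassify(
            cases_exp,
            cases_unexp,
            n1 - cases_exp,
            n0 - cases_unexp,
            spec.sensitivity,
            spec.specificity,
            rng,
        )
    )
    expected_cells = (
        n1 * p1,
        n0 * spec.incidence_unexposed,
        n1 * (1 - p1),
        n0 * (1 - spec.incidence_unexposed),
    )
    return CohortTables(
        true=true,
        observed=observed,
        small_cell_warning=any(c < 1 for c in expected_cells),
    )


def gen_bioassay(spec: BioassaySpec) -> BioassayDataset:
    """Generate per-group affected counts ~ Binomial(n, multistage P(dose))."""
    rng = np.random.default_rng(spec.seed)
    groups = []
    for dose in spec.doses:
        p = multistage_prob(spec.gamma, spec.betas, dose)
        groups.append(
            BioassayGroup(dose, spec.n_per_group, int(rng.binomial(spec.n_per_group, p)))
        )
    return BioassayDataset(f"synthetic-seed{spec.seed}", tuple(groups))


def gen_study_set(
    k: int,
    mu: float,
    tau2: float,
    se_range: tuple[float, float],
    seed: int,
    max_retries: int = 1000,
) -> list[MetaInput]:
    """Generate k study estimates with between-study variance τ².

    Effects are Normal(mu, τ² + se_i²) on the linear ratio scale with se_i
    uniform in ``se_range``; CIs are estimate ± 1.96·se_i.  Non-positive
    draws (which cannot be ratio estimates) are redrawn, with bounded
    retries.
    """
    if k < 2:
        raise ValueError("need at least 2 studies")
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    rng = np.random.default_rng(seed)
    inputs = []
    for i in range(k):
        se = float(rng.uniform(*se_range))
        sd = np.sqrt(tau2 + se**2)
        for _ in range(max_retries):
            est = float(rng.normal(mu, sd))
            if est > 0 and est - Z_95 * se > 0:
                break
        else:
            raise RuntimeError(
                f"could not draw a positive estimate for study {i} "
                f"(mu={mu}, tau2={tau2}, se={se:g})"
            )
        study = StudyEstimate(
            f"synthetic-{i}", "RR", est, est - Z_95 * se, est + Z_95 * se, "human"
        )
        inputs.append(MetaInput(study=study, se=se))
    return inputs
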