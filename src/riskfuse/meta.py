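"""Fixed-effect and DerSimonian-Laird random-effects pooling on the linear
RR scale, with Cochran's Q heterogeneity test.

Pooling is on the *linear* ratio scale by default: per-study standard
errors are recovered from the symmetric 95% CIs as (ci_high − ci_low)/(2z)
with z fixed at 1.96, weights are inverse-variance, and Cochran's Q feeds
the DL between-study variance τ² = max(0, (Q − df)/(Σw − Σw²/Σw)).  A
log-scale option is provided but off by default: the linear construction is
what reproduces the pooled estimates and symmetric CIs this pipeline
targets.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import chi2

from .fixtures_io import StudyEstimate

__all__ = [
    "Z_95",
    "MetaInput",
    "MetaResult",
    "se_from_ci",
    "as_meta_inputs",
    "pool_fixed",
    "pool_random_dl",
    "reproduce_table7",
]

#: Normal quantile used for both SE extraction and pooled CIs.
Z_95 = 1.96


@dataclass(frozen=True)
class MetaInput:
    """A study estimate with its standard error on the pooling scale."""

    study: StudyEstimate
    se: float

    def __post_init__(self) -> None:
        if self.se <= 0:
            raise ValueError(f"{self.study.label}: standard error must be positive")


@dataclass(frozen=True)
class MetaResult:
    """A pooled estimate with heterogeneity diagnostics and weights."""

    model: str  # "fixed" or "random"
    pooled: float
    ci: tuple[float, float]
    q: float
    df: int
    p_heterogeneity: float
    tau2: float
    weights: tuple[float, ...]


def se_from_ci(
    estimate: float, ci_low: float, ci_high: float, level: float = 0.95
) -> float:
    """Standard error implied by a symmetric CI: (ci_high − ci_low)/(2z)."""
    if ci_low > ci_high:
        raise ValueError(f"inverted CI ({ci_low}, {ci_high})")
    if level == 0.95:
        z = Z_95
    else:
        from scipy.stats import norm

        z = norm.ppf(0.5 + level / 2.0)
    return (ci_high - ci_low) / (2.0 * z)


def as_meta_inputs(
    studies: Sequence[StudyEstimate], scale: str = "linear"
) -> list[MetaInput]:
    """Convert study estimates to meta-analysis inputs on the chosen scale."""
    if scale not in {"linear", "log"}:
        raise ValueError("scale must be 'linear' or 'log'")
    inputs = []
    for s in studies:
        if scale == "linear":
            se = se_from_ci(s.estimate, s.ci_low, s.ci_high)
        else:
            se = se_from_ci(
                math.log(s.estimate), math.log(s.ci_low), math.log(s.ci_high)
            )
        inputs.append(MetaInput(study=s, se=se))
    return inputs


def _effects(inputs: Sequence[MetaInput], scale: str) -> np.ndarray:
    x = np.array([i.study.estimate for i in inputs], dtype=float)
    return np.log(x) if scale == "log" else x


def _finalize(pooled: float, half: float, scale: str) -> tuple[float, tuple[float, float]]:
    if scale == "log":
        return math.exp(pooled), (math.exp(pooled - half), math.exp(pooled + half))
    return pooled, (pooled - half, pooled + half)


def pool_fixed(inputs: Sequence[MetaInput], scale: str = "linear") -> MetaResult:
    """Inverse-variance fixed-effect pool with Cochran's Q."""
    if len(inputs) < 2:
        raise ValueError("meta-analysis needs at least 2 studies")
    x = _effects(inputs, scale)
    w = np.array([1.0 / i.se**2 for i in inputs])
    W = w.sum()
    mu = float((w * x).sum() / W)
    q = float((w * (x - mu) ** 2).sum())
    df = len(inputs) - 1
    pooled, ci = _finalize(mu, Z_95 / math.sqrt(W), scale)
    return MetaResult(
        model="fixed",
        pooled=pooled,
        ci=ci,
        q=q,
        df=df,
        p_heterogeneity=float(chi2.sf(q, df)),
        tau2=0.0,
        weights=tuple(float(v) for v in w),
    )


def pool_random_dl(inputs: Sequence[MetaInput], scale: str = "linear") -> MetaResult:
    """DerSimonian-Laird random-effects pool.

    τ² is the moment estimator from the fixed-effect pass, truncated at 0;
    random-effects weights are 1/(se² + τ²).
    """
    fixed = pool_fixed(inputs, scale)
    x = _effects(inputs, scale)
    w = np.array(fixed.weights)
    W = w.sum()
    denom = W - (w**2).sum() / W
    tau2 = max(0.0, (fixed.q - fixed.df) / denom) if denom > 0 else 0.0
    ws = np.array([1.0 / (i.se**2 + tau2) for i in inputs])
    Ws = ws.sum()
    mu = float((ws * x).sum() / Ws)
    pooled, ci = _finalize(mu, Z_95 / math.sqrt(Ws), scale)
    return MetaResult(
        model="random",
        pooled=pooled,
        ci=ci,
        q=fixed.q,
        df=fixed.df,
        p_heterogeneity=fixed.p_heterogeneity,
        tau2=tau2,
        weights=tuple(float(v) for v in ws),
    )


def reproduce_table7(
    meta_inputs: dict[str, list[StudyEstimate]], scale: str = "linear"
) -> dict[str, MetaResult]:
    """Pool the shipped bias-adjusted (and unadjusted) estimate sets.

    ``meta_inputs`` is the mapping returned by
    ``load_fixture("meta_inputs")``: keys human_adjusted, human_unadjusted
    and animal.  Returns fixed and DL-random pools for the human set
    (adjusted and unadjusted), the animal set, and the combined six-study
    sets.
    """
    human_adj = as_meta_inputs(meta_inputs["human_adjusted"], scale)
    human_un = as_meta_inputs(meta_inputs["human_unadjusted"], scale)
    animal = as_meta_inputs(meta_inputs["animal"], scale)
    sets = {
        "human_adjusted": human_adj,
        "human_unadjusted": human_un,
        "animal": animal,
        "all_adjusted": human_adj + animal,
        "all_unadjusted": human_un + animal,
    }
    out: dict[str, MetaResult] = {}
    for name, inputs in sets.items():
        out[f"{name}_fixed"] = pool_fixed(inputs, scale)
        out[f"{name}_random"] = pool_random_dl(inputs, scale)
    return out
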