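"""Quantal multistage dose-response fitting, benchmark dose, and
profile-likelihood BMDL.

The multistage model for a quantal endpoint is

    P(d) = γ + (1 − γ)·(1 − exp(−β₁·d − β₂·d² − ... − β_k·d^k)),

with background probability γ ∈ [0, 1) and non-negative stage coefficients,
so predicted probabilities are non-decreasing in dose.  Parameters are
estimated by maximizing the binomial log-likelihood with deterministic
multi-start constrained optimization (doses are rescaled internally by the
maximum dose so coefficients are well-scaled).

The benchmark dose (BMD) at benchmark response ``bmr`` solves the *extra
risk* equation [P(B) − P(0)]/[1 − P(0)] = bmr, i.e.
1 − exp(−Σ β_j·B^j) = bmr, which for degree ≤ 2 has a closed form.  The
BMDL is the one-sided lower profile-likelihood confidence limit: the
smallest dose B* whose constrained maximum log-likelihood (BMD pinned at B*,
coefficients non-negative) stays within χ²₁(2·confidence − 1)/2 of the
unconstrained maximum — 1.35277 for the default one-sided 95% level.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize, nnls
from scipy.special import gammaln
from scipy.stats import chi2

from .fixtures_io import BioassayDataset

__all__ = [
    "MultistageFit",
    "BmdResult",
    "DegreeSelection",
    "multistage_prob",
    "fit_multistage",
    "select_degree",
    "bmd_from_fit",
    "bmdl_profile",
    "benchmark_dose",
]

_GAMMA_MAX = 1.0 - 1e-9
_P_FLOOR = 1e-12


@dataclass(frozen=True)
class MultistageFit:
    """A fitted multistage model with its likelihood diagnostics."""

    degree: int
    gamma: float
    betas: tuple[float, ...]  # per (μg/m³)^j, j = 1..degree
    log_likelihood: float
    aic: float
    n_params: int
    scaled_residuals: tuple[float, ...]


@dataclass(frozen=True)
class BmdResult:
    """Benchmark dose and its lower confidence limit for one dataset."""

    fit: MultistageFit
    bmr: float
    bmd: float
    bmdl: float
    confidence: float

    def __post_init__(self) -> None:
        if not (0 < self.bmdl <= self.bmd):
            raise ValueError(f"BMDL {self.bmdl} must be in (0, BMD={self.bmd}]")


@dataclass(frozen=True)
class DegreeSelection:
    """AIC table and successive likelihood-ratio tests over model degrees."""

    chosen: int
    fits: dict[int, MultistageFit]
    lrt_pvalues: dict[int, float]  # degree k -> p-value of k vs k−1 (χ², 1 df)


def multistage_prob(gamma: float, betas: Sequence[float], dose) -> np.ndarray | float:
    """Multistage response probability γ + (1−γ)(1 − exp(−Σ βⱼ·doseʲ))."""
    d = np.asarray(dose, dtype=float)
    s = np.zeros_like(d)
    for j, b in enumerate(betas, start=1):
        s = s + b * d**j
    p = gamma + (1.0 - gamma) * (1.0 - np.exp(-s))
    return float(p) if np.isscalar(dose) else p


def _neg_ll(theta: np.ndarray, u: np.ndarray, n: np.ndarray, x: np.ndarray) -> float:
    """Negative binomial log-likelihood kernel in scaled-dose parameters."""
    g = theta[0]
    s = np.zeros_like(u)
    for j, b in enumerate(theta[1:], start=1):
        s = s + b * u**j
    p = g + (1.0 - g) * (1.0 - np.exp(-s))
    p = np.clip(p, _P_FLOOR, 1.0 - _P_FLOOR)
    return -float(np.sum(x * np.log(p) + (n - x) * np.log1p(-p)))


def _ll_constant(n: np.ndarray, x: np.ndarray) -> float:
    """Binomial coefficient term, so reported LL is a full log-likelihood."""
    return float(np.sum(gammaln(n + 1) - gammaln(x + 1) - gammaln(n - x + 1)))


def _starts(u: np.ndarray, n: np.ndarray, x: np.ndarray, k: int) -> list[np.ndarray]:
    """Deterministic multistart list: an NNLS-transform start plus a coarse grid."""
    p_obs = x / n
    g0 = float(np.clip(p_obs[0], 1e-4, 0.5))
    starts: list[np.ndarray] = []

    # transform start: extra risk per positive-dose group, linearized on the
    # cumulative-hazard scale, solved by non-negative least squares
    pos = u > 0
    if pos.any():
        extra = np.clip((p_obs[pos] - g0) / (1.0 - g0), 1e-6, 1.0 - 1e-6)
        hazard = -np.log1p(-extra)
        V = np.column_stack([u[pos] ** j for j in range(1, k + 1)])
        coef, _ = nnls(V, hazard)
        starts.append(np.concatenate([[g0], coef]))

    for g in (1e-3, g0, 0.1):
        for combo in itertools.product((0.0, 0.05, 0.5), repeat=k):
            starts.append(np.array([g, *combo]))
    return starts


def fit_multistage(data: BioassayDataset, degree: int) -> MultistageFit:
    """Maximum-likelihood multistage fit of the given degree.

    Maximizes the binomial log-likelihood over (γ, β₁..β_k) subject to
    βⱼ ≥ 0 and 0 ≤ γ < 1, using a fixed list of deterministic starts
    (L-BFGS-B) with a Nelder-Mead polish of the best solution.
    """
    if degree < 1:
        raise ValueError("degree must be at least 1")
    d = np.asarray(data.doses, dtype=float)
    n = np.asarray(data.n_examined, dtype=float)
    x = np.asarray(data.n_affected, dtype=float)
    dmax = d.max()
    u = d / dmax

    bounds = [(0.0, _GAMMA_MAX)] + [(0.0, None)] * degree
    best = None
    for s0 in _starts(u, n, x, degree):
        res = minimize(
            _neg_ll,
            np.clip(s0, [b[0] for b in bounds], [b[1] if b[1] is not None else np.inf for b in bounds]),
            args=(u, n, x),
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 2000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    # Nelder-Mead polish in the interior; project back onto the bounds after
    polish = minimize(
        lambda t: _neg_ll(np.clip(t, [b[0] for b in bounds], np.inf), u, n, x),
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 5000, "xatol": 1e-12, "fatol": 1e-13},
    )
    theta = np.clip(polish.x, [b[0] for b in bounds], np.inf)
    fun = _neg_ll(theta, u, n, x)
    if best.fun < fun:
        theta, fun = np.clip(best.x, [b[0] for b in bounds], np.inf), best.fun
    if not np.isfinite(fun):
        raise RuntimeError(
            f"multistage fit failed to converge for {data.label!r} degree {degree}"
        )

    gamma = float(theta[0])
    betas = tuple(float(t) / dmax**j for j, t in enumerate(theta[1:], start=1))
    ll = -fun + _ll_constant(n, x)
    n_params = 1 + degree
    p_hat = multistage_prob(gamma, betas, d)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (x - n * p_hat) / np.sqrt(n * p_hat * (1.0 - p_hat))
    return MultistageFit(
        degree=degree,
        gamma=gamma,
        betas=betas,
        log_likelihood=ll,
        aic=2.0 * n_params - 2.0 * ll,
        n_params=n_params,
        scaled_residuals=tuple(float(r) for r in resid),
    )


def select_degree(data: BioassayDataset, max_degree: int) -> DegreeSelection:
    """Fit degrees 1..max_degree; choose the minimum-AIC degree.

    Ties (within 1e-9) break toward the lower degree.  Successive
    likelihood-ratio tests (χ², 1 df) are reported alongside.
    """
    if max_degree < 1:
        raise ValueError("max_degree must be at least 1")
    fits = {k: fit_multistage(data, k) for k in range(1, max_degree + 1)}
    lrt = {
        k: float(
            chi2.sf(
                max(0.0, 2.0 * (fits[k].log_likelihood - fits[k - 1].log_likelihood)),
                1,
            )
        )
        for k in range(2, max_degree + 1)
    }
    chosen = min(fits, key=lambda k: (round(fits[k].aic, 9), k))
    return DegreeSelection(chosen=chosen, fits=fits, lrt_pvalues=lrt)


def _bmd_from_betas(betas: Sequence[float], bmr: float) -> float:
    A = -np.log1p(-bmr)
    betas = list(betas)
    if not any(b > 0 for b in betas):
        raise ValueError("no dose response: all stage coefficients are zero")
    if len(betas) == 1:
        return A / betas[0]
    if len(betas) == 2:
        b1, b2 = betas
        if b2 <= 0:
            return A / b1
        return (-b1 + np.sqrt(b1 * b1 + 4.0 * b2 * A)) / (2.0 * b2)
    # general degree: smallest positive real root of Σ βⱼ·B^j − A = 0
    coeffs = list(reversed([-A] + betas))
    roots = np.roots(coeffs)
    real = [r.real for r in roots if abs(r.imag) < 1e-9 * max(1.0, abs(r)) and r.real > 0]
    if not real:
        raise ValueError("benchmark-dose equation has no positive root")
    return float(min(real))


def bmd_from_fit(fit: MultistageFit, bmr: float) -> float:
    """Benchmark dose at extra risk ``bmr``: solves 1 − exp(−Σ βⱼ·Bʲ) = bmr."""
    if not (0 < bmr < 1):
        raise ValueError("bmr must be in (0, 1)")
    return _bmd_from_betas(fit.betas, bmr)


def _profile_ll(
    b_scaled: float,
    u: np.ndarray,
    n: np.ndarray,
    x: np.ndarray,
    k: int,
    A: float,
    warm: list,
) -> float:
    """Maximum log-likelihood kernel with the BMD pinned at ``b_scaled``.

    β₁ is eliminated through the pinned-BMD constraint
    Σ θⱼ·Bʲ = A; remaining coefficients are box-bounded so θ₁ ≥ 0.
    """

    def expand(q: np.ndarray) -> np.ndarray:
        g = q[0]
        rest = q[1:]
        t1 = (A - sum(t * b_scaled ** (j + 2) for j, t in enumerate(rest))) / b_scaled
        return np.concatenate([[g], [t1], rest])

    def obj(q: np.ndarray) -> float:
        theta = expand(q)
        if theta[1] < 0:
            return 1e8 * (1.0 + theta[1] ** 2)
        return _neg_ll(theta, u, n, x)

    bounds = [(0.0, _GAMMA_MAX)] + [
        (0.0, A / b_scaled ** (j + 2)) for j in range(k - 1)
    ]
    starts = list(warm)
    g0 = float(np.clip(x[0] / n[0], 1e-4, 0.5))
    starts.append(np.array([g0] + [0.0] * (k - 1)))
    if k >= 2:
        starts.append(np.array([g0] + [0.9 * A / b_scaled ** (j + 2) for j in range(k - 1)]))
    best = None
    for s0 in starts:
        s0 = np.clip(s0, [b[0] for b in bounds], [b[1] for b in bounds])
        res = minimize(
            obj,
            s0,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": 1000, "ftol": 1e-14, "gtol": 1e-10},
        )
        if best is None or res.fun < best.fun:
            best = res
    polish = minimize(
        lambda q: obj(np.clip(q, [b[0] for b in bounds], [b[1] for b in bounds])),
        best.x,
        method="Nelder-Mead",
        options={"maxiter": 2000, "xatol": 1e-12, "fatol": 1e-13},
    )
    q = np.clip(polish.x, [b[0] for b in bounds], [b[1] for b in bounds])
    fun = min(best.fun, obj(q))
    warm[:] = [np.clip(polish.x, [b[0] for b in bounds], [b[1] for b in bounds])]
    return -fun


def bmdl_profile(
    data: BioassayDataset,
    fit: MultistageFit,
    bmr: float,
    confidence: float = 0.95,
    rtol: float = 1e-6,
) -> float:
    """One-sided profile-likelihood lower confidence limit on the BMD.

    Finds the largest B* below the BMD at which the constrained maximum
    log-likelihood equals ``LL_max − χ²₁(2·confidence − 1)/2`` (1.35277 at
    the default one-sided 95%), by bisection on B* with an inner constrained
    maximization warm-started between bisection steps.
    """
    if not (0.5 < confidence < 1):
        raise ValueError("confidence must be in (0.5, 1)")
    d = np.asarray(data.doses, dtype=float)
    n = np.asarray(data.n_examined, dtype=float)
    x = np.asarray(data.n_affected, dtype=float)
    dmax = d.max()
    u = d / dmax
    k = fit.degree
    A = -np.log1p(-bmr)
    cutoff = chi2.ppf(2.0 * confidence - 1.0, 1) / 2.0

    bmd = bmd_from_fit(fit, bmr)
    bmd_s = bmd / dmax
    ll_kernel_max = fit.log_likelihood - _ll_constant(n, x)
    target = ll_kernel_max - cutoff

    warm: list = []
    # bracket: step down from the BMD until the profile drops below the target
    hi = bmd_s
    lo = bmd_s * 0.8
    for _ in range(60):
        if _profile_ll(lo, u, n, x, k, A, warm) < target:
            break
        hi = lo
        lo *= 0.8
    else:
        raise RuntimeError(
            f"could not bracket the BMDL for {data.label!r} (profile never "
            "crossed the confidence cutoff)"
        )
    while (hi - lo) > rtol * bmd_s:
        mid = 0.5 * (lo + hi)
        if _profile_ll(mid, u, n, x, k, A, warm) < target:
            lo = mid
        else:
            hi = mid
    return float(0.5 * (lo + hi) * dmax)


def benchmark_dose(
    data: BioassayDataset,
    degree: int | str = "auto",
    bmr: float = 0.10,
    confidence: float = 0.95,
    max_degree: int = 2,
) -> BmdResult:
    """Fit (with optional AIC degree selection), then compute BMD and BMDL."""
    if degree == "auto":
        selection = select_degree(data, max_degree)
        fit = selection.fits[selection.chosen]
    else:
        fit = fit_multistage(data, int(degree))
    bmd = bmd_from_fit(fit, bmr)
    bmdl = bmdl_profile(data, fit, bmr, confidence)
    return BmdResult(fit=fit, bmr=bmr, bmd=bmd, bmdl=bmdl, confidence=confidence)
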