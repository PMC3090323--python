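"""Linear low-dose extrapolation from the BMDL point of departure.

A line y = β₀ + β₁·x through two points — (0, control fraction affected)
and (BMDL, 0.10, the benchmark response fixed by design) — converts a rat
bioassay's point of departure into a human-equivalent risk ratio at an
ambient concentration d:

    RR(d) = (β₀ + β₁·d) / β₀.

The default target is 65 μg/m³, the 1997 24-hour fine-particle standard.
The published CIs attached for meta-analysis are exogenous fixture
inputs: their derivation is not reconstructable, so they ship as data.
"""

from __future__ import annotations

from dataclasses import dataclass

from .fixtures_io import StudyEstimate

__all__ = [
    "ExtrapolationResult",
    "DEFAULT_TARGET_DOSE",
    "pod_line",
    "rr_at_dose",
    "extrapolate_rr",
    "attach_ci",
]

#: Default ambient target concentration (μg/m³).
DEFAULT_TARGET_DOSE = 65.0


@dataclass(frozen=True)
class ExtrapolationResult:
    """A POD line evaluated at a target dose."""

    intercept: float  # background affected fraction (β₀)
    slope: float  # affected fraction per μg/m³ (β₁)
    target_dose: float
    rr: float
    ci: tuple[float, float] | None = None


def pod_line(control_fraction: float, bmdl: float, bmr: float) -> tuple[float, float]:
    """Line through (0, control_fraction) and (BMDL, bmr).

    Returns (intercept, slope).  Requires 0 < control_fraction < bmr: a zero
    control fraction makes the extrapolated RR undefined (division by β₀),
    and a control response at or above the benchmark response leaves no
    room for a positive slope.
    """
    if bmdl <= 0:
        raise ValueError("bmdl must be positive")
    if control_fraction <= 0:
        raise ValueError(
            "control fraction must be positive (RR undefined at zero background)"
        )
    if control_fraction >= bmr:
        raise ValueError(
            f"control fraction {control_fraction:g} must be below the benchmark "
            f"response {bmr:g}"
        )
    return control_fraction, (bmr - control_fraction) / bmdl


def rr_at_dose(line: tuple[float, float], target_dose: float) -> float:
    """Evaluate RR(d) = (β₀ + β₁·d)/β₀ on a POD line."""
    if target_dose < 0:
        raise ValueError("target_dose must be non-negative")
    intercept, slope = line
    return (intercept + slope * target_dose) / intercept


def extrapolate_rr(
    control_fraction: float,
    bmdl: float,
    bmr: float = 0.10,
    target_dose: float = DEFAULT_TARGET_DOSE,
) -> ExtrapolationResult:
    """POD line and RR at the target dose in one step."""
    line = pod_line(control_fraction, bmdl, bmr)
    return ExtrapolationResult(
        intercept=line[0],
        slope=line[1],
        target_dose=target_dose,
        rr=rr_at_dose(line, target_dose),
    )


def attach_ci(
    result: ExtrapolationResult, ci: tuple[float, float], label: str
) -> StudyEstimate:
    """Package an extrapolated RR with a CI as an animal StudyEstimate."""
    lo, hi = ci
    if not (lo <= result.rr <= hi):
        raise ValueError(
            f"CI ({lo}, {hi}) does not bracket the extrapolated RR {result.rr:g}"
        )
    return StudyEstimate(label, "RR", result.rr, lo, hi, "animal")
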