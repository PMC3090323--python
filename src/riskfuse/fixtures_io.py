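"""Canonical study data, exposure standardization, and tabular I/O.

The package ships the published occupational-study effect estimates and the
rat inhalation-bioassay dose-response tables as validated in-package CSV
fixtures.  Exposure regimens from the bioassays are put on a common metric
proportional to cumulative exposure: the 30-month average continuous
concentration in μg/m³.  The rounded continuous-equivalent doses shipped in
the bioassay fixture (930, 2400, 270, ... μg/m³) are canonical for all
downstream fitting; :func:`standardize_exposure` exists for new regimens.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "StudyEstimate",
    "ExposureRegimen",
    "BioassayGroup",
    "BioassayDataset",
    "FULL_WEEK_HOURS",
    "REFERENCE_MONTHS",
    "standardize_exposure",
    "load_fixture",
    "write_table",
    "read_table",
    "FIXTURE_NAMES",
]

#: Hours in a calendar week; denominator of the duty-cycle fraction.
FULL_WEEK_HOURS = 168.0
#: Reference averaging period (months) for the continuous-equivalent metric.
REFERENCE_MONTHS = 30.0


@dataclass(frozen=True)
class StudyEstimate:
    """A ratio-scale effect estimate (RR, SMR or OR) with its 95% CI."""

    label: str
    measure_kind: str  # one of {"RR", "SMR", "OR"}
    estimate: float
    ci_low: float
    ci_high: float
    population: str  # "human" or "animal"

    def __post_init__(self) -> None:
        if self.measure_kind not in {"RR", "SMR", "OR"}:
            raise ValueError(f"unknown measure kind {self.measure_kind!r}")
        if self.population not in {"human", "animal"}:
            raise ValueError(f"unknown population {self.population!r}")
        if not (self.ci_low > 0 and self.estimate > 0 and self.ci_high > 0):
            raise ValueError("estimate and CI limits must be strictly positive")
        if not (self.ci_low <= self.estimate <= self.ci_high):
            raise ValueError(
                f"{self.label}: CI ({self.ci_low}, {self.ci_high}) does not "
                f"bracket the estimate {self.estimate}"
            )


@dataclass(frozen=True)
class ExposureRegimen:
    """An inhalation exposure schedule: concentration, duty cycle, duration."""

    concentration: float  # μg/m³ during exposure
    hours_per_week: float
    months: float

    def __post_init__(self) -> None:
        if self.concentration < 0:
            raise ValueError("concentration must be non-negative")
        if not (0 < self.hours_per_week <= FULL_WEEK_HOURS):
            raise ValueError("hours_per_week must be in (0, 168]")
        if self.months <= 0:
            raise ValueError("months must be positive")


@dataclass(frozen=True)
class BioassayGroup:
    """One quantal dose group: continuous-equivalent dose, n examined, n affected."""

    dose: float  # 30-month continuous-equivalent μg/m³
    n_examined: int
    n_affected: int

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be non-negative")
        if self.n_examined <= 0:
            raise ValueError("n_examined must be positive")
        if not (0 <= self.n_affected <= self.n_examined):
            raise ValueError("n_affected must be in [0, n_examined]")

    @property
    def fraction_affected(self) -> float:
        return self.n_affected / self.n_examined


@dataclass(frozen=True)
class BioassayDataset:
    """An ordered quantal dose-response study with a zero-dose control group."""

    label: str
    groups: tuple[BioassayGroup, ...]

    def __post_init__(self) -> None:
        groups = tuple(self.groups)
        object.__setattr__(self, "groups", groups)
        if len(groups) < 3:
            raise ValueError(f"{self.label}: need at least 3 dose groups")
        doses = [g.dose for g in groups]
        if doses[0] != 0:
            raise ValueError(f"{self.label}: first group must be the zero-dose control")
        if sum(d == 0 for d in doses) != 1:
            raise ValueError(f"{self.label}: exactly one zero-dose group required")
        if any(b <= a for a, b in zip(doses, doses[1:])):
            raise ValueError(f"{self.label}: doses must be strictly increasing")

    @property
    def doses(self) -> tuple[float, ...]:
        return tuple(g.dose for g in self.groups)

    @property
    def n_examined(self) -> tuple[int, ...]:
        return tuple(g.n_examined for g in self.groups)

    @property
    def n_affected(self) -> tuple[int, ...]:
        return tuple(g.n_affected for g in self.groups)

    @property
    def control_fraction(self) -> float:
        """Fraction affected in the zero-dose control group."""
        return self.groups[0].fraction_affected


def standardize_exposure(regimen: ExposureRegimen) -> float:
    """Convert an exposure regimen to its 30-month continuous-equivalent
    concentration (μg/m³).

    The metric is proportional to cumulative exposure:
    ``concentration × (hours_per_week / 168) × (months / 30)``.
    E.g. 700 μg/m³ for 80 h/week over 24 months → 266.67 μg/m³ continuous.
    """
    return (
        regimen.concentration
        * (regimen.hours_per_week / FULL_WEEK_HOURS)
        * (regimen.months / REFERENCE_MONTHS)
    )


# ---------------------------------------------------------------------------
# Fixture loading

FIXTURE_NAMES = (
    "human_studies",
    "animal_bioassays",
    "confounding_grids",
    "misclass_grid",
    "meta_inputs",
    "table6",
)


def _data(name: str) -> pd.DataFrame:
    with resources.files("riskfuse.data").joinpath(name).open("r") as fh:
        return pd.read_csv(fh)


def load_fixture(name: str):
    """Load a named packaged fixture as validated domain objects.

    ``human_studies``     -> dict[label, StudyEstimate]
    ``animal_bioassays``  -> dict[label, BioassayDataset]
    ``confounding_grids`` -> dict[study, list[ConfoundingScenario]]
    ``misclass_grid``     -> list[MisclassScenario]
    ``meta_inputs``       -> dict with keys human_adjusted / human_unadjusted /
                             animal, each a list[StudyEstimate]
    ``table6``            -> dict[label, dict] with keys bmd, bmdl, estimate
                             (the extrapolated RR as a StudyEstimate)
    """
    if name == "human_studies":
        df = _data("human_studies.csv")
        return {
            r.label: StudyEstimate(
                r.label, r.measure_kind, r.estimate, r.ci_low, r.ci_high, r.population
            )
            for r in df.itertuples()
        }
    if name == "animal_bioassays":
        df = _data("animal_bioassays.csv")
        out: dict[str, BioassayDataset] = {}
        for label, sub in df.groupby("label", sort=False):
            groups = tuple(
                BioassayGroup(r.dose, int(r.n_examined), int(r.n_affected))
                for r in sub.itertuples()
            )
            out[label] = BioassayDataset(label, groups)
        return out
    if name == "confounding_grids":
        from .confounding import ConfoundingScenario

        df = _data("confounding_grids.csv")
        return {
            study: [
                ConfoundingScenario(r.rr_confounder, r.prev_cohort, r.prev_reference)
                for r in sub.itertuples()
            ]
            for study, sub in df.groupby("study", sort=False)
        }
    if name == "misclass_grid":
        from .misclass import MisclassScenario

        df = _data("misclass_grid.csv")
        return [
            MisclassScenario(r.p_exposed, r.sensitivity, r.specificity)
            for r in df.itertuples()
        ]
    if name == "meta_inputs":
        df = _data("meta_inputs.csv")

        def pick(population: str, adjusted: str) -> list[StudyEstimate]:
            sub = df[(df.population == population) & (df.adjusted == adjusted)]
            kinds = {"garshick": "RR", "wellmann": "SMR", "gustavsson": "RR"}
            return [
                StudyEstimate(
                    r.label,
                    kinds.get(r.label, "RR"),
                    r.estimate,
                    r.ci_low,
                    r.ci_high,
                    r.population,
                )
                for r in sub.itertuples()
            ]

        return {
            "human_adjusted": pick("human", "adjusted"),
            "human_unadjusted": pick("human", "unadjusted"),
            "animal": pick("animal", "adjusted"),
        }
    if name == "table6":
        df = _data("table6.csv")
        return {
            r.label: {
                "bmd": r.bmd,
                "bmdl": r.bmdl,
                "estimate": StudyEstimate(
                    r.label, "RR", r.rr, r.ci_low, r.ci_high, "animal"
                ),
            }
            for r in df.itertuples()
        }
    raise KeyError(
        f"unknown fixture {name!r}; known fixtures: {', '.join(FIXTURE_NAMES)}"
    )


# ---------------------------------------------------------------------------
# Tabular I/O


def _to_records(rows: Iterable) -> list[dict]:
    records = []
    for row in rows:
        if isinstance(row, dict):
            records.append(dict(row))
        elif hasattr(row, "__dataclass_fields__"):
            from dataclasses import asdict

            records.append(asdict(row))
        else:
            raise TypeError(f"cannot convert row of type {type(row).__name__}")
    keys = [tuple(r.keys()) for r in records]
    if keys and any(k != keys[0] for k in keys):
        raise ValueError("all rows must share the same schema")
    return records


def write_table(
    rows: Iterable, destination: str | Path, format: str = "CSV", columns: Sequence[str] | None = None
) -> None:
    """Write structured records as CSV (one-line header, '.' decimals) or JSON.

    Values round-trip through :func:`read_table` losslessly at full float
    precision (written with ``repr``-faithful formatting).
    """
    records = _to_records(rows)
    destination = Path(destination)
    fmt = format.upper()
    if fmt == "CSV":
        df = pd.DataFrame.from_records(records, columns=columns)
        if not records and columns is None:
            raise ValueError("empty rows need explicit columns for a CSV header")
        df.to_csv(destination, index=False)
    elif fmt == "JSON":
        destination.write_text(json.dumps(records, indent=2) + "\n")
    else:
        raise ValueError(f"unknown format {format!r}; use CSV or JSON")


def read_table(source: str | Path, format: str = "CSV") -> list[dict]:
    """Read a table written by :func:`write_table` back into records."""
    source = Path(source)
    fmt = format.upper()
    if fmt == "CSV":
        return pd.read_csv(source).to_dict(orient="records")
    if fmt == "JSON":
        return json.loads(source.read_text())
    raise ValueError(f"unknown format {format!r}; use CSV or JSON")
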