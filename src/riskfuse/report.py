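"""Full-pipeline orchestration: fixtures → bias adjustment → BMD
extrapolation → meta-analysis, with table outputs and a structured run log.

Computed values drive every stage that is verifiable from the shipped data;
where the published arithmetic is keyed to printed numbers (the rounded
continuous-equivalent doses, the extrapolation CIs, the pooled-row inputs),
the printed fixtures drive the downstream stage and any computed-vs-printed
deviation is reported as a discrepancy flag, never silently overwritten.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import scipy

from . import __version__
from .bmd import select_degree, bmd_from_fit, bmdl_profile
from .confounding import scenario_grid
from .extrapolate import DEFAULT_TARGET_DOSE, extrapolate_rr
from .fixtures_io import load_fixture, write_table
from .meta import reproduce_table7
from .misclass import GUSTAVSSON_CONFIG, run_grid

__all__ = ["PipelineConfig", "run_pipeline", "log_run"]

#: Relative deviation beyond which a computed-vs-printed difference is flagged.
FLAG_RTOL = 1e-3


@dataclass(frozen=True)
class PipelineConfig:
    """Configuration of one full pipeline run."""

    output_dir: str | Path = "riskfuse-output"
    trials: int = 10_000
    seed: int = 20110411
    target_dose: float = DEFAULT_TARGET_DOSE
    bmr: float = 0.10
    confidence: float = 0.95
    scale: str = "linear"
    max_degree: int = 2

    def __post_init__(self) -> None:
        if self.trials < 1:
            raise ValueError("trials must be at least 1")
        if not (0 < self.bmr < 1):
            raise ValueError("bmr must be in (0, 1)")
        if not (0.5 < self.confidence < 1):
            raise ValueError("confidence must be in (0.5, 1)")
        if self.scale not in {"linear", "log"}:
            raise ValueError("scale must be 'linear' or 'log'")


def _confounding_rows(study, scenarios):
    rows = []
    for bf_row, adj in scenario_grid(study, scenarios):
        rows.append(
            {
                "rr_confounder": bf_row.scenario.rr_confounder,
                "prev_cohort": bf_row.scenario.prev_cohort,
                "prev_reference": bf_row.scenario.prev_reference,
                "i_nonexp_multiplier": bf_row.i_nonexp_multiplier,
                "i_exp_multiplier": bf_row.i_exp_multiplier,
                "bias_factor": bf_row.bias_factor,
                "estimate_adj": adj.estimate_adj,
                "ci_low_adj": adj.ci_low_adj,
                "ci_high_adj": adj.ci_high_adj,
            }
        )
    return rows


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage and write table3–table7 CSVs plus a JSON summary.

    Returns the summary dict (headline pooled estimates and all discrepancy
    flags).  Two runs with identical config produce byte-identical outputs.
    """
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    flags: dict[str, dict] = {}

    human = load_fixture("human_studies")
    grids = load_fixture("confounding_grids")
    write_table(_confounding_rows(human["garshick"], grids["garshick"]), outdir / "table3.csv")
    write_table(_confounding_rows(human["wellmann"], grids["wellmann"]), outdir / "table4.csv")

    # misclassification grid
    mis_results = run_grid(
        GUSTAVSSON_CONFIG, load_fixture("misclass_grid"), config.trials, config.seed
    )
    write_table(
        [
            {
                "p_exposed": r.scenario.p_exposed,
                "sensitivity": r.scenario.sensitivity,
                "specificity": r.scenario.specificity,
                "adjusted_rr": r.adjusted_rr,
                "ci_low": r.interval[0],
                "ci_high": r.interval[1],
                "n_used": r.n_trials_used,
                "n_discarded": r.n_trials_discarded,
            }
            for r in mis_results
        ],
        outdir / "table5.csv",
    )
    if config.trials < 1000:
        flags["table5_low_precision"] = {
            "trials": config.trials,
            "note": "fewer than 1000 trials per scenario; percentiles are noisy",
        }
    # with perfect classification the ratio construction returns the observed
    # estimate exactly; the published table shows ~1.70 there instead
    identity = next(
        r
        for r in mis_results
        if r.scenario.sensitivity == 1.0 and r.scenario.specificity == 1.0
    )
    flags["table5_identity_offset"] = {
        "adjusted_at_perfect_classification": identity.adjusted_rr,
        "published_value": 1.70,
        "note": "the published Se=Sp=1 rows exceed the observed 1.63; the "
        "ratio construction used here returns the observed estimate exactly",
    }

    # BMD / BMDL / extrapolation
    bioassays = load_fixture("animal_bioassays")
    printed = load_fixture("table6")
    table6_rows = []
    for label, data in bioassays.items():
        sel = select_degree(data, config.max_degree)
        fit = sel.fits[sel.chosen]
        bmd = bmd_from_fit(fit, config.bmr)
        bmdl = bmdl_profile(data, fit, config.bmr, config.confidence)
        rr_computed = extrapolate_rr(
            data.control_fraction, bmdl, config.bmr, config.target_dose
        ).rr
        rr_from_printed = extrapolate_rr(
            data.control_fraction, printed[label]["bmdl"], config.bmr, config.target_dose
        ).rr
        row = {
            "label": label,
            "degree": sel.chosen,
            "bmd": bmd,
            "bmdl": bmdl,
            "rr": rr_computed,
            "bmd_printed": printed[label]["bmd"],
            "bmdl_printed": printed[label]["bmdl"],
            "rr_printed": printed[label]["estimate"].estimate,
            "rr_from_printed_bmdl": rr_from_printed,
        }
        table6_rows.append(row)
        for key in ("bmd", "bmdl"):
            rel = abs(row[key] - row[f"{key}_printed"]) / row[f"{key}_printed"]
            if rel > FLAG_RTOL:
                flags[f"{label}_{key}_mismatch"] = {
                    "computed": row[key],
                    "published": row[f"{key}_printed"],
                    "relative_deviation": rel,
                }
        if abs(rr_from_printed - row["rr_printed"]) / row["rr_printed"] > FLAG_RTOL:
            flags[f"{label}_rr_mismatch"] = {
                "computed_from_published_bmdl": rr_from_printed,
                "published": row["rr_printed"],
                "note": "published RR is not reproducible from its own printed inputs",
            }
    write_table(table6_rows, outdir / "table6.csv")

    # meta-analysis on the printed pooled-row inputs
    pools = reproduce_table7(load_fixture("meta_inputs"), config.scale)
    write_table(
        [
            {
                "pool": name,
                "model": r.model,
                "pooled": r.pooled,
                "ci_low": r.ci[0],
                "ci_high": r.ci[1],
                "q": r.q,
                "df": r.df,
                "p_heterogeneity": r.p_heterogeneity,
                "tau2": r.tau2,
            }
            for name, r in pools.items()
        ],
        outdir / "table7.csv",
    )
    flags["unadjusted_human_pool"] = {
        "computed": pools["human_unadjusted_random"].pooled,
        "published": 1.727,
        "note": "linear-scale DL on the printed unadjusted inputs does not "
        "reproduce the published cell; excluded from hard checks",
    }
    adj = pools["all_adjusted_random"].pooled
    unadj = pools["all_unadjusted_random"].pooled
    if adj >= unadj:
        flags["adjusted_vs_unadjusted_ordering"] = {
            "all_adjusted_random": adj,
            "all_unadjusted_random": unadj,
            "note": "published pattern (1.49 < 1.59) does not hold for pools "
            "computed from the printed inputs",
        }

    summary = {
        "headline": {
            "animal_pooled": pools["animal_random"].pooled,
            "human_adjusted_random": pools["human_adjusted_random"].pooled,
            "overall_random": pools["all_adjusted_random"].pooled,
        },
        "heterogeneity_p_six_study": pools["all_adjusted_random"].p_heterogeneity,
        "flags": flags,
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    log_run(config, summary, outdir / "run_log.json")
    return summary


def log_run(config: PipelineConfig, results: dict, destination: str | Path) -> dict:
    """Write a machine-parseable log of seeds, versions and deviation flags."""
    log = {
        "config": {**asdict(config), "output_dir": str(config.output_dir)},
        "master_seed": config.seed,
        "versions": {
            "riskfuse": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "python": platform.python_version(),
        },
        "flag_rtol": FLAG_RTOL,
        "flags": results.get("flags", {}),
    }
    Path(destination).write_text(json.dumps(log, indent=2) + "\n")
    return log
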