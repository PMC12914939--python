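"""Packaged per-trial estimates of the seven-trial Dep-GP collaboration.

The collaboration's individual participant data are confidential, but its
published per-trial summary estimates (baseline-adjusted mean differences B
with 95% CIs, Hedge's-g effect sizes, odds ratios of improvement with 95%
CIs, arm sizes, complier counts) are transcribed here as CSV fixtures.  The
replay pipeline feeds these through the stage-two machinery: standard errors
are back-derived from the printed CIs (for g, by the scale factor |g/B|
applied to the B interval), then REML-pooled per method and compared across
methods with correlation-adjusted differences.
"""
from __future__ import annotations

import importlib.resources as resources
from functools import lru_cache

import pandas as pd

from .twostage import se_from_ci
from .types import SCALE_LOG_OR, SCALE_SMD, EstimateRecord

__all__ = [
    "load_estimates",
    "load_trials",
    "smd_records",
    "log_or_records",
    "overall_compliance",
    "overall_retention",
    "trial_compliance_rates",
]

TRIALS = ("COBALT", "GENPOD", "HEALTHLINES", "IPCRESS", "MIR", "PANDA", "TREAD")


def _read(name: str) -> pd.DataFrame:
    with resources.files("cacemeta.data").joinpath(name).open() as fh:
        return pd.read_csv(fh, comment="#")


@lru_cache(maxsize=None)
def load_estimates() -> pd.DataFrame:
    """Per-trial x method published effect estimates (B, g, OR with CIs)."""
    return _read("depgp_estimates.csv")


@lru_cache(maxsize=None)
def load_trials() -> pd.DataFrame:
    """Trial-level characteristics (arm sizes, compliers, follow-up, counts)."""
    return _read("depgp_trials.csv")


def _n_analysed(trial_id: str) -> int:
    row = load_trials().set_index("trial_id").loc[trial_id]
    return int(row["n_control"] + row["n_intervention"])


def smd_records(method: str, exclude: tuple[str, ...] = ()) -> list[EstimateRecord]:
    """Hedge's-g records for one method, SEs derived from the printed B CIs.

    se(g) = |g/B| * (CI width of B) / (2 * 1.96): the g and B estimates differ
    only by the trial's standardising constant, so the same factor maps the SE.
    """
    est = load_estimates()
    out = []
    for _, row in est[est["method"] == method].iterrows():
        if row["trial_id"] in exclude:
            continue
        se_b = se_from_ci(row["B_ci_low"], row["B_ci_high"])
        scale = abs(row["g"] / row["B"])
        se_g = scale * se_b
        out.append(
            EstimateRecord(
                trial_id=row["trial_id"],
                method=method,
                scale=SCALE_SMD,
                estimate=float(row["g"]),
                se=float(se_g),
                ci_low=float(row["g"] - 1.959963984540054 * se_g),
                ci_high=float(row["g"] + 1.959963984540054 * se_g),
                n_analysed=_n_analysed(row["trial_id"]),
            )
        )
    return out


def log_or_records(method: str, exclude: tuple[str, ...] = ()) -> list[EstimateRecord]:
    """Log odds-ratio records for one method, SEs from the printed OR CIs."""
    import math

    est = load_estimates()
    out = []
    for _, row in est[est["method"] == method].iterrows():
        if row["trial_id"] in exclude:
            continue
        se = se_from_ci(row["OR_ci_low"], row["OR_ci_high"], log_scale=True)
        y = math.log(row["OR"])
        out.append(
            EstimateRecord(
                trial_id=row["trial_id"],
                method=method,
                scale=SCALE_LOG_OR,
                estimate=float(y),
                se=float(se),
                ci_low=float(math.log(row["OR_ci_low"])),
                ci_high=float(math.log(row["OR_ci_high"])),
                n_analysed=_n_analysed(row["trial_id"]),
            )
        )
    return out


def trial_compliance_rates() -> pd.Series:
    """Observed adherent fraction per trial: compliers / (intervention - missing adherence)."""
    t = load_trials().set_index("trial_id")
    return t["n_compliers"] / (t["n_intervention"] - t["adherence_missing_n"])


def overall_compliance() -> float:
    """Pooled adherent fraction across the collaboration's intervention arms."""
    t = load_trials()
    return float(t["n_compliers"].sum() / (t["n_intervention"].sum() - t["adherence_missing_n"].sum()))


def overall_retention() -> float:
    """Fraction of randomised participants with an observed follow-up outcome."""
    t = load_trials()
    return float(t["followup_n"].sum() / (t["n_control"].sum() + t["n_intervention"].sum()))


def moderators() -> pd.DataFrame:
    """Trial-level moderators for meta-regression/subgroups (type, duration, non-adherence)."""
    t = load_trials().set_index("trial_id")
    out = pd.DataFrame(
        {
            "intervention_type": t["intervention_type"],
            "duration_weeks": t["duration_weeks"].astype(float),
            "nonadherence_rate": 1.0 - trial_compliance_rates(),
            "is_cbt": (t["intervention_type"] == "CBT").astype(float),
        }
    )
    return out
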