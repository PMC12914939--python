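"""CSV input/output, schema validation, and run manifests.

The analysis CSV carries only observable columns (trial_id, participant_id,
arm, baseline, followup, responder, adhered, covariates); latent simulation
truth (underscore-prefixed columns) is written to a separate sidecar so
estimators cannot read it by accident.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .simulate import CORE_COLUMNS
from .types import SCALE_RANGES

__all__ = ["write_ipd", "read_ipd", "validate_ipd", "write_manifest", "ValidationReport"]


def write_ipd(table: pd.DataFrame, path: str | Path, sidecar: str | Path | None = None) -> None:
    """Write the analysis CSV; hidden columns go to ``sidecar`` (or are dropped)."""
    path = Path(path)
    hidden = [c for c in table.columns if c.startswith("_")]
    visible = [c for c in table.columns if not c.startswith("_")]
    table[visible].to_csv(path, index=False)
    if sidecar is not None and hidden:
        table[["trial_id", "participant_id"] + hidden].to_csv(sidecar, index=False)


def read_ipd(path: str | Path) -> pd.DataFrame:
    """Read an analysis CSV, checking the fixed core header."""
    df = pd.read_csv(path)
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


@dataclass
class ValidationReport:
    """Outcome of a schema/content check with itemised violations (row numbers are 0-based)."""

    n_rows: int
    violations: list[str] = field(default_factory=list)

    @property
    def passed(self) -> bool:
        return not self.violations

    def __str__(self) -> str:
        status = "PASS" if self.passed else "FAIL"
        lines = [f"{status}: {self.n_rows} rows, {len(self.violations)} violation(s)"]
        lines += [f"  - {v}" for v in self.violations]
        return "\n".join(lines)


def validate_ipd(
    source: str | Path | pd.DataFrame,
    scale_by_trial: dict[str, str] | None = None,
    responder_rule_by_trial: dict[str, str] | None = None,
) -> ValidationReport:
    """Check schema, arm labels, one-sided adherence, score ranges, responder consistency.

    ``scale_by_trial`` maps trial_id to "BDI"/"PHQ9" to enable range checks;
    ``responder_rule_by_trial`` enables consistency checks of the responder
    flag against the declared dichotomisation rule.
    """
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source)
    report = ValidationReport(n_rows=len(df))
    missing = [c for c in CORE_COLUMNS if c not in df.columns]
    if missing:
        report.violations.append(f"missing required columns {missing}")
        return report

    bad_arm = ~df["arm"].isin(["control", "intervention"])
    for i in df.index[bad_arm]:
        report.violations.append(f"row {i}: unknown arm {df.loc[i, 'arm']!r}")
    ctrl_adh = (df["arm"] == "control") & df["adhered"].notna()
    for i in df.index[ctrl_adh]:
        report.violations.append(f"row {i}: adherence recorded in the control arm")

    if scale_by_trial:
        for trial, scale in scale_by_trial.items():
            lo, hi = SCALE_RANGES[scale]
            sub = df[df["trial_id"] == trial]
            for col in ("baseline", "followup"):
                out = sub[(sub[col] < lo) | (sub[col] > hi)]
                for i in out.index:
                    report.violations.append(
                        f"row {i}: {col}={out.loc[i, col]} outside {scale} range [{lo}, {hi}]"
                    )

    if responder_rule_by_trial:
        from .simulate import dichotomise

        for trial, rule in responder_rule_by_trial.items():
            sub = df[df["trial_id"] == trial]
            expect = dichotomise(sub, rule)["responder"]
            both = sub["responder"].notna() & expect.notna()
            bad = both & (sub["responder"] != expect)
            for i in sub.index[bad]:
                report.violations.append(
                    f"row {i}: responder={sub.loc[i, 'responder']} inconsistent with rule {rule!r}"
                )
    return report


def _config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:16]


def write_manifest(path: str | Path, config: dict, seed: int | None, warnings: list[str] | None = None) -> None:
    """Echo all run parameters (and the seed) into a structured manifest."""
    from . import __version__

    manifest = {
        "package": "cacemeta",
        "version": __version__,
        "seed": seed,
        "config": config,
        "config_hash": _config_hash(config),
        "warnings": warnings or [],
    }
    with open(path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
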