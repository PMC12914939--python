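"""Synthetic two-arm trial collaborations with principal-stratum noncompliance.

The generator emulates the structure of a primary-care depression trial
collaboration: two-arm RCTs of a few hundred participants each, continuous
symptom scores on a BDI-II-like (0-63) or PHQ-9-like (0-27) instrument,
one-sided noncompliance (controls cannot access the intervention, so the
population splits into compliers and never-takers only), trial-specific
responder dichotomisations, and missingness in outcomes and adherence.

Generating model per participant:

* latent prognosis ``U ~ N(0, 1)``;
* complier membership: ``V = rho*U + sqrt(1-rho^2)*eps`` with
  ``rho = confounding_strength``; complier iff ``V <= Phi^-1(pi_c)``.  With
  ``rho > 0`` compliers have systematically better prognosis, which is the
  mechanism that biases per-protocol contrasts;
* baseline ``~ N(baseline_mean, baseline_sd)``, clamped/rounded to the scale;
* follow-up = baseline anchor + control improvement + prognosis loading
  ``rho * residual_sd * U`` + treatment terms + ``N(0, residual_sd)``,
  clamped/rounded.  Compliers assigned to intervention receive ``cace_effect``;
  never-takers assigned to intervention receive
  ``never_taker_assignment_effect`` (0 = exclusion restriction holds).

Latent truth (stratum, prognosis) travels in underscore-prefixed columns that
the writers strip into a sidecar, so estimators can never read it by accident.
"""
from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .types import (
    RESPONDER_RULES,
    SCALE_RANGES,
    ConfigurationError,
    TrialSimConfig,
    TruthLedger,
)

__all__ = ["simulate_trial", "simulate_collaboration", "dichotomise", "apply_missingness"]

#: analysis-facing columns, in writing order; underscore columns are sidecar-only
CORE_COLUMNS = ["trial_id", "participant_id", "arm", "baseline", "followup", "responder", "adhered"]
HIDDEN_COLUMNS = ["_stratum", "_prognosis"]


def _clamp_scores(x: np.ndarray, scale: str) -> np.ndarray:
    lo, hi = SCALE_RANGES[scale]
    return np.clip(np.rint(x), lo, hi)


def simulate_trial(config: TrialSimConfig) -> tuple[pd.DataFrame, TruthLedger]:
    """Generate one trial table plus the ledger of its true estimands.

    The ledger's ``true_pp_bias`` is the large-sample bias of the naive
    per-protocol contrast relative to the true CACE implied by the shared
    prognosis model (ignoring score clamping):
    ``rho^2 * residual_sd * (-phi(t)/Phi(t))`` with ``t = Phi^-1(pi_c)``.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_control + config.n_intervention
    arm = np.array(["control"] * config.n_control + ["intervention"] * config.n_intervention)

    u = rng.normal(size=n)  # latent prognosis
    rho = config.confounding_strength
    v = rho * u + np.sqrt(max(1.0 - rho**2, 0.0)) * rng.normal(size=n)
    pi_c = config.compliance_prob
    threshold = stats.norm.ppf(pi_c) if 0.0 < pi_c < 1.0 else (np.inf if pi_c >= 1.0 else -np.inf)
    complier = v <= threshold

    baseline_raw = rng.normal(config.baseline_mean, config.baseline_sd, size=n)
    baseline = _clamp_scores(baseline_raw, config.scale)

    assigned = arm == "intervention"
    received = assigned & complier
    fu = (
        config.baseline_mean
        + config.control_change_mean
        + config.baseline_slope * (baseline - config.baseline_mean)
        + rho * config.residual_sd * u
        + config.cace_effect * received
        + config.never_taker_assignment_effect * (assigned & ~complier)
        + rng.normal(0.0, config.residual_sd, size=n)
    )
    followup = _clamp_scores(fu, config.scale)

    adhered = np.where(assigned, complier.astype(float), np.nan)

    table = pd.DataFrame(
        {
            "trial_id": config.trial_id,
            "participant_id": [f"{config.trial_id}-{i:05d}" for i in range(n)],
            "arm": arm,
            "baseline": baseline,
            "followup": followup,
            "responder": np.nan,
            "adhered": adhered,
            "_stratum": np.where(complier, "complier", "never_taker"),
            "_prognosis": u,
        }
    )
    for spec in config.strat_factors:
        probs = spec.probs if spec.probs is not None else [1.0 / len(spec.levels)] * len(spec.levels)
        table[spec.name] = rng.choice(list(spec.levels), size=n, p=probs)

    table = dichotomise(table, config.responder_rule)
    table = apply_missingness(
        table,
        config.missing_outcome_prob,
        config.missing_adherence_prob,
        seed=int(rng.integers(2**31)),
    )

    if 0.0 < pi_c < 1.0:
        selection = -stats.norm.pdf(threshold) / stats.norm.cdf(threshold)
    else:
        selection = 0.0
    truth = TruthLedger(
        trial_id=config.trial_id,
        true_cace=config.cace_effect,
        true_itt=pi_c * config.cace_effect + (1.0 - pi_c) * config.never_taker_assignment_effect,
        true_pp_bias=rho**2 * config.residual_sd * selection,
        pi_c=pi_c,
    )
    return table, truth


def simulate_collaboration(
    configs: Sequence[TrialSimConfig],
) -> tuple[pd.DataFrame, list[TruthLedger]]:
    """Concatenate several simulated trials into one multi-trial IPD table."""
    if not configs:
        raise ConfigurationError("need at least one trial config")
    ids = [c.trial_id for c in configs]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ConfigurationError(f"duplicate trial_ids: {dupes}")
    tables, truths = [], []
    for cfg in configs:
        t, truth = simulate_trial(cfg)
        tables.append(t)
        truths.append(truth)
    return pd.concat(tables, ignore_index=True), truths


def dichotomise(table: pd.DataFrame, rule: str) -> pd.DataFrame:
    """Set the responder flag from baseline and follow-up scores.

    Rules mirror the trial-specific definitions of treatment response:

    * ``half_reduction`` — follow-up <= 50% of baseline;
    * ``below10`` — follow-up score < 10, regardless of baseline;
    * ``below10_and_minus5`` — follow-up < 10 *and* a reduction of >= 5 points.

    Missing follow-up yields a missing responder flag.
    """
    if rule not in RESPONDER_RULES:
        raise ConfigurationError(f"unknown responder rule {rule!r}; choose from {RESPONDER_RULES}")
    out = table.copy()
    base = out["baseline"].astype(float)
    fu = out["followup"].astype(float)
    if rule == "half_reduction":
        resp = fu <= 0.5 * base
    elif rule == "below10":
        resp = fu < 10
    else:
        resp = (fu < 10) & (base - fu >= 5)
    out["responder"] = np.where(fu.isna() | base.isna(), np.nan, resp.astype(float))
    return out


def apply_missingness(
    table: pd.DataFrame,
    outcome_prob: float,
    adherence_prob: float,
    seed: int = 0,
) -> pd.DataFrame:
    """MCAR missingness: follow-up/responder in both arms, adherence only where defined.

    Adherence can only go missing in the intervention arm (it is structurally
    undefined under control in a one-sided-noncompliance design).
    """
    for name, p in (("outcome_prob", outcome_prob), ("adherence_prob", adherence_prob)):
        if not 0.0 <= p <= 1.0:
            raise ConfigurationError(f"{name} must be in [0, 1], got {p}")
    if outcome_prob == 0.0 and adherence_prob == 0.0:
        return table.copy()
    rng = np.random.default_rng(seed)
    out = table.copy()
    n = len(out)
    if outcome_prob > 0.0:
        drop = rng.random(n) < outcome_prob
        out.loc[drop, ["followup", "responder"]] = np.nan
    if adherence_prob > 0.0:
        inter = (out["arm"] == "intervention").to_numpy()
        drop_a = (rng.random(n) < adherence_prob) & inter
        out.loc[drop_a, "adhered"] = np.nan
    return out
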