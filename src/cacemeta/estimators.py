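"""Per-trial estimation of the ITT, PP and CACE estimands.

Continuous outcomes use baseline-adjusted (ANCOVA-style) linear models; the
CACE is estimated by two-stage least squares with randomisation instrumenting
treatment receipt.  Binary outcomes use logistic regression for ITT/PP and a
principal-stratification mixture estimator for the CACE, with a seeded
nonparametric bootstrap for its interval.

All estimators are complete-case on the outcome, matching an ITT population
defined as randomised participants with observed outcomes.  Intervention-arm
rows with missing adherence are dropped from per-protocol and (by default)
CACE analyses; a sensitivity switch treats them as non-compliers instead.
"""
from __future__ import annotations

import math
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .types import (
    SCALE_LOG_OR,
    SCALE_RAW,
    EstimateRecord,
    EstimationError,
    SeparationError,
    WeakInstrumentError,
)

__all__ = [
    "fit_itt_continuous",
    "fit_itt_binary",
    "make_pp_table",
    "fit_cace_continuous",
    "fit_cace_binary",
    "hedges_g",
    "compliance_rate",
    "standardise_within_trial",
]

_Z95 = stats.norm.ppf(0.975)


def _arm_indicator(table: pd.DataFrame) -> np.ndarray:
    arm = table["arm"].astype(str)
    bad = set(arm.unique()) - {"control", "intervention"}
    if bad:
        raise ValueError(f"unknown arm labels: {sorted(bad)}")
    return (arm == "intervention").to_numpy(dtype=float)


def _design(table: pd.DataFrame, covariate_names: Sequence[str], adjust_baseline: bool) -> pd.DataFrame:
    """Exogenous design: intercept, baseline (optional), dummy-coded covariates."""
    cols = {"const": np.ones(len(table))}
    if adjust_baseline:
        cols["baseline"] = table["baseline"].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=table.index)
    if covariate_names:
        covs = table[list(covariate_names)]
        dummies = pd.get_dummies(covs, drop_first=True, dtype=float)
        numeric = covs.select_dtypes(include="number")
        X = pd.concat([X, numeric, dummies], axis=1)
    rank = np.linalg.matrix_rank(X.to_numpy(dtype=float))
    if rank < X.shape[1]:
        raise EstimationError(f"collinear design columns among {list(X.columns)}")
    return X


def _complete_cases(table: pd.DataFrame, outcome: str, adjust_baseline: bool) -> pd.DataFrame:
    need = [outcome] + (["baseline"] if adjust_baseline else [])
    return table.dropna(subset=need)


def _check_arms(df: pd.DataFrame, min_n: int = 2) -> None:
    counts = df["arm"].value_counts()
    for arm in ("control", "intervention"):
        if counts.get(arm, 0) < min_n:
            raise EstimationError(f"arm {arm!r} has fewer than {min_n} analysable participants")


def compliance_rate(table: pd.DataFrame) -> float:
    """Adherent fraction of intervention-arm participants with observed adherence."""
    inter = table[table["arm"] == "intervention"]
    if inter.empty:
        raise EstimationError("no intervention-arm participants")
    observed = inter["adhered"].dropna()
    if observed.empty:
        raise EstimationError("adherence is missing for every intervention participant")
    return float(observed.astype(float).mean())


def fit_itt_continuous(
    table: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    adjust_baseline: bool = True,
) -> EstimateRecord:
    """Intention-to-treat effect on the continuous score.

    Linear model of follow-up on arm + baseline + covariates over all
    randomised participants with observed outcomes; the arm coefficient is the
    unstandardised mean difference B (negative favours intervention), with a
    t-based 95% CI.
    """
    df = _complete_cases(table, "followup", adjust_baseline)
    _check_arms(df)
    z = _arm_indicator(df)
    X = _design(df, covariate_names, adjust_baseline)
    X.insert(1, "arm", z)
    fit = sm.OLS(df["followup"].to_numpy(dtype=float), X.to_numpy(dtype=float)).fit()
    est = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi = fit.conf_int()[1]
    return EstimateRecord(
        trial_id=str(df["trial_id"].iloc[0]) if "trial_id" in df else "",
        method="ITT",
        scale=SCALE_RAW,
        estimate=est,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        n_analysed=int(len(df)),
        compliance_rate=_safe_compliance(df),
    )


def _safe_compliance(df: pd.DataFrame) -> float | None:
    try:
        return compliance_rate(df)
    except EstimationError:
        return None


def fit_itt_binary(
    table: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    adjust_baseline: bool = True,
) -> EstimateRecord:
    """Intention-to-treat log odds ratio of response (improvement).

    Logistic model of the responder flag on arm + baseline + covariates;
    ``record.odds_ratio`` is exp(estimate).
    """
    df = _complete_cases(table, "responder", adjust_baseline)
    _check_arms(df)
    y = df["responder"].astype(float).to_numpy()
    z = _arm_indicator(df)
    for arm in (0.0, 1.0):
        sub = y[z == arm]
        if sub.min() == sub.max():
            name = "intervention" if arm else "control"
            raise SeparationError(
                f"responder is constant ({int(sub[0])}) in the {name} arm: odds ratio not estimable"
            )
    X = _design(df, covariate_names, adjust_baseline)
    X.insert(1, "arm", z)
    fit = sm.Logit(y, X.to_numpy(dtype=float)).fit(disp=0)
    est = float(fit.params[1])
    se = float(fit.bse[1])
    lo, hi = fit.conf_int()[1]
    return EstimateRecord(
        trial_id=str(df["trial_id"].iloc[0]) if "trial_id" in df else "",
        method="ITT",
        scale=SCALE_LOG_OR,
        estimate=est,
        se=se,
        ci_low=float(lo),
        ci_high=float(hi),
        n_analysed=int(len(df)),
        compliance_rate=_safe_compliance(df),
    )


def make_pp_table(table: pd.DataFrame, active_control_adherence: bool = False) -> pd.DataFrame:
    """Per-protocol population: all controls plus adherent intervention participants.

    Intervention rows with missing adherence cannot be classified and are
    dropped.  With ``active_control_adherence`` the same restriction is applied
    to control rows carrying an adherence flag (active-comparator designs).
    """
    ctrl = table[table["arm"] == "control"]
    inter = table[table["arm"] == "intervention"]
    adherent = inter[inter["adhered"].astype(float) == 1.0]
    if adherent.empty:
        raise EstimationError("per-protocol population is degenerate: no adherent intervention participants")
    if active_control_adherence and ctrl["adhered"].notna().any():
        ctrl = ctrl[ctrl["adhered"].astype(float) == 1.0]
    return pd.concat([ctrl, adherent]).sort_index()


def _iv_2sls(y: np.ndarray, d: np.ndarray, z: np.ndarray, X: np.ndarray, robust: bool = True):
    """Two-stage least squares with one endogenous regressor and one instrument.

    W = [d, X] regressed via projection on [z, X]; returns (beta, cov) for the
    full coefficient vector with the receipt coefficient first.  ``robust``
    selects the heteroskedasticity-consistent (HC0) IV sandwich.
    """
    W = np.column_stack([d, X])
    Zf = np.column_stack([z, X])
    ztz = Zf.T @ Zf
    ztw = Zf.T @ W
    # first-stage projection of W on the instrument set
    coef_fs = np.linalg.solve(ztz, ztw)
    What = Zf @ coef_fs
    A = What.T @ W
    if abs(np.linalg.det(A)) < 1e-12 * np.linalg.norm(A):
        raise WeakInstrumentError("instrument carries no information about receipt (first stage singular)")
    beta = np.linalg.solve(A, What.T @ y)
    resid = y - W @ beta
    Ainv = np.linalg.inv(A)
    if robust:
        meat = What.T @ (What * resid[:, None] ** 2)
        cov = Ainv @ meat @ Ainv.T
    else:
        sigma2 = float(resid @ resid) / len(y)
        cov = sigma2 * np.linalg.inv(What.T @ What)
    return beta, cov


def fit_cace_continuous(
    table: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    adjust_baseline: bool = True,
    missing_adherence: str = "drop",
    robust: bool = True,
) -> EstimateRecord:
    """Complier average causal effect on the continuous score by 2SLS.

    Randomisation instruments treatment receipt (receipt = adherence in the
    intervention arm, structurally zero under control); baseline and
    stratification covariates enter both stages as exogenous regressors.
    Without covariates this reduces exactly to the Wald ratio ITT / pi_c.
    """
    if missing_adherence not in ("drop", "as_nontaker"):
        raise ValueError("missing_adherence must be 'drop' or 'as_nontaker'")
    df = _complete_cases(table, "followup", adjust_baseline).copy()
    inter = df["arm"] == "intervention"
    if missing_adherence == "drop":
        df = df[~(inter & df["adhered"].isna())]
    else:
        df.loc[inter & df["adhered"].isna(), "adhered"] = 0.0
    _check_arms(df)
    z = _arm_indicator(df)
    d = np.where(z == 1.0, df["adhered"].astype(float).to_numpy(), 0.0)
    pi_c = float(d[z == 1.0].mean())
    if pi_c <= 0.0:
        raise WeakInstrumentError("estimated compliance is zero: CACE not identified")
    X = _design(df, covariate_names, adjust_baseline).to_numpy(dtype=float)
    beta, cov = _iv_2sls(df["followup"].to_numpy(dtype=float), d, z, X, robust=robust)
    est = float(beta[0])
    se = float(math.sqrt(cov[0, 0]))
    return EstimateRecord(
        trial_id=str(df["trial_id"].iloc[0]) if "trial_id" in df else "",
        method="CACE",
        scale=SCALE_RAW,
        estimate=est,
        se=se,
        ci_low=est - _Z95 * se,
        ci_high=est + _Z95 * se,
        n_analysed=int(len(df)),
        compliance_rate=pi_c,
    )


def _mixture_logor(resp: np.ndarray, arm: np.ndarray, adhered: np.ndarray) -> tuple[float, float, bool]:
    """Closed-form principal-stratification estimate of the complier log OR.

    Under one-sided noncompliance, monotonicity and the exclusion restriction:
    pi_c and the never-taker response rate are observed in the intervention
    arm, and the complier control response rate is recovered from the
    control-arm mixture  p_ctrl = pi_c * p_c0 + (1 - pi_c) * p_never.
    Returns (log OR, pi_c, clamped?) where clamped flags a recovered
    probability outside (0, 1).
    """
    eps = 1e-6
    int_mask = arm == 1.0
    d_int = adhered[int_mask]
    pi_c = float(d_int.mean())
    if pi_c <= 0.0:
        raise WeakInstrumentError("no compliers in the intervention arm")
    p_c1 = float(resp[int_mask & (adhered == 1.0)].mean())
    p_never = float(resp[int_mask & (adhered == 0.0)].mean()) if pi_c < 1.0 else 0.0
    p_ctrl = float(resp[~int_mask].mean())
    p_c0 = (p_ctrl - (1.0 - pi_c) * p_never) / pi_c
    clamped = not (0.0 < p_c0 < 1.0) or not (0.0 < p_c1 < 1.0)
    p_c0 = min(max(p_c0, eps), 1.0 - eps)
    p_c1 = min(max(p_c1, eps), 1.0 - eps)
    logor = math.log(p_c1 / (1 - p_c1)) - math.log(p_c0 / (1 - p_c0))
    return logor, pi_c, clamped


def fit_cace_binary(
    table: pd.DataFrame,
    covariate_names: Sequence[str] = (),
    n_bootstrap: int = 999,
    seed: int = 0,
    missing_adherence: str = "drop",
) -> EstimateRecord:
    """Complier log odds ratio of response by principal-stratification ML.

    Maximum likelihood under the one-sided-noncompliance mixture coincides
    with the closed-form moment recovery used here.  The CI is a percentile
    bootstrap over participants (stratified by arm, seeded); bootstrap
    replicates whose recovered complier probabilities fall outside (0, 1) are
    clamped and counted in ``warnings``.  Covariates are not used by the
    mixture estimator (the estimate is unadjusted); a note is recorded when
    covariates are requested.
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be positive")
    df = table.dropna(subset=["responder"]).copy()
    inter = df["arm"] == "intervention"
    if missing_adherence == "drop":
        df = df[~(inter & df["adhered"].isna())]
    elif missing_adherence == "as_nontaker":
        df.loc[inter & df["adhered"].isna(), "adhered"] = 0.0
    else:
        raise ValueError("missing_adherence must be 'drop' or 'as_nontaker'")
    _check_arms(df)
    warnings: list[str] = []
    if covariate_names:
        warnings.append("binary CACE mixture estimator is unadjusted; covariates ignored")
    arm = _arm_indicator(df)
    resp = df["responder"].astype(float).to_numpy()
    adhered = np.where(arm == 1.0, df["adhered"].astype(float).to_numpy(), 0.0)
    est, pi_c, clamped = _mixture_logor(resp, arm, adhered)
    if clamped:
        warnings.append("recovered complier probability outside (0, 1); clamped")

    rng = np.random.default_rng(seed)
    idx_c = np.flatnonzero(arm == 0.0)
    idx_i = np.flatnonzero(arm == 1.0)
    boots = np.empty(n_bootstrap)
    n_clamped = n_failed = 0
    for b in range(n_bootstrap):
        take = np.concatenate([
            rng.choice(idx_c, size=len(idx_c), replace=True),
            rng.choice(idx_i, size=len(idx_i), replace=True),
        ])
        try:
            lb, _, cl = _mixture_logor(resp[take], arm[take], adhered[take])
        except WeakInstrumentError:
            n_failed += 1
            boots[b] = np.nan
            continue
        n_clamped += cl
        boots[b] = lb
    ok = boots[np.isfinite(boots)]
    if n_failed:
        warnings.append(f"{n_failed} bootstrap replicates failed (no compliers)")
    if n_clamped:
        warnings.append(f"{n_clamped} bootstrap replicates clamped a recovered probability")
    if len(ok) < max(20, n_bootstrap // 2):
        raise EstimationError("bootstrap failed in most replicates; CACE OR not estimable")
    lo, hi = np.percentile(ok, [2.5, 97.5])
    se = float(np.std(ok, ddof=1))
    return EstimateRecord(
        trial_id=str(df["trial_id"].iloc[0]) if "trial_id" in df else "",
        method="CACE",
        scale=SCALE_LOG_OR,
        estimate=est,
        se=se,
        ci_low=float(min(lo, est)),
        ci_high=float(max(hi, est)),
        n_analysed=int(len(df)),
        compliance_rate=pi_c,
        warnings=warnings,
    )


def hedges_g(b: float, sd_pooled: float, n1: int, n2: int, se_b: float | None = None):
    """Hedge's g: bias-corrected standardised mean difference.

    g = J * B / sd_pooled with J = 1 - 3/(4(n1 + n2 - 2) - 1).  When ``se_b``
    is given, returns ``(g, se_g)`` with the SE propagated by the same scale
    factor.
    """
    if sd_pooled <= 0:
        raise ValueError("sd_pooled must be positive")
    df = n1 + n2 - 2
    if df <= 0:
        raise ValueError("need n1 + n2 > 2")
    j = 1.0 - 3.0 / (4.0 * df - 1.0)
    g = j * b / sd_pooled
    if se_b is None:
        return g
    return g, j * se_b / sd_pooled


def standardise_within_trial(table: pd.DataFrame) -> pd.DataFrame:
    """Add per-trial z-scored columns ``baseline_z`` and ``followup_z``.

    Standardisation uses the observed values of each trial (mean 0, SD 1 with
    ddof=1); a constant column within a trial raises.
    """
    out = table.copy()
    for col in ("baseline", "followup"):
        zcol = f"{col}_z"
        out[zcol] = np.nan
        for trial, sub in out.groupby("trial_id"):
            vals = sub[col].dropna()
            if len(vals) < 2:
                raise EstimationError(f"trial {trial!r}: fewer than 2 observed {col} values")
            sd = vals.std(ddof=1)
            if sd == 0:
                raise EstimationError(f"trial {trial!r}: zero variance in {col}")
            out.loc[sub.index, zcol] = (sub[col] - vals.mean()) / sd
    return out
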