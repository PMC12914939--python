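"""One-stage analyses: hierarchical models on stacked, within-trial-standardised IPD.

Continuous outcomes are z-scored per trial and fitted with a linear mixed
model (random trial intercept, optionally a random treatment effect).  Binary
outcomes use a random-intercept logistic model fitted by Gauss-Hermite
quadrature (no frequentist GLMM with quadrature is available in the installed
Python stack, so the marginal likelihood is maximised directly here).

Method comparisons duplicate and stack the data with a method indicator and
estimate the interaction jointly; standard errors use a trial-level
cluster-robust sandwich so that the shared participants between the two
copies are honoured.  The CACE enters through two-stage least squares with
randomisation as the instrument, trial intercepts fixed, and trial-clustered
standard errors -- a deliberate reconstruction, since a random treatment
effect cannot be carried inside 2SLS.  This module is validated by simulation
properties, not against published numbers (those require the confidential
participant-level data).
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import optimize, stats

from . import twostage
from .estimators import make_pp_table, standardise_within_trial
from .types import DifferenceResult, EstimationError, PooledEstimate

__all__ = ["OneStageSpec", "fit_one_stage", "one_stage_difference"]

_Z95 = stats.norm.ppf(0.975)


@dataclass
class OneStageSpec:
    """Configuration of a one-stage fit."""

    outcome_scale: str = "z_continuous"  # z_continuous | binary
    random_effects: str = "intercept_plus_treatment"  # intercept_only | intercept_plus_treatment
    method: str = "ITT"  # ITT | PP | CACE
    notes: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.outcome_scale not in ("z_continuous", "binary"):
            raise ValueError(f"unknown outcome_scale {self.outcome_scale!r}")
        if self.random_effects not in ("intercept_only", "intercept_plus_treatment"):
            raise ValueError(f"unknown random_effects {self.random_effects!r}")
        if self.method not in ("ITT", "PP", "CACE"):
            raise ValueError(f"unknown method {self.method!r}")


def _check_multitrial(ipd: pd.DataFrame) -> None:
    if ipd["trial_id"].nunique() < 2:
        raise EstimationError("one-stage models need at least two trials")


def _population(ipd: pd.DataFrame, method: str) -> pd.DataFrame:
    """Analysis population and exposure for one method (per trial for PP)."""
    if method in ("ITT", "CACE"):
        df = ipd.copy()
        inter = df["arm"] == "intervention"
        if method == "CACE":
            df = df[~(inter & df["adhered"].isna())]
    else:  # PP
        df = pd.concat(
            [make_pp_table(sub) for _, sub in ipd.groupby("trial_id")], ignore_index=False
        )
    df = df.copy()
    df["_treat"] = (df["arm"] == "intervention").astype(float)
    if method == "CACE":
        df["_receipt"] = np.where(df["_treat"] == 1.0, df["adhered"].astype(float), 0.0)
    else:
        df["_receipt"] = df["_treat"]
    return df


def _ensure_z(ipd: pd.DataFrame) -> pd.DataFrame:
    if "followup_z" in ipd.columns and "baseline_z" in ipd.columns:
        return ipd
    return standardise_within_trial(ipd)


def _pooled(est: float, se: float, tau2: float, k: int) -> PooledEstimate:
    p = float(2 * stats.norm.sf(abs(est / se))) if se > 0 else 0.0
    return PooledEstimate(
        mu=float(est), se=float(se), ci_low=float(est - _Z95 * se), ci_high=float(est + _Z95 * se),
        p=p, tau2=float(max(tau2, 0.0)), i2=float("nan"), q=float("nan"), k=k,
    )


def _fit_mixed_continuous(df: pd.DataFrame, spec: OneStageSpec) -> PooledEstimate:
    df = df.dropna(subset=["followup_z", "baseline_z"])
    endog = df["followup_z"].to_numpy(dtype=float)
    exog = np.column_stack([np.ones(len(df)), df["_treat"], df["baseline_z"]])
    groups = df["trial_id"].to_numpy()
    want_slope = spec.random_effects == "intercept_plus_treatment"
    exog_re = np.column_stack([np.ones(len(df)), df["_treat"]]) if want_slope else np.ones((len(df), 1))
    import warnings as _warnings

    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", ConvergenceWarning)
        _warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.MixedLM(endog, exog, groups=groups, exog_re=exog_re).fit(reml=True)
            singular = want_slope and (np.any(np.diag(fit.cov_re) < 1e-10) or not fit.converged)
        except (np.linalg.LinAlgError, ValueError):
            singular = True
            fit = None
        if fit is None or singular:
            if want_slope:
                spec.notes.append("random treatment effect singular; downgraded to random intercept")
                fit = sm.MixedLM(endog, exog, groups=groups, exog_re=np.ones((len(df), 1))).fit(reml=True)
                want_slope = False
    tau2 = float(fit.cov_re[1, 1]) if want_slope else 0.0
    return _pooled(fit.params[1], fit.bse[1], tau2, df["trial_id"].nunique())


def _gh_logit_random_intercept(y, X, groups, n_nodes: int = 31):
    """Random-intercept logistic regression by Gauss-Hermite quadrature.

    Maximises the marginal likelihood over (beta, log sigma_u); returns
    (beta, cov_beta, sigma_u).  Observed information from the numerical
    Hessian of the marginal log-likelihood.
    """
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    logw = np.log(weights / math.sqrt(2 * math.pi))
    labels, gidx = np.unique(groups, return_inverse=True)

    def nll(theta):
        beta, sigma = theta[:-1], math.exp(theta[-1])
        eta = X @ beta  # (n,)
        lin = eta[:, None] + sigma * nodes[None, :]  # (n, q)
        ll_obs = y[:, None] * lin - np.logaddexp(0.0, lin)
        per_group = np.zeros((len(labels), len(nodes)))
        np.add.at(per_group, gidx, ll_obs)
        return -float(np.sum(_logsumexp(per_group + logw[None, :], axis=1)))

    theta0 = np.concatenate([np.zeros(X.shape[1]), [math.log(0.5)]])
    res = optimize.minimize(nll, theta0, method="BFGS", options={"gtol": 1e-7, "maxiter": 500})
    theta = res.x
    hess = _numerical_hessian(nll, theta)
    try:
        cov = np.linalg.inv(hess)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(hess)
    p = X.shape[1]
    return theta[:p], cov[:p, :p], math.exp(theta[-1])


def _logsumexp(a, axis):
    m = np.max(a, axis=axis, keepdims=True)
    return (m + np.log(np.sum(np.exp(a - m), axis=axis, keepdims=True))).squeeze(axis)


def _numerical_hessian(f, x, eps: float = 1e-4):
    n = len(x)
    H = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            ei = np.zeros(n); ei[i] = eps
            ej = np.zeros(n); ej[j] = eps
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej) + f(x - ei - ej)
            ) / (4 * eps**2)
    return H


def _fit_binary(df: pd.DataFrame, spec: OneStageSpec) -> PooledEstimate:
    df = df.dropna(subset=["responder", "baseline_z"])
    y = df["responder"].astype(float).to_numpy()
    X = np.column_stack([np.ones(len(df)), df["_treat"], df["baseline_z"]])
    if spec.random_effects == "intercept_plus_treatment":
        spec.notes.append("binary model supports a random intercept only; treatment effect fixed")
    beta, cov, _sigma = _gh_logit_random_intercept(y, X, df["trial_id"].to_numpy())
    return _pooled(beta[1], math.sqrt(cov[1, 1]), 0.0, df["trial_id"].nunique())


def _cluster_2sls(y, W, Zf, clusters):
    """2SLS with a trial-level cluster-robust sandwich covariance."""
    coef_fs = np.linalg.lstsq(Zf, W, rcond=None)[0]
    What = Zf @ coef_fs
    A = What.T @ W
    beta = np.linalg.solve(A, What.T @ y)
    e = y - W @ beta
    Ainv = np.linalg.inv(A)
    meat = np.zeros((W.shape[1], W.shape[1]))
    for g in np.unique(clusters):
        m = clusters == g
        s = What[m].T @ e[m]
        meat += np.outer(s, s)
    cov = Ainv @ meat @ Ainv.T
    return beta, cov


def _trial_dummies(trials: np.ndarray) -> np.ndarray:
    labels = np.unique(trials)
    return np.column_stack([(trials == t).astype(float) for t in labels[1:]])


def _fit_cace_continuous_onestage(df: pd.DataFrame) -> PooledEstimate:
    df = df.dropna(subset=["followup_z", "baseline_z"])
    y = df["followup_z"].to_numpy(dtype=float)
    z = df["_treat"].to_numpy(dtype=float)
    d = df["_receipt"].to_numpy(dtype=float)
    trials = df["trial_id"].to_numpy()
    exog = np.column_stack([np.ones(len(df)), df["baseline_z"].to_numpy(dtype=float), _trial_dummies(trials)])
    W = np.column_stack([d, exog])
    Zf = np.column_stack([z, exog])
    beta, cov = _cluster_2sls(y, W, Zf, trials)
    return _pooled(beta[0], math.sqrt(cov[0, 0]), 0.0, len(np.unique(trials)))


def fit_one_stage(ipd: pd.DataFrame, spec: OneStageSpec) -> PooledEstimate:
    """One-stage pooled treatment effect for one estimation method.

    Continuous: linear mixed model on per-trial z-scores (random intercept,
    random treatment effect unless singular -- downgrades are recorded in
    ``spec.notes``).  Binary: random-intercept logistic model.  CACE enters
    via instrumented receipt (continuous) or aggregation of per-trial
    mixture estimates with a random trial effect (binary).
    """
    _check_multitrial(ipd)
    if spec.outcome_scale == "z_continuous":
        ipd = _ensure_z(ipd)
        df = _population(ipd, spec.method)
        if spec.method == "CACE":
            return _fit_cace_continuous_onestage(df)
        return _fit_mixed_continuous(df, spec)
    df = _population(ipd, spec.method)
    if spec.method == "CACE":
        deltas = _per_trial_binary(ipd, "CACE")
        pooled = twostage.pool([d for d, _ in deltas.values()], [v for _, v in deltas.values()])
        return pooled
    if "baseline_z" not in df.columns:
        df = _ensure_z(df)
    return _fit_binary(df, spec)


# ---------------------------------------------------------------------------
# method comparisons


def _per_trial_binary(ipd: pd.DataFrame, method: str) -> dict[str, tuple[float, float]]:
    """Unadjusted per-trial log odds ratio and delta-method variance for one method.

    All three methods are smooth functions of four cell proportions (control
    response rate, complier/never-taker response rates in the intervention
    arm, and the adherent fraction), so variances follow by the delta method
    from their binomial sampling variances.
    """
    out = {}
    for trial, sub in ipd.groupby("trial_id"):
        sub = sub.dropna(subset=["responder"])
        inter = sub[sub["arm"] == "intervention"].dropna(subset=["adhered"])
        ctrl = sub[sub["arm"] == "control"]
        n0 = len(ctrl)
        adh = inter["adhered"].astype(float) == 1.0
        n1a, n1n = int(adh.sum()), int((~adh).sum())
        if n0 < 2 or n1a < 1:
            raise EstimationError(f"trial {trial!r}: too few analysable participants")
        p = np.array([
            ctrl["responder"].astype(float).mean(),
            inter.loc[adh.values, "responder"].astype(float).mean(),
            inter.loc[~adh.values, "responder"].astype(float).mean() if n1n else 0.0,
            n1a / (n1a + n1n),
        ])
        v = np.array([
            p[0] * (1 - p[0]) / n0,
            p[1] * (1 - p[1]) / n1a,
            (p[2] * (1 - p[2]) / n1n) if n1n else 0.0,
            p[3] * (1 - p[3]) / (n1a + n1n),
        ])

        def logor(q, method=method):
            eps = 1e-9
            q = np.clip(q, eps, 1 - eps)
            p0, p1a, p1n, pi = q
            if method == "ITT":
                p1 = pi * p1a + (1 - pi) * p1n
                a, b = p1, p0
            elif method == "PP":
                a, b = p1a, p0
            else:  # CACE
                pc0 = np.clip((p0 - (1 - pi) * p1n) / pi, eps, 1 - eps)
                a, b = p1a, pc0
            return math.log(a / (1 - a)) - math.log(b / (1 - b))

        grad = np.array([
            (logor(p + h * np.eye(4)[i]) - logor(p - h * np.eye(4)[i])) / (2 * h)
            for i, h in zip(range(4), [1e-6] * 4)
        ])
        out[trial] = (logor(p), float(grad @ (v * grad)))
    return out


def one_stage_difference(
    ipd: pd.DataFrame,
    method_a: str,
    method_b: str,
    spec: OneStageSpec | None = None,
) -> DifferenceResult:
    """One-stage within-participant comparison of two estimation methods.

    Continuous: the data are duplicated and stacked with a method indicator;
    exposures are instrumented by randomisation (assignment itself for
    ITT/PP), and the method-by-receipt interaction is the difference, with a
    trial-clustered sandwich covariance honouring the shared participants.
    Returns ΔSMD oriented so that positive means ``method_b`` estimates a
    larger benefit; binary comparisons return a log ROR.
    """
    spec = spec or OneStageSpec()
    _check_multitrial(ipd)
    for m in (method_a, method_b):
        if m not in ("ITT", "PP", "CACE"):
            raise ValueError(f"unknown method {m!r}")

    if spec.outcome_scale == "z_continuous":
        ipd = _ensure_z(ipd)
        parts = []
        for flag, method in ((0.0, method_a), (1.0, method_b)):
            sub = _population(ipd, method).dropna(subset=["followup_z", "baseline_z"]).copy()
            sub["_m"] = flag
            parts.append(sub)
        stacked = pd.concat(parts, ignore_index=True)
        y = stacked["followup_z"].to_numpy(dtype=float)
        z = stacked["_treat"].to_numpy(dtype=float)
        d = stacked["_receipt"].to_numpy(dtype=float)
        m = stacked["_m"].to_numpy(dtype=float)
        trials = stacked["trial_id"].to_numpy()
        exog = np.column_stack(
            [np.ones(len(stacked)), m, stacked["baseline_z"].to_numpy(dtype=float), _trial_dummies(trials)]
        )
        W = np.column_stack([d, d * m, exog])
        Zf = np.column_stack([z, z * m, exog])
        beta, cov = _cluster_2sls(y, W, Zf, trials)
        eff_a, eff_b = beta[0], beta[0] + beta[1]
        grad = np.array([np.sign(eff_b) - np.sign(eff_a), np.sign(eff_b)])
        delta = abs(eff_b) - abs(eff_a)
        se = math.sqrt(float(grad @ cov[:2, :2] @ grad))
        pooled = _pooled(delta, se, 0.0, len(np.unique(trials)))
        return DifferenceResult(
            comparison=f"{method_b}_vs_{method_a}", scale="delta_smd", pooled=pooled,
            r_assumed=float("nan"), per_trial_deltas=[], warnings=list(spec.notes),
        )

    # binary: per-trial deltas of unadjusted log odds ratios; the shared-cell
    # structure makes the within-trial covariance explicit in the delta method
    da = _per_trial_binary(ipd, method_a)
    db = _per_trial_binary(ipd, method_b)
    trials = sorted(da)
    deltas, dvars = [], []
    for t in trials:
        deltas.append(db[t][0] - da[t][0])
        # conservative correlation-adjusted variance with shared participants (r from
        # the common cells): use the difference of the delta-method gradients directly
        dvars.append(max(db[t][1] + da[t][1] - 2 * math.sqrt(db[t][1] * da[t][1]), twostage.VAR_FLOOR))
    pooled = twostage.pool(deltas, dvars)
    return DifferenceResult(
        comparison=f"{method_b}_vs_{method_a}", scale="log_ror", pooled=pooled,
        r_assumed=1.0, per_trial_deltas=list(zip(trials, deltas, dvars)), warnings=list(spec.notes),
    )
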