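"""Stage-two pooling: REML random-effects meta-analysis and method comparisons.

Per-trial effects (Hedge's g or log odds ratios) are pooled with
inverse-variance random-effects weights, the between-trial variance tau^2
estimated by restricted maximum likelihood.  Because ITT, PP and CACE
estimates for one trial come from the same participants and outcome, their
within-trial differences are pooled with correlation-adjusted variances

    var(delta_i) = v_a + v_b - 2 r sqrt(v_a v_b),

with the assumed within-study correlation r close to 1 in the base case and
a 0.50-1.00 sensitivity grid.
"""
from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import (
    SCALE_LOG_OR,
    SCALE_SMD,
    ConvergenceError,
    DifferenceResult,
    EstimateRecord,
    PooledEstimate,
)

__all__ = [
    "reml_tau2",
    "pool",
    "difference_meta",
    "sensitivity_r_grid",
    "subgroup_analysis",
    "meta_regression",
    "eggers_test",
    "variance_ratio_test",
    "se_from_ci",
]

#: variance floor for correlation-adjusted differences at r ~ 1 with near-equal SEs
VAR_FLOOR = 1e-8


def se_from_ci(low: float, high: float, level: float = 0.95, log_scale: bool = False) -> float:
    """Back-derive a standard error from a printed symmetric confidence interval.

    On the log scale (odds ratios) the bounds are log-transformed first, so a
    95% interval gives ``se = (ln(high) - ln(low)) / (2 * 1.96)``.
    """
    if not high > low:
        raise ValueError("upper bound must exceed lower bound")
    if log_scale:
        if low <= 0:
            raise ValueError("log-scale bounds must be positive")
        low, high = math.log(low), math.log(high)
    z = stats.norm.ppf(0.5 + level / 2.0)
    return (high - low) / (2.0 * z)


def _check_inputs(yi, vi) -> tuple[np.ndarray, np.ndarray]:
    yi = np.asarray(yi, dtype=float)
    vi = np.asarray(vi, dtype=float)
    if yi.shape != vi.shape or yi.ndim != 1:
        raise ValueError("yi and vi must be 1-d arrays of equal length")
    if len(yi) < 2:
        raise ValueError("meta-analysis needs at least k = 2 trials")
    if np.any(vi <= 0):
        raise ValueError("all within-trial variances must be positive")
    return yi, vi


def _restricted_ll(tau2: float, yi: np.ndarray, vi: np.ndarray) -> float:
    w = 1.0 / (vi + tau2)
    mu = np.sum(w * yi) / np.sum(w)
    return -0.5 * (np.sum(np.log(vi + tau2)) + np.log(np.sum(w)) + np.sum(w * (yi - mu) ** 2))


def reml_tau2(yi: Sequence[float], vi: Sequence[float], tol: float = 1e-10, max_iter: int = 100) -> float:
    """Between-trial variance tau^2 by restricted maximum likelihood.

    Fisher scoring on the restricted log-likelihood with step-halving,
    floored at zero.  Identical effects give tau^2 = 0 exactly.
    """
    yi, vi = _check_inputs(yi, vi)
    if np.allclose(yi, yi[0]):
        return 0.0
    # DerSimonian-Laird start
    wf = 1.0 / vi
    mu_f = np.sum(wf * yi) / np.sum(wf)
    q = np.sum(wf * (yi - mu_f) ** 2)
    c = np.sum(wf) - np.sum(wf**2) / np.sum(wf)
    tau2 = max((q - (len(yi) - 1)) / c, 0.0)

    ll = _restricted_ll(tau2, yi, vi)
    for _ in range(max_iter):
        w = 1.0 / (vi + tau2)
        sw, sw2, sw3 = np.sum(w), np.sum(w**2), np.sum(w**3)
        mu = np.sum(w * yi) / sw
        score = -0.5 * (sw - sw2 / sw - np.sum(w**2 * (yi - mu) ** 2))
        info = 0.5 * (sw2 - 2.0 * sw3 / sw + (sw2 / sw) ** 2)
        if info <= 0:
            break
        step = score / info
        if tau2 == 0.0 and score < 0:  # boundary maximum
            return 0.0
        new = max(tau2 + step, 0.0)
        # step-halve until the restricted likelihood does not decrease
        for _ in range(30):
            new_ll = _restricted_ll(new, yi, vi)
            if new_ll >= ll - 1e-12:
                break
            new = 0.5 * (new + tau2)
        else:
            break
        if abs(new - tau2) < tol:
            return new
        tau2, ll = new, new_ll
    # fall back to bounded scalar maximisation before giving up
    upper = 100.0 * max(float(np.var(yi)), float(np.max(vi)), 1e-8)
    res = optimize.minimize_scalar(
        lambda t2: -_restricted_ll(t2, yi, vi), bounds=(0.0, upper), method="bounded",
        options={"xatol": 1e-12},
    )
    if not res.success:
        raise ConvergenceError("REML did not converge", last_value=tau2)
    return max(float(res.x), 0.0)


def _typical_within_variance(vi: np.ndarray) -> float:
    """Higgins' s~^2, the 'typical' within-study variance used for I^2."""
    wf = 1.0 / vi
    k = len(vi)
    return (k - 1) * np.sum(wf) / (np.sum(wf) ** 2 - np.sum(wf**2))


def pool(
    yi: Sequence[float],
    vi: Sequence[float],
    tau2: float | None = None,
    level: float = 0.95,
    knapp_hartung: bool = False,
    i2_method: str = "higgins",
) -> PooledEstimate:
    """Inverse-variance random-effects pool with normal-theory CI and p-value.

    ``tau2=None`` estimates it by REML.  Cochran's Q is computed on fixed
    (1/vi) weights.  ``i2_method="higgins"`` uses tau^2/(tau^2 + s~^2) with
    the typical within-study variance; ``"q"`` uses max(0, (Q - df)/Q).
    """
    yi, vi = _check_inputs(yi, vi)
    if tau2 is None:
        tau2 = reml_tau2(yi, vi)
    if tau2 < 0:
        raise ValueError("tau2 must be non-negative")
    w = 1.0 / (vi + tau2)
    mu = float(np.sum(w * yi) / np.sum(w))
    se = float(np.sqrt(1.0 / np.sum(w)))
    k = len(yi)

    wf = 1.0 / vi
    mu_f = np.sum(wf * yi) / np.sum(wf)
    q = float(np.sum(wf * (yi - mu_f) ** 2))
    if i2_method == "higgins":
        i2 = 100.0 * tau2 / (tau2 + _typical_within_variance(vi))
    elif i2_method == "q":
        i2 = 100.0 * max(0.0, (q - (k - 1)) / q) if q > 0 else 0.0
    else:
        raise ValueError(f"unknown i2_method {i2_method!r}")

    if knapp_hartung:
        s2 = float(np.sum(w * (yi - mu) ** 2) / (k - 1))
        se = float(np.sqrt(s2 / np.sum(w)))
        crit = stats.t.ppf(0.5 + level / 2.0, df=k - 1)
        p = float(2.0 * stats.t.sf(abs(mu / se), df=k - 1)) if se > 0 else 0.0
    else:
        crit = stats.norm.ppf(0.5 + level / 2.0)
        p = float(2.0 * stats.norm.sf(abs(mu / se))) if se > 0 else 0.0
    return PooledEstimate(
        mu=mu, se=se, ci_low=mu - crit * se, ci_high=mu + crit * se,
        p=p, tau2=float(tau2), i2=float(i2), q=q, k=k,
    )


def _align(records_a: Sequence[EstimateRecord], records_b: Sequence[EstimateRecord]):
    a = {r.trial_id: r for r in records_a}
    b = {r.trial_id: r for r in records_b}
    if set(a) != set(b):
        raise ValueError(f"trial sets differ: {sorted(set(a) ^ set(b))}")
    if len(a) != len(records_a) or len(b) != len(records_b):
        raise ValueError("duplicate trial_id in records")
    scales = {r.scale for r in list(records_a) + list(records_b)}
    if len(scales) != 1:
        raise ValueError(f"records mix scales: {sorted(scales)}")
    ids = sorted(a)
    return ids, a, b, scales.pop()


def difference_meta(
    records_a: Sequence[EstimateRecord],
    records_b: Sequence[EstimateRecord],
    r: float = 1.0,
    knapp_hartung: bool = False,
) -> DifferenceResult:
    """REML-pool the within-trial differences of two methods' estimates.

    Per trial ``delta_i = f(y_b) - f(y_a)`` with variance
    ``v_a + v_b - 2 r sqrt(v_a v_b)`` (floored at 1e-8 when the correlation
    adjustment drives it non-positive; flagged in ``warnings``).

    Orientation: on the SMD scale, where benefit is negative, deltas are
    differences of magnitudes ``|g_b| - |g_a|`` so that positive means method
    b estimates a larger benefit; on the log-OR scale deltas are plain
    differences ``log OR_b - log OR_a`` (exp of the pool is the ROR).
    """
    if not 0.0 <= r <= 1.0:
        raise ValueError(f"correlation r must be in [0, 1], got {r}")
    ids, a, b, scale = _align(records_a, records_b)
    warnings: list[str] = []
    deltas, dvars = [], []
    for t in ids:
        ya, yb = a[t].estimate, b[t].estimate
        delta = (abs(yb) - abs(ya)) if scale == SCALE_SMD else (yb - ya)
        v = a[t].variance + b[t].variance - 2.0 * r * math.sqrt(a[t].variance * b[t].variance)
        if v <= VAR_FLOOR:
            warnings.append(f"{t}: var(delta) {v:.3g} <= floor, set to {VAR_FLOOR}")
            v = VAR_FLOOR
        deltas.append(delta)
        dvars.append(v)
    pooled = pool(deltas, dvars, knapp_hartung=knapp_hartung)
    methods = ({rec.method for rec in records_a}.pop(), {rec.method for rec in records_b}.pop())
    out_scale = "delta_smd" if scale == SCALE_SMD else "log_ror"
    return DifferenceResult(
        comparison=f"{methods[1]}_vs_{methods[0]}",
        scale=out_scale,
        pooled=pooled,
        r_assumed=r,
        per_trial_deltas=list(zip(ids, deltas, dvars)),
        warnings=warnings,
    )


def sensitivity_r_grid(
    records_a: Sequence[EstimateRecord],
    records_b: Sequence[EstimateRecord],
    r_values: Sequence[float] = (0.5, 0.6, 0.7, 0.8, 0.9, 1.0),
) -> list[DifferenceResult]:
    """One correlated-difference pool per assumed correlation r.

    As r decreases the per-trial difference variances grow, so the
    heterogeneity share I^2 is non-increasing in decreasing r.
    """
    if any(not 0.0 <= r <= 1.0 for r in r_values):
        raise ValueError("all r values must lie in [0, 1]")
    return [difference_meta(records_a, records_b, r=r) for r in r_values]


def subgroup_analysis(
    yi: Sequence[float],
    vi: Sequence[float],
    groups: Sequence,
) -> tuple[dict, float, float]:
    """Group-wise REML pools plus a between-group heterogeneity test.

    Returns ``(pools_by_group, Q_between, p)`` where Q_between compares the
    group means with inverse-variance weights on a chi-square with
    (#groups - 1) degrees of freedom.  Singleton groups contribute their own
    effect and within-trial variance.
    """
    yi, vi = _check_inputs(yi, vi)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("subgroup analysis needs at least two groups")
    pools: dict = {}
    mus, ses = [], []
    for g in labels:
        m = groups == g
        if m.sum() >= 2:
            pg = pool(yi[m], vi[m])
            pools[g] = pg
            mus.append(pg.mu)
            ses.append(pg.se)
        else:
            est = float(yi[m][0])
            se = float(np.sqrt(vi[m][0]))
            z = stats.norm.ppf(0.975)
            pools[g] = PooledEstimate(
                mu=est, se=se, ci_low=est - z * se, ci_high=est + z * se,
                p=float(2 * stats.norm.sf(abs(est / se))), tau2=0.0, i2=0.0, q=0.0, k=1,
            )
            mus.append(est)
            ses.append(se)
    wg = 1.0 / np.asarray(ses) ** 2
    grand = np.sum(wg * mus) / np.sum(wg)
    q_between = float(np.sum(wg * (np.asarray(mus) - grand) ** 2))
    p = float(stats.chi2.sf(q_between, df=len(labels) - 1))
    return pools, q_between, p


def meta_regression(
    yi: Sequence[float],
    vi: Sequence[float],
    moderators: pd.DataFrame | Mapping[str, Sequence[float]],
) -> pd.DataFrame:
    """Weighted meta-regression with REML residual heterogeneity.

    Returns a coefficient table (intercept first) with SEs, z and p values,
    and the residual tau^2 attached as ``df.attrs["tau2"]``.
    """
    yi, vi = _check_inputs(yi, vi)
    X = pd.DataFrame(moderators).copy()
    if len(X) != len(yi):
        raise ValueError("moderator rows must match number of trials")
    X = pd.get_dummies(X, drop_first=True, dtype=float)
    X.insert(0, "intercept", 1.0)
    Xm = X.to_numpy(dtype=float)
    k, p_dim = Xm.shape
    if np.linalg.matrix_rank(Xm) < p_dim:
        raise ValueError(f"moderator design is rank deficient (columns: {list(X.columns)})")
    if k <= p_dim:
        raise ValueError("need more trials than moderator coefficients")

    def negll(tau2: float) -> float:
        w = 1.0 / (vi + tau2)
        W = np.diag(w)
        xtwx = Xm.T @ W @ Xm
        beta = np.linalg.solve(xtwx, Xm.T @ (w * yi))
        resid = yi - Xm @ beta
        sign, logdet = np.linalg.slogdet(xtwx)
        return 0.5 * (np.sum(np.log(vi + tau2)) + logdet + np.sum(w * resid**2))

    upper = 100.0 * max(float(np.var(yi)), float(np.max(vi)), 1e-8)
    res = optimize.minimize_scalar(negll, bounds=(0.0, upper), method="bounded", options={"xatol": 1e-12})
    tau2 = max(float(res.x), 0.0)
    w = 1.0 / (vi + tau2)
    xtwx = Xm.T @ np.diag(w) @ Xm
    beta = np.linalg.solve(xtwx, Xm.T @ (w * yi))
    cov = np.linalg.inv(xtwx)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    out = pd.DataFrame(
        {"coef": beta, "se": se, "z": z, "p": 2 * stats.norm.sf(np.abs(z))},
        index=list(X.columns),
    )
    out.attrs["tau2"] = tau2
    return out


def eggers_test(yi: Sequence[float], vi: Sequence[float]) -> tuple[float, float, float]:
    """Egger's regression test for small-study/funnel asymmetry.

    Regresses the standardised effect y_i/se_i on precision 1/se_i; returns
    ``(intercept, se_intercept, p)`` with a two-sided t test on k - 2 df.
    A symmetric funnel gives intercept 0.
    """
    yi, vi = _check_inputs(yi, vi)
    if len(yi) < 3:
        raise ValueError("Egger's test needs at least k = 3 trials")
    sei = np.sqrt(vi)
    z = yi / sei
    prec = 1.0 / sei
    X = np.column_stack([np.ones_like(prec), prec])
    beta, *_ = np.linalg.lstsq(X, z, rcond=None)
    resid = z - X @ beta
    df = len(yi) - 2
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se0 = math.sqrt(cov[0, 0])
    t0 = beta[0] / se0
    p = float(2 * stats.t.sf(abs(t0), df=df))
    return float(beta[0]), se0, p


def variance_ratio_test(sd1: float, n1: int, sd2: float, n2: int) -> tuple[float, float]:
    """Two-sided F test of equal variances: F = sd1^2/sd2^2 on (n1-1, n2-1) df."""
    if n1 < 2 or n2 < 2:
        raise ValueError("both samples need n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("standard deviations must be positive")
    f = (sd1 / sd2) ** 2
    dist = stats.f(n1 - 1, n2 - 1)
    p = float(2 * min(dist.cdf(f), dist.sf(f)))
    return float(f), min(p, 1.0)
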