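"""Per-trial estimators: exact identities, closed-form oracles, collapse properties."""
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cacemeta import estimators
from cacemeta.estimators import (
    compliance_rate,
    fit_cace_binary,
    fit_cace_continuous,
    fit_itt_binary,
    fit_itt_continuous,
    hedges_g,
    make_pp_table,
    standardise_within_trial,
)
from cacemeta.simulate import simulate_trial
from cacemeta.types import EstimationError, SeparationError, TrialSimConfig, WeakInstrumentError

from conftest import make_binary_trial


def _toy_table(rows):
    df = pd.DataFrame(rows, columns=["arm", "baseline", "followup", "adhered"])
    df["trial_id"] = "toy"
    df["participant_id"] = [str(i) for i in range(len(df))]
    df["responder"] = np.nan
    return df


def test_itt_continuous_exact_fit_on_toy_data():
    # equal baselines, intervention outcomes exactly 2 lower -> B = -2, zero residual
    table = _toy_table(
        [
            ("control", 20, 12, np.nan),
            ("control", 25, 14, np.nan),
            ("intervention", 20, 10, 1.0),
            ("intervention", 25, 12, 1.0),
        ]
    )
    rec = fit_itt_continuous(table)
    assert rec.estimate == pytest.approx(-2.0, abs=1e-10)
    assert rec.se == pytest.approx(0.0, abs=1e-8)


def test_itt_continuous_requires_both_arms():
    table = _toy_table([("control", 20, 12, np.nan), ("control", 21, 11, np.nan)])
    with pytest.raises(EstimationError, match="intervention"):
        fit_itt_continuous(table)


def test_collinear_covariates_are_named():
    cfg = TrialSimConfig.balanced("A", 50, 0.7, seed=0)
    table, _ = simulate_trial(cfg)
    table["dup"] = table["baseline"]
    with pytest.raises(EstimationError, match="collinear"):
        fit_itt_continuous(table, covariate_names=["dup"])


def test_itt_binary_matches_cross_product_odds_ratio():
    # published 2x2 for the largest CBT trial: control 167 no / 46 yes,
    # intervention 111 no / 95 yes -> OR = (95*167)/(46*111) = 3.107
    rows = (
        [("control", 0.0)] * 167 + [("control", 1.0)] * 46
        + [("intervention", 0.0)] * 111 + [("intervention", 1.0)] * 95
    )
    df = pd.DataFrame(rows, columns=["arm", "responder"])
    df["trial_id"] = "toy"
    df["baseline"] = 30.0
    df["followup"] = np.nan
    df["adhered"] = np.where(df["arm"] == "intervention", 1.0, np.nan)
    rec = fit_itt_binary(df, adjust_baseline=False)
    assert rec.odds_ratio == pytest.approx((95 * 167) / (46 * 111), rel=1e-6)


def test_itt_binary_balanced_responders_give_unit_odds_ratio():
    rows = (
        [("control", 0.0)] * 50 + [("control", 1.0)] * 50
        + [("intervention", 0.0)] * 50 + [("intervention", 1.0)] * 50
    )
    df = pd.DataFrame(rows, columns=["arm", "responder"])
    df["trial_id"] = "toy"
    df["baseline"] = 30.0
    df["followup"] = np.nan
    df["adhered"] = np.where(df["arm"] == "intervention", 1.0, np.nan)
    assert fit_itt_binary(df, adjust_baseline=False).odds_ratio == pytest.approx(1.0, abs=1e-8)


def test_itt_binary_separation_error():
    rows = [("control", 0.0)] * 30 + [("intervention", 0.0)] * 15 + [("intervention", 1.0)] * 15
    df = pd.DataFrame(rows, columns=["arm", "responder"])
    df["trial_id"] = "toy"
    df["baseline"] = 30.0
    df["followup"] = np.nan
    df["adhered"] = np.nan
    with pytest.raises(SeparationError, match="control"):
        fit_itt_binary(df, adjust_baseline=False)


def test_pp_table_construction():
    cfg = TrialSimConfig.balanced("A", 400, 0.62, missing_adherence_prob=0.05, seed=1)
    table, _ = simulate_trial(cfg)
    pp = make_pp_table(table)
    # all controls kept, only observed adherent intervention rows kept
    assert (pp[pp["arm"] == "control"].index == table[table["arm"] == "control"].index).all()
    inter = pp[pp["arm"] == "intervention"]
    assert (inter["adhered"] == 1.0).all()
    assert len(inter) == (table.loc[table["arm"] == "intervention", "adhered"] == 1.0).sum()


def test_pp_table_all_adhered_equals_itt_population():
    cfg = TrialSimConfig.balanced("A", 100, 1.0, seed=2)
    table, _ = simulate_trial(cfg)
    pd.testing.assert_frame_equal(make_pp_table(table), table)


def test_pp_table_degenerate_when_adherence_all_missing():
    cfg = TrialSimConfig.balanced("A", 50, 0.5, seed=3)
    table, _ = simulate_trial(cfg)
    table.loc[table["arm"] == "intervention", "adhered"] = np.nan
    with pytest.raises(EstimationError, match="degenerate"):
        make_pp_table(table)


@settings(max_examples=15, deadline=None, derandomize=True)
@given(
    pi=st.floats(0.2, 0.95),
    effect=st.floats(-8.0, 0.0),
    seed=st.integers(0, 10_000),
)
def test_wald_identity_without_covariates(pi, effect, seed):
    """2SLS with no exogenous adjustment equals the ITT / compliance ratio exactly."""
    cfg = TrialSimConfig.balanced("W", 300, pi, cace_effect=effect, confounding_strength=0.4, seed=seed)
    table, _ = simulate_trial(cfg)
    itt = fit_itt_continuous(table, adjust_baseline=False)
    cace = fit_cace_continuous(table, adjust_baseline=False)
    assert cace.estimate == pytest.approx(itt.estimate / compliance_rate(table), rel=1e-9)


def test_full_compliance_collapses_all_three_estimands():
    cfg = TrialSimConfig.balanced("A", 1000, 1.0, cace_effect=-4.0, seed=5)
    table, _ = simulate_trial(cfg)
    itt = fit_itt_continuous(table)
    pp = fit_itt_continuous(make_pp_table(table))
    cace = fit_cace_continuous(table)
    assert pp.estimate == pytest.approx(itt.estimate, abs=1e-9)
    assert cace.estimate == pytest.approx(itt.estimate, abs=1e-9)


def test_cace_weak_instrument_error():
    cfg = TrialSimConfig.balanced("A", 100, 0.0, seed=6)
    table, _ = simulate_trial(cfg)
    with pytest.raises(WeakInstrumentError):
        fit_cace_continuous(table)


def test_binary_cace_moment_recovery_closed_form():
    # p_ctrl = 0.34, p_never = 0.20, pi_c = 0.6 -> p_c0 = (0.34 - 0.4*0.2)/0.6 = 0.4333...
    p_c0 = (0.34 - 0.4 * 0.20) / 0.6
    assert p_c0 == pytest.approx(0.43333, abs=1e-4)
    # estimator recovers the implied complier log OR on a large direct draw
    table = make_binary_trial(
        60000, 60000, pi_c=0.6, p_c0=p_c0, p_c1=0.55, p_never=0.20, seed=7
    )
    rec = fit_cace_binary(table, n_bootstrap=49, seed=1)
    truth = math.log(0.55 / 0.45) - math.log(p_c0 / (1 - p_c0))
    assert rec.estimate == pytest.approx(truth, abs=0.05)
    assert rec.compliance_rate == pytest.approx(0.6, abs=0.01)


def _em_mixture_oracle(n0, r0, n1a, r1a, n1n, r1n, iters=2000):
    """Independent EM oracle: full ML over (pi, p_c0, p_c1, p_never) sharing
    the never-taker rate across arms through the control-arm mixture."""
    pi = n1a / (n1a + n1n)
    p_c1 = r1a / n1a
    p_n = r1n / n1n
    p_c0 = min(max((r0 / n0 - (1 - pi) * p_n) / pi, 1e-6), 1 - 1e-6)
    for _ in range(iters):
        # E-step: posterior complier weight for control responders / non-responders
        w_resp = pi * p_c0 / (pi * p_c0 + (1 - pi) * p_n)
        w_non = pi * (1 - p_c0) / (pi * (1 - p_c0) + (1 - pi) * (1 - p_n))
        nc_resp = r0 * w_resp
        nc_non = (n0 - r0) * w_non
        # M-step
        p_c0 = nc_resp / (nc_resp + nc_non)
        p_n = (r1n + (r0 - nc_resp)) / (n1n + (n0 - nc_resp - nc_non))
        pi = (n1a + nc_resp + nc_non) / (n0 + n1a + n1n)
    return p_c0, p_c1, p_n, pi


def test_binary_cace_matches_em_oracle_on_large_table():
    table = make_binary_trial(
        150000, 150000, pi_c=0.65, p_c0=0.35, p_c1=0.55, p_never=0.22, seed=11
    )
    inter = table[table["arm"] == "intervention"]
    ctrl = table[table["arm"] == "control"]
    adh = inter["adhered"] == 1.0
    p_c0_em, p_c1_em, _, _ = _em_mixture_oracle(
        len(ctrl), int(ctrl["responder"].sum()),
        int(adh.sum()), int(inter.loc[adh, "responder"].sum()),
        int((~adh).sum()), int(inter.loc[~adh, "responder"].sum()),
    )
    rec = fit_cace_binary(table, n_bootstrap=49, seed=2)
    em_logor = math.log(p_c1_em / (1 - p_c1_em)) - math.log(p_c0_em / (1 - p_c0_em))
    # implied complier probabilities from the plug-in estimate vs full-ML EM
    assert rec.estimate == pytest.approx(em_logor, abs=5e-3)


def test_binary_cace_full_compliance_reduces_to_itt():
    table = make_binary_trial(4000, 4000, pi_c=1.0, p_c0=0.3, p_c1=0.5, p_never=0.2, seed=3)
    rec = fit_cace_binary(table, n_bootstrap=99, seed=4)
    itt = fit_itt_binary(table, adjust_baseline=False)
    assert rec.estimate == pytest.approx(itt.estimate, abs=1e-6)


def test_bias_ordering_under_confounded_adherence():
    """PP drifts from the true complier effect while the IV estimator stays close."""
    rng = np.random.default_rng(2024)
    pp_est, cace_est = [], []
    truth = -8.0
    for _ in range(120):
        cfg = TrialSimConfig.balanced(
            "B", 300, 0.6, cace_effect=truth, confounding_strength=0.5,
            baseline_mean=35, baseline_sd=8, baseline_slope=0.4,
            control_change_mean=-3, residual_sd=8, seed=int(rng.integers(2**31)),
        )
        table, ledger = simulate_trial(cfg)
        pp_est.append(fit_itt_continuous(make_pp_table(table)).estimate)
        cace_est.append(fit_cace_continuous(table).estimate)
    pp_bias = np.mean(pp_est) - truth
    cace_bias = np.mean(cace_est) - truth
    assert abs(pp_bias) > abs(cace_bias)
    assert pp_bias < 0  # configured direction: compliers healthier, PP overstates benefit
    assert ledger.true_pp_bias < 0


@pytest.mark.parametrize(
    "b,sd,n1,n2,expected",
    [
        (-5.68, 13.5, 213, 206, -0.42),  # published COBALT regime
        (0.0, 10.0, 50, 50, 0.0),
    ],
)
def test_hedges_g_values(b, sd, n1, n2, expected):
    assert hedges_g(b, sd, n1, n2) == pytest.approx(expected, abs=0.005)


def test_hedges_small_sample_correction():
    # n1 = n2 = 2 -> J = 1 - 3/7
    g = hedges_g(1.0, 1.0, 2, 2)
    assert g == pytest.approx(1 - 3 / 7, abs=1e-12)


def test_hedges_g_propagates_se():
    g, se = hedges_g(-5.0, 10.0, 100, 100, se_b=2.0)
    assert se == pytest.approx(abs(g / -5.0) * 2.0, rel=1e-12)


def test_hedges_g_rejects_bad_sd():
    with pytest.raises(ValueError):
        hedges_g(1.0, 0.0, 10, 10)


def test_compliance_rate_basic():
    cfg = TrialSimConfig.balanced("A", 300, 1.0, seed=8)
    table, _ = simulate_trial(cfg)
    assert compliance_rate(table) == 1.0
    table.loc[table["arm"] == "intervention", "adhered"] = np.nan
    with pytest.raises(EstimationError):
        compliance_rate(table)


def test_standardise_within_trial_properties():
    cfg1 = TrialSimConfig.balanced("A", 200, 0.7, scale="BDI", seed=9)
    cfg2 = TrialSimConfig.balanced("B", 200, 0.7, scale="PHQ9", baseline_mean=14, baseline_sd=5,
                                   control_change_mean=-4, residual_sd=4, seed=10)
    t1, _ = simulate_trial(cfg1)
    t2, _ = simulate_trial(cfg2)
    both = standardise_within_trial(pd.concat([t1, t2], ignore_index=True))
    for trial in ("A", "B"):
        z = both.loc[both["trial_id"] == trial, "followup_z"].dropna()
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.std(ddof=1) == pytest.approx(1.0, abs=1e-12)


def test_standardise_rejects_constant_scores():
    df = pd.DataFrame(
        {"trial_id": "A", "baseline": [10.0] * 5, "followup": [3.0, 4, 5, 6, 7]}
    )
    with pytest.raises(EstimationError, match="zero variance"):
        standardise_within_trial(df)
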