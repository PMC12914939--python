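import numpy as np
import pandas as pd
import pytest

from cacemeta.simulate import simulate_collaboration
from cacemeta.types import TrialSimConfig


def make_binary_trial(
    n_control: int,
    n_intervention: int,
    pi_c: float,
    p_c0: float,
    p_c1: float,
    p_never: float,
    seed: int = 0,
    trial_id: str = "BIN",
) -> pd.DataFrame:
    """Binary-outcome trial drawn directly from principal-stratum probabilities.

    Complier control/intervention response rates p_c0/p_c1 and the never-taker
    rate p_never (same in both arms: exclusion restriction) define the truth;
    the complier log odds ratio is logit(p_c1) - logit(p_c0).
    """
    rng = np.random.default_rng(seed)
    n = n_control + n_intervention
    arm = np.array(["control"] * n_control + ["intervention"] * n_intervention)
    complier = rng.random(n) < pi_c
    assigned = arm == "intervention"
    p = np.where(
        complier, np.where(assigned, p_c1, p_c0), p_never
    )
    resp = (rng.random(n) < p).astype(float)
    return pd.DataFrame(
        {
            "trial_id": trial_id,
            "participant_id": [f"{trial_id}-{i}" for i in range(n)],
            "arm": arm,
            "baseline": 20.0,
            "followup": np.nan,
            "responder": resp,
            "adhered": np.where(assigned, complier.astype(float), np.nan),
        }
    )


@pytest.fixture(scope="session")
def small_collaboration():
    """Seven modest trials with known truths (gentle scores: negligible clamping)."""
    rng = np.random.default_rng(42)
    configs = [
        TrialSimConfig.balanced(
            f"T{i}",
            n_per_arm=250,
            compliance_prob=pc,
            baseline_mean=34.0,
            baseline_sd=8.0,
            baseline_slope=0.4,
            control_change_mean=-4.0,
            residual_sd=8.0,
            cace_effect=eff,
            confounding_strength=0.3,
            missing_outcome_prob=0.1,
            missing_adherence_prob=0.02,
            seed=int(rng.integers(2**31)),
        )
        for i, (pc, eff) in enumerate(
            [(0.62, -5.0), (0.80, -2.0), (0.72, -1.0), (0.61, -6.0), (0.72, -2.0), (0.94, -1.0), (0.57, -1.0)]
        )
    ]
    ipd, truths = simulate_collaboration(configs)
    return ipd, truths, configs
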