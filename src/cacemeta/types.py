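"""Shared result containers and configuration records.

The three estimands compared throughout the package:

* **ITT** — intention-to-treat: effect of *assignment*, comparing arms as
  randomised regardless of adherence (treatment-policy estimand).
* **PP** — per-protocol: control arm versus the adherent subset of the
  intervention arm; breaks randomisation and is vulnerable to selection bias.
* **CACE** — complier average causal effect: effect of *receipt* in the
  principal stratum of compliers, identified by using randomisation as an
  instrument under the exclusion restriction and monotonicity.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

METHODS = ("ITT", "PP", "CACE")

#: analysis scales for per-trial effects
SCALE_RAW = "raw_mean_diff"
SCALE_SMD = "smd_g"
SCALE_LOG_OR = "log_odds_ratio"

#: score ranges of the two depression instruments the generator emulates
SCALE_RANGES = {"BDI": (0, 63), "PHQ9": (0, 27)}

RESPONDER_RULES = ("half_reduction", "below10", "below10_and_minus5")


class ConfigurationError(ValueError):
    """Invalid simulation or run configuration; message names the field."""


class EstimationError(RuntimeError):
    """An estimator could not produce a valid estimate."""


class SeparationError(EstimationError):
    """Logistic outcome perfectly separated (an arm with all-0 or all-1 responders)."""


class WeakInstrumentError(EstimationError):
    """No (or almost no) compliers: randomisation carries no information about receipt."""


class ConvergenceError(EstimationError):
    """Iterative fit failed to converge; carries the last iterate."""

    def __init__(self, message: str, last_value: float | None = None):
        super().__init__(message)
        self.last_value = last_value


@dataclass
class EstimateRecord:
    """One method's effect for one trial on one analysis scale."""

    trial_id: str
    method: str  # ITT | PP | CACE
    scale: str  # raw_mean_diff | smd_g | log_odds_ratio
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    n_analysed: int
    compliance_rate: float | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.se < 0:
            raise ValueError("se must be non-negative")
        if not (self.ci_low - 1e-9 <= self.estimate <= self.ci_high + 1e-9):
            raise ValueError("confidence interval must bracket the estimate")

    @property
    def variance(self) -> float:
        return self.se**2

    @property
    def odds_ratio(self) -> float:
        if self.scale != SCALE_LOG_OR:
            raise ValueError("odds_ratio only defined on the log-odds-ratio scale")
        return math.exp(self.estimate)


@dataclass
class PooledEstimate:
    """Random-effects pooled effect with heterogeneity statistics."""

    mu: float
    se: float
    ci_low: float
    ci_high: float
    p: float
    tau2: float
    i2: float  # percent, Higgins convention by default
    q: float
    k: int

    def __post_init__(self) -> None:
        if self.tau2 < 0:
            raise ValueError("tau2 must be non-negative")
        if not (self.ci_low - 1e-9 <= self.mu <= self.ci_high + 1e-9):
            raise ValueError("confidence interval must bracket mu")

    @property
    def exp_mu(self) -> float:
        """Pooled effect back-transformed from the log scale (OR or ROR)."""
        return math.exp(self.mu)

    @property
    def exp_ci(self) -> tuple[float, float]:
        return math.exp(self.ci_low), math.exp(self.ci_high)


@dataclass
class DifferenceResult:
    """Pooled within-trial difference between two estimation methods.

    ``pooled.mu`` is a ΔSMD when ``scale == "delta_smd"`` and a log ratio of
    odds ratios when ``scale == "log_ror"`` (``pooled.exp_mu`` is the ROR).
    """

    comparison: str  # e.g. "PP_vs_ITT"
    scale: str  # delta_smd | log_ror
    pooled: PooledEstimate
    r_assumed: float
    per_trial_deltas: list[tuple[str, float, float]]  # (trial_id, delta, var)
    warnings: list[str] = field(default_factory=list)


@dataclass
class TruthLedger:
    """Known estimands of one simulated trial (sidecar, never in the analysis table).

    When the exclusion restriction holds (``never_taker_assignment_effect == 0``)
    the identity ``true_itt = pi_c * true_cace`` holds; with
    ``confounding_strength == 0`` the per-protocol contrast is unbiased for the
    CACE, so ``true_pp_bias == 0``.
    """

    trial_id: str
    true_cace: float
    true_itt: float
    true_pp_bias: float
    pi_c: float


@dataclass
class CovariateSpec:
    """Categorical stratification covariate: named levels with sampling probabilities."""

    name: str
    levels: Sequence[str]
    probs: Sequence[float] | None = None  # uniform when omitted

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ConfigurationError(f"covariate {self.name!r}: needs >= 2 levels")
        if self.probs is not None:
            if len(self.probs) != len(self.levels):
                raise ConfigurationError(f"covariate {self.name!r}: probs/levels length mismatch")
            if abs(sum(self.probs) - 1.0) > 1e-9 or min(self.probs) < 0:
                raise ConfigurationError(f"covariate {self.name!r}: probs must be a distribution")


@dataclass
class TrialSimConfig:
    """Generating parameters of one two-arm trial with one-sided noncompliance.

    Score units refer to the declared instrument scale (BDI 0-63, PHQ9 0-27).
    ``cace_effect`` is the true effect of treatment receipt among compliers
    (negative = symptom improvement).  ``confounding_strength`` is the loading
    of a shared latent prognosis variable on both complier membership and the
    follow-up score; 0 makes the per-protocol contrast unbiased.
    ``never_taker_assignment_effect`` breaks the exclusion restriction when
    non-zero.
    """

    trial_id: str
    n_control: int
    n_intervention: int
    compliance_prob: float
    scale: str = "BDI"
    baseline_mean: float = 32.0
    baseline_sd: float = 10.0
    control_change_mean: float = -12.0
    cace_effect: float = -4.0
    never_taker_assignment_effect: float = 0.0
    confounding_strength: float = 0.0
    residual_sd: float = 9.0
    baseline_slope: float = 0.5  # follow-up units per baseline unit (anchoring)
    responder_rule: str = "half_reduction"
    missing_outcome_prob: float = 0.0
    missing_adherence_prob: float = 0.0
    strat_factors: Sequence[CovariateSpec] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("compliance_prob", "missing_outcome_prob", "missing_adherence_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        for name in ("n_control", "n_intervention"):
            v = getattr(self, name)
            if not isinstance(v, (int,)) or v < 2:
                raise ConfigurationError(f"{name} must be an integer >= 2, got {v}")
        if self.scale not in SCALE_RANGES:
            raise ConfigurationError(f"scale must be one of {sorted(SCALE_RANGES)}, got {self.scale!r}")
        if self.responder_rule not in RESPONDER_RULES:
            raise ConfigurationError(
                f"responder_rule must be one of {RESPONDER_RULES}, got {self.responder_rule!r}"
            )
        if self.baseline_sd <= 0 or self.residual_sd <= 0:
            raise ConfigurationError("baseline_sd and residual_sd must be positive")

    @classmethod
    def balanced(cls, trial_id: str, n_per_arm: int, compliance_prob: float, **kwargs) -> "TrialSimConfig":
        """Convenience constructor for equal arm sizes."""
        return cls(
            trial_id=trial_id,
            n_control=n_per_arm,
            n_intervention=n_per_arm,
            compliance_prob=compliance_prob,
            **kwargs,
        )
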