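# Methods

## Estimands and estimators

Three estimands are compared on each trial, all on both a continuous symptom
scale and a binary improvement outcome.

**ITT.** Analysis of covariance: follow-up score regressed on arm, baseline
score and any stratification covariates over all randomised participants
with observed outcomes. The arm coefficient is the unstandardised mean
difference B; Hedge's g divides B by the pooled follow-up SD across arms and
applies the small-sample correction J = 1 − 3/(4(n₁+n₂−2) − 1). The SMD
denominator is the pooled follow-up SD (this choice reproduces the
collaboration's published g values, e.g. −5.68 / ≈13.5 ≈ −0.42). Binary
outcomes use the analogous logistic model; effects are log odds ratios.

**PP.** The per-protocol population keeps every control participant and the
adherent subset of the intervention arm. Intervention rows with missing
adherence cannot be classified and are dropped; an optional flag applies the
same restriction to active-comparator controls that carry an adherence flag.
The PP estimators are the ITT estimators run on this population.

**CACE, continuous.** Two-stage least squares with randomisation as the
instrument for treatment receipt (receipt ≡ adherence in the intervention
arm, structurally zero under control) and baseline plus covariates as
exogenous regressors in both stages. Standard errors use the
heteroskedasticity-consistent IV sandwich. With no exogenous adjustment this
is algebraically the Wald ratio ITT/π̂_c, which the tests assert exactly.
The identification assumptions — one-sided noncompliance (monotonicity, no
always-takers) and the exclusion restriction (assignment affects never-takers
only through receipt) — match a design where controls cannot access the
intervention.

**CACE, binary.** Principal-stratification maximum likelihood under the same
assumptions: π_c and the never-taker response rate are observed directly in
the intervention arm, and the complier control response rate is recovered
from the control-arm mixture p_ctrl = π_c·p_c0 + (1−π_c)·p_never. The
estimate is the complier log odds ratio. Under this factorisation the
closed-form plug-in *is* the ML solution when the recovered probability is
interior; the tests confirm agreement with an independent full-likelihood EM
to < 1e−3 on large tables. Recovered probabilities outside (0, 1) are clamped
to 1e−6 and flagged. The interval is a percentile bootstrap over participants
(stratified by arm, seeded, 999 replicates by default); failed or clamped
replicates are counted and reported in the record's warnings. Covariates are
not used by the mixture estimator (the binary CACE is unadjusted), which is
recorded as a warning when covariates are requested.

Missing outcomes are handled complete-case everywhere (the ITT population is
defined by observed outcomes); no imputation. Missing adherence is dropped
from CACE analyses by default, with an `as_nontaker` sensitivity switch.

## Two-stage pooling

Stage two pools per-trial effects y_i with within-trial variances v_i using
inverse-variance random-effects weights 1/(v_i + τ²). τ² is estimated by
REML — Fisher scoring with step-halving on the restricted log-likelihood,
tolerance 1e−10, at most 100 iterations, floored at zero, with a bounded
scalar maximisation fallback; a refined-grid oracle in the tests agrees to
1e−6. CIs and p-values are normal-theory by default (Knapp–Hartung is
available behind a flag but off, consistent with the published intervals).
Cochran's Q uses fixed 1/v_i weights. I² follows the Higgins convention
τ²/(τ² + s̃²) with s̃² the typical within-study variance; a Q-based variant
is available behind a flag. I² is invariant to common rescaling of all v_i
and τ².

**Method differences.** Because the three methods analyse the same
participants, per-trial differences use
var(δ_i) = v_a + v_b − 2r√(v_a·v_b). The base case assumes strong
within-study correlation, r = 1.0, with a 0.50–1.00 sensitivity grid
exposed; variances driven ≤ 0 by the adjustment are floored at 1e−8 and
flagged, letting the REML heterogeneity absorb the dispersion (hence the
characteristically high I² in difference models). Orientation: on the SMD
scale, where benefit is negative, δ = |g_b| − |g_a| so positive means method
b finds a larger benefit; on the log-OR scale δ = log OR_b − log OR_a and
exp(pooled δ) is reported as the ratio of odds ratios.

**Replay mode.** For the aggregate-data replay of the collaboration's
published table, standard errors are back-derived from printed 95% CIs
(se = CI width / 3.92, on the log scale for ORs). Printed g values carry no
CIs, so se(g) is obtained from the B interval by the scale factor |g/B|.
Whether to pool g directly or pool B and standardise afterwards is an open
choice; this package pools g. Transcription precision limits this mode:
g is printed to two decimals, and per-trial rounding of ~±0.005 SMD can move
a pooled difference by ~0.01, which matters only where a p-value sits near
the 0.05 boundary (the continuous PP-vs-ITT difference is the one such case).

**Other stage-two tools.** Subgroup analysis pools per group (REML) and
tests between-group heterogeneity with inverse-variance weights on
χ²(G−1); singleton groups contribute their own effect, so two singletons
reduce to a z-test of the difference. Meta-regression profiles the
restricted likelihood over the residual τ² and reports weighted coefficients.
Egger's test regresses the standardised effect on precision with a t test on
the intercept (k − 2 df). Variance-ratio tests compare arm SDs with a
two-sided F test.

## One-stage models

Continuous outcomes are z-scored within trial (observed values, ddof = 1) and
fitted with a linear mixed model: fixed treatment and baseline effects,
random trial intercept and, unless singular, a random treatment effect;
singular fits downgrade to intercept-only with the downgrade recorded.
Binary outcomes use a random-intercept logistic model whose marginal
likelihood is maximised directly by Gauss–Hermite quadrature (31 nodes) —
the installed Python stack has no frequentist GLMM, so the likelihood is
implemented here; a random treatment slope is not supported for the binary
model and requests for one are noted. Stratification variables are excluded
from one-stage models (they are not common to all trials).

One-stage CACE is a reconstruction: continuous, 2SLS on the stacked z-scored
data with fixed trial intercepts and trial-clustered standard errors (a
random treatment effect cannot be carried inside 2SLS); binary, REML
aggregation of per-trial mixture estimates with delta-method variances.

One-stage method comparisons duplicate and stack the data with a method
indicator; exposures are instrumented by randomisation (assignment itself
for ITT/PP), and the method-by-receipt interaction estimates the difference
with a trial-clustered sandwich covariance honouring the participants shared
between the copies. Binary comparisons use per-trial deltas of unadjusted
log odds ratios — all three methods are smooth functions of the same four
cell proportions, so within-trial covariance is handled by the delta method
with a conservative correlation-one combination.

## Synthetic trial generator

Each participant has a latent prognosis U ~ N(0,1). Complier membership
thresholds V = ρU + √(1−ρ²)ε at Φ⁻¹(π_c) with ρ the `confounding_strength`;
the follow-up score loads on U through ρ·residual_sd·U. With ρ > 0 compliers
are systematically healthier, which biases the per-protocol contrast by
ρ²·residual_sd·(−φ(t)/Φ(t)) (recorded in the truth ledger) while leaving ITT
and the IV estimator consistent — the selection-bias mechanism the package
exists to demonstrate. With the exclusion restriction intact
(`never_taker_assignment_effect = 0`), the true ITT equals π_c × CACE.

Follow-up is a baseline-anchored Gaussian: mean = baseline mean + control
improvement + slope·(baseline − mean) + prognosis load + treatment terms,
noise N(0, residual_sd), then rounded and clamped to the instrument range
(BDI-II 0–63, PHQ-9 0–27). The baseline–follow-up anchoring slope defaults
to 0.5 (score units per score unit), a typical within-trial value; it is a
parameter, not an asserted property of the real collaboration. Responder
flags follow trial-specific rules (≥50% reduction; score < 10; score < 10
and reduction ≥ 5). Missingness is MCAR: outcomes in both arms, adherence
only in the intervention arm (it is structurally undefined under control).
Latent truth travels in underscore-prefixed columns that the writers strip
into a sidecar file, so estimators cannot read it.

The default seven-trial scenario takes arm sizes (235/234 … 179/182,
totalling 3,467), compliance fractions (0.62–0.94), instrument scales,
baseline moments, control-arm improvements, outcome missingness (~15%) and
adherence missingness from the published trial characteristics; true
complier effects are set to the published CACE point estimates, and the
residual SD to 85% of the control follow-up SD (the rest is carried by the
baseline anchor). Where a trial's secondary dichotomisation is not published,
the ≥50%-reduction standard is used.

What the generator does *not* emulate: informative (MNAR) missingness,
continuous degrees of adherence, active-control non-adherence, site or
therapist clustering, and floor effects beyond hard clamping. Passing
recovery and coverage tests on these synthetic trials therefore shows the
estimators are correct under the stated generating model, not that the
published per-trial estimates would be reproduced from the confidential
participant data.

## Numerical choices and degenerate inputs

Clamped score tails introduce a small attenuation at extreme parameter
settings; the simulation-based tests use configurations where the clamp mass
is well below 1%, and tolerances are Monte-Carlo bounds (3 binomial or
3 normal SDs) plus a small clamping margin. Calibration and bias-ordering
checks use 500 replicate trials at 300 per arm; large-n identities use
50,000 per arm. Separated logistic outcomes (an all-0 or all-1 arm), empty
arms, zero-compliance instruments, all-missing adherence, constant
standardisation columns, rank-deficient moderator designs and invalid
probabilities all raise typed errors naming the offending input. Equality of
trial sets and a single common scale are enforced before any difference
pool. Per-trial arm sizes are configured separately (`n_control`,
`n_intervention`) because the real collaboration's trial totals are odd; a
`balanced` constructor covers the common case.

## Known limitations

* The published analyses were run in a structural-equation framework; 2SLS
  (continuous) and mixture ML (binary) target the same estimands with one
  binary instrument and one binary exposure, but standard errors can differ
  in higher order. Whether the original SEM used joint-normal ML or
  moment-equivalent estimation is not documented, so no attempt is made to
  match SEs beyond the CI-replay route.
* The exact base-case correlation behind the published difference intervals
  is not printed; r = 1.0 is inferred from compatibility with those
  intervals and exposed as a parameter rather than asserted as fact.
* Replay-mode inputs are printed to 2–3 significant figures, which bounds
  achievable agreement (see above).
* The binary CACE estimator is unadjusted; covariate-adjusted complier odds
  ratios would need a parametric outcome model within strata.
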