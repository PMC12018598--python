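# Methods

## Scoring model and risk groups

A tumor's profile is four histological features assessed on H&E sections
of the primary: worst pattern of invasion (WPOI, ordinal 1–4), lymphocytic
host response (LHR, ordinal 1–3), and the presence of lymphovascular (LVI)
and perineural (PNI) invasion. Point contributions are WPOI 4 → 1, LHR 2
→ 1, LHR 3 → 2, LVI → 1, PNI → 1; all other levels contribute 0. The sum
s ∈ [0, 5] defines the risk group: 0 low, 1–2 intermediate, ≥3 high. The
mapping is total over the 48 possible profiles and monotone: raising any
single feature's contribution never lowers the group.

The comparator EAU stratification uses stage and WHO grade only: pTa and
pT1G1 low, pT1G2 intermediate, pT1G3 and ≥pT2 high. The two classifiers
read disjoint inputs, enforced by their signatures (`score_profile` takes
only the feature profile; `eau_risk_group` only stage/grade). A pT1 tumor
without a recorded grade is an error under EAU grading — no default is
imputed. pT4 is accepted (EAU high); in-situ disease is rejected because
the grading targets invasive carcinoma. pT1 tumors are additionally
subclassifiable into pT1a (G1–G2, no LVI, no PNI) and pT1b (G3 and/or
LVI/PNI).

Records with a missing or out-of-range scored feature are excluded from
grading with a logged warning (hard error in strict mode); no imputation
is attempted. Presence/absence fields accept `0/1`, `present/absent`,
`yes/no`, `true/false` case-insensitively, since pathology exports vary.

## Reference aggregates and their reconstruction

The development cohort (306 patients, 102 with LNM at diagnosis) is not
public at patient level. The package ships its grouped aggregates,
reconstructed as: group sizes are published directly (111/110/85 proposed;
31/55/220 EAU); LNM-positive counts per group are
round(published group rate × group size), giving 2/35/65 and 0/10/92.
Cross-check: both sum to the published 102 LNM-positive total. The
published per-group totals appear in two slightly different versions in
the source material (one table gives 111/106/89); the 111/110/85 version
is canonical here because it is the one from which every published odds
ratio and diagnostic interval is exactly recoverable. The published
stage-by-group margins cannot be jointly reconciled with the outcome
counts, so stage marginals are carried separately and no joint
stage × group × outcome table is claimed.

`expand_fixture_to_records` inflates the aggregates into 306 per-patient
pseudo-records whose crosstab reproduces the chosen system's contingency
exactly; feature values within a group are fixed archetypes (the joint
feature distribution is unknown and not claimed), ages are seeded draws
from the published mean/sd. Quantities that need the unpublished joint
data — the stage/age-adjusted odds ratios, the pT1-subgroup odds ratios,
and the proposed-vs-EAU κ (published 0.16) — are implemented
(`fit_logistic` with covariates, `cohens_kappa`) and validated on
synthetic data and hand-computed oracles instead of on the real cohort.

## Evaluation statistics

**Dichotomization.** Diagnostic metrics compare low (test-negative)
against intermediate+high (test-positive): TP = LNM⁺ in
intermediate+high, FN = LNM⁺ in low, TN = LNM⁻ in low, FP = LNM⁻ in
intermediate+high.

**Proportion CIs.** Three conventions, always labelled in output:
`conventional_wald` (p ± z·√(p(1−p)/m) with m the metric's own
denominator), `wilson` (score interval), and `cohort_n`, a Wald interval
whose variance denominator is the full cohort size for all four metrics.
`cohort_n` is nonstandard; it is provided because it is the convention
under which every published interval of the development study is
reproduced to 2 decimals, and it is the default only in the reproduction
report. Intervals are clipped to [0, 1]. A zero-denominator metric is
returned as NaN with a `defined=False` flag, never silently 0. z is the
exact 97.5% normal quantile (1.959964…); presentation rounding is decimal
half-up, matching the published tables.

**Odds ratios.** Crude: cross-product ratio with the Woolf log-scale Wald
CI. A zero numerator cell yields OR 0 with CI (0, ∞), flagged; an optional
Haldane–Anscombe +0.5 correction is off by default. Regression:
`statsmodels` Logit (Newton/IRLS), zero-initialized, converged at relative
log-likelihood change < 1e-10 within 50 iterations; risk group is
reference-coded against low, optional covariates are stage (reference
pT1) and age (linear per year); `predictor="score"` fits the total score
as a linear dose–response term instead. Perfect separation raises an
explicit error; coefficients of essentially infinite magnitude are
flagged as quasi-separation rather than reported as converged. For the
saturated one-factor model the fitted ORs equal the closed-form
cross-product ratios (tested to 1e-6 relative, and property-tested over
random small cohorts).

**Ordinal AUC.** Tie-corrected Mann–Whitney over the group ordering
low < intermediate < high, equal to the trapezoidal area under the
three-point empirical ROC. The CI is Hanley–McNeil; the development
study's CI method is unstated, so the CI is reported but not treated as a
reproduction target. From the reconstructed counts the EAU AUC is
13415/20808 = 0.6447, which rounds to 0.64 while the study prints 0.65;
the computed value is reported unrounded and the mismatch is flagged in
the reproduction report rather than hidden.

**Agreement.** Unweighted Cohen's κ = (p_o − p_e)/(1 − p_e); κ is
undefined (flagged) when both labelings are constant and identical.

**Association.** Pearson χ² without continuity correction on the r×2
table; when any expected cell is below 5 (configurable), an exact test is
used instead — Fisher's exact for 2×2 (scipy), and for r×2 a
Freeman–Halton generalization by exhaustive enumeration of all tables
with the observed margins under the multivariate hypergeometric null.
Enumeration is exact and fast at the cohort sizes this package targets
(hundreds of patients, 3 groups). Empty groups are dropped with a warning
(error in strict mode).

## Synthetic cohorts and calibration

The generator draws WPOI, LHR, LVI, PNI, stage and grade independently
from marginal distributions, age from a normal truncated at 18
(rejection), and LNM ~ Bernoulli(logistic(β₀ + β₁·s)). Defaults are the
development cohort's published marginals — WPOI 2.6/17.3/44.1/36.0%, LHR
57.5/30.0/12.5%, LVI 36.6%, PNI 27.8%, stage pT1/pT2/pT3
35.6/41.2/23.2%, age 67.8 (10.6) — except grade, which has no published
marginal and defaults to uniform over G1–G3 (arbitrary, documented). One
seeded `numpy` generator per run; no global RNG state.

Independence of features is a deliberate simplification: only marginals
were published. Its visible consequence is that the synthetic score
distribution puts less mass on score 0 than the real cohort did (17% vs
36% low risk), because in real tumors favorable features co-occur.
Passing pipeline tests on synthetic cohorts therefore demonstrates
correctness of the statistics under the generator's assumptions, not
realism of the joint feature structure. Stage/grade are likewise
independent of the features, so the EAU grading has no predictive signal
in synthetic data — useful as a null, not a portrait of real cohorts.

`calibrate_lnm_model` inverts target group rates (r_low, r_int, r_high)
into (β₀, β₁) under the score distribution implied by the marginals
(computed exactly by enumerating the 48 profiles). Search: coarse grid
(β₀ ∈ [−10, 2], β₁ ∈ [0, 4]), trust-region least-squares refinement, then
by default a Chebyshev polish minimizing the largest absolute group-rate
error. The polish matters: two parameters cannot hit three group rates
whose generating score mixture differs from the synthetic one, and for
the published targets (1.8/31.8/76.5%) the equal-weight least-squares
optimum concentrates a 0.038 error on the low group, whereas the minimax
solution spreads the irreducible misfit evenly at ≈0.029 per group — the
best any (β₀, β₁) can do under these marginals. Tests therefore assert
the calibrated *expected* rates within 0.03 of each target and large-n
simulations within Monte-Carlo accuracy of those expectations, keeping
the deterministic and stochastic error sources separately accountable.

## Problem sizes used by the test suite

Fixture-based reproduction runs at the cohort's own n = 306.
Parameter-recovery and pipeline-AUC checks use simulated cohorts of
n = 5000; group-rate recovery uses n = 20 000; the β₁ = 0 null check uses
30 replicates of n = 306 (non-significance at α = 0.01 required in ≥27).
These sizes make every Monte-Carlo tolerance in the suite a small
multiple of the corresponding standard error.

## Known limitations

- No joint feature correlation structure, no multi-center heterogeneity,
  no survival outcomes — the generator covers exactly what the evaluation
  pipeline consumes.
- The cohort-n CI convention is reported for reproduction purposes only
  and should not be used for new studies; `conventional_wald` or `wilson`
  are the defensible choices.
- Adjusted and subgroup odds ratios are exercised on synthetic data only;
  their published counterparts are not recomputable from aggregates.
- The 2016+ TNM revisions beyond the pT1a/b rule, WHO subtype, HPV/p16
  status, and image-based feature assessment are out of scope: the
  package consumes already-scored features.
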