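"""Simulate a calibrated synthetic cohort and run the full evaluation.

Calibrates the dose-response LNM model to the published group rates,
draws a cohort of 2000 patients, grades it with both systems, and prints
the recovered group rates, AUCs and agreement.
"""

from penrisk import (
    GradingSystem,
    RISK_ORDER,
    association_test,
    calibrated_config,
    classify_record,
    cohens_kappa,
    crosstab,
    ordinal_auc,
    simulate_cohort,
)

cfg = calibrated_config(n_patients=2000, seed=42)
print(f"calibrated LNM model: logit p = {cfg.beta0:.3f} + {cfg.beta1:.3f} * score")

records = simulate_cohort(cfg)
ct = crosstab(records, GradingSystem.PROPOSED)
for g in RISK_ORDER:
    pos, neg = ct.cells(g)
    print(f"  {g.value:12s} n={pos + neg:5d}  LNM rate {pos / (pos + neg):.3f}")

print(f"ordinal AUC (proposed): {ordinal_auc(ct).point:.3f}")
print(f"ordinal AUC (EAU):      {ordinal_auc(crosstab(records, GradingSystem.EAU)).point:.3f}")
print(f"association test: p = {association_test(ct).p_value:.3g}")

kappa = cohens_kappa(
    [classify_record(r, GradingSystem.PROPOSED).value for r in records],
    [classify_record(r, GradingSystem.EAU).value for r in records],
)
print(f"proposed-vs-EAU agreement kappa: {kappa.point:.3f}")

print()
print("Group LNM rates rise with the score (dose-response); the EAU AUC is")
print("near 0.5 here because the generator draws stage and grade")
print("independently of the features, so EAU groups carry no signal --")
print("a deliberate property of the synthetic null, not of real cohorts.")
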