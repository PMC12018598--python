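"""Recompute the reference study's headline numbers from its aggregates.

Loads the reconstructed grouped contingencies of the 306-patient
development cohort and recomputes the crude odds ratios, the Table-style
diagnostic row for both grading systems, and the ordinal AUCs.
"""

from penrisk import (
    CIConvention,
    RiskGroup,
    diagnostic_metrics,
    dichotomize,
    group_odds_ratios,
    ordinal_auc,
    reference_fixture,
)

fx = reference_fixture()

print("LNM+/LNM- per risk group (proposed):",
      {g.value: fx.proposed.cells(g) for g in RiskGroup})

ors = group_odds_ratios(fx.proposed)
for g in (RiskGroup.INTERMEDIATE, RiskGroup.HIGH):
    est = ors[g]
    print(f"OR {g.value} vs low: {est.point:.2f} (95% CI {est.ci[0]:.2f}-{est.ci[1]:.2f})")

for name, ct in (("proposed", fx.proposed), ("EAU", fx.eau)):
    m = diagnostic_metrics(dichotomize(ct), CIConvention.COHORT_N, total_n=fx.n_total)
    sens, spec = m.sensitivity.as_percent(), m.specificity.as_percent()
    ppv, npv = m.ppv.as_percent(), m.npv.as_percent()
    auc = ordinal_auc(ct)
    print(f"{name:9s} sens {sens[0]:6.2f}%  spec {spec[0]:6.2f}% "
          f"({spec[1]:.2f}-{spec[2]:.2f})  PPV {ppv[0]:6.2f}%  NPV {npv[0]:6.2f}%  "
          f"AUC {auc.point:.4f}")

print()
print("Sensitivity treats low risk as test-negative and intermediate+high")
print("as test-positive. The proposed grading triples the size of the")
print("low risk group (111 vs 31 patients) at nearly unchanged NPV, which")
print("is what would spare patients unnecessary inguinal surgery.")
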