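"""Score single tumors and compare the two risk stratifications.

Builds a few histopathology profiles, computes the point score and risk
group of the proposed grading, and contrasts them with the EAU
stage/grade-based stratification for the same patients.
"""

from penrisk import (
    Grade,
    HistopathProfile,
    PTStage,
    TumorStaging,
    eau_risk_group,
    grade_profile,
    subclassify_pt1,
)

patients = [
    # (label, profile, staging)
    ("indolent front, strong host response",
     HistopathProfile(wpoi=2, lhr=1, lvi=False, pni=False),
     TumorStaging(PTStage.pT2, Grade.G2)),
    ("large islands, moderate response, LVI",
     HistopathProfile(wpoi=3, lhr=2, lvi=True, pni=False),
     TumorStaging(PTStage.pT1, Grade.G2)),
    ("small islands, no host response, LVI+PNI",
     HistopathProfile(wpoi=4, lhr=3, lvi=True, pni=True),
     TumorStaging(PTStage.pT1, Grade.G1)),
]

for label, profile, staging in patients:
    proposed = grade_profile(profile)
    eau = eau_risk_group(staging)
    line = (f"{label:45s} score={proposed.score}  "
            f"proposed={proposed.group.value:12s} eau={eau.group.value}")
    if staging.pt_stage is PTStage.pT1:
        line += f"  ({subclassify_pt1(staging, profile).value})"
    print(line)

print()
print("The point score adds 1 for WPOI type 4, 1-2 for weakening host")
print("response (LHR 2-3), and 1 each for LVI and PNI; 0 = low risk,")
print("1-2 = intermediate, >=3 = high. Note the third patient: low risk")
print("under EAU (pT1G1) but high risk histologically.")
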