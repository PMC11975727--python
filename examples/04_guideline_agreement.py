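"""The JNC 8 first-line rule engine and the guideline-agreement statistic.

CKD patients: ACEi or ARB (any race); Black patients without CKD: thiazide
or CCB; everyone else: any of the four first-line classes.  Agreement is
the share of patients whose top suggested class falls in their permitted
set.
"""

from htnrec.guidelines import (agreement_rate, class_permitted,
                               jnc8_recommended_classes)

cases = [
    {"patient_id": 1, "race": "White", "chronic_kidney_disease": 0},
    {"patient_id": 2, "race": "Black", "chronic_kidney_disease": 0},
    {"patient_id": 3, "race": "Black", "chronic_kidney_disease": 1},
]
for patient in cases:
    rec = jnc8_recommended_classes(patient)
    print(f"race={patient['race']:5s} ckd={patient['chronic_kidney_disease']} "
          f"-> rule '{rec.rule_fired}': {sorted(rec.permitted_classes)}")

rec = jnc8_recommended_classes(cases[2])
print("\ncombination semantics under the CKD rule:")
for label in ("ACEi+thiazide", "CCB+beta-blocker"):
    print(f"  {label}: permitted={class_permitted(label, rec)}")

tops = {1: "ACEi", 2: "ACEi", 3: "ARB"}  # patient 2 disagrees (Black, no CKD)
recs = {p["patient_id"]: jnc8_recommended_classes(p) for p in cases}
print(f"\nagreement over the three cases: {agreement_rate(tops, recs):.1f}%")
# 2 of 3 top classes are guideline-permitted -> 66.7%.
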