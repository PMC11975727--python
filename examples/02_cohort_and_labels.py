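"""Build the analyzable cohort and apply the rule-based success label.

Inclusion: new primary-hypertension diagnosis, established care, treatment
within 270 days, one year of follow-up, baseline BP and creatinine, a
determinable outcome.  Exclusions: new diabetes/prediabetes within a year,
rare ingredient-dose pairs.  Success = JNC 8 blood-pressure control for a
year with no moderate/severe adverse effect.
"""

from htnrec import GeneratorConfig, generate_cohort
from htnrec.pipeline import build_cohort
from htnrec.outcomes import label_cohort
from htnrec.evaluation import class_success_table

bundle, truth = generate_cohort(GeneratorConfig(n_patients=3_000, seed=7))
episodes, eligibility, train_ids, val_ids = build_cohort(
    bundle, n_validation=300, seed=7)

included = set(eligibility.loc[eligibility["included"], "patient_id"])
print(f"included {len(included)} of {len(eligibility)} patients")
print("exclusion reasons:")
failed = eligibility.loc[~eligibility["included"], "failed_criteria"]
print(failed.str.split(";").explode().value_counts().to_string())

labels = label_cohort(bundle, {p: episodes[p] for p in included})
non_excluded = labels[labels["status"] != "excluded"]
rate = (non_excluded["status"] == "success").mean()
print(f"\nmarginal success rate: {100 * rate:.1f}% "
      f"({len(non_excluded)} determinable episodes)")

table = class_success_table(
    [episodes[p].drug_class_label for p in labels["patient_id"]],
    labels["status"].tolist())
print("\ntreatment likelihood and success rate by class:")
print(table.head(8).round(1).to_string(index=False))
# Likelihoods track the configured prescription mix; per-class success rates
# track the planted class-conditional targets.
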