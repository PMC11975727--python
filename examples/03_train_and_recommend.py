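"""Train the ensemble success model and rank treatments for one patient.

Each of the ensemble members is a small feed-forward net trained on its own
80% subsample; the median member score is the success probability and the
10-90 percentile spread feeds the confidence tier (which also requires
training support for the treatment in the patient's race x age-decade cell
— the positivity filter).
"""

from htnrec import GeneratorConfig, generate_cohort
from htnrec.config import ModelConfig, RunConfig
from htnrec.model import recommend
from htnrec.outcomes import label_cohort
from htnrec.pipeline import build_cohort, train_model
from htnrec.synthetic import CANDIDATE_TREATMENTS

bundle, truth = generate_cohort(GeneratorConfig(n_patients=4_000, seed=3))
episodes, eligibility, train_ids, val_ids = build_cohort(bundle, 400, 3)
included = set(eligibility.loc[eligibility["included"], "patient_id"])
labels = label_cohort(bundle, {p: episodes[p] for p in included})

# a deliberately small ensemble so the example runs in ~a minute
model_cfg = ModelConfig(n_members=8, hidden_layers=(12,), max_iter=80)
ensemble, features = train_model(bundle, episodes, labels, train_ids,
                                 model_cfg, seed=3)

pid = sorted(val_ids)[0]
patient = features.loc[pid].to_dict()
print(f"patient {pid}: age {patient['age']:.0f}, race {patient['race']}, "
      f"pre-treatment BP {patient['sbp_pre']:.0f}/{patient['dbp_pre']:.0f}")

ranked = recommend(ensemble, patient, CANDIDATE_TREATMENTS, min_tier="medium")
print("\ntop-ranked regimens (medium+ confidence):")
for key, pred in ranked[:5]:
    print(f"  {key:50s} median {pred.median_probability:.3f} "
          f"[{pred.p10:.3f}, {pred.p90:.3f}]  tier={pred.confidence_tier}")
if not ranked:
    print("  no-confident-recommendation")
# The median is the predicted probability of year-long success; the bracket
# is the 10th-90th percentile across ensemble members.
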