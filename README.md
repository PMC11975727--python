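# htnrec

Individualized first-line antihypertensive recommendation from
longitudinal EHR-style tables, built as a causal prediction pipeline:
which drug class — and which ingredient at which daily dose — gives a
newly diagnosed hypertensive patient the best chance of a successful
first year of treatment?

**Treatment success** is defined clinically: blood pressure controlled
per age-dependent JNC 8 goals for at least one year on the initial
regimen (average < 140/90 mm Hg and never > 160/90 under age 60;
< 150/90 and never > 170/90 at 60 and over), with no moderate or severe
adverse effect (hypotension, bradycardia, creatinine rise > 30%,
dysnatremia, dyskalemia, elevated fasting glucose, or a documented
moderate/severe reaction).

The success model is a deep ensemble: 20 small feed-forward probability
estimators, each trained on its own 80% subsample of the training
episodes.  For a patient *x* and candidate regimen *t* (a set of
(ingredient, daily-dose) pairs), the prediction is

&nbsp;&nbsp;&nbsp;&nbsp;p̂(x, t) = median_k  f_k(x, t),

with the 10/25/75/90 percentiles of the member scores as uncertainty
bands.  A confidence tier (low/medium/high) combines scale-free member
disagreement, (p90 − p10) / (m(1 − m)) at the median m, with the
training support for *t* among patients of the same race and age decade;
zero support always yields *low* — the positivity filter of the causal
contract (consistency is handled by working at ingredient + daily-dose
resolution, exchangeability by feeding the model every measured
confounder).  Recommendations rank candidate regimens by median
predicted success; a JNC 8 rule engine scores guideline agreement.

Because real clinical tables cannot ship with the package, `htnrec`
includes a first-class synthetic-EHR generator with a *known*
ground-truth response surface (planted age x class, race x class and
comorbidity x class interactions, calibrated to a 33.8% marginal success
rate), so cohort filters, the outcome labeler, and the model's parameter
recovery are all testable against exact answers.

## Worked example

Generate a cohort, build the analyzable population, and label outcomes:

```python
from htnrec import GeneratorConfig, generate_cohort
from htnrec.pipeline import build_cohort
from htnrec.outcomes import label_cohort

bundle, truth = generate_cohort(GeneratorConfig(n_patients=3_000, seed=7))
episodes, eligibility, train_ids, val_ids = build_cohort(bundle, 300, seed=7)
included = set(eligibility.loc[eligibility["included"], "patient_id"])
labels = label_cohort(bundle, {p: episodes[p] for p in included})
```

Running `examples/02_cohort_and_labels.py` (the script version of the
above) prints:

```
included 2732 of 3000 patients
...
marginal success rate: 34.7% (2705 determinable episodes)

treatment likelihood and success rate by class:
           class  likelihood_pct  success_rate_pct  n_episodes
            ACEi            26.0              39.6         709
    beta-blocker            14.1              33.2         384
        thiazide            12.6              40.4         345
             CCB            11.1              31.7         302
             ARB             9.9              32.3         271
   ACEi+thiazide             4.6              50.0         126
```

268 patients are excluded, each for a named criterion (late treatment,
missing baselines, new diabetes, rare ingredient-dose pairs, ...).  The
marginal success rate fluctuates around the calibrated 33.8% with
binomial noise at this cohort size; the per-class likelihoods and
success rates track the configured prescription mix and the planted
class-conditional targets (ACEi 39.1%, thiazide 38.5%, the
ACEi+thiazide combination the most successful).

The other scripts in `examples/` are one capability each: cohort
generation (01), training + per-patient regimen ranking (03), the JNC 8
rule engine and agreement statistic (04), and age-sweep success curves
showing the planted ACEi/thiazide crossover near age 60 (05).

A CLI wraps the same stages for shell use:

```bash
htnrec simulate --n 20000 --seed 1 --out run/bundle
htnrec build-cohort --bundle run/bundle --out run/cohort --seed 1
htnrec label --bundle run/bundle --eligibility run/cohort/eligibility.csv --out run
htnrec run-all --seed 1 --out run   # everything, incl. training + reports
```

## Layout

- `src/htnrec/ehr_io.py` — the six-table CSV bundle (read/validate/write)
- `src/htnrec/synthetic.py` — synthetic cohorts + planted ground truth
- `src/htnrec/cohort.py` — measurement filters, inclusion/exclusion, split
- `src/htnrec/medication.py` — class mapping, sig parsing, timelines, episodes
- `src/htnrec/outcomes.py` — the rule-based success/failure/excluded label
- `src/htnrec/model.py` — the ensemble, confidence tiers, ranking
- `src/htnrec/guidelines.py` — JNC 8 first-line rules, agreement
- `src/htnrec/evaluation.py` — metrics, class tables, curve bundles
- `src/htnrec/pipeline.py`, `src/htnrec/cli.py` — orchestration and CLI
- `docs/methods.md` — model, assumptions, conventions, limitations
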