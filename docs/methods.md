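# Methods

`htnrec` implements an end-to-end pipeline for individualized first-line
antihypertensive recommendation from longitudinal EHR-style tables, with
a synthetic-cohort generator that carries an exact, known counterfactual
surface so every stage can be scored against ground truth.

## Outcome definition

An initial-treatment episode is a **success** when all three hold:

1. the initial regimen was maintained for at least one year;
2. blood pressure was controlled per age-dependent JNC 8 goals over the
   selected outcome window — mean SBP/DBP strictly below the goal
   (140/90 mm Hg under age 60; 150/90 at 60 and over) and no single
   reading above the never-exceed caps (160/90 and 170/90 respectively);
3. no adverse-effect criterion fired during the episode: hypotension
   (SBP < 90 or DBP < 60), bradycardia (HR < 50), serum creatinine rise
   > 30% over the pre-treatment baseline, sodium outside [130, 150]
   mEq/L, potassium outside [3.6, 5.1] mEq/L, fasting glucose
   > 120 mg/dL, or a documented moderate/severe adverse effect to an
   episode medication.  Mild documented effects never count.

**Window logic.** Outcome pressures come from 6–12 months after
treatment start.  If that window is empty and the regimen is maintained,
the earliest non-empty of 12–14, 14–18 and 18–24 months is used.  For
episodes ending before one year, readings at least 14 days after start
and at least 6 months before the episode end decide between *failure*
(high pressures) and *excluded* (controlled pressures — year-long success
unknowable).  Zero usable readings are indeterminate, never success.

**Interpretation conventions** (points the written rules leave open;
both the labeler and the independent test oracle follow them):

- month boundaries are day counts at the mean Gregorian month
  (6 m = 183 d, 14 m = 426 d, 18 m = 548 d, 24 m = 730 d); "9 months" =
  270 days inclusive, "a year" = 365 days;
- age exactly 60 falls in the older goal branch (the JNC 8 cutoff is
  "60 and over"); age is taken at treatment start;
- the never-exceed caps are evaluated over the selected window only;
- adverse effects are evaluated over the full episode (not truncated at
  one year), on valid ambulatory measurements only;
- when a single reading exceeds a cap *and* the mean misses its goal,
  the failure reason is reported as the threshold violation;
- baseline creatinine is the latest value strictly before treatment
  start.

Measurement validity: SBP/DBP/HR rows are used only when non-invasive,
sitting, arm, ambulatory; anything recorded in hospital, during
exercise, operation, anesthesia or dialysis is dropped.

## Cohort construction

Inclusion: primary-hypertension diagnosis code; at least one record of
any type before the diagnosis (established care); first antihypertensive
within 270 days of diagnosis; at least 365 days of data after treatment
start; at least one valid BP and one creatinine in the year before
treatment start; a determinable outcome (an adverse-effect criterion
fires, or the selected BP window is non-empty).  All violated criteria
are recorded per patient, not just the first.

Exclusion: a first diabetes or (separately) prediabetes code within 365
days after treatment start; and any episode containing an (ingredient,
daily dose) pair observed fewer than twice among retained episodes.  The
rare-pair filter is iterated to a fixed point because each removal can
create new rare pairs.

## Medication normalization

Prescription codes map to ingredients and drug classes through a small
packaged RxNorm-style table; combination products contribute one entry
per ingredient with its per-unit dose, so one combination pill and the
equivalent separate pills produce identical treatment episodes (the
consistency condition — treatments are defined at ingredient +
total-daily-dose resolution).  Daily dose is parsed from sig text against
a closed grammar ("take n units m times a day", "n units daily/once a
day", "n units every h hours"); anything outside the grammar is flagged,
never guessed.  Per (patient, ingredient, dose), prescription intervals
overlapping or abutting within one day are merged.  The initial regimen
collects every ingredient-dose interval starting within 14 days of the
earliest antihypertensive start (a declared convention; the episode ends
at the earliest component discontinuation).  Combination class labels
join the sorted component classes with `+` (e.g. `ACEi+thiazide`); `+`
rather than `-` because the class name `beta-blocker` contains a hyphen.

## Synthetic cohort generator

The generator emulates a newly diagnosed primary-hypertension primary
care population.  Demographics and comorbidity prevalences follow the
target cohort profile (age-band mixture with mean ≈ 61 y, 49.3% female,
92.5/3.3/4.2% White/Black/Other, seven comorbidity flags from 29.4%
tachyarrhythmia down to 3.3% gout); pre-treatment SBP/DBP are Gaussian
(137.8 ± 18.9 / 81.0 ± 11.5 mm Hg) and creatinine 1.0 ± 0.2 mg/dL.

**Treatments.** A fixed menu of 26 candidate regimens covers the five
named classes (2–4 daily-dose options each), an ACEi+thiazide
combination available as a single pill or separate pills, and an
"other" bucket of misc single agents and misc two-agent combinations.
Prescription class likelihoods are ACEi 26.5%, beta-blocker 13.9%,
thiazide 12.6%, CCB 11.2%, ARB 8.6%, ACEi+thiazide 5.4%, other 21.8%;
within the other bucket 76.15% of episodes are combinations so that
~22% of all patients start on more than one agent.  Treatment assignment
is independent of patient features (exchangeability holds by
construction; confounded-assignment scenarios are out of scope).

**Ground truth.** For every (patient, candidate regimen), the success
probability is the inverse-logit of a linear predictor with class-label
coefficients: intercept, age per decade centered at 60, race terms,
comorbidity terms, and a relative-dose term.  Planted defaults: ACEi
slope −0.15/decade vs thiazide +0.15/decade (curves cross near 60);
thiazide +0.5 and CCB +0.4 for Black patients, ACEi −0.5 and ARB −0.4;
ACEi/ARB +0.3 under chronic kidney disease; beta-blocker +0.3 with
tachyarrhythmia and −0.3 with asthma; thiazide −0.3 with gout; sex
carries no effect (a deliberate null for exchangeability checks).
Class intercepts are calibrated at config-construction time by 1-D root
finding so the class-conditional mean success over the configured
feature mixture equals its target (ACEi 39.1%, beta-blocker 30.9%,
thiazide 38.5%, CCB 29.6%, ARB 35.4%, ACEi+thiazide 44.5%); the "other"
target is derived so the likelihood-weighted mean is the 33.8% marginal.
Realized success states are drawn once per (seed, patient, treatment)
from counter-based Philox substreams keyed by (seed, treatment) with the
patient's stable index as position, so any cell is individually
addressable and regeneration is reproducible.

**Record emission.** Each patient receives a diagnosis, prior-care
visit, baseline BP/creatinine, prescriptions (30% split into abutting
refills; combination regimens arrive as a single pill half the time),
and an outcome trajectory consistent with the realized state: successes
get ~4 controlled readings in the 6–12-month window (5% only in the
fallback windows) plus safe labs; failures manifest through uncontrolled
averages, a single cap-exceeding spike, or one of the seven
adverse-effect mechanisms (30% of failures), with documented
moderate/severe effects triggering discontinuation within 30 days at
rates 0.75/0.851.  8% of patients carry an extreme hospital-context BP
row that must be filtered out.  A configured ~9.2% of patients violate
exactly one named cohort criterion (1% each, 0.2% rare pairs) drawn
independently of the realized state, so the filters are exercised
without biasing the labeled marginal.

What the generator does *not* emulate: treatment-by-indication
confounding, missing-not-at-random measurement, care-process visit
dynamics, pharmacokinetics, or free-text sig noise beyond the closed
grammar.  Passing tests therefore demonstrate correctness of the
pipeline's logic and recoverability of a planted signal under clean
conditions — not performance on real EHR data.

## Success model

The ensemble has 20 members, each a `StandardScaler` +
`MLPClassifier` pipeline (two hidden layers, default 24/12 units,
binary cross-entropy, adam, max 300 epochs), trained on its own 80%
subsample drawn without replacement with its own seed.  Features: age,
pre-treatment SBP/DBP, creatinine (continuous, untransformed at the
interface; scaling is member-internal); sex, race one-hots, seven
comorbidity flags (categorical); and the treatment as a per-ingredient
daily-dose vector normalized by reference doses.  A missing feature is
a hard error, never imputed (the completeness requirement of the causal
contract).  The median member score is the success probability;
10/25/75/90 percentiles (linear interpolation between order statistics)
form the bands.

**Confidence tiers and positivity.**  The tier combines (a) member
disagreement, measured as the (p90 − p10) band width divided by the
binomial scale m(1 − m) at the clipped median — raw band width grows
mechanically with m(1 − m) for probability outputs, so the unnormalized
width would grade low-probability predictions as confident regardless of
agreement — and (b) the training support count for the exact treatment
within the patient's (race, age-decade) cell.  Zero support is a hard
positivity violation and always yields *low*.  Dispersion cutoffs are
recalibrated at fit time as training-set quantiles targeting 41.8%
medium+high and 17.3% high fractions; support minima default to 5
(medium) and 10 (high).

**Operating point.**  The success/failure classification threshold
defaults to the training-set success prevalence (~0.34) rather than 0.5:
a calibrated model of a ~34%-prevalent outcome almost never produces a
median above 0.5, which makes precision/recall degenerate and inverts
the confidence-recall ordering.  The threshold is a config knob.

**Recommendation.**  Candidates below the requested tier are dropped;
the rest are ranked by median probability, ties broken by higher support
then lexicographic treatment key.  Class-level scores are
prescription-probability-weighted means of the ingredient-dose scores
within the class (weights must sum to 1 per class).

## Guideline engine and evaluation

JNC 8 first-line rules: chronic kidney disease → {ACEi, ARB} (any race,
CKD takes precedence); else Black → {thiazide, CCB}; else all four
first-line classes.  A combination is permitted when every component
class is permitted, except under the CKD rule, where containing at least
one of {ACEi, ARB} suffices.  Agreement is the percentage of patients
whose top suggested class is permitted, to one decimal; patients without
a prediction are dropped from the denominator with a warning.

Precision/recall/F1 treat success as the positive class; zero
denominators yield an undefined-metric signal, never 0.  Metrics are
recomputed on the medium+high and high tiers; excluded labels are
dropped from all denominators.  Curve bundles sweep age or pre-treatment
SBP for a reference case (White, no comorbidities, creatinine
0.8 mg/dL, BP 160/90, age 50) and report class-aggregated medians and
bands for the top three classes.

## Numerical and scale choices

- Calibration sample 160,000 feature draws with a fixed internal seed;
  brentq on [−8, 8] with 1e-10 tolerance.
- Percentages reported at one decimal (round-half-even).
- Study-condition checks run at n = 20,000 patients with a 1,000-patient
  validation split, the full 20-member ensemble and the default
  architecture; unit tests use cohorts of 300–3,000 and smaller
  ensembles.  These sizes are the package's test conditions, chosen to
  keep the statistical targets (marginal rate ±1 point, parameter
  recovery MAE ≤ 0.05) resolvable above binomial noise.
- Ties among adverse-effect criteria on the same day break in a fixed
  order (hypotension, bradycardia, creatinine rise, natremia, kalemia,
  glucose, documented AE).

## Known limitations

- The generator's independent treatment assignment means the model is
  never stress-tested against confounding; exchangeability is validated
  only as a null (a zero-coefficient feature moves predictions only
  within noise).
- Ground-truth effects act on the class label, not additively on
  components, so misc combinations inherit the "other" bucket's
  coefficients.
- The rare-pair planting grid holds 40 unique off-menu recipes; beyond
  ~40 planted violators (n ≫ 20,000 at default rates) recipes repeat and
  such pairs stop being rare.
- Confidence calibration uses in-sample (training) dispersion quantiles;
  validation fractions drift a few points around the targets.
- The guideline engine covers only the first-line class rules, not BP
  goals by diabetes status or later escalation steps.
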