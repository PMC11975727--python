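"""Synthetic longitudinal EHR cohorts with a known treatment-response model.

The generator emulates the statistical structure of a newly diagnosed
primary-hypertension primary-care population: the age/sex/race mixture
and comorbidity prevalences of the study cohort, per-class prescription
likelihoods, class-conditional success rates whose likelihood-weighted
mean is the 33.8% marginal success rate, adverse-effect-linked
discontinuation, and planted subgroup x treatment interactions (age,
race, comorbidity) so parameter recovery can be scored against an exact
counterfactual surface.

Ground truth: for every patient and every candidate ingredient-dose
regimen, success probability is the inverse-logit of a configured linear
predictor; realized success states are drawn once per (seed, patient,
treatment) from counter-based substreams.  The emitted tables are
constructed so the rule-based labeler recovers the realized state of
(almost) every non-excluded episode, and a documented fraction of
patients violates each cohort criterion so the filters are exercised.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .config import (COMORBIDITIES, COMORBIDITY_CODES, ConfigurationError,
                     GeneratorConfig)
from .ehr_io import EHRBundle

__all__ = [
    "Treatment",
    "GroundTruth",
    "CANDIDATE_TREATMENTS",
    "generate_cohort",
    "ground_truth_success",
    "simulate_adverse_events",
    "calibrate_effects",
    "MODERATE_DISCONTINUE_P",
    "SEVERE_DISCONTINUE_P",
]

EPOCH = pd.Timestamp("2005-01-01")

#: documented adverse effects of moderate/severe tier are linked to
#: discontinuation within a month at these rates
MODERATE_DISCONTINUE_P = 0.75
SEVERE_DISCONTINUE_P = 0.851

INGREDIENT_CLASS = {
    "lisinopril": "ACEi", "enalapril": "ACEi",
    "losartan": "ARB", "valsartan": "ARB",
    "hydrochlorothiazide": "thiazide", "chlorthalidone": "thiazide",
    "amlodipine": "CCB", "diltiazem": "CCB",
    "metoprolol": "beta-blocker", "atenolol": "beta-blocker",
    "clonidine": "other", "hydralazine": "other", "doxazosin": "other",
}

#: reference total daily dose per ingredient (denominator of the relative
#: dose deviation entering the ground-truth linear predictor)
REF_DAILY_DOSE = {
    "lisinopril": 20.0, "enalapril": 20.0,
    "losartan": 50.0, "valsartan": 160.0,
    "hydrochlorothiazide": 25.0, "chlorthalidone": 25.0,
    "amlodipine": 5.0, "diltiazem": 240.0,
    "metoprolol": 100.0, "atenolol": 50.0,
    "clonidine": 0.4, "hydralazine": 100.0, "doxazosin": 4.0,
}


@dataclass(frozen=True)
class Treatment:
    """A candidate regimen: components at ingredient-daily-dose resolution.

    ``prescriptions`` is the separate-pill form ((code, sig), ...);
    ``combo_product`` is the equivalent single-pill product when one exists.
    """

    treatment_id: int
    components: tuple           # sorted ((ingredient, daily_dose_mg), ...)
    prescriptions: tuple        # ((code, sig_text), ...) one per component
    combo_product: tuple | None = None

    @property
    def class_label(self) -> str:
        return "+".join(sorted({INGREDIENT_CLASS[i] for i, _ in self.components}))

    @property
    def key(self) -> str:
        return "+".join(f"{i}:{d:g}" for i, d in self.components)

    @property
    def dose_dev(self) -> float:
        return float(np.mean([d / REF_DAILY_DOSE[i] - 1.0 for i, d in self.components]))


def _t(tid, comps, rx, combo=None):
    comps = tuple(sorted(comps))
    return Treatment(tid, comps, tuple(rx), combo)


_D = "1 tablet daily"
_BID = "take 1 tablet 2 times a day"
_Q12 = "1 tablet every 12 hours"

#: the fixed candidate menu; weights below are within-class prescription
#: probabilities (they feed both sampling and class-level aggregation)
CANDIDATE_TREATMENTS: tuple[Treatment, ...] = (
    # ACEi
    _t(0, [("lisinopril", 10.0)], [(100001, _D)]),
    _t(1, [("lisinopril", 20.0)], [(100002, _D)]),
    _t(2, [("lisinopril", 40.0)], [(100002, _Q12)]),
    _t(3, [("enalapril", 20.0)], [(100003, _BID)]),
    # ARB
    _t(4, [("losartan", 50.0)], [(100011, _D)]),
    _t(5, [("losartan", 100.0)], [(100012, _D)]),
    _t(6, [("valsartan", 160.0)], [(100013, _D)]),
    # thiazide
    _t(7, [("hydrochlorothiazide", 12.5)], [(100021, _D)]),
    _t(8, [("hydrochlorothiazide", 25.0)], [(100022, _D)]),
    _t(9, [("chlorthalidone", 25.0)], [(100023, _D)]),
    # CCB
    _t(10, [("amlodipine", 5.0)], [(100031, _D)]),
    _t(11, [("amlodipine", 10.0)], [(100032, _D)]),
    _t(12, [("diltiazem", 240.0)], [(100033, "take 1 capsule 2 times a day")]),
    # beta-blocker
    _t(13, [("metoprolol", 50.0)], [(100041, _D)]),
    _t(14, [("metoprolol", 100.0)], [(100042, _D)]),
    _t(15, [("metoprolol", 200.0)], [(100042, _Q12)]),
    _t(16, [("atenolol", 50.0)], [(100043, _D)]),
    # other single agents
    _t(17, [("clonidine", 0.4)], [(100051, _BID)]),
    _t(18, [("hydralazine", 100.0)], [(100052, _Q12)]),
    _t(19, [("doxazosin", 4.0)], [(100053, _D)]),
    # ACEi + thiazide combinations (single-pill product available)
    _t(20, [("lisinopril", 10.0), ("hydrochlorothiazide", 12.5)],
       [(100001, _D), (100021, _D)], combo=((100061, _D),)),
    _t(21, [("lisinopril", 20.0), ("hydrochlorothiazide", 25.0)],
       [(100002, _D), (100022, _D)], combo=((100062, _D),)),
    # misc combinations (fall in the "other" prescription bucket)
    _t(22, [("metoprolol", 50.0), ("hydrochlorothiazide", 25.0)],
       [(100041, _D), (100022, _D)]),
    _t(23, [("amlodipine", 5.0), ("lisinopril", 10.0)],
       [(100031, _D), (100001, _D)]),
    _t(24, [("losartan", 50.0), ("hydrochlorothiazide", 12.5)],
       [(100011, _D), (100021, _D)]),
    _t(25, [("amlodipine", 5.0), ("metoprolol", 50.0)],
       [(100031, _D), (100041, _D)]),
)

#: within-class option ids and prescription weights
CLASS_OPTIONS: dict[str, tuple[tuple[int, ...], tuple[float, ...]]] = {
    "ACEi": ((0, 1, 2, 3), (0.45, 0.35, 0.10, 0.10)),
    "ARB": ((4, 5, 6), (0.50, 0.30, 0.20)),
    "thiazide": ((7, 8, 9), (0.40, 0.40, 0.20)),
    "CCB": ((10, 11, 12), (0.45, 0.35, 0.20)),
    "beta-blocker": ((13, 14, 15, 16), (0.35, 0.35, 0.15, 0.15)),
    "ACEi+thiazide": ((20, 21), (0.60, 0.40)),
    "other_single": ((17, 18, 19), (0.30, 0.30, 0.40)),
    "other_combo": ((22, 23, 24, 25), (0.25, 0.25, 0.25, 0.25)),
}

#: unique off-menu (code, sig) recipes for planting rare ingredient-dose
#: pairs; the (n, m) products are distinct within each code so no two
#: planted pairs collide on daily dose
_RARE_GRID = tuple(
    (code, f"take {n} tablets {m} times a day")
    for code in (100001, 100011, 100021, 100031, 100041, 100051, 100052, 100053)
    for (n, m) in ((3, 1), (2, 3), (3, 3), (4, 3), (4, 4))
)

_CODE_UNIT_DOSE = {
    100001: 10.0, 100002: 20.0, 100003: 10.0, 100011: 50.0, 100012: 100.0,
    100013: 160.0, 100021: 12.5, 100022: 25.0, 100023: 25.0, 100031: 5.0,
    100032: 10.0, 100033: 120.0, 100041: 50.0, 100042: 100.0, 100043: 50.0,
    100051: 0.2, 100052: 50.0, 100053: 4.0, 100061: 22.5, 100062: 45.0,
}
_CODE_NAME = {
    100001: "lisinopril 10 mg tablet", 100002: "lisinopril 20 mg tablet",
    100003: "enalapril 10 mg tablet", 100011: "losartan 50 mg tablet",
    100012: "losartan 100 mg tablet", 100013: "valsartan 160 mg tablet",
    100021: "hydrochlorothiazide 12.5 mg tablet",
    100022: "hydrochlorothiazide 25 mg tablet",
    100023: "chlorthalidone 25 mg tablet", 100031: "amlodipine 5 mg tablet",
    100032: "amlodipine 10 mg tablet", 100033: "diltiazem 120 mg capsule",
    100041: "metoprolol 50 mg tablet", 100042: "metoprolol 100 mg tablet",
    100043: "atenolol 50 mg tablet", 100051: "clonidine 0.2 mg tablet",
    100052: "hydralazine 50 mg tablet", 100053: "doxazosin 4 mg tablet",
    100061: "lisinopril-hydrochlorothiazide 10-12.5 mg tablet",
    100062: "lisinopril-hydrochlorothiazide 20-25 mg tablet",
}
_CODE_INGREDIENT = {
    100001: "lisinopril", 100002: "lisinopril", 100003: "enalapril",
    100011: "losartan", 100012: "losartan", 100013: "valsartan",
    100021: "hydrochlorothiazide", 100022: "hydrochlorothiazide",
    100023: "chlorthalidone", 100031: "amlodipine", 100032: "amlodipine",
    100033: "diltiazem", 100041: "metoprolol", 100042: "metoprolol",
    100043: "atenolol", 100051: "clonidine", 100052: "hydralazine",
    100053: "doxazosin",
}


# ---------------------------------------------------------------------------
# ground-truth model

def _effect_for(label: str, coefficients: dict):
    eff = coefficients.get(label)
    return eff if eff is not None else coefficients["other"]


def _linear_predictor(eff, age, black, other_race, female, comorb_flags: dict,
                      dose_dev):
    lp = eff.intercept \
        + eff.age_per_decade * (age - 60.0) / 10.0 \
        + eff.black * black + eff.other_race * other_race \
        + eff.female * female + eff.dose * dose_dev
    for cond, coef in eff.comorbidity.items():
        lp = lp + coef * comorb_flags[cond]
    return lp


def ground_truth_success(patient_features: dict, treatment, coefficients: dict) -> float:
    """Exact planted success probability for one patient-treatment pair.

    ``patient_features`` needs ``age``, ``race``, ``female`` and the seven
    comorbidity flags; ``treatment`` is a :class:`Treatment` or an iterable
    of (ingredient, daily_dose) components.  Unknown ingredients raise
    ``KeyError`` (a treatment outside the candidate universe has no
    counterfactual surface).
    """
    if not isinstance(treatment, Treatment):
        comps = tuple(sorted(treatment))
        for ing, _ in comps:
            if ing not in INGREDIENT_CLASS:
                raise KeyError(f"unknown treatment ingredient {ing!r}")
        treatment = Treatment(-1, comps, ())
    eff = _effect_for(treatment.class_label, coefficients)
    if eff.intercept is None:
        raise ConfigurationError("effect_coefficients",
                                 f"intercept for {treatment.class_label!r} not calibrated")
    flags = {c: float(patient_features.get(c, 0.0)) for c in COMORBIDITIES}
    lp = _linear_predictor(
        eff, float(patient_features["age"]),
        1.0 if patient_features.get("race") == "Black" else 0.0,
        1.0 if patient_features.get("race") == "Other" else 0.0,
        float(patient_features.get("female", 0.0)), flags, treatment.dose_dev)
    return float(expit(lp))


def _sample_features(config: GeneratorConfig, n: int, rng: np.random.Generator):
    bands = sorted(config.age_band_probs)
    probs = np.array([config.age_band_probs[b] for b in bands])
    idx = rng.choice(len(bands), size=n, p=probs)
    lo = np.array([b[0] for b in bands], dtype=float)
    hi = np.array([b[1] for b in bands], dtype=float)
    age = rng.uniform(lo[idx], hi[idx] + 1.0)
    female = rng.random(n) < config.female_fraction
    race_names = sorted(config.race_probs)
    race = np.array(race_names)[rng.choice(
        len(race_names), size=n, p=[config.race_probs[r] for r in race_names])]
    comorb = {c: rng.random(n) < config.comorbidity_prevalences.get(c, 0.0)
              for c in COMORBIDITIES}
    return age, female, race, comorb


def _bucket_probabilities(config, age, female, race, comorb, effects,
                          option_ids, option_weights, rng):
    """Mean planted success probability per patient for a mixture of menu
    options (used both for calibration and for drawing observed options)."""
    opt = rng.choice(option_ids, size=len(age), p=option_weights)
    black = (race == "Black").astype(float)
    other = (race == "Other").astype(float)
    lp = np.zeros(len(age))
    for tid in set(opt.tolist()):
        t = CANDIDATE_TREATMENTS[tid]
        eff = _effect_for(t.class_label, effects)
        mask = opt == tid
        lp[mask] = _linear_predictor(
            eff, age[mask], black[mask], other[mask],
            female[mask].astype(float),
            {c: comorb[c][mask].astype(float) for c in COMORBIDITIES},
            t.dose_dev)
    return lp, opt


def _other_bucket(config):
    ids_s, w_s = CLASS_OPTIONS["other_single"]
    ids_c, w_c = CLASS_OPTIONS["other_combo"]
    share = config.other_combo_share
    ids = ids_s + ids_c
    weights = tuple(w * (1 - share) for w in w_s) + tuple(w * share for w in w_c)
    return ids, weights


def derived_other_target(config: GeneratorConfig) -> float:
    """Success target for the 'other' bucket such that the prescription-
    likelihood-weighted mean equals the configured marginal rate."""
    named = sum(config.class_likelihoods[c] * t
                for c, t in config.class_success_targets.items())
    l_other = config.class_likelihoods.get("other", 0.0)
    if l_other <= 0:
        raise ConfigurationError("class_likelihoods", "'other' likelihood must be positive")
    target = (config.marginal_success - named) / l_other
    if not (0.01 < target < 0.99):
        raise ConfigurationError("class_success_targets",
                                 f"derived 'other' target {target:.3f} infeasible")
    return target


def calibrate_effects(config: GeneratorConfig, n_sample: int = 160_000,
                      cal_seed: int = 20_130) -> dict:
    """Fill missing class intercepts so class-conditional mean success hits
    the configured targets over the configured feature distribution.

    Uses a fixed internal feature sample (independent of the cohort seed)
    and 1-D root finding on the population-mean inverse-logit.
    """
    rng = np.random.default_rng(cal_seed)
    age, female, race, comorb = _sample_features(config, n_sample, rng)
    effects = {k: replace(v) for k, v in config.effect_coefficients.items()}
    if "other" not in effects:
        raise ConfigurationError("effect_coefficients", "'other' fallback entry required")

    targets = dict(config.class_success_targets)
    targets["other"] = derived_other_target(config)

    for cls in sorted(config.class_likelihoods):
        key = cls if cls in effects else "other"
        eff = effects[key]
        if cls == "other":
            ids, weights = _other_bucket(config)
        else:
            ids, weights = CLASS_OPTIONS[cls]
        weights = np.asarray(weights) / np.sum(weights)
        target = targets[cls]
        base = replace(eff, intercept=0.0)
        tmp = dict(effects)
        tmp[key] = base
        lp0, _ = _bucket_probabilities(
            config, age, female, race, comorb,
            {k: (base if k == key else v if v.intercept is not None
                 else replace(v, intercept=0.0)) for k, v in tmp.items()},
            np.array(ids), weights, np.random.default_rng(cal_seed + 1))

        def gap(b):
            return float(np.mean(expit(lp0 + b))) - target

        eff.intercept = brentq(gap, -8.0, 8.0, xtol=1e-10)
    return effects


# ---------------------------------------------------------------------------
# adverse-effect simulation

def simulate_adverse_events(patient_id: int, medication_code: int,
                            start_day: int, ae_rates, rng: np.random.Generator):
    """Draw at most one documented adverse event for an episode.

    ``ae_rates`` = (mild, moderate, severe) event probabilities.  Returns
    ``(records, discontinue_day)``: allergy-table rows as dicts, and the
    day the prescription ends when the event triggers discontinuation.
    Moderate events discontinue within 30 days with probability 0.75,
    severe with probability 0.851; mild events never discontinue.
    """
    mild, moderate, severe = ae_rates
    if any(not (0.0 <= r <= 1.0) for r in ae_rates):
        raise ConfigurationError("ae_rates", f"rates {ae_rates} outside [0, 1]")
    u = rng.random()
    if u < severe:
        severity = "severe"
    elif u < severe + moderate:
        severity = "moderate"
    elif u < severe + moderate + mild:
        severity = "mild"
    else:
        return [], None
    day = start_day + int(rng.integers(20, 330))
    record = {"patient_id": patient_id, "medication_code": medication_code,
              "severity": severity, "date": day}
    disc = None
    p_disc = {"mild": 0.0, "moderate": MODERATE_DISCONTINUE_P,
              "severe": SEVERE_DISCONTINUE_P}[severity]
    if rng.random() < p_disc:
        disc = day + int(rng.integers(1, 31))
    return [record], disc


# ---------------------------------------------------------------------------
# cohort generation

@dataclass
class GroundTruth:
    """Planted counterfactual surface and realized states.

    ``probabilities``: long table (patient_id, treatment_id,
    success_probability, realized) over every candidate treatment;
    ``observed``: one row per patient with the prescribed option, its
    realized state, the planted violation (or 'none') and failure mode;
    ``effects``: the calibrated coefficient set actually used.
    """

    treatments: pd.DataFrame
    probabilities: pd.DataFrame
    observed: pd.DataFrame
    effects: dict

    def probability_matrix(self) -> pd.DataFrame:
        return self.probabilities.pivot(index="patient_id",
                                        columns="treatment_id",
                                        values="success_probability")


def _treatment_frame() -> pd.DataFrame:
    return pd.DataFrame({
        "treatment_id": [t.treatment_id for t in CANDIDATE_TREATMENTS],
        "key": [t.key for t in CANDIDATE_TREATMENTS],
        "class_label": [t.class_label for t in CANDIDATE_TREATMENTS],
        "n_components": [len(t.components) for t in CANDIDATE_TREATMENTS],
        "dose_dev": [t.dose_dev for t in CANDIDATE_TREATMENTS],
    })


def _all_probabilities(config, effects, age, female, race, comorb):
    """(n_patients x n_treatments) planted probability matrix."""
    n = len(age)
    black = (race == "Black").astype(float)
    other = (race == "Other").astype(float)
    flags = {c: comorb[c].astype(float) for c in COMORBIDITIES}
    probs = np.empty((n, len(CANDIDATE_TREATMENTS)))
    for t in CANDIDATE_TREATMENTS:
        eff = _effect_for(t.class_label, effects)
        lp = _linear_predictor(eff, age, black, other, female.astype(float),
                               flags, t.dose_dev)
        probs[:, t.treatment_id] = expit(lp)
    return probs


def _realized_states(seed: int, n: int) -> np.ndarray:
    """(n x T) uniform draws from counter-based substreams keyed by
    (seed, treatment); the patient's stable index is the stream position,
    so any (seed, patient, treatment) cell is individually addressable."""
    u = np.empty((n, len(CANDIDATE_TREATMENTS)))
    for t in CANDIDATE_TREATMENTS:
        bitgen = np.random.Philox(key=np.array(
            [seed % (2**64), 10_007 + t.treatment_id], dtype=np.uint64))
        u[:, t.treatment_id] = np.random.Generator(bitgen).random(n)
    return u


def generate_cohort(config: GeneratorConfig | None = None):
    """Generate ``(EHRBundle, GroundTruth)`` for the configured population."""
    config = GeneratorConfig() if config is None else config
    config.validate()
    n = config.n_patients
    effects = (calibrate_effects(config)
               if any(e.intercept is None for e in config.effect_coefficients.values())
               else {k: replace(v) for k, v in config.effect_coefficients.items()})

    pop_rng = np.random.default_rng([config.seed, 11])
    age, female, race, comorb = _sample_features(config, n, pop_rng)

    # pre-treatment measurements
    sbp0 = np.clip(pop_rng.normal(config.sbp_mean, config.sbp_sd, n), 95.0, 220.0)
    dbp0 = np.minimum(np.clip(pop_rng.normal(config.dbp_mean, config.dbp_sd, n),
                              50.0, 125.0), sbp0 - 15.0)
    creat0 = np.clip(pop_rng.normal(config.creatinine_mean, config.creatinine_sd, n),
                     0.4, 3.0)

    # calendar anchors (integer days since EPOCH)
    dx_day = pop_rng.integers(1_826, 5_100, size=n)
    start_off = pop_rng.integers(30, 261, size=n)

    # planted violations
    viol_names = sorted(config.planted_violations)
    viol_probs = [config.planted_violations[v] for v in viol_names]
    cats = ["none"] + viol_names
    probs = [1.0 - sum(viol_probs)] + viol_probs
    violation = np.array(cats)[pop_rng.choice(len(cats), size=n, p=probs)]
    start_off = np.where(violation == "late_treatment",
                         pop_rng.integers(271, 401, size=n), start_off)
    start_day = dx_day + start_off

    # observed prescription: class bucket, then option within bucket
    class_keys = sorted(config.class_likelihoods)
    cls_draw = np.array(class_keys)[pop_rng.choice(
        len(class_keys), size=n, p=[config.class_likelihoods[c] for c in class_keys])]
    observed_tid = np.empty(n, dtype=int)
    for cls in class_keys:
        mask = cls_draw == cls
        if not mask.any():
            continue
        ids, weights = (_other_bucket(config) if cls == "other"
                        else CLASS_OPTIONS[cls])
        w = np.asarray(weights) / np.sum(weights)
        observed_tid[mask] = pop_rng.choice(ids, size=int(mask.sum()), p=w)

    probs_matrix = _all_probabilities(config, effects, age, female, race, comorb)
    realized_matrix = _realized_states(config.seed, n) < probs_matrix
    realized_obs = realized_matrix[np.arange(n), observed_tid]

    builder = _RecordBuilder(config, effects)
    rare_counter = 0
    for i in range(n):
        rng = np.random.default_rng([config.seed, 23, i])
        rare_idx = None
        if violation[i] == "rare_pair":
            rare_idx = rare_counter
            rare_counter += 1
        builder.emit_patient(
            pid=i + 1, rng=rng, age=age[i], female=bool(female[i]), race=race[i],
            comorb={c: bool(comorb[c][i]) for c in COMORBIDITIES},
            sbp0=float(sbp0[i]), dbp0=float(dbp0[i]), creat0=float(creat0[i]),
            dx_day=int(dx_day[i]), start_day=int(start_day[i]),
            treatment=CANDIDATE_TREATMENTS[observed_tid[i]],
            realized=bool(realized_obs[i]), violation=str(violation[i]),
            rare_idx=rare_idx)

    bundle = builder.to_bundle()

    pid = np.arange(1, n + 1)
    long = pd.DataFrame({
        "patient_id": np.repeat(pid, len(CANDIDATE_TREATMENTS)),
        "treatment_id": np.tile(np.arange(len(CANDIDATE_TREATMENTS)), n),
        "success_probability": probs_matrix.ravel(),
        "realized": realized_matrix.ravel(),
    })
    observed = pd.DataFrame({
        "patient_id": pid,
        "treatment_id": observed_tid,
        "class_label": [CANDIDATE_TREATMENTS[t].class_label for t in observed_tid],
        "success_probability": probs_matrix[np.arange(n), observed_tid],
        "realized_success": realized_obs,
        "violation": violation,
        "failure_mode": builder.failure_modes,
        "age": age, "female": female, "race": race,
    })
    truth = GroundTruth(treatments=_treatment_frame(), probabilities=long,
                        observed=observed, effects=effects)
    return bundle, truth


class _RecordBuilder:
    """Accumulates raw rows (integer day offsets) and assembles the bundle."""

    def __init__(self, config: GeneratorConfig, effects: dict):
        self.cfg = config
        self.effects = effects
        self.patients: list[tuple] = []
        self.diagnoses: list[tuple] = []
        self.vitals: list[tuple] = []
        self.labs: list[tuple] = []
        self.medications: list[tuple] = []
        self.allergies: list[tuple] = []
        self.failure_modes: list[str] = []

    # -- row helpers ------------------------------------------------------
    def _vital(self, pid, kind, value, day, context="ambulatory",
               position="sitting", site="arm", invasive=0):
        self.vitals.append((pid, kind, round(float(value), 1), day,
                            position, site, invasive, context))

    def _bp_pair(self, pid, sbp, dbp, day, **kw):
        sbp = max(float(sbp), float(dbp) + 5.0)
        self._vital(pid, "SBP", sbp, day, **kw)
        self._vital(pid, "DBP", dbp, day, **kw)

    def _lab(self, pid, analyte, value, day, units=None):
        units = units or {"creatinine": "mg/dL", "sodium": "mEq/L",
                          "potassium": "mEq/L", "glucose_fasting": "mg/dL"}[analyte]
        self.labs.append((pid, analyte, round(float(value), 2), units, day))

    def _safe_lab_panel(self, pid, rng, creat0, day):
        self._lab(pid, "creatinine", creat0 * rng.uniform(0.9, 1.15), day)
        self._lab(pid, "sodium", np.clip(rng.normal(140, 2.5), 131, 149), day)
        self._lab(pid, "potassium", np.clip(rng.normal(4.3, 0.3), 3.7, 5.05), day)
        self._lab(pid, "glucose_fasting", np.clip(rng.normal(95, 9), 75, 118), day)

    def _controlled_bp(self, pid, rng, thr, days):
        t_sbp = rng.uniform(116.0, thr.avg_sbp_limit - 8.0)
        t_dbp = rng.uniform(68.0, 80.0)
        for d in days:
            sbp = np.clip(rng.normal(t_sbp, self.cfg.bp_noise_sd),
                          95.0, thr.avg_sbp_limit - 1.0)
            dbp = np.clip(rng.normal(t_dbp, self.cfg.bp_noise_sd * 0.75),
                          62.0, 88.0)
            self._bp_pair(pid, sbp, dbp, d)
            self._vital(pid, "HR", np.clip(rng.normal(72, 8), 55, 100), d)

    def _reading_days(self, rng, lo, hi, k):
        k = max(1, min(k, hi - lo))
        return sorted(int(d) for d in rng.choice(np.arange(lo, hi + 1),
                                                 size=k, replace=False))

    # -- main emitter ------------------------------------------------------
    def emit_patient(self, pid, rng, age, female, race, comorb, sbp0, dbp0,
                     creat0, dx_day, start_day, treatment, realized,
                     violation, rare_idx=None):
        from .outcomes import bp_thresholds

        cfg = self.cfg
        birth_day = dx_day - int(round(age * 365.25))
        self.patients.append((pid, birth_day, "F" if female else "M", race))

        if violation != "no_primary_htn":
            self.diagnoses.append((pid, "I10", dx_day, "ambulatory"))
        for cond, flag in comorb.items():
            if flag:
                d = dx_day if violation == "no_established_care" \
                    else dx_day - int(rng.integers(30, 800))
                self.diagnoses.append((pid, COMORBIDITY_CODES[cond], d, "ambulatory"))
        if violation != "no_established_care":
            self._vital(pid, "HR", np.clip(rng.normal(72, 8), 55, 95),
                        dx_day - int(rng.integers(60, 400)))

        # baseline measurements precede treatment start; for planted
        # no-established-care violators they must not precede the diagnosis
        def _baseline_day():
            d = start_day - int(rng.integers(7, 200))
            return max(d, dx_day) if violation == "no_established_care" else d

        if violation != "no_baseline_bp":
            self._bp_pair(pid, sbp0, dbp0, _baseline_day())
        if violation != "no_baseline_creatinine":
            self._lab(pid, "creatinine", creat0, _baseline_day())
        if violation == "new_diabetes":
            self.diagnoses.append((pid, "R73.03",
                                   start_day + int(rng.integers(30, 300)), "ambulatory"))

        age_start = age + (start_day - dx_day) / 365.25
        thr = bp_thresholds(age_start)

        # choose the prescription rows first so allergy records can be
        # linked to the codes the patient actually received
        if rare_idx is not None:
            code, sig = _RARE_GRID[rare_idx % len(_RARE_GRID)]
            rx_rows = ((code, sig),)
        elif treatment.combo_product is not None and rng.random() < 0.5:
            rx_rows = treatment.combo_product
        else:
            rx_rows = treatment.prescriptions

        end_day, failure_mode = self._emit_outcome(
            pid, rng, thr, creat0, start_day, treatment, realized, violation,
            rx_codes=tuple(code for code, _ in rx_rows))
        self.failure_modes.append(failure_mode)

        horizon_cap = start_day + 300 if violation == "short_followup" else None

        if rng.random() < cfg.invalid_bp_fraction:
            d = start_day + int(rng.integers(30, 300))
            if horizon_cap is None or d <= horizon_cap:
                self._bp_pair(pid, rng.uniform(180, 210), rng.uniform(95, 115),
                              d, context="hospital")

        self._emit_prescriptions(pid, rng, start_day, end_day, rx_rows)

        # an explicit follow-up marker so "one year of data" is satisfiable
        # even for sparse failure trajectories
        if horizon_cap is None:
            self._vital(pid, "HR", np.clip(rng.normal(72, 8), 55, 95),
                        start_day + int(rng.integers(366, 430)))

    def _emit_outcome(self, pid, rng, thr, creat0, start, treatment,
                      realized, violation, rx_codes):
        """Emit post-treatment vitals/labs/allergies; returns (end_day, mode)."""
        cfg = self.cfg
        k = max(1, int(rng.poisson(cfg.mean_outcome_readings)))
        default_end = (None if rng.random() < cfg.open_end_fraction
                       else start + int(rng.integers(380, 720)))

        if violation == "discontinued_controlled":
            end = start + int(rng.integers(220, 340))
            days = self._reading_days(rng, start + 14, end - 183, max(1, k - 2))
            self._controlled_bp(pid, rng, thr, days)
            self._safe_lab_panel(pid, rng, creat0, start + int(rng.integers(30, 180)))
            return end, "planted_exclusion"
        if violation == "no_outcome_bp":
            self._safe_lab_panel(pid, rng, creat0, start + int(rng.integers(30, 330)))
            return None, "planted_exclusion"
        if violation == "short_followup":
            days = self._reading_days(rng, start + 187, start + 290, k)
            self._controlled_bp(pid, rng, thr, days)
            self._safe_lab_panel(pid, rng, creat0, start + int(rng.integers(30, 180)))
            return None, "planted_exclusion"

        if realized:
            if rng.random() < cfg.fallback_window_fraction:
                lo, hi = [(367, 426), (428, 547), (549, 729)][
                    rng.choice(3, p=[0.5, 0.3, 0.2])]
                days = self._reading_days(rng, start + lo, start + hi, k)
                end = None  # regimen maintained through the fallback window
            else:
                days = self._reading_days(rng, start + 187, start + 360, k)
                end = default_end
            self._controlled_bp(pid, rng, thr, days)
            self._safe_lab_panel(pid, rng, creat0, start + int(rng.integers(30, 330)))
            mild_rate = self._ae_rates_for(treatment)[0]
            if rng.random() < mild_rate:
                code = rx_codes[int(rng.integers(len(rx_codes)))]
                self.allergies.append((pid, code, "mild",
                                       start + int(rng.integers(20, 200))))
            return end, "success"

        # realized failure
        if rng.random() < cfg.ae_failure_share:
            return self._emit_ae_failure(pid, rng, thr, creat0, start,
                                         treatment, default_end, k, rx_codes)
        return self._emit_bp_failure(pid, rng, thr, creat0, start,
                                     default_end, k)

    def _emit_bp_failure(self, pid, rng, thr, creat0, start, default_end, k):
        cfg = self.cfg
        k = max(2, k)
        if rng.random() < cfg.bp_failure_discontinue_frac:
            end = start + int(rng.integers(240, 356))
            days = self._reading_days(rng, start + 14, end - 183, k)
        else:
            end = default_end
            days = self._reading_days(rng, start + 187, start + 360, k)
        if rng.random() < cfg.bp_threshold_share:
            mode = "bp_threshold"
            spike = int(rng.integers(len(days)))
            t_dbp = rng.uniform(68, 80)
            for j, d in enumerate(days):
                if j == spike:
                    if rng.random() < 0.7:
                        sbp = thr.max_sbp_limit + rng.uniform(4, 18)
                        dbp = np.clip(rng.normal(t_dbp, 6), 62, 88)
                    else:
                        sbp = np.clip(rng.normal(130, 8), 100, thr.avg_sbp_limit - 1)
                        dbp = thr.max_dbp_limit + rng.uniform(1, 8)
                else:
                    sbp = np.clip(rng.normal(128, cfg.bp_noise_sd), 95,
                                  thr.avg_sbp_limit - 1)
                    dbp = np.clip(rng.normal(t_dbp, 6), 62, 88)
                self._bp_pair(pid, sbp, dbp, d)
                self._vital(pid, "HR", np.clip(rng.normal(72, 8), 55, 100), d)
        else:
            mode = "bp_average"
            t_sbp = thr.avg_sbp_limit + rng.uniform(3, 12)
            for d in days:
                sbp = np.clip(rng.normal(t_sbp, cfg.bp_noise_sd),
                              thr.avg_sbp_limit + 1, thr.max_sbp_limit - 1)
                dbp = np.clip(rng.normal(76, 6), 62, 88)
                self._bp_pair(pid, sbp, dbp, d)
                self._vital(pid, "HR", np.clip(rng.normal(72, 8), 55, 100), d)
        self._safe_lab_panel(pid, rng, creat0, start + int(rng.integers(30, 180)))
        return end, mode

    def _ae_rates_for(self, treatment):
        classes = sorted({INGREDIENT_CLASS[i] for i, _ in treatment.components})
        for cls in classes:
            if cls in self.cfg.ae_rates:
                return self.cfg.ae_rates[cls]
        return self.cfg.ae_rates["other"]

    def _emit_ae_failure(self, pid, rng, thr, creat0, start, treatment,
                         default_end, k, rx_codes):
        cfg = self.cfg
        modes = sorted(cfg.ae_mode_weights)
        weights = np.array([cfg.ae_mode_weights[m] for m in modes])
        mode = modes[int(rng.choice(len(modes), p=weights / weights.sum()))]

        days = self._reading_days(rng, start + 187, start + 360, k)
        self._controlled_bp(pid, rng, thr, days)
        self._safe_lab_panel(pid, rng, creat0, start + int(rng.integers(30, 180)))
        end = default_end
        d = start + int(rng.integers(30, 330))
        # vitals-based events stay clear of the outcome-window reading days
        d_vital = start + int(rng.integers(30, 181))

        if mode == "documented_ae":
            mild, m_w, s_w = self._ae_rates_for(treatment)
            total = m_w + s_w
            severity = "severe" if rng.random() < (s_w / total if total else 0.3) \
                else "moderate"
            code = rx_codes[int(rng.integers(len(rx_codes)))]
            self.allergies.append((pid, code, severity, d))
            p_disc = SEVERE_DISCONTINUE_P if severity == "severe" else MODERATE_DISCONTINUE_P
            if rng.random() < p_disc:
                end = d + int(rng.integers(1, 31))
        elif mode == "hypotension":
            self._bp_pair(pid, rng.uniform(78, 88), rng.uniform(48, 58), d_vital)
        elif mode == "bradycardia":
            self._vital(pid, "HR", rng.uniform(38, 48), d_vital)
        elif mode == "creatinine_rise":
            self._lab(pid, "creatinine", creat0 * rng.uniform(1.35, 1.8), d)
        elif mode == "natremia":
            val = rng.uniform(123, 128) if rng.random() < 0.5 else rng.uniform(151, 156)
            self._lab(pid, "sodium", val, d)
        elif mode == "kalemia":
            val = rng.uniform(2.9, 3.5) if rng.random() < 0.5 else rng.uniform(5.2, 6.0)
            self._lab(pid, "potassium", val, d)
        elif mode == "glucose":
            self._lab(pid, "glucose_fasting", rng.uniform(125, 165), d)
        return end, mode

    def _emit_prescriptions(self, pid, rng, start, end, rx_rows):
        cfg = self.cfg
        split = rng.random() < cfg.refill_split_fraction
        mid = start + int(rng.integers(60, 150)) if split else None
        for code, sig in rx_rows:
            rows = [(start, end)]
            if split and (end is None or end > mid + 10):
                rows = [(start, mid), (mid + 1, end)]
            for s, e in rows:
                self.medications.append((pid, code, _CODE_NAME[code],
                                         _CODE_UNIT_DOSE[code], sig, s, e))

    # -- assembly ----------------------------------------------------------
    def to_bundle(self) -> EHRBundle:
        def days_to_ts(series):
            return EPOCH + pd.to_timedelta(series, unit="D")

        patients = pd.DataFrame(self.patients, columns=[
            "patient_id", "birth_date", "sex", "race"])
        patients["birth_date"] = days_to_ts(patients["birth_date"])
        diagnoses = pd.DataFrame(self.diagnoses, columns=[
            "patient_id", "code", "date", "setting"])
        diagnoses["date"] = days_to_ts(diagnoses["date"])
        vitals = pd.DataFrame(self.vitals, columns=[
            "patient_id", "kind", "value", "date",
            "position", "body_site", "invasive_flag", "context"])
        vitals["date"] = days_to_ts(vitals["date"])
        labs = pd.DataFrame(self.labs, columns=[
            "patient_id", "analyte", "value", "units", "date"])
        labs["date"] = days_to_ts(labs["date"])
        medications = pd.DataFrame(self.medications, columns=[
            "patient_id", "code", "name", "per_unit_dose_mg",
            "sig_text", "start_date", "end_date"])
        medications["start_date"] = days_to_ts(medications["start_date"])
        medications["end_date"] = days_to_ts(medications["end_date"])
        allergies = pd.DataFrame(self.allergies, columns=[
            "patient_id", "medication_code", "severity", "date"])
        allergies["date"] = days_to_ts(allergies["date"])
        bundle = EHRBundle(patients=patients, diagnoses=diagnoses,
                           vitals=vitals, labs=labs, medications=medications,
                           allergies=allergies).sorted_copy()
        bundle.validate()
        return bundle
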