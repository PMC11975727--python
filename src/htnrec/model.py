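"""Ensemble success model with positivity-aware confidence tiers.

Per (patient, ingredient-dose regimen) the model predicts the
probability of treatment success (year-long blood-pressure control with
no moderate/severe adverse effect).  The prediction is the median of 20
small feed-forward probability estimators, each trained on its own 80%
subsample of the training set with its own seed; the 10/25/75/90
percentiles of the member scores form uncertainty bands.

A confidence tier (low/medium/high) combines ensemble dispersion with
the training support for the candidate treatment among feature-similar
patients (same race and age decade).  Dispersion is the p90 - p10 band
width normalized by the binomial scale at the median, m(1 - m): raw band
width grows mechanically with m(1 - m) for probability outputs, so the
unnormalized width would grade low-probability predictions as
"confident" regardless of member agreement.  Zero support is a hard
positivity violation and always yields the low tier, implementing the
overlap filter of the causal contract: only treatments actually observed
in a subpopulation are compared within it.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .config import COMORBIDITIES, COMORBIDITY_CODES, ModelConfig
from .cohort import age_at, filter_bp_measurements
from .synthetic import REF_DAILY_DOSE

__all__ = [
    "FEATURE_NAMES",
    "INGREDIENTS",
    "PredictedSuccess",
    "SuccessEnsemble",
    "featurize",
    "treatment_key",
    "extract_patient_features",
    "build_training_matrix",
    "confidence_tier",
    "calibrate_confidence",
    "recommend",
    "aggregate_to_class",
    "TIER_ORDER",
]

INGREDIENTS = tuple(sorted(REF_DAILY_DOSE))

FEATURE_NAMES = (
    ("age", "sbp_pre", "dbp_pre", "creatinine", "female", "race_black",
     "race_other") + COMORBIDITIES + tuple(f"dose_{i}" for i in INGREDIENTS)
)

TIER_ORDER = {"low": 0, "medium": 1, "high": 2}

_ING_INDEX = {ing: i for i, ing in enumerate(INGREDIENTS)}


@dataclass(frozen=True)
class PredictedSuccess:
    """Ensemble prediction for one patient-treatment pair."""

    median_probability: float
    p10: float
    p25: float
    p75: float
    p90: float
    confidence_tier: str
    support_count: int

    @property
    def dispersion(self) -> float:
        return self.p90 - self.p10


def treatment_key(components) -> str:
    """Canonical string for a set of (ingredient, daily dose) components."""
    return "+".join(f"{i}:{d:g}" for i, d in sorted(components))


def _treatment_vector(components) -> np.ndarray:
    doses = np.zeros(len(INGREDIENTS))
    for ing, dose in components:
        if ing not in _ING_INDEX:
            raise KeyError(f"unknown treatment ingredient {ing!r}")
        doses[_ING_INDEX[ing]] = dose / REF_DAILY_DOSE[ing]
    return doses


def featurize(patient: dict, components) -> np.ndarray:
    """Deterministic feature vector for one patient-treatment pair.

    Continuous values are passed through untransformed (scaling is a
    member-internal detail).  Any missing or non-finite field is a hard
    error — the causal contract requires complete features, never
    imputation.
    """
    values = []
    for name in ("age", "sbp_pre", "dbp_pre", "creatinine"):
        if name not in patient or patient[name] is None or \
                not np.isfinite(patient[name]):
            raise ValueError(f"missing required feature {name!r}")
        values.append(float(patient[name]))
    if "female" not in patient or "race" not in patient:
        raise ValueError("missing required feature 'female' or 'race'")
    values.append(float(patient["female"]))
    values.append(1.0 if patient["race"] == "Black" else 0.0)
    values.append(1.0 if patient["race"] == "Other" else 0.0)
    for cond in COMORBIDITIES:
        if cond not in patient or patient[cond] is None:
            raise ValueError(f"missing required feature {cond!r}")
        values.append(float(patient[cond]))
    return np.concatenate([np.asarray(values), _treatment_vector(components)])


def support_key(patient: dict, components) -> tuple:
    """(treatment, race, age decade): the cell whose training count gauges
    positivity for this prediction."""
    return (treatment_key(components), patient["race"], int(patient["age"] // 10))


def extract_patient_features(bundle, episodes: dict) -> pd.DataFrame:
    """Pre-treatment feature table, one row per patient with an episode.

    Age at treatment start; latest valid ambulatory BP and latest
    creatinine before start; sex, race and the seven comorbidity flags
    (any diagnosis code on or before start).
    """
    patients = bundle.patients.set_index("patient_id")
    bp = filter_bp_measurements(bundle.vitals)
    bp_by = dict(tuple(bp.groupby("patient_id"))) if len(bp) else {}
    creat = bundle.labs[bundle.labs["analyte"] == "creatinine"]
    cr_by = dict(tuple(creat.groupby("patient_id"))) if len(creat) else {}
    dx_by = dict(tuple(bundle.diagnoses.groupby("patient_id"))) \
        if len(bundle.diagnoses) else {}

    rows = {}
    for pid, ep in sorted(episodes.items()):
        p = patients.loc[pid]
        row = {"age": age_at(p["birth_date"], ep.start),
               "female": 1.0 if p["sex"] == "F" else 0.0,
               "race": p["race"]}
        pbp = bp_by.get(pid)
        if pbp is not None:
            pre = pbp[pbp["date"] < ep.start]
            if len(pre):
                last = pre[pre["date"] == pre["date"].max()]
                sbp = last.loc[last["kind"] == "SBP", "value"]
                dbp = last.loc[last["kind"] == "DBP", "value"]
                row["sbp_pre"] = float(sbp.iloc[0]) if len(sbp) else np.nan
                row["dbp_pre"] = float(dbp.iloc[0]) if len(dbp) else np.nan
        pcr = cr_by.get(pid)
        if pcr is not None:
            pre = pcr[pcr["date"] < ep.start]
            if len(pre):
                row["creatinine"] = float(
                    pre.sort_values("date")["value"].iloc[-1])
        pdx = dx_by.get(pid)
        for cond, code in COMORBIDITY_CODES.items():
            row[cond] = 0.0
            if pdx is not None and \
                    ((pdx["code"] == code) & (pdx["date"] <= ep.start)).any():
                row[cond] = 1.0
        rows[pid] = row
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "patient_id"
    return df


def build_training_matrix(features: pd.DataFrame, episodes: dict,
                          labels: pd.DataFrame):
    """(X, y, support_keys, patient_ids) over non-excluded labeled episodes."""
    lab = labels.set_index("patient_id")
    lab = lab[lab["status"].isin(["success", "failure"])]
    X, y, keys, pids = [], [], [], []
    for pid in lab.index:
        row = features.loc[pid].to_dict()
        comps = episodes[pid].components
        X.append(featurize(row, comps))
        y.append(lab.loc[pid, "status"] == "success")
        keys.append(support_key(row, comps))
        pids.append(pid)
    return np.asarray(X), np.asarray(y, dtype=bool), keys, np.asarray(pids)


class SuccessEnsemble:
    """20 feed-forward members on independent 80% subsamples.

    The median member score is the success probability; percentile bands
    use linear interpolation between order statistics.
    """

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        self.members_: list[Pipeline] | None = None
        self.member_seeds_: np.ndarray | None = None
        self.subsample_indices_: list[np.ndarray] | None = None
        self.support_index_: Counter | None = None

    # -- training ----------------------------------------------------------
    def fit(self, X: np.ndarray, y: np.ndarray, seed: int,
            support_keys: list | None = None) -> "SuccessEnsemble":
        cfg = self.config
        cfg.validate()
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=bool)
        if len(np.unique(y)) < 2:
            raise ValueError("degenerate labels: need both successes and failures")
        n = len(y)
        n_sub = int(np.floor(cfg.subsample * n))
        rng = np.random.default_rng([seed, 101])
        seeds = []
        while len(seeds) < cfg.n_members:  # member seeds must be distinct
            s = int(rng.integers(0, 2**31 - 1))
            if s not in seeds:
                seeds.append(s)
        self.member_seeds_ = np.asarray(seeds)
        self.members_ = []
        self.subsample_indices_ = []
        for s in seeds:
            mrng = np.random.default_rng(s)
            idx = mrng.choice(n, size=n_sub, replace=False)
            member = Pipeline([
                ("scale", StandardScaler()),
                ("net", MLPClassifier(
                    hidden_layer_sizes=tuple(cfg.hidden_layers),
                    max_iter=cfg.max_iter, alpha=cfg.alpha,
                    batch_size=min(cfg.batch_size, n_sub),
                    learning_rate_init=cfg.learning_rate_init,
                    random_state=s)),
            ])
            member.fit(X[idx], y[idx])
            self.members_.append(member)
            self.subsample_indices_.append(idx)
        self.support_index_ = Counter(support_keys or [])
        return self

    def _check_fitted(self):
        if self.members_ is None:
            raise RuntimeError("ensemble is untrained; call fit() first")

    # -- prediction --------------------------------------------------------
    def member_scores(self, X: np.ndarray) -> np.ndarray:
        """(n_cases, n_members) success probabilities."""
        self._check_fitted()
        X = np.atleast_2d(np.asarray(X, dtype=float))
        cols = []
        for member in self.members_:
            idx = list(member.named_steps["net"].classes_).index(True)
            cols.append(member.predict_proba(X)[:, idx])
        return np.column_stack(cols)

    def predict_bands(self, X: np.ndarray) -> pd.DataFrame:
        scores = self.member_scores(X)
        q = np.percentile(scores, [10, 25, 50, 75, 90], axis=1,
                          method="linear")
        return pd.DataFrame({"p10": q[0], "p25": q[1], "median": q[2],
                             "p75": q[3], "p90": q[4]})

    def support_count(self, patient: dict, components) -> int:
        self._check_fitted()
        return int(self.support_index_.get(support_key(patient, components), 0))

    def predict_success(self, patient: dict, components) -> PredictedSuccess:
        """Median + percentile bands + confidence tier for one pair."""
        bands = self.predict_bands(featurize(patient, components)[None, :]).iloc[0]
        support = self.support_count(patient, components)
        disp = normalized_dispersion(bands["p10"], bands["p90"], bands["median"])
        tier = confidence_tier(float(disp), support, self.config)
        return PredictedSuccess(
            median_probability=float(bands["median"]),
            p10=float(bands["p10"]), p25=float(bands["p25"]),
            p75=float(bands["p75"]), p90=float(bands["p90"]),
            confidence_tier=tier, support_count=support)


def normalized_dispersion(p10, p90, median):
    """Member disagreement on a scale-free basis: the 10-90 band width
    divided by the binomial scale m(1 - m) at the (clipped) median."""
    m = np.clip(np.asarray(median, dtype=float), 0.02, 0.98)
    return (np.asarray(p90, dtype=float) - np.asarray(p10, dtype=float)) \
        / (m * (1.0 - m))


def confidence_tier(dispersion: float, support_count: int,
                    config: ModelConfig) -> str:
    """Tier from normalized ensemble dispersion and training support.

    Zero support is a positivity violation: always low, whatever the
    member agreement.
    """
    if support_count <= 0:
        return "low"
    if dispersion <= config.dispersion_high and \
            support_count >= config.support_min_high:
        return "high"
    if dispersion <= config.dispersion_medium and \
            support_count >= config.support_min_medium:
        return "medium"
    return "low"


def calibrate_confidence(dispersions: np.ndarray, supports: np.ndarray,
                         config: ModelConfig) -> ModelConfig:
    """Set dispersion thresholds so tier fractions on a reference case set
    approximate ``config.calibration_fractions`` (medium+high, high).

    Thresholds are dispersion quantiles among cases with sufficient
    support; the support minima are left as configured.
    """
    dispersions = np.asarray(dispersions, dtype=float)
    supports = np.asarray(supports)
    n = len(dispersions)
    f_mh, f_h = config.calibration_fractions
    out = ModelConfig(**{**config.__dict__})

    elig_h = dispersions[supports >= config.support_min_high]
    if len(elig_h):
        q = min(1.0, f_h * n / len(elig_h))
        out.dispersion_high = float(np.quantile(elig_h, q))
    elig_m = dispersions[supports >= config.support_min_medium]
    if len(elig_m):
        q = min(1.0, f_mh * n / len(elig_m))
        out.dispersion_medium = float(max(np.quantile(elig_m, q),
                                          out.dispersion_high))
    return out


def recommend(ensemble: SuccessEnsemble, patient: dict, candidates,
              min_tier: str = "low"):
    """Rank candidate regimens for one patient.

    ``candidates`` is an iterable of component sets (or objects with a
    ``components`` attribute).  Candidates below ``min_tier`` are dropped;
    the rest are sorted by median success probability (descending), ties
    broken by higher support, then lexicographic treatment key.  An empty
    result signals that no candidate clears the confidence bar.
    """
    if min_tier not in TIER_ORDER:
        raise ValueError(f"unknown tier {min_tier!r}")
    ranked = []
    for cand in candidates:
        comps = getattr(cand, "components", cand)
        pred = ensemble.predict_success(patient, comps)
        if TIER_ORDER[pred.confidence_tier] < TIER_ORDER[min_tier]:
            continue
        ranked.append((treatment_key(comps), pred))
    ranked.sort(key=lambda kp: (-kp[1].median_probability,
                                -kp[1].support_count, kp[0]))
    return ranked


def aggregate_to_class(predictions: dict, prescription_probabilities: dict,
                       class_of: dict) -> dict:
    """Class-level success scores: prescription-probability-weighted mean of
    the ingredient-dose scores within each class.

    ``predictions``/``prescription_probabilities``/``class_of`` are all
    keyed by treatment key; weights must sum to 1 within each class.
    """
    by_class: dict[str, list] = {}
    for key, score in predictions.items():
        cls = class_of[key]
        by_class.setdefault(cls, []).append(
            (prescription_probabilities[key], score))
    out = {}
    for cls, pairs in sorted(by_class.items()):
        total = sum(w for w, _ in pairs)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(
                f"prescription probabilities for class {cls!r} sum to {total}, not 1")
        out[cls] = float(sum(w * s for w, s in pairs))
    return out
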