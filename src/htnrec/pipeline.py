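"""End-to-end orchestration: simulate -> cohort -> label -> train -> evaluate.

Each stage writes its outputs to files so stages are independently
inspectable and resumable; a manifest records the configuration hash,
seed and per-stage row counts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
import pickle

import numpy as np
import pandas as pd
import yaml

from . import cohort as cohort_mod
from . import evaluation as eval_mod
from . import guidelines as guide_mod
from . import medication as med_mod
from . import outcomes as out_mod
from .config import RunConfig, save_config
from .ehr_io import write_bundle
from .model import (SuccessEnsemble, build_training_matrix, calibrate_confidence,
                    extract_patient_features, featurize, treatment_key)
from .synthetic import CANDIDATE_TREATMENTS, generate_cohort

logger = logging.getLogger(__name__)

__all__ = [
    "run_pipeline",
    "build_cohort",
    "train_model",
    "predict_cases",
    "evaluate_model",
    "save_model",
    "load_model",
    "REFERENCE_PATIENT",
]

#: representative case for the curve bundles: White patient, no
#: comorbidities, creatinine 0.8 mg/dL, pre-treatment BP 160/90, age 50
REFERENCE_PATIENT = {
    "age": 50.0, "sbp_pre": 160.0, "dbp_pre": 90.0, "creatinine": 0.8,
    "female": 0.0, "race": "White",
    "tachyarrhythmia": 0.0, "type2_diabetes": 0.0,
    "ischemic_heart_disease": 0.0, "asthma": 0.0,
    "chronic_kidney_disease": 0.0, "congestive_heart_failure": 0.0,
    "gout": 0.0,
}


def build_cohort(bundle, n_validation: int, seed: int):
    """Episodes, eligibility log and train/validation split."""
    episodes, problems = med_mod.episodes_for_bundle(bundle)
    records = cohort_mod.apply_inclusion(bundle, episodes)
    records = cohort_mod.apply_exclusions(records, bundle, episodes)
    eligibility = cohort_mod.eligibility_frame(records)
    included = eligibility.loc[eligibility["included"], "patient_id"].tolist()
    train_ids, val_ids = cohort_mod.split_train_validation(
        included, n_validation, seed)
    logger.info("cohort: %d included of %d (%d problems); train %d / validation %d",
                len(included), len(eligibility), len(problems),
                len(train_ids), len(val_ids))
    return episodes, eligibility, train_ids, val_ids


def train_model(bundle, episodes, labels: pd.DataFrame, train_ids,
                model_config, seed: int):
    """Fit the ensemble on the training episodes and calibrate confidence
    thresholds on the training-set dispersion distribution."""
    lab_train = labels[labels["patient_id"].isin(train_ids)]
    features = extract_patient_features(
        bundle, {p: episodes[p] for p in labels["patient_id"] if p in episodes})
    X, y, keys, pids = build_training_matrix(features, episodes, lab_train)
    ensemble = SuccessEnsemble(model_config).fit(X, y, seed=seed, support_keys=keys)
    if ensemble.config.success_threshold is None:
        ensemble.config.success_threshold = float(np.mean(y))

    bands = ensemble.predict_bands(X)
    from .model import normalized_dispersion
    disp = normalized_dispersion(bands["p10"], bands["p90"], bands["median"])
    supports = np.asarray([ensemble.support_index_.get(k, 0) for k in keys])
    ensemble.config = calibrate_confidence(disp, supports, ensemble.config)
    logger.info("trained %d members on %d episodes; dispersion thresholds "
                "medium %.4f high %.4f", ensemble.config.n_members, len(y),
                ensemble.config.dispersion_medium, ensemble.config.dispersion_high)
    return ensemble, features


def predict_cases(ensemble, features: pd.DataFrame, episodes, ids) -> pd.DataFrame:
    """Per-case prediction on the observed treatment: bands, tier, support.

    Batched over cases (one member pass over the whole matrix)."""
    from .model import confidence_tier, normalized_dispersion

    ids = sorted(ids)
    if not ids:
        return pd.DataFrame(columns=["patient_id", "treatment", "class_label",
                                     "median", "p10", "p25", "p75", "p90",
                                     "tier", "support"])
    X, supports = [], []
    for pid in ids:
        patient = features.loc[pid].to_dict()
        comps = episodes[pid].components
        X.append(featurize(patient, comps))
        supports.append(ensemble.support_count(patient, comps))
    bands = ensemble.predict_bands(np.vstack(X))
    disp = normalized_dispersion(bands["p10"], bands["p90"], bands["median"])
    tiers = [confidence_tier(float(d), s, ensemble.config)
             for d, s in zip(disp, supports)]
    return pd.DataFrame({
        "patient_id": ids,
        "treatment": [treatment_key(episodes[p].components) for p in ids],
        "class_label": [episodes[p].drug_class_label for p in ids],
        "median": bands["median"].to_numpy(), "p10": bands["p10"].to_numpy(),
        "p25": bands["p25"].to_numpy(), "p75": bands["p75"].to_numpy(),
        "p90": bands["p90"].to_numpy(), "tier": tiers, "support": supports,
    })


def top_class_per_patient(ensemble, features: pd.DataFrame, ids) -> dict:
    """Model's top suggested drug class per patient.

    Class scores are prescription-weighted means over the class menu,
    evaluated in one batched member pass for all patients."""
    ids = sorted(ids)
    menus = {cls: eval_mod.class_menu(cls) for cls in eval_mod.REPORTED_CLASSES}
    X, meta = [], []
    for pid in ids:
        patient = features.loc[pid].to_dict()
        for cls, menu in menus.items():
            for t, w in menu:
                X.append(featurize(patient, t.components))
                meta.append((pid, cls, w))
    bands = ensemble.predict_bands(np.vstack(X))
    scores = pd.DataFrame(meta, columns=["patient_id", "class", "w"])
    scores["wm"] = scores["w"] * bands["median"].to_numpy()
    agg = scores.groupby(["patient_id", "class"])["wm"].sum().reset_index()
    out = {}
    for pid, grp in agg.groupby("patient_id"):
        grp = grp.sort_values(["wm", "class"], ascending=[False, True])
        out[int(pid)] = grp.iloc[0]["class"]
    return out


def evaluate_model(ensemble, bundle, episodes, labels, features,
                   val_ids, threshold: float = 0.5):
    """Validation report: overall + stratified metrics, class table on the
    labeled episodes, and guideline agreement for model and physician."""
    lab = labels.set_index("patient_id")
    val_labeled = [p for p in sorted(val_ids)
                   if p in lab.index and lab.loc[p, "status"] != "excluded"]
    preds = predict_cases(ensemble, features, episodes, val_labeled)
    statuses = [lab.loc[p, "status"] for p in preds["patient_id"]]

    overall = eval_mod.precision_recall_f1(statuses, preds["median"], threshold)
    strat = eval_mod.confidence_stratified_metrics(
        statuses, preds["median"], preds["tier"], threshold)

    class_table = eval_mod.class_success_table(
        [episodes[p].drug_class_label for p in lab.index if p in episodes],
        lab["status"].tolist())

    recs = {p: guide_mod.jnc8_recommended_classes(
        {"patient_id": p, **features.loc[p].to_dict()}) for p in val_labeled}
    model_top = top_class_per_patient(ensemble, features, val_labeled)
    physician_top = {p: episodes[p].drug_class_label for p in val_labeled}
    agreement = {
        "model": guide_mod.agreement_rate(model_top, recs),
        "physician": guide_mod.agreement_rate(physician_top, recs),
    }
    report = eval_mod.EvaluationReport(
        n_cases=overall["n"], precision=overall["precision"],
        recall=overall["recall"], f1=overall["f1"], stratified=strat,
        class_table=class_table, agreement=agreement)
    return report, preds


def save_model(ensemble, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    with open(os.path.join(directory, "model_config.yaml"), "w") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in ensemble.config.__dict__.items()}, fh)
    with open(os.path.join(directory, "ensemble.pkl"), "wb") as fh:
        pickle.dump(ensemble, fh)


def load_model(directory: str):
    with open(os.path.join(directory, "ensemble.pkl"), "rb") as fh:
        return pickle.load(fh)


def _config_hash(cfg: RunConfig) -> str:
    tmp = os.path.join(cfg.out_dir, "config.yaml")
    save_config(cfg, tmp)
    with open(tmp, "rb") as fh:
        return hashlib.sha256(fh.read()).hexdigest()[:16]


def run_pipeline(cfg: RunConfig) -> dict:
    """Run every stage; returns a dict of artifact paths."""
    cfg.validate()
    os.makedirs(cfg.out_dir, exist_ok=True)
    paths = {"out_dir": cfg.out_dir}
    counts = {}

    gen_cfg = cfg.generator
    gen_cfg.seed = cfg.seed
    bundle, truth = generate_cohort(gen_cfg)
    bundle_dir = os.path.join(cfg.out_dir, "bundle")
    write_bundle(bundle, bundle_dir)
    truth.observed.to_csv(os.path.join(cfg.out_dir, "ground_truth_observed.csv"),
                          index=False)
    paths["bundle"] = bundle_dir
    counts["patients"] = bundle.n_patients()
    logger.info("simulate: %d patients", bundle.n_patients())

    episodes, eligibility, train_ids, val_ids = build_cohort(
        bundle, cfg.n_validation, cfg.seed)
    elig_path = os.path.join(cfg.out_dir, "eligibility.csv")
    eligibility.to_csv(elig_path, index=False)
    paths["eligibility"] = elig_path
    counts["included"] = int(eligibility["included"].sum())

    included = set(eligibility.loc[eligibility["included"], "patient_id"])
    labels = out_mod.label_cohort(bundle, {p: episodes[p] for p in included})
    labels_path = os.path.join(cfg.out_dir, "labels.csv")
    labels.to_csv(labels_path, index=False)
    paths["labels"] = labels_path
    counts["labeled"] = len(labels)
    non_exc = labels[labels["status"] != "excluded"]
    counts["success_rate_pct"] = round(
        100.0 * float((non_exc["status"] == "success").mean()), 3)
    logger.info("label: %d labels, success rate %.2f%%",
                len(labels), counts["success_rate_pct"])

    ensemble, features = train_model(bundle, episodes, labels, train_ids,
                                     cfg.model, cfg.seed)
    model_dir = os.path.join(cfg.out_dir, "model")
    save_model(ensemble, model_dir)
    paths["model"] = model_dir

    report, preds = evaluate_model(ensemble, bundle, episodes, labels,
                                   features, val_ids,
                                   threshold=ensemble.config.success_threshold)
    preds_path = os.path.join(cfg.out_dir, "validation_predictions.csv")
    preds.to_csv(preds_path, index=False)
    report.class_table.to_csv(os.path.join(cfg.out_dir, "class_table.csv"),
                              index=False)
    summary_path = os.path.join(cfg.out_dir, "summary.txt")
    with open(summary_path, "w") as fh:
        fh.write("\n".join(report.summary_lines()) + "\n")
    paths["summary"] = summary_path
    counts["validation_cases"] = report.n_cases

    if cfg.write_curves:
        curves = eval_mod.success_curves(
            ensemble, REFERENCE_PATIENT, "age", list(range(30, 86, 5)))
        curves.to_csv(os.path.join(cfg.out_dir, "curves_age.csv"), index=False)
        curves_sbp = eval_mod.success_curves(
            ensemble, REFERENCE_PATIENT, "SBP", list(range(120, 201, 10)))
        curves_sbp.to_csv(os.path.join(cfg.out_dir, "curves_sbp.csv"), index=False)

    manifest = {"config_hash": _config_hash(cfg), "seed": cfg.seed,
                "counts": counts}
    with open(os.path.join(cfg.out_dir, "manifest.json"), "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    paths["manifest"] = os.path.join(cfg.out_dir, "manifest.json")
    return paths
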