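"""Evaluation metrics and reports for the success model.

Precision/recall/F1 of predicted vs labeled treatment success (overall
and stratified by confidence tier), the per-class treatment likelihood
and success-rate table, guideline-agreement percentages, and
success-vs-age/SBP curve bundles with ensemble percentile bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import CANDIDATE_TREATMENTS, CLASS_OPTIONS

__all__ = [
    "EvaluationReport",
    "precision_recall_f1",
    "f1_from_pr",
    "confidence_stratified_metrics",
    "class_success_table",
    "success_curves",
    "pct",
]

#: classes reported by the curve bundle and class-level aggregation
REPORTED_CLASSES = ("ACEi", "ARB", "thiazide", "CCB", "beta-blocker",
                    "ACEi+thiazide")


def pct(x: float | None) -> float | None:
    """Percentage to one decimal (round-half-even, matching report style)."""
    return None if x is None else round(float(x), 1)


def precision_recall_f1(labels, predicted_probabilities, threshold: float = 0.5) -> dict:
    """Success-prediction metrics on percentage scale.

    ``labels``: iterable of 'success'/'failure' (excluded already dropped);
    positive class is success, predicted positive when probability >=
    threshold.  Undefined metrics (zero denominator) are ``None``, never 0.
    """
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold {threshold} outside (0, 1)")
    y = np.asarray([s == "success" for s in labels], dtype=bool)
    bad = [s for s in labels if s not in ("success", "failure")]
    if bad:
        raise ValueError(f"unexpected label {bad[0]!r}; drop excluded episodes first")
    pred = np.asarray(predicted_probabilities, dtype=float) >= threshold
    tp = int((y & pred).sum())
    fp = int((~y & pred).sum())
    fn = int((y & ~pred).sum())
    precision = 100.0 * tp / (tp + fp) if tp + fp else None
    recall = 100.0 * tp / (tp + fn) if tp + fn else None
    f1 = (f1_from_pr(precision, recall)
          if precision not in (None, 0) or recall not in (None, 0) else None)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    return {"n": int(len(y)), "tp": tp, "fp": fp, "fn": fn,
            "precision": precision, "recall": recall, "f1": f1}


def f1_from_pr(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall, on the same scale as its inputs."""
    if precision is None or recall is None:
        raise ValueError("precision and recall must be defined")
    if precision < 0 or recall < 0 or precision + recall == 0:
        raise ValueError("precision and recall must be positive")
    return 2.0 * precision * recall / (precision + recall)


def confidence_stratified_metrics(labels, predicted_probabilities, tiers,
                                  threshold: float = 0.5) -> dict:
    """Metrics recomputed on {all}, {medium, high} and {high} tier subsets."""
    labels = list(labels)
    probs = np.asarray(predicted_probabilities, dtype=float)
    tiers = np.asarray(list(tiers))
    subsets = {
        "all": np.ones(len(labels), dtype=bool),
        "medium+high": np.isin(tiers, ["medium", "high"]),
        "high": tiers == "high",
    }
    out = {}
    for name, mask in subsets.items():
        sub_labels = [s for s, m in zip(labels, mask) if m]
        if not sub_labels:
            out[name] = {"n": 0, "tp": 0, "fp": 0, "fn": 0,
                         "precision": None, "recall": None, "f1": None}
            continue
        out[name] = precision_recall_f1(sub_labels, probs[mask], threshold)
    return out


def class_success_table(episode_classes, statuses) -> pd.DataFrame:
    """Treatment likelihood and average success rate by drug class.

    Likelihood = share of all episodes; success rate = successes among
    non-excluded episodes of the class (``None`` when every episode of a
    class is excluded).  Sorted by likelihood descending.
    """
    df = pd.DataFrame({"class": list(episode_classes),
                       "status": list(statuses)})
    n = len(df)
    rows = []
    for cls, grp in df.groupby("class"):
        non_exc = grp[grp["status"] != "excluded"]
        rate = (100.0 * (non_exc["status"] == "success").mean()
                if len(non_exc) else None)
        rows.append({"class": cls,
                     "likelihood_pct": 100.0 * len(grp) / n,
                     "success_rate_pct": rate,
                     "n_episodes": len(grp)})
    out = pd.DataFrame(rows).sort_values(
        ["likelihood_pct", "class"], ascending=[False, True]).reset_index(drop=True)
    return out


def class_menu(cls: str):
    """Within-class candidate treatments with prescription weights."""
    ids, weights = CLASS_OPTIONS[cls]
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    return [(CANDIDATE_TREATMENTS[i], float(wi)) for i, wi in zip(ids, w)]


def class_level_prediction(ensemble, patient: dict, cls: str) -> dict:
    """Prescription-weighted class score with aggregated percentile bands."""
    from .model import featurize
    menu = class_menu(cls)
    X = np.vstack([featurize(patient, t.components) for t, _ in menu])
    bands = ensemble.predict_bands(X)
    w = np.asarray([wi for _, wi in menu])
    return {stat: float(np.sum(w * bands[stat].to_numpy()))
            for stat in ("median", "p10", "p25", "p75", "p90")}


def success_curves(ensemble, reference_patient: dict, sweep_variable: str,
                   grid, classes=None, top_k: int = 3) -> pd.DataFrame:
    """Success probability vs age or pre-treatment SBP per drug class.

    For each grid point and each of the top-``top_k`` classes (ranked by
    class score at the reference point), the prescription-weighted class
    median and 10/25/75/90 percentile bands.  Tidy frame: one row per
    (class, grid point).
    """
    var = {"age": "age", "SBP": "sbp_pre"}.get(sweep_variable)
    if var is None:
        raise ValueError(f"sweep_variable must be 'age' or 'SBP', got {sweep_variable!r}")
    grid = list(grid)
    if not grid:
        raise ValueError("empty sweep grid")
    candidates = list(classes) if classes is not None else list(REPORTED_CLASSES)
    ref_scores = {cls: class_level_prediction(ensemble, reference_patient, cls)["median"]
                  for cls in candidates}
    top = sorted(candidates, key=lambda c: -ref_scores[c])[:top_k]
    rows = []
    for cls in top:
        for value in grid:
            patient = dict(reference_patient)
            patient[var] = float(value)
            pred = class_level_prediction(ensemble, patient, cls)
            rows.append({"class": cls, sweep_variable: float(value), **pred})
    return pd.DataFrame(rows)


@dataclass
class EvaluationReport:
    """Validation-set report: overall and confidence-stratified metrics,
    class table and guideline agreement."""

    n_cases: int
    precision: float | None
    recall: float | None
    f1: float | None
    stratified: dict = field(default_factory=dict)
    class_table: pd.DataFrame | None = None
    agreement: dict = field(default_factory=dict)

    def summary_lines(self) -> list[str]:
        def fmt(v):
            return "undefined" if v is None else f"{pct(v):.1f}%"
        lines = [f"validation cases: {self.n_cases}",
                 f"precision {fmt(self.precision)}, recall {fmt(self.recall)}, "
                 f"F1 {fmt(self.f1)}"]
        for tier, m in self.stratified.items():
            lines.append(f"  [{tier}] n={m['n']} precision {fmt(m['precision'])}, "
                         f"recall {fmt(m['recall'])}, F1 {fmt(m['f1'])}")
        for method, v in self.agreement.items():
            lines.append(f"guideline agreement ({method}): {v:.1f}%")
        return lines
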