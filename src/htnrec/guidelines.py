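"""JNC 8 first-line drug-class recommendation engine and agreement metric.

The encoded rules: patients with chronic kidney disease start on an ACE
inhibitor or ARB; Black patients without CKD start on a thiazide or
calcium channel blocker; everyone else may start on any of ACEi, ARB,
thiazide or CCB.  Single or combination agents are allowed: a
combination is permitted when every component class is permitted, except
under the CKD rule, where a combination containing at least one of
{ACEi, ARB} qualifies.  CKD takes precedence over race when both apply.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "GuidelineRecommendation",
    "jnc8_recommended_classes",
    "class_permitted",
    "agreement_rate",
    "FIRST_LINE_CLASSES",
]

FIRST_LINE_CLASSES = frozenset({"ACEi", "ARB", "thiazide", "CCB"})
_CKD_CLASSES = frozenset({"ACEi", "ARB"})
_BLACK_CLASSES = frozenset({"thiazide", "CCB"})


@dataclass(frozen=True)
class GuidelineRecommendation:
    patient_id: int
    permitted_classes: frozenset
    rule_fired: str  # ckd | black | general


def jnc8_recommended_classes(patient: dict) -> GuidelineRecommendation:
    """Permitted first-line classes for one patient.

    ``patient`` needs ``race`` and ``chronic_kidney_disease`` (plus an
    optional ``patient_id``).
    """
    pid = int(patient.get("patient_id", -1))
    if patient["chronic_kidney_disease"]:
        return GuidelineRecommendation(pid, _CKD_CLASSES, "ckd")
    if patient["race"] == "Black":
        return GuidelineRecommendation(pid, _BLACK_CLASSES, "black")
    return GuidelineRecommendation(pid, FIRST_LINE_CLASSES, "general")


def class_permitted(class_label: str, rec: GuidelineRecommendation) -> bool:
    """Whether a (possibly combination) class label satisfies the rule.

    Component classes are read from the '+'-joined label.  General/Black
    rules require every component permitted; the CKD rule accepts any
    combination containing an ACEi or ARB.
    """
    components = set(class_label.split("+"))
    if rec.rule_fired == "ckd" and len(components) > 1:
        return bool(components & _CKD_CLASSES)
    return components <= rec.permitted_classes


def agreement_rate(top_classes: dict, recommendations: dict) -> float:
    """Percentage of patients whose top model class lies in the JNC 8
    permitted set; reported to one decimal.

    Patients missing a prediction are dropped from the denominator.
    """
    import logging
    n = 0
    agree = 0
    for pid, rec in recommendations.items():
        cls = top_classes.get(pid)
        if cls is None:
            logging.getLogger(__name__).warning(
                "patient %s has no top class; dropped from agreement", pid)
            continue
        n += 1
        agree += class_permitted(cls, rec)
    if n == 0:
        raise ValueError("no patients with both a prediction and a recommendation")
    return round(100.0 * agree / n, 1)
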