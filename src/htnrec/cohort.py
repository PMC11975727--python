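"""Cohort construction: measurement filters, inclusion/exclusion, split.

The analyzable cohort is every newly diagnosed primary-hypertension
patient with established care before diagnosis, antihypertensive
treatment within 9 months (270 days) of diagnosis, at least one year of
follow-up after treatment start, baseline blood-pressure and creatinine
measurements in the year before treatment, and a determinable outcome.
Exclusions: a new diabetes/prediabetes diagnosis within a year of
treatment start, and initial regimens containing an (ingredient, daily
dose) pair observed fewer than twice cohort-wide (iterated to a fixed
point, since removals can create new rare pairs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import medication

__all__ = [
    "filter_bp_measurements",
    "filter_vitals",
    "apply_inclusion",
    "apply_exclusions",
    "split_train_validation",
    "EligibilityRecord",
    "TREATMENT_WINDOW_DAYS",
    "FOLLOWUP_DAYS",
    "BASELINE_WINDOW_DAYS",
]

TREATMENT_WINDOW_DAYS = 270   # "within 9 months of hypertension diagnosis"
FOLLOWUP_DAYS = 365           # "at least 1 year of follow-up post-treatment"
BASELINE_WINDOW_DAYS = 365    # baseline BP/creatinine lookback

PRIMARY_HTN_CODE = "I10"
DIABETES_CODE_PREFIXES = ("E11", "R73")  # type II diabetes, prediabetes

#: inclusion criteria in evaluation order
INCLUSION_CRITERIA = (
    "primary_htn_dx",
    "established_care",
    "treatment_within_9_months",
    "followup_1_year",
    "baseline_bp",
    "baseline_creatinine",
    "outcome_measurable",
)


@dataclass
class EligibilityRecord:
    patient_id: int
    included: bool
    failed_criteria: list = field(default_factory=list)
    dx_date: pd.Timestamp | None = None
    treatment_start: pd.Timestamp | None = None


def _valid_vital_mask(vitals: pd.DataFrame) -> pd.Series:
    """Ambulatory, non-invasive, sitting, arm measurements only.

    Invasive readings, those recorded during exercise/operation/
    anesthesia/dialysis, positions other than sitting, body sites other
    than the arm, and anything during hospitalization are dropped.
    """
    return (
        (vitals["context"] == "ambulatory")
        & (vitals["position"] == "sitting")
        & (vitals["body_site"] == "arm")
        & (vitals["invasive_flag"].astype(int) == 0)
    )


def filter_vitals(vitals: pd.DataFrame, kinds=("SBP", "DBP")) -> pd.DataFrame:
    mask = vitals["kind"].isin(kinds) & _valid_vital_mask(vitals)
    return vitals[mask]


def filter_bp_measurements(vitals: pd.DataFrame) -> pd.DataFrame:
    """Valid ambulatory SBP/DBP rows (see :func:`filter_vitals`)."""
    return filter_vitals(vitals, kinds=("SBP", "DBP"))


def age_at(birth_date: pd.Timestamp, date: pd.Timestamp) -> float:
    return (date - birth_date).days / 365.25


def apply_inclusion(bundle, episodes=None) -> list[EligibilityRecord]:
    """Classify every patient against the inclusion criteria.

    All failed criteria are recorded, not just the first.  ``episodes``
    may be precomputed via :func:`htnrec.medication.episodes_for_bundle`.
    """
    from . import outcomes  # local import: outcomes uses our BP filter

    if episodes is None:
        episodes, _ = medication.episodes_for_bundle(bundle)
    ctx = outcomes.LabelerContext(bundle)

    dx = bundle.diagnoses
    htn_dx = (dx[dx["code"] == PRIMARY_HTN_CODE]
              .groupby("patient_id")["date"].min())

    valid_bp = filter_bp_measurements(bundle.vitals)
    bp_by_pid = dict(tuple(valid_bp.groupby("patient_id"))) if len(valid_bp) else {}
    creat = bundle.labs[bundle.labs["analyte"] == "creatinine"]
    creat_by_pid = dict(tuple(creat.groupby("patient_id"))) if len(creat) else {}

    # earliest and latest record of any type, per patient
    stamps = []
    for name, df in bundle.tables().items():
        if name == "patients" or df.empty:
            continue
        col = "start_date" if name == "medications" else "date"
        stamps.append(df[["patient_id", col]].rename(columns={col: "date"}))
    all_dates = pd.concat(stamps) if stamps else pd.DataFrame(columns=["patient_id", "date"])
    first_rec = all_dates.groupby("patient_id")["date"].min()
    last_rec = all_dates.groupby("patient_id")["date"].max()

    records = []
    for patient in bundle.patients.itertuples():
        pid = patient.patient_id
        failed = []
        dx_date = htn_dx.get(pid)
        ep = episodes.get(pid)
        start = ep.start if ep is not None else None

        if dx_date is None:
            failed.append("primary_htn_dx")
        if dx_date is not None and not (
                pid in first_rec.index and first_rec[pid] < dx_date):
            failed.append("established_care")
        if ep is None or dx_date is None or \
                (start - dx_date).days > TREATMENT_WINDOW_DAYS or start < dx_date:
            failed.append("treatment_within_9_months")
        if start is not None:
            if pid not in last_rec.index or \
                    (last_rec[pid] - start).days < FOLLOWUP_DAYS:
                failed.append("followup_1_year")
            lo = start - pd.Timedelta(days=BASELINE_WINDOW_DAYS)
            bp = bp_by_pid.get(pid)
            if bp is None or not ((bp["date"] >= lo) & (bp["date"] < start)).any():
                failed.append("baseline_bp")
            cr = creat_by_pid.get(pid)
            if cr is None or not ((cr["date"] >= lo) & (cr["date"] < start)).any():
                failed.append("baseline_creatinine")
            if ep is not None and not ctx.measurable(ep):
                failed.append("outcome_measurable")
        records.append(EligibilityRecord(
            patient_id=pid, included=not failed, failed_criteria=failed,
            dx_date=dx_date, treatment_start=start))
    return records


def apply_exclusions(records: list[EligibilityRecord], bundle,
                     episodes=None) -> list[EligibilityRecord]:
    """Apply the exclusion criteria to already-included records, in place.

    New diabetes/prediabetes within 365 days of treatment start, and the
    rare (ingredient, daily dose) pair filter iterated to a fixed point.
    """
    if episodes is None:
        episodes, _ = medication.episodes_for_bundle(bundle)

    # a *new* diagnosis: the first diabetes (or, separately, prediabetes)
    # code falls inside the post-treatment year
    dx = bundle.diagnoses
    firsts = []
    for prefix in DIABETES_CODE_PREFIXES:
        sub = dx[dx["code"].str.startswith(prefix)]
        firsts.append(sub.groupby("patient_id")["date"].min())

    for rec in records:
        if not rec.included or rec.treatment_start is None:
            continue
        for first in firsts:
            d = first.get(rec.patient_id)
            if d is not None and rec.treatment_start < d <= \
                    rec.treatment_start + pd.Timedelta(days=365):
                rec.included = False
                rec.failed_criteria.append("new_diabetes")
                break

    # rare-pair fixed point: a retained episode may not contain a component
    # pair observed fewer than twice among retained episodes
    while True:
        active = [r for r in records if r.included and r.patient_id in episodes]
        counts: dict[tuple, int] = {}
        for r in active:
            for comp in episodes[r.patient_id].components:
                counts[comp] = counts.get(comp, 0) + 1
        changed = False
        for r in active:
            if any(counts[c] < 2 for c in episodes[r.patient_id].components):
                r.included = False
                r.failed_criteria.append("rare_pair")
                changed = True
        if not changed:
            break
    return records


def eligibility_frame(records: list[EligibilityRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in records],
        "included": [r.included for r in records],
        "failed_criteria": [";".join(r.failed_criteria) for r in records],
        "dx_date": [r.dx_date for r in records],
        "treatment_start": [r.treatment_start for r in records],
    })


def split_train_validation(included_ids, n_validation: int, seed: int):
    """Disjoint, exhaustive, seed-reproducible train/validation split."""
    ids = sorted(included_ids)
    if n_validation >= len(ids):
        raise ValueError(
            f"n_validation={n_validation} must be smaller than cohort size {len(ids)}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    ids = np.asarray(ids)
    validation = set(ids[perm[:n_validation]].tolist())
    train = set(ids[perm[n_validation:]].tolist())
    return train, validation
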