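"""Rule-based treatment-success labeling.

Success = blood pressure controlled per JNC 8 age-dependent goals over
the selected outcome window AND no moderate/severe adverse effect, with
the initial regimen maintained for at least one year.  Episodes
discontinued before one year are failures when pre-discontinuation
pressures were high and excluded (outcome unknowable) when controlled.

Window logic: outcome pressures come from 6-12 months after treatment
start; when that window is empty and the regimen is maintained, the
earliest non-empty of 12-14, 14-18 and 18-24 months is used; for
episodes ending before one year, readings at least 14 days after start
and at least 6 months before the episode end are used.

The public operations take the bundle's DataFrames; internally the
labeler runs on per-patient integer-day arrays so labeling a cohort
stays linear and fast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cohort import filter_vitals, age_at

__all__ = [
    "BPThresholds",
    "OutcomeLabel",
    "bp_thresholds",
    "select_bp_window",
    "bp_control_outcome",
    "bp_failure_reason",
    "adverse_effect_failure",
    "label_treatment",
    "label_cohort",
    "LabelerContext",
    "outcome_measurable",
]


# month m -> days, using the mean Gregorian month length
def _months(m: float) -> int:
    return round(30.4375 * m)


PRIMARY_WINDOW = ("6-12m", _months(6), 365)
FALLBACK_WINDOWS = (
    ("12-14m", 365, _months(14)),
    ("14-18m", _months(14), _months(18)),
    ("18-24m", _months(18), _months(24)),
)

#: fixed tie-break order when adverse-effect criteria fire on the same day
AE_CRITERIA_ORDER = (
    "hypotension", "bradycardia", "creatinine_rise",
    "natremia", "kalemia", "glucose", "documented_ae",
)

_LAB_LIMITS = {
    # analyte -> (low, high); outside (low, high) fires
    "sodium": (130.0, 150.0),
    "potassium": (3.6, 5.1),
}


@dataclass(frozen=True)
class BPThresholds:
    """JNC 8-based control limits (mm Hg): average goals and never-exceed caps."""

    avg_sbp_limit: float
    avg_dbp_limit: float
    max_sbp_limit: float
    max_dbp_limit: float


@dataclass(frozen=True)
class OutcomeLabel:
    patient_id: int
    status: str                 # success | failure | excluded
    failure_reason: str | None
    bp_window_used: str         # 6-12m | 12-14m | 14-18m | 18-24m | discontinuation
    n_bp_readings: int


def bp_thresholds(age_years: float) -> BPThresholds:
    """Age-dependent goals: <60 years avg <140/90, never >160/90;
    60 and above avg <150/90, never >170/90 (age 60 exactly falls in the
    older branch, matching the JNC 8 cutoff)."""
    if age_years < 60:
        return BPThresholds(140.0, 90.0, 160.0, 90.0)
    return BPThresholds(150.0, 90.0, 170.0, 90.0)


def _to_day(ts) -> int:
    return int(np.datetime64(ts, "D").astype(int))


def _episode_days(episode) -> tuple[int, int | None]:
    start = _to_day(episode.start)
    end = None if episode.end is None else _to_day(episode.end)
    return start, end


def _persisted_one_year(start: int, end: int | None) -> bool:
    return end is None or end - start >= 365


# ---------------------------------------------------------------------------
# array core

def _select_window_mask(day: np.ndarray, start: int, end: int | None):
    """Window id + boolean mask over BP rows given integer days."""
    rel = day - start
    if _persisted_one_year(start, end):
        name, lo, hi = PRIMARY_WINDOW
        mask = (rel >= lo) & (rel <= hi)
        if mask.any():
            return name, mask
        for name, lo, hi in FALLBACK_WINDOWS:
            if end is not None and end - start < hi:
                continue  # regimen not maintained through this window
            mask = (rel > lo) & (rel <= hi)
            if mask.any():
                return name, mask
        return PRIMARY_WINDOW[0], np.zeros(len(day), dtype=bool)
    mask = (rel >= 14) & (day <= end - _months(6))
    return "discontinuation", mask


def _bp_reason_arrays(sbp: np.ndarray, dbp: np.ndarray, thr: BPThresholds):
    if len(sbp) + len(dbp) == 0:
        return None
    if (len(sbp) and (sbp > thr.max_sbp_limit).any()) or \
            (len(dbp) and (dbp > thr.max_dbp_limit).any()):
        return "bp_threshold"
    if (len(sbp) and sbp.mean() >= thr.avg_sbp_limit) or \
            (len(dbp) and dbp.mean() >= thr.avg_dbp_limit):
        return "bp_average"
    return None


def _first_ae(pdata, baseline_creatinine: float, start: int, end: int | None,
              codes: frozenset):
    """Earliest fired adverse-effect criterion; ties broken in fixed order."""
    events = []

    def window(day):
        ok = day > start
        if end is not None:
            ok &= day <= end
        return ok

    w = window(pdata.bp_day)
    hypo = w & ((pdata.bp_is_sbp & (pdata.bp_val < 90))
                | (~pdata.bp_is_sbp & (pdata.bp_val < 60)))
    if hypo.any():
        events.append((pdata.bp_day[hypo].min(), 0, "hypotension"))
    w = window(pdata.hr_day)
    brady = w & (pdata.hr_val < 50)
    if brady.any():
        events.append((pdata.hr_day[brady].min(), 1, "bradycardia"))

    w = window(pdata.lab_day)
    fired = {
        "creatinine_rise": (2, w & (pdata.lab_analyte == "creatinine")
                            & (pdata.lab_val > 1.3 * baseline_creatinine)),
        "natremia": (3, w & (pdata.lab_analyte == "sodium")
                     & ((pdata.lab_val < _LAB_LIMITS["sodium"][0])
                        | (pdata.lab_val > _LAB_LIMITS["sodium"][1]))),
        "kalemia": (4, w & (pdata.lab_analyte == "potassium")
                    & ((pdata.lab_val < _LAB_LIMITS["potassium"][0])
                       | (pdata.lab_val > _LAB_LIMITS["potassium"][1]))),
        "glucose": (5, w & (pdata.lab_analyte == "glucose_fasting")
                    & (pdata.lab_val > 120.0)),
    }
    for reason, (order, mask) in fired.items():
        if mask.any():
            events.append((pdata.lab_day[mask].min(), order, reason))

    w = window(pdata.al_day)
    doc = w & pdata.al_modsev & np.isin(pdata.al_code, list(codes))
    if doc.any():
        events.append((pdata.al_day[doc].min(), 6, "documented_ae"))

    if not events:
        return None
    day, _, reason = min(events)
    return reason, day


@dataclass
class _PatientData:
    """Filtered per-patient measurements as integer-day arrays."""

    bp_day: np.ndarray
    bp_is_sbp: np.ndarray
    bp_val: np.ndarray
    hr_day: np.ndarray
    hr_val: np.ndarray
    lab_day: np.ndarray
    lab_analyte: np.ndarray
    lab_val: np.ndarray
    al_day: np.ndarray
    al_modsev: np.ndarray
    al_code: np.ndarray


_EMPTY_I = np.empty(0, dtype=np.int64)
_EMPTY_F = np.empty(0, dtype=float)
_EMPTY_B = np.empty(0, dtype=bool)
_EMPTY_O = np.empty(0, dtype=object)

_EMPTY_PATIENT = _PatientData(_EMPTY_I, _EMPTY_B, _EMPTY_F, _EMPTY_I, _EMPTY_F,
                              _EMPTY_I, _EMPTY_O, _EMPTY_F, _EMPTY_I, _EMPTY_B,
                              _EMPTY_I)


def _split_by_pid(pids: np.ndarray, *cols):
    """dict pid -> tuple of column slices, via a single sort."""
    order = np.argsort(pids, kind="stable")
    pids = pids[order]
    cols = [c[order] for c in cols]
    out = {}
    if len(pids) == 0:
        return out
    uniq, starts = np.unique(pids, return_index=True)
    bounds = np.append(starts, len(pids))
    for i, pid in enumerate(uniq):
        sl = slice(bounds[i], bounds[i + 1])
        out[int(pid)] = tuple(c[sl] for c in cols)
    return out


class LabelerContext:
    """Per-cohort precomputation so labeling stays linear in patients."""

    def __init__(self, bundle):
        valid = filter_vitals(bundle.vitals, kinds=("SBP", "DBP", "HR"))
        bp = valid[valid["kind"].isin(["SBP", "DBP"])]
        hr = valid[valid["kind"] == "HR"]
        self._bp = _split_by_pid(
            bp["patient_id"].to_numpy(),
            bp["date"].to_numpy().astype("datetime64[D]").astype(np.int64),
            (bp["kind"] == "SBP").to_numpy(),
            bp["value"].to_numpy(dtype=float))
        self._hr = _split_by_pid(
            hr["patient_id"].to_numpy(),
            hr["date"].to_numpy().astype("datetime64[D]").astype(np.int64),
            hr["value"].to_numpy(dtype=float))
        labs = bundle.labs
        self._labs = _split_by_pid(
            labs["patient_id"].to_numpy(),
            labs["date"].to_numpy().astype("datetime64[D]").astype(np.int64),
            labs["analyte"].to_numpy(dtype=object),
            labs["value"].to_numpy(dtype=float))
        al = bundle.allergies
        self._al = _split_by_pid(
            al["patient_id"].to_numpy(),
            al["date"].to_numpy().astype("datetime64[D]").astype(np.int64),
            al["severity"].isin(["moderate", "severe"]).to_numpy(),
            al["medication_code"].to_numpy(dtype=np.int64))
        self._birth = bundle.patients.set_index("patient_id")["birth_date"]

    def patient_data(self, pid: int) -> _PatientData:
        bp = self._bp.get(pid, (_EMPTY_I, _EMPTY_B, _EMPTY_F))
        hr = self._hr.get(pid, (_EMPTY_I, _EMPTY_F))
        lb = self._labs.get(pid, (_EMPTY_I, _EMPTY_O, _EMPTY_F))
        al = self._al.get(pid, (_EMPTY_I, _EMPTY_B, _EMPTY_I))
        return _PatientData(*bp, *hr, *lb, *al)

    def baseline_creatinine(self, pid: int, start_day: int) -> float | None:
        day, analyte, val = self._labs.get(pid, (_EMPTY_I, _EMPTY_O, _EMPTY_F))
        mask = (analyte == "creatinine") & (day < start_day)
        if not mask.any():
            return None
        return float(val[mask][np.argmax(day[mask])])

    def age_at_start(self, pid: int, start) -> float:
        return age_at(self._birth[pid], start)

    def label(self, episode) -> OutcomeLabel:
        pid = episode.patient_id
        start, end = _episode_days(episode)
        pdata = self.patient_data(pid)
        window_id, mask = _select_window_mask(pdata.bp_day, start, end)
        n = int(mask.sum())

        base_cr = self.baseline_creatinine(pid, start)
        ae = None
        if base_cr is not None:
            ae = _first_ae(pdata, base_cr, start, end, episode.codes)
        if ae is not None:
            return OutcomeLabel(pid, "failure", ae[0], window_id, n)
        if n == 0:
            return OutcomeLabel(pid, "excluded", None, window_id, 0)

        thr = bp_thresholds(self.age_at_start(pid, episode.start))
        sbp = pdata.bp_val[mask & pdata.bp_is_sbp]
        dbp = pdata.bp_val[mask & ~pdata.bp_is_sbp]
        reason = _bp_reason_arrays(sbp, dbp, thr)
        if reason is not None:
            return OutcomeLabel(pid, "failure", reason, window_id, n)
        if _persisted_one_year(start, end):
            return OutcomeLabel(pid, "success", None, window_id, n)
        # discontinued with controlled pressures: year-long success unknowable
        return OutcomeLabel(pid, "excluded", None, window_id, n)

    def measurable(self, episode) -> bool:
        """An outcome is determinable when an adverse-effect criterion fires
        or the selected BP window holds at least one reading."""
        pid = episode.patient_id
        start, end = _episode_days(episode)
        pdata = self.patient_data(pid)
        base_cr = self.baseline_creatinine(pid, start)
        if base_cr is not None and \
                _first_ae(pdata, base_cr, start, end, episode.codes) is not None:
            return True
        _, mask = _select_window_mask(pdata.bp_day, start, end)
        return bool(mask.any())


# ---------------------------------------------------------------------------
# DataFrame-facing operations

def select_bp_window(measurements: pd.DataFrame, episode) -> tuple[str, pd.DataFrame]:
    """Pick the outcome BP readings for an episode.

    ``measurements`` must already be filtered to valid ambulatory SBP/DBP
    rows for this patient.  Returns ``(window_id, readings)``; empty
    readings signal an indeterminate outcome, never success.
    """
    start, end = _episode_days(episode)
    day = measurements["date"].to_numpy().astype("datetime64[D]").astype(np.int64) \
        if len(measurements) else _EMPTY_I
    window_id, mask = _select_window_mask(day, start, end)
    return window_id, measurements[mask] if len(measurements) else measurements


def bp_control_outcome(readings: pd.DataFrame, thresholds: BPThresholds) -> bool:
    """Controlled iff mean SBP/DBP are strictly below the average goals and
    no single reading exceeds the never-exceed caps.  Zero readings are
    indeterminate and return False (never success)."""
    return len(readings) > 0 and bp_failure_reason(readings, thresholds) is None


def bp_failure_reason(readings: pd.DataFrame, thresholds: BPThresholds) -> str | None:
    """``bp_threshold`` when any reading exceeds a cap, else ``bp_average``
    when a mean misses its goal, else None (controlled)."""
    sbp = readings.loc[readings["kind"] == "SBP", "value"].to_numpy(dtype=float)
    dbp = readings.loc[readings["kind"] == "DBP", "value"].to_numpy(dtype=float)
    return _bp_reason_arrays(sbp, dbp, thresholds)


def adverse_effect_failure(labs: pd.DataFrame, vitals: pd.DataFrame,
                           allergies: pd.DataFrame, baseline_creatinine: float,
                           episode) -> tuple[str, pd.Timestamp] | None:
    """First adverse-effect failure criterion fired within the episode.

    Criteria: hypotension (<90 systolic or <60 diastolic), bradycardia
    (HR <50), creatinine rise >30% over baseline, sodium outside
    [130, 150], potassium outside [3.6, 5.1], fasting glucose >120, or a
    documented moderate/severe adverse effect to an episode medication.
    Mild documented effects never count.  ``vitals`` must already be
    filtered to valid ambulatory rows (SBP/DBP/HR).
    """
    bp = vitals[vitals["kind"].isin(["SBP", "DBP"])]
    hr = vitals[vitals["kind"] == "HR"]

    def days(df, col="date"):
        return df[col].to_numpy().astype("datetime64[D]").astype(np.int64) \
            if len(df) else _EMPTY_I

    pdata = _PatientData(
        bp_day=days(bp), bp_is_sbp=(bp["kind"] == "SBP").to_numpy(),
        bp_val=bp["value"].to_numpy(dtype=float),
        hr_day=days(hr), hr_val=hr["value"].to_numpy(dtype=float),
        lab_day=days(labs), lab_analyte=labs["analyte"].to_numpy(dtype=object),
        lab_val=labs["value"].to_numpy(dtype=float),
        al_day=days(allergies),
        al_modsev=allergies["severity"].isin(["moderate", "severe"]).to_numpy(),
        al_code=allergies["medication_code"].to_numpy(dtype=np.int64)
        if len(allergies) else _EMPTY_I)
    start, end = _episode_days(episode)
    hit = _first_ae(pdata, baseline_creatinine, start, end, episode.codes)
    if hit is None:
        return None
    reason, day = hit
    return reason, pd.Timestamp(np.datetime64(int(day), "D"))


def label_treatment(episode, ctx: LabelerContext) -> OutcomeLabel:
    """One label per episode.

    Any adverse-effect criterion firing is a failure regardless of blood
    pressure.  Otherwise the selected window decides: no readings ->
    excluded (indeterminate); uncontrolled -> failure; controlled ->
    success when the regimen persisted >= 1 year, excluded when it was
    discontinued earlier (year-long success unknowable).
    """
    return ctx.label(episode)


def outcome_measurable(bundle, episode) -> bool:
    return LabelerContext(bundle).measurable(episode)


def label_cohort(bundle, episodes: dict) -> pd.DataFrame:
    """Label every episode; returns one row per patient."""
    ctx = LabelerContext(bundle)
    rows = [ctx.label(ep) for _, ep in sorted(episodes.items())]
    return pd.DataFrame({
        "patient_id": [r.patient_id for r in rows],
        "status": [r.status for r in rows],
        "failure_reason": [r.failure_reason for r in rows],
        "bp_window_used": [r.bp_window_used for r in rows],
        "n_bp_readings": [r.n_bp_readings for r in rows],
    })
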