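"""Medication normalization: drug-class mapping, sig parsing, timelines.

Treatments are handled at ingredient + total-daily-dose resolution so a
combination product and the equivalent separate pills define the same
treatment (the "consistency" condition of the causal analysis).  A
packaged RxNorm-style table maps prescription codes to ingredients and
antihypertensive drug classes; free-text prescription instructions
("take 2 pills 3 times a day") are parsed against a closed grammar to
compute daily dose in mg.
"""

from __future__ import annotations

import importlib.resources
import logging
import re
from dataclasses import dataclass, field
from functools import lru_cache

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "DRUG_CLASSES",
    "load_class_table",
    "map_to_class",
    "parse_sig",
    "build_timeline",
    "initial_treatment",
    "episodes_for_bundle",
    "class_label",
    "IngredientDoseInterval",
    "TreatmentEpisode",
    "SigParseError",
    "UnmappedCodeError",
]

#: single-agent drug classes; combinations are labeled by joining the sorted
#: component classes with "+" (e.g. "ACEi+thiazide").
DRUG_CLASSES = ("ACEi", "ARB", "CCB", "beta-blocker", "other", "thiazide")

#: grace window (days) for grouping near-simultaneous starts into one
#: initial regimen; the analysis unit is the first regimen.
GRACE_DAYS = 14


class SigParseError(ValueError):
    """Prescription instruction outside the supported grammar."""

    def __init__(self, sig_text: str):
        self.sig_text = sig_text
        super().__init__(f"unparseable sig text: {sig_text!r}")


class UnmappedCodeError(KeyError):
    def __init__(self, code):
        self.code = code
        super().__init__(f"medication code {code!r} not in class mapping table")


@lru_cache(maxsize=1)
def load_class_table() -> pd.DataFrame:
    """Packaged code -> (ingredient, class, unit dose) mapping.

    Combination products occupy one row per ingredient, carrying that
    ingredient's per-unit dose within the product.
    """
    with importlib.resources.files("htnrec.data").joinpath("drug_classes.csv").open() as fh:
        df = pd.read_csv(fh)
    return df


@lru_cache(maxsize=1)
def _default_code_index() -> dict:
    idx: dict[int, list] = {}
    for r in load_class_table().itertuples():
        idx.setdefault(int(r.code), []).append(
            (r.ingredient, r.drug_class, float(r.unit_dose_mg)))
    return idx


def map_to_class(code: int, table: pd.DataFrame | None = None) -> list[tuple[str, str, float]]:
    """Map a medication code to ``[(ingredient, drug_class, unit_dose_mg), ...]``.

    Combination products return one entry per ingredient.  Unknown codes
    raise :class:`UnmappedCodeError`; callers that must not fail log the
    code instead (see :func:`build_timeline`).
    """
    if table is None:
        parts = _default_code_index().get(int(code))
        if not parts:
            raise UnmappedCodeError(code)
        return list(parts)
    rows = table[table["code"] == int(code)]
    if rows.empty:
        raise UnmappedCodeError(code)
    return [(r.ingredient, r.drug_class, float(r.unit_dose_mg))
            for r in rows.itertuples()]


_UNIT = r"(?:pill|pills|tablet|tablets|capsule|capsules)"
_SIG_PATTERNS = [
    # "take 2 pills 3 times a day"
    (re.compile(rf"^take\s+(\d+)\s+{_UNIT}\s+(\d+)\s+times\s+a\s+day$"),
     lambda m: int(m.group(1)) * int(m.group(2))),
    # "1 tablet daily" / "1 tablet once a day"
    (re.compile(rf"^(\d+)\s+{_UNIT}\s+(?:daily|once\s+a\s+day)$"),
     lambda m: int(m.group(1))),
    # "1 tablet every 12 hours"
    (re.compile(rf"^(\d+)\s+{_UNIT}\s+every\s+(\d+)\s+hours$"),
     lambda m: int(m.group(1)) * 24.0 / int(m.group(2))),
]


@lru_cache(maxsize=4096)
def _units_per_day(text: str) -> float | None:
    for pattern, units_per_day in _SIG_PATTERNS:
        m = pattern.match(text)
        if m:
            return float(units_per_day(m))
    return None


def parse_sig(sig_text: str, per_unit_dose_mg: float) -> float:
    """Daily dose in mg from a sig string and the per-unit dose.

    Supported grammar: ``take <n> <unit> <m> times a day`` |
    ``<n> <unit> daily|once a day`` | ``<n> <unit> every <h> hours``.
    Anything else raises :class:`SigParseError` so episodes are flagged
    rather than dosed by guesswork.
    """
    text = " ".join(str(sig_text).lower().split())
    per_day = _units_per_day(text)
    if per_day is None:
        raise SigParseError(sig_text)
    return float(per_unit_dose_mg) * per_day


@dataclass(frozen=True)
class IngredientDoseInterval:
    """One merged on-treatment interval at ingredient-daily-dose resolution."""

    patient_id: int
    ingredient: str
    drug_class: str
    daily_dose_mg: float
    start: pd.Timestamp
    end: pd.Timestamp | None  # None = open / still prescribed
    codes: frozenset = field(default_factory=frozenset)


def class_label(classes) -> str:
    """Deterministic label: sorted unique component classes joined with '+'."""
    return "+".join(sorted(set(classes)))


@dataclass(frozen=True)
class TreatmentEpisode:
    """A patient's initial regimen: set of (ingredient, daily dose) components."""

    patient_id: int
    components: frozenset  # of (ingredient, daily_dose_mg)
    drug_class_label: str
    start: pd.Timestamp
    end: pd.Timestamp | None  # earliest discontinuation of any component
    codes: frozenset = field(default_factory=frozenset)

    @property
    def duration_days(self) -> float:
        if self.end is None:
            return float("inf")
        return float((self.end - self.start).days)


def _merge_intervals(raws: list[tuple]) -> list[tuple]:
    """Merge overlapping or abutting (gap <= 1 day) [start, end] intervals."""
    raws = sorted(raws, key=lambda r: (r[0], pd.Timestamp.max if r[1] is None else r[1]))
    merged: list[list] = []
    for start, end, codes in raws:
        if merged:
            cur = merged[-1]
            cur_end = cur[1]
            if cur_end is None or start <= cur_end + pd.Timedelta(days=1):
                if cur_end is not None and (end is None or end > cur_end):
                    cur[1] = end
                cur[2] = cur[2] | codes
                continue
        merged.append([start, end, set(codes)])
    return [tuple(m) for m in merged]


def build_timeline(medications: pd.DataFrame,
                   table: pd.DataFrame | None = None,
                   ) -> tuple[list[IngredientDoseInterval], pd.DataFrame]:
    """Normalize prescription rows into merged ingredient-dose intervals.

    Returns ``(intervals, problems)`` where ``problems`` collects rows with
    unmapped codes or unparseable sigs (logged, never silently dropped).
    """
    table = load_class_table() if table is None else table
    buckets: dict[tuple, list] = {}
    problems = []
    for row in medications.itertuples():
        try:
            parts = map_to_class(row.code, table)
        except UnmappedCodeError:
            problems.append((row.Index, row.patient_id, row.code, "unmapped_code"))
            continue
        end = None if pd.isna(row.end_date) else row.end_date
        for ingredient, drug_class, unit_dose in parts:
            try:
                daily = parse_sig(row.sig_text, unit_dose)
            except SigParseError:
                problems.append((row.Index, row.patient_id, row.code, "unparseable_sig"))
                break
            if end is not None and end < row.start_date:
                raise ValueError(
                    f"medications row {row.Index}: end_date before start_date")
            key = (row.patient_id, ingredient, drug_class, daily)
            buckets.setdefault(key, []).append(
                (row.start_date, end, frozenset([int(row.code)])))
    problems_df = pd.DataFrame(
        problems, columns=["row", "patient_id", "code", "problem"])
    for _, pid, code, why in problems:
        logger.warning("medication row skipped (%s): patient %s code %s", why, pid, code)

    intervals = []
    for (pid, ingredient, drug_class, daily), raws in buckets.items():
        for start, end, codes in _merge_intervals(raws):
            intervals.append(IngredientDoseInterval(
                patient_id=pid, ingredient=ingredient, drug_class=drug_class,
                daily_dose_mg=daily, start=start, end=end,
                codes=frozenset(codes)))
    intervals.sort(key=lambda iv: (iv.patient_id, iv.start, iv.ingredient, iv.daily_dose_mg))
    return intervals, problems_df


def initial_treatment(intervals: list[IngredientDoseInterval],
                      grace_days: int = GRACE_DAYS) -> TreatmentEpisode | None:
    """The initial regimen: components starting within ``grace_days`` of the
    earliest antihypertensive start.  Returns None when untreated."""
    if not intervals:
        return None
    pid = intervals[0].patient_id
    t0 = min(iv.start for iv in intervals)
    cutoff = t0 + pd.Timedelta(days=grace_days)
    comp = [iv for iv in intervals if iv.start <= cutoff]
    # one interval per (ingredient, dose): the earliest-starting one
    chosen: dict[tuple, IngredientDoseInterval] = {}
    for iv in comp:
        key = (iv.ingredient, iv.daily_dose_mg)
        if key not in chosen or iv.start < chosen[key].start:
            chosen[key] = iv
    members = list(chosen.values())
    ends = [iv.end for iv in members]
    end = None if all(e is None for e in ends) else min(e for e in ends if e is not None)
    codes = frozenset().union(*[iv.codes for iv in members])
    return TreatmentEpisode(
        patient_id=pid,
        components=frozenset((iv.ingredient, iv.daily_dose_mg) for iv in members),
        drug_class_label=class_label(iv.drug_class for iv in members),
        start=t0, end=end, codes=codes)


def episodes_for_bundle(bundle, grace_days: int = GRACE_DAYS,
                        ) -> tuple[dict[int, TreatmentEpisode], pd.DataFrame]:
    """Initial treatment episode per patient (untreated patients absent)."""
    intervals, problems = build_timeline(bundle.medications)
    by_patient: dict[int, list] = {}
    for iv in intervals:
        by_patient.setdefault(iv.patient_id, []).append(iv)
    episodes = {}
    for pid, ivs in by_patient.items():
        ep = initial_treatment(ivs, grace_days=grace_days)
        if ep is not None:
            episodes[pid] = ep
    return episodes, problems
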