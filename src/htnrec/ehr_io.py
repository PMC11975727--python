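"""Read, validate and write the six-table EHR-style CSV bundle.

All pipeline stages exchange data through this bundle: patients,
diagnoses, ambulatory vitals, labs, medication prescriptions and
allergy/adverse-effect records, keyed by ``patient_id``.  Files are
plain UTF-8 CSV with a header row and ISO-8601 dates so fixtures stay
diffable and language-neutral.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, fields

import pandas as pd

__all__ = [
    "EHRBundle",
    "BundleValidationError",
    "read_bundle",
    "write_bundle",
    "TABLE_COLUMNS",
]

#: column contract per table (order is the canonical on-disk order)
TABLE_COLUMNS: dict[str, list[str]] = {
    "patients": ["patient_id", "birth_date", "sex", "race"],
    "diagnoses": ["patient_id", "code", "date", "setting"],
    "vitals": [
        "patient_id", "kind", "value", "date",
        "position", "body_site", "invasive_flag", "context",
    ],
    "labs": ["patient_id", "analyte", "value", "units", "date"],
    "medications": [
        "patient_id", "code", "name", "per_unit_dose_mg",
        "sig_text", "start_date", "end_date",
    ],
    "allergies": ["patient_id", "medication_code", "severity", "date"],
}

VITAL_KINDS = {"SBP", "DBP", "HR"}
VITAL_CONTEXTS = {"ambulatory", "hospital", "exercise", "operation", "anesthesia", "dialysis"}
LAB_ANALYTES = {"creatinine", "sodium", "potassium", "glucose_fasting"}
AE_SEVERITIES = {"mild", "moderate", "severe"}

_DATE_COLS = {
    "patients": ["birth_date"],
    "diagnoses": ["date"],
    "vitals": ["date"],
    "labs": ["date"],
    "medications": ["start_date", "end_date"],
    "allergies": ["date"],
}

_SORT_KEYS = {
    "patients": ["patient_id"],
    "diagnoses": ["patient_id", "date", "code"],
    "vitals": ["patient_id", "date", "kind", "value"],
    "labs": ["patient_id", "date", "analyte", "value"],
    "medications": ["patient_id", "start_date", "code", "per_unit_dose_mg"],
    "allergies": ["patient_id", "date", "medication_code"],
}


class BundleValidationError(ValueError):
    """A bundle invariant is violated; carries table and row index."""

    def __init__(self, table: str, row: int | None, message: str):
        self.table = table
        self.row = row
        where = f"{table}" + (f" row {row}" if row is not None else "")
        super().__init__(f"{where}: {message}")


@dataclass
class EHRBundle:
    """Container of the six linked EHR tables for one cohort."""

    patients: pd.DataFrame
    diagnoses: pd.DataFrame
    vitals: pd.DataFrame
    labs: pd.DataFrame
    medications: pd.DataFrame
    allergies: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def n_patients(self) -> int:
        return len(self.patients)

    def validate(self) -> None:
        """Raise :class:`BundleValidationError` on the first violated invariant."""
        for name, df in self.tables().items():
            missing = [c for c in TABLE_COLUMNS[name] if c not in df.columns]
            if missing:
                raise BundleValidationError(name, None, f"missing columns {missing}")

        known = set(self.patients["patient_id"])
        if len(known) != len(self.patients):
            raise BundleValidationError("patients", None, "duplicate patient_id")
        for name, df in self.tables().items():
            if name == "patients" or df.empty:
                continue
            orphan = ~df["patient_id"].isin(known)
            if orphan.any():
                raise BundleValidationError(name, int(df.index[orphan][0]),
                                            "patient_id not present in patients table")

        v = self.vitals
        if not v.empty:
            bad = ~v["kind"].isin(VITAL_KINDS)
            if bad.any():
                raise BundleValidationError("vitals", int(v.index[bad][0]),
                                            f"unknown vital kind {v.loc[v.index[bad][0], 'kind']!r}")
            bad = ~v["context"].isin(VITAL_CONTEXTS)
            if bad.any():
                raise BundleValidationError("vitals", int(v.index[bad][0]),
                                            f"unknown vital context {v.loc[v.index[bad][0], 'context']!r}")
            nonpos = v["value"] <= 0
            if nonpos.any():
                raise BundleValidationError("vitals", int(v.index[nonpos][0]),
                                            "non-positive vital value")
            # paired SBP/DBP at the same timestamp must satisfy SBP > DBP
            bp = v[v["kind"].isin(["SBP", "DBP"])]
            wide = bp.pivot_table(index=["patient_id", "date", "context"],
                                  columns="kind", values="value", aggfunc="first")
            if {"SBP", "DBP"} <= set(wide.columns):
                both = wide.dropna(subset=["SBP", "DBP"])
                viol = both[both["SBP"] <= both["DBP"]]
                if len(viol):
                    pid, date, _ = viol.index[0]
                    raise BundleValidationError(
                        "vitals", None,
                        f"SBP <= DBP for patient {pid} at {date.date()}")

        lb = self.labs
        if not lb.empty:
            bad = ~lb["analyte"].isin(LAB_ANALYTES)
            if bad.any():
                raise BundleValidationError("labs", int(lb.index[bad][0]),
                                            f"unknown analyte {lb.loc[lb.index[bad][0], 'analyte']!r}")

        al = self.allergies
        if not al.empty:
            bad = ~al["severity"].isin(AE_SEVERITIES)
            if bad.any():
                raise BundleValidationError("allergies", int(al.index[bad][0]),
                                            f"unknown severity {al.loc[al.index[bad][0], 'severity']!r}")

        md = self.medications
        if not md.empty:
            both = md["end_date"].notna()
            bad = both & (md["end_date"] < md["start_date"])
            if bad.any():
                raise BundleValidationError("medications", int(md.index[bad][0]),
                                            "end_date before start_date")

    def sorted_copy(self) -> "EHRBundle":
        """Deterministically ordered copy (canonical row and column order)."""
        out = {}
        for name, df in self.tables().items():
            cols = TABLE_COLUMNS[name]
            out[name] = (df[cols].sort_values(_SORT_KEYS[name], kind="mergesort")
                         .reset_index(drop=True))
        return EHRBundle(**out)


def _parse_dates(name: str, df: pd.DataFrame) -> pd.DataFrame:
    for col in _DATE_COLS[name]:
        try:
            df[col] = pd.to_datetime(df[col], format="ISO8601")
        except (ValueError, TypeError) as exc:
            raise BundleValidationError(name, None, f"unparseable date in {col}: {exc}") from exc
    return df


def read_bundle(directory: str | os.PathLike) -> EHRBundle:
    """Load and validate a bundle from ``<directory>/<table>.csv`` files."""
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        path = os.path.join(directory, f"{name}.csv")
        if not os.path.exists(path):
            raise FileNotFoundError(f"bundle table missing: {path}")
        df = pd.read_csv(path, dtype={"patient_id": "int64"})
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise BundleValidationError(name, None, f"missing columns {missing}")
        tables[name] = _parse_dates(name, df[cols])
    bundle = EHRBundle(**tables)
    bundle.validate()
    import logging
    logging.getLogger(__name__).info(
        "read bundle from %s: %s", directory,
        {name: len(df) for name, df in bundle.tables().items()})
    return bundle


def write_bundle(bundle: EHRBundle, directory: str | os.PathLike) -> list[str]:
    """Write the bundle as six CSVs with deterministic ordering; returns paths."""
    bundle.validate()
    os.makedirs(directory, exist_ok=True)
    canon = bundle.sorted_copy()
    written = []
    for name, df in canon.tables().items():
        df = df.copy()
        for col in _DATE_COLS[name]:
            df[col] = pd.to_datetime(df[col]).dt.strftime("%Y-%m-%d")
        path = os.path.join(directory, f"{name}.csv")
        df.to_csv(path, index=False, float_format="%.6f", lineterminator="\n")
        written.append(path)
    return written
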