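"""Shared fixtures: hand-built micro-bundles and a full-size synthetic run.

The session-scoped 20,000-patient run (generation, cohort construction,
labeling, ensemble training) is built once and shared by the tests that
score the pipeline's statistical behavior.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from htnrec import medication as med_mod
from htnrec import outcomes as out_mod
from htnrec import pipeline as pipe
from htnrec.config import GeneratorConfig, RunConfig
from htnrec.ehr_io import EHRBundle, TABLE_COLUMNS
from htnrec.synthetic import generate_cohort

#: fixed seed for the full-size statistical fixtures
FULL_SEED = 7
FULL_N = 20_000


def _date(s):
    return pd.Timestamp(s)


def empty_tables() -> dict:
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        tables[name] = pd.DataFrame({c: pd.Series(dtype="object") for c in cols})
    return tables


def make_bundle(patients=(), diagnoses=(), vitals=(), labs=(), medications=(),
                allergies=()) -> EHRBundle:
    """Build a small bundle from row tuples (see TABLE_COLUMNS for order)."""
    data = {
        "patients": patients, "diagnoses": diagnoses, "vitals": vitals,
        "labs": labs, "medications": medications, "allergies": allergies,
    }
    date_cols = {"patients": ["birth_date"], "diagnoses": ["date"],
                 "vitals": ["date"], "labs": ["date"],
                 "medications": ["start_date", "end_date"], "allergies": ["date"]}
    tables = {}
    for name, rows in data.items():
        cols = TABLE_COLUMNS[name]
        df = pd.DataFrame(list(rows), columns=cols)
        for c in date_cols[name]:
            df[c] = pd.to_datetime(df[c]) if len(df) else pd.Series(
                dtype="datetime64[ns]")
        tables[name] = df
    return EHRBundle(**tables)


def vital_row(pid, kind, value, date, position="sitting", site="arm",
              invasive=0, context="ambulatory"):
    return (pid, kind, value, date, position, site, invasive, context)


def make_episode(pid=1, components=(("lisinopril", 10.0),), start="2015-01-01",
                 end=None, codes=(100001,)):
    from htnrec.synthetic import INGREDIENT_CLASS

    comps = frozenset(components)
    label = med_mod.class_label(INGREDIENT_CLASS[i] for i, _ in comps)
    return med_mod.TreatmentEpisode(
        patient_id=pid, components=comps, drug_class_label=label,
        start=pd.Timestamp(start),
        end=None if end is None else pd.Timestamp(end),
        codes=frozenset(codes))


@pytest.fixture(scope="session")
def small_run():
    """A 1,500-patient cohort: bundle, truth, episodes, eligibility, labels."""
    cfg = GeneratorConfig(n_patients=1_500, seed=11)
    bundle, truth = generate_cohort(cfg)
    episodes, eligibility, train_ids, val_ids = pipe.build_cohort(
        bundle, n_validation=200, seed=11)
    included = set(eligibility.loc[eligibility["included"], "patient_id"])
    labels = out_mod.label_cohort(bundle, {p: episodes[p] for p in included})
    return {"bundle": bundle, "truth": truth, "episodes": episodes,
            "eligibility": eligibility, "labels": labels,
            "train_ids": train_ids, "val_ids": val_ids, "config": cfg}


@pytest.fixture(scope="session")
def full_run():
    """The full-size study-condition cohort (n=20,000, fixed seed)."""
    cfg = GeneratorConfig(n_patients=FULL_N, seed=FULL_SEED)
    bundle, truth = generate_cohort(cfg)
    episodes, eligibility, train_ids, val_ids = pipe.build_cohort(
        bundle, n_validation=1_000, seed=FULL_SEED)
    included = set(eligibility.loc[eligibility["included"], "patient_id"])
    labels = out_mod.label_cohort(bundle, {p: episodes[p] for p in included})
    return {"bundle": bundle, "truth": truth, "episodes": episodes,
            "eligibility": eligibility, "labels": labels,
            "train_ids": train_ids, "val_ids": val_ids, "config": cfg}


@pytest.fixture(scope="session")
def full_ensemble(full_run):
    """The 20-member ensemble trained on the full-size cohort."""
    cfg = RunConfig(seed=FULL_SEED)
    ensemble, features = pipe.train_model(
        full_run["bundle"], full_run["episodes"], full_run["labels"],
        full_run["train_ids"], cfg.model, FULL_SEED)
    return {"ensemble": ensemble, "features": features}
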