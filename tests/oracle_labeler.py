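"""Independent brute-force outcome labeler used as a test oracle.

Deliberately written as a literal, row-by-row walk of the clinical
rules, sharing no code with ``htnrec.outcomes``: plain Python loops over
record dicts, hand-written window arithmetic, explicit threshold
constants.  Interpretation conventions mirror the documented ones (day
counts for month boundaries, age-60 branch, AEs over the full episode).
"""

from __future__ import annotations

import pandas as pd


def _valid(row):
    return (row["context"] == "ambulatory" and row["position"] == "sitting"
            and row["body_site"] == "arm" and int(row["invasive_flag"]) == 0)


def oracle_label(bundle, episode):
    """Return (status, failure_reason, window_id, n_readings)."""
    pid = episode.patient_id
    start = episode.start
    end = episode.end

    vit = [r for r in bundle.vitals.to_dict("records")
           if r["patient_id"] == pid and _valid(r)]
    bp = [r for r in vit if r["kind"] in ("SBP", "DBP")]
    hr = [r for r in vit if r["kind"] == "HR"]
    labs = [r for r in bundle.labs.to_dict("records") if r["patient_id"] == pid]
    allergies = [r for r in bundle.allergies.to_dict("records")
                 if r["patient_id"] == pid]
    patient = bundle.patients.set_index("patient_id").loc[pid]

    # baseline creatinine: latest value strictly before treatment start
    pre_cr = sorted((r for r in labs
                     if r["analyte"] == "creatinine" and r["date"] < start),
                    key=lambda r: r["date"])
    baseline_cr = pre_cr[-1]["value"] if pre_cr else None

    def within_episode(d):
        return d > start and (end is None or d <= end)

    # ---- adverse-effect criteria, each walked separately ----
    events = []
    for r in bp:
        if within_episode(r["date"]):
            if r["kind"] == "SBP" and r["value"] < 90:
                events.append((r["date"], 0, "hypotension"))
            if r["kind"] == "DBP" and r["value"] < 60:
                events.append((r["date"], 0, "hypotension"))
    for r in hr:
        if within_episode(r["date"]) and r["value"] < 50:
            events.append((r["date"], 1, "bradycardia"))
    if baseline_cr is not None:
        for r in labs:
            if not within_episode(r["date"]):
                continue
            a, v = r["analyte"], r["value"]
            if a == "creatinine" and v > baseline_cr * 1.3:
                events.append((r["date"], 2, "creatinine_rise"))
            if a == "sodium" and (v < 130 or v > 150):
                events.append((r["date"], 3, "natremia"))
            if a == "potassium" and (v < 3.6 or v > 5.1):
                events.append((r["date"], 4, "kalemia"))
            if a == "glucose_fasting" and v > 120:
                events.append((r["date"], 5, "glucose"))
        for r in allergies:
            if within_episode(r["date"]) and r["severity"] in ("moderate", "severe") \
                    and r["medication_code"] in episode.codes:
                events.append((r["date"], 6, "documented_ae"))
    ae = min(events) if events else None

    # ---- outcome window ----
    persisted = end is None or (end - start).days >= 365
    if persisted:
        window_id = "6-12m"
        readings = [r for r in bp if 183 <= (r["date"] - start).days <= 365]
        if not readings:
            for name, lo, hi in (("12-14m", 365, 426), ("14-18m", 426, 548),
                                 ("18-24m", 548, 730)):
                if end is not None and (end - start).days < hi:
                    continue
                cand = [r for r in bp if lo < (r["date"] - start).days <= hi]
                if cand:
                    window_id, readings = name, cand
                    break
    else:
        window_id = "discontinuation"
        readings = [r for r in bp
                    if (r["date"] - start).days >= 14
                    and r["date"] <= end - pd.Timedelta(days=183)]
    n = len(readings)

    if ae is not None:
        return "failure", ae[2], window_id, n
    if n == 0:
        return "excluded", None, window_id, 0

    # ---- JNC 8 control ----
    age = (start - patient["birth_date"]).days / 365.25
    if age < 60:
        avg_s, avg_d, max_s, max_d = 140, 90, 160, 90
    else:
        avg_s, avg_d, max_s, max_d = 150, 90, 170, 90
    sbps = [r["value"] for r in readings if r["kind"] == "SBP"]
    dbps = [r["value"] for r in readings if r["kind"] == "DBP"]
    if any(v > max_s for v in sbps) or any(v > max_d for v in dbps):
        return "failure", "bp_threshold", window_id, n
    mean = lambda xs: sum(xs) / len(xs)  # noqa: E731
    if (sbps and mean(sbps) >= avg_s) or (dbps and mean(dbps) >= avg_d):
        return "failure", "bp_average", window_id, n
    if persisted:
        return "success", None, window_id, n
    return "excluded", None, window_id, n
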