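"""Cohort construction: measurement filters, criteria, rare pairs, split."""

import copy

import pandas as pd
import pytest

from htnrec import cohort as co
from htnrec import medication as med

from conftest import make_bundle, vital_row


class TestFilterBP:
    def _vitals(self, **overrides):
        row = {"patient_id": 1, "kind": "SBP", "value": 130.0,
               "date": pd.Timestamp("2015-01-01"), "position": "sitting",
               "body_site": "arm", "invasive_flag": 0, "context": "ambulatory"}
        row.update(overrides)
        return pd.DataFrame([row])

    def test_valid_ambulatory_sitting_arm_row_retained(self):
        assert len(co.filter_bp_measurements(self._vitals())) == 1

    @pytest.mark.parametrize("overrides", [
        {"invasive_flag": 1},
        {"context": "hospital"},
        {"context": "exercise"},
        {"context": "operation"},
        {"context": "anesthesia"},
        {"context": "dialysis"},
        {"position": "supine"},
        {"body_site": "leg"},
        {"kind": "HR"},
    ])
    def test_excluded_measurement_conditions(self, overrides):
        assert co.filter_bp_measurements(self._vitals(**overrides)).empty


def _cohort_bundle(treat_start="2015-03-01", dx="2015-01-01",
                   extra_dx=(), extra_meds=(), last_record_offset=400,
                   with_baseline_bp=True, with_baseline_cr=True,
                   with_prior_care=True, outcome_days=(210, 290)):
    """One-patient bundle satisfying every criterion unless overridden."""
    start = pd.Timestamp(treat_start)
    vitals, labs = [], []
    if with_prior_care:
        vitals.append(vital_row(1, "HR", 70, pd.Timestamp(dx) - pd.Timedelta(days=90)))
    if with_baseline_bp:
        vitals += [vital_row(1, "SBP", 138, start - pd.Timedelta(days=30)),
                   vital_row(1, "DBP", 86, start - pd.Timedelta(days=30))]
    if with_baseline_cr:
        labs.append((1, "creatinine", 1.0, "mg/dL", start - pd.Timedelta(days=20)))
    for d in outcome_days:
        vitals += [vital_row(1, "SBP", 125, start + pd.Timedelta(days=d)),
                   vital_row(1, "DBP", 78, start + pd.Timedelta(days=d))]
    vitals.append(vital_row(1, "HR", 72, start + pd.Timedelta(days=last_record_offset)))
    meds = [(1, 100001, "lisinopril 10 mg tablet", 10.0, "1 tablet daily",
             treat_start, None)] + list(extra_meds)
    return make_bundle(
        patients=[(1, "1960-01-01", "F", "White")],
        diagnoses=[(1, "I10", dx, "ambulatory")] + list(extra_dx),
        vitals=vitals, labs=labs, medications=meds)


def _failed(bundle):
    recs = co.apply_inclusion(bundle)
    assert len(recs) == 1
    return recs[0]


class TestInclusion:
    def test_fully_eligible_patient_has_no_failed_criteria(self):
        rec = _failed(_cohort_bundle())
        assert rec.included and rec.failed_criteria == []

    def test_treatment_300_days_after_dx_fails_nine_month_window(self):
        rec = _failed(_cohort_bundle(treat_start="2015-10-28"))  # day 300
        assert "treatment_within_9_months" in rec.failed_criteria

    def test_treatment_on_day_270_is_inside_the_window(self):
        rec = _failed(_cohort_bundle(treat_start="2015-09-28"))  # day 270
        assert "treatment_within_9_months" not in rec.failed_criteria

    def test_missing_baseline_creatinine(self):
        rec = _failed(_cohort_bundle(with_baseline_cr=False))
        assert "baseline_creatinine" in rec.failed_criteria

    def test_missing_baseline_bp(self):
        rec = _failed(_cohort_bundle(with_baseline_bp=False))
        assert "baseline_bp" in rec.failed_criteria

    def test_no_primary_htn_code(self):
        bundle = _cohort_bundle()
        bundle.diagnoses = bundle.diagnoses[bundle.diagnoses["code"] != "I10"]
        rec = _failed(bundle)
        assert "primary_htn_dx" in rec.failed_criteria

    def test_no_record_before_diagnosis_fails_established_care(self):
        # baselines land after the diagnosis here, so without the prior-care
        # visit nothing precedes the diagnosis date
        rec = _failed(_cohort_bundle(with_prior_care=False))
        assert "established_care" in rec.failed_criteria

    def test_less_than_year_of_followup(self):
        rec = _failed(_cohort_bundle(last_record_offset=200,
                                     outcome_days=(190,)))
        assert "followup_1_year" in rec.failed_criteria

    def test_no_outcome_readings_fails_measurability(self):
        rec = _failed(_cohort_bundle(outcome_days=()))
        assert "outcome_measurable" in rec.failed_criteria

    def test_all_failures_recorded_not_just_first(self):
        rec = _failed(_cohort_bundle(with_baseline_bp=False,
                                     with_baseline_cr=False))
        assert {"baseline_bp", "baseline_creatinine"} <= set(rec.failed_criteria)


class TestExclusions:
    def test_prediabetes_200_days_post_treatment_excludes(self):
        bundle = _cohort_bundle(extra_dx=[(1, "R73.03", "2015-09-17", "ambulatory")])
        recs = co.apply_exclusions(co.apply_inclusion(bundle), bundle)
        assert not recs[0].included
        assert "new_diabetes" in recs[0].failed_criteria

    def test_preexisting_diabetes_is_not_a_new_diagnosis(self):
        bundle = _cohort_bundle(extra_dx=[
            (1, "E11", "2014-06-01", "ambulatory"),
            (1, "E11", "2015-06-01", "ambulatory")])
        recs = co.apply_exclusions(co.apply_inclusion(bundle), bundle)
        assert "new_diabetes" not in recs[0].failed_criteria

    def _rare_bundle(self, n_with_pair):
        patients, diagnoses, vitals, labs, meds = [], [], [], [], []
        start = pd.Timestamp("2015-03-01")
        for pid in range(1, n_with_pair + 3):
            patients.append((pid, "1960-01-01", "F", "White"))
            diagnoses.append((pid, "I10", "2015-01-01", "ambulatory"))
            vitals += [vital_row(pid, "HR", 70, "2014-10-01"),
                       vital_row(pid, "SBP", 138, "2015-02-01"),
                       vital_row(pid, "DBP", 86, "2015-02-01"),
                       vital_row(pid, "SBP", 125, "2015-10-01"),
                       vital_row(pid, "DBP", 78, "2015-10-01"),
                       vital_row(pid, "HR", 72, "2016-04-01")]
            labs.append((pid, "creatinine", 1.0, "mg/dL", "2015-02-10"))
            code, sig = ((100001, "1 tablet daily") if pid <= n_with_pair
                         else (100021, "1 tablet daily"))
            meds.append((pid, code, "x", 10.0, sig, "2015-03-01", None))
        return make_bundle(patients=patients, diagnoses=diagnoses,
                           vitals=vitals, labs=labs, medications=meds)

    def test_pair_occurring_once_is_excluded(self):
        bundle = self._rare_bundle(n_with_pair=1)
        recs = co.apply_exclusions(co.apply_inclusion(bundle), bundle)
        by_pid = {r.patient_id: r for r in recs}
        assert not by_pid[1].included
        assert "rare_pair" in by_pid[1].failed_criteria

    def test_pair_occurring_exactly_twice_is_retained(self):
        bundle = self._rare_bundle(n_with_pair=2)
        recs = co.apply_exclusions(co.apply_inclusion(bundle), bundle)
        by_pid = {r.patient_id: r for r in recs}
        assert by_pid[1].included and by_pid[2].included

    def test_rare_pair_filter_reaches_fixed_point(self):
        # removing one patient leaves another's pair below two: the filter
        # must cascade until no retained pair is rare
        def ep(pid, *ingredients):
            return med.TreatmentEpisode(
                pid, frozenset((i, 1.0) for i in ingredients), "other",
                pd.Timestamp("2015-01-01"), None, frozenset())

        # 'a' is a singleton; dropping patient 1 leaves 'b' a singleton too
        episodes = {1: ep(1, "a", "b"), 2: ep(2, "b"),
                    3: ep(3, "c"), 4: ep(4, "c")}
        records = [co.EligibilityRecord(pid, True, [],
                                        pd.Timestamp("2014-12-01"),
                                        pd.Timestamp("2015-01-01"))
                   for pid in episodes]
        bundle = make_bundle(patients=[(p, "1960-01-01", "F", "White")
                                       for p in episodes])
        out = co.apply_exclusions(records, bundle, episodes)
        by_pid = {r.patient_id: r for r in out}
        assert not by_pid[1].included  # singleton pair 'a'
        assert not by_pid[2].included  # cascade: 'b' became a singleton
        assert by_pid[3].included and by_pid[4].included
        counts = {}
        for r in out:
            if r.included:
                for comp in episodes[r.patient_id].components:
                    counts[comp] = counts.get(comp, 0) + 1
        assert all(v >= 2 for v in counts.values())

    def test_filters_are_idempotent(self):
        bundle = self._rare_bundle(n_with_pair=1)
        recs1 = co.apply_exclusions(co.apply_inclusion(bundle), bundle)
        recs2 = co.apply_exclusions(copy.deepcopy(recs1), bundle)
        assert [(r.patient_id, r.included, sorted(set(r.failed_criteria)))
                for r in recs1] == \
            [(r.patient_id, r.included, sorted(set(r.failed_criteria)))
             for r in recs2]


class TestSplit:
    def test_split_is_disjoint_exhaustive_and_sized(self):
        ids = list(range(100, 400))
        train, val = co.split_train_validation(ids, 50, seed=3)
        assert len(val) == 50 and len(train) == 250
        assert train & val == set()
        assert train | val == set(ids)

    def test_same_seed_reproduces_split(self):
        ids = list(range(50))
        assert co.split_train_validation(ids, 10, 9) == \
            co.split_train_validation(ids, 10, 9)

    def test_oversized_validation_rejected(self):
        with pytest.raises(ValueError, match="n_validation"):
            co.split_train_validation([1, 2, 3], 3, 0)


def test_planted_violations_map_to_their_criteria(small_run):
    """Every synthetic patient planted with a specific criterion violation is
    excluded for (at least) that criterion; clean patients are included."""
    ef = small_run["eligibility"].set_index("patient_id")
    obs = small_run["truth"].observed.set_index("patient_id")
    expected = {
        "no_primary_htn": "primary_htn_dx",
        "no_established_care": "established_care",
        "late_treatment": "treatment_within_9_months",
        "short_followup": "followup_1_year",
        "no_baseline_bp": "baseline_bp",
        "no_baseline_creatinine": "baseline_creatinine",
        "new_diabetes": "new_diabetes",
        "rare_pair": "rare_pair",
        "no_outcome_bp": "outcome_measurable",
    }
    for violation, criterion in expected.items():
        pids = obs.index[obs["violation"] == violation]
        assert len(pids) > 0
        for pid in pids:
            assert criterion in ef.loc[pid, "failed_criteria"].split(";"), \
                f"{violation}: patient {pid} not excluded for {criterion}"
    clean = obs.index[obs["violation"] == "none"]
    assert ef.loc[clean, "included"].all()
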