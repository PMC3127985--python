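"""Comorbidity measures: unit examples, invariants, brute-force equivalence."""

import datetime as dt

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from comorbibench import (DRUG_COUNT_CAP, ELIXHAUSER_ORDER,
                          build_general_cohort, build_profiles, cds_score,
                          charlson_score, count_distinct_diagnoses,
                          count_drug_classes, elixhauser_vector,
                          filter_eligible_diagnoses, match_conditions)
from comorbibench.cohorts import Cohort
from comorbibench.mappings import (load_cds_table, load_charlson_map,
                                   load_elixhauser_map,
                                   load_pregnancy_exclusions, normalize_code)
from conftest import COMORBIDITY_YEAR, make_bundle

WINDOW = COMORBIDITY_YEAR


class TestEligibilityFilter:
    def test_complication_dropped_for_index_kept_for_count(self):
        bundle = make_bundle(hospital=[
            {"record_id": 1, "code": "I50", "system": "ICD10",
             "dx_type": "comorbid"},
            {"record_id": 1, "code": "J96", "system": "ICD10",
             "dx_type": "post_admission_complication"}])
        for_index = filter_eligible_diagnoses(bundle, WINDOW, "for_index")
        assert list(for_index["code"]) == ["I50"]
        for_count = filter_eligible_diagnoses(bundle, WINDOW, "for_count")
        assert sorted(for_count["code"]) == ["I50", "J96"]

    def test_pregnancy_codes_removed_under_both_policies(self):
        bundle = make_bundle(physician=[{"code": "650"}])
        for policy in ("for_count", "for_index"):
            assert filter_eligible_diagnoses(bundle, WINDOW, policy).empty

    def test_out_of_window_events_dropped(self):
        bundle = make_bundle(physician=[{"code": "428",
                                         "service_date": "2000-06-01"}])
        assert filter_eligible_diagnoses(bundle, WINDOW, "for_count").empty

    def test_unknown_policy_rejected(self):
        bundle = make_bundle()
        with pytest.raises(ValueError, match="policy"):
            filter_eligible_diagnoses(bundle, WINDOW, "bogus")


class TestDiagnosisCount:
    def test_truncation_and_system_distinctness(self):
        events = pd.DataFrame({
            "person_id": [1, 1, 1],
            "code": ["I21.0", "I21.4", "410"],
            "system": ["ICD10", "ICD10", "ICD9"]})
        assert count_distinct_diagnoses(events)[1] == 2

    def test_duplicates_counted_once(self):
        events = pd.DataFrame({"person_id": [1, 1],
                               "code": ["428", "428"],
                               "system": ["ICD9", "ICD9"]})
        assert count_distinct_diagnoses(events)[1] == 1

    def test_empty_events(self):
        assert count_distinct_diagnoses(pd.DataFrame(
            columns=["person_id", "code", "system"])).empty


class TestCharlson:
    def test_all_false_scores_zero(self):
        flags = [False] * 17
        assert charlson_score(flags) == 0

    def test_chf_plus_metastatic_is_seven(self):
        cmap = load_charlson_map()
        flags = pd.DataFrame([{c: False for c in cmap.conditions}])
        flags["congestive_heart_failure"] = True
        flags["metastatic_solid_tumor"] = True
        assert charlson_score(flags).iloc[0] == 7

    def test_diabetes_hierarchy_contributes_two_not_three(self):
        cmap = load_charlson_map()
        flags = pd.DataFrame([{c: False for c in cmap.conditions}])
        flags["diabetes_without_complication"] = True
        flags["diabetes_with_complication"] = True
        assert charlson_score(flags).iloc[0] == 2

    def test_metastatic_suppresses_malignancy(self):
        cmap = load_charlson_map()
        flags = pd.DataFrame([{c: False for c in cmap.conditions}])
        flags["any_malignancy"] = True
        flags["metastatic_solid_tumor"] = True
        assert charlson_score(flags).iloc[0] == 6

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            charlson_score([True] * 16)

    def test_attainable_maximum(self):
        """All 17 conditions flagged: hierarchies cap the sum at 29."""
        assert charlson_score([True] * 17) == 29


class TestElixhauserVector:
    def test_zero_vector(self):
        assert elixhauser_vector([False] * 31).sum() == 0

    def test_single_flag_position(self):
        idx = ELIXHAUSER_ORDER.index("hypertension_uncomplicated")
        flags = [False] * 31
        flags[idx] = True
        vec = elixhauser_vector(flags)
        assert vec[idx] == 1 and vec.sum() == 1

    def test_length_is_31(self):
        assert len(elixhauser_vector([False] * 31)) == 31
        with pytest.raises(ValueError):
            elixhauser_vector([False] * 30)


class TestDrugCount:
    def _disp(self, classes):
        return pd.DataFrame({
            "person_id": 1,
            "dispense_date": pd.Timestamp("2001-06-01"),
            "ahfs_class": classes, "ingredient": ""})

    def test_distinct_two_level_classes(self):
        counts = count_drug_classes(self._disp(["08:12", "08:12", "24:06"]),
                                    WINDOW)
        assert counts[1] == 2

    def test_three_level_codes_collapse_to_two_level(self):
        counts = count_drug_classes(self._disp(["08:12:04", "08:12:06"]),
                                    WINDOW)
        assert counts[1] == 1

    def test_cap_at_125(self):
        classes = [f"{i:02d}:{j:02d}" for i in range(13) for j in range(10)]
        assert len(set(classes)) == 130
        counts = count_drug_classes(self._disp(classes), WINDOW)
        assert counts[1] == DRUG_COUNT_CAP == 125

    def test_malformed_class_warns_and_skips(self):
        with pytest.warns(UserWarning, match="two-level"):
            counts = count_drug_classes(self._disp(["08", "24:06"]), WINDOW)
        assert counts[1] == 1

    def test_empty(self):
        assert count_drug_classes(pd.DataFrame(
            columns=["person_id", "dispense_date", "ahfs_class",
                     "ingredient"]), WINDOW).empty


class TestCds:
    def _disp(self, classes):
        return pd.DataFrame({
            "person_id": 1,
            "dispense_date": pd.Timestamp("2001-06-01"),
            "ahfs_class": classes, "ingredient": ""})

    def test_no_dispensations(self):
        scores = cds_score(pd.DataFrame(
            columns=["person_id", "dispense_date", "ahfs_class",
                     "ingredient"]), window=WINDOW)
        assert scores.empty

    def test_single_condition_tiered_once(self):
        """Two heart-disease classes: the tier-2 score, counted once."""
        table = load_cds_table()
        scores = cds_score(self._disp(["24:04", "40:28"]), window=WINDOW)
        assert scores[1] == table.score_for("heart_disease", 2) == 4

    def test_unmapped_classes_score_zero(self):
        scores = cds_score(self._disp(["88:08", "84:04"]), window=WINDOW)
        assert scores.empty

    def test_maximal_profile_is_35(self):
        table = load_cds_table()
        scores = cds_score(self._disp(sorted(table.class_to_condition)),
                           window=WINDOW)
        assert scores[1] == 35


class TestBuildProfiles:
    def test_empty_cohort(self, small_bundle):
        cohort = Cohort("general", build_general_cohort(small_bundle)
                        .members.iloc[0:0])
        profiles = build_profiles(small_bundle, cohort, WINDOW)
        assert len(profiles) == 0

    def test_member_without_claims_gets_zero_profile(self):
        bundle = make_bundle(registry=[{"person_id": 1}, {"person_id": 2}],
                             physician=[{"person_id": 2, "code": "428"}])
        cohort = build_general_cohort(bundle)
        profiles = build_profiles(bundle, cohort, WINDOW).set_index("person_id")
        row = profiles.loc[1]
        assert row["n_diagnoses"] == row["charlson"] == row["n_drugs"] == \
            row["cds"] == 0
        assert row.filter(like="elix_").sum() == 0

    def test_row_count_equals_cohort_size(self, small_bundle):
        cohort = build_general_cohort(small_bundle)
        profiles = build_profiles(small_bundle, cohort, WINDOW)
        assert len(profiles) == len(cohort)

    def test_missing_member_raises_integrity_error(self, small_bundle):
        from comorbibench import IntegrityError
        cohort = build_general_cohort(small_bundle)
        members = pd.concat([cohort.members,
                             cohort.members.iloc[:1].assign(person_id=10**9)])
        with pytest.raises(IntegrityError):
            build_profiles(small_bundle, Cohort("general", members), WINDOW)


# --- properties ---------------------------------------------------------------

_event = st.tuples(
    st.sampled_from(["I50.0", "410", "E11.2", "C78", "401", "F32", "462",
                     "K25.7", "J44", "650"]),
    st.sampled_from(["ICD9", "ICD10"]))


class TestProperties:
    @given(st.lists(_event, max_size=12))
    @settings(max_examples=60, deadline=None)
    def test_duplication_leaves_measures_unchanged(self, events):
        phys = [{"code": c, "service_date": "2001-06-01"}
                for c, s in events if s == "ICD9"]
        hosp = [{"record_id": i, "code": c, "system": s,
                 "admission_date": "2001-06-01"}
                for i, (c, s) in enumerate(events) if s == "ICD10"]
        b1 = make_bundle(physician=phys, hospital=hosp)
        b2 = make_bundle(physician=phys * 2,
                         hospital=hosp + [dict(h, record_id=h["record_id"] + 500)
                                          for h in hosp])
        c1 = build_general_cohort(b1)
        p1 = build_profiles(b1, c1, WINDOW)
        p2 = build_profiles(b2, build_general_cohort(b2), WINDOW)
        pd.testing.assert_frame_equal(p1, p2)

    @given(st.lists(_event, min_size=1, max_size=10), _event)
    @settings(max_examples=60, deadline=None)
    def test_adding_event_never_decreases_measures(self, events, extra):
        def profile(evts):
            phys = [{"code": c, "service_date": "2001-06-01"}
                    for c, s in evts if s == "ICD9"]
            hosp = [{"record_id": i, "code": c, "system": s,
                     "admission_date": "2001-06-01"}
                    for i, (c, s) in enumerate(evts) if s == "ICD10"]
            b = make_bundle(physician=phys, hospital=hosp)
            return build_profiles(b, build_general_cohort(b),
                                  WINDOW).iloc[0]
        before = profile(events)
        after = profile(events + [extra])
        assert after["n_diagnoses"] >= before["n_diagnoses"]
        # hierarchy suppression cannot break monotonicity: every superior
        # condition carries a strictly larger weight than the one it masks
        assert after["charlson"] >= before["charlson"]
        for col in before.index:
            if col.startswith("elix_"):
                assert after[col] >= before[col]


# --- brute-force oracle -------------------------------------------------------

def brute_force_profiles(bundle, cohort, window):
    """Independent direct-semantics scorer: per-person Python loops."""
    charl, elix = load_charlson_map(), load_elixhauser_map()
    cds_table = load_cds_table()
    preg = load_pregnancy_exclusions()
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])

    def is_preg(code, system):
        n = normalize_code(code)
        return any(n.startswith(p) for p in preg[system])

    def eligible(pid, policy):
        out = []
        hosp = bundle.hospital
        for row in hosp[hosp["person_id"] == pid].itertuples(index=False):
            if not (start <= row.admission_date <= end):
                continue
            if policy == "for_index" and \
                    row.dx_type == "post_admission_complication":
                continue
            if is_preg(row.code, row.system):
                continue
            out.append((row.code, row.system))
        phys = bundle.physician
        for row in phys[phys["person_id"] == pid].itertuples(index=False):
            if not (start <= row.service_date <= end):
                continue
            if is_preg(row.code, "ICD9"):
                continue
            out.append((row.code, "ICD9"))
        return out

    def flags_for(events, cmap):
        out = {}
        for cond in cmap.conditions:
            hit = False
            for code, system in events:
                n = normalize_code(code)
                if any(n.startswith(p)
                       for p in cmap.patterns_for(system, cond)):
                    hit = True
                    break
            out[cond] = hit
        return out

    rows = []
    for pid in cohort.person_ids():
        count_events = eligible(pid, "for_count")
        index_events = eligible(pid, "for_index")
        n_dx = len({(s, normalize_code(c)[:3]) for c, s in count_events})

        cflags = flags_for(index_events, charl)
        for sup, inf in charl.hierarchy:
            if cflags[sup]:
                cflags[inf] = False
        charlson = sum(charl.weights[c] for c, v in cflags.items() if v)

        eflags = flags_for(index_events, elix)

        d = bundle.drugs
        classes = set()
        for row in d[d["person_id"] == pid].itertuples(index=False):
            if start <= row.dispense_date <= end:
                parts = str(row.ahfs_class).split(":")
                if len(parts) >= 2:
                    classes.add(":".join(parts[:2]))
        n_drugs = min(len(classes), 125)

        per_cond = {}
        for cls in classes:
            cond = cds_table.class_to_condition.get(cls)
            if cond:
                per_cond[cond] = per_cond.get(cond, 0) + 1
        cds = sum(cds_table.score_for(c, k) for c, k in per_cond.items())

        row_out = {"person_id": pid, "n_diagnoses": n_dx,
                   "charlson": charlson, "n_drugs": n_drugs, "cds": cds}
        row_out.update({f"elix_{c}": int(v) for c, v in eflags.items()})
        rows.append(row_out)
    return pd.DataFrame(rows)


class TestOracleEquivalence:
    def test_all_measures_match_brute_force(self, small_bundle):
        cohort = build_general_cohort(small_bundle)
        fast = build_profiles(small_bundle, cohort, WINDOW)
        slow = brute_force_profiles(small_bundle, cohort, WINDOW)
        fast = fast.set_index("person_id").sort_index()
        slow = slow.set_index("person_id").sort_index()[fast.columns]
        pd.testing.assert_frame_equal(fast, slow, check_dtype=False)
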