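"""Generator contracts: determinism, marginals, calibration, integrity."""

import math

import numpy as np
import pandas as pd
import pytest
from pandas.testing import assert_frame_equal

from comorbibench import (ConfigError, GeneratorConfig, build_general_cohort,
                          build_profiles, generate_bundle, generate_registry)


def logit(p: float) -> float:
    return math.log(p / (1 - p))


class TestConfigValidation:
    def test_bad_fraction_names_field(self):
        with pytest.raises(ConfigError, match="female_fraction"):
            GeneratorConfig(female_fraction=1.5)

    def test_unknown_prevalence_key_rejected(self):
        with pytest.raises(ConfigError, match="condition_prevalences"):
            GeneratorConfig(condition_prevalences={"not_a_condition": 0.1})

    def test_unknown_coefficient_name_rejected(self):
        with pytest.raises(ConfigError, match="death_coefficients"):
            GeneratorConfig(
                death_coefficients={"intercept": -4.0, "not_a_covariate": 1.0})

    def test_absent_condition_coefficient_contributes_nothing(self):
        """A coefficient for a condition that is never simulated is inert."""
        base = dict(n_persons=2000, seed=21,
                    condition_prevalences={"congestive_heart_failure": 0.2})
        cfg_a = GeneratorConfig(
            **base, death_coefficients={"intercept": -3.0})
        cfg_b = GeneratorConfig(
            **base, death_coefficients={"intercept": -3.0,
                                        "metastatic_cancer": 2.0})
        b_a, b_b = generate_bundle(cfg_a), generate_bundle(cfg_b)
        assert b_a.registry["death_date"].equals(b_b.registry["death_date"])

    def test_reversed_interval_rejected(self):
        import datetime as dt
        with pytest.raises(ConfigError, match="outcome_year"):
            GeneratorConfig(outcome_year=(dt.date(2003, 1, 1),
                                          dt.date(2002, 1, 1)))


class TestDeterminism:
    def test_identical_seed_identical_bundle(self):
        cfg = GeneratorConfig(n_persons=500, seed=7)
        b1, b2 = generate_bundle(cfg), generate_bundle(cfg)
        for name in ("registry", "coverage", "hospital", "physician",
                     "drugs", "truth"):
            assert_frame_equal(getattr(b1, name), getattr(b2, name))

    def test_different_seed_differs(self):
        b1 = generate_bundle(GeneratorConfig(n_persons=500, seed=7))
        b2 = generate_bundle(GeneratorConfig(n_persons=500, seed=8))
        assert not b1.registry["birth_date"].equals(b2.registry["birth_date"])


class TestRegistryMarginals:
    def test_degenerate_female_fraction(self):
        reg, _ = generate_registry(GeneratorConfig(n_persons=200, seed=1,
                                                   female_fraction=1.0))
        assert (reg["sex"] == "F").all()

    def test_count(self):
        reg, _ = generate_registry(GeneratorConfig(n_persons=1234, seed=1))
        assert len(reg) == 1234
        assert reg["person_id"].is_unique

    def test_quintiles_uniform_within_3se(self):
        n = 50_000
        reg, _ = generate_registry(GeneratorConfig(
            n_persons=n, seed=5, quintile_missing_fraction=0.0))
        freq = reg["income_quintile"].value_counts(normalize=True)
        se = math.sqrt(0.2 * 0.8 / n)
        for q in "12345":
            assert abs(freq[q] - 0.2) < 3 * se


class TestHistory:
    def test_degenerate_rates_give_empty_tables(self):
        cfg = GeneratorConfig(
            n_persons=200, seed=3, condition_prevalences={},
            drug_class_rate=0.0, noise_dx_rate=0.0, pregnancy_event_rate=0.0,
            hospitalization_coefficients={"intercept": -math.inf},
            death_coefficients={"intercept": -20.0})
        b = generate_bundle(cfg)
        assert b.hospital.empty
        assert b.physician.empty
        assert b.drugs.empty

    def test_certain_condition_always_coded(self, ):
        cfg = GeneratorConfig(
            n_persons=300, seed=9, coverage_gap_fraction=0.0,
            condition_prevalences={"congestive_heart_failure": 1.0},
            noise_dx_rate=0.0, pregnancy_event_rate=0.0)
        b = generate_bundle(cfg)
        cohort = build_general_cohort(b)
        profiles = build_profiles(b, cohort, cfg.comorbidity_year)
        assert (profiles["elix_congestive_heart_failure"] == 1).all()

    def test_flag_rate_recovers_prevalence(self):
        n = 50_000
        cfg = GeneratorConfig(
            n_persons=n, seed=11, coverage_gap_fraction=0.0,
            condition_prevalences={"congestive_heart_failure": 0.10},
            noise_dx_rate=0.0, pregnancy_event_rate=0.0)
        b = generate_bundle(cfg)
        cohort = build_general_cohort(b)
        profiles = build_profiles(b, cohort, cfg.comorbidity_year)
        rate = profiles["elix_congestive_heart_failure"].mean()
        se = math.sqrt(0.10 * 0.90 / n)
        assert abs(rate - 0.10) < 3 * se

    def test_events_fall_inside_coverage(self):
        cfg = GeneratorConfig(n_persons=400, seed=13,
                              coverage_gap_fraction=0.5)
        b = generate_bundle(cfg)
        cov = b.coverage
        for table, col in ((b.hospital, "admission_date"),
                           (b.physician, "service_date"),
                           (b.drugs, "dispense_date")):
            if table.empty:
                continue
            merged = table.reset_index().merge(cov, on="person_id")
            inside = ((merged[col] >= merged["start"])
                      & (merged[col] <= merged["end"]))
            # every event lies in at least one of its person's intervals
            assert inside.groupby(merged["index"]).any().all()


class TestOutcomeModels:
    def test_intercept_only_death_calibration(self):
        n = 100_000
        cfg = GeneratorConfig(
            n_persons=n, seed=17,
            death_coefficients={"intercept": logit(0.013)},
            hospitalization_coefficients={"intercept": -math.inf})
        b = generate_bundle(cfg)
        rate = b.registry["death_date"].notna().mean()
        se = math.sqrt(0.013 * 0.987 / n)
        assert abs(rate - 0.013) < 3 * se

    def test_zero_rate_means_no_outcome_hospitalizations(self):
        cfg = GeneratorConfig(
            n_persons=300, seed=19,
            hospitalization_coefficients={"intercept": -math.inf})
        b = generate_bundle(cfg)
        outcome_start = pd.Timestamp(cfg.outcome_year[0])
        assert (b.hospital["admission_date"] < outcome_start).all()

    def test_death_rate_monotone_in_charlson_strata(self):
        cfg = GeneratorConfig(
            n_persons=50_000, seed=23,
            death_coefficients={"intercept": -4.0, "charlson": 0.6},
            hospitalization_coefficients={"intercept": -math.inf})
        b = generate_bundle(cfg)
        truth = b.truth
        died = b.registry["death_date"].notna().to_numpy()
        strata = np.minimum(truth["charlson_true"].to_numpy(), 2)
        rates = [died[strata == s].mean() for s in (0, 1, 2)]
        assert rates[0] <= rates[1] <= rates[2]


class TestIntegrity:
    def test_no_orphan_person_ids(self, medium_bundle):
        medium_bundle.validate()  # raises on violation

    def test_truth_isolation(self, medium_bundle):
        """Downstream stages never read the truth table."""
        import comorbibench as cb
        cfg = GeneratorConfig(n_persons=2000, seed=7)
        with_truth = medium_bundle
        stripped = medium_bundle.without_truth()
        g1 = cb.build_general_cohort(with_truth)
        g2 = cb.build_general_cohort(stripped)
        assert_frame_equal(g1.members, g2.members)
        p1 = cb.build_profiles(with_truth, g1, cfg.comorbidity_year)
        p2 = cb.build_profiles(stripped, g2, cfg.comorbidity_year)
        assert_frame_equal(p1, p2)
        o1 = cb.derive_outcomes(with_truth, g1, cfg.outcome_year)
        o2 = cb.derive_outcomes(stripped, g2, cfg.outcome_year)
        assert_frame_equal(o1, o2)

    def test_csv_roundtrip(self, tmp_path, small_bundle):
        small_bundle.to_csv(tmp_path / "bundle")
        loaded = type(small_bundle).from_csv(tmp_path / "bundle")
        assert len(loaded.registry) == len(small_bundle.registry)
        assert (tmp_path / "bundle" / "truth_flags.csv").exists()
        assert loaded.hospital["code"].dtype == object
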