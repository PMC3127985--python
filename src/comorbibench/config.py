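"""Configuration objects for the synthetic-claims generator and the pipeline.

Defaults emulate a linked provincial claims system observed over fiscal years
(April 1 to March 31): a six-year case-finding history (1996/97-2001/02), a
one-year comorbidity-assessment window (2001/02) and a one-year outcome
window (2002/03).  Default marginal rates are anchored to a general adult
population: ~1.3% one-year mortality, ~17% with at least one hospitalization,
a mean of ~3.9 distinct recorded diagnoses and ~1.8 distinct dispensed drug
classes per person-year.
"""

from __future__ import annotations

import datetime as dt
import math
from dataclasses import dataclass, field, replace

from .mappings import load_charlson_map, load_elixhauser_map

__all__ = ["ConfigError", "GeneratorConfig", "CohortSpec", "RunConfig",
           "DEFAULT_PREVALENCES", "DEFAULT_DEATH_COEFFICIENTS",
           "DEFAULT_HOSPITALIZATION_COEFFICIENTS"]


class ConfigError(ValueError):
    """A configuration field failed validation; the message names the field."""


DateInterval = tuple[dt.date, dt.date]

STUDY_WINDOW: DateInterval = (dt.date(1996, 4, 1), dt.date(2002, 3, 31))
COMORBIDITY_YEAR: DateInterval = (dt.date(2001, 4, 1), dt.date(2002, 3, 31))
OUTCOME_YEAR: DateInterval = (dt.date(2002, 4, 1), dt.date(2003, 3, 31))

#: Annual prevalence of each latent chronic condition.  The Elixhauser-named
#: entries follow the observed general-population prevalences of a western
#: Canadian adult population; conditions reachable only through the Charlson
#: map (infarction, stroke, dementia) and the osteoporosis cohort trigger are
#: added so every downstream measure has signal.
DEFAULT_PREVALENCES: dict[str, float] = {
    "hypertension_uncomplicated": 0.167,
    "chronic_pulmonary_disease": 0.084,
    "depression": 0.056,
    "hypothyroidism": 0.034,
    "solid_tumor_without_metastasis": 0.025,
    "congestive_heart_failure": 0.020,
    "psychoses": 0.013,
    "rheumatoid_arthritis": 0.012,
    "diabetes_complicated": 0.010,
    "valvular_disease": 0.010,
    "other_neurological_disorders": 0.010,
    "cardiac_arrhythmias": 0.008,
    "fluid_electrolyte_disorders": 0.008,
    "coagulopathy": 0.008,
    "metastatic_cancer": 0.008,
    "renal_failure": 0.006,
    "drug_abuse": 0.005,
    "peripheral_vascular_disorders": 0.004,
    "deficiency_anemia": 0.004,
    "hypertension_complicated": 0.003,
    "pulmonary_circulation_disorders": 0.003,
    "liver_disease": 0.003,
    "alcohol_abuse": 0.003,
    "diabetes_uncomplicated": 0.002,
    "obesity": 0.002,
    "paralysis": 0.002,
    "peptic_ulcer_disease": 0.001,
    "lymphoma": 0.001,
    "weight_loss": 0.001,
    "blood_loss_anemia": 0.0005,
    "aids_hiv": 0.0003,
    "myocardial_infarction": 0.008,
    "cerebrovascular_disease": 0.015,
    "dementia": 0.010,
    "osteoporosis": 0.030,
}

#: Logit-scale death model: heterogeneous per-condition effects concentrated
#: in the conditions that dominate one-year mortality, deliberately not
#: proportional to any single summary weight.
DEFAULT_DEATH_COEFFICIENTS: dict[str, float] = {
    "intercept": -4.9,
    "age10": 0.55,            # per decade above age 60
    "metastatic_cancer": 2.6,
    "weight_loss": 1.5,
    "congestive_heart_failure": 1.4,
    "renal_failure": 1.3,
    "liver_disease": 1.2,
    "solid_tumor_without_metastasis": 1.0,
    "fluid_electrolyte_disorders": 0.9,
    "cardiac_arrhythmias": 0.8,
    "dementia": 0.8,
    "chronic_pulmonary_disease": 0.6,
    "cerebrovascular_disease": 0.6,
    "coagulopathy": 0.5,
    "myocardial_infarction": 0.5,
    "paralysis": 0.4,
    "diabetes_complicated": 0.4,
    "depression": 0.1,
    "hypertension_uncomplicated": 0.05,
}

#: Log-rate Poisson model for outcome-year hospitalization counts, driven by
#: total recorded diagnosis burden (conditions plus incidental diagnoses).
DEFAULT_HOSPITALIZATION_COEFFICIENTS: dict[str, float] = {
    "intercept": -2.45,
    "age10": 0.12,
    "dx_burden": 0.17,
}

_VALID_SPECIAL_COVARIATES = {"intercept", "age10", "charlson", "dx_burden"}


def _known_condition_names() -> set[str]:
    names = set(load_elixhauser_map().conditions) | set(load_charlson_map().conditions)
    names.add("osteoporosis")
    return names


def _check_interval(name: str, interval: DateInterval) -> None:
    start, end = interval
    if not (isinstance(start, dt.date) and isinstance(end, dt.date)):
        raise ConfigError(f"{name}: endpoints must be dates")
    if end < start:
        raise ConfigError(f"{name}: interval is not well ordered ({start} > {end})")


def _check_fraction(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name}: proportion {value} outside [0, 1]")


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic linked-claims generator.

    The outcome-generating models are explicit so that downstream parameter
    and ranking recovery can be tested: death is Bernoulli on an inverse-logit
    linear predictor, hospitalization counts are Poisson on a log-linear
    predictor.  Coefficient keys may be ``intercept``, ``age10`` (decades
    above 60), ``charlson`` (the latent Charlson score), ``dx_burden`` (the
    person's total distinct-diagnosis burden) or any condition name present
    in the bundled maps.
    """

    n_persons: int = 1000
    seed: int = 0
    study_window: DateInterval = STUDY_WINDOW
    comorbidity_year: DateInterval = COMORBIDITY_YEAR
    outcome_year: DateInterval = OUTCOME_YEAR
    age_range: tuple[int, int] = (20, 90)
    female_fraction: float = 0.513
    urban_fraction: float = 0.582
    region_missing_fraction: float = 0.002
    quintile_missing_fraction: float = 0.012
    condition_prevalences: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_PREVALENCES))
    drug_class_rate: float = 1.8
    death_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_DEATH_COEFFICIENTS))
    hospitalization_coefficients: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HOSPITALIZATION_COEFFICIENTS))
    coverage_gap_fraction: float = 0.05
    # Emission mechanics (see docs/methods.md for rationale).
    physician_channel_fraction: float = 0.7
    icd10_fraction: float = 0.5
    era_realism: bool = False
    history_emission_prob: float = 0.9
    condition_drug_prob: float = 0.7
    noise_dx_rate: float = 3.4
    pregnancy_event_rate: float = 0.04

    def __post_init__(self) -> None:
        if self.n_persons <= 0:
            raise ConfigError("n_persons: must be a positive integer")
        for nm in ("study_window", "comorbidity_year", "outcome_year"):
            _check_interval(nm, getattr(self, nm))
        lo, hi = self.age_range
        if lo < 0 or hi <= lo:
            raise ConfigError(f"age_range: invalid ({lo}, {hi})")
        for nm in ("female_fraction", "urban_fraction", "coverage_gap_fraction",
                   "physician_channel_fraction", "icd10_fraction",
                   "history_emission_prob", "condition_drug_prob",
                   "region_missing_fraction", "quintile_missing_fraction"):
            _check_fraction(nm, getattr(self, nm))
        for nm in ("drug_class_rate", "noise_dx_rate", "pregnancy_event_rate"):
            if getattr(self, nm) < 0:
                raise ConfigError(f"{nm}: must be non-negative")
        known = _known_condition_names()
        for cond, prev in self.condition_prevalences.items():
            if cond not in known:
                raise ConfigError(
                    f"condition_prevalences: unknown condition {cond!r}")
            _check_fraction(f"condition_prevalences[{cond}]", prev)
        for nm in ("death_coefficients", "hospitalization_coefficients"):
            coefs = getattr(self, nm)
            if "intercept" not in coefs:
                raise ConfigError(f"{nm}: missing 'intercept'")
            for key, val in coefs.items():
                if key not in _VALID_SPECIAL_COVARIATES and key not in known:
                    raise ConfigError(f"{nm}: unknown covariate {key!r}")
                if not (math.isfinite(val) or (key == "intercept" and val == -math.inf)):
                    raise ConfigError(f"{nm}[{key}]: non-finite coefficient")

    def with_seed(self, seed: int) -> "GeneratorConfig":
        return replace(self, seed=seed)


@dataclass(frozen=True)
class CohortSpec:
    """Eligibility rules for one study cohort.

    ``as_of_date`` is the single reference date at which age (in completed
    years) and vital status are assessed; ``coverage_period`` spans the
    comorbidity and outcome years, over which uninterrupted health coverage
    is required (coverage up to death counts as uninterrupted for persons
    dying inside the period, since death is itself a study outcome).
    """

    label: str = "general"
    min_age: int = 20
    case_window: DateInterval = STUDY_WINDOW
    coverage_period: DateInterval = (COMORBIDITY_YEAR[0], OUTCOME_YEAR[1])
    as_of_date: dt.date = OUTCOME_YEAR[0]

    def __post_init__(self) -> None:
        if self.label not in ("general", "diabetes", "osteoporosis"):
            raise ConfigError(f"label: unknown cohort label {self.label!r}")
        if self.min_age < 0:
            raise ConfigError("min_age: must be non-negative")
        _check_interval("case_window", self.case_window)
        _check_interval("coverage_period", self.coverage_period)

    @classmethod
    def general(cls, **kw) -> "CohortSpec":
        return cls(label="general", min_age=kw.pop("min_age", 20), **kw)

    @classmethod
    def diabetes(cls, **kw) -> "CohortSpec":
        return cls(label="diabetes", min_age=kw.pop("min_age", 20), **kw)

    @classmethod
    def osteoporosis(cls, **kw) -> "CohortSpec":
        return cls(label="osteoporosis", min_age=kw.pop("min_age", 50), **kw)


@dataclass(frozen=True)
class RunConfig:
    """Top-level pipeline configuration (generator, cohorts, evaluation)."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    cohort_labels: tuple[str, ...] = ("general", "diabetes", "osteoporosis")
    restrict_65plus: bool = True
    hl_groups: int = 10
    ci_level: float = 0.95
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        for label in self.cohort_labels:
            if label not in ("general", "diabetes", "osteoporosis"):
                raise ConfigError(f"cohort_labels: unknown label {label!r}")
        if not (0.0 < self.ci_level < 1.0):
            raise ConfigError("ci_level: must lie in (0, 1)")
        if self.hl_groups < 2:
            raise ConfigError("hl_groups: need at least 2 groups")

    def cohort_specs(self) -> list[CohortSpec]:
        factory = {"general": CohortSpec.general,
                   "diabetes": CohortSpec.diabetes,
                   "osteoporosis": CohortSpec.osteoporosis}
        window = (self.generator.comorbidity_year[0], self.generator.outcome_year[1])
        return [factory[label](case_window=self.generator.study_window,
                               coverage_period=window,
                               as_of_date=self.generator.outcome_year[0])
                for label in self.cohort_labels]
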