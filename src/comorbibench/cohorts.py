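"""Cohort construction from a claims bundle.

Three cohorts are supported:

* **general** -- all registered persons aged ``min_age``+ (default 20) at the
  reference date.
* **diabetes** -- national-surveillance case definition: at least one
  hospital diagnosis of diabetes (ICD-9 250, ICD-10 E10-E14) or at least two
  physician claims with such codes no more than 730 days apart, within the
  case-finding window; the index date is the earliest qualifying diagnosis.
* **osteoporosis** -- persons aged 50+ with an osteoporosis diagnosis
  (ICD-9 733, ICD-10 M80/M81) in hospital or physician data, or at least one
  dispensation of an osteoprotective drug; persons with a Paget's disease
  diagnosis (ICD-9 731.0, ICD-10 M88.0/M88.8/M88.9) are excluded.

All cohorts additionally require the person to be alive at the reference
date and to hold uninterrupted health coverage over the coverage period.
Coverage running up to the death date counts as uninterrupted for persons
dying inside the period, because death is itself a study outcome.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .config import CohortSpec
from .mappings import (load_osteoprotective_drugs, normalize_code,
                       expand_range)

__all__ = ["Cohort", "has_continuous_coverage", "build_cohort",
           "build_general_cohort", "build_diabetes_cohort",
           "build_osteoporosis_cohort", "restrict_age"]

DIABETES_PATTERNS = {"ICD9": ("250",), "ICD10": tuple(expand_range("E10-E14"))}
OSTEO_PATTERNS = {"ICD9": ("733",), "ICD10": ("M80", "M81")}
PAGET_PATTERNS = {"ICD9": ("7310",), "ICD10": ("M880", "M888", "M889")}

TWO_YEARS_DAYS = 730


@dataclass(frozen=True)
class Cohort:
    """A labelled set of cohort members with eligibility metadata.

    ``members`` columns: person_id, index_date (NaT for the general cohort),
    age_at_reference (completed years), sex, region, income_quintile.
    """

    label: str
    members: pd.DataFrame

    def __len__(self) -> int:
        return len(self.members)

    def person_ids(self) -> np.ndarray:
        return self.members["person_id"].to_numpy()


def _merge_intervals(intervals: list[tuple]) -> list[tuple]:
    """Merge overlapping or date-adjacent coverage intervals."""
    merged: list[list] = []
    one_day = dt.timedelta(days=1)
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1] + one_day:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [tuple(iv) for iv in merged]


def has_continuous_coverage(intervals, period, death_date=None) -> bool:
    """True iff coverage spans ``period`` with no gap.

    ``intervals`` is an iterable of (start, end) pairs.  When the person dies
    inside the period, coverage need only run to the death date.
    """
    start, end = period
    if death_date is not None and not pd.isna(death_date):
        death_date = pd.Timestamp(death_date).date() \
            if isinstance(death_date, pd.Timestamp) else death_date
        if start <= death_date <= end:
            end = death_date
    for iv_start, iv_end in _merge_intervals(
            [(_as_date(a), _as_date(b)) for a, b in intervals]):
        if iv_start <= start and iv_end >= end:
            return True
    return False


def _as_date(value) -> dt.date:
    if isinstance(value, pd.Timestamp):
        return value.date()
    if isinstance(value, np.datetime64):
        return pd.Timestamp(value).date()
    return value


def _coverage_ok(bundle: ClaimsBundle, spec: CohortSpec) -> pd.Series:
    """Vectorized coverage predicate per registry person (index: person_id)."""
    period_start = pd.Timestamp(spec.coverage_period[0])
    period_end = pd.Timestamp(spec.coverage_period[1])

    cov = bundle.coverage.sort_values(["person_id", "start"], kind="stable").copy()
    # merge adjacent/overlapping intervals within person
    prev_end = cov.groupby("person_id")["end"].shift()
    new_block = (prev_end.isna()
                 | (cov["start"] > prev_end + pd.Timedelta(days=1)))
    cov["block"] = new_block.cumsum()
    blocks = cov.groupby(["person_id", "block"]).agg(
        start=("start", "min"), end=("end", "max")).reset_index()

    death = bundle.registry.set_index("person_id")["death_date"]
    blocks = blocks.merge(death.rename("death_date"), on="person_id", how="left")
    eff_end = pd.Series(period_end, index=blocks.index)
    dying_inside = (blocks["death_date"].notna()
                    & (blocks["death_date"] >= period_start)
                    & (blocks["death_date"] <= period_end))
    eff_end[dying_inside] = blocks.loc[dying_inside, "death_date"]
    ok = (blocks["start"] <= period_start) & (blocks["end"] >= eff_end)
    per_person = ok.groupby(blocks["person_id"]).any()
    return per_person.reindex(bundle.registry["person_id"], fill_value=False)


def _age_completed_years(birth: pd.Series, as_of: dt.date) -> pd.Series:
    as_of = pd.Timestamp(as_of)
    years = as_of.year - birth.dt.year
    before_birthday = ((birth.dt.month > as_of.month)
                       | ((birth.dt.month == as_of.month)
                          & (birth.dt.day > as_of.day)))
    return years - before_birthday.astype(int)


def _match_any(codes: pd.Series, systems: pd.Series | str,
               patterns: dict[str, tuple[str, ...]]) -> pd.Series:
    norm = codes.map(normalize_code)
    if isinstance(systems, str):
        mask = pd.Series(False, index=codes.index)
        for p in patterns[systems]:
            mask |= norm.str.startswith(p)
        return mask
    mask = pd.Series(False, index=codes.index)
    for system, pats in patterns.items():
        sys_mask = systems == system
        if not sys_mask.any():
            continue
        sub = pd.Series(False, index=codes.index)
        for p in pats:
            sub |= norm.str.startswith(p)
        mask |= sys_mask & sub
    return mask


def _apply_demographic_filters(bundle: ClaimsBundle, spec: CohortSpec,
                               index_dates: pd.Series | None) -> pd.DataFrame:
    reg = bundle.registry
    age = _age_completed_years(reg["birth_date"], spec.as_of_date)
    alive = reg["death_date"].isna() | (reg["death_date"]
                                        >= pd.Timestamp(spec.as_of_date))
    covered = _coverage_ok(bundle, spec).to_numpy()
    keep = (age >= spec.min_age) & alive & covered
    if index_dates is not None:
        qualifies = reg["person_id"].isin(index_dates.index)
        keep &= qualifies
    members = reg.loc[keep, ["person_id", "sex", "region",
                             "income_quintile"]].copy()
    members["age_at_reference"] = age[keep].to_numpy()
    if index_dates is not None:
        members["index_date"] = members["person_id"].map(index_dates)
    else:
        members["index_date"] = pd.NaT
    cols = ["person_id", "index_date", "age_at_reference", "sex", "region",
            "income_quintile"]
    return members[cols].reset_index(drop=True)


def build_general_cohort(bundle: ClaimsBundle, spec: CohortSpec | None = None) -> Cohort:
    """All registered persons meeting the age, vital-status and coverage rules."""
    spec = spec or CohortSpec.general()
    if bundle.registry.empty:
        warnings.warn("empty registry: general cohort is empty", stacklevel=2)
        return Cohort("general", _apply_demographic_filters(bundle, spec, None))
    return Cohort("general", _apply_demographic_filters(bundle, spec, None))


def _window_mask(dates: pd.Series, window) -> pd.Series:
    return (dates >= pd.Timestamp(window[0])) & (dates <= pd.Timestamp(window[1]))


def build_diabetes_cohort(bundle: ClaimsBundle, spec: CohortSpec | None = None) -> Cohort:
    """Surveillance case definition: 1 hospital code or 2 physician claims
    with diabetes codes at most two years apart, inside the case window."""
    spec = spec or CohortSpec.diabetes()
    hosp = bundle.hospital
    hosp_q = hosp[_window_mask(hosp["admission_date"], spec.case_window)
                  & _match_any(hosp["code"], hosp["system"], DIABETES_PATTERNS)]
    hosp_index = hosp_q.groupby("person_id")["admission_date"].min()

    phys = bundle.physician
    phys_q = phys[_window_mask(phys["service_date"], spec.case_window)
                  & _match_any(phys["code"], "ICD9", DIABETES_PATTERNS)]
    phys_index = _paired_claim_index(phys_q, TWO_YEARS_DAYS)

    index_dates = _min_over([hosp_index, phys_index])
    members = _apply_demographic_filters(bundle, spec, index_dates)
    return Cohort("diabetes", members)


def _min_over(series_list: list[pd.Series]) -> pd.Series:
    parts = [s for s in series_list if not s.empty]
    if not parts:
        return pd.Series(dtype="datetime64[ns]")
    return pd.concat(parts).groupby(level=0).min()


def _paired_claim_index(claims: pd.DataFrame, max_gap_days: int) -> pd.Series:
    """Earliest date of a pair of claims no more than ``max_gap_days`` apart.

    A sliding-window reading of "two claims within a two-year period": any
    pair of claim dates whose difference is at most the gap qualifies, and
    sorted order makes it sufficient to inspect consecutive dates.
    """
    if claims.empty:
        return pd.Series(dtype="datetime64[ns]")
    s = claims.sort_values(["person_id", "service_date"], kind="stable")
    gap_ok = ((s.groupby("person_id")["service_date"].shift(-1)
               - s["service_date"]).dt.days <= max_gap_days)
    first = s[gap_ok].groupby("person_id")["service_date"].min()
    return first


def build_osteoporosis_cohort(bundle: ClaimsBundle,
                              spec: CohortSpec | None = None) -> Cohort:
    """Diagnosed or pharmacologically treated osteoporosis, Paget excluded."""
    spec = spec or CohortSpec.osteoporosis()
    hosp, phys, drugs = bundle.hospital, bundle.physician, bundle.drugs

    hosp_in = _window_mask(hosp["admission_date"], spec.case_window)
    hosp_q = hosp[hosp_in & _match_any(hosp["code"], hosp["system"], OSTEO_PATTERNS)]
    phys_in = _window_mask(phys["service_date"], spec.case_window)
    phys_q = phys[phys_in & _match_any(phys["code"], "ICD9", OSTEO_PATTERNS)]

    ingredients, fallback_classes = load_osteoprotective_drugs()
    drug_in = _window_mask(drugs["dispense_date"], spec.case_window)
    ing = drugs["ingredient"].fillna("").astype(str).str.lower()
    has_ing = ing != ""
    drug_match = np.where(has_ing, ing.isin(ingredients),
                          drugs["ahfs_class"].isin(fallback_classes))
    drug_q = drugs[drug_in & drug_match]

    index_dates = _min_over([
        hosp_q.groupby("person_id")["admission_date"].min(),
        phys_q.groupby("person_id")["service_date"].min(),
        drug_q.groupby("person_id")["dispense_date"].min(),
    ])

    paget = hosp[hosp_in & _match_any(hosp["code"], hosp["system"], PAGET_PATTERNS)]
    paget_phys = phys[phys_in & _match_any(phys["code"], "ICD9", PAGET_PATTERNS)]
    excluded = set(paget["person_id"]) | set(paget_phys["person_id"])
    index_dates = index_dates[~index_dates.index.isin(excluded)]

    members = _apply_demographic_filters(bundle, spec, index_dates)
    return Cohort("osteoporosis", members)


_BUILDERS = {"general": build_general_cohort,
             "diabetes": build_diabetes_cohort,
             "osteoporosis": build_osteoporosis_cohort}


def build_cohort(bundle: ClaimsBundle, spec: CohortSpec) -> Cohort:
    return _BUILDERS[spec.label](bundle, spec)


def restrict_age(cohort: Cohort, min_age: int = 65) -> Cohort:
    """Subset of a built cohort with age_at_reference >= min_age."""
    keep = cohort.members["age_at_reference"] >= min_age
    return Cohort(cohort.label, cohort.members[keep].reset_index(drop=True))
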