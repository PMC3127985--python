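"""The five claims-based comorbidity measures.

All measures are computed from one year of claims (the comorbidity
assessment window):

* ``n_diagnoses`` -- number of different diagnoses truncated to the third
  character, pooled over hospital and physician sources but kept distinct
  across coding systems (no ICD-9/ICD-10 cross-walk is attempted).
* ``charlson`` -- weighted sum over the 17 Charlson conditions, with the
  diabetes, liver-disease and malignancy hierarchies preventing
  double-counting of graded conditions.
* ``elixhauser`` -- 31 binary condition indicators in a fixed documented
  order; no summary score is computed.
* ``n_drugs`` -- number of distinct two-level ("four-digit") AHFS drug
  classes, capped at 125.
* ``cds`` -- Chronic Disease Score: drug classes are mapped to 17 chronic
  conditions, each condition contributes a tiered score of 1-5 (escalating
  with the number of distinct matched classes), and scores are summed
  (range 0-35).

Diagnoses coded as pregnancy, childbirth or abortion are excluded from every
measure.  Diagnoses flagged as in-hospital complications (developed after
admission) are excluded from the index measures (Charlson, Elixhauser) but
retained in the plain diagnosis count, where they are configurable.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle, IntegrityError
from .cohorts import Cohort
from .mappings import (CdsTable, ConditionMap, load_cds_table,
                       load_charlson_map, load_elixhauser_map,
                       load_pregnancy_exclusions, match_flags, normalize_code)

__all__ = ["filter_eligible_diagnoses", "count_distinct_diagnoses",
           "match_conditions", "charlson_score", "elixhauser_vector",
           "count_drug_classes", "cds_score", "build_profiles",
           "DRUG_COUNT_CAP", "ELIXHAUSER_ORDER", "elix_columns"]

DRUG_COUNT_CAP = 125

POLICIES = ("for_count", "for_index")

ELIXHAUSER_ORDER: tuple[str, ...] = load_elixhauser_map().conditions


def elix_columns() -> list[str]:
    """Profile column names for the 31 Elixhauser indicators, in order."""
    return [f"elix_{c}" for c in ELIXHAUSER_ORDER]


def _pregnancy_mask(codes: pd.Series, systems: pd.Series) -> pd.Series:
    """True where a diagnosis code falls in the pregnancy exclusion set."""
    exclusions = load_pregnancy_exclusions()
    norm = codes.map(normalize_code)
    mask = pd.Series(False, index=codes.index)
    for system, patterns in exclusions.items():
        sys_mask = systems == system
        if not sys_mask.any():
            continue
        by_len: dict[int, set[str]] = {}
        for p in patterns:
            by_len.setdefault(len(p), set()).add(p)
        sub = pd.Series(False, index=codes.index)
        for length, pats in by_len.items():
            sub |= norm.str.slice(0, length).isin(pats)
        mask |= sys_mask & sub
    return mask


def filter_eligible_diagnoses(bundle: ClaimsBundle, window, policy: str,
                              person_ids=None) -> pd.DataFrame:
    """Diagnosis events eligible for measure construction.

    Parameters
    ----------
    window : (start, end) dates of the comorbidity assessment year.
    policy : "for_count" keeps in-hospital complication diagnoses (they are
        recorded diagnoses); "for_index" drops them, as required for the
        Charlson and Elixhauser calculations.
    person_ids : optional iterable restricting the output.

    Returns
    -------
    DataFrame with columns person_id, date, code, system, source, dx_type.
    """
    if policy not in POLICIES:
        raise ValueError(f"unknown policy {policy!r}; expected one of {POLICIES}")
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])

    hosp = bundle.hospital
    hosp = hosp[(hosp["admission_date"] >= start) & (hosp["admission_date"] <= end)]
    if policy == "for_index" and not hosp.empty:
        hosp = hosp[hosp["dx_type"] != "post_admission_complication"]
    hosp_events = pd.DataFrame({
        "person_id": hosp["person_id"], "date": hosp["admission_date"],
        "code": hosp["code"], "system": hosp["system"],
        "source": "hospital", "dx_type": hosp["dx_type"]})

    phys = bundle.physician
    phys = phys[(phys["service_date"] >= start) & (phys["service_date"] <= end)]
    phys_events = pd.DataFrame({
        "person_id": phys["person_id"], "date": phys["service_date"],
        "code": phys["code"], "system": "ICD9",
        "source": "physician", "dx_type": pd.NA})

    events = pd.concat([hosp_events, phys_events], ignore_index=True)
    if person_ids is not None:
        events = events[events["person_id"].isin(set(person_ids))]
    if events.empty:
        return events.reset_index(drop=True)
    keep = ~_pregnancy_mask(events["code"], events["system"])
    return events[keep].reset_index(drop=True)


def count_distinct_diagnoses(events: pd.DataFrame) -> pd.Series:
    """Distinct (coding system, 3-character rubric) pairs per person.

    Codes from different systems never collapse onto one another.
    """
    if events.empty:
        return pd.Series(dtype=int).rename_axis("person_id")
    rubric = events["code"].map(normalize_code).str.slice(0, 3)
    key = events["system"].astype(str) + ":" + rubric
    return events.assign(key=key).groupby("person_id")["key"].nunique()


def match_conditions(events: pd.DataFrame, cmap: ConditionMap) -> pd.DataFrame:
    """Per-person binary condition flags (one column per map condition)."""
    return match_flags(events, cmap)


def charlson_score(flags, cmap: ConditionMap | None = None):
    """Weighted Charlson sum with hierarchy resolution.

    ``flags`` may be a DataFrame (persons x 17 conditions) giving a Series of
    scores, or a single length-17 sequence giving one integer.  Hierarchies:
    complicated diabetes suppresses uncomplicated diabetes, moderate/severe
    liver disease suppresses mild liver disease, and metastatic solid tumor
    suppresses non-metastatic malignancy.
    """
    cmap = cmap or load_charlson_map()
    single = not isinstance(flags, pd.DataFrame)
    if single:
        arr = np.asarray(flags, dtype=bool)
        if arr.shape != (len(cmap.conditions),):
            raise ValueError(
                f"expected {len(cmap.conditions)} condition flags, got {arr.shape}")
        flags = pd.DataFrame([arr], columns=list(cmap.conditions))
    else:
        missing = set(cmap.conditions) - set(flags.columns)
        if missing:
            raise ValueError(f"flag table missing conditions: {sorted(missing)}")
    resolved = flags[list(cmap.conditions)].astype(bool).copy()
    for superior, inferior in cmap.hierarchy:
        resolved[inferior] &= ~resolved[superior]
    weights = pd.Series(cmap.weights)[list(cmap.conditions)]
    scores = resolved.to_numpy() @ weights.to_numpy()
    if single:
        return int(scores[0])
    return pd.Series(scores, index=flags.index, name="charlson")


def elixhauser_vector(flags) -> np.ndarray | pd.DataFrame:
    """The ordered 31-indicator vector (or persons x 31 table), values 0/1."""
    if isinstance(flags, pd.DataFrame):
        missing = set(ELIXHAUSER_ORDER) - set(flags.columns)
        if missing:
            raise ValueError(f"flag table missing conditions: {sorted(missing)}")
        return flags[list(ELIXHAUSER_ORDER)].astype(int)
    arr = np.asarray(flags, dtype=bool).astype(int)
    if arr.shape != (len(ELIXHAUSER_ORDER),):
        raise ValueError(f"expected {len(ELIXHAUSER_ORDER)} flags, got {arr.shape}")
    return arr


def _two_level_class(ahfs: pd.Series) -> pd.Series:
    parts = ahfs.astype(str).str.split(":")
    ok = parts.str.len() >= 2
    return parts.str[:2].str.join(":").where(ok)


def count_drug_classes(dispensations: pd.DataFrame, window,
                       cap: int = DRUG_COUNT_CAP) -> pd.Series:
    """Distinct two-level AHFS classes per person within the window, capped.

    Dispensations lacking the two-level class prefix are rejected with a
    warning.
    """
    if dispensations.empty:
        return pd.Series(dtype=int).rename_axis("person_id")
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    d = dispensations[(dispensations["dispense_date"] >= start)
                      & (dispensations["dispense_date"] <= end)].copy()
    d["cls"] = _two_level_class(d["ahfs_class"])
    bad = d["cls"].isna()
    if bad.any():
        warnings.warn(f"{int(bad.sum())} dispensation(s) lack a two-level "
                      "AHFS class and were ignored", stacklevel=2)
        d = d[~bad]
    counts = d.groupby("person_id")["cls"].nunique()
    return counts.clip(upper=cap)


def cds_score(dispensations: pd.DataFrame, table: CdsTable | None = None,
              window=None) -> pd.Series:
    """Chronic Disease Score per person from dispensed drug classes.

    Each of the 17 conditions contributes its tier score once, indexed by
    the number of distinct matched classes; tiers never decrease with more
    classes and are capped at 5.
    """
    table = table or load_cds_table()
    if dispensations.empty:
        return pd.Series(dtype=int).rename_axis("person_id")
    d = dispensations
    if window is not None:
        start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
        d = d[(d["dispense_date"] >= start) & (d["dispense_date"] <= end)]
    d = d.assign(cls=_two_level_class(d["ahfs_class"]))
    d = d.dropna(subset=["cls"])
    d = d.assign(condition=d["cls"].map(table.class_to_condition))
    d = d.dropna(subset=["condition"])
    if d.empty:
        return pd.Series(dtype=int).rename_axis("person_id")
    n_classes = (d.groupby(["person_id", "condition"])["cls"].nunique()
                 .reset_index(name="k"))
    n_classes["score"] = [
        table.score_for(cond, k)
        for cond, k in zip(n_classes["condition"], n_classes["k"])]
    return n_classes.groupby("person_id")["score"].sum()


def build_profiles(bundle: ClaimsBundle, cohort: Cohort, window) -> pd.DataFrame:
    """One comorbidity profile per cohort member.

    Columns: person_id, n_diagnoses, charlson, elix_<condition> x 31,
    n_drugs, cds.  Members with no claims receive all-zero measures.
    """
    pids = cohort.person_ids()
    known = set(bundle.registry["person_id"])
    missing = set(pids) - known
    if missing:
        raise IntegrityError(
            f"{len(missing)} cohort member(s) missing from registry")

    out = pd.DataFrame({"person_id": pids})
    if len(pids) == 0:
        cols = ["n_diagnoses", "charlson", *elix_columns(), "n_drugs", "cds"]
        for c in cols:
            out[c] = pd.Series(dtype=int)
        return out

    count_events = filter_eligible_diagnoses(bundle, window, "for_count", pids)
    index_events = filter_eligible_diagnoses(bundle, window, "for_index", pids)

    n_dx = count_distinct_diagnoses(count_events)
    charl_flags = match_conditions(index_events, load_charlson_map())
    charl = charlson_score(charl_flags) if len(charl_flags) else pd.Series(dtype=int)
    elix_flags = match_conditions(index_events, load_elixhauser_map())

    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    drugs = bundle.drugs
    drugs = drugs[drugs["person_id"].isin(set(pids))]
    n_drugs = count_drug_classes(drugs, window)
    cds = cds_score(drugs, window=window)

    out["n_diagnoses"] = out["person_id"].map(n_dx).fillna(0).astype(int)
    out["charlson"] = out["person_id"].map(charl).fillna(0).astype(int)
    elix = (elix_flags.reindex(pids, fill_value=False).astype(int)
            if len(elix_flags) else
            pd.DataFrame(0, index=pids, columns=list(ELIXHAUSER_ORDER)))
    elix.columns = elix_columns()
    out = out.join(elix.reset_index(drop=True))
    out["n_drugs"] = out["person_id"].map(n_drugs).fillna(0).astype(int)
    out["cds"] = out["person_id"].map(cds).fillna(0).astype(int)
    return out
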