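"""Outcome derivation: death and hospitalization over the outcome year.

Three binary indicators per cohort member: death inside the outcome year,
at least one hospitalization, and two or more hospitalizations.  Stays whose
most responsible diagnosis is pregnancy-, childbirth- or abortion-related are
excluded from the hospitalization counts; stays are attributed to the window
by admission date, and transfers or readmissions count as separate stays.
"""

from __future__ import annotations

import pandas as pd

from .bundle import ClaimsBundle, IntegrityError
from .cohorts import Cohort
from .measures import _pregnancy_mask

__all__ = ["derive_death", "derive_hospitalizations", "derive_outcomes"]


def derive_death(bundle: ClaimsBundle, cohort: Cohort, window) -> pd.Series:
    """Death indicator: 1 iff the registry death date falls inside the window."""
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    reg = bundle.registry.set_index("person_id")
    death = reg["death_date"].reindex(cohort.person_ids())
    before_window = death.notna() & (death < start)
    if before_window.any():
        bad = death[before_window].index[:3].tolist()
        raise IntegrityError(
            f"cohort member(s) died before the outcome window (e.g. {bad}); "
            "they should have been excluded at cohort construction")
    out = ((death >= start) & (death <= end)).astype(int)
    out.name = "death"
    return out


def derive_hospitalizations(bundle: ClaimsBundle, cohort: Cohort,
                            window) -> pd.DataFrame:
    """Outcome-year hospitalization counts and threshold indicators.

    A stay is pregnancy-related (and excluded) when its *most responsible*
    diagnosis is in the pregnancy exclusion set; secondary pregnancy codes do
    not exclude the stay.
    """
    start, end = pd.Timestamp(window[0]), pd.Timestamp(window[1])
    hosp = bundle.hospital
    hosp = hosp[(hosp["admission_date"] >= start)
                & (hosp["admission_date"] <= end)
                & hosp["person_id"].isin(set(cohort.person_ids()))]

    if hosp.empty:
        counts = pd.Series(0, index=cohort.person_ids())
    else:
        mrdx = hosp[hosp["dx_type"] == "most_responsible"]
        pregnant_records = set(
            mrdx.loc[_pregnancy_mask(mrdx["code"], mrdx["system"]), "record_id"])
        stays = hosp[["person_id", "record_id"]].drop_duplicates()
        stays = stays[~stays["record_id"].isin(pregnant_records)]
        counts = (stays.groupby("person_id").size()
                  .reindex(cohort.person_ids(), fill_value=0))

    out = pd.DataFrame({
        "person_id": cohort.person_ids(),
        "n_hospitalizations": counts.to_numpy(int),
    })
    out["hosp_ge1"] = (out["n_hospitalizations"] >= 1).astype(int)
    out["hosp_ge2"] = (out["n_hospitalizations"] >= 2).astype(int)
    return out


def derive_outcomes(bundle: ClaimsBundle, cohort: Cohort, window) -> pd.DataFrame:
    """Full outcome table: person_id, death, hosp_ge1, hosp_ge2, n_hospitalizations."""
    death = derive_death(bundle, cohort, window)
    hosp = derive_hospitalizations(bundle, cohort, window)
    hosp.insert(1, "death", death.to_numpy())
    return hosp[["person_id", "death", "hosp_ge1", "hosp_ge2",
                 "n_hospitalizations"]]
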