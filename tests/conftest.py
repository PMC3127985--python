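"""Shared fixtures: hand-built micro-bundles and small generated bundles."""

from __future__ import annotations

import datetime as dt

import pandas as pd
import pytest

from comorbibench import ClaimsBundle, GeneratorConfig, generate_bundle

COMORBIDITY_YEAR = (dt.date(2001, 4, 1), dt.date(2002, 3, 31))
OUTCOME_YEAR = (dt.date(2002, 4, 1), dt.date(2003, 3, 31))
STUDY_WINDOW = (dt.date(1996, 4, 1), dt.date(2002, 3, 31))


def make_bundle(registry=None, coverage=None, hospital=None, physician=None,
                drugs=None) -> ClaimsBundle:
    """Assemble a bundle from row dictionaries, with permissive defaults.

    Registry rows default to a middle-aged covered woman; coverage defaults
    to one interval spanning the whole study period for every person.
    """
    registry = registry or [{"person_id": 1}]
    reg_rows = []
    for row in registry:
        base = {"person_id": 1, "birth_date": "1950-06-15", "sex": "F",
                "region": "urban", "income_quintile": "3", "death_date": None}
        base.update(row)
        reg_rows.append(base)
    reg = pd.DataFrame(reg_rows)
    reg["birth_date"] = pd.to_datetime(reg["birth_date"])
    reg["death_date"] = pd.to_datetime(reg["death_date"])

    if coverage is None:
        coverage = [{"person_id": p, "start": "1995-01-01", "end": "2004-01-01"}
                    for p in reg["person_id"]]
    cov = pd.DataFrame(coverage)
    cov["start"] = pd.to_datetime(cov["start"])
    cov["end"] = pd.to_datetime(cov["end"])

    hosp_rows = []
    for i, row in enumerate(hospital or []):
        base = {"person_id": 1, "record_id": 100 + i,
                "admission_date": "2001-06-01", "separation_date": None,
                "code": "428", "system": "ICD9", "dx_type": "comorbid"}
        base.update(row)
        if base["separation_date"] is None:
            base["separation_date"] = base["admission_date"]
        hosp_rows.append(base)
    hosp = pd.DataFrame(hosp_rows, columns=["person_id", "record_id",
                                            "admission_date",
                                            "separation_date", "code",
                                            "system", "dx_type"])
    for col in ("admission_date", "separation_date"):
        hosp[col] = pd.to_datetime(hosp[col]) if len(hosp) else pd.Series(
            dtype="datetime64[ns]")

    phys_rows = []
    for row in physician or []:
        base = {"person_id": 1, "service_date": "2001-06-01", "code": "428"}
        base.update(row)
        phys_rows.append(base)
    phys = pd.DataFrame(phys_rows, columns=["person_id", "service_date", "code"])
    phys["service_date"] = pd.to_datetime(phys["service_date"]) if len(phys) \
        else pd.Series(dtype="datetime64[ns]")

    drug_rows = []
    for row in drugs or []:
        base = {"person_id": 1, "dispense_date": "2001-06-01",
                "ahfs_class": "08:12", "ingredient": ""}
        base.update(row)
        drug_rows.append(base)
    drug = pd.DataFrame(drug_rows, columns=["person_id", "dispense_date",
                                            "ahfs_class", "ingredient"])
    drug["dispense_date"] = pd.to_datetime(drug["dispense_date"]) if len(drug) \
        else pd.Series(dtype="datetime64[ns]")

    return ClaimsBundle(registry=reg, coverage=cov, hospital=hosp,
                        physician=phys, drugs=drug)


@pytest.fixture(scope="session")
def small_bundle() -> ClaimsBundle:
    """200-person generated bundle with elevated prevalences (oracle tests)."""
    prev = dict(GeneratorConfig().condition_prevalences)
    for k in prev:
        prev[k] = min(prev[k] * 4, 0.5)
    cfg = GeneratorConfig(n_persons=200, seed=42, condition_prevalences=prev,
                          drug_class_rate=3.0)
    return generate_bundle(cfg)


@pytest.fixture(scope="session")
def medium_bundle() -> ClaimsBundle:
    """2,000-person generated bundle at default study conditions."""
    return generate_bundle(GeneratorConfig(n_persons=2000, seed=7))
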