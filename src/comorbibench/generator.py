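"""Synthetic linked administrative-claims generator.

Emulates a provincial claims system (population registry, hospital discharge
abstracts, physician billing claims, outpatient drug dispensations) with
known outcome-generating models, so that cohort construction, comorbidity
coding and model evaluation are testable end to end and parameter/ranking
recovery can be measured against ground truth.

Generating process, per person:

1. Demographics (age, sex, region, income quintile) and coverage intervals
   are drawn from the configured marginals; a configurable fraction of
   persons receives a coverage gap.
2. Latent chronic-condition flags are drawn independently per condition from
   the configured annual prevalences.  Every flagged condition emits at
   least one correspondingly mapped diagnosis code inside the comorbidity
   year (physician claim where the condition has a 3-digit ICD-9 rubric,
   hospital abstract otherwise), and emits cohort-qualifying history codes
   inside the six-year case-finding window with configured probability.
   Incidental ("noise") diagnoses unrelated to any chronic condition are
   added at a configurable rate; they carry no mortality signal but
   contribute to the total diagnosis burden.
3. Drug dispensations combine condition-linked classes (e.g. antidiabetic
   agents for diabetics) and background classes at ``drug_class_rate``.
4. Outcome-year death is Bernoulli on an inverse-logit linear predictor and
   the outcome-year hospitalization count is Poisson on a log-linear
   predictor; both predictors are configurable and recorded in the truth
   table.  Decedents' events are truncated at the death date.

Conditions are modelled independently of one another; see docs/methods.md
for what this simplification does and does not allow tests to show.
"""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
from scipy.special import expit

from .bundle import ClaimsBundle
from .config import ConfigError, GeneratorConfig
from .mappings import load_charlson_map, load_elixhauser_map

__all__ = ["generate_registry", "generate_history", "generate_outcome_year",
           "generate_bundle"]

# --- fixed emission vocabulary ------------------------------------------------

#: Latent condition name -> Charlson condition (for the truth Charlson score).
_TO_CHARLSON = {
    "myocardial_infarction": "myocardial_infarction",
    "congestive_heart_failure": "congestive_heart_failure",
    "peripheral_vascular_disorders": "peripheral_vascular_disease",
    "cerebrovascular_disease": "cerebrovascular_disease",
    "dementia": "dementia",
    "chronic_pulmonary_disease": "chronic_pulmonary_disease",
    "rheumatoid_arthritis": "rheumatic_disease",
    "peptic_ulcer_disease": "peptic_ulcer_disease",
    "liver_disease": "mild_liver_disease",
    "diabetes_uncomplicated": "diabetes_without_complication",
    "diabetes_complicated": "diabetes_with_complication",
    "paralysis": "hemiplegia_paraplegia",
    "renal_failure": "renal_disease",
    "solid_tumor_without_metastasis": "any_malignancy",
    "lymphoma": "any_malignancy",
    "metastatic_cancer": "metastatic_solid_tumor",
    "aids_hiv": "aids_hiv",
}

#: Condition -> dispensed AHFS class(es) when treated pharmacologically.
_CONDITION_AHFS = {
    "diabetes_uncomplicated": ["68:20"],
    "diabetes_complicated": ["68:20"],
    "congestive_heart_failure": ["24:04", "40:28"],
    "myocardial_infarction": ["24:12", "20:12"],
    "cardiac_arrhythmias": ["24:04"],
    "hypertension_uncomplicated": ["24:08"],
    "hypertension_complicated": ["24:08", "40:36"],
    "chronic_pulmonary_disease": ["12:12"],
    "rheumatoid_arthritis": ["60:00"],
    "solid_tumor_without_metastasis": ["10:00"],
    "metastatic_cancer": ["10:00"],
    "lymphoma": ["10:00"],
    "hypothyroidism": ["68:36"],
    "other_neurological_disorders": ["28:12"],
    "peptic_ulcer_disease": ["56:28"],
    "depression": ["28:16"],
    "psychoses": ["28:16"],
    "osteoporosis": ["92:24"],
}

#: 3-digit ICD-9 rubrics for incidental acute diagnoses; none of these match
#: any bundled condition map or the pregnancy exclusion set.
_NOISE_ICD9 = [
    "460", "461", "462", "463", "464", "465", "466", "472", "473", "477",
    "487", "520", "521", "523", "524", "528", "550", "553", "560", "562",
    "564", "566", "574", "575", "577", "600", "610", "611", "616", "620",
    "622", "623", "626", "627", "680", "681", "682", "684", "686", "690",
    "691", "692", "693", "696", "703", "704", "706", "707", "708", "719",
    "721", "722", "723", "724", "726", "727", "729", "786", "787", "788",
]

#: Background (non-chronic) drug classes: antibiotics, analgesics, topicals...
_BACKGROUND_AHFS = [
    "08:12", "08:24", "08:36", "28:08", "28:24", "52:04", "52:08", "56:12",
    "56:22", "84:04", "84:06", "84:80", "88:08", "88:12", "88:16", "88:20",
    "92:02", "04:04", "48:16", "56:40",
]

_PREGNANCY_PHYS = "650"          # normal delivery, 3-digit rubric
_PREGNANCY_HOSP = ("65001", "O80")
_PAGET_HOSP = ("7310", "M880")


def _uniform_dates(rng: np.random.Generator, interval, size: int) -> np.ndarray:
    """Uniform dates (datetime64[ns]) inside a closed date interval."""
    start, end = interval
    ndays = (end - start).days + 1
    offs = rng.integers(0, ndays, size=size)
    return np.datetime64(start, "ns") + offs.astype("timedelta64[D]")


def _codebook() -> dict[str, dict[str, str | None]]:
    """Per latent condition: emission codes for each channel."""
    elix, charl = load_elixhauser_map(), load_charlson_map()
    book: dict[str, dict[str, str | None]] = {}
    names = set(elix.conditions) | set(charl.conditions) | {"osteoporosis"}
    for cond in names:
        if cond == "osteoporosis":
            book[cond] = {"hosp9": "7330", "hosp10": "M81", "phys": "733"}
            continue
        cmap = elix if cond in elix.conditions else charl
        book[cond] = {
            "hosp9": cmap.example_code(cond, "ICD9"),
            "hosp10": cmap.example_code(cond, "ICD10"),
            "phys": cmap.physician_code(cond),
        }
    return book


# --- registry -----------------------------------------------------------------

def generate_registry(config: GeneratorConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Draw the population registry and coverage tables.

    Returns (registry, coverage).  Deterministic for identical config.
    """
    rng = np.random.default_rng([config.seed, 0])
    n = config.n_persons
    person_id = np.arange(1, n + 1)

    ref = np.datetime64(config.outcome_year[0], "ns")
    lo, hi = config.age_range
    ages = rng.uniform(lo, hi, size=n)
    birth_date = ref - (ages * 365.2425).astype("timedelta64[D]")

    sex = np.where(rng.random(n) < config.female_fraction, "F", "M")
    region = np.where(rng.random(n) < config.urban_fraction, "urban", "rural")
    region = np.where(rng.random(n) < config.region_missing_fraction,
                      "missing", region)
    quintile = rng.integers(1, 6, size=n).astype(str)
    quintile = np.where(rng.random(n) < config.quintile_missing_fraction,
                        "missing", quintile)

    registry = pd.DataFrame({
        "person_id": person_id,
        "birth_date": pd.to_datetime(birth_date),
        "sex": sex,
        "region": region,
        "income_quintile": quintile,
        "death_date": pd.NaT,
    })

    cov_start = np.datetime64(config.study_window[0], "ns")
    cov_end = np.datetime64(config.outcome_year[1], "ns") + np.timedelta64(90, "D")
    has_gap = rng.random(n) < config.coverage_gap_fraction
    gap_anchor = _uniform_dates(
        rng, (config.study_window[0], config.outcome_year[1]), n)
    gap_len = rng.integers(1, 61, size=n).astype("timedelta64[D]")

    rows = []
    for pid, g, anchor, length in zip(person_id, has_gap, gap_anchor, gap_len):
        if g:
            rows.append((pid, cov_start, anchor - np.timedelta64(1, "D")))
            rows.append((pid, anchor + length, cov_end))
        else:
            rows.append((pid, cov_start, cov_end))
    coverage = pd.DataFrame(rows, columns=["person_id", "start", "end"])
    coverage["start"] = pd.to_datetime(coverage["start"])
    coverage["end"] = pd.to_datetime(coverage["end"])
    return registry, coverage


def _in_coverage(events: pd.DataFrame, coverage: pd.DataFrame,
                 date_col: str) -> pd.Series:
    """Boolean mask: event date lies inside one of the person's intervals."""
    if events.empty:
        return pd.Series(dtype=bool)
    idx = events.reset_index(drop=True)
    merged = idx.reset_index().merge(coverage, on="person_id", how="left")
    inside = (merged[date_col] >= merged["start"]) & (merged[date_col] <= merged["end"])
    return inside.groupby(merged["index"]).any().reindex(
        range(len(idx)), fill_value=False)


# --- history ------------------------------------------------------------------

def generate_history(registry: pd.DataFrame, coverage: pd.DataFrame,
                     config: GeneratorConfig
                     ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate diagnosis and dispensation histories plus latent truth flags.

    Returns (hospital, physician, drugs, truth).
    """
    rng = np.random.default_rng([config.seed, 1])
    n = len(registry)
    pid = registry["person_id"].to_numpy()
    book = _codebook()
    conds = sorted(config.condition_prevalences)

    flags = pd.DataFrame({"person_id": pid}).set_index("person_id")
    hosp_rows: list[pd.DataFrame] = []
    phys_rows: list[pd.DataFrame] = []
    drug_rows: list[pd.DataFrame] = []

    def add_hosp(pids, dates, codes, systems, dx_type):
        hosp_rows.append(pd.DataFrame({
            "person_id": pids, "admission_date": dates, "code": codes,
            "system": systems, "dx_type": dx_type}))

    def add_phys(pids, dates, codes):
        phys_rows.append(pd.DataFrame({
            "person_id": pids, "service_date": dates, "code": codes}))

    def add_drug(pids, dates, classes, ingredient=""):
        drug_rows.append(pd.DataFrame({
            "person_id": pids, "dispense_date": dates,
            "ahfs_class": classes, "ingredient": ingredient}))

    def hospital_system(dates: np.ndarray, size: int) -> np.ndarray:
        if config.era_realism:
            cut = np.datetime64(dt.date(2002, 4, 1), "ns")
            return np.where(dates < cut, "ICD9", "ICD10")
        return np.where(rng.random(size) < config.icd10_fraction, "ICD10", "ICD9")

    for cond in conds:
        prev = config.condition_prevalences[cond]
        z = rng.random(n) < prev
        flags[cond] = z.astype(int)
        members = pid[z]
        m = len(members)
        if m == 0:
            continue

        codes = book[cond]
        # Guaranteed comorbidity-year emission.
        via_phys = ((rng.random(m) < config.physician_channel_fraction)
                    & (codes["phys"] is not None))
        cy_dates = _uniform_dates(rng, config.comorbidity_year, m)
        if codes["phys"] is not None and via_phys.any():
            add_phys(members[via_phys], cy_dates[via_phys], codes["phys"])
        hosp_mask = ~via_phys if codes["phys"] is not None else np.ones(m, bool)
        if hosp_mask.any():
            hdates = cy_dates[hosp_mask]
            systems = hospital_system(hdates, hosp_mask.sum())
            hcodes = np.where(systems == "ICD10", codes["hosp10"], codes["hosp9"])
            add_hosp(members[hosp_mask], hdates, hcodes, systems, "comorbid")

        # Cohort-qualifying history emission inside the case-finding window.
        hist = rng.random(m) < config.history_emission_prob
        hmembers = members[hist]
        h = len(hmembers)
        if h:
            if cond in ("diabetes_uncomplicated", "diabetes_complicated"):
                via_hosp = rng.random(h) < 0.3
                hd = _uniform_dates(rng, config.study_window, h)
                hs = hospital_system(hd, h)
                hc = np.where(hs == "ICD10", codes["hosp10"], codes["hosp9"])
                add_hosp(hmembers[via_hosp], hd[via_hosp], hc[via_hosp],
                         hs[via_hosp], "comorbid")
                # two physician claims within 730 days
                claim_members = hmembers[~via_hosp]
                k = len(claim_members)
                if k:
                    last_start = config.study_window[1] - dt.timedelta(days=730)
                    d1 = _uniform_dates(rng, (config.study_window[0], last_start), k)
                    delta = rng.integers(1, 730, size=k).astype("timedelta64[D]")
                    add_phys(claim_members, d1, "250")
                    add_phys(claim_members, d1 + delta, "250")
            elif cond == "osteoporosis":
                via_drug = rng.random(h) < 0.5
                hd = _uniform_dates(rng, config.study_window, h)
                add_drug(hmembers[via_drug], hd[via_drug], "92:24", "alendronate")
                add_phys(hmembers[~via_drug], hd[~via_drug], "733")
                # Rare Paget's disease co-diagnosis (exclusion pathway).
                paget = rng.random(h) < 0.02
                if paget.any():
                    pd_dates = _uniform_dates(rng, config.study_window, int(paget.sum()))
                    ps = hospital_system(pd_dates, int(paget.sum()))
                    pc = np.where(ps == "ICD10", _PAGET_HOSP[1], _PAGET_HOSP[0])
                    add_hosp(hmembers[paget], pd_dates, pc, ps, "comorbid")
            else:
                hd = _uniform_dates(rng, config.study_window, h)
                if codes["phys"] is not None:
                    add_phys(hmembers, hd, codes["phys"])
                else:
                    hs = hospital_system(hd, h)
                    hc = np.where(hs == "ICD10", codes["hosp10"], codes["hosp9"])
                    add_hosp(hmembers, hd, hc, hs, "comorbid")

        # Condition-linked drug dispensations in the comorbidity year.
        for ahfs in _CONDITION_AHFS.get(cond, []):
            treated = rng.random(m) < config.condition_drug_prob
            if treated.any():
                ddates = _uniform_dates(rng, config.comorbidity_year,
                                        int(treated.sum()))
                add_drug(members[treated], ddates, ahfs)

    # Incidental diagnoses: no mortality signal, but real diagnosis burden.
    n_noise = rng.poisson(config.noise_dx_rate, size=n)
    total = int(n_noise.sum())
    if total:
        noise_pid = np.repeat(pid, n_noise)
        noise_codes = rng.choice(_NOISE_ICD9, size=total)
        noise_dates = _uniform_dates(rng, config.comorbidity_year, total)
        add_phys(noise_pid, noise_dates, noise_codes)
    # distinct noise rubrics per person (the burden actually recorded)
    noise_burden = np.zeros(n)
    if total:
        nb = (pd.DataFrame({"person_id": noise_pid, "code": noise_codes})
              .groupby("person_id")["code"].nunique())
        noise_burden = nb.reindex(pid, fill_value=0).to_numpy(float)

    # Pregnancy-related events for women of childbearing age.
    age = (np.datetime64(config.outcome_year[0], "ns")
           - registry["birth_date"].to_numpy()) / np.timedelta64(365, "D")
    fertile = (registry["sex"].to_numpy() == "F") & (age >= 20) & (age <= 45)
    pregnant = fertile & (rng.random(n) < config.pregnancy_event_rate)
    if pregnant.any():
        k = int(pregnant.sum())
        pdates = _uniform_dates(rng, config.comorbidity_year, k)
        add_phys(pid[pregnant], pdates, _PREGNANCY_PHYS)
        in_hosp = rng.random(k) < 0.5
        if in_hosp.any():
            hdates = _uniform_dates(rng, config.comorbidity_year, int(in_hosp.sum()))
            hs = hospital_system(hdates, int(in_hosp.sum()))
            hc = np.where(hs == "ICD10", _PREGNANCY_HOSP[1], _PREGNANCY_HOSP[0])
            add_hosp(pid[pregnant][in_hosp], hdates, hc, hs, "most_responsible")

    # Background drug classes.
    n_bg = rng.poisson(config.drug_class_rate, size=n)
    bg_total = int(n_bg.sum())
    if bg_total:
        bg_pid = np.repeat(pid, n_bg)
        bg_classes = rng.choice(_BACKGROUND_AHFS, size=bg_total)
        bg_dates = _uniform_dates(rng, config.comorbidity_year, bg_total)
        add_drug(bg_pid, bg_dates, bg_classes)

    physician = (pd.concat(phys_rows, ignore_index=True) if phys_rows
                 else pd.DataFrame(columns=["person_id", "service_date", "code"]))
    drugs = (pd.concat(drug_rows, ignore_index=True) if drug_rows
             else pd.DataFrame(columns=["person_id", "dispense_date",
                                        "ahfs_class", "ingredient"]))

    hospital = (pd.concat(hosp_rows, ignore_index=True) if hosp_rows
                else pd.DataFrame(columns=["person_id", "admission_date",
                                           "code", "system", "dx_type"]))
    if not hospital.empty:
        hospital = hospital.sort_values(
            ["person_id", "admission_date"], kind="stable").reset_index(drop=True)
        hospital["record_id"] = np.arange(1, len(hospital) + 1)
        los = rng.integers(1, 8, size=len(hospital)).astype("timedelta64[D]")
        hospital["separation_date"] = (
            pd.to_datetime(hospital["admission_date"]) + los)
        # occasional in-hospital complication recorded on the same abstract
        compl = rng.random(len(hospital)) < 0.15
        if compl.any():
            extra = hospital[compl].copy()
            extra["code"] = rng.choice(_NOISE_ICD9, size=len(extra))
            extra["system"] = "ICD9"
            extra["dx_type"] = "post_admission_complication"
            hospital = pd.concat([hospital, extra], ignore_index=True)
    else:
        hospital["record_id"] = pd.Series(dtype=int)
        hospital["separation_date"] = pd.Series(dtype="datetime64[ns]")

    # Events must fall inside coverage intervals.
    def clip(frame: pd.DataFrame, date_col: str) -> pd.DataFrame:
        if frame.empty:
            return frame
        frame = frame.copy()
        frame[date_col] = pd.to_datetime(frame[date_col])
        keep = _in_coverage(frame, coverage, date_col).to_numpy()
        return frame[keep].reset_index(drop=True)

    hospital = clip(hospital, "admission_date")
    physician = clip(physician, "service_date")
    drugs = clip(drugs, "dispense_date")

    hospital = hospital[["person_id", "record_id", "admission_date",
                         "separation_date", "code", "system", "dx_type"]]

    truth = flags.reset_index()
    truth["age10"] = (age - 60.0) / 10.0
    cond_flags = truth[conds].to_numpy() if conds else np.zeros((n, 0))
    truth["dx_burden"] = cond_flags.sum(axis=1) + noise_burden
    truth["charlson_true"] = _latent_charlson(truth, conds)
    return hospital, physician, drugs, truth


def _latent_charlson(truth: pd.DataFrame, conds: list[str]) -> np.ndarray:
    """Charlson score implied by the latent flags (hierarchy applied)."""
    charl = load_charlson_map()
    cflags: dict[str, np.ndarray] = {}
    for cond in conds:
        target = _TO_CHARLSON.get(cond)
        if target is None:
            continue
        flag = truth[cond].to_numpy(bool)
        cflags[target] = cflags.get(target, False) | flag
    for superior, inferior in charl.hierarchy:
        if superior in cflags and inferior in cflags:
            cflags[inferior] = cflags[inferior] & ~cflags[superior]
    score = np.zeros(len(truth))
    for cname, flag in cflags.items():
        score += charl.weights[cname] * flag
    return score


# --- outcome year -------------------------------------------------------------

def _linear_predictor(coefs: dict[str, float], truth: pd.DataFrame) -> np.ndarray:
    lp = np.full(len(truth), coefs["intercept"], dtype=float)
    for name, beta in coefs.items():
        if name == "intercept":
            continue
        if name in ("age10", "charlson", "dx_burden"):
            col = {"charlson": "charlson_true"}.get(name, name)
            if col not in truth.columns:
                raise ConfigError(f"coefficient {name!r} has no matching "
                                  "truth covariate")
        else:
            # a condition not simulated (no prevalence entry) is never
            # present, so its coefficient contributes nothing
            col = name
            if col not in truth.columns:
                continue
        lp += beta * truth[col].to_numpy(float)
    return lp


def generate_outcome_year(registry: pd.DataFrame, coverage: pd.DataFrame,
                          truth: pd.DataFrame, config: GeneratorConfig
                          ) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw outcome-year deaths and hospitalizations from the truth models.

    Returns (registry with death dates, outcome-year hospital table, truth
    augmented with the linear predictors).
    """
    rng = np.random.default_rng([config.seed, 2])
    n = len(registry)
    truth = truth.sort_values("person_id").reset_index(drop=True)
    if not np.array_equal(truth["person_id"].to_numpy(),
                          registry["person_id"].to_numpy()):
        raise ConfigError("truth and registry person_ids do not align")

    lp_death = _linear_predictor(config.death_coefficients, truth)
    lp_hosp = _linear_predictor(config.hospitalization_coefficients, truth)
    p_death = expit(lp_death)
    died = rng.random(n) < p_death
    death_dates = pd.Series(pd.NaT, index=registry.index, dtype="datetime64[ns]")
    if died.any():
        death_dates[died] = pd.to_datetime(
            _uniform_dates(rng, config.outcome_year, int(died.sum())))

    registry = registry.copy()
    registry["death_date"] = death_dates.to_numpy()

    lam = np.exp(lp_hosp)
    counts = rng.poisson(lam)
    pid = registry["person_id"].to_numpy()
    book = _codebook()
    conds = sorted(config.condition_prevalences)
    flag_mat = truth[conds].to_numpy(bool) if conds else np.zeros((n, 0), bool)
    start = np.datetime64(config.outcome_year[0], "ns")
    rows = []
    for i in np.flatnonzero(counts):
        k = int(counts[i])
        end = (death_dates.iloc[i] if died[i]
               else np.datetime64(config.outcome_year[1], "ns"))
        span = max(int((np.datetime64(end, "ns") - start)
                       / np.timedelta64(1, "D")), 0) + 1
        dates = start + rng.integers(0, span, size=k).astype("timedelta64[D]")
        own = np.flatnonzero(flag_mat[i])
        for d in dates:
            if own.size and rng.random() < 0.5:
                cond = conds[int(own[int(rng.integers(own.size))])]
                use10 = rng.random() < config.icd10_fraction
                code = book[cond]["hosp10"] if use10 else book[cond]["hosp9"]
                system = "ICD10" if use10 else "ICD9"
            else:
                code = _NOISE_ICD9[int(rng.integers(len(_NOISE_ICD9)))]
                system = "ICD9"
            rows.append((pid[i], d, code, system))

    hospital = pd.DataFrame(rows, columns=["person_id", "admission_date",
                                           "code", "system"])
    if not hospital.empty:
        hospital["admission_date"] = pd.to_datetime(hospital["admission_date"])
        hospital = hospital.sort_values(
            ["person_id", "admission_date"], kind="stable").reset_index(drop=True)
        hospital["record_id"] = np.arange(10_000_000, 10_000_000 + len(hospital))
        los = rng.integers(1, 8, size=len(hospital)).astype("timedelta64[D]")
        hospital["separation_date"] = hospital["admission_date"] + los
        hospital["dx_type"] = "most_responsible"
        keep = _in_coverage(hospital, coverage, "admission_date").to_numpy()
        hospital = hospital[keep].reset_index(drop=True)
    else:
        for col, dtype in (("record_id", int),
                           ("separation_date", "datetime64[ns]"),
                           ("dx_type", object)):
            hospital[col] = pd.Series(dtype=dtype)
    hospital = hospital[["person_id", "record_id", "admission_date",
                         "separation_date", "code", "system", "dx_type"]]

    truth = truth.copy()
    truth["lp_death"] = lp_death
    truth["lp_hosp"] = lp_hosp
    return registry, hospital, truth


def generate_bundle(config: GeneratorConfig) -> ClaimsBundle:
    """Run the full generator and return a validated claims bundle."""
    registry, coverage = generate_registry(config)
    hospital, physician, drugs, truth = generate_history(registry, coverage, config)
    registry, outcome_hosp, truth = generate_outcome_year(
        registry, coverage, truth, config)
    frames = [f for f in (hospital, outcome_hosp) if not f.empty]
    hospital = (pd.concat(frames, ignore_index=True) if frames
                else hospital)
    bundle = ClaimsBundle(registry=registry, coverage=coverage,
                          hospital=hospital, physician=physician,
                          drugs=drugs, truth=truth)
    bundle.validate()
    return bundle
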