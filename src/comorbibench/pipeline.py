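"""End-to-end pipeline: generate -> cohorts -> score -> outcomes -> evaluate.

A run writes, under the output directory:

* the five claims tables (plus ``truth_flags.csv``) as CSV,
* cohort membership, comorbidity profiles and outcomes per cohort,
* a descriptives table (age, sex, residence, income quintiles, outcome
  frequencies, measure means/SDs) for every cohort variant (full and 65+),
* an Elixhauser category prevalence table across cohort variants,
* one model-performance table per cohort, and
* a machine-readable run manifest (config hash, seed, package versions).

Runs are deterministic given the configured seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .bundle import ClaimsBundle
from .cohorts import Cohort, build_cohort, restrict_age
from .config import RunConfig
from .generator import generate_bundle
from .measures import ELIXHAUSER_ORDER, build_profiles, elix_columns
from .model import evaluate_measures
from .outcomes import derive_outcomes

__all__ = ["run_pipeline", "render_table", "cohort_descriptives",
           "elixhauser_prevalence"]

logger = logging.getLogger(__name__)

_MEASURE_COLS = ("n_diagnoses", "charlson", "n_drugs", "cds")


def _config_hash(config: RunConfig) -> str:
    def default(obj):
        if dataclasses.is_dataclass(obj):
            return dataclasses.asdict(obj)
        return str(obj)
    blob = json.dumps(dataclasses.asdict(config), default=default,
                      sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def cohort_descriptives(cohort: Cohort, profiles: pd.DataFrame,
                        outcomes: pd.DataFrame, variant: str) -> dict:
    """One cohort-characteristics row (demographics, outcomes, measures)."""
    m = cohort.members
    n = len(m)
    row: dict = {"cohort": cohort.label, "variant": variant, "n": n}
    if n == 0:
        return row
    row["age_mean"] = m["age_at_reference"].mean()
    row["age_sd"] = m["age_at_reference"].std()
    row["female_pct"] = 100 * (m["sex"] == "F").mean()
    row["urban_pct"] = 100 * (m["region"] == "urban").mean()
    row["region_missing_pct"] = 100 * (m["region"] == "missing").mean()
    q = m["income_quintile"].astype(str)
    for level in ("1", "2", "3", "4", "5", "missing"):
        row[f"quintile_{level}_pct"] = 100 * (q == level).mean()
    for col, name in (("death", "death_pct"), ("hosp_ge1", "hosp_ge1_pct"),
                      ("hosp_ge2", "hosp_ge2_pct")):
        row[name] = 100 * outcomes[col].mean()
    for col in _MEASURE_COLS:
        row[f"{col}_mean"] = profiles[col].mean()
        row[f"{col}_sd"] = profiles[col].std()
    return row


def elixhauser_prevalence(profiles: pd.DataFrame, cohort: Cohort,
                          variant: str) -> pd.DataFrame:
    """Per-condition indicator prevalence (%) for one cohort variant."""
    cols = elix_columns()
    pct = 100 * profiles[cols].mean()
    return pd.DataFrame({
        "cohort": cohort.label, "variant": variant,
        "condition": list(ELIXHAUSER_ORDER),
        "prevalence_pct": pct.to_numpy(),
    })


def render_table(results: pd.DataFrame) -> str:
    """Printable model-comparison table (model, c (95% CI), Brier (SD), dc (%)).

    Values are rounded to three decimals; the base row shows ``--`` in the
    delta column.
    """
    header = f"{'Model':<16s} {'c (95% CI)':<24s} {'Brier (SD)':<16s} {'dc (%)':<18s}"
    lines = [header]
    for _, r in results.iterrows():
        c_txt = f"{r['c']:.3f} ({r['ci_low']:.3f}, {r['ci_high']:.3f})"
        b_txt = f"{r['brier']:.3f} ({r['brier_sd']:.3f})"
        if pd.isna(r["delta_c"]):
            d_txt = "--"
        else:
            d_txt = f"{r['delta_c']:.3f} ({r['pct_change_c']:.2f})"
        lines.append(f"{r['model']:<16s} {c_txt:<24s} {b_txt:<16s} {d_txt:<18s}")
    return "\n".join(lines)


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline; returns the manifest dictionary.

    Raises with the failing stage named; partial outputs stay on disk.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), 20))
    manifest: dict = {
        "seed": config.generator.seed,
        "config_sha256": _config_hash(config),
        "n_persons": config.generator.n_persons,
        "versions": {"numpy": np.__version__, "pandas": pd.__version__},
        "stages": {},
    }
    stage = "generate"
    try:
        t0 = time.perf_counter()
        bundle = generate_bundle(config.generator)
        bundle.to_csv(out / "bundle")
        manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        analysis_bundle = bundle.without_truth()
        comorbidity_year = config.generator.comorbidity_year
        outcome_year = config.generator.outcome_year

        descriptive_rows = []
        elix_tables = []
        for spec in config.cohort_specs():
            stage = f"cohort:{spec.label}"
            t0 = time.perf_counter()
            cohort = build_cohort(analysis_bundle, spec)
            logger.info("%s cohort: %d members", spec.label, len(cohort))
            variants = [("full", cohort)]
            if config.restrict_65plus:
                variants.append(("65plus", restrict_age(cohort, 65)))
            cohort.members.assign(label=spec.label).to_csv(
                out / f"cohort_{spec.label}.csv", index=False)
            manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

            for variant, sub in variants:
                tag = f"{spec.label}_{variant}"
                stage = f"score:{tag}"
                t0 = time.perf_counter()
                profiles = build_profiles(analysis_bundle, sub, comorbidity_year)
                profiles.to_csv(out / f"profiles_{tag}.csv", index=False)
                outcomes = derive_outcomes(analysis_bundle, sub, outcome_year)
                outcomes.to_csv(out / f"outcomes_{tag}.csv", index=False)
                manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

                descriptive_rows.append(
                    cohort_descriptives(sub, profiles, outcomes, variant))
                elix_tables.append(elixhauser_prevalence(profiles, sub, variant))

                stage = f"evaluate:{tag}"
                t0 = time.perf_counter()
                perf = evaluate_measures(tag, profiles, outcomes, sub.members,
                                         hl_groups=config.hl_groups,
                                         ci_level=config.ci_level)
                perf.to_csv(out / f"performance_{tag}.csv", index=False,
                            float_format="%.6g")
                with open(out / f"performance_{tag}.txt", "w") as fh:
                    for outcome in ("death", "hosp_ge1", "hosp_ge2"):
                        fh.write(f"== {outcome} ==\n")
                        fh.write(render_table(perf[perf["outcome"] == outcome]))
                        fh.write("\n")
                manifest["stages"][stage] = round(time.perf_counter() - t0, 3)

        stage = "report"
        pd.DataFrame(descriptive_rows).to_csv(
            out / "descriptives.csv", index=False, float_format="%.6g")
        pd.concat(elix_tables, ignore_index=True).to_csv(
            out / "elixhauser_prevalence.csv", index=False, float_format="%.6g")
    except Exception as exc:
        manifest["failed_stage"] = stage
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    checksums = {}
    for path in sorted(out.rglob("*.csv")):
        checksums[str(path.relative_to(out))] = hashlib.sha256(
            path.read_bytes()).hexdigest()
    manifest["output_sha256"] = checksums
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
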