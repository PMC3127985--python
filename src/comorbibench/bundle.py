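"""The linked claims bundle: five administrative tables plus generator truth.

Tables are plain pandas DataFrames keyed by ``person_id``:

``registry``
    person_id, birth_date, sex (F/M), region (urban/rural/missing),
    income_quintile (1..5/missing), death_date (may be missing).
``coverage``
    person_id, start, end -- health-insurance coverage intervals,
    non-overlapping and ordered within person.
``hospital``
    person_id, record_id, admission_date, separation_date, code, system
    (ICD9/ICD10), dx_type (most_responsible/comorbid/
    post_admission_complication); one row per recorded diagnosis.
``physician``
    person_id, service_date, code -- 3-character ICD-9 rubrics.
``drugs``
    person_id, dispense_date, ahfs_class (two-level, e.g. "08:12"),
    ingredient (may be empty).
``truth``
    Generator-internal latent condition flags and linear predictors; written
    with a ``truth_`` filename prefix and never consumed by analysis stages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

_DATE_COLS = {
    "registry": ["birth_date", "death_date"],
    "coverage": ["start", "end"],
    "hospital": ["admission_date", "separation_date"],
    "physician": ["service_date"],
    "drugs": ["dispense_date"],
    "truth": [],
}

DX_TYPES = ("most_responsible", "comorbid", "post_admission_complication")


class IntegrityError(ValueError):
    """Referential-integrity violation between bundle tables."""


@dataclass
class ClaimsBundle:
    registry: pd.DataFrame
    coverage: pd.DataFrame
    hospital: pd.DataFrame
    physician: pd.DataFrame
    drugs: pd.DataFrame
    truth: pd.DataFrame | None = field(default=None, repr=False)

    def _tables(self) -> dict[str, pd.DataFrame]:
        out = {"registry": self.registry, "coverage": self.coverage,
               "hospital": self.hospital, "physician": self.physician,
               "drugs": self.drugs}
        if self.truth is not None:
            out["truth"] = self.truth
        return out

    def validate(self) -> None:
        """Check referential integrity: no orphan person_ids in event tables."""
        known = set(self.registry["person_id"])
        for name in ("coverage", "hospital", "physician", "drugs"):
            table = getattr(self, name)
            if table.empty:
                continue
            orphans = set(table["person_id"]) - known
            if orphans:
                raise IntegrityError(
                    f"{name}: {len(orphans)} person_ids missing from registry "
                    f"(e.g. {sorted(orphans)[:3]})")

    def without_truth(self) -> "ClaimsBundle":
        return ClaimsBundle(self.registry, self.coverage, self.hospital,
                            self.physician, self.drugs, truth=None)

    def to_csv(self, directory: str | Path) -> None:
        """Write all tables as UTF-8 CSV with ISO-8601 dates."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, table in self._tables().items():
            fname = f"truth_flags.csv" if name == "truth" else f"{name}.csv"
            out = table.copy()
            for col in _DATE_COLS[name]:
                if col in out.columns:
                    out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
            out.to_csv(directory / fname, index=False)

    @classmethod
    def from_csv(cls, directory: str | Path) -> "ClaimsBundle":
        directory = Path(directory)
        frames: dict[str, pd.DataFrame] = {}
        for name in ("registry", "coverage", "hospital", "physician", "drugs"):
            df = pd.read_csv(directory / f"{name}.csv",
                             dtype={"code": str, "ahfs_class": str},
                             keep_default_na=False, na_values=[""])
            for col in _DATE_COLS[name]:
                if col in df.columns:
                    df[col] = pd.to_datetime(df[col])
            frames[name] = df
        truth_path = directory / "truth_flags.csv"
        truth = pd.read_csv(truth_path) if truth_path.exists() else None
        return cls(truth=truth, **frames)
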