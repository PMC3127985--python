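"""Condition mapping tables for diagnosis- and drug-based comorbidity measures.

Three coding algorithms ship as versioned CSV files under ``comorbibench/data``:

* ``charlson.csv`` -- the 17-condition Charlson index with integer weights
  (1, 2, 3 or 6) and the three hierarchy groups (diabetes, liver disease,
  malignancy) that prevent double counting of graded conditions.
* ``elixhauser.csv`` -- the 31 Elixhauser condition indicators.  File order
  defines the documented indicator order used everywhere downstream.
* ``cds.csv`` -- the Chronic Disease Score: 17 conditions inferred from
  two-level ("four-digit") AHFS drug classes, each scored 1-5 with tiers
  that escalate with the number of distinct dispensed classes.  The
  per-condition maxima sum to 35, the score's documented ceiling.

Diagnosis patterns are code prefixes on normalized codes (periods stripped,
upper case); ranges such as ``E10-E14`` are expanded to explicit prefixes at
load time, so matching is always ``code.startswith(prefix)``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from functools import lru_cache

import pandas as pd

SYSTEMS = ("ICD9", "ICD10")

_RANGE_RE = re.compile(r"^([A-Z]*)(\d+)-([A-Z]*)(\d+)$")


class MappingError(ValueError):
    """Raised when a bundled or user-supplied mapping table fails validation."""


def normalize_code(code: str) -> str:
    """Normalize a diagnosis code: strip periods and whitespace, upper-case."""
    return str(code).replace(".", "").replace(" ", "").upper()


def expand_range(pattern: str) -> list[str]:
    """Expand a code range like ``E10-E14`` or ``430-438`` into prefixes.

    Both endpoints must share their alphabetic prefix and have numeric parts
    of equal width; zero padding is preserved (``042-044`` -> 042, 043, 044).
    """
    m = _RANGE_RE.match(pattern)
    if m is None:
        raise MappingError(f"malformed range pattern: {pattern!r}")
    alpha_lo, num_lo, alpha_hi, num_hi = m.groups()
    if alpha_lo != alpha_hi or len(num_lo) != len(num_hi):
        raise MappingError(f"range endpoints incompatible: {pattern!r}")
    lo, hi = int(num_lo), int(num_hi)
    if hi < lo:
        raise MappingError(f"range is reversed: {pattern!r}")
    width = len(num_lo)
    return [f"{alpha_lo}{i:0{width}d}" for i in range(lo, hi + 1)]


@dataclass(frozen=True)
class ConditionMap:
    """A diagnosis-based condition mapping with optional weights and hierarchy.

    Attributes
    ----------
    name : str
        Short identifier ("charlson" or "elixhauser").
    conditions : tuple of str
        Condition categories in their fixed documented order.
    weights : dict
        condition -> integer weight; empty for weightless (Elixhauser) maps.
    prefixes : dict
        (system, condition) -> tuple of normalized code prefixes.
    hierarchy : tuple of (superior, inferior) pairs
        Flagging the superior condition suppresses the inferior's
        contribution to a summary score.
    """

    name: str
    conditions: tuple[str, ...]
    weights: dict[str, int]
    prefixes: dict[tuple[str, str], tuple[str, ...]]
    hierarchy: tuple[tuple[str, str], ...] = field(default_factory=tuple)

    def patterns_for(self, system: str, condition: str) -> tuple[str, ...]:
        return self.prefixes.get((system, condition), ())

    def example_code(self, condition: str, system: str) -> str | None:
        """A concrete code guaranteed to flag `condition` under `system`."""
        pats = self.patterns_for(system, condition)
        return pats[0] if pats else None

    def physician_code(self, condition: str) -> str | None:
        """A 3-character ICD-9 code that flags `condition`, if one exists.

        Physician claims carry only 3-digit ICD-9 rubrics, so a condition is
        reachable through the physician channel only when it has a pattern of
        three or fewer characters.
        """
        for p in self.patterns_for("ICD9", condition):
            if len(p) <= 3:
                return p.ljust(3, "0")
        return None


def _data_path(filename: str):
    return resources.files("comorbibench.data").joinpath(filename)


def _read_bundled_csv(filename: str) -> pd.DataFrame:
    with resources.as_file(_data_path(filename)) as path:
        return pd.read_csv(path, dtype=str, keep_default_na=False)


def _load_condition_map(filename: str, name: str) -> ConditionMap:
    df = _read_bundled_csv(filename)
    required = {"condition", "system", "pattern_type", "pattern", "weight",
                "hierarchy_group", "hierarchy_rank"}
    missing = required - set(df.columns)
    if missing:
        raise MappingError(f"{filename}: missing columns {sorted(missing)}")
    if (df["pattern"] == "").any():
        raise MappingError(f"{filename}: empty pattern")
    bad_sys = set(df["system"]) - set(SYSTEMS)
    if bad_sys:
        raise MappingError(f"{filename}: unknown coding systems {sorted(bad_sys)}")

    conditions = tuple(dict.fromkeys(df["condition"]))  # file order, de-duplicated
    prefixes: dict[tuple[str, str], list[str]] = {}
    for row in df.itertuples(index=False):
        pats = (expand_range(row.pattern) if row.pattern_type == "range"
                else [normalize_code(row.pattern)])
        if row.pattern_type not in ("prefix", "range"):
            raise MappingError(f"{filename}: unknown pattern_type {row.pattern_type!r}")
        prefixes.setdefault((row.system, row.condition), []).extend(pats)

    weights: dict[str, int] = {}
    for cond, grp in df.groupby("condition", sort=False):
        w = set(grp["weight"])
        if w == {""}:
            continue
        if len(w) != 1:
            raise MappingError(f"{filename}: inconsistent weight for {cond}")
        weights[cond] = int(w.pop())

    # A higher hierarchy_rank within a group suppresses every lower rank.
    hier: list[tuple[str, str]] = []
    ranked = (df[df["hierarchy_group"] != ""]
              .groupby("condition", sort=False)
              .agg(group=("hierarchy_group", "first"), rank=("hierarchy_rank", "first"))
              .reset_index())
    for _, grp in ranked.groupby("group"):
        ordered = grp.sort_values("rank", key=lambda s: s.astype(int))
        conds = list(ordered["condition"])
        for hi_idx in range(len(conds) - 1, 0, -1):
            for lo_idx in range(hi_idx):
                hier.append((conds[hi_idx], conds[lo_idx]))

    return ConditionMap(
        name=name,
        conditions=conditions,
        weights=weights,
        prefixes={k: tuple(v) for k, v in prefixes.items()},
        hierarchy=tuple(hier),
    )


@lru_cache(maxsize=None)
def load_charlson_map() -> ConditionMap:
    """The 17-condition Charlson map with weights in {1, 2, 3, 6}."""
    cmap = _load_condition_map("charlson.csv", "charlson")
    if len(cmap.conditions) != 17:
        raise MappingError(f"charlson map has {len(cmap.conditions)} conditions, expected 17")
    if not set(cmap.weights.values()) <= {1, 2, 3, 6}:
        raise MappingError("charlson weights must lie in {1, 2, 3, 6}")
    return cmap


@lru_cache(maxsize=None)
def load_elixhauser_map() -> ConditionMap:
    """The 31-condition Elixhauser map (weightless indicators)."""
    cmap = _load_condition_map("elixhauser.csv", "elixhauser")
    if len(cmap.conditions) != 31:
        raise MappingError(f"elixhauser map has {len(cmap.conditions)} conditions, expected 31")
    return cmap


@dataclass(frozen=True)
class CdsTable:
    """Chronic Disease Score lookup: AHFS class -> condition, with tier scores.

    ``tiers[condition]`` is a (one-class, two-class, three-plus) score triple;
    the score for a condition is the entry indexed by the number of distinct
    dispensed classes mapped to it (capped at the top tier).
    """

    conditions: tuple[str, ...]
    class_to_condition: dict[str, str]
    tiers: dict[str, tuple[int, int, int]]

    def score_for(self, condition: str, n_classes: int) -> int:
        if n_classes <= 0:
            return 0
        t = self.tiers[condition]
        return t[min(n_classes, 3) - 1]

    @property
    def max_total(self) -> int:
        return sum(t[-1] for t in self.tiers.values())


@lru_cache(maxsize=None)
def load_cds_table() -> CdsTable:
    df = _read_bundled_csv("cds.csv")
    conditions = tuple(dict.fromkeys(df["condition"]))
    if len(conditions) != 17:
        raise MappingError(f"CDS table has {len(conditions)} conditions, expected 17")
    class_to_condition: dict[str, str] = {}
    tiers: dict[str, tuple[int, int, int]] = {}
    for row in df.itertuples(index=False):
        if row.ahfs_class in class_to_condition:
            raise MappingError(f"AHFS class {row.ahfs_class} mapped twice")
        class_to_condition[row.ahfs_class] = row.condition
        tier = (int(row.score_1_class), int(row.score_2_classes),
                int(row.score_3plus_classes))
        if tiers.setdefault(row.condition, tier) != tier:
            raise MappingError(f"inconsistent tiers for {row.condition}")
    for cond, tier in tiers.items():
        if not all(1 <= s <= 5 for s in tier) or list(tier) != sorted(tier):
            raise MappingError(f"CDS tiers for {cond} must be non-decreasing in 1..5")
    table = CdsTable(conditions, class_to_condition, tiers)
    if table.max_total != 35:
        raise MappingError(f"CDS per-condition maxima sum to {table.max_total}, expected 35")
    return table


@lru_cache(maxsize=None)
def load_pregnancy_exclusions() -> dict[str, tuple[str, ...]]:
    """Per-system code prefixes flagging pregnancy, childbirth or abortion."""
    df = _read_bundled_csv("pregnancy_exclusions.csv")
    out: dict[str, list[str]] = {s: [] for s in SYSTEMS}
    for row in df.itertuples(index=False):
        pats = (expand_range(row.pattern) if row.pattern_type == "range"
                else [normalize_code(row.pattern)])
        out[row.system].extend(pats)
    return {s: tuple(v) for s, v in out.items()}


@lru_cache(maxsize=None)
def load_osteoprotective_drugs() -> tuple[frozenset[str], frozenset[str]]:
    """(ingredient labels, fallback AHFS two-level classes) for osteoporosis care."""
    df = _read_bundled_csv("osteoprotective_drugs.csv")
    return (frozenset(df["ingredient"].str.lower()),
            frozenset(df["ahfs_class"]))


def build_prefix_lookup(cmap: ConditionMap) -> dict[str, dict[int, dict[str, list[str]]]]:
    """Index a map for vectorized matching: system -> prefix length -> prefix -> conditions."""
    lookup: dict[str, dict[int, dict[str, list[str]]]] = {s: {} for s in SYSTEMS}
    for (system, condition), pats in cmap.prefixes.items():
        for p in pats:
            lookup[system].setdefault(len(p), {}).setdefault(p, []).append(condition)
    return lookup


def match_flags(events: pd.DataFrame, cmap: ConditionMap) -> pd.DataFrame:
    """Binary condition flags per person from a table of diagnosis events.

    Parameters
    ----------
    events : DataFrame with columns ``person_id``, ``code``, ``system``.
    cmap : ConditionMap

    Returns
    -------
    DataFrame indexed by person_id with one boolean column per condition,
    in the map's documented order.  Only persons with at least one matching
    event appear; absent persons implicitly carry all-false flags.
    """
    cols = list(cmap.conditions)
    if events.empty:
        return pd.DataFrame(columns=cols, dtype=bool).rename_axis("person_id")
    lookup = build_prefix_lookup(cmap)
    codes = events["code"].map(normalize_code)
    hits: list[pd.DataFrame] = []
    for system in SYSTEMS:
        sys_mask = events["system"].to_numpy() == system
        if not sys_mask.any():
            continue
        sys_codes = codes[sys_mask]
        persons = events.loc[sys_mask, "person_id"]
        for length, table in lookup[system].items():
            trunc = sys_codes.str.slice(0, length)
            matched = trunc.map(table)
            ok = matched.notna()
            if ok.any():
                sub = pd.DataFrame({"person_id": persons[ok].to_numpy(),
                                    "condition": matched[ok].to_numpy()})
                hits.append(sub.explode("condition"))
    if not hits:
        return pd.DataFrame(columns=cols, dtype=bool).rename_axis("person_id")
    allhits = pd.concat(hits, ignore_index=True)
    flags = (allhits.assign(v=True)
             .pivot_table(index="person_id", columns="condition", values="v",
                          aggfunc="any", fill_value=False))
    return flags.reindex(columns=cols, fill_value=False).astype(bool)
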