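"""Logistic risk models and the base-vs-full comorbidity comparison.

The modelling objects follow the Model/Results convention: a
:class:`ComorbidityModel` is built from a merged person-level table
(demographics + comorbidity profile + outcome), its :meth:`fit` returns a
:class:`ComorbidityModelResults` carrying coefficient estimates, fitted
probabilities, discrimination (c-statistic with its nonparametric CI) and
calibration (Brier score, Hosmer-Lemeshow) diagnostics, with a
``summary()`` table.

The *base* model adjusts for age, a quadratic age effect, sex, region of
residence and income quintile.  A *full* model adds exactly one comorbidity
measure: the diagnosis count, Charlson score, drug-class count and Chronic
Disease Score enter as single continuous columns; the Elixhauser index
enters as 31 separate indicator columns.  :class:`MeasureComparison` fits
the base model and all five full models per outcome and quantifies each
measure's added value (delta-c, percentage change in c, paired test on the
correlated c-statistics).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .measures import elix_columns
from .metrics import (brier, c_statistic, delong_ci, delong_paired_test,
                      hosmer_lemeshow)

__all__ = ["ModelSpec", "FitResult", "build_design_matrix", "fit_logistic",
           "ComorbidityModel", "ComorbidityModelResults",
           "MeasureComparison", "MeasureComparisonResults",
           "evaluate_measures", "COMORBIDITY_TERMS", "OUTCOMES",
           "SeparationError"]

logger = logging.getLogger(__name__)

OUTCOMES = ("death", "hosp_ge1", "hosp_ge2")
COMORBIDITY_TERMS = ("none", "n_diagnoses", "charlson", "elixhauser_31",
                     "n_drugs", "cds")

MODEL_LABELS = {
    "none": "Base model",
    "n_diagnoses": "+ # diagnoses",
    "charlson": "+ Charlson",
    "elixhauser_31": "+ Elixhauser",
    "n_drugs": "+ # drugs",
    "cds": "+ CDS",
}


class SeparationError(RuntimeError):
    """Perfect separation: a covariate fully determines the outcome."""


@dataclass(frozen=True)
class ModelSpec:
    """Outcome plus the single comorbidity term entering the full model."""

    outcome: str = "death"
    comorbidity_term: str = "none"

    def __post_init__(self) -> None:
        if self.outcome not in OUTCOMES:
            raise ValueError(f"unknown outcome {self.outcome!r}")
        if self.comorbidity_term not in COMORBIDITY_TERMS:
            raise ValueError(f"unknown comorbidity term {self.comorbidity_term!r}")

    @property
    def is_base(self) -> bool:
        return self.comorbidity_term == "none"

    @property
    def label(self) -> str:
        return MODEL_LABELS[self.comorbidity_term]


def build_design_matrix(data: pd.DataFrame, spec: ModelSpec
                        ) -> tuple[pd.DataFrame, list[str]]:
    """Numeric design matrix for one model.

    ``data`` is the merged person-level table with demographics
    (age_at_reference, sex, region, income_quintile) and the profile
    columns.  Reference levels: male, rural residence, income quintile 1;
    missing region/quintile are explicit categories.  Zero-variance columns
    are dropped with a logged warning (they arise in small cohorts, e.g.
    empty Elixhauser categories).

    Returns (X, dropped_columns).
    """
    if spec.outcome in data.columns:
        y = data[spec.outcome]
        if y.min() == y.max():
            raise ValueError(
                f"outcome {spec.outcome!r} is constant; refusing to fit")

    age = data["age_at_reference"].astype(float)
    X = pd.DataFrame(index=data.index)
    X["const"] = 1.0
    X["age"] = age
    X["age_sq"] = age ** 2
    X["sex_F"] = (data["sex"] == "F").astype(float)
    X["region_urban"] = (data["region"] == "urban").astype(float)
    X["region_missing"] = (data["region"] == "missing").astype(float)
    quintile = data["income_quintile"].astype(str)
    for q in ("2", "3", "4", "5"):
        X[f"quintile_{q}"] = (quintile == q).astype(float)
    X["quintile_missing"] = (quintile == "missing").astype(float)

    if spec.comorbidity_term == "elixhauser_31":
        for col in elix_columns():
            X[col] = data[col].astype(float)
    elif spec.comorbidity_term != "none":
        X[spec.comorbidity_term] = data[spec.comorbidity_term].astype(float)

    dropped: list[str] = []
    for col in list(X.columns):
        if col != "const" and X[col].nunique() <= 1:
            dropped.append(col)
            del X[col]
    if dropped:
        logger.warning("dropped zero-variance column(s): %s", dropped)
    return X, dropped


@dataclass
class FitResult:
    """Maximum-likelihood logistic fit: estimates, uncertainty, diagnostics."""

    params: pd.Series
    bse: pd.Series
    fitted: np.ndarray
    converged: bool
    n_iter: int
    dropped: list[str] = field(default_factory=list)
    llf: float = float("nan")


def fit_logistic(X: pd.DataFrame, y, maxiter: int = 100,
                 tol: float = 1e-8) -> FitResult:
    """Fit a logistic regression by maximum likelihood (Newton-Raphson).

    Collinear columns (beyond the zero-variance ones already pruned) are
    removed by QR pivoting before fitting.  Perfect separation raises
    :class:`SeparationError` naming the offending column.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary")
    if y.min() == y.max():
        raise ValueError("outcome is constant; cannot fit")

    Xv = X.to_numpy(dtype=float)
    rank_dropped: list[str] = []
    _, r = np.linalg.qr(Xv)
    diag = np.abs(np.diag(r))
    if (diag < 1e-10 * max(diag.max(), 1.0)).any():
        # greedy selection of an independent column subset, first-come order
        keep: list[int] = []
        basis = np.empty((Xv.shape[0], 0))
        for j in range(Xv.shape[1]):
            candidate = np.column_stack([basis, Xv[:, j]])
            if np.linalg.matrix_rank(candidate) > basis.shape[1]:
                keep.append(j)
                basis = candidate
        keep_mask = np.zeros(Xv.shape[1], dtype=bool)
        keep_mask[keep] = True
        rank_dropped = [c for c, k in zip(X.columns, keep_mask) if not k]
        logger.warning("dropped collinear column(s): %s", rank_dropped)
        X = X.loc[:, keep_mask]

    model = sm.GLM(y, X, family=sm.families.Binomial())
    try:
        import warnings
        from statsmodels.tools.sm_exceptions import PerfectSeparationWarning
        with np.errstate(all="ignore"), warnings.catch_warnings():
            # separation is detected and reported explicitly below
            warnings.simplefilter("ignore", PerfectSeparationWarning)
            res = model.fit(maxiter=maxiter, tol=tol)
    except Exception as exc:  # statsmodels PerfectSeparationError et al.
        if "separation" in str(exc).lower() or "Singular" in str(exc):
            col = _separating_column(X, y)
            raise SeparationError(
                f"perfect separation detected (offending column: {col})"
            ) from exc
        raise
    n_iter = len(res.fit_history.get("deviance", [])) - 1
    if not getattr(res, "converged", True):
        raise RuntimeError(
            f"logistic fit did not converge in {maxiter} iterations")
    fitted = np.asarray(res.predict(X))
    events = y == 1
    if fitted[events].min() > 1 - 1e-6 and fitted[~events].max() < 1e-6:
        col = _separating_column(X, y)
        raise SeparationError(
            f"perfect separation detected (offending column: {col})")
    return FitResult(params=res.params, bse=res.bse, fitted=fitted,
                     converged=True, n_iter=max(n_iter, 0),
                     dropped=rank_dropped, llf=float(res.llf))


def _separating_column(X: pd.DataFrame, y: np.ndarray) -> str:
    """Best-effort identification of a perfectly separating covariate."""
    yb = y.astype(bool)
    for col in X.columns:
        v = X[col].to_numpy()
        if col == "const":
            continue
        if v[yb].size and v[~yb].size and (v[yb].min() > v[~yb].max()
                                           or v[~yb].min() > v[yb].max()):
            return col
    return "<unidentified>"


class ComorbidityModel:
    """Logistic model of one outcome on demographics + one comorbidity term.

    Parameters
    ----------
    data : DataFrame
        Person-level table containing the outcome column, demographics and
        comorbidity profile columns (as produced by
        :func:`ComorbidityModel.from_tables`).
    outcome : {"death", "hosp_ge1", "hosp_ge2"}
    comorbidity_term : one of ``COMORBIDITY_TERMS``; "none" is the base model.
    """

    def __init__(self, data: pd.DataFrame, outcome: str = "death",
                 comorbidity_term: str = "none", hl_groups: int = 10,
                 ci_level: float = 0.95):
        self.spec = ModelSpec(outcome=outcome, comorbidity_term=comorbidity_term)
        self.data = data
        self.hl_groups = hl_groups
        self.ci_level = ci_level

    @classmethod
    def from_tables(cls, profiles: pd.DataFrame, outcomes: pd.DataFrame,
                    demographics: pd.DataFrame, **kwargs) -> "ComorbidityModel":
        """Assemble the person-level table from the three pipeline outputs."""
        data = (demographics.merge(profiles, on="person_id")
                .merge(outcomes, on="person_id"))
        return cls(data, **kwargs)

    def fit(self) -> "ComorbidityModelResults":
        X, dropped = build_design_matrix(self.data, self.spec)
        y = self.data[self.spec.outcome].to_numpy(dtype=float)
        fit = fit_logistic(X, y)
        fit.dropped = dropped + fit.dropped
        c, lo, hi = delong_ci(fit.fitted, y, level=self.ci_level)
        b, b_sd = brier(fit.fitted, y)
        try:
            hl_chi2, hl_df, hl_p = hosmer_lemeshow(fit.fitted, y,
                                                   groups=self.hl_groups)
        except ValueError:
            hl_chi2 = hl_df = hl_p = float("nan")
        return ComorbidityModelResults(
            model=self, fit=fit, y=y, c=c, ci95=(lo, hi), brier=b,
            brier_sd=b_sd, hl_chi2=hl_chi2, hl_df=hl_df, hl_p=hl_p,
            n_events=int(y.sum()))


@dataclass
class ComorbidityModelResults:
    """Fitted model with discrimination and calibration diagnostics."""

    model: ComorbidityModel
    fit: FitResult
    y: np.ndarray
    c: float
    ci95: tuple[float, float]
    brier: float
    brier_sd: float
    hl_chi2: float
    hl_df: float
    hl_p: float
    n_events: int

    @property
    def fittedvalues(self) -> np.ndarray:
        return self.fit.fitted

    @property
    def params(self) -> pd.Series:
        return self.fit.params

    @property
    def bse(self) -> pd.Series:
        return self.fit.bse

    @property
    def unstable(self) -> bool:
        """Fewer than 10 events: estimates reported but flagged unstable."""
        return self.n_events < 10

    def compare(self, base: "ComorbidityModelResults"
                ) -> tuple[float, float, float]:
        """(delta_c, pct change in c, DeLong p) against a base-model fit."""
        delta, _, p = delong_paired_test(base.fittedvalues, self.fittedvalues,
                                         self.y)
        return delta, 100.0 * delta / base.c, p

    def summary(self) -> str:
        spec = self.model.spec
        lines = [
            f"Logistic model: {spec.outcome} ~ base"
            + ("" if spec.is_base else f" + {spec.comorbidity_term}"),
            f"  n = {len(self.y)}, events = {self.n_events}"
            + ("  [unstable: < 10 events]" if self.unstable else ""),
            f"  c-statistic = {self.c:.3f} "
            f"({self.ci95[0]:.3f}, {self.ci95[1]:.3f})",
            f"  Brier = {self.brier:.3f} (SD {self.brier_sd:.3f})",
            f"  Hosmer-Lemeshow chi2({int(self.hl_df)}) = {self.hl_chi2:.2f},"
            f" p = {self.hl_p:.3f}",
            "  coefficients:",
        ]
        for name, est in self.fit.params.items():
            lines.append(f"    {name:<28s} {est:+10.4f}  "
                         f"(SE {self.fit.bse[name]:.4f})")
        if self.fit.dropped:
            lines.append(f"  dropped columns: {', '.join(self.fit.dropped)}")
        return "\n".join(lines)


class MeasureComparison:
    """Base model vs the five comorbidity-augmented models, per outcome."""

    def __init__(self, data: pd.DataFrame, outcomes=OUTCOMES,
                 hl_groups: int = 10, ci_level: float = 0.95):
        self.data = data
        self.outcomes = tuple(outcomes)
        self.hl_groups = hl_groups
        self.ci_level = ci_level

    @classmethod
    def from_tables(cls, profiles: pd.DataFrame, outcomes_table: pd.DataFrame,
                    demographics: pd.DataFrame, **kwargs) -> "MeasureComparison":
        data = (demographics.merge(profiles, on="person_id")
                .merge(outcomes_table, on="person_id"))
        return cls(data, **kwargs)

    def fit(self) -> "MeasureComparisonResults":
        rows = []
        fits: dict[tuple[str, str], ComorbidityModelResults] = {}
        for outcome in self.outcomes:
            base = ComorbidityModel(self.data, outcome, "none",
                                    self.hl_groups, self.ci_level).fit()
            fits[(outcome, "none")] = base
            rows.append(self._row(outcome, "none", base, None))
            for term in COMORBIDITY_TERMS[1:]:
                res = ComorbidityModel(self.data, outcome, term,
                                       self.hl_groups, self.ci_level).fit()
                fits[(outcome, term)] = res
                rows.append(self._row(outcome, term, res, base))
        table = pd.DataFrame(rows)
        return MeasureComparisonResults(comparison=self, table=table, fits=fits)

    @staticmethod
    def _row(outcome: str, term: str, res: ComorbidityModelResults,
             base: ComorbidityModelResults | None) -> dict:
        row = {
            "outcome": outcome, "term": term,
            "model": MODEL_LABELS[term],
            "c": res.c, "ci_low": res.ci95[0], "ci_high": res.ci95[1],
            "brier": res.brier, "brier_sd": res.brier_sd,
            "delta_c": np.nan, "pct_change_c": np.nan, "p_delong": np.nan,
            "hl_chi2": res.hl_chi2, "hl_p": res.hl_p,
            "n_events": res.n_events, "unstable": res.unstable,
        }
        if base is not None:
            row["delta_c"], row["pct_change_c"], row["p_delong"] = \
                res.compare(base)
        return row


@dataclass
class MeasureComparisonResults:
    """Tidy per-model performance table plus the underlying fits."""

    comparison: MeasureComparison
    table: pd.DataFrame
    fits: dict

    def best_term(self, outcome: str) -> str:
        """Comorbidity term with the largest c-statistic for an outcome."""
        sub = self.table[(self.table["outcome"] == outcome)
                         & (self.table["term"] != "none")]
        return sub.loc[sub["c"].idxmax(), "term"]

    def summary(self) -> str:
        from .pipeline import render_table
        parts = []
        for outcome in self.comparison.outcomes:
            sub = self.table[self.table["outcome"] == outcome]
            parts.append(f"== {outcome} ==")
            parts.append(render_table(sub))
        return "\n".join(parts)


def evaluate_measures(cohort_label: str, profiles: pd.DataFrame,
                      outcomes_table: pd.DataFrame,
                      demographics: pd.DataFrame,
                      hl_groups: int = 10, ci_level: float = 0.95
                      ) -> pd.DataFrame:
    """Fit 1 base + 5 full models per outcome; return the performance table.

    Convenience functional wrapper around :class:`MeasureComparison`.
    """
    res = MeasureComparison.from_tables(profiles, outcomes_table, demographics,
                                        hl_groups=hl_groups,
                                        ci_level=ci_level).fit()
    table = res.table.copy()
    table.insert(0, "cohort", cohort_label)
    return table
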