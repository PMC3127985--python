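"""Discrimination and calibration metrics for binary risk models.

Implements the c-statistic (area under the ROC curve) by the midrank
method, its nonparametric variance and the paired test for correlated
c-statistics via placement values, the Brier score with its per-person
standard deviation, the Hosmer-Lemeshow goodness-of-fit test over deciles
of predicted risk, and McNemar's test for paired binary outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["c_statistic", "delong_ci", "delong_paired_test", "brier",
           "hosmer_lemeshow", "mcnemar", "McNemarResult"]


def _check_binary(y: np.ndarray) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, (0, 1)).all():
        raise ValueError("outcome vector must be binary (0/1)")
    if y.min() == y.max():
        raise ValueError("outcome vector has a single class; the c-statistic "
                         "is undefined")
    return y.astype(bool)


def c_statistic(scores, y) -> float:
    """Probability that a random event outranks a random non-event.

    Computed from midranks; ties between a case and a control contribute
    one half, exactly as in the brute-force pair count.
    """
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    ranks = stats.rankdata(scores)
    m = int(y.sum())
    n = int((~y).sum())
    return float((ranks[y].sum() - m * (m + 1) / 2) / (m * n))


def _placements(scores: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """DeLong placement values (V10 per case, V01 per control), midrank ties."""
    cases, controls = scores[y], scores[~y]
    m, n = len(cases), len(controls)
    all_ranks = stats.rankdata(np.concatenate([cases, controls]))
    case_ranks = stats.rankdata(cases)
    control_ranks = stats.rankdata(controls)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    return v10, v01


def _delong_variance(scores: np.ndarray, y: np.ndarray) -> float:
    v10, v01 = _placements(scores, y)
    m, n = len(v10), len(v01)
    if m < 2 or n < 2:
        raise ValueError("DeLong variance requires at least 2 events and "
                         "2 non-events")
    return float(np.var(v10, ddof=1) / m + np.var(v01, ddof=1) / n)


def delong_ci(scores, y, level: float = 0.95) -> tuple[float, float, float]:
    """c-statistic with its normal-approximation confidence interval.

    The variance is the nonparametric placement-value estimator; the
    interval is truncated to [0, 1].  Perfectly separating scores have zero
    placement variance and yield a degenerate interval.
    """
    y = _check_binary(y)
    scores = np.asarray(scores, dtype=float)
    c = c_statistic(scores, y)
    var = _delong_variance(scores, y)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return c, max(0.0, c - half), min(1.0, c + half)


def delong_paired_test(scores_base, scores_full, y) -> tuple[float, float, float]:
    """Paired test of two correlated c-statistics on the same persons.

    Returns (delta_c, z, two-sided p) where delta_c = c_full - c_base.  When
    the two score vectors induce an identical ranking the variance of the
    difference is zero; a zero difference then yields p = 1.
    """
    y = _check_binary(y)
    sb = np.asarray(scores_base, dtype=float)
    sf = np.asarray(scores_full, dtype=float)
    if sb.shape != sf.shape or sb.shape != y.shape:
        raise ValueError("score vectors and outcome must share one length")

    vb10, vb01 = _placements(sb, y)
    vf10, vf01 = _placements(sf, y)
    m, n = len(vb10), len(vb01)
    c_base = float(np.mean(vb10))
    c_full = float(np.mean(vf10))
    delta = c_full - c_base

    s10 = np.cov(np.vstack([vf10, vb10]), ddof=1)
    s01 = np.cov(np.vstack([vf01, vb01]), ddof=1)
    var = ((s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m
           + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n)
    if var <= 0:
        if abs(delta) < 1e-15:
            return delta, 0.0, 1.0
        return delta, np.inf * np.sign(delta), 0.0
    z = delta / np.sqrt(var)
    p = 2 * stats.norm.sf(abs(z))
    return float(delta), float(z), float(p)


def brier(probabilities, y) -> tuple[float, float]:
    """Mean squared prediction error and the SD of per-person squared errors."""
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    if p.shape != y.shape:
        raise ValueError("probabilities and outcomes must share one length")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("probabilities must lie in [0, 1]")
    sq = (p - y) ** 2
    sd = float(np.std(sq, ddof=1)) if len(sq) > 1 else 0.0
    return float(sq.mean()), sd


def hosmer_lemeshow(probabilities, y, groups: int = 10
                    ) -> tuple[float, int, float]:
    """Hosmer-Lemeshow chi-square over groups of predicted risk.

    Persons are stably sorted by predicted probability and split into
    ``groups`` near-equal groups (boundary ties fall to the lower group by
    the stable ordering).  Returns (chi2, df, p) with df = groups - 2.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(p)
    if n < 2 * groups:
        raise ValueError(f"need at least {2 * groups} observations for "
                         f"{groups} groups")
    order = np.argsort(p, kind="stable")
    group_idx = np.minimum(np.arange(n) * groups // n, groups - 1)

    chi2 = 0.0
    for g in range(groups):
        sel = order[group_idx == g]
        n_g = len(sel)
        expected = p[sel].sum()
        observed = y[sel].sum()
        denom = expected * (1 - expected / n_g)
        if denom <= 0:
            raise ValueError(
                f"group {g} has zero expected-event variance; use fewer groups")
        chi2 += (observed - expected) ** 2 / denom
    df = groups - 2
    return float(chi2), df, float(stats.chi2.sf(chi2, df))


@dataclass(frozen=True)
class McNemarResult:
    chi2: float | None
    p: float | None
    n_discordant_ab: int    # outcome present in A only
    n_discordant_ba: int    # outcome present in B only
    status: str             # "ok", "exact", or "no_discordance"


def mcnemar(outcomes_a, outcomes_b, exact_threshold: int = 25) -> McNemarResult:
    """McNemar's test on paired binary outcomes for the same persons.

    Uses the uncorrected chi-square on the discordant counts, falling back
    to the exact binomial test when fewer than ``exact_threshold`` pairs are
    discordant.  With no discordant pairs the test is undefined.
    """
    a = np.asarray(outcomes_a).astype(bool)
    b_arr = np.asarray(outcomes_b).astype(bool)
    if a.shape != b_arr.shape:
        raise ValueError("paired outcome vectors must share one length")
    b = int((a & ~b_arr).sum())
    c = int((~a & b_arr).sum())
    if b + c == 0:
        return McNemarResult(None, None, b, c, "no_discordance")
    chi2 = (b - c) ** 2 / (b + c)
    if b + c < exact_threshold:
        p = stats.binomtest(b, b + c, 0.5).pvalue
        return McNemarResult(float(chi2), float(p), b, c, "exact")
    p = stats.chi2.sf(chi2, 1)
    return McNemarResult(float(chi2), float(p), b, c, "ok")
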