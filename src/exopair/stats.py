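"""Shared statistical primitives: BH adjustment, rank tests, chi-square,
Kaplan-Meier and log-rank.

These wrap scipy/statsmodels/lifelines behind the small surface the rest of
the package needs, with the tie-handling and exactness conventions fixed in
one place.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines.statistics import multivariate_logrank_test
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

log = logging.getLogger(__name__)


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (one family per call)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def rank_sum_test(x, y, exact_max_n: int = 20) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration when both groups have <= ``exact_max_n`` observations
    and there are no ties; otherwise the normal approximation with tie
    correction (no continuity correction).  Returns ``(U_statistic, p)``
    with U counted for the first sample.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if len(x) <= exact_max_n and len(y) <= exact_max_n and not has_ties:
        res = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
    else:
        res = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=False
        )
    return float(res.statistic), float(res.pvalue)


def kruskal_test(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction across >= 2 groups."""
    stat, p = sps.kruskal(*groups)
    return float(stat), float(p)


def chi_square_test(table) -> tuple[float, int, float, np.ndarray]:
    """Pearson chi-square without continuity correction.

    Returns (statistic, df, p, expected).  Raises on a zero row/column
    margin; warns when any expected count is below 5.
    """
    tab = np.asarray(table, dtype=float)
    if tab.shape[0] < 2 or tab.shape[1] < 2:
        raise ValueError("contingency table needs >= 2 rows and columns")
    if (tab.sum(axis=0) == 0).any() or (tab.sum(axis=1) == 0).any():
        raise ValueError("degenerate contingency table: zero row or column margin")
    stat, p, dof, expected = sps.chi2_contingency(tab, correction=False)
    if (expected < 5).any():
        log.warning("chi-square: %d expected counts below 5", int((expected < 5).sum()))
    return float(stat), int(dof), float(p), expected


def significance_stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


# ---------------------------------------------------------------------------
# censored-survival primitives
# ---------------------------------------------------------------------------


@dataclass
class KMCurve:
    """Product-limit survival estimate: step function S(t)."""

    times: np.ndarray       # distinct event times, ascending
    survival: np.ndarray    # S(t) just after each event time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def at(self, t: float) -> float:
        """S(t), right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def at_left(self, t: float) -> float:
        """S(t-), the left limit."""
        idx = np.searchsorted(self.times, t, side="left") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimate of S(t) from right-censored data."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]
    ev_times = np.unique(time[event == 1])
    n = len(time)
    surv, at_risk, n_ev = [], [], []
    s = 1.0
    for t in ev_times:
        r = int(np.sum(time >= t))
        d = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - d / r
        surv.append(s)
        at_risk.append(r)
        n_ev.append(d)
    return KMCurve(ev_times, np.array(surv), np.array(at_risk), np.array(n_ev))


def censoring_km(time, event) -> KMCurve:
    """KM estimate of the censoring distribution G(t) = P(C > t)."""
    event = np.asarray(event, dtype=int)
    return km_estimate(time, 1 - event)


def logrank_test(time, event, groups) -> tuple[float, int, float]:
    """k-sample log-rank test over shared risk sets.

    Returns (chi-square statistic, df = k-1, p).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = np.unique(groups)
    if len(labels) < 2:
        raise ValueError("log-rank test needs >= 2 groups")
    if event.sum() == 0:
        raise ValueError("log-rank test needs >= 1 event")
    res = multivariate_logrank_test(time, groups, event)
    return float(res.test_statistic), len(labels) - 1, float(res.p_value)


def km_by_group(time, event, groups) -> dict:
    """Per-group Kaplan-Meier curves keyed by group label."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    out = {}
    for lab in np.unique(groups):
        mask = groups == lab
        if mask.sum() == 0:
            raise ValueError(f"group {lab!r} has zero samples")
        out[lab] = km_estimate(time[mask], event[mask])
    return out
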