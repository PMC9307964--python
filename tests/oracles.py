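"""Independent brute-force oracles used to pin the fast implementations.

Everything here is written for clarity over speed and stays independent of
the code paths it checks: explicit loops, direct textbook formulas, and
exhaustive enumeration at small n.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import chi2 as chi2_dist
from scipy.stats import rankdata


def bh_oracle(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up: sort, scale by n/i, cumulative min."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(n)
    running = 1.0
    for rank_from_top in range(n, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, p[i] * n / rank_from_top)
        adj[i] = running
    return adj


def valid_pair_oracle(binary: np.ndarray, min_fraction: float) -> list[int]:
    """Row indices whose ones-count keeps both classes above the fraction."""
    keep = []
    n = binary.shape[1]
    for i, row in enumerate(binary):
        ones = int(sum(int(v) for v in row))
        if ones / n > min_fraction and (n - ones) / n > min_fraction:
            keep.append(i)
    return keep


def km_oracle(time, event) -> list[tuple[float, float]]:
    """Product-limit estimate: [(event_time, S(t)), ...]."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    out = []
    s = 1.0
    for t in sorted(set(time[event == 1])):
        at_risk = int(np.sum(time >= t))
        deaths = int(np.sum((time == t) & (event == 1)))
        s *= 1.0 - deaths / at_risk
        out.append((float(t), s))
    return out


def logrank_oracle(time, event, groups) -> tuple[float, int, float]:
    """k-sample log-rank via explicit risk sets and the full covariance."""
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    groups = np.asarray(groups)
    labels = sorted(set(groups.tolist()))
    k = len(labels)
    observed = np.zeros(k)
    expected = np.zeros(k)
    cov = np.zeros((k, k))
    for t in sorted(set(time[event == 1])):
        at_risk = time >= t
        big_n = int(at_risk.sum())
        d = int(((time == t) & (event == 1)).sum())
        if big_n <= 1:
            continue
        n_g = np.array([int((at_risk & (groups == lab)).sum()) for lab in labels], dtype=float)
        o_g = np.array(
            [int(((time == t) & (event == 1) & (groups == lab)).sum()) for lab in labels],
            dtype=float,
        )
        observed += o_g
        expected += d * n_g / big_n
        factor = d * (big_n - d) / (big_n - 1)
        for a in range(k):
            for b in range(k):
                delta = 1.0 if a == b else 0.0
                cov[a, b] += factor * (delta * n_g[a] * big_n - n_g[a] * n_g[b]) / big_n**2
    diff = (observed - expected)[: k - 1]
    stat = float(diff @ np.linalg.solve(cov[: k - 1, : k - 1], diff))
    p = float(chi2_dist.sf(stat, k - 1))
    return stat, k - 1, p


def chi_square_oracle(table) -> tuple[float, int, float]:
    """Pearson chi-square by the definition sum (O - E)^2 / E."""
    tab = np.asarray(table, dtype=float)
    total = tab.sum()
    stat = 0.0
    for i in range(tab.shape[0]):
        for j in range(tab.shape[1]):
            e = tab[i].sum() * tab[:, j].sum() / total
            stat += (tab[i, j] - e) ** 2 / e
    df = (tab.shape[0] - 1) * (tab.shape[1] - 1)
    return float(stat), df, float(chi2_dist.sf(stat, df))


def mannwhitney_u(x, y) -> float:
    """U statistic for x with the half-count tie convention."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def wilcoxon_exact_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided rank-sum p by enumerating all group assignments."""
    x = list(map(float, x))
    y = list(map(float, y))
    pooled = x + y
    n = len(x)
    u_obs = mannwhitney_u(x, y)
    center = len(x) * len(y) / 2.0
    count = 0
    total = 0
    for idx in combinations(range(len(pooled)), n):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        u = mannwhitney_u(xs, ys)
        total += 1
        if abs(u - center) >= abs(u_obs - center) - 1e-12:
            count += 1
    return u_obs, count / total


def auc_no_censoring_oracle(scores, time, event, horizon) -> float:
    """Cumulative/dynamic AUC with complete follow-up = the normalized
    Mann-Whitney statistic of the event-by-horizon indicator."""
    scores = np.asarray(scores, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    case = (time <= horizon) & (event == 1)
    control = time > horizon
    u = mannwhitney_u(scores[case], scores[control])
    return u / (case.sum() * control.sum())


def ssgsea_oracle(values, in_set_mask, alpha) -> float:
    """Hand-walked integrated running-sum enrichment score for one sample."""
    values = np.asarray(values, dtype=float)
    in_set_mask = np.asarray(in_set_mask, dtype=bool)
    n = len(values)
    ranks = rankdata(values)
    order = sorted(range(n), key=lambda i: -values[i])
    total_w = sum(ranks[i] ** alpha for i in order if in_set_mask[i])
    n_out = n - int(in_set_mask.sum())
    es = 0.0
    cum_in = 0.0
    cum_out = 0.0
    for i in order:
        if in_set_mask[i]:
            cum_in += ranks[i] ** alpha / total_w
        else:
            cum_out += 1.0 / n_out
        es += cum_in - cum_out
    return es
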