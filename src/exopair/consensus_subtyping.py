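"""Resampling-based consensus clustering and subtype characterization.

Monti-style consensus clustering: repeatedly subsample a fraction of the
samples, cluster each subsample with a base clusterer (agglomerative,
average linkage, 1 - Pearson correlation distance), and record how often
each sample pair lands in the same cluster among the replicates where both
were drawn.  The per-k consensus matrices are summarized by the empirical
CDF of their off-diagonal entries; the optimal k is taken at the delta-area
elbow of the CDF areas.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from exopair.data_io import ConsensusResult, PairMatrix, SurvivalTable
from exopair.stats import KMCurve, chi_square_test, km_by_group, logrank_test

log = logging.getLogger(__name__)

__all__ = ["consensus_cluster", "subtype_km_logrank", "subtype_category_test"]


def _sample_distance(x: np.ndarray, metric: str) -> np.ndarray:
    """Pairwise distance between sample columns of a features x samples matrix."""
    if metric == "pearson":
        xs = x - x.mean(axis=0, keepdims=True)
        sd = xs.std(axis=0)
        sd[sd == 0] = 1.0  # constant profile: define correlation 0 with everything
        z = xs / sd
        r = (z.T @ z) / x.shape[0]
        r = np.clip(r, -1.0, 1.0)
        d = 1.0 - r
        np.fill_diagonal(d, 0.0)
        return d
    if metric == "euclidean":
        sq = np.sum(x**2, axis=0)
        d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (x.T @ x), 0.0)
        d = np.sqrt(d2)
        np.fill_diagonal(d, 0.0)
        return d
    raise ValueError(f"unknown distance metric {metric!r}")


def _cut(dist: np.ndarray, k: int, method: str) -> np.ndarray:
    z = linkage(squareform(dist, checks=False), method=method)
    return fcluster(z, t=k, criterion="maxclust")


def consensus_cluster(
    features,
    k_max: int = 9,
    reps: int = 100,
    p_item: float = 0.8,
    seed: int = 0,
    k_min: int = 2,
    linkage_method: str = "average",
    distance: str = "pearson",
    delta_area_threshold: float = 0.1,
) -> ConsensusResult:
    """Consensus clustering of samples over k = k_min..k_max.

    ``features`` is a PairMatrix or a features x samples DataFrame.  Each of
    the ``reps`` replicates draws ``ceil(p_item * n)`` samples without
    replacement, clusters them hierarchically on the chosen distance, and
    for every k accumulates co-clustering and co-sampling counts.  The
    consensus entry (i, j) is the co-clustering count divided by the
    co-sampling count (0/0 -> 0, logged).  Final per-k assignments cluster
    1 - consensus hierarchically.  ``chosen_k`` is the largest k whose
    relative CDF-area gain exceeds ``delta_area_threshold``.
    """
    if isinstance(features, PairMatrix):
        df = features.values.astype(float)
    else:
        df = pd.DataFrame(features).astype(float)
    x = df.to_numpy()
    sample_ids = list(df.columns)
    n = len(sample_ids)
    if k_max >= n:
        raise ValueError(f"k_max ({k_max}) must be below the sample count ({n})")
    if reps < 2 and p_item < 1.0:
        raise ValueError("need reps >= 2 when subsampling")
    if np.allclose(x, x[:, :1]):
        log.warning("all samples identical: consensus clustering is degenerate")

    k_range = list(range(k_min, k_max + 1))
    rng = np.random.default_rng(seed)
    dist_full = _sample_distance(x, distance)
    m = math.ceil(p_item * n)
    co_sampled = np.zeros((n, n))
    connected = {k: np.zeros((n, n)) for k in k_range}
    for _ in range(reps):
        idx = np.sort(rng.choice(n, size=m, replace=False))
        sub = dist_full[np.ix_(idx, idx)]
        z = linkage(squareform(sub, checks=False), method=linkage_method)
        co_sampled[np.ix_(idx, idx)] += 1.0
        for k in k_range:
            labels = fcluster(z, t=k, criterion="maxclust")
            if len(np.unique(labels)) < k:
                log.info("replicate degenerated to %d clusters at k=%d",
                         len(np.unique(labels)), k)
            same = labels[:, None] == labels[None, :]
            connected[k][np.ix_(idx, idx)] += same

    never = co_sampled == 0
    np.fill_diagonal(never, False)
    if never.any():
        log.warning("%d sample pairs never co-sampled; consensus set to 0",
                    int(never.sum() // 2))
    consensus: dict[int, np.ndarray] = {}
    for k in k_range:
        with np.errstate(divide="ignore", invalid="ignore"):
            c = np.where(co_sampled > 0, connected[k] / co_sampled, 0.0)
        np.fill_diagonal(c, 1.0)
        consensus[k] = c

    cdf: dict[int, tuple[np.ndarray, np.ndarray]] = {}
    area: dict[int, float] = {}
    iu = np.triu_indices(n, k=1)
    for k in k_range:
        vals = np.sort(consensus[k][iu])
        xs = np.concatenate([[0.0], vals, [1.0]])
        ys = np.concatenate([[0.0], np.arange(1, len(vals) + 1) / len(vals), [1.0]])
        cdf[k] = (xs, ys)
        area[k] = float(np.sum(np.diff(xs) * ys[1:]))

    delta_area: dict[int, float] = {k_range[0]: area[k_range[0]]}
    for prev, k in zip(k_range, k_range[1:]):
        delta_area[k] = (area[k] - area[prev]) / area[prev] if area[prev] > 0 else 0.0
    exceed = [k for k in k_range if delta_area[k] > delta_area_threshold]
    chosen_k = max(exceed) if exceed else k_range[0]

    assignments: dict[int, pd.Series] = {}
    for k in k_range:
        labels = _cut(1.0 - consensus[k], k, linkage_method)
        assignments[k] = pd.Series(labels, index=sample_ids, name=f"k{k}")

    return ConsensusResult(
        k_range=k_range,
        sample_ids=sample_ids,
        consensus=consensus,
        cdf=cdf,
        area=area,
        delta_area=delta_area,
        chosen_k=chosen_k,
        assignments=assignments,
    )


def subtype_km_logrank(assignments: pd.Series, surv: SurvivalTable):
    """Per-subtype Kaplan-Meier curves plus the k-sample log-rank test.

    Returns ``(curves, statistic, df, p)`` where ``curves`` maps subtype
    label to a :class:`~exopair.stats.KMCurve`.
    """
    common = [s for s in assignments.index if s in set(surv.sample_ids)]
    if not common:
        raise ValueError("assignments and survival table share no samples")
    grp = assignments.loc[common].to_numpy()
    sub = surv.subset(common)
    time, event = sub.time.to_numpy(), sub.event.to_numpy()
    curves = km_by_group(time, event, grp)
    stat, df, p = logrank_test(time, event, grp)
    return curves, stat, df, p


def subtype_category_test(assignments: pd.Series, covariate: pd.Series):
    """Pearson chi-square of subtype membership against a categorical covariate.

    Returns ``(statistic, df, p, expected)`` on the aligned contingency
    table (no continuity correction; expected counts < 5 trigger a warning).
    """
    common = [s for s in assignments.index if s in set(covariate.index)]
    if not common:
        raise ValueError("assignments and covariate share no samples")
    table = pd.crosstab(assignments.loc[common], covariate.loc[common])
    return chi_square_test(table.to_numpy())
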