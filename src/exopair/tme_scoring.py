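"""Single-sample enrichment scoring and group-comparison statistics.

``ssgsea`` implements the integrated running-sum single-sample enrichment
statistic: per sample, genes are ranked by expression (average ranks for
ties), the in-set weighted ECDF (weights ``rank^alpha``) is walked down the
ranked list against the out-of-set uniform ECDF, and the enrichment score
is the sum of the running difference.  Because only within-sample ranks
enter, scores are exactly invariant to strictly increasing transforms of a
sample's expression vector.

``estimate_scores`` layers the stromal/immune/purity summary on top: the
two signature scores, their sum, and the published cosine calibration for
tumor purity (external constants, not derived here).
"""

from __future__ import annotations

import logging
from importlib import resources

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from exopair.data_io import ExpressionMatrix, GeneSetCollection, read_gmt
from exopair.stats import bh_adjust, kruskal_test, rank_sum_test, significance_stars

log = logging.getLogger(__name__)

__all__ = [
    "ssgsea",
    "estimate_scores",
    "group_compare",
    "load_fixture_gmt",
    "ESTIMATE_PURITY_INTERCEPT",
    "ESTIMATE_PURITY_SLOPE",
]

# Published ESTIMATE calibration for tumor purity as a function of the
# combined (stromal + immune) score.  External constants; they cannot be
# derived from anything in this package.
ESTIMATE_PURITY_INTERCEPT = 0.6049872018
ESTIMATE_PURITY_SLOPE = 0.0001467884


def load_fixture_gmt(name: str) -> GeneSetCollection:
    """Load a packaged GMT fixture (e.g. ``checkpoint_panel``,
    ``immune29_synthetic``, ``estimate_synthetic``)."""
    ref = resources.files("exopair") / "fixtures" / f"{name}.gmt"
    with resources.as_file(ref) as path:
        return read_gmt(path)


def _sample_es(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """Enrichment score of one sample: integrated running-sum statistic."""
    n = len(values)
    ranks = rankdata(values)          # ascending, average ties: top gene ~ n
    order = np.argsort(-values, kind="stable")
    member = in_set[order]
    w = ranks[order] ** alpha
    w_in = np.where(member, w, 0.0)
    denom_in = w_in.sum()
    n_out = n - member.sum()
    p_in = np.cumsum(w_in) / denom_in
    p_out = np.cumsum(~member) / n_out
    return float(np.sum(p_in - p_out))


def ssgsea(
    expr: ExpressionMatrix,
    sets: GeneSetCollection,
    alpha: float = 0.25,
    normalize: bool = False,
) -> pd.DataFrame:
    """Per-sample enrichment score of each gene set (samples x sets).

    Genes absent from the matrix are dropped from each set (logged); a set
    with no gene present scores NaN for every sample and the run continues.
    With ``normalize=True`` scores are min-max scaled across samples per
    set.
    """
    if expr.n_genes < 2:
        raise ValueError("ssgsea needs >= 2 genes")
    genes = expr.gene_ids
    gene_pos = {g: i for i, g in enumerate(genes)}
    x = expr.values.to_numpy(dtype=float)
    out = {}
    for name, members in sets.items():
        present = [g for g in members if g in gene_pos]
        if len(present) < len(members):
            log.info("set %r: dropped %d absent genes", name, len(members) - len(present))
        if not present:
            log.warning("set %r has no gene present in the matrix; scored NaN", name)
            out[name] = np.full(expr.n_samples, np.nan)
            continue
        if len(present) == len(genes):
            log.warning("set %r covers every gene; score undefined, scored NaN", name)
            out[name] = np.full(expr.n_samples, np.nan)
            continue
        in_set = np.zeros(len(genes), dtype=bool)
        in_set[[gene_pos[g] for g in present]] = True
        scores = np.array([_sample_es(x[:, j], in_set, alpha) for j in range(expr.n_samples)])
        out[name] = scores
    table = pd.DataFrame(out, index=expr.sample_ids)
    if normalize:
        rng_ = table.max() - table.min()
        rng_ = rng_.replace(0.0, 1.0)
        table = (table - table.min()) / rng_
    return table


def estimate_scores(
    expr: ExpressionMatrix,
    stromal_set,
    immune_set,
) -> pd.DataFrame:
    """Stromal, immune, combined and purity scores per sample.

    Stromal and immune scores are unnormalized single-sample enrichment
    scores of the two signatures; ``combined`` is their sum and ``purity``
    the published cosine calibration
    ``cos(0.6049872018 + 0.0001467884 * combined)``.  Purity values outside
    [0, 1] are flagged (``purity_in_calibration`` column).
    """
    stromal_genes = list(stromal_set)
    immune_genes = list(immune_set)
    gsc = GeneSetCollection({"stromal": stromal_genes, "immune": immune_genes})
    scores = ssgsea(expr, gsc, alpha=0.25, normalize=False)
    combined = scores["stromal"] + scores["immune"]
    purity = np.cos(ESTIMATE_PURITY_INTERCEPT + ESTIMATE_PURITY_SLOPE * combined)
    in_cal = (purity >= 0.0) & (purity <= 1.0)
    if not in_cal.all():
        log.warning("%d purity values outside [0, 1] (out of calibration range)",
                    int((~in_cal).sum()))
    return pd.DataFrame(
        {
            "stromal": scores["stromal"],
            "immune": scores["immune"],
            "combined": combined,
            "purity": purity,
            "purity_in_calibration": in_cal,
        },
        index=scores.index,
    )


def group_compare(table: pd.DataFrame, groups: pd.Series) -> pd.DataFrame:
    """Per-feature nonparametric comparison across groups with BH adjustment.

    ``table`` is features x samples (an expression panel, a score table
    transposed, or a compositional relative-abundance table).  Two groups
    use the Wilcoxon rank-sum test, three or more the Kruskal-Wallis test
    (tie-corrected).  Constant features get p = 1 (logged).  BH adjustment
    spans the features of this one call; stars encode significance at
    0.05 / 0.01 / 0.001.
    """
    common = [s for s in table.columns if s in set(groups.index)]
    if not common:
        raise ValueError("table and groups share no samples")
    grp = groups.loc[common]
    labels = sorted(grp.dropna().unique())
    if len(labels) < 2:
        raise ValueError("group_compare needs >= 2 groups")
    for lab in labels:
        if (grp == lab).sum() == 0:
            raise ValueError(f"group {lab!r} is empty")
    sub = table[common]
    rows = []
    for feat in sub.index:
        vals = sub.loc[feat].to_numpy(dtype=float)
        if np.all(vals == vals[0]):
            log.info("feature %r constant across samples; p = 1", feat)
            rows.append({"feature": feat, "statistic": 0.0, "pvalue": 1.0})
            continue
        parts = [vals[(grp == lab).to_numpy()] for lab in labels]
        if len(labels) == 2:
            stat, p = rank_sum_test(parts[0], parts[1])
        else:
            stat, p = kruskal_test(parts)
        rows.append({"feature": feat, "statistic": stat, "pvalue": p})
    out = pd.DataFrame(rows).set_index("feature")
    out["fdr"] = bh_adjust(out["pvalue"].to_numpy())
    out["stars"] = [significance_stars(p) for p in out["pvalue"]]
    return out
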