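"""Candidate-selection funnel: unit conversion, differential expression, and
the seed-mRNA / lncRNA co-expression screen.

The funnel mirrors the usual two-stage selection for "related lncRNAs":
first keep lncRNAs co-expressed with a seed mRNA panel (Pearson r > 0.4,
p < 0.001 against any panel member, computed on tumor samples), then keep
those that are differentially expressed between tumor and normal
(|log2 FC| > 1 at BH FDR < 0.05).  All thresholds are strict inequalities
and exposed as parameters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from exopair.data_io import ExpressionMatrix
from exopair.stats import bh_adjust

log = logging.getLogger(__name__)

__all__ = [
    "DEResult",
    "CoexpressionResult",
    "fpkm_to_tpm",
    "differential_expression",
    "coexpression_screen",
    "select_candidate_lncrnas",
]


@dataclass
class DEResult:
    """Per-gene tumor-vs-normal differential expression table.

    ``table`` columns: log2fc (tumor mean - normal mean on log2 scale),
    pvalue (Welch t), fdr (BH within this call), direction (up/down/ns).
    """

    table: pd.DataFrame
    lfc_threshold: float
    fdr_threshold: float

    @property
    def significant_genes(self) -> list[str]:
        mask = self.table["direction"] != "ns"
        return list(self.table.index[mask])


@dataclass
class CoexpressionResult:
    """Pearson r and p for every (seed mRNA, lncRNA) combination.

    ``r`` and ``p`` are seed-mRNA x lncRNA DataFrames; ``selected`` lists
    lncRNAs for which at least one combination passed both thresholds.
    Combinations skipped because a gene was constant hold NaN.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    selected: list[str]
    r_threshold: float
    p_threshold: float


def fpkm_to_tpm(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Rescale each sample so values sum to one million.

    TPM_g = FPKM_g / sum_g' FPKM_g' * 1e6, per sample.  Requires FPKM input
    and rejects samples whose values are all zero (the ratio is undefined).
    """
    if expr.scale != "FPKM":
        raise ValueError(f"fpkm_to_tpm requires FPKM input, got scale {expr.scale!r}")
    totals = expr.values.sum(axis=0)
    zero = totals[totals == 0]
    if len(zero):
        raise ValueError(f"all-zero FPKM sample(s): {list(zero.index)[:5]}")
    tpm = expr.values / totals * 1e6
    return ExpressionMatrix(tpm, "TPM", dict(expr.biotype))


def differential_expression(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
) -> DEResult:
    """Welch two-sample t-test per gene on log2(x+1) values, BH-adjusted.

    Both matrices must share gene IDs and have >= 2 samples per group.
    Genes with zero variance in both groups get p = 1 (logged); the log2
    fold change is tumor mean minus normal mean.  Direction is ``up`` iff
    log2fc > lfc_threshold and FDR < fdr_threshold (strict), symmetrically
    for ``down``.
    """
    genes = [g for g in tumor.gene_ids if g in set(normal.gene_ids)]
    if not genes:
        raise ValueError("tumor and normal matrices share no genes")
    if tumor.n_samples < 2 or normal.n_samples < 2:
        raise ValueError("differential expression needs >= 2 samples per group")
    xt = tumor.subset_genes(genes).log2_values().to_numpy()
    xn = normal.subset_genes(genes).log2_values().to_numpy()
    logfc = xt.mean(axis=1) - xn.mean(axis=1)
    tstat, pvals = sps.ttest_ind(xt, xn, axis=1, equal_var=False)
    flat = np.isnan(pvals)
    if flat.any():
        log.info("differential_expression: %d genes with zero variance in both groups "
                 "(p set to 1)", int(flat.sum()))
        pvals = np.where(flat, 1.0, pvals)
    fdr = bh_adjust(pvals)
    direction = np.where(
        (logfc > lfc_threshold) & (fdr < fdr_threshold),
        "up",
        np.where((logfc < -lfc_threshold) & (fdr < fdr_threshold), "down", "ns"),
    )
    table = pd.DataFrame(
        {"log2fc": logfc, "pvalue": pvals, "fdr": fdr, "direction": direction},
        index=pd.Index(genes, name="gene_id"),
    )
    return DEResult(table, lfc_threshold, fdr_threshold)


def _pearson_block(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r between rows of x and rows of y (shared columns).

    Rows with zero variance yield NaN (handled by the caller).
    """
    n = x.shape[1]
    xs = x - x.mean(axis=1, keepdims=True)
    ys = y - y.mean(axis=1, keepdims=True)
    xsd = xs.std(axis=1)
    ysd = ys.std(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (xs @ ys.T) / n / np.outer(xsd, ysd)
    r = np.clip(r, -1.0, 1.0)
    return r, np.full_like(r, n, dtype=float)


def coexpression_screen(
    lnc_expr: ExpressionMatrix,
    seed_mrna_expr: ExpressionMatrix,
    r_threshold: float = 0.4,
    p_threshold: float = 0.001,
    use_absolute_r: bool = False,
) -> CoexpressionResult:
    """Screen lncRNAs for co-expression with a seed mRNA panel.

    Pearson r on log2(x+1) values with a two-sided p from the t distribution
    on n-2 df, for every (seed mRNA, lncRNA) combination over shared
    samples.  A lncRNA is selected iff any combination satisfies
    r > r_threshold (or |r| with ``use_absolute_r``) and p < p_threshold,
    both strict.  Constant genes are skipped with a warning and can never
    be selected.
    """
    shared = [s for s in seed_mrna_expr.sample_ids if s in set(lnc_expr.sample_ids)]
    if len(shared) < 3:
        raise ValueError("co-expression screen needs >= 3 shared samples")
    xm = seed_mrna_expr.subset_samples(shared).log2_values().to_numpy()
    xl = lnc_expr.subset_samples(shared).log2_values().to_numpy()
    n = len(shared)
    r, _ = _pearson_block(xm, xl)
    if np.isnan(r).any():
        log.warning("coexpression_screen: constant gene(s) produced %d skipped combinations",
                    int(np.isnan(r).sum()))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    rmat = pd.DataFrame(r, index=seed_mrna_expr.gene_ids, columns=lnc_expr.gene_ids)
    pmat = pd.DataFrame(p, index=seed_mrna_expr.gene_ids, columns=lnc_expr.gene_ids)
    reff = np.abs(r) if use_absolute_r else r
    with np.errstate(invalid="ignore"):
        hit = (reff > r_threshold) & (p < p_threshold)
    hit = np.where(np.isnan(r), False, hit)
    selected = [g for g, any_hit in zip(lnc_expr.gene_ids, hit.any(axis=0)) if any_hit]
    return CoexpressionResult(rmat, pmat, selected, r_threshold, p_threshold)


def select_candidate_lncrnas(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    seed_mrna_ids,
    r_threshold: float = 0.4,
    p_threshold: float = 0.001,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    use_absolute_r: bool = False,
) -> tuple[list[str], CoexpressionResult, DEResult]:
    """Run the full funnel: co-expression screen on tumor samples, then
    differential expression of the surviving lncRNAs against normals.

    Returns the final candidate lncRNA list plus both intermediate results.
    """
    lnc_ids = tumor.genes_of_biotype("lncRNA")
    if not lnc_ids:
        raise ValueError("no lncRNAs annotated in the tumor matrix")
    seed_ids = [g for g in seed_mrna_ids if g in set(tumor.gene_ids)]
    if not seed_ids:
        raise ValueError("no seed mRNAs present in the tumor matrix")
    coexp = coexpression_screen(
        tumor.subset_genes(lnc_ids),
        tumor.subset_genes(seed_ids),
        r_threshold,
        p_threshold,
        use_absolute_r,
    )
    if not coexp.selected:
        log.warning("co-expression screen selected no lncRNAs")
        return [], coexp, None
    de = differential_expression(
        tumor.subset_genes(coexp.selected),
        normal.subset_genes([g for g in coexp.selected if g in set(normal.gene_ids)]),
        lfc_threshold,
        fdr_threshold,
    )
    return de.significant_genes, coexp, de
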