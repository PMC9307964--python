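"""Within-sample rank-pair encoding of lncRNA expression.

The core transform: for every unordered gene combination {A, B} (canonical
orientation A < B lexicographically) and every sample s, the indicator
S(A|B, s) = 1 iff expression(A, s) strictly exceeds expression(B, s), else 0
(ties give 0).  Because only within-sample orderings enter, the encoding is
exactly invariant to any strictly increasing per-sample transform — unit
changes, monotone normalizations, and monotone batch distortions all leave
it untouched.

A pair is "valid" (informative) when neither class is rare: the fraction of
ones must lie strictly inside (min_fraction, 1 - min_fraction).
"""

from __future__ import annotations

import logging
from typing import Sequence

import numpy as np
import pandas as pd

from exopair.data_io import ExpressionMatrix, PairMatrix, RiskModel

log = logging.getLogger(__name__)

__all__ = ["encode_pairs", "filter_valid_pairs", "score_new_samples"]


def _as_frame(expr) -> pd.DataFrame:
    if isinstance(expr, ExpressionMatrix):
        return expr.values
    return expr


def encode_pairs(expr, genes: Sequence[str] | None = None) -> PairMatrix:
    """Encode all n(n-1)/2 gene pairs of ``expr`` as binary indicators.

    ``genes`` optionally restricts and must all be present; genes are sorted
    lexicographically and pairs oriented A < B.  Strictly-greater rule: ties
    encode as 0.
    """
    df = _as_frame(expr)
    if genes is not None:
        missing = [g for g in genes if g not in df.index]
        if missing:
            raise KeyError(f"lncRNAs absent from matrix: {missing[:10]}")
        df = df.loc[list(genes)]
    gene_ids = sorted(df.index)
    n = len(gene_ids)
    if n < 2:
        raise ValueError(f"pair encoding needs >= 2 genes, got {n}")
    vals = df.loc[gene_ids].to_numpy(dtype=float)
    ia, ib = np.triu_indices(n, k=1)
    s = (vals[ia] > vals[ib]).astype(np.int8)
    pair_ids = [f"{gene_ids[i]}|{gene_ids[j]}" for i, j in zip(ia, ib)]
    return PairMatrix(pd.DataFrame(s, index=pair_ids, columns=df.columns))


def filter_valid_pairs(pm: PairMatrix, min_fraction: float = 0.20,
                       two_sided: bool = True) -> PairMatrix:
    """Keep informative pairs whose ones-fraction exceeds ``min_fraction``
    on both sides (strictly inside ``(min_fraction, 1 - min_fraction)``).

    With ``two_sided=False`` only the lower bound applies, but constant
    pairs (fraction 0 or 1) are always removed.  An empty result is allowed
    (warning logged).
    """
    frac = pm.ones_fraction.to_numpy()
    if two_sided:
        keep = (frac > min_fraction) & (frac < 1.0 - min_fraction)
    else:
        keep = (frac > min_fraction) & (frac < 1.0)
    kept = [p for p, k in zip(pm.pair_ids, keep) if k]
    if not kept:
        log.warning("filter_valid_pairs: no pair passed the validity filter")
        return PairMatrix(pm.values.iloc[:0].copy())
    return pm.subset_pairs(kept)


def score_new_samples(model, expr) -> PairMatrix:
    """Re-encode a model's pairs on new expression data.

    ``model`` is a RiskModel or an explicit list of pair IDs.  The stored
    pair orientation is respected (no re-canonicalization) and no validity
    refiltering happens — validity is a training-time concept.  Raises if
    any model gene is missing, listing all of them.
    """
    pair_ids = model.pairs if isinstance(model, RiskModel) else list(model)
    df = _as_frame(expr)
    needed = {g for pid in pair_ids for g in pid.split("|")}
    missing = sorted(g for g in needed if g not in df.index)
    if missing:
        raise KeyError(f"model lncRNAs absent from matrix: {missing}")
    rows = []
    for pid in pair_ids:
        a, b = pid.split("|")
        rows.append((df.loc[a].to_numpy(dtype=float) > df.loc[b].to_numpy(dtype=float)))
    s = np.asarray(rows, dtype=np.int8)
    return PairMatrix(pd.DataFrame(s, index=pair_ids, columns=df.columns))
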