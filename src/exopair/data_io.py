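"""Domain containers and file I/O.

The package works with four kinds of tabular inputs: gene-by-sample
expression matrices (TSV), per-sample survival/clinical tables (TSV),
gene-set collections (GMT), and binary pair-indicator matrices (TSV with a
JSON sidecar).  All containers validate their invariants on construction so
downstream modules can assume well-formed data.

Expression values carry an explicit ``scale`` tag (``FPKM``, ``TPM`` or
``LOG2``); nothing in the package ever converts units implicitly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

VALID_SCALES = ("FPKM", "TPM", "LOG2")
VALID_BIOTYPES = ("lncRNA", "mRNA", "other")

__all__ = [
    "ExpressionMatrix",
    "SurvivalTable",
    "GeneSetCollection",
    "PairMatrix",
    "RiskModel",
    "ConsensusResult",
    "read_expression",
    "write_expression",
    "read_gmt",
    "write_gmt",
    "read_survival",
    "write_survival",
    "read_pair_matrix",
    "write_pair_matrix",
    "align_cohort",
    "write_manifest",
]


class ParseError(ValueError):
    """A file violated its declared format."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with a declared unit scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene ID with sample IDs as columns.
    scale
        One of ``FPKM``, ``TPM``, ``LOG2``.
    biotype
        Mapping gene ID -> ``lncRNA`` | ``mRNA`` | ``other``.  Genes absent
        from the mapping are filled in as ``other``.
    """

    values: pd.DataFrame
    scale: str
    biotype: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise ValueError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        if self.values.index.duplicated().any():
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dupes[:5]}")
        if self.values.columns.duplicated().any():
            dupes = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dupes[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.scale in ("FPKM", "TPM") and (arr < 0).any():
            raise ValueError(f"negative values not allowed on {self.scale} scale")
        bt = dict(self.biotype)
        for g in self.values.index:
            t = bt.setdefault(g, "other")
            if t not in VALID_BIOTYPES:
                raise ValueError(f"invalid biotype {t!r} for gene {g!r}")
        self.biotype = bt

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def genes_of_biotype(self, biotype: str) -> list[str]:
        return [g for g in self.values.index if self.biotype[g] == biotype]

    def subset_genes(self, genes: Sequence[str]) -> "ExpressionMatrix":
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not in matrix: {missing[:10]}")
        return ExpressionMatrix(
            self.values.loc[list(genes)].copy(),
            self.scale,
            {g: self.biotype[g] for g in genes},
        )

    def subset_samples(self, samples: Sequence[str]) -> "ExpressionMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[list(samples)].copy(), self.scale, dict(self.biotype))

    def log2_values(self) -> pd.DataFrame:
        """Values on log2 scale: ``log2(x + 1)`` for linear scales, as-is for LOG2."""
        if self.scale == "LOG2":
            return self.values
        return np.log2(self.values + 1.0)


@dataclass
class SurvivalTable:
    """Per-sample follow-up time, event indicator, and clinical covariates.

    ``data`` is indexed by sample ID and must contain ``time`` and ``event``
    columns; any further columns are treated as covariates.  The time unit is
    carried as opaque metadata and never converted.
    """

    data: pd.DataFrame
    time_unit: str = "months"

    def __post_init__(self) -> None:
        for col in ("time", "event"):
            if col not in self.data.columns:
                raise ValueError(f"survival table missing required column {col!r}")
        if self.data.index.duplicated().any():
            raise ValueError("duplicate sample IDs in survival table")
        t = self.data["time"].to_numpy(dtype=float)
        if np.nanmin(t, initial=np.inf) < 0:
            raise ValueError("negative survival times")
        ev = self.data["event"].dropna().to_numpy(dtype=float)
        if not np.isin(ev, (0.0, 1.0)).all():
            raise ValueError("event indicator must be 0 or 1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def time(self) -> pd.Series:
        return self.data["time"].astype(float)

    @property
    def event(self) -> pd.Series:
        return self.data["event"].astype(int)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.data.drop(columns=["time", "event"])

    def subset(self, samples: Sequence[str]) -> "SurvivalTable":
        missing = [s for s in samples if s not in self.data.index]
        if missing:
            raise KeyError(f"samples not in survival table: {missing[:10]}")
        return SurvivalTable(self.data.loc[list(samples)].copy(), self.time_unit)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. immune signatures) as ``{name: [gene, ...]}``."""

    sets: dict[str, list[str]]

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    def __getitem__(self, name: str) -> list[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def names(self) -> list[str]:
        return list(self.sets)


@dataclass
class PairMatrix:
    """Binary pair-indicator matrix: ordered pairs ``"A|B"`` x samples.

    Each entry is 1 iff gene A's expression strictly exceeded gene B's in
    that sample.  The ones-fraction per pair is derived from the values and
    drives the validity filter.
    """

    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate pair IDs")
        arr = self.values.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("pair matrix entries must be 0 or 1")
        for pid in self.values.index:
            parts = pid.split("|")
            if len(parts) != 2 or parts[0] == parts[1]:
                raise ValueError(f"malformed pair ID {pid!r}")
        self.values = self.values.astype(np.int8)

    @property
    def pair_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def ones_fraction(self) -> pd.Series:
        return self.values.mean(axis=1)

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid in self.values.index:
            a, b = pid.split("|")
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def subset_pairs(self, pair_ids: Sequence[str]) -> "PairMatrix":
        missing = [p for p in pair_ids if p not in self.values.index]
        if missing:
            raise KeyError(f"pairs not in matrix: {missing[:10]}")
        return PairMatrix(self.values.loc[list(pair_ids)].copy())

    def subset_samples(self, samples: Sequence[str]) -> "PairMatrix":
        missing = [s for s in samples if s not in self.values.columns]
        if missing:
            raise KeyError(f"samples not in matrix: {missing[:10]}")
        return PairMatrix(self.values[list(samples)].copy())


@dataclass
class RiskModel:
    """A fitted pair-based Cox risk score: pairs, coefficients, cutoffs.

    The risk score of a sample is ``sum_i beta_i * S_i`` over the model
    pairs.  ``cutoffs`` maps an evaluation horizon (stringified, in the
    training table's time unit) to the Youden-optimal dichotomizing cutoff.
    """

    pairs: list[str]
    beta: list[float]
    cutoffs: dict[str, float] = field(default_factory=dict)
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.beta):
            raise ValueError("pairs and beta must have equal length")

    @property
    def genes(self) -> list[str]:
        seen: dict[str, None] = {}
        for pid in self.pairs:
            a, b = pid.split("|")
            seen.setdefault(a)
            seen.setdefault(b)
        return list(seen)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "pairs": self.pairs,
            "beta": self.beta,
            "cutoffs": self.cutoffs,
            "training_meta": self.training_meta,
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "RiskModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            pairs=list(payload["pairs"]),
            beta=[float(b) for b in payload["beta"]],
            cutoffs={str(k): float(v) for k, v in payload.get("cutoffs", {}).items()},
            training_meta=payload.get("training_meta", {}),
        )


@dataclass
class ConsensusResult:
    """Output of resampling consensus clustering over a range of k."""

    k_range: list[int]
    sample_ids: list[str]
    consensus: dict[int, np.ndarray]
    cdf: dict[int, tuple[np.ndarray, np.ndarray]]
    area: dict[int, float]
    delta_area: dict[int, float]
    chosen_k: int
    assignments: dict[int, pd.Series]

    def to_json(self, path: str | Path, matrix_decimals: int = 4) -> None:
        payload = {
            "k_range": self.k_range,
            "sample_ids": self.sample_ids,
            "chosen_k": self.chosen_k,
            "area": {str(k): self.area[k] for k in self.k_range},
            "delta_area": {str(k): self.delta_area[k] for k in self.k_range},
            "assignments": {
                str(k): [int(x) for x in self.assignments[k].to_numpy()] for k in self.k_range
            },
            "consensus": {
                str(k): np.round(self.consensus[k], matrix_decimals).tolist()
                for k in self.k_range
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv_strict(path: str | Path) -> pd.DataFrame:
    """Read a genes/pairs x samples TSV, raising on duplicate sample IDs and
    non-numeric cells (with the offending row/column named)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
    samples = header[1:]
    if len(set(samples)) != len(samples):
        dupes = sorted({s for s in samples if samples.count(s) > 1})
        raise ParseError(f"{path}: duplicate sample IDs in header: {dupes[:5]}")
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str, keep_default_na=False)
    raw.columns = samples  # preserve exact header (pandas would mangle dupes)
    probe = raw.apply(lambda c: pd.to_numeric(c, errors="coerce"))
    bad = probe.isna().to_numpy()
    if bad.any():
        i, j = map(int, np.argwhere(bad)[0])
        raise ParseError(
            f"{path}: non-numeric value {raw.iat[i, j]!r} at row {raw.index[i]!r}, "
            f"column {raw.columns[j]!r}"
        )
    # numpy's parser is correctly rounded (exact text round-trips), pandas' is not
    return pd.DataFrame(raw.to_numpy(dtype=np.float64), index=raw.index, columns=raw.columns)


def read_expression(
    path: str | Path,
    scale: str,
    biotype_path: str | Path | None = None,
) -> ExpressionMatrix:
    """Read a genes x samples TSV into a validated :class:`ExpressionMatrix`.

    Duplicate gene rows are collapsed by keeping the row with the highest
    mean expression (logged).  An optional two-column TSV
    (``gene_id<TAB>biotype``) supplies biotype annotation; genes without an
    entry default to ``other``.
    """
    num = _read_tsv_strict(path)
    if num.index.duplicated().any():
        means = num.mean(axis=1).to_numpy()
        best: dict[str, int] = {}
        for pos, g in enumerate(num.index):
            if g not in best or means[pos] > means[best[g]]:
                best[g] = pos
        n_dropped = len(num) - len(best)
        num = num.iloc[sorted(best.values())]
        log.info("collapsed %d duplicate gene rows (kept highest-mean row)", n_dropped)
    biotype: dict[str, str] = {}
    if biotype_path is not None:
        ann = pd.read_csv(biotype_path, sep="\t", dtype=str)
        if not {"gene_id", "biotype"} <= set(ann.columns):
            raise ParseError(f"{biotype_path}: needs columns gene_id, biotype")
        biotype = dict(zip(ann["gene_id"], ann["biotype"]))
    return ExpressionMatrix(num, scale, biotype)


def write_expression(em: ExpressionMatrix, path: str | Path) -> None:
    """Write the matrix as TSV at full float precision (round-trips exactly)."""
    df = em.values.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: per line ``name<TAB>description<TAB>gene...``.

    Descriptions are discarded; duplicate genes within a set are
    deduplicated preserving order.
    """
    sets: dict[str, list[str]] = {}
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: GMT line has fewer than 3 fields")
            name = fields[0]
            if name in sets:
                raise ParseError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes = list(dict.fromkeys(g for g in fields[2:] if g))
            sets[name] = genes
    if not sets:
        log.warning("GMT file %s contained no gene sets", path)
    return GeneSetCollection(sets)


def write_gmt(gsc: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in gsc.items():
            fh.write("\t".join([name, "na", *genes]) + "\n")


def read_survival(path: str | Path, time_unit: str = "months") -> SurvivalTable:
    """Read a clinical TSV with required columns sample_id, time, event."""
    df = pd.read_csv(path, sep="\t")
    if not {"sample_id", "time", "event"} <= set(df.columns):
        raise ParseError(f"{path}: needs columns sample_id, time, event")
    df = df.set_index("sample_id")
    return SurvivalTable(df, time_unit)


def write_survival(st: SurvivalTable, path: str | Path) -> None:
    df = st.data.copy()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_pair_matrix(path: str | Path) -> PairMatrix:
    num = _read_tsv_strict(path)
    return PairMatrix(num.astype(np.int8))


def write_pair_matrix(pm: PairMatrix, path: str | Path, sidecar: bool = True) -> None:
    """Write pairs x samples 0/1 TSV plus a JSON sidecar with ones-fractions."""
    df = pm.values.copy()
    df.index.name = "pair_id"
    df.to_csv(path, sep="\t")
    if sidecar:
        side = Path(str(path) + ".json")
        frac = {p: float(f) for p, f in pm.ones_fraction.items()}
        side.write_text(json.dumps({"ones_fraction": frac}, indent=2, sort_keys=True) + "\n")


# ---------------------------------------------------------------------------
# cohort alignment
# ---------------------------------------------------------------------------


def align_cohort(
    expr: ExpressionMatrix, surv: SurvivalTable
) -> tuple[ExpressionMatrix, SurvivalTable]:
    """Restrict both objects to shared samples with usable follow-up.

    Samples are kept in the expression matrix's order.  Samples with
    non-positive follow-up time or a missing event indicator are dropped
    (counts logged).  Raises if no sample survives.
    """
    common = set(expr.sample_ids) & set(surv.sample_ids)
    if not common:
        raise ValueError("expression and survival tables share no samples")
    ordered = [s for s in expr.sample_ids if s in common]
    sub = surv.data.loc[ordered]
    usable = (sub["time"].astype(float) > 0) & sub["event"].notna()
    n_dropped = int((~usable).sum())
    if n_dropped:
        log.info("align_cohort: dropped %d samples (time <= 0 or missing event)", n_dropped)
    kept = [s for s, ok in zip(ordered, usable) if ok]
    if not kept:
        raise ValueError("no samples with positive follow-up time remain")
    return expr.subset_samples(kept), surv.subset(kept)


def write_manifest(path: str | Path, entries: Mapping) -> None:
    """Write a deterministic run manifest (seeds, thresholds, versions)."""
    from exopair import __version__

    payload = {"exopair_version": __version__, **dict(entries)}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str) + "\n")
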