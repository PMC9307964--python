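"""Synthetic two-cohort study generator with planted ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at desk scale:

* log-scale expression with gene-specific baselines;
* "exosome-related" seed mRNAs and lncRNAs co-expressed with them through a
  shared one-factor model (loading ``lambda``), giving population Pearson
  correlation ``lambda^2 / (lambda^2 + sigma^2)`` between a seed mRNA and
  its partner lncRNA;
* tumor-vs-normal differential expression as an additive log2 shift
  ``delta`` on a subset of lncRNAs;
* survival driven by planted binary pair indicators through an exponential
  proportional-hazards model ``T ~ Exp(h0 * exp(sum beta_j S_j))`` with
  independent exponential censoring calibrated to a target censored
  fraction;
* a second cohort that differs from the first by a strictly monotone
  per-sample distortion of the expression values (emulating a batch/platform
  shift that within-sample rank encodings are invariant to).

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from exopair.data_io import ExpressionMatrix, PairMatrix, SurvivalTable

log = logging.getLogger(__name__)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedStudy",
    "simulate_expression",
    "simulate_survival",
    "apply_batch_distortion",
    "simulate_study",
]


@dataclass
class SimulationConfig:
    """Knobs of the synthetic study.

    Defaults describe the desk-scale study the package's tests and
    acceptance runs use: two cohorts of 300 tumor samples, 30 normals,
    40 seed mRNAs, 300 lncRNAs of which 30 are co-expressed with seed
    mRNAs (loading ``lambda_loading``) and 20 of those are differentially
    expressed; survival follows an exponential proportional-hazards model
    driven by 3 planted pair indicators with log-hazard ratio 1.
    """

    n_samples_per_cohort: int = 300
    n_normal: int = 30
    n_mrna_seed: int = 40
    n_lncrna: int = 300
    n_coexpressed: int = 30
    n_de: int = 20
    lambda_loading: float = 3.0
    delta_de: float = 3.0
    noise_sd: float = 1.0
    prob_de_up: float = 0.75
    background_mass: float = 2e6  # unmodeled library mass per sample (linear units)
    n_planted_pairs: int = 3
    beta_planted: float = 1.0
    planted_pairs: list[tuple[str, float]] | None = None
    baseline_hazard: float = 0.015  # per month; median survival ~46 months at eta=0
    censoring_rate: float = 0.30
    batch_distortion: dict = field(
        default_factory=lambda: {"a": (0.5, 2.0), "b": (0.8, 1.4), "c": (0.0, 5.0)}
    )
    time_unit: str = "months"
    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_samples_per_cohort": self.n_samples_per_cohort,
            "n_normal": self.n_normal,
            "n_mrna_seed": self.n_mrna_seed,
            "n_lncrna": self.n_lncrna,
            "n_coexpressed": self.n_coexpressed,
            "n_de": self.n_de,
            "n_planted_pairs": self.n_planted_pairs,
        }
        for name, v in counts.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.n_coexpressed > self.n_lncrna:
            raise ValueError("n_coexpressed cannot exceed n_lncrna")
        if self.n_de > self.n_lncrna:
            raise ValueError("n_de cannot exceed n_lncrna")
        if self.n_coexpressed and self.n_mrna_seed == 0:
            raise ValueError("co-expressed lncRNAs need at least one seed mRNA")
        if 2 * self.n_planted_pairs > min(self.n_de, self.n_coexpressed):
            raise ValueError("not enough DE co-expressed lncRNAs to host the planted pairs")
        if not (0.0 <= self.censoring_rate < 1.0):
            raise ValueError("censoring_rate must be in [0, 1)")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")


@dataclass
class GroundTruth:
    """What was planted: recoverable answers for every pipeline stage."""

    er_lncrnas: list[str]                    # co-expressed with a seed mRNA
    de_lncrnas: dict[str, str]               # lncRNA id -> "up" | "down"
    planted_pairs: list[tuple[str, float]]   # (pair_id "A|B", beta)
    factor_of_gene: dict[str, int]
    linear_predictor: dict[str, pd.Series] = field(default_factory=dict)

    def __post_init__(self) -> None:
        er = set(self.er_lncrnas)
        for pid, _ in self.planted_pairs:
            a, b = pid.split("|")
            if a not in er or b not in er:
                raise ValueError(f"planted pair {pid} uses genes outside the ER-lncRNA set")


@dataclass
class SimulatedStudy:
    """Two synthetic cohorts plus the planted truth."""

    tumor1: ExpressionMatrix
    normal1: ExpressionMatrix
    survival1: SurvivalTable
    tumor2: ExpressionMatrix
    normal2: ExpressionMatrix
    survival2: SurvivalTable
    truth: GroundTruth
    config: SimulationConfig


# ---------------------------------------------------------------------------
# structure (shared across cohorts, deterministic in config.seed)
# ---------------------------------------------------------------------------


def _structure(config: SimulationConfig) -> dict:
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    mrnas = [f"EXOM{i:04d}" for i in range(config.n_mrna_seed)]
    lncs = [f"LNC{i:04d}" for i in range(config.n_lncrna)]
    genes = mrnas + lncs
    mu = rng.uniform(2.0, 8.0, size=len(genes))
    coexpressed = lncs[: config.n_coexpressed]
    # factor assignment: seed mRNA j carries factor j; partner lncRNAs reuse them
    factor_of_gene = {g: j for j, g in enumerate(mrnas)}
    for i, g in enumerate(coexpressed):
        factor_of_gene[g] = i % config.n_mrna_seed

    # DE lncRNAs drawn from the co-expressed set first so the screening
    # funnel (co-expression then DE) has recoverable positives
    de_pool = coexpressed + [g for g in lncs if g not in coexpressed]
    de_lncs = de_pool[: config.n_de]

    if config.planted_pairs is not None:
        planted = list(config.planted_pairs)
    else:
        hosts = [g for g in de_lncs if g in coexpressed][: 2 * config.n_planted_pairs]
        planted = []
        for i in range(config.n_planted_pairs):
            a, b = sorted((hosts[2 * i], hosts[2 * i + 1]))
            planted.append((f"{a}|{b}", config.beta_planted))

    gene_pos = {g: i for i, g in enumerate(genes)}
    # planted pair members share a baseline so the indicator is informative
    # (ones-fraction near 0.5) and survives the validity filter
    for pid, _ in planted:
        a, b = pid.split("|")
        mu[gene_pos[b]] = mu[gene_pos[a]]
    # ...and share a DE direction so the tumor shift cancels within the pair
    de_sign = {}
    planted_genes = {g for pid, _ in planted for g in pid.split("|")}
    for g in de_lncs:
        if g in planted_genes:
            de_sign[g] = 1.0
        else:
            de_sign[g] = 1.0 if rng.random() < config.prob_de_up else -1.0

    biotype = {g: "mRNA" for g in mrnas}
    biotype.update({g: "lncRNA" for g in lncs})
    return {
        "genes": genes,
        "mrnas": mrnas,
        "lncs": lncs,
        "mu": mu,
        "coexpressed": coexpressed,
        "de_lncs": de_lncs,
        "de_sign": de_sign,
        "planted": planted,
        "factor_of_gene": factor_of_gene,
        "biotype": biotype,
    }


def _draw_cohort(
    config: SimulationConfig, struct: dict, n: int, tumor: bool, sample_ids: list[str], rng
) -> pd.DataFrame:
    genes = struct["genes"]
    vals = struct["mu"][:, None] + rng.normal(0.0, config.noise_sd, size=(len(genes), n))
    factors = rng.normal(0.0, 1.0, size=(config.n_mrna_seed, n))
    for g, j in struct["factor_of_gene"].items():
        vals[genes.index(g)] += config.lambda_loading * factors[j]
    if tumor:
        for g in struct["de_lncs"]:
            vals[genes.index(g)] += config.delta_de * struct["de_sign"][g]
    # log2 -> TPM: exponentiate and renormalize each sample to 1e6.  The
    # modeled panel is a small slice of a real library, so the denominator
    # includes a fixed background mass for the unmodeled transcriptome;
    # otherwise panel-level perturbations would recouple every gene through
    # the per-sample total.
    lin = np.exp2(vals)
    tpm = lin / (lin.sum(axis=0, keepdims=True) + config.background_mass) * 1e6
    return pd.DataFrame(tpm, index=genes, columns=sample_ids)


def simulate_expression(
    config: SimulationConfig, cohort: int = 1
) -> tuple[ExpressionMatrix, ExpressionMatrix, GroundTruth]:
    """Simulate tumor and normal expression for one cohort (TPM scale).

    The gene-level structure (baselines, co-expression wiring, DE genes,
    planted pairs) is shared by every cohort generated from the same config;
    samples are drawn independently per cohort.
    """
    struct = _structure(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 211, cohort]))
    tum_ids = [f"C{cohort}T{i:04d}" for i in range(config.n_samples_per_cohort)]
    nor_ids = [f"C{cohort}N{i:04d}" for i in range(config.n_normal)]
    tum = _draw_cohort(config, struct, len(tum_ids), True, tum_ids, rng)
    nor = _draw_cohort(config, struct, len(nor_ids), False, nor_ids, rng)
    truth = GroundTruth(
        er_lncrnas=list(struct["coexpressed"]),
        de_lncrnas={g: ("up" if struct["de_sign"][g] > 0 else "down") for g in struct["de_lncs"]},
        planted_pairs=list(struct["planted"]),
        factor_of_gene=dict(struct["factor_of_gene"]),
    )
    bt = struct["biotype"]
    return (
        ExpressionMatrix(tum, "TPM", dict(bt)),
        ExpressionMatrix(nor, "TPM", dict(bt)),
        truth,
    )


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def _calibrate_censoring_rate(event_rates: np.ndarray, target: float) -> float:
    """Find the exponential censoring rate c with E[censored fraction] = target.

    For independent exponentials, P(C < T | rate_s) = c / (c + rate_s); the
    expectation over samples is continuous and increasing in c, so bisection
    applies.
    """

    def f(c: float) -> float:
        return float(np.mean(c / (c + event_rates))) - target

    lo = float(event_rates.min()) * 1e-9
    hi = float(event_rates.max()) * 1e9
    return float(brentq(f, lo, hi, xtol=1e-12, rtol=1e-12))


def simulate_survival(
    pairs: PairMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
    cohort: int = 1,
) -> SurvivalTable:
    """Draw exponential PH survival times driven by the planted pair indicators.

    ``T ~ Exp(h0 * exp(sum beta_j S_j))``; censoring is an independent
    exponential whose rate is calibrated by root-finding so the expected
    censored fraction equals ``config.censoring_rate``.  Adds independent
    noise covariates (stage, grade, age) for downstream association tests.
    """
    if config.censoring_rate >= 1.0:
        raise ValueError("censoring_rate must be < 1")
    missing = [pid for pid, _ in truth.planted_pairs if pid not in pairs.values.index]
    if missing:
        raise KeyError(f"planted pairs absent from PairMatrix: {missing}")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 307, cohort]))
    samples = pairs.sample_ids
    eta = np.zeros(len(samples))
    for pid, beta in truth.planted_pairs:
        eta += beta * pairs.values.loc[pid].to_numpy(dtype=float)
    rates = config.baseline_hazard * np.exp(eta)
    t_event = rng.exponential(1.0 / rates)
    if config.censoring_rate == 0.0:
        time, event = t_event, np.ones(len(samples), dtype=int)
    else:
        c_rate = _calibrate_censoring_rate(rates, config.censoring_rate)
        t_cens = rng.exponential(1.0 / c_rate, size=len(samples))
        time = np.minimum(t_event, t_cens)
        event = (t_event <= t_cens).astype(int)
    stage = rng.choice(["I", "II", "III"], size=len(samples), p=[0.3, 0.4, 0.3])
    grade = rng.choice(["G1", "G2", "G3"], size=len(samples), p=[0.25, 0.5, 0.25])
    age = np.round(rng.normal(62.0, 8.0, size=len(samples)), 1)
    df = pd.DataFrame(
        {"time": time, "event": event, "stage": stage, "grade": grade, "age": age},
        index=pd.Index(samples, name="sample_id"),
    )
    truth.linear_predictor[f"cohort{cohort}"] = pd.Series(eta, index=samples)
    return SurvivalTable(df, config.time_unit)


# ---------------------------------------------------------------------------
# batch distortion
# ---------------------------------------------------------------------------


def apply_batch_distortion(
    expr: ExpressionMatrix, cohort_tag: str, config: SimulationConfig
) -> ExpressionMatrix:
    """Apply a strictly increasing per-sample transform ``x -> a*x^b + c``.

    Per-sample parameters are drawn from the ranges in
    ``config.batch_distortion`` (all requiring ``a > 0`` and ``b > 0``, so
    the map is strictly increasing on non-negative data and within-sample
    gene ranks are untouched).  ``cohort_tag`` seeds the parameter draw so
    distinct cohorts get distinct distortions.
    """
    ranges = config.batch_distortion
    a_lo, a_hi = ranges["a"]
    b_lo, b_hi = ranges["b"]
    c_lo, c_hi = ranges["c"]
    if a_lo <= 0 or b_lo <= 0:
        raise ValueError("distortion requires a > 0 and b > 0 (strict monotonicity)")
    if c_lo < 0:
        raise ValueError("distortion offset c must be >= 0 to preserve non-negativity")
    tag_seed = int(np.frombuffer(cohort_tag.encode().ljust(8, b"_")[:8], dtype=np.uint32)[0])
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 401, tag_seed]))
    n = expr.n_samples
    a = rng.uniform(a_lo, a_hi, size=n)
    b = rng.uniform(b_lo, b_hi, size=n)
    c = rng.uniform(c_lo, c_hi, size=n)
    x = expr.values.to_numpy(dtype=float)
    out = a[None, :] * np.power(x, b[None, :]) + c[None, :]
    return ExpressionMatrix(
        pd.DataFrame(out, index=expr.values.index, columns=expr.values.columns),
        expr.scale,
        dict(expr.biotype),
    )


# ---------------------------------------------------------------------------
# whole-study convenience
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig, distort_cohort2: bool = True) -> SimulatedStudy:
    """Generate the full two-cohort study: expression, survival, distortion.

    Cohort 2 shares the planted structure but has independent samples and,
    by default, a monotone per-sample batch distortion applied to both its
    tumor and normal matrices.
    """
    from exopair.pairing import encode_pairs

    tum1, nor1, truth = simulate_expression(config, cohort=1)
    tum2, nor2, _ = simulate_expression(config, cohort=2)
    planted_genes = sorted({g for pid, _ in truth.planted_pairs for g in pid.split("|")})
    surv1 = simulate_survival(encode_pairs(tum1, planted_genes), truth, config, cohort=1)
    surv2 = simulate_survival(encode_pairs(tum2, planted_genes), truth, config, cohort=2)
    if distort_cohort2:
        tum2 = apply_batch_distortion(tum2, "cohort2", config)
        nor2 = apply_batch_distortion(nor2, "cohort2_normal", config)
    return SimulatedStudy(tum1, nor1, surv1, tum2, nor2, surv2, truth, config)
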