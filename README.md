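# exopair

Rank-based lncRNA-pair prognostic signatures for cancer transcriptomics.

Cross-cohort prognostic models built on absolute expression values are
fragile: platform, normalization, and batch effects shift every gene's
measured level. A signature built instead on **within-sample gene-pair
orderings** sidesteps the problem entirely. For an ordered pair of lncRNAs
(A, B) and a sample *s*, define the indicator

```
S(A|B, s) = 1  if expr(A, s) > expr(B, s), else 0
```

Because S depends only on the ordering of two genes inside one sample, it is
exactly invariant to any strictly increasing per-sample transform — unit
changes (FPKM vs TPM), monotone normalizations, and monotone batch
distortions all leave it untouched. `exopair` implements the complete
analysis built on this primitive:

1. **Screening** — seed a panel of exosome-related mRNAs, keep lncRNAs
   co-expressed with at least one panel member (Pearson *r* > 0.4,
   *p* < 0.001, tumor samples), then keep those differentially expressed
   between tumor and normal (|log2 FC| > 1, BH FDR < 0.05).
2. **Pair encoding** — all n(n−1)/2 candidate pairs, keeping "valid"
   (informative) pairs whose ones-fraction lies strictly inside (0.2, 0.8).
3. **Molecular subtyping** — Monti resampling consensus clustering over the
   valid pair matrix (hierarchical base clusterer, 1 − Pearson distance),
   optimal k from the CDF delta-area elbow, Kaplan–Meier / log-rank and
   chi-square subtype characterization.
4. **Risk model** — univariate Cox screen (Wald *p* < 0.001) → repeated
   10-fold cross-validated LASSO-Cox with a selection-frequency vote →
   backward AIC-minimal multivariate Cox. The risk score is
   `sum_i beta_i * S_i`; cutoffs come from the Youden point of IPCW
   time-dependent ROC curves, and evaluation covers KM/log-rank, clinical
   association (chi-square, Wilcoxon), independence Cox models, and
   decision-curve analysis.
5. **TME scoring** — single-sample gene-set enrichment (integrated
   running-sum statistic, exponent α = 0.25), ESTIMATE-style
   stromal/immune/purity scores, and Kruskal–Wallis / Wilcoxon group
   comparisons for signature panels and compositional tables.

A first-class synthetic-data module generates two-cohort studies with
planted ground truth at every stage — co-expressed mRNA–lncRNA blocks,
differentially expressed lncRNAs, exponential proportional-hazards survival
driven by planted pair indicators, calibrated censoring, and a monotone
per-sample batch distortion between cohorts — so the whole pipeline is
testable without downloading any cohort.

## Worked example

```python
from exopair.synthetic_data import SimulationConfig, simulate_study
from exopair.screening import select_candidate_lncrnas
from exopair.pairing import encode_pairs, filter_valid_pairs, score_new_samples
from exopair.prognostic_model import (univariate_cox_screen, lasso_cox_select,
    stepwise_aic_cox, risk_score, time_dependent_roc, dichotomize_and_test)

study = simulate_study(SimulationConfig(seed=1))
cand, coexp, de = select_candidate_lncrnas(
    study.tumor1, study.normal1, study.tumor1.genes_of_biotype("mRNA"))
print(f"co-expressed lncRNAs: {len(coexp.selected)}; DE candidates: {len(cand)}")

pairs = filter_valid_pairs(encode_pairs(study.tumor1, cand))
print(f"valid pairs: {len(pairs.pair_ids)} of {len(cand) * (len(cand) - 1) // 2}")

uni = univariate_cox_screen(pairs, study.survival1, p_threshold=0.001)
flagged = list(uni.index[uni["selected"]])
sel = lasso_cox_select(pairs.subset_pairs(flagged), study.survival1, n_cycles=50, seed=1)
model = stepwise_aic_cox(pairs.subset_pairs(sel.selected), study.survival1)
for pid, beta in zip(model.pairs, model.beta):
    print(f"model pair {pid}: beta = {beta:+.3f}")

scores = risk_score(model, pairs)
roc = time_dependent_roc(scores, study.survival1, horizon=12.0)
print(f"1-year AUC (training) = {roc.auc:.3f}, Youden cutoff = {roc.cutoff:.3f}")

val_scores = risk_score(model, score_new_samples(model, study.tumor2))
labels, _, stat, p = dichotomize_and_test(val_scores, roc.cutoff, study.survival2)
print(f"validation log-rank: chi2 = {stat:.1f}, p = {p:.3g}")
```

Output:

```
co-expressed lncRNAs: 30; DE candidates: 20
valid pairs: 130 of 190
model pair LNC0000|LNC0001: beta = +1.144
model pair LNC0002|LNC0003: beta = +1.077
model pair LNC0004|LNC0005: beta = +0.810
1-year AUC (training) = 0.763, Youden cutoff = 1.144
validation log-rank: chi2 = 72.1, p = 2.08e-17
```

The three recovered pairs are exactly the planted ones
(`study.truth.planted_pairs`), with coefficients near the planted
log-hazard ratio of 1 (the mild shrinkage toward ~0.8 marginally is the
usual non-collapsibility attenuation of Cox models). The cutoff learned on
cohort 1 cleanly separates cohort 2, which differs by a monotone per-sample
distortion — the rank encoding makes the transfer exact.

## Command-line interface

Each stage is also exposed as a subcommand of `exopair` (`simulate`,
`screen`, `pair`, `cluster`, `fit`, `evaluate`, `tme`, `read-check`), and
`exopair run --config config.yaml --out out/` drives the whole pipeline —
screen, pair, cluster, fit, validate — from a single YAML file whose keys
mirror every threshold above. `cluster` and `evaluate` accept `--plots` to
emit consensus-CDF, ROC, and KM figures. All
randomized stages take an explicit `--seed` and write a run manifest next
to their outputs; reruns with the same inputs are byte-identical.

```sh
exopair simulate --config sim.yaml --out data/
exopair screen --tumor data/cohort1_tumor.tsv --normal data/cohort1_normal.tsv \
    --biotype data/biotype.tsv --seed-genes seeds.txt --out screen/
exopair pair --expr data/cohort1_tumor.tsv --genes screen/candidates.tsv --out pairs.tsv
exopair fit --pairs pairs.tsv --surv data/cohort1_survival.tsv --seed 7 --out model.json
exopair evaluate --model model.json --expr data/cohort2_tumor.tsv \
    --surv data/cohort2_survival.tsv --out eval/
```

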