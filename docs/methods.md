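# Methods

This note documents the models, conventions, and design choices behind
`exopair`, and what the synthetic-data tests do and do not establish about
real data.

## The pair encoding and its invariance

The primitive is the binary indicator `S(A|B, s) = [expr(A, s) > expr(B, s)]`
for an ordered lncRNA pair and a sample. "Higher than" is strict; ties
encode as 0. With continuous expression ties are measure-zero, but
integer-rounded or thresholded inputs make the tie rule load-bearing, so it
is fixed and tested. Pairs are canonically oriented A < B
(lexicographically) at encoding time; a fitted model stores its pairs'
orientation explicitly and `score_new_samples` honors it without
re-canonicalizing.

Because S uses only the within-sample ordering of two genes, it is exactly
invariant to any strictly increasing per-sample transform. This is the
package's substitute for explicit batch correction: instead of adjusting
cohorts toward each other, the encoding is provably unaffected by monotone
per-sample distortions, and that invariance is asserted bit-exactly in the
tests rather than assumed.

**Validity filter.** A pair is informative only if neither class is rare.
The filter keeps pairs whose ones-fraction lies strictly inside
`(0.2, 0.8)`. The two-sided reading is deliberate: a one-sided rule would
retain constant-1 pairs that carry no ordering information. Both the
threshold and the sidedness are parameters. The boundary is exclusive:
a fraction of exactly 0.2 or 0.8 is removed.

## Screening funnel

* **FPKM → TPM**: per sample, `TPM_g = FPKM_g / sum(FPKM) * 1e6`. Column
  sums equal 1e6 to numerical tolerance; all-zero samples are an error.
* **Co-expression screen** (tumor samples): Pearson r on `log2(x+1)`
  between every seed mRNA and every lncRNA, two-sided p from the
  t-distribution on n−2 df. A lncRNA is kept iff any seed-mRNA combination
  has r > 0.4 and p < 0.001 (strict). Positive r only by default — the
  screen looks for co-expression, not anti-correlation; `use_absolute_r`
  exposes the alternative. Constant genes are skipped with a warning.
* **Differential expression**: Welch's two-sample t-test per gene on
  `log2(x+1)`, BH adjustment across all tested genes as one family,
  direction assigned at |log2 FC| > 1 and FDR < 0.05 (strict). This is a
  deliberately standard, documented test; moderated/empirical-Bayes
  variants are out of scope. Zero-variance-in-both-groups genes get p = 1
  (logged), not an error.

The funnel order is co-expression first, then differential expression of
the survivors — the second stage's BH family is therefore the co-expressed
set only.

## Synthetic study generator

The generator is the package's ground truth and its defaults define the
study conditions used throughout the tests and the acceptance script.

* **Expression** (log2 scale): gene g, sample s has
  `mu_g + lambda * F + delta_g * [tumor] + eps`, with `mu_g ~ U(2, 8)`,
  `eps ~ N(0, sigma^2)` (`sigma = 1`), and F a standard-normal factor shared
  between each seed mRNA and its co-expressed lncRNAs (`lambda = 3`). The
  one-factor model gives the closed-form population correlation
  `lambda^2 / (lambda^2 + sigma^2) = 0.9` that the screen-recovery tests
  check against.
* **Differential expression**: `delta = 3` log2 units on 20 of the 30
  co-expressed lncRNAs (75% up). The gene-level sd under the factor model
  is `sqrt(lambda^2 + sigma^2) ~ 3.2`, so a shift must sit several sd above
  the screen's log2 FC > 1 threshold for the planted genes to be reliably
  recoverable; 3 (8-fold, unremarkable for lncRNAs) leaves the funnel's
  power concentrated where the method's claims are, in the pair machinery.
* **TPM conversion**: values are exponentiated and renormalized per sample
  against the modeled panel **plus a fixed background library mass**
  (2e6 linear units). The modeled 340 genes are a tiny slice of a real
  library; without the background term the panel would dominate its own
  denominator and per-sample renormalization would recouple all genes and
  bias fold changes.
* **Survival**: exponential proportional hazards,
  `T ~ Exp(h0 * exp(sum beta_j S_j))` with `h0 = 0.015`/month (median ~46
  months at baseline) and three planted pairs at `beta = 1`. Planted pair
  members share a baseline mean and load different factors, so their
  indicator has a ones-fraction near 0.5 and survives the validity filter —
  planting an effect on a pair the filter would discard would make recovery
  ill-posed. Censoring is an independent exponential whose rate is solved
  by root-finding so the expected censored fraction equals the 30% target;
  the Cox machinery never sees any of this structure.
* **Batch distortion**: cohort 2 receives `x -> a_s * x^b_s + c_s` with
  per-sample parameters drawn from positive ranges — strictly increasing on
  non-negative data, hence exactly rank-preserving. Survival for cohort 2 is
  drawn from its pair indicators before distortion; since the encoding is
  distortion-invariant this choice is immaterial, and the tests verify it.

**What the generator does not emulate**: read-count noise (negative
binomial), library-size artifacts, probe-level effects, real marginal
distributions of any cohort, correlated censoring, or time-varying hazards.
Passing tests establish that the pipeline recovers the structure it is
designed to detect under its stated model — not that a particular public
cohort would yield a particular signature.

## Consensus clustering

Monti-style resampling: each of 100 replicates draws `ceil(0.8 * n)`
samples without replacement (features are never subsampled), clusters them
with average-linkage agglomerative hierarchical clustering on
`1 − Pearson` distance between sample profiles, and for each k in 2..k_max
accumulates co-clustering and co-sampling counts. Consensus(i, j) is their
ratio (never-co-sampled pairs are 0 with a warning; at 100 replicates and
80% sampling this is vanishingly rare). Per-k assignments come from
hierarchically clustering `1 − consensus`.

The CDF of the upper-triangle consensus values is summarized by its area
A(k); `delta_area(k) = (A(k) − A(k−1)) / A(k−1)` with A(k_min) as its own
baseline. The chosen k is the largest k whose delta-area exceeds a
threshold (default 0.1) — an explicit, reproducible elbow instead of a
visual call; the full CDF/area table is emitted so a human can override.
Base clusterer, linkage, and distance are parameters; the defaults are the
method's conventional ones. Samples with a constant profile are assigned
zero correlation with everything rather than NaN.

## Risk model

* **Univariate screen**: one Cox fit per pair (single binary covariate),
  hand-rolled Newton iterations on the Breslow partial likelihood with a
  centered covariate for stability. Wald p against HR = 1; candidates at
  p < 0.001 (strict). Diverging fits (|beta| > 20 — e.g. complete
  separation) are dropped with a warning rather than reported.
* **Repeated CV-LASSO**: each cycle draws fresh 10-fold assignments, fits
  the L1 Cox path (scikit-survival's Coxnet), and scores each penalty by
  the Verweij–van Houwelingen cross-validated partial-likelihood deviance
  `−2 (ll(all; beta) − ll(train; beta))`. The per-cycle penalty follows the
  **one-standard-error rule** (sparsest penalty within one SE of the
  minimum mean deviance); `lambda_rule="min"` is available. The 1-SE
  default is deliberate: at the exact minimizer, pairs that are merely
  correlated with a true pair enter with selection frequency ~1, the
  frequency vote cannot remove them, and the downstream AIC step inherits
  selection-inflated effects. Pairs selected in more than 50% of cycles
  (default) survive. The cycle count is configuration-scaled: 50 is the
  desk default used by the tests and the acceptance script; the repeated
  resampling converges long before that for candidate sets of this size.
* **Backward AIC**: starting from the full multivariate Cox fit
  (lifelines), iteratively remove the covariate whose removal most
  decreases `AIC = −2 logPL + 2p`, stopping when no removal helps; the
  empty model (null partial likelihood) is a legal endpoint. Non-convergent
  fits retry with a small ridge penalty (logged).
* **Tie handling**: the hand-rolled partial likelihood uses Breslow's
  approximation; lifelines' multivariate fits use Efron's. Simulated event
  times are continuous, so ties are measure-zero and the two coincide; with
  heavily tied real data the multivariate coefficients would follow Efron.

## Evaluation

* **Time-dependent ROC**: cumulative-case / dynamic-control estimator at a
  horizon t. Cases (event by t) are weighted by `1 / G(T−)`, where G is the
  Kaplan–Meier estimate of the censoring survival function; controls
  (at risk past t) carry the constant weight `1 / G(t)`, which cancels.
  AUC by trapezoid over the threshold staircase (vertical risers are
  area-free by lexicographic point ordering). With no censoring the AUC
  reduces exactly to the tie-corrected Mann–Whitney statistic of the
  event-by-horizon indicator — the oracle that pins the implementation.
  The cutoff maximizes Youden's J = sensitivity + specificity − 1, ties
  broken toward the lower score; samples exactly at the cutoff are
  low-risk (`high` iff score strictly > cutoff).
* **Group tests**: Pearson chi-square without continuity correction
  (expected counts < 5 warn); two-sided Wilcoxon rank-sum, exact by
  enumeration for tie-free groups of ≤ 20, otherwise the normal
  approximation with tie correction and no continuity correction (which
  makes the two-group Kruskal–Wallis identity H = z² exact);
  Kruskal–Wallis with tie correction for ≥ 3 groups; BH across the features
  of one call.
* **Independence Cox**: univariate models per term plus one multivariate
  model of score + covariates, complete cases only, categorical covariates
  ordinal-encoded in sorted level order. Rank-deficient designs refit with
  a small ridge penalty (warning).
* **Decision curves**: the binary outcome is event-by-horizon (samples
  censored before the horizon are excluded and logged). The continuous
  score maps to a risk probability through an unpenalized logistic fit of
  the outcome on the score; net benefit at threshold p_t is
  `TP/n − FP/n * p_t/(1 − p_t)` for "treat iff risk > p_t", with treat-all
  and treat-none references.

## Single-sample enrichment and purity

`ssgsea` is the integrated running-sum variant: genes ranked per sample
(average ranks for ties), in-set genes weighted by `rank^alpha`
(`alpha = 0.25`, the statistic's canonical exponent) and normalized within
the set, walked against the uniform out-of-set ECDF; the score is the sum
of the running difference, not the maximum deviation. Scores are exactly
invariant to strictly increasing transforms of a sample's vector. Optional
per-set min-max normalization across samples is off by default. A set with
no gene present scores NaN and the run continues.

ESTIMATE-style scores are the unnormalized enrichment scores of a stromal
and an immune signature; `combined` is their sum and
`purity = cos(0.6049872018 + 0.0001467884 * combined)` — published external
calibration constants, recorded as such and not derivable from anything in
this package. Purity values outside [0, 1] are flagged as out of the
calibration's range. The packaged 29-signature immune panel and
stromal/immune signature fixtures carry **synthetic placeholder gene
memberships** (filenames say so); users supply real GMT collections for
real analyses. The immune-checkpoint panel (PDCD1, CTLA4, HAVCR2, LAG3) is
a real gene list.

## Numerical conventions and degenerate inputs

* All thresholds are strict inequalities exactly as stated above.
* Every randomized operation takes an explicit integer seed; CLI stages
  write a manifest (seeds, thresholds, version) and are byte-reproducible.
* Duplicate gene rows on input collapse to the highest-mean row (logged).
* Cohort alignment drops samples with non-positive follow-up or missing
  event indicators (logged) and is idempotent.
* Time units are opaque metadata; ROC horizons are given in the survival
  table's unit (the synthetic study uses months, horizons 12/24/36/48).
* Parsing uses numpy's correctly-rounded float reader so written matrices
  round-trip bit-exactly.

## Problem sizes

The test suite and acceptance script run at desk scale, chosen so every
stochastic check has clear margins: two cohorts of 300 tumor samples
(30 normals), 340 modeled genes, 20 candidate lncRNAs giving ~130 valid
pairs, 50 LASSO cycles, 100 consensus replicates, and 10–200 seed
replicates per stochastic assertion. Scaling the generator up is a config
change; none of the algorithms holds state that depends on these sizes.

## Known limitations

* The generator's exponential baseline hazard cannot probe departures from
  proportional hazards.
* Recovery claims are conditional on the generator's model (see above);
  the screening thresholds' real-data operating characteristics depend on
  cohort size and correlation structure not emulated here.
* The backward-AIC step inherits whatever selection bias survives the
  1-SE LASSO vote; coefficients of retained extras are not de-biased.
* No deconvolution backends, pathway-variation scoring, drug-response
  prediction, or external-cohort retrieval; compositional tables are
  compared feature-wise only.
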