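# Methods

## Problem setting

Tertiary lymphoid structures (TLS) are organized lymphoid aggregates inside
tumors whose presence predicts favorable prognosis and response to immune
checkpoint blockade (ICB). `tlsmeta` implements a transcriptomic pipeline
for TLS gene signatures: per-sample signature scoring, per-cohort effect
estimation against ICB response and overall survival, cross-cohort
meta-analysis, de novo signature discovery by a meta-analyzed log-odds
cutoff sweep, and validation on held-out cohorts and on spatial
transcriptomics spot grids. Because real multi-cohort ICB compendia cannot
ship with a package, a synthetic generator with a planted TLS program
provides ground truth for every stage.

## Per-sample scores

**Z-scoring.** Each gene row is standardized to mean 0, SD 1 using the
population SD convention (`ddof=0`). Constant rows cannot be standardized;
they become all-zero rows and are flagged (`attrs["constant_genes"]` plus a
warning) rather than dropped, so matrix shapes stay aligned.

**Single-sample enrichment (`gsva_like_score`).** A deterministic score in
the ssGSEA family. For one sample, genes are ordered by decreasing z-value;
ties are broken by lexicographic gene symbol, which makes the score
invariant to the input row order. Walking down the list, a running sum
gains `|z|^tau / sum_in-set |z|^tau` at in-set genes and loses `1/(G - m)`
at out-of-set genes (`G` genes total, `m` in the set). The enrichment score
is the "maxdiff" statistic: the largest positive plus the smallest negative
deviation of the walk, bounded in [-1, 1]. Defaults: `tau = 1`.
Degenerate cases are pinned down explicitly: a set covering every gene
scores +1 (there is no out-of-set pool to walk through), and if every
in-set `|z|` is exactly zero the increments fall back to `1/m`. We chose
this fully specified rank statistic over GSVA's kernel-CDF dialect because
it has no density-estimation freedom, admits an exhaustive running-sum
oracle in the tests, and — being a monotone set-activity summary — supports
the same downstream inferences.

**COX-IS.** The log2 ratio of pro-tumor (CP: VEGFA, CCL2, IL8/CXCL8, CXCL1,
CXCL2, CSF3, IL6, IL1B, IL1A) over anti-tumor (CI: CCL5, CXCL9, CXCL10,
CXCL11, IL12A, IL12B, IFNG, CD8A, CD8B, GZMA, GZMB, EOMES, PRF1, STAT1,
TBX21) inflammatory gene expression. Input log2(x+1) values are mapped back
to linear scale (`2^x - 1`), averaged within each list, and combined as
`log2((mean_CP + eps) / (mean_CI + eps))` with `eps = 1e-6`. The score is 0
when both axes are equally expressed and is invariant to global
multiplicative rescaling of linear expression (up to `eps`). Symbols are
matched with a small alias table (IL8 <-> CXCL8) and hyphen stripping
(ICAM-1 -> ICAM1).

**TMB.** Nonsynonymous mutations (missense + frameshift indels + stop
codons) per megabase; the default territory is 38 Mb (whole-exome).
Synonymous and other classes are excluded.

**Median stratification.** `high` strictly above the median, `low`
otherwise; assigning ties to `low` is an arbitrary but fixed convention,
and an all-constant input warns.

## Per-cohort effects

**Responder rule.** CR/PR are responders, PD non-responders; SD is a
responder unless a progression event occurred within 6 months; SD with
missing PFS is non-assessable and excluded from response models and AUCs.
Without RECIST the 6-month PFS rule decides alone. A patient censored for
PFS before 6 months while SD counts as a responder — the window is simply
event-free at face value.

**Cox.** Univariate proportional-hazards fit maximizing the Breslow-ties
partial likelihood by Newton–Raphson with step halving; the covariate is
centered for numerical stability (the estimate is location-invariant); the
SE is the inverse observed information. Breslow was chosen because it
admits a transparent brute-force likelihood oracle; with no tied event
times it coincides with Efron, which is how the implementation is
cross-checked against lifelines. Non-convergence is flagged on the result,
never silent.

**Logistic.** Univariate ML fit by IRLS (intercept + slope; the slope is
the log odds ratio per covariate unit). If IRLS diverges or the information
matrix degenerates — typical under quasi-separation in small ICB cohorts —
the model is refit with Jeffreys-prior (Firth) penalization, which is
always finite, and the result is flagged (`converged=False`,
`method="firth"`).

**AUC and DeLong.** AUC is the Mann–Whitney statistic divided by
`n_R * n_NR` with ties counted 0.5. Paired AUC differences use DeLong's
covariance of midrank placements with a two-sided normal test; a degenerate
variance with zero difference returns p = 1, with a nonzero difference it
is an error rather than a fabricated p-value.

**Group comparisons.** Continuous data use the Wilcoxon rank-sum test when
both groups have >= 10 observations, otherwise a permutation test of the
rank-sum statistic (exact enumeration up to 50,000 assignments, else seeded
Monte-Carlo with the observed assignment included in the count).
Categorical data route to Fisher's exact test. Two-sided p-values
throughout.

**Kaplan–Meier / log-rank.** Median split of the score (ties to low),
product-limit curves and the standard 1-df log-rank test via lifelines.

## Meta-analysis

Fixed-effect pooling uses inverse-variance weights `w_k = 1/s_k^2`;
DerSimonian–Laird adds the moment estimate

    Q    = sum w_k (theta_k - theta_fixed)^2
    tau2 = max(0, (Q - (K-1)) / (sum w - sum w^2 / sum w))

to every study variance before reweighting. The overall effect is tested
with a normal z-test (no Knapp–Hartung adjustment), matching the common
`metagen` reporting style. tau2 truncates at 0, so the random-effects SE is
never below the fixed-effects SE. Both models are exposed side by side;
subgroup pooling (hot vs cold immune context, or cancer type) pools each
subgroup independently. Multiple testing uses Benjamini–Hochberg, one
family per (outcome x model x subgroup) analysis.

## Signature discovery

Candidates with >50% zero expression in any discovery cohort are excluded
(exactly 50% is kept; cohorts lacking the gene do not count against it).
For each surviving gene, expression is z-scored within each cohort, a
univariate logistic model against responder status is fit per cohort, and
the log odds ratios are pooled by DerSimonian–Laird (fixed-effect
available); BH-FDR is computed across genes. Genes are ranked by signed
pooled logOR — the sweep "from 0 up" is only meaningful on the positive
scale, so negatively associated genes are reported but never included.
At each cutoff `c` in [0, 0.5] step 0.005 (101 cutoffs), the signature is
`{genes: pooled logOR >= c}`; each nonempty signature is scored in every
discovery cohort and its mean response AUC recorded; the selected cutoff
maximizes that mean, ties resolved toward the larger cutoff (smaller
signature). Validation runs only on cohorts disjoint from discovery — an
overlap is a hard error — and reports per-cohort AUC, DeLong comparisons
against competitor signatures, a Cox fit of the score against OS, and
median-split KM curves.

Per-cohort (rather than pooled) z-scoring was chosen because ICB cohorts
come from different platforms and normalization pipelines; within-cohort
standardization is the only version that is invariant to cohort-level
location/scale batch effects.

## Spatial evaluation

Spot expression is z-scored across spots and each spot receives the
enrichment score of the signature. Detection is summarized as the
spot-level AUC with positives = all annotated TLS spots (mature or
immature); treating immature spots as negatives instead would inflate
mature-sample AUCs and was rejected. TLS-negative samples have one class
only and carry a missing AUC instead of raising. Summaries report
min/median/max AUC per sample-level maturity group.

## Synthetic data

The generator is the package's study design, not a test fixture.

* **Latent structure.** Each patient has a TLS-program activity
  `a ~ N(0,1)`. Signature genes read `baseline + loading_g * a + noise` on
  the log2(x+1) scale (clipped at 0); loadings are Uniform(0.8, 1.5), i.e.
  per-gene correlations with the program of roughly 0.6–0.8 at the default
  `noise_sd = 1`, the coherence one sees in curated immune signatures.
  A 10-gene decoy module shares its own latent factor but is unlinked to
  outcome, so co-expression alone cannot identify the program; remaining
  genes are independent noise with per-gene baselines Uniform(1.5, 6), a
  small fraction centered below zero so they clip to >50% zeros and
  exercise the zero-expression filter.
* **Outcomes.** Response ~ Bernoulli(logistic(alpha_k + gamma * a)) with
  cohort intercepts alpha_k (default -0.5, ~38% prevalence — published ICB
  response rates cluster between 20 and 40% and vary by cohort, so the
  intercept is an exposed knob rather than a constant).
  OS is exponential with hazard `lambda * exp(delta * a)`,
  `lambda = 0.04/month` (median ~17 months at average activity), censored
  uniformly on [0, 2/lambda], giving ~30–50% censoring. RECIST is drawn
  consistently with the responder rule — responders among CR/PR/SD without
  an early event, non-responders among PD/SD with one — so classification
  exactly inverts the generator; RECIST is never missing in simulated data
  for that reason.
* **Spatial.** Full spot grids with non-overlapping disks (bounded retry
  placement); inside disks the signature genes rise by `effect` (mature) or
  `effect/3` (immature); `negative` samples place nothing.
* **Mutations.** Nonsynonymous totals are lognormal with median
  `mean_tmb * territory`, split ~75/12/13% across missense / frameshift /
  stop; synonymous and other counts scale with the load.
* **Determinism.** Every generator takes a mandatory seed and uses a single
  private `default_rng` stream; no global RNG state is touched. Identical
  arguments give byte-identical outputs.

What the generator does **not** emulate: count noise and dropout of real
scRNA data, library-size variation, platform batch effects, correlated
survival/response beyond the single shared latent factor, and clinical
covariates (age, stage). Passing tests therefore demonstrate correctness of
the algorithms and calibration of the inference under a clean single-factor
world; they do not certify performance on real ICB cohorts.

## Benchmark problem sizes

The discovery benchmark simulates 10 discovery cohorts of 120 patients and
5 validation cohorts of 100 (about 1,700 patients total) with 15 planted
genes among 74 candidates in a 300-gene universe — the scale of a real
multi-cohort ICB compendium, where a published discovery analysis of this
kind pooled over a thousand treated patients. At this scale the planted
program's pooled log odds ratios (~0.9–1.3) separate cleanly from noise
(|logOR| < 0.25), yet selection by in-sample mean AUC retains a small
overfitting bias: a handful of chance-correlated candidates can ride into
the selected signature, so planted-set recovery is high (Jaccard 0.7–1.0
across seeds) but not guaranteed perfect. The no-signal control
(gamma = 0) yields validation AUCs tightly around 0.5, confirming the
discovery/validation split prevents optimism from the sweep itself. The
end-to-end demo configuration (`RunConfig()`) is deliberately small
(6 cohorts, 200 genes) so the full driver runs in about a second.

## Numerical conventions

* Population-SD z-scores; constant rows flagged, mapped to zero.
* Median ties to "low"; enrichment rank ties by gene symbol.
* tau2 and I2 truncated at 0; weights reported normalized to sum 1.
* COX-IS eps 1e-6; logistic IRLS tolerance 1e-10, 50 iterations, Firth
  tolerance 1e-9; Cox Newton tolerance 1e-10 with step halving.
* Table artifacts are written with 6-significant-digit floats so manifest
  hashes are platform-stable; expression round-trip I/O uses full precision.

## Known limitations

* The enrichment score is an ssGSEA-family statistic, not GSVA's
  kernel-CDF; absolute score values are not comparable with R GSVA output,
  though rankings of coherent signatures are.
* Breslow tie handling only; with heavy ties and many events per time the
  log hazard ratio is biased toward zero relative to Efron.
* The cutoff-sweep selection maximizes in-sample discovery AUC and inherits
  that criterion's mild optimism; an inner cross-validation loop would
  reduce it but is not part of the procedure implemented here.
* Spot-level evaluation assumes annotation arrives as a per-spot label;
  no image registration or neighborhood smoothing is attempted.
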