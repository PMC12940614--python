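# tlsmeta

Tertiary lymphoid structures (TLS) — lymph-node-like immune aggregates that
form inside tumors — predict prognosis and response to immune checkpoint
blockade (ICB), and transcriptomic gene signatures are the practical way to
quantify them at scale. `tlsmeta` is a tested Python implementation of a
pan-cancer TLS-signature analysis pipeline for computational immunologists
and biomarker developers:

* **Scoring** — per-gene z-scoring; a deterministic single-sample
  enrichment score (ssGSEA family); the COX-IS pro-/anti-tumor inflammation
  log-ratio; tumor mutational burden; median stratification.
* **Association** — RECIST + 6-month-PFS responder classification,
  univariate Cox (Breslow ties, Newton–Raphson) and logistic (IRLS with
  Firth fallback under separation) effects, response AUC with DeLong paired
  comparisons, Kaplan–Meier/log-rank, Wilcoxon/Fisher with small-sample
  permutation fallback, median Spearman signature correlations.
* **Meta-analysis** — fixed-effect inverse-variance and DerSimonian–Laird
  random-effects pooling with Q, tau², I², z-test, BH-FDR, and hot/cold
  subgroup pooling.
* **Discovery** — de novo signature construction: zero-expression filter,
  per-gene meta-analyzed log odds ratios, a cutoff sweep over [0, 0.5]
  (step 0.005) selecting the signature with the best mean discovery AUC,
  and leakage-guarded validation against competitor signatures.
* **Spatial** — spot-level signature scoring of Visium-like grids and TLS
  detection AUC stratified by TLS maturity.
* **Synthetic data** — a seeded multi-cohort generator with a planted TLS
  program (latent activity → expression, response, survival), decoy
  co-expression module, spatial disk grids and mutation tables, providing
  ground truth for every stage.

The package ships the 17-gene **PredictTLS** signature (CCL8, CXCL9,
CXCL10, CXCL11, CXCR3, CCR3, CCR5, ICAM1, CXCL13, CD40, CD38, DERL3, SSR4,
PDCD1, TIGIT, CD274, PIM2) and the COX-IS CP/CI gene lists as a bundled
GMT.

## The model in brief

For sample *j* with z-scored expression, a signature's enrichment score
walks the genes ranked by decreasing z and accumulates
`|z|^tau / Σ_in |z|^tau` at in-set genes and `−1/(G−m)` elsewhere; the
score is the largest positive plus smallest negative deviation of the walk.
Per cohort *k*, the score's effect on response or survival is a log odds
ratio or log hazard ratio `θ̂_k` with standard error `s_k`; cohorts are
pooled as

    θ̂ = Σ_k ω_k θ̂_k / Σ_k ω_k ,   ω_k = 1 / (s_k² + τ²)

with `τ² = max(0, (Q − (K−1)) / (Σω − Σω²/Σω))` (DerSimonian–Laird; τ² = 0
gives the fixed-effect model). Discovery ranks candidate genes by pooled
logOR and sweeps an inclusion cutoff, scoring each nested signature by mean
discovery-cohort response AUC.

## Worked example

```python
from tlsmeta.synthetic import make_truth, simulate_cohorts
from tlsmeta.scoring import zscore_expression, gsva_like_score
from tlsmeta.association import classify_cohort, fit_logistic_univariate, auc
from tlsmeta.meta import pool_dersimonian_laird
from tlsmeta.datatypes import GeneSet

truth = make_truth(gamma=2.0, seed=7)           # planted TLS program
cohorts, truth = simulate_cohorts(4, [80, 60, 100, 70], 200, truth, seed=7)
sig = GeneSet("planted", truth.signature_genes)

effects = []
for c in cohorts:
    labels = classify_cohort(c.clinical)
    keep = labels[labels != "non_assessable"].index
    z = zscore_expression(c.expression[list(keep)])
    scores = gsva_like_score(z, sig)
    y = (labels.loc[keep] == "R").astype(int).to_numpy()
    s = (scores - scores.mean()) / scores.std()
    fit = fit_logistic_univariate(s.to_numpy(), y, cohort_id=c.cohort_id)
    print(f"{c.cohort_id}: logOR={fit.estimate:+.3f} (se {fit.se:.3f}), "
          f"AUC={auc(scores.to_numpy(), y):.3f}, n={fit.n}")
    effects.append(fit)

pooled = pool_dersimonian_laird(effects)
print(f"pooled logOR={pooled.pooled:+.3f} (se {pooled.se:.3f}), "
      f"tau2={pooled.tau2:.3f}, p={pooled.p:.2e}")
```

Output:

```
cohort_01: logOR=+1.419 (se 0.331), AUC=0.818, n=80
cohort_02: logOR=+1.812 (se 0.427), AUC=0.880, n=60
cohort_03: logOR=+1.850 (se 0.338), AUC=0.880, n=100
cohort_04: logOR=+1.596 (se 0.374), AUC=0.854, n=70
pooled logOR=+1.654 (se 0.181), tau2=0.000, p=6.16e-20
```

Each cohort's standardized signature score carries a log odds ratio of
~1.4–1.9 per z-unit for ICB response (AUC 0.82–0.88); the studies are
homogeneous (τ² = 0) and pool to logOR 1.65 — the planted effect is
recovered with high confidence.

The same stages are available from the shell:

```bash
tls-meta simulate --out data/ --seed 7
tls-meta score --expr data/cohort_01_expr.tsv --gmt sets.gmt --method gsva --out scores.tsv
tls-meta discover --cohorts data/ --candidates cand.gmt --out disc/
tls-meta validate --sig disc/signature.gmt --cohorts holdout/ --out report.json
tls-meta evaluate-spatial --spots spots.csv --expr sp_expr.tsv --sig disc/signature.gmt --out spatial.json
tls-meta benchmark --out bench/ --seed 7      # full end-to-end driver + manifest
```

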