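"""De novo TLS signature construction by meta-analyzed log-odds sweep.

Pipeline: candidate genes are filtered for excessive zero expression, each
surviving gene's per-cohort log odds ratio for immune-checkpoint response is
pooled by random-effects meta-analysis, genes are ranked by pooled log-odds,
and nested signatures are generated by sweeping an inclusion cutoff over
[0, 0.5] in steps of 0.005.  Each nonempty signature is scored by the
single-sample enrichment score in every discovery cohort; the cutoff whose
signature maximizes the mean discovery response-AUC is selected (ties broken
toward the larger cutoff, i.e. the smaller signature).  Validation on held
out cohorts reports AUC against competitor signatures and the association of
the signature score with overall survival.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .association import (
    auc,
    classify_cohort,
    compare_auc,
    fit_cox_univariate,
    fit_logistic_univariate,
    km_logrank,
)
from .datatypes import CohortDataset, GeneSet, SweepResult
from .meta import bh_fdr, pool_dersimonian_laird, pool_fixed
from .scoring import GsvaContext, zscore_expression

__all__ = [
    "filter_zero_genes",
    "per_gene_meta_logor",
    "rank_and_sweep",
    "validate_signature",
    "jaccard",
]

ZERO_FRACTION_LIMIT = 0.5


def jaccard(a: Sequence[str], b: Sequence[str]) -> float:
    """Jaccard index |A n B| / |A u B| between two gene collections."""
    sa, sb = set(a), set(b)
    union = sa | sb
    return len(sa & sb) / len(union) if union else 1.0


def filter_zero_genes(
    expressions: Sequence[pd.DataFrame], candidates: GeneSet
) -> GeneSet:
    """Drop candidates with >50% zero expression in any cohort.

    A fraction of exactly 50% is kept.  Cohorts lacking a gene do not count
    against it.  Raises if no candidate survives.
    """
    if not expressions:
        raise ValueError("no cohorts given")
    kept = []
    for gene in candidates.members:
        excluded = False
        for expr in expressions:
            if gene not in expr.index:
                continue
            frac_zero = float((expr.loc[gene] == 0.0).mean())
            if frac_zero > ZERO_FRACTION_LIMIT:
                excluded = True
                break
        if not excluded:
            kept.append(gene)
    if not kept:
        raise ValueError("all candidate genes excluded by the zero-expression filter")
    return GeneSet(name=f"{candidates.name}_filtered", members=tuple(kept))


def _prepare_cohort(cohort: CohortDataset):
    """Z-scored expression and binary response (non-assessable excluded)."""
    labels = classify_cohort(cohort.clinical)
    assessable = labels[labels != "non_assessable"].index
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # constant rows are expected in sims
        z = zscore_expression(cohort.expression[list(assessable)])
    y = (labels.loc[assessable] == "R").astype(int).to_numpy()
    return z, y


def per_gene_meta_logor(
    cohorts: Sequence[CohortDataset],
    candidates: GeneSet,
    model: str = "random",
) -> pd.DataFrame:
    """Per-gene pooled log odds ratio for response across cohorts.

    Expression is z-scored within each cohort; a univariate logistic model is
    fit per gene per cohort and pooled ("random" = DerSimonian-Laird,
    "fixed" = inverse variance).  Returns a frame indexed by gene with
    columns ``pooled_logor, pooled_se, p, fdr, n_cohorts_used`` plus one
    ``logor_<cohort>`` / ``se_<cohort>`` pair per cohort.
    """
    pooler = {"random": pool_dersimonian_laird, "fixed": pool_fixed}[model]
    prepared = [(c.cohort_id, *_prepare_cohort(c)) for c in cohorts]
    for cid, _z, y in prepared:
        if y.min() == y.max():
            raise ValueError(f"cohort {cid!r} lacks one of the responder classes")
    rows = []
    percohort: dict[str, dict[str, float]] = {}
    for gene in candidates.members:
        effects = []
        for cid, z, y in prepared:
            if gene not in z.index:
                continue
            x = z.loc[gene].to_numpy()
            if np.ptp(x) == 0:
                continue
            effects.append(fit_logistic_univariate(x, y, cohort_id=cid, covariate=gene))
        if not effects:
            rows.append(
                {"gene": gene, "pooled_logor": np.nan, "pooled_se": np.nan,
                 "p": np.nan, "n_cohorts_used": 0}
            )
            continue
        pooled = pooler(effects)
        rows.append(
            {
                "gene": gene,
                "pooled_logor": pooled.pooled,
                "pooled_se": pooled.se,
                "p": pooled.p,
                "n_cohorts_used": len(effects),
            }
        )
        percohort[gene] = {}
        for e in effects:
            percohort[gene][f"logor_{e.cohort_id}"] = e.estimate
            percohort[gene][f"se_{e.cohort_id}"] = e.se
    table = pd.DataFrame(rows).set_index("gene")
    usable = table["p"].notna()
    fdr = pd.Series(np.nan, index=table.index)
    if usable.any():
        fdr[usable] = bh_fdr(table.loc[usable, "p"].to_numpy())
    table.insert(3, "fdr", fdr)
    wide = pd.DataFrame.from_dict(percohort, orient="index")
    return table.join(wide)


def _cutoff_grid(lo: float, hi: float, step: float) -> list[float]:
    if step <= 0 or hi < lo:
        raise ValueError("cutoff grid must satisfy step > 0 and hi >= lo")
    n = int(round((hi - lo) / step))
    return [round(lo + i * step, 10) for i in range(n + 1)]


def rank_and_sweep(
    table: pd.DataFrame,
    discovery_cohorts: Sequence[CohortDataset],
    cutoff_lo: float = 0.0,
    cutoff_hi: float = 0.5,
    step: float = 0.005,
    signature_name: str = "discovered",
) -> SweepResult:
    """Sweep the log-odds inclusion cutoff and pick the best signature.

    Genes are ranked by signed pooled log odds ratio; at cutoff ``c`` the
    signature contains every gene with pooled logOR >= c (negatively
    associated genes are never included).  Empty signatures are skipped; the
    selected cutoff maximizes the mean discovery-cohort response AUC, ties
    broken toward the larger cutoff.
    """
    if table.empty:
        raise ValueError("empty gene meta table")
    logor = table["pooled_logor"].dropna()
    cutoffs = _cutoff_grid(cutoff_lo, cutoff_hi, step)
    contexts = []
    for cohort in discovery_cohorts:
        z, y = _prepare_cohort(cohort)
        contexts.append((GsvaContext(z), y))

    cache: dict[frozenset, float] = {}

    def mean_auc(members: tuple[str, ...]) -> float:
        key = frozenset(members)
        if key not in cache:
            vals = []
            for ctx, y in contexts:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    scores = ctx.score(members)
                vals.append(auc(scores.to_numpy(), y))
            cache[key] = float(np.mean(vals))
        return cache[key]

    sizes, aucs, members_per_cutoff = [], [], []
    best: tuple[float, float, tuple[str, ...]] | None = None  # (auc, cutoff, members)
    for c in cutoffs:
        members = tuple(g for g in table.index if logor.get(g, -np.inf) >= c)
        sizes.append(len(members))
        members_per_cutoff.append(members)
        if not members:
            aucs.append(float("nan"))
            continue
        a = mean_auc(members)
        aucs.append(a)
        # >= so that ties move to the larger cutoff (smaller signature)
        if best is None or a >= best[0]:
            best = (a, c, members)
    if best is None:
        raise ValueError("no cutoff yields a nonempty signature")
    _, selected_cutoff, selected_members = best
    return SweepResult(
        cutoffs=cutoffs,
        sizes=sizes,
        mean_aucs=aucs,
        members=members_per_cutoff,
        selected_cutoff=selected_cutoff,
        final_signature=GeneSet(name=signature_name, members=selected_members),
    )


def sweep_table(result: SweepResult) -> pd.DataFrame:
    """Sweep curve as a frame: cutoff, signature size, mean discovery AUC."""
    return pd.DataFrame(
        {"cutoff": result.cutoffs, "size": result.sizes, "mean_auc": result.mean_aucs}
    )


def validate_signature(
    sig: GeneSet,
    validation_cohorts: Sequence[CohortDataset],
    competitors: Sequence[GeneSet] = (),
    discovery_ids: Optional[Sequence[str]] = None,
) -> dict:
    """Evaluate a signature on held-out cohorts.

    Refuses to run on any cohort whose id appears in ``discovery_ids``
    (information leakage).  Per cohort: response AUC of the signature and of
    each competitor, paired DeLong comparisons, a univariate Cox fit of the
    signature score against overall survival, and median-split Kaplan-Meier
    curves with the log-rank test.
    """
    discovery_ids = set(discovery_ids or ())
    leaked = [c.cohort_id for c in validation_cohorts if c.cohort_id in discovery_ids]
    if leaked:
        raise ValueError(f"validation cohorts overlap discovery cohorts: {leaked}")
    per_cohort: dict[str, dict] = {}
    sig_aucs = []
    comp_aucs: dict[str, list[float]] = {c.name: [] for c in competitors}
    for cohort in validation_cohorts:
        z, y = _prepare_cohort(cohort)
        present = sig.intersect(z.index)
        if len(present) < 1:
            raise ValueError(
                f"signature {sig.name!r} has no gene in cohort {cohort.cohort_id!r}"
            )
        ctx = GsvaContext(z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sig_scores = ctx.score(sig.members)
        entry: dict = {"n": len(y), "auc": auc(sig_scores.to_numpy(), y)}
        sig_aucs.append(entry["auc"])
        entry["competitors"] = {}
        for comp in competitors:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                comp_scores = ctx.score(comp.members)
            cmp_res = compare_auc(sig_scores.to_numpy(), comp_scores.to_numpy(), y)
            entry["competitors"][comp.name] = {
                "auc": cmp_res.auc_b,
                "delta_auc": cmp_res.delta,
                "p": cmp_res.p,
            }
            comp_aucs[comp.name].append(cmp_res.auc_b)
        # survival association on all samples of the cohort
        clin = cohort.clinical_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            z_all = zscore_expression(cohort.expression)
            os_scores = GsvaContext(z_all).score(sig.members)
        cox = fit_cox_univariate(
            os_scores.to_numpy(),
            clin["os_time"].to_numpy(),
            clin["os_event"].to_numpy(),
            cohort_id=cohort.cohort_id,
            covariate=sig.name,
        )
        entry["cox_os"] = {
            "log_hr": cox.estimate,
            "se": cox.se,
            "p": cox.p,
            "converged": cox.converged,
        }
        try:
            km = km_logrank(
                os_scores, clin["os_time"].to_numpy(), clin["os_event"].to_numpy()
            )
            entry["km"] = {"chi2": km.chi2, "p": km.p, "split_value": km.split_value}
        except ValueError as exc:  # an arm without events
            entry["km"] = {"error": str(exc)}
        per_cohort[cohort.cohort_id] = entry
    return {
        "signature": sig.name,
        "n_cohorts": len(validation_cohorts),
        "mean_auc": float(np.mean(sig_aucs)),
        "competitor_mean_auc": {k: float(np.mean(v)) if v else None for k, v in comp_aucs.items()},
        "per_cohort": per_cohort,
    }
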