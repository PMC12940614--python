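"""End-to-end benchmark on synthetic data.

Mirrors the study flow: simulate multi-cohort checkpoint-blockade data with
a planted TLS program, score registered signatures per sample, estimate
per-cohort logistic (response) and Cox (overall survival) effects, pool them
by fixed- and random-effects meta-analysis with hot/cold subgroup pooling
and FDR across signatures, run the de novo signature discovery sweep on the
discovery split, validate on the held-out split, and evaluate spot-level TLS
detection on simulated spatial sections.  Every table is written as text
with 6-significant-digit floats and a manifest records the config hash, seed
and artifact checksums, so identical runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import platform
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .association import auc, fit_cox_univariate, fit_logistic_univariate
from .datatypes import CohortDataset, GeneSet
from .discovery import (
    filter_zero_genes,
    jaccard,
    per_gene_meta_logor,
    rank_and_sweep,
    sweep_table,
    validate_signature,
    _prepare_cohort,
)
from .io import FLOAT_FORMAT, write_gmt
from .meta import bh_fdr, pool_dersimonian_laird, pool_fixed, subgroup_meta
from .scoring import GsvaContext, zscore_expression
from .spatial import evaluate_sample, maturity_summary
from .synthetic import make_truth, simulate_cohorts, simulate_spatial

__all__ = ["RunConfig", "run_benchmark", "discovery_benchmark", "candidate_gene_set"]

ARTIFACTS = (
    "effects.tsv",
    "meta_summary.tsv",
    "gene_meta_table.tsv",
    "sweep.tsv",
    "signature.gmt",
    "validation_report.json",
    "spatial_report.json",
)


@dataclass
class RunConfig:
    """Configuration of one benchmark run."""

    seed: int = 0
    n_discovery: int = 4
    n_validation: int = 2
    samples_per_discovery: int = 40
    samples_per_validation: int = 60
    n_genes: int = 200
    n_candidates: int = 74
    n_signature: int = 15
    gamma: float = 2.0  # log-odds of response per unit activity
    delta: float = 0.5  # log-hazard per unit activity
    noise_sd: float = 1.0
    cutoff_lo: float = 0.0
    cutoff_hi: float = 0.5
    cutoff_step: float = 0.005
    spatial_grid: int = 20
    spatial_radius: int = 3
    spatial_n_tls: int = 2
    spatial_effect: float = 3.0
    n_spatial_per_group: int = 2

    def __post_init__(self) -> None:
        if self.cutoff_step <= 0 or self.cutoff_hi < self.cutoff_lo:
            raise ValueError("invalid cutoff grid")
        if self.n_discovery < 1 or self.n_validation < 1:
            raise ValueError("need at least one discovery and one validation cohort")

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))


def candidate_gene_set(cohorts: Sequence[CohortDataset], n_candidates: int) -> GeneSet:
    """Candidate universe for discovery: every planted and decoy gene plus
    noise/low-expression fillers up to ``n_candidates`` genes, in the
    simulated gene order."""
    genes = list(cohorts[0].expression.index)
    planted = [g for g in genes if g.startswith(("TLSG", "DECOY", "LOWG"))]
    fillers = [g for g in genes if g.startswith("NOISE")]
    members = (planted + fillers)[:n_candidates]
    return GeneSet(name="candidates", members=tuple(members))


def _split_cohorts(cohorts, config):
    if len(cohorts) != config.n_discovery + config.n_validation:
        raise ValueError("discovery/validation split must partition the cohorts")
    disc = cohorts[: config.n_discovery]
    val = cohorts[config.n_discovery :]
    disc_ids = {c.cohort_id for c in disc}
    val_ids = {c.cohort_id for c in val}
    if disc_ids & val_ids or len(disc_ids | val_ids) != len(cohorts):
        raise ValueError("discovery/validation split must partition the cohorts")
    return disc, val


def _signature_effects(
    cohorts: Sequence[CohortDataset], signatures: Sequence[GeneSet]
) -> pd.DataFrame:
    """Per-cohort logistic (response) and Cox (OS) effects of each
    signature's standardized enrichment score."""
    rows = []
    for cohort in cohorts:
        z_resp, y = _prepare_cohort(cohort)
        ctx_resp = GsvaContext(z_resp)
        clin = cohort.clinical_frame()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            ctx_all = GsvaContext(zscore_expression(cohort.expression))
        for sig in signatures:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                s_resp = ctx_resp.score(sig.members).to_numpy()
                s_all = ctx_all.score(sig.members).to_numpy()

            def _standardize(v):
                sd = v.std()
                return (v - v.mean()) / sd if sd > 0 else v

            logit = fit_logistic_univariate(
                _standardize(s_resp), y, cohort_id=cohort.cohort_id, covariate=sig.name
            )
            cox = fit_cox_univariate(
                _standardize(s_all),
                clin["os_time"].to_numpy(),
                clin["os_event"].to_numpy(),
                cohort_id=cohort.cohort_id,
                covariate=sig.name,
            )
            for outcome, eff in (("response", logit), ("os", cox)):
                rows.append(
                    {
                        "cohort_id": cohort.cohort_id,
                        "immune_context": cohort.immune_context,
                        "signature": sig.name,
                        "outcome": outcome,
                        "estimate": eff.estimate,
                        "se": eff.se,
                        "p": eff.p,
                        "n": eff.n,
                        "events": eff.events,
                        "converged": eff.converged,
                        "auc": auc(s_resp, y) if outcome == "response" else np.nan,
                    }
                )
    return pd.DataFrame(rows)


def _meta_summary(effects: pd.DataFrame) -> pd.DataFrame:
    """Pool each (signature, outcome) over cohorts: fixed + random models,
    overall and within hot/cold subgroups, FDR across signatures per
    (outcome, model, subgroup) family."""
    from .datatypes import EffectEstimate

    rows = []
    for (sig, outcome), grp in effects.groupby(["signature", "outcome"], sort=True):
        ok = grp[grp["converged"] & np.isfinite(grp["se"])]
        if ok.empty:
            continue
        eff = [
            EffectEstimate(
                cohort_id=r.cohort_id, covariate=sig, estimate=r.estimate,
                se=r.se, p=r.p, n=int(r.n), events=int(r.events),
            )
            for r in ok.itertuples()
        ]
        groups = dict(zip(ok["cohort_id"], ok["immune_context"]))
        for model, pooler in (("fixed", pool_fixed), ("random", pool_dersimonian_laird)):
            res = pooler(eff)
            rows.append(
                {
                    "signature": sig, "outcome": outcome, "model": model,
                    "subgroup": "all", "pooled": res.pooled, "se": res.se,
                    "z": res.z, "p": res.p, "tau2": res.tau2, "Q": res.Q,
                    "I2": res.I2, "K": res.K,
                }
            )
            for label, sub in subgroup_meta(eff, groups, model=model).items():
                rows.append(
                    {
                        "signature": sig, "outcome": outcome, "model": model,
                        "subgroup": label, "pooled": sub.pooled, "se": sub.se,
                        "z": sub.z, "p": sub.p, "tau2": sub.tau2, "Q": sub.Q,
                        "I2": sub.I2, "K": sub.K,
                    }
                )
    out = pd.DataFrame(rows)
    out["fdr"] = np.nan
    for _, idx in out.groupby(["outcome", "model", "subgroup"]).groups.items():
        out.loc[idx, "fdr"] = bh_fdr(out.loc[idx, "p"].to_numpy())
    return out.sort_values(["outcome", "model", "subgroup", "signature"]).reset_index(drop=True)


def run_benchmark(config: RunConfig, out_dir) -> dict:
    """Run the full synthetic benchmark and write all artifacts to
    ``out_dir``.  Returns a summary dict (also stored in the manifest)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n_cohorts = config.n_discovery + config.n_validation
    sizes = [config.samples_per_discovery] * config.n_discovery + [
        config.samples_per_validation
    ] * config.n_validation
    truth = make_truth(
        n_signature=config.n_signature,
        gamma=config.gamma,
        delta=config.delta,
        seed=config.seed,
    )
    cohorts, truth = simulate_cohorts(
        n_cohorts, sizes, config.n_genes, truth,
        noise_sd=config.noise_sd, seed=config.seed,
    )
    discovery, validation = _split_cohorts(cohorts, config)

    planted_sig = GeneSet(name="planted_truth", members=truth.signature_genes)
    decoy_sig = GeneSet(
        name="decoy_module",
        members=tuple(g for g in cohorts[0].expression.index if g.startswith("DECOY")),
    )
    effects = _signature_effects(cohorts, [planted_sig, decoy_sig])
    meta_summary = _meta_summary(effects)

    candidates = candidate_gene_set(cohorts, config.n_candidates)
    filtered = filter_zero_genes([c.expression for c in discovery], candidates)
    gene_table = per_gene_meta_logor(discovery, filtered)
    sweep = rank_and_sweep(
        gene_table, discovery,
        cutoff_lo=config.cutoff_lo, cutoff_hi=config.cutoff_hi, step=config.cutoff_step,
    )
    report = validate_signature(
        sweep.final_signature,
        validation,
        competitors=[planted_sig, decoy_sig],
        discovery_ids=[c.cohort_id for c in discovery],
    )
    report["selected_cutoff"] = sweep.selected_cutoff
    report["signature_size"] = len(sweep.final_signature)
    report["jaccard_vs_planted"] = jaccard(
        sweep.final_signature.members, truth.signature_genes
    )

    spatial_reports = []
    for i in range(config.n_spatial_per_group):
        for maturity in ("mature", "immature", "negative"):
            sample = simulate_spatial(
                config.spatial_grid, config.spatial_grid,
                config.spatial_n_tls, config.spatial_radius,
                planted_sig, config.spatial_effect, maturity,
                seed=config.seed * 1000 + i * 10 + {"mature": 0, "immature": 1, "negative": 2}[maturity],
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spatial_reports.append(evaluate_sample(sample, planted_sig))
    spatial_df = maturity_summary(spatial_reports)

    # ---- write artifacts -------------------------------------------------
    effects.to_csv(out / "effects.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    meta_summary.to_csv(out / "meta_summary.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    gene_table.to_csv(out / "gene_meta_table.tsv", sep="\t", float_format=FLOAT_FORMAT)
    sweep_table(sweep).to_csv(out / "sweep.tsv", sep="\t", index=False, float_format=FLOAT_FORMAT)
    write_gmt([sweep.final_signature], out / "signature.gmt")
    with open(out / "validation_report.json", "w") as fh:
        json.dump(_round_floats(report), fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(out / "spatial_report.json", "w") as fh:
        json.dump(
            _round_floats(
                {
                    "summary": spatial_df.reset_index().to_dict(orient="records"),
                    "samples": [vars(r) for r in spatial_reports],
                }
            ),
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")

    config_json = json.dumps(asdict(config), sort_keys=True)
    manifest = {
        "config": asdict(config),
        "config_sha256": hashlib.sha256(config_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": {
            "tlsmeta": __version__,
            "python": platform.python_version(),
        },
        "artifacts": {
            name: hashlib.sha256((out / name).read_bytes()).hexdigest()
            for name in ARTIFACTS
        },
        "summary": _round_floats(
            {
                "selected_cutoff": sweep.selected_cutoff,
                "signature_size": len(sweep.final_signature),
                "jaccard_vs_planted": report["jaccard_vs_planted"],
                "validation_mean_auc": report["mean_auc"],
                "n_nonconverged_fits": int((~effects["converged"]).sum()),
            }
        ),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return manifest


def discovery_benchmark(
    seed: int,
    gamma: float = 2.0,
    n_discovery: int = 10,
    n_validation: int = 5,
    samples_per_discovery: int = 120,
    samples_per_validation: int = 100,
    n_genes: int = 300,
    n_candidates: int = 74,
    n_signature: int = 15,
    delta: float = 0.5,
    noise_sd: float = 1.0,
) -> dict:
    """Discovery-to-validation pipeline on a fresh simulation.

    The default sizes mirror a realistic multi-cohort checkpoint-blockade
    compendium (about 1200 discovery and 500 validation patients).  Returns
    the selected cutoff, signature size, Jaccard index against the planted
    program and the mean validation response-AUC.
    """
    truth = make_truth(n_signature=n_signature, gamma=gamma, delta=delta, seed=seed)
    sizes = [samples_per_discovery] * n_discovery + [samples_per_validation] * n_validation
    cohorts, truth = simulate_cohorts(
        n_discovery + n_validation, sizes, n_genes, truth, noise_sd=noise_sd, seed=seed
    )
    discovery = cohorts[:n_discovery]
    validation = cohorts[n_discovery:]
    candidates = candidate_gene_set(cohorts, n_candidates)
    filtered = filter_zero_genes([c.expression for c in discovery], candidates)
    table = per_gene_meta_logor(discovery, filtered)
    sweep = rank_and_sweep(table, discovery)
    report = validate_signature(
        sweep.final_signature, validation,
        discovery_ids=[c.cohort_id for c in discovery],
    )
    return {
        "selected_cutoff": sweep.selected_cutoff,
        "signature_size": len(sweep.final_signature),
        "jaccard_vs_planted": jaccard(sweep.final_signature.members, truth.signature_genes),
        "validation_mean_auc": report["mean_auc"],
        "signature": sweep.final_signature,
        "truth": truth,
    }


def _round_floats(obj, ndigits: int = 6):
    """Round floats recursively so JSON artifacts hash identically."""
    if isinstance(obj, float):
        return float(f"{obj:.6g}")
    if isinstance(obj, dict):
        return {k: _round_floats(v, ndigits) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, ndigits) for v in obj]
    if isinstance(obj, (np.floating,)):
        return float(f"{float(obj):.6g}")
    if isinstance(obj, (np.integer,)):
        return int(obj)
    return obj
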