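"""Synthetic multi-cohort, spatial and mutation data with known ground truth.

The generative model is intentionally minimal but makes every downstream
stage nontrivial:

* Each patient carries a latent TLS-program activity ``a ~ N(0, 1)``.
* Planted signature genes read ``baseline + loading_g * a + noise`` on the
  log2(x+1) scale (clipped at 0); a decoy module shares its own latent
  factor but is unlinked to outcome, so co-expression alone cannot identify
  the true program; remaining genes are independent noise, a few of them
  expressed near zero to exercise the zero-expression filter.
* Response is Bernoulli(logistic(alpha_k + gamma * a)) with cohort-specific
  intercepts alpha_k; overall survival is exponential with hazard
  ``lambda * exp(delta * a)`` under uniform censoring on [0, 2/lambda]
  (roughly 30-50% censoring, typical of checkpoint-blockade cohorts).
* RECIST categories are drawn consistently with the responder rule
  (CR/PR/SD-without-early-event for responders; PD/SD-with-early-event for
  non-responders) so that responder classification inverts the generator.

All generators take a mandatory seed and use one private RNG stream per
call; identical arguments give byte-identical output.
"""

from __future__ import annotations

import math
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .datatypes import (
    CohortDataset,
    GeneSet,
    MutationTable,
    PatientRecord,
    SpatialSample,
    TruthSet,
)
from .signatures import COLD_CANCER_TYPES, HOT_CANCER_TYPES, immune_context

__all__ = ["make_truth", "simulate_cohorts", "simulate_spatial", "simulate_mutations"]

DEFAULT_INTERCEPT = -0.5  # response prevalence ~0.38 at average activity
DEFAULT_BASELINE = 4.0  # log2 units, mid-range bulk expression
DEFAULT_HAZARD = 0.04  # per month; median OS ~17 months at average activity
N_DECOY_GENES = 10
PFS_WINDOW = 6.0


def make_truth(
    n_signature: int = 15,
    gamma: float = 2.0,
    delta: float = 0.5,
    seed: int = 0,
    loading_range: tuple[float, float] = (0.8, 1.5),
) -> TruthSet:
    """Construct a planted truth: signature genes TLSG01.. with loadings
    drawn uniformly from ``loading_range``."""
    rng = np.random.default_rng(seed)
    genes = tuple(f"TLSG{i + 1:02d}" for i in range(n_signature))
    loadings = {g: float(rng.uniform(*loading_range)) for g in genes}
    return TruthSet(
        signature_genes=genes,
        gene_loadings=loadings,
        activity_effect_response=gamma,
        activity_effect_hazard=delta,
    )


def _gene_universe(truth: TruthSet, n_genes: int) -> tuple[list[str], int, int]:
    n_sig = len(truth.signature_genes)
    if n_genes <= n_sig:
        raise ValueError(
            f"n_genes={n_genes} must exceed the {n_sig} signature genes"
        )
    n_decoy = min(N_DECOY_GENES, n_genes - n_sig)
    n_filler = n_genes - n_sig - n_decoy
    n_low = max(2, n_filler // 20) if n_filler >= 2 else 0
    n_noise = n_filler - n_low
    genes = (
        list(truth.signature_genes)
        + [f"DECOY{i + 1:02d}" for i in range(n_decoy)]
        + [f"NOISE{i + 1:04d}" for i in range(n_noise)]
        + [f"LOWG{i + 1:02d}" for i in range(n_low)]
    )
    return genes, n_decoy, n_low


def simulate_cohorts(
    n_cohorts: int,
    n_samples: Sequence[int],
    n_genes: int,
    truth: TruthSet,
    noise_sd: float = 1.0,
    seed: int = 0,
    baseline: float = DEFAULT_BASELINE,
    hazard: float = DEFAULT_HAZARD,
    cancer_types: Optional[Sequence[str]] = None,
) -> tuple[list[CohortDataset], TruthSet]:
    """Simulate ``n_cohorts`` checkpoint-blockade-like cohorts.

    Returns the cohorts plus a copy of ``truth`` whose ``cohort_intercepts``
    cover every generated cohort (missing intercepts default to
    ``DEFAULT_INTERCEPT``).
    """
    if n_cohorts < 1:
        raise ValueError("n_cohorts must be >= 1")
    if len(n_samples) != n_cohorts:
        raise ValueError("n_samples must list one size per cohort")
    if any(n < 4 for n in n_samples):
        raise ValueError("every cohort needs at least 4 samples")
    genes, n_decoy, n_low = _gene_universe(truth, n_genes)
    n_sig = len(truth.signature_genes)
    rng = np.random.default_rng(seed)

    if cancer_types is None:
        # alternate hot and cold contexts across cohorts
        cancer_types = [
            HOT_CANCER_TYPES[(i // 2) % len(HOT_CANCER_TYPES)]
            if i % 2 == 0
            else COLD_CANCER_TYPES[(i // 2) % len(COLD_CANCER_TYPES)]
            for i in range(n_cohorts)
        ]
    elif len(cancer_types) != n_cohorts:
        raise ValueError("cancer_types must list one type per cohort")

    cohort_ids = [f"cohort_{i + 1:02d}" for i in range(n_cohorts)]
    intercepts = {
        cid: float(truth.cohort_intercepts.get(cid, DEFAULT_INTERCEPT))
        for cid in cohort_ids
    }
    truth_out = TruthSet(
        signature_genes=truth.signature_genes,
        gene_loadings=dict(truth.gene_loadings),
        activity_effect_response=truth.activity_effect_response,
        activity_effect_hazard=truth.activity_effect_hazard,
        cohort_intercepts=intercepts,
    )

    loadings = np.array([truth.gene_loadings[g] for g in truth.signature_genes])
    # per-gene baselines shared across cohorts (drawn once per call)
    n_noise = n_genes - n_sig - n_decoy - n_low
    noise_baselines = rng.uniform(1.5, 6.0, size=n_noise)
    low_baseline = -0.3 * noise_sd  # >50% of values clip to exactly zero

    gamma = truth.activity_effect_response
    delta = truth.activity_effect_hazard
    cohorts: list[CohortDataset] = []
    for cid, ctype, n_k in zip(cohort_ids, cancer_types, n_samples):
        a = rng.standard_normal(n_k)  # latent TLS-program activity
        d = rng.standard_normal(n_k)  # decoy-module latent factor
        sample_ids = [f"{cid}_s{j + 1:03d}" for j in range(n_k)]

        values = np.empty((n_genes, n_k))
        values[:n_sig] = baseline + loadings[:, None] * a[None, :]
        values[n_sig : n_sig + n_decoy] = baseline + 1.0 * d[None, :]
        values[n_sig + n_decoy : n_sig + n_decoy + n_noise] = noise_baselines[:, None]
        if n_low:
            values[n_sig + n_decoy + n_noise :] = low_baseline
        values += rng.normal(0.0, noise_sd, size=values.shape)
        np.clip(values, 0.0, None, out=values)
        expr = pd.DataFrame(values, index=genes, columns=sample_ids)
        expr.attrs["latent_activity"] = a.copy()  # diagnostic ground truth

        p_resp = expit(intercepts[cid] + gamma * a)
        responder = rng.random(n_k) < p_resp
        os_rate = hazard * np.exp(delta * a)
        t_event = rng.exponential(1.0 / os_rate)
        censor = rng.uniform(0.0, 2.0 / hazard, size=n_k)
        os_time = np.maximum(np.minimum(t_event, censor), 1e-3)
        os_event = (t_event <= censor).astype(int)
        tmb = rng.lognormal(mean=math.log(5.0), sigma=0.8, size=n_k)

        clinical = []
        for j in range(n_k):
            if responder[j]:
                recist = rng.choice(["CR", "PR", "SD"], p=[0.15, 0.55, 0.30])
                pfs_event = int(rng.random() < 0.5)
                if pfs_event:
                    pfs_time = PFS_WINDOW + rng.exponential(8.0)  # event after window
                else:
                    pfs_time = rng.uniform(1.0, 24.0)
            else:
                recist = rng.choice(["PD", "SD"], p=[0.8, 0.2])
                pfs_event = 1
                pfs_time = rng.uniform(0.5, PFS_WINDOW)
            clinical.append(
                PatientRecord(
                    sample_id=sample_ids[j],
                    recist=str(recist),
                    pfs_time=float(pfs_time),
                    pfs_event=pfs_event,
                    os_time=float(os_time[j]),
                    os_event=int(os_event[j]),
                    tmb=float(tmb[j]),
                )
            )
        cohorts.append(
            CohortDataset(
                cohort_id=cid,
                cancer_type=str(ctype),
                immune_context=immune_context(str(ctype)),
                expression=expr,
                clinical=clinical,
            )
        )
    return cohorts, truth_out


def simulate_spatial(
    width: int,
    height: int,
    n_tls: int,
    radius: int,
    signature: GeneSet,
    effect: float,
    maturity: str,
    seed: int = 0,
    n_background_genes: int = 100,
    baseline: float = 3.0,
    noise_sd: float = 1.0,
    sample_id: Optional[str] = None,
    section_type: str = "frozen",
    max_tries: int = 500,
) -> SpatialSample:
    """Simulate a spot grid with disk-shaped TLS regions.

    Inside each disk the signature genes are raised by ``effect`` (mature
    samples) or ``effect / 3`` (immature).  ``maturity="negative"`` ignores
    ``n_tls`` and annotates nothing.
    """
    if maturity not in ("mature", "immature", "negative"):
        raise ValueError(f"unknown maturity {maturity!r}")
    if effect < 0:
        raise ValueError("effect must be >= 0")
    place_disks = maturity != "negative" and n_tls > 0
    if place_disks and n_tls * math.pi * radius**2 >= width * height:
        raise ValueError("requested disks cannot fit in the grid")
    rng = np.random.default_rng(seed)
    xs, ys = np.meshgrid(np.arange(width), np.arange(height), indexing="ij")
    spots = list(zip(xs.ravel().tolist(), ys.ravel().tolist()))
    spot_ids = [f"spot_{x}_{y}" for x, y in spots]
    n_spots = len(spots)

    centers: list[tuple[int, int]] = []
    if place_disks:
        if 2 * radius >= width or 2 * radius >= height:
            raise ValueError("radius too large for the grid")
        for _ in range(max_tries):
            cx = int(rng.integers(radius, width - radius))
            cy = int(rng.integers(radius, height - radius))
            if all((cx - ox) ** 2 + (cy - oy) ** 2 > (2 * radius) ** 2 for ox, oy in centers):
                centers.append((cx, cy))
                if len(centers) == n_tls:
                    break
        else:
            raise RuntimeError(
                f"could not place {n_tls} non-overlapping disks in {max_tries} tries"
            )

    sx = np.array([x for x, _ in spots])
    sy = np.array([y for _, y in spots])
    in_disk = np.zeros(n_spots, dtype=bool)
    for cx, cy in centers:
        in_disk |= (sx - cx) ** 2 + (sy - cy) ** 2 <= radius**2

    genes = list(signature.members) + [f"BG{i + 1:04d}" for i in range(n_background_genes)]
    values = baseline + rng.normal(0.0, noise_sd, size=(len(genes), n_spots))
    if place_disks:
        bump = effect if maturity == "mature" else effect / 3.0
        values[: len(signature.members), in_disk] += bump
    np.clip(values, 0.0, None, out=values)
    expr = pd.DataFrame(values, index=genes, columns=spot_ids)
    expr.attrs["tls_centers"] = list(centers)  # diagnostic ground truth

    label = {"mature": "mature_tls", "immature": "immature_tls"}.get(maturity)
    annotation = [
        label if (place_disks and flag) else "none" for flag in in_disk
    ]
    return SpatialSample(
        sample_id=sample_id or f"spatial_{maturity}_{seed}",
        section_type=section_type,
        spots=spots,
        expression=expr,
        tls_annotation=annotation,
        maturity_label=maturity,
    )


def simulate_mutations(
    n_samples: int,
    mean_tmb: float,
    seed: int = 0,
    territory_mb: float = 38.0,
    sigma: float = 0.6,
) -> MutationTable:
    """Simulate per-sample mutation counts by consequence class.

    Nonsynonymous totals are lognormal with median ``mean_tmb * territory_mb``
    and are split across missense, frameshift indels and stop codons;
    synonymous and other counts scale with the nonsynonymous load.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not mean_tmb > 0:
        raise ValueError("mean_tmb must be positive")
    rng = np.random.default_rng(seed)
    samples = [f"S{i + 1:04d}" for i in range(n_samples)]
    nonsyn = np.round(
        rng.lognormal(mean=math.log(mean_tmb * territory_mb), sigma=sigma, size=n_samples)
    ).astype(int)
    counts: dict[str, dict[str, int]] = {}
    for s, total in zip(samples, nonsyn):
        split = rng.multinomial(int(total), [0.75, 0.12, 0.13])
        counts[s] = {
            "missense": int(split[0]),
            "frameshift_indel": int(split[1]),
            "stop_codon": int(split[2]),
            "synonymous": int(rng.poisson(0.35 * total)),
            "other": int(rng.poisson(0.10 * total)),
        }
    return MutationTable(samples=samples, counts=counts)
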