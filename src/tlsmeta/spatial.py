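"""Spot-level TLS detection in spatial transcriptomics samples.

Each spot of a sample is scored with the single-sample enrichment score of a
signature (genes z-scored across spots first); the score's ability to
separate pathologist-annotated TLS spots from the rest is summarized as a
spot-level AUC, reported per sample and stratified by the sample's TLS
maturity label (mature / immature / negative).
"""

from __future__ import annotations

import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from .association import auc
from .datatypes import GeneSet, SpatialSample, SpotAUCReport
from .scoring import GsvaContext, zscore_expression

__all__ = ["score_spots", "spot_auc", "maturity_summary"]


def score_spots(sample: SpatialSample, sig: GeneSet) -> pd.Series:
    """Per-spot enrichment score of ``sig`` (z-scored across spots)."""
    if sample.n_spots < 2:
        raise ValueError("need at least 2 spots")
    z = zscore_expression(sample.expression)
    if z.attrs.get("constant_genes"):
        warnings.warn(
            f"{sample.sample_id}: {len(z.attrs['constant_genes'])} constant "
            "gene row(s); scores may be degenerate",
            stacklevel=2,
        )
    return GsvaContext(z).score(sig.members)


def spot_auc(sample: SpatialSample, scores: pd.Series) -> SpotAUCReport:
    """Spot-level AUC of ``scores`` against the TLS annotation.

    Any annotated spot (mature or immature TLS) counts as positive.  Samples
    with a single class (e.g. TLS-negative sections) carry a missing AUC
    rather than raising.
    """
    labels = np.array([a != "none" for a in sample.tls_annotation])
    n_tls = int(labels.sum())
    if n_tls == 0 or n_tls == sample.n_spots:
        return SpotAUCReport(
            sample_id=sample.sample_id,
            maturity_label=sample.maturity_label,
            n_spots=sample.n_spots,
            n_tls_spots=n_tls,
            auc=None,
        )
    value = auc(np.asarray(scores, dtype=float), labels.astype(int))
    return SpotAUCReport(
        sample_id=sample.sample_id,
        maturity_label=sample.maturity_label,
        n_spots=sample.n_spots,
        n_tls_spots=n_tls,
        auc=value,
    )


def evaluate_sample(sample: SpatialSample, sig: GeneSet) -> SpotAUCReport:
    """Convenience: score the spots and compute the spot-level AUC."""
    return spot_auc(sample, score_spots(sample, sig))


def maturity_summary(reports: Sequence[SpotAUCReport]) -> pd.DataFrame:
    """Min/median/max spot AUC per maturity group.

    Groups whose samples have no defined AUC (TLS-negative sections) appear
    with missing summary values.
    """
    if not reports:
        raise ValueError("no reports given")
    rows = []
    for label in ("mature", "immature", "negative"):
        group = [r for r in reports if r.maturity_label == label]
        if not group:
            continue
        aucs = [r.auc for r in group if r.auc is not None]
        rows.append(
            {
                "maturity": label,
                "n_samples": len(group),
                "n_with_auc": len(aucs),
                "auc_min": min(aucs) if aucs else np.nan,
                "auc_median": float(np.median(aucs)) if aucs else np.nan,
                "auc_max": max(aucs) if aucs else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("maturity")
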