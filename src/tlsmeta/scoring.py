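"""Per-sample signature scores.

Four scores are implemented:

* :func:`zscore_expression` — per-gene standardization (population SD).
* :func:`gsva_like_score` — a deterministic single-sample enrichment score in
  the ssGSEA family.  For each sample the genes are ranked by z-value
  (descending, ties broken by lexicographic gene symbol so the score does
  not depend on input row order); a running sum gains
  ``|z|^tau`` (normalized over the in-set genes) at in-set positions and
  loses ``1/(G-m)`` at out-of-set positions.  The enrichment score is the
  "maxdiff" statistic: largest positive deviation plus smallest negative
  deviation of the running sum.
* :func:`coxis_score` — log2 ratio of mean linear-scale expression of the
  cancer-promoting (CP) over cancer-inhibitory (CI) inflammation genes.
* :func:`tmb` — nonsynonymous mutations per megabase of sequenced territory.

:func:`median_stratify` splits any per-sample score at its median
(ties assigned to "low").
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datatypes import GeneSet, MutationTable, NONSYNONYMOUS_CLASSES
from .signatures import coxis_ci_genes, coxis_cp_genes, resolve_symbol

__all__ = [
    "zscore_expression",
    "gsva_like_score",
    "GsvaContext",
    "coxis_score",
    "tmb",
    "median_stratify",
]


def zscore_expression(expr: pd.DataFrame) -> pd.DataFrame:
    """Standardize each gene row to mean 0 / SD 1 (population convention).

    Constant rows cannot be standardized; they are mapped to all-zero rows,
    recorded in ``result.attrs["constant_genes"]`` and reported via a warning.
    """
    if expr.shape[1] < 2:
        raise ValueError("z-scoring needs at least 2 samples")
    values = expr.to_numpy(dtype=float)
    mean = values.mean(axis=1, keepdims=True)
    sd = values.std(axis=1, ddof=0, keepdims=True)
    constant = sd[:, 0] == 0.0
    sd[constant] = 1.0
    z = (values - mean) / sd
    z[constant, :] = 0.0
    out = pd.DataFrame(z, index=expr.index, columns=expr.columns)
    out.attrs["constant_genes"] = list(expr.index[constant])
    if constant.any():
        warnings.warn(
            f"{int(constant.sum())} constant gene row(s) mapped to zeros",
            stacklevel=2,
        )
    return out


class GsvaContext:
    """Precomputed per-sample rankings for repeated enrichment scoring.

    Sorting a z-matrix dominates the cost of the enrichment score; the
    discovery sweep evaluates many gene sets against the same matrix, so the
    sort is done once here and reused by :meth:`score`.
    """

    def __init__(self, z_expr: pd.DataFrame, tau: float = 1.0):
        if tau < 0:
            raise ValueError("tau must be >= 0")
        # canonical (lexicographic) gene order makes rank ties, and hence the
        # score, invariant to the input row order
        z_expr = z_expr.sort_index(kind="stable")
        self.genes = list(z_expr.index)
        self.samples = list(z_expr.columns)
        self.tau = tau
        self._gene_pos = {g: i for i, g in enumerate(self.genes)}
        z = z_expr.to_numpy(dtype=float)
        # stable argsort of -z: descending z, ties keep canonical gene order
        self.order = np.argsort(-z, axis=0, kind="stable")  # G x N
        sorted_z = np.take_along_axis(z, self.order, axis=0)
        self.sorted_weight = np.abs(sorted_z) ** tau

    def score(self, members: Sequence[str]) -> pd.Series:
        present = [g for g in members if g in self._gene_pos]
        if not present:
            raise ValueError("no gene-set member present in the matrix")
        if len(present) < len(members):
            warnings.warn(
                f"{len(members) - len(present)} gene-set member(s) absent from "
                "the matrix; dropped",
                stacklevel=3,
            )
        G = len(self.genes)
        m = len(present)
        if m == G:
            # no out-of-set genes to walk through: degenerate, defined as +1
            return pd.Series(1.0, index=self.samples)
        member_idx = np.fromiter((self._gene_pos[g] for g in present), dtype=int)
        in_set = np.zeros(G, dtype=bool)
        in_set[member_idx] = True
        sorted_in = in_set[self.order]  # G x N
        w = np.where(sorted_in, self.sorted_weight, 0.0)
        denom = w.sum(axis=0, keepdims=True)
        # all in-set |z| can be zero (e.g. all members constant): fall back to
        # equal increments so the walk still sums to +1 over in-set positions
        zero_denom = denom == 0.0
        if zero_denom.any():
            w = np.where(zero_denom & sorted_in, 1.0, w)
            denom = np.where(zero_denom, float(m), denom)
        steps = w / denom
        steps[~sorted_in] = -1.0 / (G - m)
        runsum = np.cumsum(steps, axis=0)
        es = np.maximum(runsum.max(axis=0), 0.0) + np.minimum(runsum.min(axis=0), 0.0)
        return pd.Series(es, index=self.samples)


def gsva_like_score(z_expr: pd.DataFrame, gene_set: GeneSet, tau: float = 1.0) -> pd.Series:
    """Single-sample enrichment score of ``gene_set`` for each sample.

    ``z_expr`` should already be z-scored per gene (see
    :func:`zscore_expression`).  Returns a per-sample Series in [-1, 1]
    (degenerate all-genes case: +1).
    """
    return GsvaContext(z_expr, tau=tau).score(gene_set.members)


_COXIS_EPS = 1e-6


def coxis_score(
    expr: pd.DataFrame,
    cp_genes: Optional[GeneSet] = None,
    ci_genes: Optional[GeneSet] = None,
) -> pd.Series:
    """COX-IS: log2 ratio of CP over CI mean linear-scale expression.

    ``expr`` is on the log2(x+1) scale; rows are mapped back to linear scale
    (``2**x - 1``) before averaging within each gene list, and the score is
    ``log2((mean_CP + eps) / (mean_CI + eps))``.  Positive scores indicate
    pro-tumor inflammation dominating the anti-tumor axis.
    """
    cp = cp_genes if cp_genes is not None else coxis_cp_genes()
    ci = ci_genes if ci_genes is not None else coxis_ci_genes()
    available = set(expr.index)
    cp_present = [r for g in cp.members if (r := resolve_symbol(g, available))]
    ci_present = [r for g in ci.members if (r := resolve_symbol(g, available))]
    if not cp_present:
        raise ValueError("no CP gene present in the expression matrix")
    if not ci_present:
        raise ValueError("no CI gene present in the expression matrix")
    n_missing = (len(cp.members) - len(cp_present)) + (len(ci.members) - len(ci_present))
    if n_missing:
        warnings.warn(f"COX-IS: {n_missing} gene(s) absent; dropped", stacklevel=2)
    linear = np.power(2.0, expr.to_numpy(dtype=float)) - 1.0
    lin = pd.DataFrame(linear, index=expr.index, columns=expr.columns)
    pos = lin.loc[cp_present].mean(axis=0)
    neg = lin.loc[ci_present].mean(axis=0)
    return np.log2((pos + _COXIS_EPS) / (neg + _COXIS_EPS))


def tmb(mutations: MutationTable, territory_mb: float = 38.0) -> pd.Series:
    """Tumor mutational burden: nonsynonymous mutations per megabase.

    Counts missense, frameshift indels and stop codons; synonymous and other
    classes are excluded.  TCGA exomes use a 38 Mb territory.
    """
    if not territory_mb > 0:
        raise ValueError("territory_mb must be positive")
    totals = {
        s: sum(mutations.counts.get(s, {}).get(c, 0) for c in NONSYNONYMOUS_CLASSES)
        for s in mutations.samples
    }
    return pd.Series(totals, dtype=float) / territory_mb


def median_stratify(values: pd.Series) -> pd.Series:
    """Split samples into "high"/"low" at the median; ties go to "low"."""
    vals = values.dropna()
    if len(vals) < 2:
        raise ValueError("median stratification needs at least 2 non-missing values")
    med = float(vals.median())
    if float(vals.max()) == float(vals.min()):
        warnings.warn("all values identical; every sample assigned 'low'", stacklevel=2)
    labels = pd.Series(
        np.where(values.to_numpy(dtype=float) > med, "high", "low"),
        index=values.index,
    )
    labels[values.isna()] = pd.NA
    return labels
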