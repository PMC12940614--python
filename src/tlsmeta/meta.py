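"""Inverse-variance meta-analysis of per-cohort effects.

Fixed-effect pooling weights each study by ``1/se_k^2``; the
DerSimonian-Laird random-effects model adds the moment estimate of the
between-study variance tau^2 to every study variance before reweighting:

    Q    = sum_k w_k (theta_k - theta_fixed)^2,      w_k = 1/se_k^2
    tau2 = max(0, (Q - (K-1)) / (sum w_k - sum w_k^2 / sum w_k))
    w*_k = 1 / (se_k^2 + tau2)

The overall effect is tested with a normal z-test (no Knapp-Hartung
adjustment).  Multiple-testing correction uses Benjamini-Hochberg.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import EffectEstimate, MetaResult

__all__ = ["pool_fixed", "pool_dersimonian_laird", "bh_fdr", "subgroup_meta"]


def _validate(effects: Sequence[EffectEstimate]) -> None:
    if not effects:
        raise ValueError("no effects to pool")
    for e in effects:
        if not (math.isfinite(e.estimate) and math.isfinite(e.se) and e.se > 0):
            raise ValueError(
                f"non-finite effect for cohort {e.cohort_id!r}: "
                f"estimate={e.estimate}, se={e.se}"
            )


def _pool(effects: Sequence[EffectEstimate], tau2: float, Q: float, I2: float, model: str) -> MetaResult:
    est = np.array([e.estimate for e in effects])
    var = np.array([e.se**2 for e in effects]) + tau2
    w = 1.0 / var
    pooled = float(np.sum(w * est) / np.sum(w))
    se = float(1.0 / math.sqrt(np.sum(w)))
    z = pooled / se
    p = 2.0 * stats.norm.sf(abs(z))
    wnorm = w / np.sum(w)
    return MetaResult(
        pooled=pooled,
        se=se,
        z=float(z),
        p=float(p),
        tau2=float(tau2),
        Q=float(Q),
        I2=float(I2),
        K=len(effects),
        weights={e.cohort_id: float(wk) for e, wk in zip(effects, wnorm)},
        model=model,
    )


def _heterogeneity(effects: Sequence[EffectEstimate]) -> tuple[float, float, float]:
    """Cochran's Q, DerSimonian-Laird tau^2 and I^2 from fixed weights."""
    est = np.array([e.estimate for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    theta_fixed = float(np.sum(w * est) / np.sum(w))
    Q = float(np.sum(w * (est - theta_fixed) ** 2))
    K = len(effects)
    if K < 2:
        return Q, 0.0, 0.0
    denom = float(np.sum(w) - np.sum(w**2) / np.sum(w))
    tau2 = max(0.0, (Q - (K - 1)) / denom) if denom > 0 else 0.0
    I2 = max(0.0, (Q - (K - 1)) / Q) if Q > 0 else 0.0
    return Q, tau2, I2


def pool_fixed(effects: Sequence[EffectEstimate]) -> MetaResult:
    """Fixed-effect (inverse-variance) pooled estimate."""
    _validate(effects)
    Q, _tau2, I2 = _heterogeneity(effects)
    return _pool(effects, tau2=0.0, Q=Q, I2=I2, model="fixed")


def pool_dersimonian_laird(effects: Sequence[EffectEstimate]) -> MetaResult:
    """DerSimonian-Laird random-effects pooled estimate.

    With a single study (or homogeneous studies, Q <= K-1) tau^2 truncates to
    0 and the result coincides with :func:`pool_fixed`.
    """
    _validate(effects)
    Q, tau2, I2 = _heterogeneity(effects)
    return _pool(effects, tau2=tau2, Q=Q, I2=I2, model="random")


def bh_fdr(p: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    arr = np.asarray(p, dtype=float)
    if arr.size == 0:
        return arr.copy()
    if np.any(~np.isfinite(arr)) or np.any(arr < 0) or np.any(arr > 1):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(arr, method="fdr_bh")[1]


def subgroup_meta(
    effects: Sequence[EffectEstimate],
    groups: Mapping[str, str],
    model: str = "random",
) -> dict[str, MetaResult]:
    """Pool effects independently within each subgroup label.

    ``groups`` maps cohort_id -> label (e.g. hot/cold immune context).  Every
    cohort in ``effects`` must be labeled.
    """
    pooler = {"fixed": pool_fixed, "random": pool_dersimonian_laird}[model]
    by_label: dict[str, list[EffectEstimate]] = {}
    for e in effects:
        if e.cohort_id not in groups:
            raise KeyError(f"cohort {e.cohort_id!r} has no subgroup label")
        by_label.setdefault(groups[e.cohort_id], []).append(e)
    return {label: pooler(subset) for label, subset in sorted(by_label.items())}


def effects_table(effects: Iterable[EffectEstimate], result: MetaResult | None = None) -> pd.DataFrame:
    """Forest-plot-ready table: one row per study plus an optional pooled row."""
    rows = [
        {
            "study": e.cohort_id,
            "estimate": e.estimate,
            "se": e.se,
            "p": e.p,
            "n": e.n,
            "events": e.events,
            "converged": e.converged,
            "weight": result.weights.get(e.cohort_id, float("nan")) if result else float("nan"),
        }
        for e in effects
    ]
    if result is not None:
        rows.append(
            {
                "study": f"pooled ({result.model})",
                "estimate": result.pooled,
                "se": result.se,
                "p": result.p,
                "n": sum(r["n"] for r in rows),
                "events": sum(r["events"] for r in rows),
                "converged": True,
                "weight": 1.0,
            }
        )
    return pd.DataFrame(rows)
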