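"""Per-cohort effect estimation and group comparison.

Effects are always reported on the log scale (log hazard ratio from a
univariate Cox model, log odds ratio from a univariate logistic model) with a
Wald standard error, matching the inputs the meta-analysis layer expects.

The Cox model maximizes the Breslow-ties partial likelihood by
Newton-Raphson with step halving; the logistic model is fit by iteratively
reweighted least squares and falls back to Jeffreys-prior (Firth)
penalization when the maximum-likelihood path diverges, which is common in
small checkpoint-blockade cohorts with quasi-separated scores.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass
from typing import Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import EffectEstimate

__all__ = [
    "classify_response",
    "SurvivalRecord",
    "fit_cox_univariate",
    "fit_logistic_univariate",
    "auc",
    "compare_auc",
    "km_logrank",
    "compare_groups",
    "correlate_signatures",
]


@dataclass(frozen=True)
class SurvivalRecord:
    """A single right-censored survival observation (time in months)."""

    time: float
    event: int

    def __post_init__(self) -> None:
        if not self.time > 0:
            raise ValueError(f"time must be strictly positive, got {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"event must be 0/1, got {self.event}")


# ---------------------------------------------------------------------------
# Responder classification

PFS_WINDOW_MONTHS = 6.0


def classify_response(
    recist: Optional[str],
    pfs_time: Optional[float] = None,
    pfs_event: Optional[int] = None,
) -> str:
    """Classify a patient as responder ("R"), non-responder ("NR") or
    "non_assessable" from RECIST category and progression-free survival.

    CR/PR are responders and PD non-responders outright.  SD counts as
    response unless a PFS event occurred within 6 months; SD with missing PFS
    is non-assessable.  Without RECIST, the 6-month PFS rule alone decides.
    """
    has_pfs = pfs_time is not None and pfs_event is not None
    early_event = has_pfs and pfs_event == 1 and pfs_time <= PFS_WINDOW_MONTHS
    if recist is None:
        if not has_pfs:
            raise ValueError("cannot classify: RECIST and PFS both missing")
        return "NR" if early_event else "R"
    if recist in ("CR", "PR"):
        return "R"
    if recist == "PD":
        return "NR"
    if recist == "SD":
        if not has_pfs:
            return "non_assessable"
        return "NR" if early_event else "R"
    raise ValueError(f"unknown RECIST category {recist!r}")


def classify_cohort(clinical) -> pd.Series:
    """Vectorized :func:`classify_response` over patient records."""
    return pd.Series(
        {
            r.sample_id: classify_response(r.recist, r.pfs_time, r.pfs_event)
            for r in clinical
        }
    )


# ---------------------------------------------------------------------------
# Univariate Cox regression (Breslow ties)


def _cox_sums(beta: float, x: np.ndarray, time: np.ndarray, event: np.ndarray):
    """Log-likelihood, gradient and information of the Breslow partial
    likelihood for a single centered covariate."""
    order = np.argsort(-time, kind="stable")  # descending: risk sets accumulate
    xs, ts, ds = x[order], time[order], event[order]
    eta = beta * xs
    r = np.exp(eta)
    s0 = np.cumsum(r)
    s1 = np.cumsum(r * xs)
    s2 = np.cumsum(r * xs * xs)
    # risk set at an event time t includes everyone with time >= t, i.e. all
    # subjects up to the last index sharing that time in the descending order
    ll = grad = info = 0.0
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j + 1 < n and ts[j + 1] == ts[i]:
            j += 1
        d = ds[i : j + 1].sum()
        if d > 0:
            S0, S1, S2 = s0[j], s1[j], s2[j]
            ll += eta[i : j + 1][ds[i : j + 1] == 1].sum() - d * math.log(S0)
            grad += xs[i : j + 1][ds[i : j + 1] == 1].sum() - d * S1 / S0
            info += d * (S2 / S0 - (S1 / S0) ** 2)
        i = j + 1
    return ll, grad, info


def cox_partial_loglik(beta: float, score, time, event) -> float:
    """Breslow-ties partial log-likelihood at ``beta`` (centered covariate)."""
    x = np.asarray(score, dtype=float)
    x = x - x.mean()
    return _cox_sums(beta, x, np.asarray(time, float), np.asarray(event, int).astype(float))[0]


def fit_cox_univariate(
    score,
    time,
    event,
    cohort_id: str = "",
    covariate: str = "score",
    max_iter: int = 100,
    tol: float = 1e-10,
) -> EffectEstimate:
    """Univariate Cox proportional-hazards fit (log hazard ratio per unit).

    Newton-Raphson with step halving on the Breslow-ties partial likelihood;
    the standard error comes from the inverse observed information.
    Non-convergence is flagged on the returned estimate, never silent.
    """
    x = np.asarray(score, dtype=float)
    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=float)
    if not (len(x) == len(t) == len(d)):
        raise ValueError("score, time and event must have equal length")
    if np.any(t <= 0):
        raise ValueError("survival times must be strictly positive")
    n_events = int(d.sum())
    if n_events < 2:
        raise ValueError(f"need >= 2 events, got {n_events}")
    if np.ptp(x) == 0:
        raise ValueError("score has zero variance")
    xc = x - x.mean()
    beta = 0.0
    ll, grad, info = _cox_sums(beta, xc, t, d)
    converged = False
    for _ in range(max_iter):
        if info <= 0:
            break
        step = grad / info
        new_beta = beta + step
        new_ll, new_grad, new_info = _cox_sums(new_beta, xc, t, d)
        halvings = 0
        while (not math.isfinite(new_ll) or new_ll < ll - 1e-12) and halvings < 30:
            step /= 2.0
            new_beta = beta + step
            new_ll, new_grad, new_info = _cox_sums(new_beta, xc, t, d)
            halvings += 1
        beta, ll, grad, info = new_beta, new_ll, new_grad, new_info
        if abs(step) < tol and abs(grad) < 1e-6:
            converged = True
            break
    if not math.isfinite(beta) or abs(beta) > 1e3:
        converged = False
    se = 1.0 / math.sqrt(info) if info > 0 and converged else float("nan")
    z = beta / se if se == se and se > 0 else float("nan")
    p = 2.0 * stats.norm.sf(abs(z)) if z == z else float("nan")
    return EffectEstimate(
        cohort_id=cohort_id,
        covariate=covariate,
        estimate=float(beta),
        se=float(se),
        p=float(p),
        n=len(x),
        events=n_events,
        converged=converged,
        method="cox_breslow",
    )


# ---------------------------------------------------------------------------
# Univariate logistic regression with Firth fallback


def _logit_design(score) -> np.ndarray:
    x = np.asarray(score, dtype=float)
    return np.column_stack([np.ones(len(x)), x])


def _irls(X: np.ndarray, y: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    beta = np.zeros(X.shape[1])
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        XtWX = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(XtWX, X.T @ (y - p))
        except np.linalg.LinAlgError:
            return beta, None, False
        beta = beta + step
        if np.max(np.abs(beta)) > 50.0:
            return beta, None, False
        if np.max(np.abs(step)) < tol:
            eta = X @ beta
            p = 1.0 / (1.0 + np.exp(-eta))
            W = p * (1.0 - p)
            XtWX = X.T @ (X * W[:, None])
            try:
                cov = np.linalg.inv(XtWX)
            except np.linalg.LinAlgError:
                return beta, None, False
            return beta, cov, True
    return beta, None, False


def _firth(X: np.ndarray, y: np.ndarray, max_iter: int = 200, tol: float = 1e-9):
    """Jeffreys-prior penalized logistic fit (finite under separation)."""
    beta = np.zeros(X.shape[1])
    cov = None
    for _ in range(max_iter):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        W = p * (1.0 - p)
        sqw = np.sqrt(W)
        XtWX = X.T @ (X * W[:, None])
        try:
            cov = np.linalg.inv(XtWX)
        except np.linalg.LinAlgError:
            return beta, None, False
        # hat diagonal of W^(1/2) X (X'WX)^-1 X' W^(1/2)
        B = (X * sqw[:, None]) @ cov
        h = np.einsum("ij,ij->i", B, X * sqw[:, None])
        score_mod = X.T @ (y - p + h * (0.5 - p))
        step = cov @ score_mod
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            return beta, cov, True
    return beta, cov, False


def fit_logistic_univariate(
    score,
    response,
    cohort_id: str = "",
    covariate: str = "score",
) -> EffectEstimate:
    """Univariate logistic fit of responder status on a score (log odds
    ratio per unit).

    ``response`` may be "R"/"NR" labels or a 0/1 vector (1 = responder).
    On separation or non-convergence of maximum likelihood, refits with
    Firth penalization and flags ``converged=False`` / ``method="firth"``.
    """
    y = _response_to_binary(response)
    x = np.asarray(score, dtype=float)
    if len(x) != len(y):
        raise ValueError("score and response must have equal length")
    if y.min() == y.max():
        raise ValueError("both responder classes must be present")
    if np.ptp(x) == 0:
        raise ValueError("score has zero variance")
    X = _logit_design(x)
    beta, cov, ok = _irls(X, y)
    method = "ml"
    if not ok or cov is None or not np.all(np.isfinite(np.sqrt(np.diag(cov)))):
        beta, cov, firth_ok = _firth(X, y)
        method = "firth"
        if cov is None:
            raise RuntimeError("logistic fit failed even with Firth penalization")
        ok = False  # ML path did not converge; Firth estimate is flagged
    se = float(math.sqrt(cov[1, 1]))
    est = float(beta[1])
    z = est / se
    p = 2.0 * stats.norm.sf(abs(z))
    return EffectEstimate(
        cohort_id=cohort_id,
        covariate=covariate,
        estimate=est,
        se=se,
        p=float(p),
        n=len(y),
        events=int(y.sum()),
        converged=bool(ok),
        method=method,
    )


def _response_to_binary(response) -> np.ndarray:
    arr = np.asarray(response)
    if arr.dtype.kind in "biuf":
        y = arr.astype(float)
        if not set(np.unique(y)) <= {0.0, 1.0}:
            raise ValueError("numeric response must be 0/1")
        return y
    labels = set(np.unique(arr))
    if not labels <= {"R", "NR"}:
        raise ValueError(
            f"response labels must be R/NR (exclude non_assessable first), got {labels}"
        )
    return (arr == "R").astype(float)


# ---------------------------------------------------------------------------
# AUC and the DeLong paired comparison


def auc(score, labels) -> float:
    """Probability a responder outscores a non-responder (ties count 0.5).

    Equivalent to the Mann-Whitney U statistic divided by n_R * n_NR.
    """
    y = _response_to_binary(labels)
    x = np.asarray(score, dtype=float)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present")
    ranks = stats.rankdata(x)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def _midrank_placements(x_pos: np.ndarray, x_neg: np.ndarray):
    """DeLong structural components (placements) for one score."""
    n1, n0 = len(x_pos), len(x_neg)
    allv = np.concatenate([x_pos, x_neg])
    tz = stats.rankdata(allv)
    tx = stats.rankdata(x_pos)
    ty = stats.rankdata(x_neg)
    v10 = (tz[:n1] - tx) / n0  # per positive
    v01 = 1.0 - (tz[n1:] - ty) / n1  # per negative
    return v10, v01


class AUCComparison(NamedTuple):
    auc_a: float
    auc_b: float
    delta: float
    z: float
    p: float


def compare_auc(score_a, score_b, labels) -> AUCComparison:
    """Paired DeLong test for the difference of two AUCs on the same samples."""
    y = _response_to_binary(labels)
    a = np.asarray(score_a, dtype=float)
    b = np.asarray(score_b, dtype=float)
    if not (len(a) == len(b) == len(y)):
        raise ValueError("scores and labels must cover the same samples")
    if y.min() == y.max():
        raise ValueError("both classes must be present")
    pos, neg = y == 1, y == 0
    v10a, v01a = _midrank_placements(a[pos], a[neg])
    v10b, v01b = _midrank_placements(b[pos], b[neg])
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    n1, n0 = int(pos.sum()), int(neg.sum())
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1) if n1 > 1 else np.zeros((2, 2))
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1) if n0 > 1 else np.zeros((2, 2))
    var = (
        (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / n1
        + (s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]) / n0
    )
    delta = auc_a - auc_b
    if var <= 1e-15:
        if abs(delta) < 1e-12:
            return AUCComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
        raise ValueError("degenerate DeLong variance with nonzero AUC difference")
    z = delta / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a, auc_b, float(delta), float(z), float(p))


# ---------------------------------------------------------------------------
# Kaplan-Meier at median split with log-rank test


class KMResult(NamedTuple):
    curves: dict  # arm -> DataFrame(time, survival)
    chi2: float
    p: float
    split_value: float


def km_logrank(scores: pd.Series, time, event) -> KMResult:
    """Median-split Kaplan-Meier curves plus the log-rank test (1 df)."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    from .scoring import median_stratify

    t = np.asarray(time, dtype=float)
    d = np.asarray(event, dtype=int)
    arms = median_stratify(pd.Series(np.asarray(scores, dtype=float)))
    curves = {}
    for label in ("high", "low"):
        mask = (arms == label).to_numpy()
        if mask.sum() == 0 or d[mask].sum() == 0:
            raise ValueError(f"arm {label!r} is empty or has no events")
        kmf = KaplanMeierFitter()
        kmf.fit(t[mask], d[mask], label=label)
        sf = kmf.survival_function_
        curves[label] = pd.DataFrame(
            {"time": sf.index.to_numpy(), "survival": sf[label].to_numpy()}
        )
    hi = (arms == "high").to_numpy()
    res = logrank_test(t[hi], t[~hi], event_observed_A=d[hi], event_observed_B=d[~hi])
    med = float(pd.Series(np.asarray(scores, dtype=float)).median())
    return KMResult(curves=curves, chi2=float(res.test_statistic), p=float(res.p_value), split_value=med)


# ---------------------------------------------------------------------------
# Group comparisons with small-sample permutation fallback


class GroupComparison(NamedTuple):
    statistic: float
    p: float
    method: str


SMALL_SAMPLE_N = 10
_EXACT_LIMIT = 50_000


def compare_groups(
    x,
    y,
    kind: str = "auto",
    seed: Optional[int] = None,
    n_permutations: int = 10_000,
) -> GroupComparison:
    """Compare two groups: Wilcoxon rank-sum for continuous data, with a
    seeded permutation test of the rank-sum statistic when either group has
    fewer than 10 observations; Fisher's exact test for categorical data.
    """
    x_arr = np.asarray(x)
    y_arr = np.asarray(y)
    if len(x_arr) == 0 or len(y_arr) == 0:
        raise ValueError("both groups must be nonempty")
    if kind == "auto":
        kind = "continuous" if x_arr.dtype.kind in "biuf" else "categorical"
    if kind == "categorical":
        return _fisher(x_arr, y_arr)
    xf = x_arr.astype(float)
    yf = y_arr.astype(float)
    if min(len(xf), len(yf)) >= SMALL_SAMPLE_N:
        u, p = stats.mannwhitneyu(xf, yf, alternative="two-sided")
        return GroupComparison(float(u), float(p), "wilcoxon")
    return _permutation_ranksum(xf, yf, seed=seed, n_permutations=n_permutations)


def _permutation_ranksum(x, y, seed, n_permutations) -> GroupComparison:
    n1, n = len(x), len(x) + len(y)
    pooled_ranks = stats.rankdata(np.concatenate([x, y]))
    t_obs = pooled_ranks[:n1].sum()
    center = n1 * (n + 1) / 2.0  # exact null mean of the rank sum
    dev_obs = abs(t_obs - center)
    n_comb = math.comb(n, n1)
    if n_comb <= _EXACT_LIMIT:
        count = sum(
            1
            for idx in itertools.combinations(range(n), n1)
            if abs(pooled_ranks[list(idx)].sum() - center) >= dev_obs - 1e-9
        )
        return GroupComparison(float(t_obs), count / n_comb, "permutation_exact")
    rng = np.random.default_rng(seed)
    count = 1  # include the observed assignment
    for _ in range(n_permutations):
        idx = rng.choice(n, size=n1, replace=False)
        if abs(pooled_ranks[idx].sum() - center) >= dev_obs - 1e-9:
            count += 1
    return GroupComparison(float(t_obs), count / (n_permutations + 1), "permutation_mc")


def _fisher(x: np.ndarray, y: np.ndarray) -> GroupComparison:
    cats = sorted(set(x.tolist()) | set(y.tolist()))
    if len(cats) == 1:
        return GroupComparison(1.0, 1.0, "fisher")
    if len(cats) != 2:
        raise ValueError(f"Fisher's exact test needs exactly 2 categories, got {cats}")
    table = [
        [int(np.sum(x == cats[0])), int(np.sum(x == cats[1]))],
        [int(np.sum(y == cats[0])), int(np.sum(y == cats[1]))],
    ]
    odds, p = stats.fisher_exact(table, alternative="two-sided")
    return GroupComparison(float(odds), float(p), "fisher")


# ---------------------------------------------------------------------------
# Median Spearman correlation across cohorts


def correlate_signatures(score_frames: Mapping[str, pd.DataFrame]) -> pd.DataFrame:
    """Median-across-cohorts Spearman correlation between signature scores.

    Each value of ``score_frames`` is a samples x signatures frame for one
    cohort; all cohorts must carry the same signature columns.  Constant
    score vectors yield missing correlations (with a warning) and are
    ignored by the median.
    """
    frames = list(score_frames.values())
    if not frames:
        raise ValueError("no cohorts given")
    sigs = list(frames[0].columns)
    if len(sigs) < 2:
        raise ValueError("need at least 2 signatures")
    mats = []
    for cid, frame in score_frames.items():
        if list(frame.columns) != sigs:
            raise ValueError(f"cohort {cid!r}: signature columns differ")
        if frame.shape[0] < 3:
            raise ValueError(f"cohort {cid!r}: need >= 3 samples")
        vals = frame.to_numpy(dtype=float)
        const = vals.std(axis=0) == 0
        if const.any():
            warnings.warn(
                f"cohort {cid!r}: constant score for "
                f"{[s for s, c in zip(sigs, const) if c]}; correlations missing",
                stacklevel=2,
            )
        rho = frame.corr(method="spearman").to_numpy()
        rho[const, :] = np.nan
        rho[:, const] = np.nan
        mats.append(rho)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
        med = np.nanmedian(np.stack(mats), axis=0)
    np.fill_diagonal(med, 1.0)
    return pd.DataFrame(med, index=sigs, columns=sigs)
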