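"""Core value types shared across the package.

Expression matrices are plain :class:`pandas.DataFrame` objects with gene
symbols as the row index and sample ids as columns, on the log2(x+1) scale
unless a function documents otherwise.  The small dataclasses below carry
everything else: gene sets, per-cohort effect estimates, pooled meta-analysis
results, simulated cohorts and spatial samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import pandas as pd

RECIST_CATEGORIES = ("CR", "PR", "SD", "PD")
MUTATION_CLASSES = ("missense", "frameshift_indel", "stop_codon", "synonymous", "other")
NONSYNONYMOUS_CLASSES = ("missense", "frameshift_indel", "stop_codon")
SPOT_ANNOTATIONS = ("mature_tls", "immature_tls", "none")
MATURITY_LABELS = ("mature", "immature", "negative")


@dataclass(frozen=True)
class GeneSet:
    """A named, ordered set of unique gene symbols."""

    name: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        members = tuple(self.members)
        if not members:
            raise ValueError(f"gene set {self.name!r} is empty")
        if len(set(members)) != len(members):
            dups = sorted({g for g in members if members.count(g) > 1})
            raise ValueError(f"gene set {self.name!r} has duplicate members: {dups}")
        object.__setattr__(self, "members", members)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)

    def intersect(self, genes: Sequence[str]) -> tuple[str, ...]:
        """Members present in ``genes``, in signature order."""
        pool = set(genes)
        return tuple(g for g in self.members if g in pool)


@dataclass
class EffectEstimate:
    """One cohort's log-scale effect (log hazard ratio or log odds ratio).

    ``estimate`` and ``se`` are on the log scale per one unit of the
    covariate (one z-unit when the score was standardized upstream).
    """

    cohort_id: str
    covariate: str
    estimate: float
    se: float
    p: float
    n: int
    events: int
    converged: bool = True
    method: str = "ml"

    def __post_init__(self) -> None:
        if self.converged and not (math.isfinite(self.se) and self.se > 0):
            raise ValueError(
                f"converged estimate for {self.cohort_id}/{self.covariate} "
                f"has invalid se={self.se}"
            )


@dataclass
class MetaResult:
    """Pooled effect across cohorts (fixed or DerSimonian-Laird random)."""

    pooled: float
    se: float
    z: float
    p: float
    tau2: float
    Q: float
    I2: float
    K: int
    weights: dict[str, float]
    model: str  # "fixed" | "random"


@dataclass
class PatientRecord:
    sample_id: str
    recist: Optional[str]  # CR/PR/SD/PD or None
    pfs_time: Optional[float]  # months, > 0
    pfs_event: Optional[int]  # 0/1
    os_time: float  # months, > 0
    os_event: int  # 0/1
    tmb: Optional[float] = None  # mutations/Mb

    def __post_init__(self) -> None:
        if self.recist is not None and self.recist not in RECIST_CATEGORIES:
            raise ValueError(f"unknown RECIST category {self.recist!r}")
        for name, t in (("pfs_time", self.pfs_time), ("os_time", self.os_time)):
            if t is not None and not t > 0:
                raise ValueError(f"{name} must be strictly positive, got {t}")
        for name, e in (("pfs_event", self.pfs_event), ("os_event", self.os_event)):
            if e is not None and e not in (0, 1):
                raise ValueError(f"{name} must be 0 or 1, got {e}")


@dataclass
class CohortDataset:
    """One ICB-like cohort: expression plus aligned clinical records."""

    cohort_id: str
    cancer_type: str
    immune_context: str  # "hot" | "cold"
    expression: pd.DataFrame  # genes x samples, log2(x+1)
    clinical: list[PatientRecord]

    def __post_init__(self) -> None:
        if self.immune_context not in ("hot", "cold"):
            raise ValueError(f"immune_context must be hot/cold, got {self.immune_context!r}")
        ids = [r.sample_id for r in self.clinical]
        if len(set(ids)) != len(ids):
            raise ValueError(f"cohort {self.cohort_id}: duplicate sample ids")
        if list(self.expression.columns) != ids:
            raise ValueError(
                f"cohort {self.cohort_id}: clinical records not aligned with "
                "expression columns"
            )

    @property
    def n_samples(self) -> int:
        return self.expression.shape[1]

    def clinical_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "recist": r.recist if r.recist is not None else "missing",
                "pfs_time": r.pfs_time,
                "pfs_event": r.pfs_event,
                "os_time": r.os_time,
                "os_event": r.os_event,
                "tmb": r.tmb,
            }
            for r in self.clinical
        ]
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class SpatialSample:
    """A spot grid with expression and per-spot TLS annotation."""

    sample_id: str
    section_type: str  # "frozen" | "FFPE"
    spots: list[tuple[int, int]]
    expression: pd.DataFrame  # genes x spots
    tls_annotation: list[str]  # per spot: mature_tls / immature_tls / none
    maturity_label: str  # sample level: mature / immature / negative

    def __post_init__(self) -> None:
        if self.maturity_label not in MATURITY_LABELS:
            raise ValueError(f"unknown maturity label {self.maturity_label!r}")
        if len(self.tls_annotation) != len(self.spots):
            raise ValueError("annotation length != number of spots")
        if self.expression.shape[1] != len(self.spots):
            raise ValueError("expression columns != number of spots")
        bad = set(self.tls_annotation) - set(SPOT_ANNOTATIONS)
        if bad:
            raise ValueError(f"unknown spot annotations: {sorted(bad)}")
        if self.maturity_label == "negative" and any(
            a == "mature_tls" for a in self.tls_annotation
        ):
            raise ValueError("TLS-negative sample has spots annotated mature_tls")

    @property
    def n_spots(self) -> int:
        return len(self.spots)


@dataclass
class TruthSet:
    """Ground truth of the synthetic generator.

    The planted TLS program is a single latent activity per patient; each
    signature gene loads on it with loading ``gene_loadings[g]``, response is
    Bernoulli(logistic(alpha_k + gamma * activity)) and overall survival has
    hazard lambda * exp(delta * activity).
    """

    signature_genes: tuple[str, ...]
    gene_loadings: dict[str, float]
    activity_effect_response: float  # gamma, log-odds per unit activity
    activity_effect_hazard: float  # delta, log-hazard per unit activity
    cohort_intercepts: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.signature_genes:
            raise ValueError("signature_genes must be nonempty")
        if set(self.gene_loadings) != set(self.signature_genes):
            raise ValueError("gene_loadings keys must equal signature_genes")


@dataclass
class MutationTable:
    """Per-sample mutation counts by consequence class."""

    samples: list[str]
    counts: dict[str, dict[str, int]]  # sample -> class -> count

    def __post_init__(self) -> None:
        for s in self.samples:
            for cls, c in self.counts.get(s, {}).items():
                if cls not in MUTATION_CLASSES:
                    raise ValueError(f"unknown consequence class {cls!r}")
                if c < 0 or int(c) != c:
                    raise ValueError(f"negative or non-integer count for {s}/{cls}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [[self.counts[s].get(c, 0) for c in MUTATION_CLASSES] for s in self.samples],
            index=self.samples,
            columns=list(MUTATION_CLASSES),
        )


@dataclass
class SpotAUCReport:
    """Spot-level TLS detection for one spatial sample."""

    sample_id: str
    maturity_label: str
    n_spots: int
    n_tls_spots: int
    auc: Optional[float]  # None when only one class is present


@dataclass
class SweepResult:
    """Result of the log-odds cutoff sweep."""

    cutoffs: list[float]
    sizes: list[int]  # 0 where the signature was empty
    mean_aucs: list[float]  # NaN where the signature was empty
    members: list[tuple[str, ...]]
    selected_cutoff: float
    final_signature: GeneSet
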