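"""Bundled gene signatures and gene-symbol normalization.

The packaged GMT carries the 17-gene PredictTLS signature plus the
cancer-promoting (CP) and cancer-inhibitory (CI) inflammatory gene lists that
make up the COX-IS score.  Symbols are matched HGNC-style: hyphens and dots
are stripped (``ICAM-1`` -> ``ICAM1``) and a small alias table maps legacy
names to current ones (``IL8`` <-> ``CXCL8``) so either spelling is found in
an expression matrix.
"""

from __future__ import annotations

from importlib import resources

from .datatypes import GeneSet
from .io import read_gmt

# legacy -> current HGNC symbol; matching tries both directions
SYMBOL_ALIASES = {
    "IL8": "CXCL8",
    "GPR15": "GPR15",
}
_REVERSE_ALIASES = {v: k for k, v in SYMBOL_ALIASES.items()}


def normalize_symbol(symbol: str) -> str:
    """Canonicalize a gene symbol (uppercase, strip hyphens/dots)."""
    return symbol.strip().upper().replace("-", "").replace(".", "")


def resolve_symbol(symbol: str, available: set[str]) -> str | None:
    """Find ``symbol`` in ``available``, trying aliases; None if absent."""
    if symbol in available:
        return symbol
    norm = normalize_symbol(symbol)
    if norm in available:
        return norm
    for table in (SYMBOL_ALIASES, _REVERSE_ALIASES):
        alias = table.get(symbol) or table.get(norm)
        if alias and alias in available:
            return alias
    return None


def _bundled_sets() -> dict[str, GeneSet]:
    path = resources.files("tlsmeta").joinpath("data/tls_signatures.gmt")
    with resources.as_file(path) as p:
        return {gs.name: gs for gs in read_gmt(p)}


def predicttls_signature() -> GeneSet:
    """The 17-gene PredictTLS signature."""
    return _bundled_sets()["PredictTLS"]


def coxis_cp_genes() -> GeneSet:
    """Cancer-promoting (CP) inflammatory genes of COX-IS."""
    return _bundled_sets()["COXIS_CP"]


def coxis_ci_genes() -> GeneSet:
    """Cancer-inhibitory (CI) inflammatory genes of COX-IS."""
    return _bundled_sets()["COXIS_CI"]


# TCGA cancer-type stratification by immune infiltration context.
HOT_CANCER_TYPES = (
    "BLCA", "BRCA", "CESC", "COAD", "READ", "HNSC", "KIRC", "LIHC", "LUAD",
    "LUSC", "LUNG", "MESO", "OV", "PAAD", "PRAD", "SKCM", "STAD", "UCEC",
)
COLD_CANCER_TYPES = (
    "ACC", "CHOL", "DLBC", "ESCA", "KICH", "KIRP", "TGCT", "THCA", "THYM",
    "UCS", "UVM", "GBM", "LGG", "PCPG", "SARC",
)


def immune_context(cancer_type: str) -> str:
    """Map a cancer-type code to its hot/cold immune context."""
    if cancer_type in HOT_CANCER_TYPES:
        return "hot"
    if cancer_type in COLD_CANCER_TYPES:
        return "cold"
    raise KeyError(f"cancer type {cancer_type!r} has no hot/cold assignment")
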