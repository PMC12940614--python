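"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects:

* **GMT** — one gene set per line: ``name<TAB>description<TAB>gene1<TAB>...``.
* **Expression TSV** — genes as rows (first column ``gene``), one column per
  sample, tab separated, log2(x+1) values.
* **Clinical TSV** — columns ``sample_id, recist, pfs_time, pfs_event,
  os_time, os_event, tmb``; missing values written as ``NA``.
* **Spot CSV** — columns ``spot_id, x, y, annotation``.

All float output uses 6 significant digits so that file hashes are portable.
"""

from __future__ import annotations

import json
import math
import warnings
from pathlib import Path
from typing import Iterable, Optional, Union

import numpy as np
import pandas as pd

from .datatypes import (
    GeneSet,
    MutationTable,
    PatientRecord,
    RECIST_CATEGORIES,
    SPOT_ANNOTATIONS,
    SpatialSample,
    TruthSet,
)

FLOAT_FORMAT = "%.6g"

PathLike = Union[str, Path]


class FormatError(ValueError):
    """Malformed input file; message carries the offending line number."""


# ---------------------------------------------------------------------------
# GMT gene sets


def read_gmt(path: PathLike) -> list[GeneSet]:
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f"at least one member (got {len(fields)} fields)"
                )
            name, _desc, *members = fields
            members = [m for m in members if m]
            unique = list(dict.fromkeys(members))
            if len(unique) != len(members):
                warnings.warn(
                    f"{path}:{lineno}: gene set {name!r} has duplicate members; "
                    "deduplicated",
                    stacklevel=2,
                )
            sets.append(GeneSet(name=name, members=tuple(unique)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: PathLike, description: str = "") -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.name, description, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# Expression matrices


def read_expression_tsv(path: PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.index.name = "gene"
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()].unique().tolist()
        raise FormatError(f"{path}: duplicate gene symbols: {dup[:5]}")
    if df.isna().any().any():
        gene = df.index[df.isna().any(axis=1)][0]
        raise FormatError(f"{path}: missing value in gene row {gene!r}")
    return df.astype(float)


def write_expression_tsv(
    expr: pd.DataFrame, path: PathLike, float_format: Optional[str] = None
) -> None:
    """Write a genes x samples matrix; full float precision by default so a
    write/read round trip is lossless (pass ``FLOAT_FORMAT`` for fixed-width
    output when portable file hashes matter)."""
    out = expr.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=float_format)


# ---------------------------------------------------------------------------
# Clinical tables

_CLINICAL_COLUMNS = ["sample_id", "recist", "pfs_time", "pfs_event", "os_time", "os_event", "tmb"]


def _opt_float(value, field: str, row: int, path) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)) or value == "NA":
        return None
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(f"{path}: row {row}: bad {field} value {value!r}") from None


def read_clinical_tsv(path: PathLike) -> list[PatientRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "recist": str})
    missing = set(_CLINICAL_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    records: list[PatientRecord] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):  # 1-based + header
        recist = row.recist
        if recist in ("missing", "NA", "", None) or (
            isinstance(recist, float) and math.isnan(recist)
        ):
            recist = None
        elif recist not in RECIST_CATEGORIES:
            raise FormatError(f"{path}: row {i}: unknown RECIST value {row.recist!r}")
        pfs_time = _opt_float(row.pfs_time, "pfs_time", i, path)
        pfs_event = _opt_float(row.pfs_event, "pfs_event", i, path)
        os_time = _opt_float(row.os_time, "os_time", i, path)
        os_event = _opt_float(row.os_event, "os_event", i, path)
        tmb = _opt_float(row.tmb, "tmb", i, path)
        if os_time is None or os_event is None:
            raise FormatError(f"{path}: row {i}: os_time/os_event are required")
        try:
            records.append(
                PatientRecord(
                    sample_id=str(row.sample_id),
                    recist=recist,
                    pfs_time=pfs_time,
                    pfs_event=None if pfs_event is None else int(pfs_event),
                    os_time=os_time,
                    os_event=int(os_event),
                    tmb=tmb,
                )
            )
        except ValueError as exc:
            raise FormatError(f"{path}: row {i}: {exc}") from None
    return records


def write_clinical_tsv(records: Iterable[PatientRecord], path: PathLike) -> None:
    rows = []
    for r in records:
        rows.append(
            {
                "sample_id": r.sample_id,
                "recist": r.recist if r.recist is not None else "NA",
                "pfs_time": r.pfs_time,
                "pfs_event": r.pfs_event,
                "os_time": r.os_time,
                "os_event": r.os_event,
                "tmb": r.tmb,
            }
        )
    pd.DataFrame(rows, columns=_CLINICAL_COLUMNS).to_csv(
        path, sep="\t", index=False, float_format=FLOAT_FORMAT, na_rep="NA"
    )


# ---------------------------------------------------------------------------
# Spatial samples


def write_spatial(sample: SpatialSample, spot_csv: PathLike, expr_tsv: PathLike) -> None:
    spot_ids = list(sample.expression.columns)
    pd.DataFrame(
        {
            "spot_id": spot_ids,
            "x": [x for x, _ in sample.spots],
            "y": [y for _, y in sample.spots],
            "annotation": sample.tls_annotation,
        }
    ).to_csv(spot_csv, index=False)
    write_expression_tsv(sample.expression, expr_tsv)


def read_spatial(
    spot_csv: PathLike,
    expr_tsv: PathLike,
    sample_id: str = "sample",
    section_type: str = "frozen",
    maturity_label: Optional[str] = None,
) -> SpatialSample:
    spots_df = pd.read_csv(spot_csv, dtype={"spot_id": str})
    for col in ("spot_id", "x", "y", "annotation"):
        if col not in spots_df.columns:
            raise FormatError(f"{spot_csv}: missing column {col!r}")
    bad = ~spots_df["annotation"].isin(SPOT_ANNOTATIONS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0]) + 2
        raise FormatError(
            f"{spot_csv}: row {row}: unknown annotation "
            f"{spots_df['annotation'][bad].iloc[0]!r}"
        )
    expr = read_expression_tsv(expr_tsv)
    if list(expr.columns) != spots_df["spot_id"].tolist():
        raise FormatError(f"{expr_tsv}: spot columns do not match {spot_csv}")
    annotation = spots_df["annotation"].tolist()
    if maturity_label is None:
        if "mature_tls" in annotation:
            maturity_label = "mature"
        elif "immature_tls" in annotation:
            maturity_label = "immature"
        else:
            maturity_label = "negative"
    return SpatialSample(
        sample_id=sample_id,
        section_type=section_type,
        spots=list(zip(spots_df["x"].astype(int), spots_df["y"].astype(int))),
        expression=expr,
        tls_annotation=annotation,
        maturity_label=maturity_label,
    )


# ---------------------------------------------------------------------------
# Truth sets and mutation tables


def write_truth_json(truth: TruthSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "signature_genes": list(truth.signature_genes),
                "gene_loadings": truth.gene_loadings,
                "activity_effect_response": truth.activity_effect_response,
                "activity_effect_hazard": truth.activity_effect_hazard,
                "cohort_intercepts": truth.cohort_intercepts,
            },
            fh,
            indent=2,
            sort_keys=True,
        )
        fh.write("\n")


def read_truth_json(path: PathLike) -> TruthSet:
    with open(path) as fh:
        d = json.load(fh)
    return TruthSet(
        signature_genes=tuple(d["signature_genes"]),
        gene_loadings={k: float(v) for k, v in d["gene_loadings"].items()},
        activity_effect_response=float(d["activity_effect_response"]),
        activity_effect_hazard=float(d["activity_effect_hazard"]),
        cohort_intercepts={k: float(v) for k, v in d.get("cohort_intercepts", {}).items()},
    )


def write_mutation_tsv(table: MutationTable, path: PathLike) -> None:
    df = table.to_frame()
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t")


def read_mutation_tsv(path: PathLike) -> MutationTable:
    df = pd.read_csv(path, sep="\t", index_col=0)
    counts = {
        str(s): {c: int(df.loc[s, c]) for c in df.columns} for s in df.index
    }
    return MutationTable(samples=[str(s) for s in df.index], counts=counts)
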