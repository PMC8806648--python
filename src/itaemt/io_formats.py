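"""Readers and writers for the delimited-text formats the pipeline touches.

GMT (MSigDB dialect: name, description, genes, tab-separated) for gene
sets; headed TSV/CSV for expression, signature and clinical tables.
Gene identifiers are matched by exact, case-sensitive string equality;
missing expression values abort the read rather than being imputed,
because every downstream score is a mean over genes.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    ExpressionMatrix,
    GeneSetCollection,
    SignatureMatrix,
    ValidationError,
)

log = logging.getLogger(__name__)

__all__ = [
    "read_gmt",
    "write_gmt",
    "read_expression_table",
    "write_expression_table",
    "read_signature_table",
    "read_clinical_table",
    "write_clinical_table",
    "align_cohort",
]

#: accepted spellings for the event indicator (case-insensitive)
DEFAULT_EVENT_ALIASES = {
    "0": 0, "1": 1, "alive": 0, "dead": 1, "censored": 0, "deceased": 1,
    "false": 0, "true": 1,
}


def read_gmt(path) -> GeneSetCollection:
    """Parse a GMT file: one gene set per line, ``name<TAB>desc<TAB>genes...``.

    Duplicate genes within a line are dropped (first occurrence kept) with
    a warning; a duplicate set name or a line with fewer than three fields
    is an error.
    """
    path = Path(path)
    sets: dict = {}
    with path.open() as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValidationError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, expected >= 3"
                )
            name = fields[0]
            if name in sets:
                raise ValidationError(f"{path}:{lineno}: duplicate set name {name!r}")
            genes, seen = [], set()
            n_dup = 0
            for g in fields[2:]:
                if not g:
                    continue
                if g in seen:
                    n_dup += 1
                    continue
                seen.add(g)
                genes.append(g)
            if n_dup:
                log.warning("%s:%d: dropped %d duplicate genes in set %s",
                            path, lineno, n_dup, name)
            if not genes:
                raise ValidationError(f"{path}:{lineno}: set {name!r} has no genes")
            sets[name] = genes
    return GeneSetCollection(sets=sets, source_tag=str(path))


def write_gmt(collection: GeneSetCollection, path, description: str = "na") -> None:
    path = Path(path)
    with path.open("w") as fh:
        for name, genes in collection.sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")


def _read_table(path, sep: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)


def _to_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    out = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna()
        if bad.any():
            row = df.index[bad.to_numpy().argmax()]
            raise ValidationError(
                f"{path}: non-numeric value {df.loc[row, col]!r} at row {row!r}, column {col!r}"
            )
        out[:, j] = converted.to_numpy()
    return pd.DataFrame(out, index=df.index, columns=df.columns)


def read_expression_table(path, orientation: str = "genes_in_rows",
                          sep: str = "\t") -> ExpressionMatrix:
    """Read a headed expression table into genes x samples orientation.

    ``orientation`` declares the layout on disk (``genes_in_rows`` or
    ``samples_in_rows``); the returned matrix is always genes x samples.
    Non-numeric cells, duplicate gene ids and negative values are errors.
    """
    if orientation not in ("genes_in_rows", "samples_in_rows"):
        raise ValidationError(f"unknown orientation {orientation!r}")
    df = _to_numeric(_read_table(path, sep), path)
    if orientation == "samples_in_rows":
        df = df.T
    return ExpressionMatrix(df, scale_tag="linear")


def write_expression_table(expr: ExpressionMatrix, path, sep: str = "\t") -> None:
    expr.data.to_csv(path, sep=sep, index_label="gene_id", float_format="%.10g")


def read_signature_table(path, sep: str = "\t") -> SignatureMatrix:
    """Read a genes x cell-types signature table (e.g. an LM22-style matrix)."""
    return SignatureMatrix(_to_numeric(_read_table(path, sep), path))


def read_clinical_table(path, column_map: dict | None = None, sep: str = "\t",
                        event_aliases: dict | None = None,
                        cohort: str = "unlabeled") -> ClinicalTable:
    """Read per-sample survival follow-up.

    ``column_map`` maps the canonical names ``sample_id``, ``os_time``,
    ``os_event`` (optionally ``cohort``) to the column names on disk.
    Rows with a missing time or event are dropped with a logged count;
    event spellings are resolved through ``event_aliases``.
    """
    column_map = column_map or {}
    aliases = dict(DEFAULT_EVENT_ALIASES)
    if event_aliases:
        aliases.update({str(k).lower(): v for k, v in event_aliases.items()})
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    names = {
        "sample_id": column_map.get("sample_id", "sample_id"),
        "os_time": column_map.get("os_time", "os_time"),
        "os_event": column_map.get("os_event", "os_event"),
    }
    for canon, col in names.items():
        if col not in df.columns:
            raise ValidationError(f"{path}: missing column {col!r} (mapped from {canon})")
    sub = df[[names["sample_id"], names["os_time"], names["os_event"]]].copy()
    sub.columns = ["sample_id", "os_time", "os_event"]
    missing = (sub["os_time"].str.strip() == "") | (sub["os_event"].str.strip() == "") \
        | sub["os_time"].str.lower().isin(["na", "nan"]) \
        | sub["os_event"].str.lower().isin(["na", "nan"])
    if missing.any():
        log.info("%s: dropped %d rows with missing time/event", path, int(missing.sum()))
    sub = sub[~missing]
    times = pd.to_numeric(sub["os_time"], errors="coerce")
    if times.isna().any():
        bad = sub["os_time"][times.isna()].iloc[0]
        raise ValidationError(f"{path}: non-numeric os_time {bad!r}")
    events = []
    for v in sub["os_event"]:
        key = str(v).strip().lower()
        if key not in aliases:
            raise ValidationError(f"{path}: unrecognized event value {v!r}")
        events.append(aliases[key])
    cohort_col = column_map.get("cohort")
    cohorts = df.loc[sub.index, cohort_col] if cohort_col else cohort
    out = pd.DataFrame(
        {"os_time": times.to_numpy(dtype=float),
         "os_event": np.asarray(events, dtype=int),
         "cohort": cohorts},
    )
    out.index = pd.Index(sub["sample_id"].to_numpy(), name="sample_id")
    return ClinicalTable(out)


def write_clinical_table(clin: ClinicalTable, path, sep: str = "\t") -> None:
    clin.data.to_csv(path, sep=sep, index_label="sample_id", float_format="%.10g")


def align_cohort(expr: ExpressionMatrix, clin: ClinicalTable):
    """Restrict expression and clinical data to their shared samples.

    Both outputs follow the expression matrix's sample order restricted to
    the intersection; an empty intersection is an error.  Idempotent.
    """
    shared = [s for s in expr.sample_ids if s in set(clin.sample_ids)]
    if not shared:
        raise ValidationError("no samples shared between expression and clinical data")
    log.info("align_cohort: %d shared samples (expr %d, clinical %d)",
             len(shared), len(expr.sample_ids), len(clin.sample_ids))
    expr_out = ExpressionMatrix(expr.data.loc[:, shared], scale_tag=expr.scale_tag)
    clin_out = ClinicalTable(clin.data.loc[shared].copy())
    return expr_out, clin_out
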