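"""Marker selection and mean-log biomarker scores.

Infiltrating T-cell abundance (ITA) is the per-sample arithmetic mean of
log2(expression + pseudocount) over T-cell marker genes; the EMT score is
the same statistic over an epithelial-mesenchymal-transition gene set
(200 genes in the hallmark collection).  Markers are genes whose
signature-matrix expression, after dividing each gene row by its mean
across all cell types, averages strictly above a fold-change threshold
(default 2) over the T-lineage columns.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ScoreVector, SignatureMatrix, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "MarkerSelection",
    "select_t_cell_markers",
    "mean_log_score",
    "ita_score",
    "emt_score",
]


@dataclass
class MarkerSelection:
    """Outcome of T-cell marker selection on a signature matrix."""

    marker_genes: list
    threshold: float
    t_cell_labels: list
    normalization_tag: str = "row_mean"

    def __len__(self) -> int:
        return len(self.marker_genes)


def select_t_cell_markers(sig: SignatureMatrix, t_cell_labels,
                          threshold: float = 2.0) -> MarkerSelection:
    """Select genes over-represented in the T-lineage signature columns.

    Each gene row is normalized by its mean across *all* cell-type
    columns, so the threshold reads as "at least ``threshold``-fold above
    the gene's average across cell types".  A gene is selected iff its
    mean normalized value over ``t_cell_labels`` is strictly greater than
    ``threshold``.  All-zero rows are excluded with a warning (their
    normalization is undefined).  Output preserves signature gene order.
    """
    t_cell_labels = list(t_cell_labels)
    if not t_cell_labels:
        raise ValidationError("t_cell_labels must be non-empty")
    unknown = [c for c in t_cell_labels if c not in sig.data.columns]
    if unknown:
        raise ValidationError(f"unknown cell-type labels: {unknown}")

    vals = sig.data.to_numpy(dtype=float)
    row_mean = vals.mean(axis=1)
    zero = row_mean == 0
    if zero.any():
        log.warning("select_t_cell_markers: excluded %d all-zero gene rows", int(zero.sum()))
    t_idx = [sig.data.columns.get_loc(c) for c in t_cell_labels]
    with np.errstate(divide="ignore", invalid="ignore"):
        normalized_t_mean = vals[:, t_idx].mean(axis=1) / row_mean
    keep = (~zero) & (normalized_t_mean > threshold)
    markers = [g for g, k in zip(sig.data.index, keep) if k]
    log.info("select_t_cell_markers: %d markers (threshold %g, %d T-cell columns)",
             len(markers), threshold, len(t_cell_labels))
    return MarkerSelection(marker_genes=markers, threshold=float(threshold),
                           t_cell_labels=t_cell_labels)


def mean_log_score(expr: ExpressionMatrix, genes, pseudocount: float = 1.0,
                   name: str = "other") -> ScoreVector:
    """Per-sample arithmetic mean of log2(x + pseudocount) over ``genes``.

    Genes absent from the matrix are dropped from the mean (not imputed)
    and counted in ``n_genes_missing``; no gene found at all is an error,
    as is an already log-transformed matrix (double-log guard).
    """
    if expr.scale_tag != "linear":
        raise ValidationError(
            f"mean_log_score requires linear-scale expression, got {expr.scale_tag!r}"
        )
    genes = list(genes)
    present = [g for g in genes if g in expr.data.index]
    n_missing = len(genes) - len(present)
    if not present:
        raise ValidationError(f"none of the {len(genes)} listed genes found in expression")
    if n_missing:
        log.warning("mean_log_score(%s): %d of %d genes missing from expression",
                    name, n_missing, len(genes))
    sub = expr.data.loc[present].to_numpy(dtype=float)
    scores = np.log2(sub + pseudocount).mean(axis=0)
    return ScoreVector(
        pd.Series(scores, index=expr.data.columns),
        name=name, adjusted=False,
        n_genes_used=len(present), n_genes_missing=n_missing,
    )


def ita_score(expr: ExpressionMatrix, markers: MarkerSelection,
              pseudocount: float = 1.0) -> ScoreVector:
    """Infiltrating T-cell abundance: mean log2 expression of marker genes."""
    if not markers.marker_genes:
        raise ValidationError("marker selection is empty")
    return mean_log_score(expr, markers.marker_genes, pseudocount=pseudocount, name="ITA")


def emt_score(expr: ExpressionMatrix, emt_set, pseudocount: float = 1.0) -> ScoreVector:
    """EMT signature score: mean log2 expression of the EMT gene set."""
    return mean_log_score(expr, emt_set, pseudocount=pseudocount, name="EMT")
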