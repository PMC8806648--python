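"""Single-sample gene-set enrichment (ssGSEA) and score correlations.

The enrichment statistic is the ssGSEA running sum: within each sample,
genes are ranked by expression (average ranks for ties, so the statistic
is invariant under strictly monotone transforms of the column); walking
the genes in descending expression order, the running sum gains
``rank^alpha`` (normalized over the in-set total) at set members and
loses ``1/(N - |G|)`` at non-members; the enrichment score is the sum of
the running-sum values over all positions.  ``alpha`` defaults to 0.25,
the conventional ssGSEA rank-weight exponent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSetCollection, ScoreVector, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "EnrichmentMatrix",
    "ssgsea_sample",
    "enrich_all",
    "correlate_with_score",
    "pearson_with_p",
]


@dataclass
class EnrichmentMatrix:
    """Enrichment scores, gene sets in rows, samples in columns."""

    data: pd.DataFrame
    method_tag: str = "ssgsea_running_sum"
    alpha: float = 0.25

    @property
    def set_names(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)


def _running_sum_score(values: np.ndarray, in_set: np.ndarray, alpha: float) -> float:
    """ssGSEA score for one sample given a membership mask over genes.

    ``values`` and ``in_set`` are aligned over the same gene order.
    Traversal order is descending expression with ties broken by gene
    position; tie groups share their average rank as the hit weight.
    """
    n = values.shape[0]
    n_in = int(in_set.sum())
    if n_in == 0:
        raise ValidationError("gene set has no overlap with the expression genes")
    if n_in == n:
        raise ValidationError("gene set covers every gene; miss penalty undefined")
    ranks = stats.rankdata(values, method="average")  # highest expression -> rank n
    order = np.argsort(-values, kind="stable")
    hit = in_set[order]
    weights = np.abs(ranks[order]) ** alpha
    hit_w = np.where(hit, weights, 0.0)
    denom_hit = hit_w.sum()
    p_hit = np.cumsum(hit_w) / denom_hit
    p_miss = np.cumsum(np.where(hit, 0.0, 1.0)) / (n - n_in)
    return float(np.sum(p_hit - p_miss))


def ssgsea_sample(expr_column: pd.Series, gene_set, alpha: float = 0.25) -> float:
    """Enrichment score of ``gene_set`` in one sample's expression column."""
    expr_column = pd.Series(expr_column, dtype=float)
    members = set(gene_set)
    in_set = expr_column.index.isin(members)
    return _running_sum_score(expr_column.to_numpy(), in_set, alpha)


def enrich_all(expr: ExpressionMatrix, collection: GeneSetCollection,
               alpha: float = 0.25) -> EnrichmentMatrix:
    """Enrichment of every set in every sample; sets covering zero or all
    genes are skipped with a log message."""
    genes = expr.data.index
    vals = expr.data.to_numpy(dtype=float)
    n_genes, n_samples = vals.shape

    # Per-sample rank structure is shared by all sets; precompute it once.
    orders = np.argsort(-vals, axis=0, kind="stable")
    weights = np.empty_like(vals)
    for j in range(n_samples):
        weights[:, j] = np.abs(stats.rankdata(vals[:, j], method="average")) ** alpha

    rows, names = [], []
    for name, gene_list in collection.sets.items():
        in_set = genes.isin(set(gene_list))
        n_in = int(in_set.sum())
        if n_in == 0 or n_in == n_genes:
            log.info("enrich_all: skipping set %s (overlap %d of %d genes)",
                     name, n_in, n_genes)
            continue
        scores = np.empty(n_samples)
        for j in range(n_samples):
            o = orders[:, j]
            hit = in_set[o]
            hit_w = np.where(hit, weights[o, j], 0.0)
            p_hit = np.cumsum(hit_w) / hit_w.sum()
            p_miss = np.cumsum(~hit) / (n_genes - n_in)
            scores[j] = np.sum(p_hit - p_miss)
        rows.append(scores)
        names.append(name)
    if not rows:
        raise ValidationError("no gene set overlaps the expression matrix")
    df = pd.DataFrame(np.vstack(rows), index=names, columns=expr.data.columns)
    return EnrichmentMatrix(df, alpha=alpha)


def pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple:
    """Pearson r and the two-sided p-value from the t statistic
    r*sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ValidationError("correlation requires at least 3 samples")
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r = float(np.corrcoef(x, y)[0, 1])
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def correlate_with_score(es: EnrichmentMatrix, score: ScoreVector,
                         method: str = "pearson") -> pd.DataFrame:
    """Correlate every enrichment row with a biomarker score.

    Returns a table (set_name index) with columns ``r``, ``p``, ``n`` and
    ``flagged`` (True where a zero-variance row made r undefined), sorted
    by r descending; flagged rows sort last, they are never dropped.
    """
    shared = [s for s in es.data.columns if s in set(score.sample_ids)]
    if len(shared) < 3:
        raise ValidationError("need at least 3 shared samples for correlation")
    y = score.values.reindex(shared).to_numpy()
    if method == "spearman":
        y_used = stats.rankdata(y)
    elif method == "pearson":
        y_used = y
    else:
        raise ValidationError(f"unknown correlation method {method!r}")
    records = []
    for name in es.data.index:
        x = es.data.loc[name, shared].to_numpy(dtype=float)
        if method == "spearman":
            x = stats.rankdata(x)
        r, p = pearson_with_p(x, y_used)
        records.append((name, r, p, len(shared), not np.isfinite(r)))
    out = pd.DataFrame(records, columns=["set_name", "r", "p", "n", "flagged"])
    out = out.sort_values("r", ascending=False, na_position="last").set_index("set_name")
    return out
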