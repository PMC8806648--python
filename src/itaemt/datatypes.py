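"""Shared data containers for the pipeline.

All tabular data are held as pandas objects with validated labels:
expression and signature matrices are genes x columns DataFrames,
clinical data a per-sample DataFrame, gene sets an ordered mapping.
Validation happens at construction so downstream code can assume
unique identifiers, finite values and a declared expression scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ValidationError",
    "ExpressionMatrix",
    "SignatureMatrix",
    "GeneSetCollection",
    "ClinicalTable",
    "ScoreVector",
]


class ValidationError(ValueError):
    """Raised when an input violates a structural invariant."""


def _check_unique(labels, what: str) -> None:
    idx = pd.Index(labels)
    if idx.has_duplicates:
        dups = idx[idx.duplicated()].unique().tolist()[:5]
        raise ValidationError(f"duplicate {what}: {dups}")


@dataclass
class ExpressionMatrix:
    """Gene-level expression, genes in rows, samples in columns.

    ``scale_tag`` declares whether values are on the linear abundance
    scale (``"linear"``, TPM/RSEM-like, non-negative) or already
    log-transformed (``"log2p1"``).  Scoring refuses to re-log a
    logged matrix.
    """

    data: pd.DataFrame
    scale_tag: str = "linear"

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.scale_tag not in ("linear", "log2p1"):
            raise ValidationError(f"unknown scale_tag {self.scale_tag!r}")
        _check_unique(self.data.index, "gene ids")
        _check_unique(self.data.columns, "sample ids")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("expression matrix contains non-finite values")
        if self.scale_tag == "linear" and (vals < 0).any():
            raise ValidationError("linear-scale expression must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple:
        return self.data.shape


@dataclass
class SignatureMatrix:
    """Marker-gene expression across immune cell types (genes x cell types)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        _check_unique(self.data.index, "signature gene ids")
        _check_unique(self.data.columns, "cell type labels")
        vals = self.data.to_numpy()
        if not np.isfinite(vals).all():
            raise ValidationError("signature matrix contains non-finite values")
        if (vals < 0).any():
            raise ValidationError("signature matrix must be non-negative")

    @property
    def gene_ids(self) -> list:
        return list(self.data.index)

    @property
    def cell_type_labels(self) -> list:
        return list(self.data.columns)


@dataclass
class GeneSetCollection:
    """Named gene sets (e.g. a hallmark collection parsed from GMT).

    ``sets`` maps set name -> ordered list of gene identifiers; names are
    unique, sets are non-empty and contain no duplicate genes.
    """

    sets: dict
    source_tag: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if len(genes) == 0:
                raise ValidationError(f"gene set {name!r} is empty")
            if len(set(genes)) != len(genes):
                raise ValidationError(f"gene set {name!r} has duplicate genes")

    def __getitem__(self, name: str) -> list:
        return self.sets[name]

    def __contains__(self, name: str) -> bool:
        return name in self.sets

    def __len__(self) -> int:
        return len(self.sets)

    def names(self) -> list:
        return list(self.sets)


@dataclass
class ClinicalTable:
    """Per-sample overall-survival follow-up.

    ``data`` is indexed by sample id with columns ``os_time`` (days,
    >= 0), ``os_event`` (1 = death observed, 0 = censored) and
    ``cohort`` (free label).
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"os_time", "os_event"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValidationError(f"clinical table missing columns {sorted(missing)}")
        if "cohort" not in self.data.columns:
            self.data = self.data.assign(cohort="unlabeled")
        _check_unique(self.data.index, "sample ids")
        t = self.data["os_time"].to_numpy(dtype=float)
        e = self.data["os_event"].to_numpy()
        if not np.isfinite(t).all() or (t < 0).any():
            raise ValidationError("os_time must be finite and non-negative")
        if not np.isin(e, [0, 1]).all():
            raise ValidationError("os_event must be coded 0/1")

    @property
    def sample_ids(self) -> list:
        return list(self.data.index)

    @property
    def os_time(self) -> pd.Series:
        return self.data["os_time"].astype(float)

    @property
    def os_event(self) -> pd.Series:
        return self.data["os_event"].astype(int)

    def __len__(self) -> int:
        return len(self.data)


@dataclass
class ScoreVector:
    """A per-sample biomarker score (log2-scale units).

    ``name`` identifies the biomarker ("ITA", "EMT", ...), ``adjusted``
    flags purity-residualized scores, and the gene bookkeeping records
    how many listed genes contributed to the mean.
    """

    values: pd.Series
    name: str = "other"
    adjusted: bool = False
    n_genes_used: int = 0
    n_genes_missing: int = 0

    def __post_init__(self) -> None:
        self.values = pd.Series(self.values, dtype=float)
        _check_unique(self.values.index, "score sample ids")
        if not np.isfinite(self.values.to_numpy()).all():
            raise ValidationError("score vector contains non-finite values")

    @property
    def sample_ids(self) -> list:
        return list(self.values.index)

    def reindex(self, sample_ids) -> "ScoreVector":
        sub = self.values.reindex(sample_ids)
        if sub.isna().any():
            missing = [s for s in sample_ids if s not in self.values.index][:5]
            raise ValidationError(f"score missing samples: {missing}")
        return ScoreVector(
            sub,
            name=self.name,
            adjusted=self.adjusted,
            n_genes_used=self.n_genes_used,
            n_genes_missing=self.n_genes_missing,
        )

    def __len__(self) -> int:
        return len(self.values)
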