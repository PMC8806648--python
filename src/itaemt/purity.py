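"""Tumor purity estimation and purity residualization of biomarker scores.

Stromal and immune scores are single-sample enrichment scores of the
corresponding gene sets; their sum maps to tumor purity through the
published ESTIMATE cosine calibration
``purity = cos(0.6049872018 + 0.0001467884 * estimate_score)``.
A biomarker score is purity-adjusted by ordinary least squares on
``score ~ 1 + log(1 - purity)``; the adjusted score is the residual,
which is exactly orthogonal to the regressor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import ExpressionMatrix, ScoreVector, ValidationError
from .enrichment import enrich_all, pearson_with_p
from .datatypes import GeneSetCollection

log = logging.getLogger(__name__)

__all__ = [
    "PurityResult",
    "AdjustedScore",
    "ESTIMATE_INTERCEPT",
    "ESTIMATE_SLOPE",
    "estimate_scores",
    "estimate_purity",
    "adjust_for_purity",
    "score_purity_correlation",
]

# published calibration of the ESTIMATE purity formula
ESTIMATE_INTERCEPT = 0.6049872018
ESTIMATE_SLOPE = 0.0001467884


@dataclass
class PurityResult:
    """Per-sample stromal/immune/ESTIMATE scores and mapped purity.

    ``data`` is indexed by sample id with columns ``stromal_score``,
    ``immune_score``, ``estimate_score``, ``purity`` (NaN until mapped)
    and ``flagged`` (purity clamped at the formula's boundary).
    """

    data: pd.DataFrame

    @property
    def purity(self) -> pd.Series:
        return self.data["purity"]


@dataclass
class AdjustedScore:
    """A purity-residualized score plus the regression it came from."""

    base: ScoreVector
    intercept: float
    slope: float
    r_squared: float
    regressor_tag: str = "log(1-purity)"
    excluded_samples: list = None

    @property
    def values(self) -> pd.Series:
        return self.base.values


def estimate_scores(expr: ExpressionMatrix, stromal_set, immune_set,
                    alpha: float = 0.25) -> PurityResult:
    """Stromal and immune enrichment scores per sample (purity unset)."""
    collection = GeneSetCollection(
        sets={"__stromal__": list(stromal_set), "__immune__": list(immune_set)},
        source_tag="estimate",
    )
    es = enrich_all(expr, collection, alpha=alpha)
    for key in ("__stromal__", "__immune__"):
        if key not in es.data.index:
            which = "stromal" if key == "__stromal__" else "immune"
            raise ValidationError(f"{which} gene set has no overlap with the expression genes")
    df = pd.DataFrame(
        {
            "stromal_score": es.data.loc["__stromal__"],
            "immune_score": es.data.loc["__immune__"],
        }
    )
    df["estimate_score"] = df["stromal_score"] + df["immune_score"]
    df["purity"] = np.nan
    df["flagged"] = False
    return PurityResult(df)


def estimate_purity(estimate_score, intercept: float = ESTIMATE_INTERCEPT,
                    slope: float = ESTIMATE_SLOPE, eps: float = 1e-6):
    """Map ESTIMATE scores to tumor purity via the cosine calibration.

    Returns ``(purity, flagged)``; purity is clamped to ``(eps, 1]`` and
    samples whose raw cosine fell at or below zero are flagged.  Accepts a
    scalar or an array/Series and returns matching shapes.
    """
    scalar = np.isscalar(estimate_score)
    s = np.asarray(estimate_score, dtype=float)
    raw = np.cos(intercept + slope * s)
    flagged = raw <= 0
    purity = np.clip(raw, eps, 1.0)
    if flagged.any():
        log.warning("estimate_purity: %d samples at or below the purity boundary",
                    int(np.sum(flagged)))
    if scalar:
        return float(purity), bool(flagged)
    return purity, flagged


def apply_purity(result: PurityResult, intercept: float = ESTIMATE_INTERCEPT,
                 slope: float = ESTIMATE_SLOPE) -> PurityResult:
    """Fill the purity column of a PurityResult in place and return it."""
    purity, flagged = estimate_purity(result.data["estimate_score"].to_numpy(),
                                      intercept=intercept, slope=slope)
    result.data["purity"] = purity
    result.data["flagged"] = flagged
    return result


def _ols_two_param(x: np.ndarray, y: np.ndarray) -> tuple:
    """Closed-form normal equations for y = a + b*x."""
    xm, ym = x.mean(), y.mean()
    sxx = np.sum((x - xm) ** 2)
    if sxx == 0:
        raise ValidationError("purity regressor is constant; adjustment is degenerate")
    b = np.sum((x - xm) * (y - ym)) / sxx
    a = ym - b * xm
    return a, b


def adjust_for_purity(score: ScoreVector, purity) -> AdjustedScore:
    """Residualize a score on ``log(1 - purity)``.

    Samples with purity exactly 1 cannot enter the regression
    (``log(0)``); they are excluded from the fit but retained with
    adjusted value ``score - intercept`` and listed in
    ``excluded_samples``.  Requires >= 3 regressable samples.
    """
    purity = pd.Series(purity, dtype=float)
    common = [s for s in score.sample_ids if s in purity.index]
    if len(common) != len(score.sample_ids):
        missing = [s for s in score.sample_ids if s not in purity.index][:5]
        raise ValidationError(f"purity missing for samples {missing}")
    p = purity.reindex(common)
    if ((p <= 0) | (p > 1)).any():
        raise ValidationError("purity values must lie in (0, 1]")
    usable = p < 1.0
    excluded = [s for s, u in zip(common, usable) if not u]
    if excluded:
        log.warning("adjust_for_purity: %d samples with purity == 1 excluded from fit",
                    len(excluded))
    if int(usable.sum()) < 3:
        raise ValidationError("need at least 3 samples with purity < 1 to fit")
    y_all = score.values.reindex(common).to_numpy()
    x = np.log(1.0 - p[usable].to_numpy())
    y = y_all[usable.to_numpy()]
    a, b = _ols_two_param(x, y)
    fitted = a + b * x
    resid = y - fitted
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0

    adjusted = pd.Series(index=pd.Index(common), dtype=float)
    adjusted[usable[usable].index] = resid
    for s in excluded:
        adjusted[s] = score.values[s] - a
    out = ScoreVector(
        adjusted, name=score.name, adjusted=True,
        n_genes_used=score.n_genes_used, n_genes_missing=score.n_genes_missing,
    )
    return AdjustedScore(base=out, intercept=float(a), slope=float(b),
                         r_squared=float(r2), excluded_samples=excluded)


def score_purity_correlation(score: ScoreVector, purity,
                             use_log1m: bool = False) -> tuple:
    """Pearson correlation (r, p) between a score and purity.

    With ``use_log1m=True`` the correlation is taken against
    ``log(1 - purity)`` instead (the adjustment regressor).
    """
    purity = pd.Series(purity, dtype=float)
    p = purity.reindex(score.sample_ids)
    if p.isna().any():
        raise ValidationError("purity missing for some scored samples")
    x = p.to_numpy()
    if use_log1m:
        if (x >= 1).any():
            raise ValidationError("log(1-purity) undefined at purity == 1")
        x = np.log(1.0 - x)
    return pearson_with_p(x, score.values.to_numpy())
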