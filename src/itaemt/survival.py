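"""Survival statistics for biomarker scores.

Cox proportional-hazards models are fit by Newton-Raphson on the partial
likelihood with Breslow handling of tied event times; hazard ratios are
reported on the interquartile-range scale, exp(beta * (q75 - q25)), with
two-sided 95% Wald intervals.  Group comparisons use Kaplan-Meier
product-limit curves and the log-rank test (via lifelines).  Per-gene
models regress survival on log2(expression + 1) while controlling for
ITA; genes are selected at an uncorrected p < 0.05, with a
Benjamini-Hochberg column reported alongside as an extension.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test

from .datatypes import ClinicalTable, ExpressionMatrix, ScoreVector, ValidationError

log = logging.getLogger(__name__)

__all__ = [
    "CoxResult",
    "GroupAssignment",
    "KMCurve",
    "fit_cox",
    "cox_score_test",
    "hr_iqr",
    "median_split",
    "four_group",
    "km_logrank",
    "rank_emt_genes",
    "validate_genes",
    "FOUR_GROUP_LEVELS",
]

#: two-sided 95% Wald critical value
Z_95 = 1.959963985

FOUR_GROUP_LEVELS = [
    "lowEMT-lowITA", "lowEMT-highITA", "highEMT-lowITA", "highEMT-highITA",
]


@dataclass
class CoxResult:
    """Summary of a fitted Cox proportional-hazards model."""

    covariate_names: list
    beta: np.ndarray
    se: np.ndarray
    wald_p: np.ndarray
    loglik: float
    n: int
    n_events: int
    converged: bool
    iterations: int
    information: np.ndarray = None

    def summary(self) -> pd.DataFrame:
        z = self.beta / self.se
        return pd.DataFrame(
            {"beta": self.beta, "se": self.se, "z": z, "wald_p": self.wald_p},
            index=self.covariate_names,
        )


@dataclass
class GroupAssignment:
    """Per-sample group labels with the cutpoints that produced them."""

    labels: pd.Series
    cutpoints: dict
    levels: list

    @property
    def sample_ids(self) -> list:
        return list(self.labels.index)

    def counts(self) -> pd.Series:
        return self.labels.value_counts().reindex(self.levels, fill_value=0)


@dataclass
class KMCurve:
    """Product-limit curve for one group."""

    group: str
    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"group": self.group, "time": self.times,
             "survival": self.survival, "at_risk": self.at_risk}
        )


def _prepare(X: pd.DataFrame, clin: ClinicalTable):
    shared = [s for s in X.index if s in set(clin.sample_ids)]
    if not shared:
        raise ValidationError("no samples shared between covariates and clinical data")
    Xs = X.loc[shared].to_numpy(dtype=float)
    time = clin.os_time.reindex(shared).to_numpy()
    event = clin.os_event.reindex(shared).to_numpy()
    if event.sum() == 0:
        raise ValidationError("no events observed; Cox model is undefined")
    var = Xs.var(axis=0)
    if (var == 0).any():
        dead = [c for c, v in zip(X.columns, var) if v == 0]
        raise ValidationError(f"zero-variance covariates: {dead}")
    return Xs, time, event, shared


def _breslow_derivatives(X: np.ndarray, time: np.ndarray, event: np.ndarray,
                         beta: np.ndarray):
    """Log partial likelihood, gradient and Hessian under Breslow ties.

    The risk set at an event time t is every subject with time >= t;
    tied events share the same risk-set sums.
    """
    n, p = X.shape
    order = np.argsort(time, kind="stable")
    Xo, to, eo = X[order], time[order], event[order]
    eta = Xo @ beta
    eta = eta - eta.max()  # guard exp overflow; cancels in ratios
    w = np.exp(eta)
    # reverse cumulative sums: S0[i] = sum_{j >= i} w_j, etc.
    S0 = np.cumsum(w[::-1])[::-1]
    S1 = np.cumsum((w[:, None] * Xo)[::-1], axis=0)[::-1]
    outer = w[:, None, None] * (Xo[:, :, None] * Xo[:, None, :])
    S2 = np.cumsum(outer[::-1], axis=0)[::-1]
    # first index of each tie block: all tied times share the block head sums
    first = np.searchsorted(to, to, side="left")
    ev = eo.astype(bool)
    f = first[ev]
    s0 = S0[f]
    s1 = S1[f]
    s2 = S2[f]
    loglik = float(np.sum(eta[ev]) - np.sum(np.log(s0)))
    mean1 = s1 / s0[:, None]
    grad = Xo[ev].sum(axis=0) - mean1.sum(axis=0)
    hess = -(s2 / s0[:, None, None] - mean1[:, :, None] * mean1[:, None, :]).sum(axis=0)
    return loglik, grad, hess


def fit_cox(X: pd.DataFrame, clin: ClinicalTable, tol: float = 1e-9,
            max_iter: int = 100) -> CoxResult:
    """Fit a Cox PH model by Newton-Raphson (Breslow ties).

    ``X`` is samples x covariates; samples are matched to the clinical
    table by id.  Convergence is declared when the log partial likelihood
    changes by <= ``tol``; non-convergence is flagged on the result, not
    silent.  Standard errors come from the inverse observed information.
    """
    Xs, time, event, shared = _prepare(X, clin)
    center = Xs.mean(axis=0)
    Xc = Xs - center  # improves conditioning; beta unchanged
    p = Xc.shape[1]
    beta = np.zeros(p)
    loglik, grad, hess = _breslow_derivatives(Xc, time, event, beta)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        step = np.linalg.solve(-hess, grad)
        new_beta = beta + step
        new_ll, new_grad, new_hess = _breslow_derivatives(Xc, time, event, new_beta)
        halvings = 0
        while new_ll < loglik and halvings < 30:
            step = step / 2.0
            new_beta = beta + step
            new_ll, new_grad, new_hess = _breslow_derivatives(Xc, time, event, new_beta)
            halvings += 1
        delta = new_ll - loglik
        beta, loglik, grad, hess = new_beta, new_ll, new_grad, new_hess
        if abs(delta) <= tol:
            converged = True
            break
    if not converged:
        log.warning("fit_cox: Newton-Raphson did not converge in %d iterations", max_iter)
    info = -hess
    cov = np.linalg.inv(info)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    wald_p = 2.0 * stats.norm.sf(np.abs(z))
    return CoxResult(
        covariate_names=list(X.columns), beta=beta, se=se, wald_p=wald_p,
        loglik=loglik, n=len(shared), n_events=int(event.sum()),
        converged=converged, iterations=it, information=info,
    )


def cox_score_test(X: pd.DataFrame, clin: ClinicalTable) -> tuple:
    """Cox score test at beta = 0: statistic U' I^{-1} U and its
    chi-square p-value on p degrees of freedom.  For a two-group
    indicator with no tied event times this equals the log-rank test."""
    Xs, time, event, _ = _prepare(X, clin)
    Xc = Xs - Xs.mean(axis=0)
    _, grad, hess = _breslow_derivatives(Xc, time, event, np.zeros(Xc.shape[1]))
    info = -hess
    chi2 = float(grad @ np.linalg.solve(info, grad))
    df = Xc.shape[1]
    return chi2, df, float(stats.chi2.sf(chi2, df))


def hr_iqr(result: CoxResult, score: ScoreVector, covariate: str | None = None) -> dict:
    """Interquartile-range-scaled hazard ratio with a 95% Wald interval.

    ``hr = exp(beta * (q75 - q25))`` of the score; the CI exponentiates
    the Wald endpoints of beta times the same spread.
    """
    name = covariate if covariate is not None else score.name
    if name not in result.covariate_names:
        raise ValidationError(f"covariate {name!r} not in fitted model")
    k = result.covariate_names.index(name)
    q25, q75 = np.percentile(score.values.to_numpy(), [25, 75])
    delta = q75 - q25
    if delta == 0:
        raise ValidationError("score interquartile range is zero")
    b, s = result.beta[k], result.se[k]
    return {
        "covariate": name,
        "hr_iqr": float(np.exp(b * delta)),
        "ci95_low": float(np.exp((b - Z_95 * s) * delta)),
        "ci95_high": float(np.exp((b + Z_95 * s) * delta)),
        "iqr": float(delta),
        "beta": float(b),
        "se": float(s),
        "wald_p": float(result.wald_p[k]),
    }


def median_split(score: ScoreVector, level_prefix: str = "") -> GroupAssignment:
    """Dichotomize at the within-cohort median; ties go to "low"."""
    vals = score.values
    if vals.nunique() < 2:
        raise ValidationError("cannot median-split a constant score")
    med = float(vals.median())
    levels = [f"{level_prefix}low", f"{level_prefix}high"]
    labels = pd.Series(np.where(vals > med, levels[1], levels[0]), index=vals.index)
    return GroupAssignment(labels=labels, cutpoints={score.name or "score": med},
                           levels=levels)


def four_group(emt: ScoreVector, ita: ScoreVector) -> GroupAssignment:
    """Cross of the EMT and ITA median splits into four fixed levels."""
    shared = [s for s in emt.sample_ids if s in set(ita.sample_ids)]
    if len(shared) < 4:
        raise ValidationError("need at least 4 shared samples for the 2x2 grouping")
    e = ScoreVector(emt.values.reindex(shared), name="EMT")
    i = ScoreVector(ita.values.reindex(shared), name="ITA")
    ge = median_split(e)
    gi = median_split(i)
    labels = ge.labels.str.cat(gi.labels, sep="EMT-") + "ITA"
    return GroupAssignment(
        labels=labels,
        cutpoints={"EMT": ge.cutpoints["EMT"], "ITA": gi.cutpoints["ITA"]},
        levels=list(FOUR_GROUP_LEVELS),
    )


def km_logrank(groups: GroupAssignment, clin: ClinicalTable):
    """Kaplan-Meier curves per group plus the log-rank test.

    Empty groups are dropped with a warning and the degrees of freedom
    adjusted.  Returns ``(curves, chi2, df, p)`` where ``curves`` maps
    group label -> KMCurve.
    """
    shared = [s for s in groups.sample_ids if s in set(clin.sample_ids)]
    labels = groups.labels.reindex(shared)
    time = clin.os_time.reindex(shared)
    event = clin.os_event.reindex(shared)
    if event.sum() == 0:
        raise ValidationError("no events observed")
    present = [lv for lv in groups.levels if (labels == lv).any()]
    dropped = [lv for lv in groups.levels if lv not in present]
    if dropped:
        log.warning("km_logrank: dropped empty groups %s", dropped)
    if len(present) < 2:
        raise ValidationError("need at least 2 non-empty groups")
    curves = {}
    for lv in present:
        mask = (labels == lv).to_numpy()
        kmf = KaplanMeierFitter()
        kmf.fit(time[mask], event_observed=event[mask])
        sf = kmf.survival_function_
        tbl = kmf.event_table
        curves[lv] = KMCurve(
            group=lv,
            times=sf.index.to_numpy(dtype=float),
            survival=sf.iloc[:, 0].to_numpy(dtype=float),
            at_risk=tbl["at_risk"].reindex(sf.index).to_numpy(dtype=float),
        )
    keep = labels.isin(present).to_numpy()
    res = multivariate_logrank_test(time[keep], labels[keep], event[keep])
    df = len(present) - 1
    return curves, float(res.test_statistic), df, float(res.p_value)


def _bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values."""
    m = len(p)
    order = np.argsort(p)
    ranked = p[order] * m / (np.arange(m) + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.clip(ranked, 0, 1)
    return out


def _per_gene_cox(expr: ExpressionMatrix, genes, ita: ScoreVector,
                  clin: ClinicalTable, p_cutoff: float,
                  pseudocount: float = 1.0) -> pd.DataFrame:
    shared = [s for s in expr.sample_ids
              if s in set(ita.sample_ids) and s in set(clin.sample_ids)]
    if len(shared) < 4:
        raise ValidationError("too few shared samples for per-gene models")
    ita_vals = ita.values.reindex(shared)
    records = []
    for g in genes:
        if g not in expr.data.index:
            records.append((g, np.nan, np.nan, np.nan, "untestable", False, False))
            continue
        x = np.log2(expr.data.loc[g, shared].to_numpy(dtype=float) + pseudocount)
        if np.var(x) == 0:
            log.warning("per-gene Cox: skipping zero-variance gene %s", g)
            records.append((g, np.nan, np.nan, np.nan, "untestable", False, False))
            continue
        X = pd.DataFrame({"gene": x, "ITA": ita_vals.to_numpy()}, index=shared)
        res = fit_cox(X, clin)
        beta, se, p = res.beta[0], res.se[0], res.wald_p[0]
        direction = "risk" if beta > 0 else "favorable"
        records.append((g, beta, se, p, direction, p < p_cutoff, True))
    out = pd.DataFrame(
        records,
        columns=["gene", "beta", "se", "wald_p", "direction", "selected", "testable"],
    )
    testable = out["testable"].to_numpy()
    q = np.full(len(out), np.nan)
    if testable.any():
        q[testable] = _bh_adjust(out.loc[testable, "wald_p"].to_numpy())
    out["q_bh"] = q  # multiplicity-corrected column, reported as an extension
    out = out.sort_values("wald_p", na_position="last").reset_index(drop=True)
    return out


def rank_emt_genes(expr: ExpressionMatrix, emt_set, ita: ScoreVector,
                   clin: ClinicalTable, p_cutoff: float = 0.05,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Per-gene Cox on (log2 gene expression, ITA); select at p < cutoff.

    Returns a table sorted by Wald p ascending with columns ``gene``,
    ``beta``, ``se``, ``wald_p``, ``q_bh``, ``direction`` (risk if beta >
    0 else favorable), ``selected`` and ``testable``.
    """
    genes = [g for g in emt_set if g in expr.data.index]
    if not genes:
        raise ValidationError("no EMT gene present in the expression matrix")
    return _per_gene_cox(expr, genes, ita, clin, p_cutoff, pseudocount)


def validate_genes(genes, expr2: ExpressionMatrix, clin2: ClinicalTable,
                   ita2: ScoreVector, p_cutoff: float = 0.05,
                   pseudocount: float = 1.0) -> pd.DataFrame:
    """Re-test candidate genes in a second cohort with the same per-gene
    model (ITA recomputed on that cohort and passed as ``ita2``).

    A gene validates iff p < cutoff; genes absent from the cohort are
    reported as untestable rather than failed.  An empty gene list yields
    an empty table.
    """
    genes = list(genes)
    if not genes:
        return pd.DataFrame(columns=["gene", "beta", "se", "wald_p", "direction",
                                     "selected", "testable", "q_bh"])
    return _per_gene_cox(expr2, genes, ita2, clin2, p_cutoff, pseudocount)
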