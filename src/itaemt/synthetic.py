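"""Synthetic cohorts with known ground truth.

The generator emulates the statistical structure the analysis assumes in
a bulk colon-cancer cohort: each sample is a mixture of tumor, immune
and stromal compartments (fractions summing to one); T-cell marker
genes are expressed by the immune compartment, so their bulk abundance
scales with the immune fraction and carries a latent infiltration
signal; EMT genes are expressed by both tumor and stromal cells (with a
configurable stromal weight below one, tumor cells dominating), so the
raw EMT and ITA scores load on purity in *opposite* directions -- the
confounding that purity residualization removes, which is why the
adjusted EMT-ITA correlation exceeds the raw one; overall survival
follows a proportional-hazards law driven by
the standardized latent EMT and infiltration values, with exponential
baseline hazard, administrative censoring at a follow-up horizon and
independent uniform censoring.

Latent infiltration is the standardized log immune *share* (the immune
fraction of the non-tumor compartment), i.e. the component of
infiltration that is not mechanically determined by purity; the bulk
marker expression still scales with the full immune fraction, so raw
scores correlate negatively with purity and the purity residualization
has genuine confounding to remove.  Latent EMT activity is
``lambda * z_infiltration + sqrt(1 - lambda^2) * noise`` with ``lambda``
equal to the target EMT-ITA correlation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict

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
    "SimulationConfig",
    "SyntheticCohort",
    "DEFAULT_T_CELL_LABELS",
    "generate_signature_matrix",
    "generate_cohort",
    "simulate_survival_from_covariates",
    "summarize_truth",
]

#: T-lineage columns of the 22-type signature matrix
DEFAULT_T_CELL_LABELS = [
    "T cells CD8",
    "T cells CD4 naive",
    "T cells CD4 memory resting",
    "T cells CD4 memory activated",
    "T cells follicular helper",
    "T cells regulatory",
    "T cells gamma delta",
]

_OTHER_CELL_LABELS = [
    "B cells naive", "B cells memory", "Plasma cells",
    "NK cells resting", "NK cells activated", "Monocytes",
    "Macrophages M0", "Macrophages M1", "Macrophages M2",
    "Dendritic cells resting", "Dendritic cells activated",
    "Mast cells resting", "Mast cells activated",
    "Eosinophils", "Neutrophils",
]


@dataclass
class SimulationConfig:
    """Parameters of a synthetic cohort.

    Defaults mirror the analysis' study conditions: 469 samples (the
    size of the discovery cohort), 159 T-cell marker genes, a 200-gene
    EMT set, fairly pure tumors (Beta(12, 4) purity, mean 0.75), a
    latent EMT-infiltration correlation of 0.62, harmful EMT
    (``beta_emt`` = +0.5 log-hazard per SD) and protective infiltration
    (``beta_ita`` = -0.5), a baseline hazard of 5e-4 per day (median
    survival about 3.8 years) and a 10-year follow-up horizon.
    """

    n_samples: int = 469
    n_genes: int = 1000
    n_marker_genes: int = 159
    n_emt_genes: int = 200
    purity_beta_params: tuple = (12.0, 4.0)
    emt_ita_target_corr: float = 0.62
    beta_emt: float = 0.5
    beta_ita: float = -0.5
    baseline_hazard: float = 5e-4
    censor_horizon: float = 3650.0
    noise_sigma: float = 0.25
    seed: int = 0
    # compartment / signal structure
    immune_split_beta_params: tuple = (6.0, 6.0)
    marker_gain: float = 2.0
    emt_gain: float = 1.0
    stromal_emt_weight: float = 0.5
    n_stromal_set: int = 50
    n_immune_set: int = 50
    n_extra_sets: int = 47
    extra_set_size: int = 30
    n_signature_background: int = 400
    confound_by_purity: bool = True
    uniform_censor_scale: float = 2.0

    def __post_init__(self) -> None:
        a, b = self.purity_beta_params
        if a <= 0 or b <= 0:
            raise ValidationError("purity Beta shape parameters must be positive")
        if abs(self.emt_ita_target_corr) >= 1:
            raise ValidationError("emt_ita_target_corr must lie strictly in (-1, 1)")
        if self.n_marker_genes + self.n_emt_genes > self.n_genes:
            raise ValidationError("marker + EMT genes exceed n_genes")
        reserved = (self.n_marker_genes + self.n_emt_genes
                    + self.n_stromal_set + self.n_immune_set)
        if reserved > self.n_genes:
            raise ValidationError("designated gene groups exceed n_genes")
        if self.baseline_hazard <= 0:
            raise ValidationError("baseline_hazard must be positive")
        if self.noise_sigma < 0:
            raise ValidationError("noise_sigma must be non-negative")


@dataclass
class SyntheticCohort:
    """A generated cohort with its ground truth."""

    expr: ExpressionMatrix
    clin: ClinicalTable
    signature: SignatureMatrix
    gene_sets: GeneSetCollection
    truth: pd.DataFrame
    true_betas: tuple
    config: SimulationConfig

    @property
    def emt_set(self) -> list:
        return self.gene_sets["EMT"]


def _streams(seed: int, n: int = 8):
    """Fixed split of one seed into independent sub-generators, so adding
    genes or sets never perturbs the clinical draws."""
    children = np.random.SeedSequence(seed).spawn(n)
    return [np.random.default_rng(c) for c in children]


def _standardize(x: np.ndarray) -> np.ndarray:
    s = x.std()
    if s == 0:
        return np.zeros_like(x)
    return (x - x.mean()) / s


def _gene_ids(n: int) -> list:
    return [f"G{i:05d}" for i in range(1, n + 1)]


def generate_signature_matrix(config: SimulationConfig) -> SignatureMatrix:
    """A 22-cell-type signature whose first ``n_marker_genes`` genes are
    constructed to pass the marker selector at threshold 2.

    Marker rows: uniform(8, 12) in the seven T-cell columns, uniform(0.1,
    1) elsewhere -- their row-mean-normalized T-cell mean always exceeds
    2.4.  Background rows: uniform(0.8, 1.25) everywhere -- normalized
    T-cell mean always below 1.4.  The margins make the selector's output
    deterministic under any draw.
    """
    rng = _streams(config.seed)[6]
    nm = config.n_marker_genes
    # background signature genes come from the non-marker, non-EMT pool
    n_bg = min(config.n_signature_background,
               max(0, config.n_genes - nm - config.n_emt_genes))
    labels = DEFAULT_T_CELL_LABELS + _OTHER_CELL_LABELS
    n_t = len(DEFAULT_T_CELL_LABELS)
    n_o = len(_OTHER_CELL_LABELS)
    ids = _gene_ids(config.n_genes)
    rows = []
    for _ in range(nm):
        rows.append(np.concatenate([rng.uniform(8.0, 12.0, n_t),
                                    rng.uniform(0.1, 1.0, n_o)]))
    for _ in range(n_bg):
        rows.append(rng.uniform(0.8, 1.25, n_t + n_o))
    data = pd.DataFrame(
        np.vstack(rows) if rows else np.empty((0, n_t + n_o)),
        index=ids[:nm] + ids[nm + config.n_emt_genes:
                             nm + config.n_emt_genes + n_bg],
        columns=labels,
    )
    return SignatureMatrix(data)


def simulate_survival_from_covariates(covariates: pd.DataFrame, betas,
                                      baseline_hazard: float,
                                      censor_horizon: float, seed: int,
                                      uniform_censor_scale: float = 2.0,
                                      cohort: str = "synthetic") -> ClinicalTable:
    """Exponential proportional-hazards survival for given covariates.

    hazard_i = baseline * exp(sum_k beta_k * x_ik); follow-up is censored
    at ``censor_horizon`` and additionally by an independent
    Uniform(0, uniform_censor_scale * horizon) time.
    """
    rng_s, rng_c = _streams(seed)[4], _streams(seed)[5]
    X = covariates.to_numpy(dtype=float)
    betas = np.asarray(betas, dtype=float)
    hazard = baseline_hazard * np.exp(X @ betas)
    t_event = rng_s.exponential(1.0 / hazard)
    c = np.minimum(censor_horizon,
                   rng_c.uniform(0, uniform_censor_scale * censor_horizon, len(hazard)))
    os_time = np.minimum(t_event, c)
    os_event = (t_event <= c).astype(int)
    df = pd.DataFrame({"os_time": os_time, "os_event": os_event, "cohort": cohort},
                      index=covariates.index)
    return ClinicalTable(df)


def generate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a full synthetic cohort (expression, clinical, signature,
    gene sets, ground truth).  Deterministic in ``config.seed``."""
    cfg = config
    rng_mix, rng_lat, rng_prof, rng_noise = _streams(cfg.seed)[:4]
    rng_sets = _streams(cfg.seed)[7]
    n = cfg.n_samples
    ng = cfg.n_genes

    # compartment mixture
    a, b = cfg.purity_beta_params
    purity = rng_mix.beta(a, b, n)
    aw, bw = cfg.immune_split_beta_params
    w = rng_mix.beta(aw, bw, n)  # immune share of the non-tumor compartment
    i_frac = (1.0 - purity) * w
    s_frac = (1.0 - purity) * (1.0 - w)

    # latent signals
    z_ita = _standardize(np.log2(w))  # purity-independent infiltration component
    lam = cfg.emt_ita_target_corr
    emt_raw = lam * z_ita + np.sqrt(1.0 - lam**2) * rng_lat.standard_normal(n)
    z_emt = _standardize(emt_raw)

    # gene partition
    ids = _gene_ids(ng)
    nm, ne = cfg.n_marker_genes, cfg.n_emt_genes
    ns, ni = cfg.n_stromal_set, cfg.n_immune_set
    marker_ids = ids[:nm]
    emt_ids = ids[nm:nm + ne]
    stromal_ids = ids[nm + ne:nm + ne + ns]
    immune_ids = ids[nm + ne + ns:nm + ne + ns + ni]
    background_ids = ids[nm + ne + ns + ni:]

    # Marker/EMT/compartment-set genes get a higher baseline abundance than
    # background genes: curated panels are well-expressed transcripts, and a
    # mean-log score over near-zero genes would be dominated by the
    # pseudocount rather than the signal.
    base = rng_prof.lognormal(mean=3.5, sigma=1.2, size=ng)
    n_designated = nm + ne + ns + ni
    base[:n_designated] = rng_prof.lognormal(mean=5.5, sigma=0.8, size=n_designated)
    expr = np.empty((ng, n))

    def _norm(x):
        m = x.mean()
        return x / m if m > 0 else x

    sl = {"marker": slice(0, nm), "emt": slice(nm, nm + ne),
          "stromal": slice(nm + ne, nm + ne + ns),
          "immune": slice(nm + ne + ns, nm + ne + ns + ni),
          "background": slice(nm + ne + ns + ni, ng)}

    marker_signal = 2.0 ** (cfg.marker_gain * z_ita)
    emt_signal = 2.0 ** (cfg.emt_gain * z_emt)
    if cfg.confound_by_purity:
        marker_comp = _norm(i_frac)
        emt_comp = _norm(purity + cfg.stromal_emt_weight * s_frac)
    else:
        marker_comp = np.ones(n)
        emt_comp = np.ones(n)
    expr[sl["marker"]] = np.outer(base[sl["marker"]], marker_comp * marker_signal)
    expr[sl["emt"]] = np.outer(base[sl["emt"]], emt_comp * emt_signal)
    expr[sl["stromal"]] = np.outer(base[sl["stromal"]], _norm(s_frac))
    expr[sl["immune"]] = np.outer(base[sl["immune"]], _norm(i_frac))
    # background: alternate flat and tumor-tracking genes
    bg = np.arange(sl["background"].start, ng)
    flat = bg[(bg - sl["background"].start) % 2 == 0]
    tum = bg[(bg - sl["background"].start) % 2 == 1]
    expr[flat] = base[flat, None] * np.ones(n)[None, :]
    expr[tum] = np.outer(base[tum], _norm(purity))

    if cfg.noise_sigma > 0:
        expr *= np.exp(rng_noise.normal(0.0, cfg.noise_sigma, (ng, n)))

    sample_ids = [f"S{i:04d}" for i in range(1, n + 1)]
    expr_mat = ExpressionMatrix(pd.DataFrame(expr, index=ids, columns=sample_ids))

    covs = pd.DataFrame({"z_emt": z_emt, "z_ita": z_ita}, index=sample_ids)
    clin = simulate_survival_from_covariates(
        covs, (cfg.beta_emt, cfg.beta_ita), cfg.baseline_hazard,
        cfg.censor_horizon, cfg.seed,
        uniform_censor_scale=cfg.uniform_censor_scale,
    )

    signature = generate_signature_matrix(cfg)

    sets = {}
    if emt_ids:
        sets["EMT"] = list(emt_ids)
    if stromal_ids:
        sets["STROMAL_SIGNATURE"] = list(stromal_ids)
    if immune_ids:
        sets["IMMUNE_SIGNATURE"] = list(immune_ids)
    pool = list(background_ids)
    size = min(cfg.extra_set_size, max(1, len(pool)))
    for k in range(cfg.n_extra_sets):
        if not pool:
            break
        members = rng_sets.choice(pool, size=min(size, len(pool)), replace=False)
        sets[f"SET_{k + 1:02d}"] = sorted(members.tolist())
    gene_sets = GeneSetCollection(sets=sets, source_tag="synthetic")

    truth = pd.DataFrame(
        {"purity": purity, "immune_frac": i_frac, "stromal_frac": s_frac,
         "latent_ita": z_ita, "latent_emt": z_emt},
        index=sample_ids,
    )
    frac_dev = np.abs(truth[["purity", "immune_frac", "stromal_frac"]].sum(axis=1) - 1.0)
    assert frac_dev.max() <= 1e-12

    return SyntheticCohort(
        expr=expr_mat, clin=clin, signature=signature, gene_sets=gene_sets,
        truth=truth, true_betas=(cfg.beta_emt, cfg.beta_ita), config=cfg,
    )


def summarize_truth(cohort: SyntheticCohort, pseudocount: float = 1.0) -> dict:
    """Realized cohort-level summaries: EMT-ITA and score-purity
    correlations of the computed scores, censoring fraction, event count
    and mean purity.  Correlations are NaN when undefined (n < 2)."""
    from .scoring import emt_score, ita_score, select_t_cell_markers

    cfg = cohort.config
    n = len(cohort.clin)
    events = int(cohort.clin.os_event.sum())
    out = {
        "n_samples": n,
        "n_events": events,
        "censoring_fraction": 1.0 - events / n,
        "mean_purity": float(cohort.truth["purity"].mean()),
    }

    def _corr(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        if len(x) < 2 or x.std() == 0 or y.std() == 0:
            return float("nan")
        return float(np.corrcoef(x, y)[0, 1])

    if cfg.n_marker_genes > 0 and cfg.n_emt_genes > 0:
        markers = select_t_cell_markers(cohort.signature, DEFAULT_T_CELL_LABELS)
        ita = ita_score(cohort.expr, markers, pseudocount=pseudocount)
        emt = emt_score(cohort.expr, cohort.emt_set, pseudocount=pseudocount)
        p = cohort.truth["purity"].to_numpy()
        out.update({
            "emt_ita_corr": _corr(emt.values, ita.values),
            "ita_purity_corr": _corr(ita.values, p),
            "emt_purity_corr": _corr(emt.values, p),
            "latent_emt_ita_corr": _corr(cohort.truth["latent_emt"],
                                         cohort.truth["latent_ita"]),
        })
    return out
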