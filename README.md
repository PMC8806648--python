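# itaemt

Infiltrating T-cell abundance (ITA) combined with epithelial–mesenchymal
transition (EMT) gene expression as a purity-adjusted prognostic factor
for bulk tumor transcriptomes, with a ground-truth synthetic cohort
generator that makes the entire analysis testable without external data.

## What it does

Bulk tumor expression mixes tumor, stromal and immune cells, so naive
immune and EMT scores are confounded by tumor purity. This package
implements the full analysis chain:

1. **Marker selection** — T-cell marker genes are picked from a 22
   cell-type signature matrix: each gene row is normalized by its mean
   across cell types, and a gene is a marker when its mean normalized
   value over the seven T-lineage columns strictly exceeds 2.
2. **Scoring** — ITA is the mean log2(expression + 1) over the marker
   genes; the EMT score is the same statistic over a 200-gene EMT set.
3. **Enrichment** — single-sample gene-set enrichment (ssGSEA running
   sum, alpha = 0.25) for any gene-set collection, plus correlation of
   each set's enrichment with ITA.
4. **Purity adjustment** — tumor purity comes either from ground truth
   (synthetic mode) or from the ESTIMATE cosine calibration
   `purity = cos(0.6049872018 + 0.0001467884 * estimate_score)`, where
   the ESTIMATE score is the sum of stromal and immune enrichment
   scores. Each score is residualized on `log(1 - purity)` by ordinary
   least squares; the residual is exactly orthogonal to the regressor.
5. **Survival** — Cox proportional-hazards models (Newton–Raphson,
   Breslow ties, IQR-scaled hazard ratios with 95% Wald intervals),
   median splits and the 2×2 EMT×ITA grouping, Kaplan–Meier curves and
   log-rank tests, per-EMT-gene Cox screening controlled for ITA, and
   re-testing of selected genes in a second cohort.
6. **Synthetic cohorts** — a generator that draws tumor/immune/stromal
   compartment fractions, latent infiltration and EMT activity with a
   configurable correlation, purity-confounded expression for marker,
   EMT, stromal and immune genes, and exponential survival driven by
   the latents. Ground truth (purity, fractions, latents) is returned
   alongside, so calibration and parameter recovery are checkable.

## Worked example

```python
import numpy as np, pandas as pd
from itaemt import *

cohort = generate_cohort(SimulationConfig(seed=1))          # 469 samples
markers = select_t_cell_markers(cohort.signature, DEFAULT_T_CELL_LABELS)
ita = ita_score(cohort.expr, markers)
emt = emt_score(cohort.expr, cohort.emt_set)

purity = cohort.truth["purity"]
adj_ita = adjust_for_purity(ita, purity)
adj_emt = adjust_for_purity(emt, purity)

print(len(markers.marker_genes))                            # 159
r_raw = np.corrcoef(emt.values, ita.values)[0, 1]           # 0.582
r_adj = np.corrcoef(adj_emt.values, adj_ita.values)[0, 1]   # 0.630

groups = four_group(adj_emt.base, adj_ita.base)
curves, chi2, df, p = km_logrank(groups, cohort.clin)
# chi2 = 14.55 (df = 3), p = 2.24e-03

def z(sv): v = sv.values; return (v - v.mean()) / v.std()
res = fit_cox(pd.DataFrame({"EMT": z(adj_emt.base), "ITA": z(adj_ita.base)}),
              cohort.clin)
# EMT: beta = +0.537 (se 0.077, p = 4.2e-12)  -> higher EMT is harmful
# ITA: beta = -0.544 (se 0.079, p = 7.7e-12)  -> higher infiltration protects
```

Running this prints the numbers shown in the comments: purity
adjustment raises the EMT–ITA correlation (the purity components of the
two scores are oppositely signed and attenuate the raw correlation),
the four-group stratification separates survival, and the joint Cox
model recovers the generator's true effects (+0.5 / −0.5 per latent
standard deviation).

## Command line

Every stage is also a CLI subcommand (`itaemt --help`):

```bash
itaemt simulate --seed 1 --out-dir cohort/        # expression.tsv, clinical.tsv, ...
itaemt score --expression cohort/expression.tsv \
    --signature cohort/signature.tsv --gene-sets cohort/gene_sets.gmt \
    --out scores.tsv
itaemt adjust --scores scores.tsv --expression cohort/expression.tsv \
    --gene-sets cohort/gene_sets.gmt --out adjusted.tsv
itaemt survival --scores adjusted.tsv --clinical cohort/clinical.tsv \
    --out-dir surv/
itaemt run-all --seed 1 --out-dir run/            # full pipeline + manifest.json
```

`run-all` writes every result table (markers, raw/adjusted scores,
enrichment, Cox, KM curves, log-rank, gene ranking and validation) plus
a `manifest.json` with config, counts and headline results. With a
fixed seed every result table is byte-identical across runs.

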