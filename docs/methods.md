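# Methods

This note documents the statistical model, the synthetic-data
generator, the numerical choices and the known limitations of the
package. It makes no empirical claims beyond what the test suite and
`scripts/acceptance.py` compute.

## Scores

**Marker selection.** Given a signature matrix of 22 cell-type
expression profiles, each gene row is divided by its mean over the 22
columns. A gene is a T-cell marker when the mean of its normalized
values over the seven T-lineage columns (CD8, CD4 naive, CD4 memory
resting/activated, follicular helper, regulatory, gamma delta) strictly
exceeds the threshold (default 2). All-zero rows are excluded with a
warning. The inequality is strict so a gene exactly at the threshold is
not selected.

**ITA and EMT scores.** Both are the unweighted mean of
`log2(x + pseudocount)` over the respective gene set, computed on
linear-scale expression (a scale tag prevents double-logging). Genes
missing from the matrix are dropped and counted on the returned score;
a score with zero usable genes is an error, never a silent zero.

## Enrichment (ssGSEA)

For one sample, genes are ranked by expression descending (average
ranks for ties; traversal ties broken by gene position). Walking down
the ranking, a gene in the set adds `rank^alpha / sum_in_set(rank^alpha)`
and a gene outside subtracts `1 / (N - |G|)`; the enrichment score is
the sum of the running sum over all positions. `alpha = 0.25` is the
default exponent. Sets covering every gene (miss denominator zero) or
no gene are rejected. The statistic depends on expression only through
ranks, so it is invariant to monotone transformations.

## Purity

The ESTIMATE score is the sum of stromal and immune ssGSEA scores;
purity is `cos(0.6049872018 + 0.0001467884 * estimate_score)` — the
published ESTIMATE calibration — clamped to `(1e-6, 1]` with clamped
samples flagged. In synthetic mode the generator's true purity can be
used directly (the default), which separates the adjustment's
statistical behavior from the purity estimator's error.

**Adjustment.** A score is regressed on `1 + log(1 - purity)` by
closed-form normal equations; the adjusted score is the residual.
Consequences enforced by tests: the residual is orthogonal to the
regressor to 1e-10, sums to ~0, and the operation is idempotent to
1e-9. Samples with purity exactly 1 cannot enter the fit (log of zero);
they are excluded from the regression, retained with adjusted value
`score - intercept`, and listed on the result. `log(1 - purity)` is
used rather than purity itself because enrichment-type scores of
non-tumor programs scale roughly with the log of the non-tumor
fraction, making the relation closer to linear.

## Survival

**Cox proportional hazards.** Newton–Raphson on the Breslow partial
likelihood with step-halving (up to 30 halvings per iteration),
convergence when the log-likelihood changes by ≤ 1e-9, at most 100
iterations; non-convergence is flagged, not silent. Covariates are
mean-centered for conditioning (the estimate is unchanged). Tied event
times share the risk-set sums of their tie-block head (reverse
cumulative sums indexed by `searchsorted`). Standard errors come from
the inverse observed information; p-values are two-sided Wald. The
score test at beta = 0 reduces to the log-rank test for a two-group
indicator without ties, which the tests verify to 1e-8.

**Hazard-ratio scale.** Continuous scores are reported as IQR-scaled
hazard ratios `exp(beta * (q75 - q25))` with 95% intervals
`exp((beta ± 1.959963985 * se) * (q75 - q25))`, so the effect is per
interquartile spread rather than per raw unit, which is invariant to
affine rescaling of the score.

**Groupings.** Median splits send ties to "low" (a sample exactly at
the median is "low"); the 2×2 grouping crosses the EMT and ITA splits
into fixed levels `lowEMT-lowITA, lowEMT-highITA, highEMT-lowITA,
highEMT-highITA`. Kaplan–Meier curves and the multivariate log-rank
test are delegated to lifelines; empty groups are dropped with a
warning and the degrees of freedom adjusted.

**Per-gene screening.** Each EMT gene is tested in a bivariate Cox
model on `(log2(expression + 1), ITA)` so the gene effect is estimated
net of infiltration. Genes are selected at an uncorrected p < 0.05 (the
study's criterion); a Benjamini–Hochberg `q_bh` column is reported
alongside as an extension, not used for selection. Genes absent or
constant in a cohort are reported as untestable rather than failed.
Validation re-runs the same model in a second cohort with that cohort's
own ITA.

## Synthetic cohort generator

The generator emulates the *structure* of a purity-confounded bulk
expression study; its defaults are the study conditions (469 samples,
1000 genes, 159 markers, a 200-gene EMT set).

**Compartments.** Purity `p ~ Beta(12, 4)` (mean 0.75, typical of
solid-tumor cohorts); the non-tumor compartment splits into immune and
stromal by `w ~ Beta(6, 6)`, giving `immune_frac = (1-p)w` and
`stromal_frac = (1-p)(1-w)`. The three fractions sum to 1 exactly.

**Latents.** The infiltration latent is the standardized `log2 w` —
the purity-*independent* component of immune composition. The EMT
latent is `lambda * z_ita + sqrt(1 - lambda^2) * noise` with
`lambda = emt_ita_target_corr` (default 0.62). The hazard is
`5e-4 * exp(0.5 * z_emt - 0.5 * z_ita)` per day (exponential survival),
censored at min(3650 days, Uniform(0, 7300)). Defining the hazard
latents as the purity-orthogonal components is deliberate: the
prescribed `log(1 - purity)` residualization then recovers exactly the
quantity that drives survival, which is what makes Wald CI coverage on
the adjusted scores a meaningful check. Bulk expression, by contrast,
retains the purity confounding.

**Expression.** Marker genes scale with the normalized immune fraction
times `2^(2.0 * z_ita)`; EMT genes with `(p + 0.5 * stromal_frac)` —
tumor-dominant EMT expression with mild stromal contamination — times
`2^(1.0 * z_emt)`; stromal/immune signature sets track their fractions;
background genes are half flat, half purity-tracking. Multiplicative
lognormal noise (sigma = 0.25) is applied throughout. Designated genes
get higher baselines (lognormal(5.5, 0.8)) than background
(lognormal(3.5, 1.2)) so the log2(x+1) pseudocount nonlinearity does
not distort their scores. Because marker and EMT genes load on purity
with opposite signs, the raw EMT–ITA correlation is attenuated below
`lambda` and purity adjustment raises it — the qualitative pattern the
analysis is designed to expose. `confound_by_purity=False` removes the
compartment factors from marker/EMT genes for differential testing.

**Signature matrix.** Marker rows are Uniform(8, 12) in the seven
T-lineage columns and Uniform(0.1, 1) elsewhere; background rows are
Uniform(0.8, 1.25) everywhere. These margins make the selector's output
deterministic (normalized T-means always above 2.4 and below 1.4
respectively), so the constructed marker count is recovered exactly
under any draw.

**Randomness.** One seed spawns eight independent `SeedSequence`
streams (mixtures, latents, profiles, noise, survival, censoring,
signature, gene sets), so enlarging one component never perturbs
another; cohorts are bitwise reproducible per seed.

**What the generator does not emulate.** Real marker co-expression
structure and cell-type cross-talk; count noise (reads are continuous
lognormal, not negative binomial); batch effects; non-proportional
hazards or competing risks; correlated censoring; the LM22 matrix's
actual expression values. Per-gene effect sizes within the EMT set are
all driven by one shared latent, so the set behaves more coherently
than a real 200-gene program.

## Numerical choices

- Exponential overflow in the Cox likelihood is guarded by subtracting
  `max(eta)`; the shift cancels exactly in the likelihood, gradient and
  Hessian.
- Pearson p-values use the exact t-transform with n − 2 degrees of
  freedom; zero-variance inputs yield NaN with a flag rather than an
  exception.
- All result tables are written with `%.10g` float formatting, making
  pipeline outputs byte-identical across reruns at a fixed seed (the
  manifest's wall-clock timings are the single documented exception).
- Derived seeds are kept below 2^31 for portability.

## Open design decisions

- **ITA–purity vs EMT–purity signs.** ITA is strongly negatively
  correlated with purity (T cells are non-tumor); EMT is mildly
  positively correlated (EMT programs here are tumor-dominant with
  `stromal_emt_weight = 0.5`). Opposite signs are what make purity
  attenuate the raw EMT–ITA correlation, matching the motivating
  observation that the adjusted correlation exceeds the raw one.
- **lifelines for KM/log-rank, in-package Cox/OLS/ssGSEA.** Algorithms
  whose details the analysis prescribes (Breslow Cox, normal-equation
  OLS, the running-sum statistic) are authored here and verified
  against independent oracles; standard non-prescribed estimators
  (product-limit curves, multivariate log-rank) use the established
  library, which in turn serves as a cross-check for the in-package
  Cox implementation.
- **True purity by default in synthetic mode.** Using ground-truth
  purity isolates the adjustment's properties from ESTIMATE's
  estimation error; the ESTIMATE path is exercised separately and can
  be switched on with `use_true_purity=False`.

## Limitations

- The ESTIMATE cosine calibration was fit on real Affymetrix data; its
  numeric outputs on synthetic enrichment scores are only qualitatively
  meaningful (monotone decreasing in the score), so synthetic-mode
  analyses default to true purity.
- Per-gene screening at uncorrected p < 0.05 replicates the study's
  criterion and inflates false positives by design; `q_bh` is provided
  but not applied.
- The generator's single shared EMT latent means per-gene validation
  rates in synthetic data are higher than one should expect on real
  cohorts.
- Cox standard errors assume the usual asymptotics; no small-sample or
  robust variance options are provided.
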