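# Methods

This note documents the statistical procedures `convergex` implements, the
assumptions of its synthetic-data generators, and the numerical choices made
where the design was genuinely open. It states no empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Differential expression

Each (cell line, drug) condition is analyzed separately against its matched
vehicle control (H2O for propranolol, DMSO for primidone); samples from the
other drug and its control are excluded from the fit.

**Filter.** A gene is retained when its abundance is at least
`min_abundance` (default 10) in at least `ceil(min_fraction × n_samples)`
samples (default 90%). The threshold applies to whatever per-gene abundance
the input table carries; the simulator emits counts large enough that the
default is meaningful. The `ceil` is computed with a 1e−9 guard against
binary-float artifacts (0.9 × 10 must require 9 samples, not 10).

**Model.** For each retained gene, OLS of `y = log2(abundance + 0.5)` on an
intercept plus dummy-coded `plate`, `buffer` and `treatment`. Factors that
are constant within the analyzed subset (e.g. buffer, which is shared by a
drug and its control) are dropped automatically; a rank-deficient design
(treatment aliased with plate) raises an error naming the factors. The
treatment coefficient is the log2 fold change; its Wald statistic
`beta/se` yields the two-sided p.

**Reference distribution and the Z-score (a deliberate choice).** With
three replicates per arm the residual degrees of freedom are ~3, and a
normal reference for `beta/se` would reject ~14% of null genes at p < 0.05.
The default `reference="t"` therefore takes p from the Student-t on the
residual df and defines the reported Z as the signed standard-normal
quantile of that p: `z = sign(beta) · Φ⁻¹(1 − p/2)`. This Z is exactly
N(0,1) under the null whenever p is calibrated, which is the property the
downstream Stouffer combination requires. In `reference="normal"` mode,
`z = beta/se` and `p = 2Φ(−|z|)` (the raw Wald convention); that mode is
anticonservative at small n and exists for comparison with tools that use
it. p-values are floored at 1e−300 before the quantile so z stays finite
(~37) instead of overflowing.

**Multiple testing.** Benjamini-Hochberg across retained genes
(statsmodels' `fdr_bh` behind `bh_adjust`; the step-up definition is
enforced against a brute-force oracle in the test suite). Output rows are
sorted by q with a stable gene-id tie-break.

Not reproduced: bootstrap-based variance shrinkage of transcript-abundance
tools. The meta-analysis consumes only (log2fc, z, p), which this model
supplies under the same design.

## Convergence meta-analysis

Per-condition Z panels are intersected: a gene filtered out of any
condition is absent from that set's combination (no imputation). For a
condition set of size k, `Z_set = (Σ z_i)/√k`, two-sided normal p, BH
within each of the five sets (prop, prim, daoy, npc, all) separately —
five families, matching per-set q-values. The combination is normalized by
√k because the raw sum is not N(0,1)-calibrated; `normalize=False` gives
the literal sum for inspection. Opposite-signed effects cancel by
construction, which encodes the meaning of "convergent".

Cross-condition correlations are Pearson on the raw Z vectors, or on
`z·|z|`-transformed vectors in weighted mode. The weighting squares the
magnitude while keeping the sign, so the most significant genes dominate
without collapsing up- and downregulation.

## TWAS regression

OLS of `TWAS.Z` on `Drug.Z + gene_length + gc_fraction + intercept` over
the gene intersection (≥ 10 genes required). The drug Z defaults to the
Stouffer-combined Z of a condition set, since the scan's purpose is
comparing meta-analysis conditions against tissues. Weighted mode applies
`z·|z|` to both response and predictor; a `literal_squared` flag squares
outright (discarding sign) for comparison with the sign-free reading of the
squared-form specification — the sign-preserving form is the default
because the weighting's stated purpose is to retain direction. GC enters
as a fraction and length in bp untransformed; `log_length=True` uses
log10(length). BH is applied across the full tissue × condition-set ×
weighting scan as one family. Pairs with insufficient gene overlap are
reported as missing rows, not errors.

## Cell-type enrichment

Genes below `min_count` in at least `max_low_celltypes` cell types are
removed first (defaults used in the cerebellar analysis family: < 0.5
counts in 7/10 cell types; cortical: < 1 in 85/121), countering drop-out
zero inflation. For a gene set with n ≥ 2 members present,

    z = (mean_set − mean_all_genes) / (sd_set / √n)

in the default `standard` mode — the one-sample Z-test with the all-gene
column mean as the population reference (set members included in it). The
`literal` mode divides by `sd_set × √n` instead, reproducing a formula
sometimes printed for this test; it equals `standard`/n and is kept only
for comparison, since it contradicts the named one-sample Z-test. Two-sided
normal p; BH within each gene set across cell types.

**Known bias.** On right-skewed profiles the statistic has a negative null
bias of order `skewness/(2√n)` (the classic one-sample t skew bias): random
size-50 sets on the generator's default profile average z ≈ −0.15. The
calibration tests therefore distinguish a mildly dispersed regime (where
mean z is within ±0.1 of 0) from the default skew (where the bias is
negative and bounded). Real single-cell average profiles are more skewed
still; a green test here does not establish calibration on such data.

## Constraint matching

o/e display transform: `score × 100`, with scores above 10 mapped to 100%.
The cap is applied literally even though real constraint scores rarely
exceed ~2; note it makes the transform non-monotone across the cap (5 →
500%, 12 → 100%). It affects only displayed percentages — the Wilcoxon
test runs on raw o/e.

Propensity scores come from a logistic model of DEG membership on
`cds_length + gc_fraction` (covariates standardized internally for
conditioning; constant covariates are dropped, so with all covariates
constant every score equals the DEG prevalence). Nearest-neighbor matching
on the propensity scale selects, for each DEG, the `ratio` closest
background genes — with replacement across DEGs, without replacement within
one DEG's match set, ties broken to the smallest control index for
determinism. The default ratio is the maximum, `floor(n_background /
n_deg)`, reflecting the "maximum number of matches" convention that yields
data-derived ratios.

The Wilcoxon rank-sum statistic W is the rank-sum of the first sample
(DEGs), with midranks for ties; `W = U + n_x(n_x+1)/2` relative to the
Mann-Whitney U. The two-sided p is exact by enumeration when
`n_x + n_y ≤ 12` and otherwise a normal approximation with tie correction
and 0.5 continuity correction. W conventions differ across packages, so
reported W values are comparable only within this implementation.

The up/down split of convergent DEGs uses the sign of the all-set Stouffer
Z (`convergent_genes(..., direction=)`), the natural choice when the DEG
list itself is defined by that statistic.

## Synthetic data

All generators draw from one `numpy.random.default_rng(seed)`; identical
seeds give byte-identical outputs.

**Experiment.** Two cell lines × four arms (propranolol/H2O,
primidone/DMSO) × 3 replicates. Counts are negative-binomial with
`log2 mean = baseline + plate + buffer + treatment`:

- baseline per gene ~ Normal(8.0, 1.2) on the log2 scale (mean ≈ 256
  counts). This represents a deeply sequenced experiment; it also ensures
  genes carrying a −2 log2 effect stay above the 10-in-90%-of-samples
  filter, without which strongly downregulated truth genes would be
  unfilterable-out yet undetectable and no generator could meet a 90%
  recovery target.
- plate: two levels crossing arms (replicates alternate), gene-specific
  effect ~ Normal(0, plate_sd = 0.1).
- buffer: tied to the arm (H2O vs DMSO), gene-specific effect
  ~ Normal(0, buffer_sd = 0.1).
- treatment: `round(frac_convergent × n_genes)` genes carry the same
  ±`effect_size_log2` effect in all four conditions;
  `round(frac_condition_specific × n_genes)` carry it in one random
  condition. Truth counts equal the rounded fractions exactly.
- dispersion: NB with α = 0.1 (variance μ + αμ²), a typical bulk RNA-seq
  overdispersion. The emulated study reports no library-size or dispersion
  characteristics, so these defaults are documented, not calibrated.

**Annotation.** Gene length lognormal (median 20 kb), GC ~ Beta(20, 28)
(mean ≈ 0.42), CDS a Beta(2, 8) fraction of gene length (≥ 90 bp),
o/e lognormal with median 0.6 for tolerant genes and 0.15 for the
constrained fraction — echoing the bimodality of population constraint
scores.

**TWAS.** `twas = rho · standardize(drug_z) + √(1−rho²) · ε` with ε iid
standard normal: population correlation exactly rho, and at |rho| = 1 the
output is an affine transform of the input. A rank-based copula was
considered and rejected: drug Z-scores are already near-normal and the
linear form makes the rho = 1 edge case exact.

**Profiles.** Gene baseline lognormal(log 5, 0.5) shared across columns,
per-(gene, cell type) lognormal(0, 0.3) noise, enriched sets multiplied by
`fold` in their target column. Columns are exchangeable under the null.
Both log-sd scales are exposed; see the enrichment bias note above for why
heavier tails degrade the statistic's calibration. Not simulated: reads,
UMIs, drop-out structure, or cell-level counts — only the derived average
matrices the pipeline consumes.

## What the tests establish

Unit tests pin every operation to hand-computed or brute-force oracles
(normal equations for the OLS Wald test, step-up enumeration for BH, exact
rank enumeration for the Wilcoxon, raw-column recomputation for the
enrichment Z). The acceptance suite checks, on seeded synthetic worlds:
Stouffer calibration (mean within ±0.02, variance within 1 ± 0.03 over 1e5
combined genes), type-I error 0.05 ± 0.01 and ≤ 5 BH false positives in
≥ 90% of null replicates, ≥ 90% sensitivity with ≤ 10% FDR for convergent
50-gene recovery at |log2FC| = 2, TWAS slope detection at rho = 0.5 in
≥ 95% of replicates with ≤ 10% false scans at rho = 0, geneset-level
enrichment recovery (arg-max cell type, decoy-set FDR ≤ 10%), and
post-matching covariate balance no worse than pre-matching in ≥ 95% of
confounded replicates. These are statements about the generators' stated
worlds; they do not certify behavior on real data with unmodeled structure
(batch effects beyond plate/buffer, correlated genes, heavy-tailed
profiles).

## Limitations

- The DE estimator is OLS on log-transformed abundance, not a count GLM;
  with very low counts the log transform's variance stabilization is poor.
- Stouffer combination assumes independent Z's across conditions; shared
  samples or correlated noise would inflate combined significance.
- The enrichment Z treats genes as independent units and is skew-biased
  (see above).
- Matching balances only the modeled covariates (CDS length, GC); unmodeled
  confounders of DEG membership and constraint remain.
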