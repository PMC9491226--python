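# Methods

This document describes the statistical models implemented by `seragut`,
the defaults they run with, the synthetic generator used to validate them,
and the numerical choices and limitations worth knowing about.

## Preprocessing

**PQN (probabilistic quotient normalization).** The reference spectrum is
the per-feature median over the QC injections (`qc_median`, default) or
over all samples (`all_median`). Each sample is divided by the median of
its feature-wise quotients against the reference, computed over features
with a positive reference value. PQN is exactly scale-equivariant, and is
idempotent in the pure-dilution regime (every sample equal to the reference
profile times a scalar); with residual analytic noise a second pass changes
values at the percent level, which is expected, not a defect.

**QC-RSC (QC-based robust LOESS signal correction).** Per feature and
batch, a robust degree-1 locally weighted regression (tricube weights,
Tukey-bisquare reweighting, 2 iterations, span 0.75 by default) of QC
intensity on injection order is fitted; the correction curve is linear
interpolation between the QC fits, clamped to the nearest QC fit outside
the QC range; values are divided by the curve and rescaled to the batch QC
median. Consequences of this design: within-batch drift is flattened
(planted smooth drift that inflates QC CV to ≥ 0.2 is corrected below
0.05), but *between-batch* level differences persist by construction —
each batch is rescaled to its own QC median. At least 4 QC injections per
batch are required; a feature whose fitted curve is non-positive anywhere
falls back to identity and is logged.

**Filters.** The QC-CV filter removes features whose QC coefficient of
variation (ddof = 1) exceeds 30%; zero QC mean counts as infinite CV. The
annotation filter removes features without an annotation class and reports
positive/negative-mode survivor counts.

## Differential screening

The composite screen requires all three of: PLS-DA VIP > 1, |log2 fold
change| ≥ 0.25 (ratio of arithmetic group means of normalized intensities),
and p < 0.05 from Welch's t (unpaired) or the paired t. PLS-DA is a NIPALS
PLS1 on autoscaled data with a ±1 response; VIP scores satisfy
mean(VIP²) = 1 exactly. The conjunction is stricter than the p-criterion
alone: the measured null pass rate is ~3–5% per feature.

Supporting tests: Welch's t (raw or summary n/mean/SD form), paired t,
Fisher's exact test by hypergeometric enumeration, exact Wilcoxon rank-sum
and signed-rank by enumeration for small samples (with tie-corrected,
continuity-corrected normal approximations otherwise), Kruskal–Wallis,
Benjamini–Hochberg FDR, and hypergeometric over-representation.

## Microbiome screens

Alpha diversity: Shannon (natural log), Simpson (1 − Σp²), observed
richness; all scale-invariant except richness. Clade expansion aggregates
species rows to all seven ranks; every rank preserves the per-sample total.

The LEfSe-style screen scales samples to a per-million total, retains
features with Kruskal–Wallis p < 0.05, then averages over 30 bootstrap
subsamples (2/3 per class) a ridge-regularized Fisher discriminant; the
per-feature effect is the mean of the weighted discriminant contribution
and the raw class-mean difference, reported as sign × log10(1 + effect),
with |score| ≥ 2 required to pass. **Calibration caveat:** for abundant
features the |LDA| ≥ 2 cut does not bind (null class-mean differences on
the per-million scale are essentially always above 100), so the false-call
rate is governed by the KW stage alone — expect ≈ kw_alpha false calls per
feature on abundant panels. This mirrors the known anti-conservatism of
the original two-class procedure.

## Co-abundance modules

Signed adjacency a = ((1 + r)/2)^β on feature–feature Pearson correlations
(log2-transformed intensities by default). The soft threshold scan fits
log10 p(k) against log10 k over β = 1…30 and picks the smallest β whose
signed R² (sign of the slope times R²) reaches 0.85; betas whose mean
connectivity falls below 1.0 are declared unevaluable, because nearly
edgeless networks mimic power laws spuriously. When no β qualifies, module
detection proceeds at the configured default (β = 9).

The topological overlap matrix is
ω_ij = (Σ_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij); modules are
branches of the average-linkage dendrogram of 1 − ω selected by a dynamic
hybrid criterion: a branch of at least `min_size` leaves qualifies if it
completes below a deepSplit-dependent core-scatter bound and is separated
from its parent by a minimum gap (the root never qualifies as one module).
Unassigned features with kME ≥ 0.3 to a module eigenfeature are rescued;
modules whose eigenfeatures are correlated above 1 − merge_height (default
merge_height 0.25) are merged. Module eigenfeatures are the first principal
component of the autoscaled module block, signed to correlate positively
with the module mean profile. Module–trait association uses Spearman
correlation plus a rank-based partial correlation given a covariate
(df = n − 3), with degenerate denominators (≤ 1e-12) reported as NA.

The pipeline fits the network on **all** study samples (module structure is
a property of the metabolome), and restricts the trait/covariate
association and cross-domain analyses to **baseline** samples.

## Cross-domain integration

**Procrustes/PROTEST.** Symmetric Procrustes with reflections permitted;
M² = 1 − (trace Σ)² on unit-norm centered configurations. PROTEST permutes
the rows of one configuration (p = (1 + #{M²_perm ≤ M²_obs}) / (1 + n_perm),
999 permutations by default). Null calibration is verified at ≤ 0.08
empirical rate of p ≤ 0.05.

**Differential-feature correlation.** All pairs of differential metabolites
× differential taxa, Spearman r with exact permutation p for n ≤ 8 samples
(full enumeration of rank permutations) and the t approximation otherwise,
BH-FDR appended; constant vectors yield NA with a reason.

**KEGG-module phenotype test.** Per KO, Spearman r with the trait; per
module, a two-sided Wilcoxon rank-sum of member-KO r values against
non-member r values. Note: this test assumes exchangeability between member
and background correlations; a strongly co-correlated module carries
essentially one correlation value, so the test is anti-conservative under
trait permutation in that regime (this is inherent to the member-vs-
background design, not an implementation artifact).

**Cross-domain map.** For each selected (module, cluster) pair — modules
selected by the phenotype test, clusters by covariate-adjusted trait
association — the per-KO Spearman correlations with the cluster
eigenfeature are compared member-vs-background (Wilcoxon), and the reported
effect is `scc_bg_adj` = median member r − median all-KO r. BH-FDR across
all populated cells, marked at q < 0.1 / 0.05 / 0.01. Sign recovery of
planted links is exact; null mark-rate is ~1% against the 10% bound.

## Synthetic generator

The cohort generator draws paired pre/post subjects in three response bands
(GR improvement ≥ 0.76, PR < 0.50, moderate in between) with BMI higher in
PR, and latent factors F1 (tracks dPASI) and F2 (tracks BMI) shared across
domains. The metabolome is multiplicative:
value = base × dilution × drift × batch, with log-normal bases
(block-correlated within planted clusters through the latent factors),
per-sample dilution (sd 0.15), per-feature smooth cubic drift (max/min =
1 + amplitude), and per-batch×feature multipliers. QC injections carry the
pooled mean profile exactly (dilution 1, no analytic noise) times drift
and batch. Differential features are planted at ±effect_log2 between GR
and PR at baseline. The microbiome is Dirichlet-compositional over five
dominant phyla with discriminative species boosted tenfold in PR; KO
abundances are driven by per-module latent factors, the first KO module
sharing the first metabolite cluster's factor (the planted cross-domain
link, with configurable sign).

Realism and limits: the generator reproduces the *mechanisms* the pipeline
must handle (dilution, drift, batches, compositionality, block
correlation, cross-domain latent sharing), not the marginal distributions
of any real instrument. Effects are planted independently; real data has
correlated confounding the generator does not model. Cohort sizes default
to the motivating study's 8/6/1.

## Numerical choices

- TSV round trips are bit-exact: floats are written with `repr` and parsed
  with strtod (`astype(float)`), avoiding pandas' lossy fast parser.
- All stochastic procedures take explicit integer seeds; the pipeline
  derives every stage's randomness from the single config seed, and reruns
  are byte-identical (the parameter hash excludes the output directory).
- Exact enumeration cutoffs: Fisher always exact; rank-sum exact for
  n1 + n2 ≤ 16; signed-rank exact for n ≤ 12; Spearman permutation p exact
  for n ≤ 8.
- Degenerate cases surface as explicit errors or NA-with-reason rather
  than silent numbers (zero-variance Welch, constant correlation vectors,
  partial-correlation denominators below 1e-12, empty cross-domain
  selections).

## Limitations

- The soft-threshold scan's scale-free criterion is only meaningful for
  heterogeneous networks; equal-size orthogonal block data is not
  scale-free and will (correctly) fail to qualify, and qualification on
  structured data is seed-sensitive at small sample sizes.
- The LEfSe effect-size threshold does not control false calls for
  abundant features (see above).
- The KEGG-module phenotype test is anti-conservative for internally
  correlated modules under the permutation null (see above).
- QC-RSC deliberately leaves cross-batch level differences in place.
- With ~15 baseline samples, permutation p-value resolution and network
  stability are limited; the pipeline mitigates the latter by fitting
  networks on all study samples.
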