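# Methods

This document describes the models and algorithms implemented in
`stresscore`, the parameters they expose, and the design decisions and
limitations behind them. The package identifies *core* (shared across
all stressors) versus *stress-specific* responsive genes from
multi-stressor, multi-batch expression data, using two complementary
routes — explicit set operations on per-experiment fold-change calls and
a hold-one-stressor-out machine-learning consensus — supported by batch
correction, coexpression-module, enrichment and regulatory-network
analyses. All stages run end to end on a seeded synthetic-data
generator, so every number the pipeline reports is reproducible from a
single `(config, seed)` pair.

## 1. Synthetic data generator (`stresscore.simulate`)

Real multi-stress meta-analyses draw on thousands of public samples that
cannot be bundled with a software package. The generator replaces them
with a desk-scale simulation whose ground truth is known exactly,
enabling recovery and calibration tests that are impossible with opaque
real data.

**Model.** Expression is log-normal on the log2 scale. For gene *g* in
sample *s*:

```
x_gs = baseline_g + effect_gs + batch_loc_b + batch_scale_b * eps_gs
TPM_gs = 2^x_gs
```

- `baseline_g` ~ Uniform(`baseline_log_mean_range`, default 2–8) is the
  gene's log2 expression level.
- `effect_gs` is `±log2(core_effect)` (default 8×) for planted core
  genes in every stress sample, `±log2(specific_effect)` for planted
  specific genes in their single stressor's stress samples, and 0
  otherwise. Optional `n_mixed_direction` genes flip direction between
  stressors.
- `batch_loc_b` ~ Normal(0, `batch_location_sd`) and
  `batch_scale_b` ~ |Normal(1, `batch_scale_sd`)| are per-batch
  location/scale distortions, mimicking independent experiments
  (BioProjects). Each (stressor, batch) pair carries its *own* control
  group, as in real compendia where controls are never shared across
  experiments.
- `eps_gs` ~ Normal(0, `noise_sd`) is replicate noise.

Default scale: 2,000 genes, 6 stressors (cold, drought, flooding, heat,
low nitrogen, salt) × 2 batches × 4 replicates per group = 96 samples;
30 core-up, 20 core-down, 15 specific-up and 15 specific-down genes per
stressor; master seed 7. These sizes are *package choices* made so that
the full pipeline and test suite run in minutes on one CPU; they are not
estimates of any real dataset's dimensions.

`simulate_annotations` plants transcription-factor families and
ontology-like terms: every gene is annotated at a base rate, and a small
number of families/terms are enriched among planted core genes by a
configurable factor, giving ground truth for the enrichment stage.

**Seeding.** All derived seeds come from
`numpy.random.SeedSequence(entropy=master, spawn_key=...)`, reduced
mod 2^31, so independent stages never share streams and every value is
reproducible bit for bit.

## 2. Preprocessing (`stresscore.prep`, `stresscore.combat`)

Zero-variance genes are dropped, expression is transformed to
log2(TPM+1), and batch effects are removed with ComBat. Matrices carry a
`scale_tag` (`tpm` → `log2p1` → `batch_corrected` → `zscore`) and each
stage validates the tag of its input, so raw-scale and corrected-scale
computations cannot be accidentally mixed.

**ComBat.** `stresscore.combat.combat` is a from-scratch implementation
of parametric empirical-Bayes ComBat (location and scale): the matrix is
standardized against a batch-design least-squares fit and pooled
variance; per-batch location (γ) and scale (δ²) estimates are shrunk
toward normal / inverse-gamma priors whose hyperparameters come from
method-of-moments estimates across genes; the shrinkage equations are
iterated to convergence (1e-4) and the data de-standardized. It was
hand-implemented because no ComBat package is available in the target
environment; its output was verified during development against the
reference R implementation (`sva::ComBat`) on frozen two-batch toys to
~1e-15, and those frozen references ship in the test suite.

A consequence of empirical-Bayes shrinkage worth knowing: batch means
are *exactly* equalized only when the per-gene batch-mean estimates are
homogeneous enough that the location prior is degenerate; on generic
data a small shrinkage residual of order δ(γ̂−γ̄)/(n·t2+δ) remains. This
is a property of parametric ComBat itself, not of this implementation.

**Overview plots/tables.** `pca_overview` (samples as observations,
scikit-learn full SVD) and `cluster_treatments` (average-linkage
hierarchy over the seven treatment mean profiles — six stressors plus
pooled control — on z-scored corrected data) provide the usual
global-structure diagnostics.

## 3. Set operations (`stresscore.setops`)

The **TN-ratio** of gene *g* in experiment (batch) *e* is

```
TN = (mean stress TPM + 1) / (mean control TPM + 1)
```

computed on *raw TPM within each batch*, so additive cross-batch
distortions affect numerator and denominator of the same experiment and
largely cancel; this is why the ratio deliberately does not use the
batch-corrected matrix (correction operates on the log scale and would
change the ratio's interpretation). The pseudocount (default 1)
stabilizes low-expression genes. Calls are strict: up if TN > 2, down if
TN < 0.5 (exact equality is *not* a call).

Per-stressor **unions** of the per-experiment up (down) calls are
intersected across all stressors to give `core_up` (`core_down`). A
gene is **specific** to stressor *s* if it appears in one of *s*'s
unions and in *no* union of any other stressor, in either direction —
so specific sets are disjoint across stressors and from the core by
construction.

`simple_de_flag` is deliberately lightweight plumbing (per-contrast
Welch t-test on log2(TPM+1), BH-adjusted within contrast, flagged if
significant anywhere) used only to annotate genes as differentially
expressed or not in the combined report.

## 4. Hold-one-stressor-out random forest (`stresscore.rf`)

For each stressor, its stress samples plus the control samples of its
batches form the held-out test set; everything else is training data.
This evaluates whether "stress vs control" generalizes to an *unseen
stressor*, which is the claim behind calling a signature "core".

- **SMOTE** balances training classes: synthetic minority points
  `x + u·(nn − x)` with `u ~ Uniform(0,1)` and `nn` one of the k=5
  nearest minority neighbours. Hand-implemented (no imbalanced-learn in
  the target environment); synthetic points provably lie on segments
  between minority samples, which the tests check geometrically.
- **Tuning**: `RandomizedSearchCV` (20 candidates, stratified 3-fold,
  ROC-AUC scoring) over bootstrap, depth, feature fraction, leaf/split
  minima and tree count. SMOTE and the search see only training data;
  metrics (accuracy, AUC of the stress-class probability, F1) come from
  the untouched held-out set.
- **Feature ladder**: optional refits on the top-50 … top-15,000
  important genes reproduce the feature-selection-curve analysis; sizes
  exceeding the gene universe are skipped with a warning.
- **RF core set**: intersection of each model's top-N important genes
  (ties broken by importance descending, then gene id ascending, so the
  set is deterministic). N defaults to 6,000 in `RFConfig` to mirror
  the analysis recipe at full scale; the pipeline's desk-scale default
  is `rf_top_n=500` of 2,000 genes, the same quarter-of-universe
  proportion.

## 5. Combined core report (`stresscore.pipeline.combine_core_sets`)

The report has three rows — set operations, random forest, combined —
each split into up / down / no-differential-expression. RF-only genes
get a direction from the majority of their per-experiment TN calls
(ties place the gene in both lists); RF genes never DE-flagged go to
the no-DE column. The combined set is the plain union of both methods'
core sets.

## 6. Coexpression network (`stresscore.coexpression`)

The weighted-coexpression recipe: unsigned adjacency `|cor|^β` (β = 9;
a signed variant `((1+cor)/2)^β` is available), **topological overlap**

```
TOM_ij = (Σ_k a_ik a_kj + a_ij) / (min(k_i, k_j) + 1 − a_ij)
```

and average-linkage hierarchical clustering of `1 − TOM` with a
**static height cut** (0.95) and minimum module size 20. The static cut
is a deliberate simplification of dynamic tree cutting: it is fully
reproducible, has one interpretable parameter, and recovers planted
block structure in the tests; it will fragment or merge modules in
regimes where dynamic cutting adapts, which we accept for
determinism. Modules are labelled M1, M2, … by decreasing size (ties by
smallest member id), so labels are invariant to gene order.

**Eigengenes** are first principal components of the standardized
module submatrices, unit-variance and oriented to correlate positively
with the module's mean profile. **kME** is the signed correlation of
every gene with every eigengene. **Hubs** are genes whose *own-module*
|kME| lies strictly above the 95th-percentile quantile of own-module
|kME| (or an explicit override such as 0.86). Own-module kME is used
because membership strength is only meaningful relative to the module a
gene belongs to.

## 7. Enrichment (`stresscore.enrichment`)

One engine serves every over-representation question: one-sided Fisher
p-values as upper hypergeometric tails `P(X ≥ overlap)`
(`scipy.stats.hypergeom.sf`), cross-product odds ratios, and a
hand-rolled Benjamini–Hochberg step-up adjustment (statsmodels is used
only as a test oracle). Results are tiered: *enriched* (adjusted
p < 0.05), *near-enriched* (< 0.1), *ns*. Correction defaults to
within-query scope (BH across annotations separately per query set);
`global` is available. Optional term-parent propagation adds each
term's genes to all ancestors before testing ("classic" scheme), with
cycle protection.

## 8. Regulatory network (`stresscore.grn`)

**GENIE3-style weights.** For each target, a random-forest regression
of its standardized profile on all candidate regulators (self
excluded), with each regulator's share of the forest's impurity
importance normalized to sum to one per target. Self-edges are NaN in
the dense targets × regulators frame. `max_features` defaults to
`"sqrt"` (the usual GENIE3 choice for large regulator panels); with
small panels, importance spreads over correlated noise regulators, so
the planted-recovery tests and small-panel analyses use
`max_features=1.0`.

**Repeated Dunnett.** Per-target mean weights from the regulators of
interest are grouped (core / specific:stressor / other) and compared
many-to-one against the "other" control group:

```
t_i = (ȳ_i − ȳ_c) / (s_pooled · sqrt(1/n_i + 1/n_c))
ρ_ij = sqrt(n_i n_j / ((n_i + n_c)(n_j + n_c)))
```

with the max-|t| null evaluated by Monte Carlo from the equicorrelated
multivariate-t representation `T = (λ z0 + sqrt(1−λ²) z_i) / sqrt(χ²_ν/ν)`
and p-values floored at 1/(draws+1). Because the tail is Monte-Carlo
estimated, the test is repeated (default 5,000 times in `GRNConfig`;
the pipeline's desk-scale default is 2,000) and a central 97.5%
interval of the p-value sample summarizes it; a comparison is
**significant when the interval's upper bound is below α = 0.05**. In
the default `resample="mc"` mode the data are fixed and only the
Monte-Carlo evaluation varies between repetitions — the interval
quantifies *evaluation* uncertainty, not sampling uncertainty;
`resample="bootstrap"` additionally resamples group values to include
the latter. The implementation was cross-checked against
`scipy.stats.dunnett` and, for a single comparison, against the
closed-form pooled t-test.

In the pipeline, regulators are the simulated TF genes; regulators of
interest are combined-core TFs belonging to enriched or near-enriched
families (falling back to all core TFs, with a warning, if no family is
enriched); targets are the core and specific genes plus a seeded random
background sample (default 300 genes).

## 9. Pipeline and determinism (`stresscore.pipeline`)

`run_pipeline` executes simulate → preprocess → setops → RF →
coexpression → enrichment → GRN, with per-stage toggles, writes TSV
tables plus `report.json` (sorted keys) and `manifest.json` (SHA-256 of
every artifact, no timestamps). Every stage seed derives from the master
seed via fixed spawn keys, so two runs with the same config and seed are
byte-identical — which the test suite asserts literally.

## 10. Limitations

- The generator is log-normal with additive batch location/scale
  effects; it does not model count overdispersion, library-size
  artefacts, or correlated gene programs beyond the planted blocks.
- Parametric ComBat assumes normal/inverse-gamma priors; non-parametric
  priors and covariate preservation are not implemented.
- The static tree cut replaces dynamic tree cutting (see §6).
- TN-ratio thresholds (2 / 0.5) are conventions, not inferences; no
  per-gene significance accompanies a call (the Welch flag is a
  separate, deliberately simple annotation).
- Impurity-based RF importances are biased toward high-cardinality
  features in general; with all-continuous standardized inputs this is
  benign, but permutation importance is not implemented.
- The repeated-Dunnett interval in `mc` mode covers Monte-Carlo
  evaluation error only (§8).
- Desk-scale defaults (2,000 genes, 96 samples) are chosen for
  runtime, not realism; all counts reported by the pipeline refer to
  the synthetic dataset in use.
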