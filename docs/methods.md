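# Methods

## Model

For a functional module F and gene universe U (the genes carrying a ranking
statistic), membership is modelled as a Bernoulli outcome over genes:

- univariate: `logit P(g ∈ F) = c + α X_g`
- bivariate: `logit P(g ∈ F) = c + α X_g + β Y_g + γ X_g Y_g`

X and Y are arbitrary per-gene statistics (t-statistics, hazard ratios, SNP
odds ratios, splicing indices, …) used on their **raw scale** by default:
coefficients are then interpretable as log odds ratios per unit of the
statistic as measured. `standardize=True` (or `--standardize`) rescales each
column to mean 0, sd 1; this changes the coefficient scale but, by affine
equivariance of the MLE, not the Wald p-values.

The test is competitive and gene-sampling: the distribution of the
statistic inside F is compared with its complement U \ F, and genes — not
the subjects of the upstream experiment — are the sampling units.
P-values therefore speak about the gene list, not about the subject-level
comparison that produced it.

An intercept is always included; without it the competitive baseline
(the overall fraction of annotated genes) would be absorbed into the
slopes and the coefficients would be meaningless.

## Fitting and inference

- **Optimizer.** Iteratively reweighted least squares, initialised at the
  null model (intercept = logit of the membership fraction, slopes 0);
  convergence when the deviance changes by < 1e-8, at most 25 iterations.
  The design is checked for numerical full rank up front (a collinear pair
  of rankings is an error, not a silent drop).
- **Separation.** Fits that cannot converge in 25 iterations are returned
  with `converged=False` and a warning rather than raised or penalised, so
  extreme modules remain visible in the output table. Complete separation
  typically *does* meet the deviance criterion at a degenerate optimum; it
  is harmless for inference because the standard errors explode and the
  Wald p-value goes to 1. An optional ridge stabiliser on the slopes
  (`GsaConfig(ridge=...)`, default 0) is available for users who prefer
  finite estimates.
- **Wald tests.** z = coefficient / standard error against the standard
  normal, two-sided. Likelihood-ratio and permutation alternatives are out
  of scope.
- **Multiplicity.** Benjamini–Hochberg step-up, applied separately within
  each coefficient family — all tested modules' α together, all β, all γ —
  and only across the modules actually fitted (those surviving the size
  filter). The implementation delegates to
  `statsmodels.stats.multitest.multipletests(method="fdr_bh")`; the test
  suite checks it against an independently coded step-up formula.
- **Size filter.** Modules with fewer than 10 or more than 500 genes *in
  the universe* are excluded: tiny sets cannot support a stable fit, huge
  sets are too generic to interpret. Effective (post-intersection) sizes
  are used because the model only sees universe genes; the filter is
  idempotent.

## Pattern classification

Each coefficient's *effective sign* is its estimate's sign if its
BH-adjusted p-value is strictly below the threshold (default 0.05), else 0;
ties at the threshold are non-significant. The sign triple (α, β, γ) maps
onto 15 labels (see README table). When γ is significant the quadrant label
is the one opposite the saddle point (−β/γ, −α/γ): x-direction
sign(βγ), y-direction sign(αγ), falling back on the other main effect's own
sign when one main is null. This single rule generates the canonical
taxonomy rows and extends them deterministically to the four triples with a
significant interaction and opposite-sign main effects, which the plain quadrant reading
leaves implicit. Bimodal labels follow the interaction sign: `b13` for
γ > 0 (quadrants 1 and 3), `b24` for γ < 0 (quadrants 2 and 4).

Classification uses adjusted p-values, matching the reporting convention of
the result tables.

## Synthetic data generator

`generate(SimulationSpec)` emulates a two-statistic genome scan:

- background genes iid standard bivariate normal — the scale-free reference
  against which the effect size δ is expressed;
- planted modules: members' means shifted to the signed corner (±δ, ±δ) for
  quadrant patterns, a single axis (±δ, 0)/(0, ±δ) for `xh/xl/yh/yl`, and
  half-and-half between opposite corners for the bimodal patterns;
- intra-module correlation ρ (default 0) via a shared per-module latent
  term per dimension, `x = √ρ·z_set + √(1−ρ)·z_gene (+ shift)`, giving
  exact equicorrelation ρ with unit marginal variance;
- modules are disjoint blocks; optional extra null modules
  (`n_null_sets`) share no genes with planted ones;
- every draw flows from the single integer `seed` (replicates use
  `SeedSequence.spawn`, so reports are bit-reproducible).

Defaults (universe 5,000 genes, module size 50, δ = 0.7, ρ = 0,
200 replicates) describe a mid-sized experiment with a moderately shifted
module. What the generator does **not** emulate: heavy-tailed or skewed
statistic distributions, overlapping modules, correlation *between* the
two dimensions in the background, and annotation bias — so passing tests
demonstrate correctness of the machinery under a clean Gaussian null, not
robustness to every property of real data.

Note that a pure corner shift creates main effects only (the log density
ratio of two unit-variance Gaussians is linear): planted `q1i`-geometry
modules are legitimately recovered as `q1f` unless the membership truly
depends on the product XY. Interaction-driven data can be produced with
`sample_from_model`, which draws membership directly from the bivariate
logistic model with chosen (c, α, β, γ).

## Calibration and power studies

`calibrate` (effect = 0) fits the bivariate model on fresh null data per
replicate and reports per-coefficient rejection rates at the nominal level
with exact Clopper–Pearson CIs, using **raw** p-values (BH would confound
level estimation). `power` (effect > 0) runs the full pipeline including BH
and reports pattern-recovery rates.

Study sizes used by the test suite and `scripts/acceptance.py`: universe
2,000 genes, one module of 100 genes, 1,000 replicates for calibration;
universe 5,000, module of 50, 200 replicates for pattern recovery. Module
size 100 for calibration keeps the study about the correlation effect
rather than small-sample behaviour: with 50-gene modules the interaction
Wald test is intrinsically slightly anticonservative (empirical level
≈ 0.057 at nominal 0.05, regardless of universe size), a known limitation
of Wald inference at modest event counts.

With ρ = 0.5 the studies reproduce the qualitative behaviour expected of
competitive gene-sampling tests under intra-module correlation: main-effect
levels inflate to ≈ 0.7 while the interaction level drops to ≈ 0.02 —
anticonservative mains, conservative interaction.

## Numerical and design choices

- Deterministic outputs: gene universes are ordered (lexicographic after
  `align`), result rows sorted by set id, numbers written with 6
  significant digits; identical inputs give byte-identical TSVs.
- Duplicate gene rows in a ranking are mean-aggregated (symmetric,
  order-independent); non-finite rows are dropped with a logged count.
- Exon/subunit-level values are collapsed per gene by the median (midpoint
  convention for even counts) so single aberrant subunits do not dominate.
- Confidence ellipses: sample mean and covariance; boundary at squared
  Mahalanobis distance `chi2.ppf(level, 2)`, level 0.95 by default.
  Rendering is separated from the numeric summary so the statistics are
  testable headlessly.
- The universe is defined by the ranking input, not the annotation: genes
  annotated but unmeasured are dropped with a logged count, since the
  competitive complement only makes sense among measured genes.

## Known limitations

- Gene-sampling p-values are miscalibrated under intra-module correlation
  (by design of the method family); the simulation harness quantifies the
  direction and rough magnitude but the pipeline applies no correction.
  Subject-level permutation would be the remedy and is out of scope.
- The interaction Wald test is slightly anticonservative for modules of
  ≲ 50 genes (see above).
- Bimodal (`b13`) recovery at δ = 0.7 with 50-gene modules plateaus around
  76–79%: roughly 12% of replicates miss interaction significance and in
  another ~10% a chance-significant main effect relabels the module into a
  quadrant pattern. Stronger splits or larger modules push recovery toward 1.
- No GO hierarchy handling: terms are treated as flat, independent sets.
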