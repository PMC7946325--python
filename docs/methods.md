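# Methods

## The model

`iggsca` fits composite-based structural models for imaging-genetics data.
Observed variables — SNP genotype codes, regional brain measures (e.g. left
and right cortical thickness of a region of interest), behavioral scores and
covariates — are collected in a J-vector **z**, standardized to mean 0 and
variance 1.  A P-vector of components **γ** is defined by three sub-models:

* weighted relation: **γ** = **W z** — each component (a gene, an ROI, a
  behavioral construct) is a weighted sum of its own indicators;
* measurement: **z** = **C γ** + **ε** — each indicator is regressed on its
  own component, giving loadings;
* structural: **γ** = **B γ** + **ζ** — directed paths among components.

Stacking **V** = [**I**; **W**] and **A** = [**C**; **B**] combines the three
into a single residual **Vz − AWz**.  Component interactions (gene×environment,
gene×gene) enter as the elementwise product of their two parent score
vectors, rescaled to unit variance; an interaction has no indicators or
loadings of its own and — because the product is built from the parents'
composites — no weights of its own either (the shared-weight rule).

## Estimation

Parameters minimize the penalized least-squares criterion

    phi(W, C, B) = Σᵢ ‖V zᵢ − A W zᵢ‖² + λ Σ |b|^τ,

subject to every component score having unit variance with divisor N
(Σᵢ diag(γᵢγᵢ′) = N·I).  τ = 2 penalizes the free path coefficients with a
ridge penalty (the default; components and their interactions are typically
highly collinear), τ = 1 with a lasso.  Weights and loadings are never
penalized.  The structural residual block sums over dependent components
(those receiving at least one path); exogenous components, whose structural
residual would be their own unit-variance score, contribute only a constant
and are omitted.

An alternating regularized least-squares loop repeats three exact block
updates until the relative decrease of phi falls below `tol` (default 1e-5,
`max_iter` 300):

1. **Weights.**  For each composite component, every residual term that
   depends on its weight vector w — its own measurement block, its own
   structural equation, every equation in which it appears as a predictor,
   and every equation in which one of its interactions appears (the product
   is exactly linear in w once the partner score is held fixed) — is
   collected into a quadratic `w′Hw − 2g′w` under the constraint
   `w′Sw = N`, with S the indicator-block Gram matrix.  This
   norm-constrained least-squares problem is solved *exactly*: whiten by S,
   diagonalize, and solve the secular equation Σ cᵢ²/(λᵢ+μ)² = N with a
   safeguarded Newton iteration (the degenerate "hard case", where the
   gradient has no component on the smallest eigenspace, is handled
   explicitly).  Because each update is the global constrained minimizer,
   the criterion cannot increase at this step — a stronger guarantee than
   the classical solve-then-normalize heuristic.  After each parent update
   the interaction products and their unit-variance rescaling factors are
   refreshed; the rescaling is treated as a constant inside the update.
2. **Loadings.**  Closed form: with unit-variance scores the least-squares
   loading of an indicator on its own component equals their covariance.
3. **Paths.**  Per dependent component, ridge rows are solved in closed
   form, `(X′X + λI)⁻¹X′y`; lasso rows by covariance-form coordinate descent
   with soft threshold λ/2 (tolerance 1e-12·N on the largest coordinate
   change).  Dependent components sharing a predictor set share one Gram
   factorization.  At λ = 0 a collinear system falls back to the
   minimum-norm solution, with a log message.

Free weights initialize uniform(−1, 1) from a caller seed and are
normalized; one closed-form pass initializes loadings and paths.  Warm
starts (`start=`) reuse a previous solution, which the cross-validation and
bootstrap loops exploit.

**Sign convention.**  Composites are identified only up to sign.  After
every fit each composite is flipped so its loading sum is positive (tie →
first weight positive); bootstrap resamples are instead aligned to the
full-sample solution, and recovery replicates to the generating values.
Interactions flip as the product of their parents' flips, which leaves the
fitted model invariant.

**Interaction scores and the constraint.**  The unit-variance constraint is
applied to interaction columns through the rescaling factor
s = √N/‖γₐ∘γᵦ‖, stored with the parameters and reused when scoring new
rows (cross-validation, conditional effects).  Product scores are *not*
re-centered: the constraint is on second moments, and the sample mean of a
product of standardized scores is not exactly zero.  Monotonicity of the
criterion is therefore exact up to the rescaling refresh, and asserted in
tests at a 1e-8 relative tolerance (plain floating-point slack on models
without interactions).

**Row compression.**  All block updates depend on the data only through
cross-products of the columns of `[Z, partner⊙Z_block]` (the extra columns
linearize each interaction in its composite parent's weights).  Whenever
every composite interaction parent has a single-indicator partner — true of
both the motivating application design and the simulation preset — the
solver runs on the triangular QR factor of that matrix: numerically
identical results (asserted by test to 1e-10) at per-iteration cost
independent of N.  Models with two-composite interactions fall back to the
raw rows.

## Penalty selection and inference

λ is chosen by K-fold cross-validation (default K = 5, matching the
motivating application).  Rows are partitioned by a seeded shuffle; held-out
rows are standardized with the training fold's centering and scaling, and
the loss is the held-out combined-model residual sum of squares at the
training-fold parameters (the unpenalized part of the fitting criterion —
the natural choice where no loss is prescribed).  Ties resolve to the
smaller λ.  The default grid is 0 plus 30 log-spaced values on 1e-2…1e4;
the recovery study uses the coarse grid {0, 1, 10, 100, 1000}.

Standard errors and 95% intervals come from a nonparametric bootstrap
(default B = 500): rows resampled with replacement, refit at the *same* λ
and τ (λ is not re-selected per resample, keeping resamples comparable),
signs aligned to the full-sample fit, SE = resample standard deviation,
interval = empirical 2.5/97.5 percentiles, significance = interval excludes
0.  Percentile rather than BCa intervals are used — no bias correction is
part of the method.  Resamples with a zero-variance column are redrawn;
non-convergent refits are dropped from the effective count (warning below
90% survival).  A standardized single-indicator component forces weight and
loading 1 in every resample, so those rows report SE 0.00 and interval
[1.00, 1.00] exactly.

Conditional (simple-slope) effects of a predictor at moderator level m are
`b_main + b_int·s·z(m)`, where s is the interaction's rescaling factor and
z(m) the moderator's standardized score at raw level m; for genotype-coded
moderators the default levels are the codes observed in the data.  Slope
draws combine each resample's coefficients with its own rescaling factor;
raw levels are standardized with the full-sample statistics (resample-level
restandardization of the levels is a second-order effect and is not
propagated).  Indirect effects are products of chained coefficients with
percentile intervals of the elementwise product of the draws.

## Synthetic data

The generator draws exogenous component scores iid standard normal, builds
interaction scores as products of exogenous parents divided by their
population standard deviation (√(1+ρ²) for correlated normal parents), and
endogenous scores recursively with residual standard deviations chosen so
every component's population variance is 1.  The full implied score
covariance is computed analytically (Isserlis' identity for the product
terms) both to set residual variances and to validate feasibility — a
dependent equation whose implied explained variance reaches 1 is rejected.

Indicators are generated *composite-consistently*: for a k-indicator block
with loading c,

    z_j = c·γ + (η_j − mean(η_block)),   η_j iid N(0, (1−c²)·k/(k−1)),

so each measurement residual has standard deviation √(1−c²) but the
residuals sum to zero within the block.  Then the component is an *exact*
weighted sum of its indicators (equal weights 1/(kc)), the composite model
holds exactly in population, and weights, loadings and paths are all
consistently estimable.  This matters: with *independent* residuals of the
same size (a common-factor construction), the population value of the
composite loading for a 2-indicator block at c = 0.8 is ≈ 0.906, and a
recovery study would show loading "bias" ≈ +0.11 that is attenuation, not
estimator error.  The near-zero loading biases a recovery study should
exhibit are only attainable under a data-generating process for which the
composite estimand equals the generating loading.  Blocks with unequal
loadings are not supported by this construction and are rejected.

What the generator does *not* emulate: discrete genotype distributions
(continuous indicators are the default; an opt-in quantile discretization
maps SNP columns to codes {1,2,3} at specified genotype frequencies),
linkage disequilibrium between SNPs, inter-hemisphere asymmetries or any
spatial structure among ROIs, and correlated exogenous genes.  Passing
tests therefore demonstrate correct recovery of the model's own structure,
not robustness to coarse genotype coding or real LD patterns.

### The study preset

`study_design()` builds the benchmark design: nine genes with
one, two or four SNPs (3/3/3 split, 21 SNPs), sixty ROIs with two
indicators, one single-indicator environment variable, one outcome, nine
gene×environment interactions; genes, environment and interactions point at
every ROI (19 declared paths per ROI equation), ROIs and environment at the
outcome.  Default generating values: loadings 0.8, nonzero paths 0.3.  The
exact zero/nonzero arrow pattern is not enumerable from the source figure,
so a seeded random pattern stands in and the truth is carried alongside the
data.  Sparsity (default 0.5) is applied *per ROI equation* (a balanced 10
of 19 zeros) rather than globally, which keeps every equation's implied
explained variance below 1 (≈ 0.81 at the defaults).  The outcome equation
is treated separately: sixty mutually correlated ROIs at coefficient 0.3
would imply an outcome variance far above 1 for any substantial nonzero
fraction, so the preset gives the outcome three nonzero ROI paths plus the
environment path (implied explained variance ≈ 0.67) — the same order as
the handful of significant outcome effects in the motivating application.

## The recovery study

`run_recovery_study` draws `reps` datasets per sample size, selects λ by
five-fold CV on the coarse grid, refits, aligns signs to the truth, and
aggregates per free parameter: bias = mean(estimate) − truth (signed — the
standard definition), SD across replicates (divisor reps−1), and
RMSE = √mean((estimate−truth)²), so RMSE ≥ |bias| holds per parameter
before group averaging.  Group cells average per-parameter values over
gene loadings, ROI loadings, and the zero/nonzero path blocks
(genes/environment→ROI, G×E→ROI, ROI→outcome).  Defaults are reps = 200 at
N ∈ {250, 2000} — chosen as the package's routine desk-scale configuration;
a larger study (e.g. 1000 replicates over four sample sizes) is available
through `reps`/`N_list`.  Monte-Carlo error of a group bias at these
settings is well below the 0.005 tolerance used in the acceptance checks.

## Numerical choices and limitations

* Convergence: relative criterion decrease < 1e-5, max 300 iterations;
  non-convergence returns a flagged result with a warning rather than an
  error.
* Whitening cutoff 1e-12 on relative eigenvalues of indicator Gram blocks;
  secular-equation Newton iterations stop at |f−N| ≤ 1e-13·N.
* Ties in CV totals resolve to the smaller penalty; ties in the sign
  convention to the first indicator's weight sign.
* Missing data are rejected outright (complete-data method).  Zero-variance
  columns abort with the column named.
* Structural cycles are legal in estimation but not in generation (the
  generator needs a topological order).
* Interactions are sources only (never path targets), may not be nested,
  and in the generator must have exogenous parents.
* The ALS criterion is non-convex; different seeds can reach different
  local optima on pathological data.  The acceptance suite checks the
  converged criterion against a generic numerical minimizer and random
  feasible draws on small instances.
* Overall fit indices from the wider composite-modeling literature (FIT,
  AFIT) and multiple-testing corrections across the path matrix are out of
  scope; raw 95% intervals are reported per parameter.
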