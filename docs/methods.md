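# Methods

`sludgeqspr` implements a quantitative structure–property relationship
(QSPR) pipeline for the sludge/water partition coefficient of
pharmaceuticals.  The target variable is log10 K_d (K_d in L kg⁻¹), the
equilibrium ratio of sorbed to aqueous concentration of an active
pharmaceutical ingredient (API) in sewage sludge.  The pipeline covers
descriptor reduction, linear reference models, and Bayesian-regularized
neural-network committees, together with a synthetic-data generator that
reproduces the statistical structure of a curated literature K_d dataset
so that every stage can be validated against known ground truth.

## Data model

One row is one literature measurement: compound id, charge class of the
dominant protomer near pH 7.4 (uncharged / positive / negative /
zwitterion — supplied with the data, never computed), log K_ow, optional
log D_ow at pH 7.4, measured log K_d, and an arbitrary block of numeric
molecular descriptors.  A compound may contribute several measurements
made in different sludges and studies; all are kept rather than averaged,
which deliberately injects the between-study variability that limits
attainable model accuracy.

## Synthetic generator

The generator emulates a 297-measurement / 148-compound dataset with
charge-class measurement counts 92 (uncharged), 105 (positive), 76
(negative) and 24 (zwitterion), and compound counts 44/60/28/16.

* **Replicate structure.** Per-compound measurement counts are drawn from
  a geometric-like distribution (most compounds have 1–3 measurements,
  tail capped at 12) and repaired to the exact class totals.
* **Latent truth.** Per compound,
  `log K_d = a_c + b_c·logKow + A·tanh(s1 + s2) + ε`,
  with class slopes b = 0.42 / 0.45 / 0.0 / 0.1 and intercepts
  a = 1.07 / 1.53 / 1.73 / 1.5, compound-level noise
  ε ~ N(0, 0.5²) log units, and an optional smooth bounded nonlinearity
  in two standard-normal signal descriptors s1, s2 (amplitude A, default
  0 — a purely linear truth).
* **Replicate noise.** Each measurement adds uniform noise whose
  half-width is calibrated from the drawn replicate-count mix so that the
  expected mean within-compound range equals the configured target
  (default 0.91 log units): the range of m iid U(0, w) draws has
  expectation w(m−1)/(m+1), so the calibration is closed-form.
* **Descriptors.** An exact copy of log K_ow, the two signal columns,
  independent standard-normal noise columns, and near-collinear
  "redundant" columns built as linear combinations of 2–3 other columns
  plus N(0, 0.05²) noise — these give unsupervised forward selection a
  known correct answer.  log K_ow is drawn N(2, 2²), spanning the −3..7
  range typical of APIs.
* **Nonlinear study condition.** `nonlinear_config()` sets A = 1.2; at
  that amplitude the variance a linear model cannot capture implies an
  ANN-over-PLS test-set R² gain of roughly 0.1, the same order as the
  improvement nonlinear models show on the real literature data.  Because
  test sets hold only 60 measurements, the realized gain fluctuates from
  seed to seed (it is positive in expectation and for most seeds, not for
  every seed).

What the generator does **not** emulate: real molecular-descriptor
marginals or correlations, pH/protomer effects, sludge-type covariates,
or heavy-tailed measurement error.  Passing recovery tests therefore
demonstrates algorithmic correctness under the stated statistical
structure, not predictive validity on laboratory data.

## Descriptor reduction

1. **CV filter** removes descriptors with coefficient of variation
   |sd/mean| below a threshold (default 0.05).  |mean| is used so sign
   conventions cannot flip the filter; columns with mean ≈ 0 are kept
   (CV effectively infinite) unless they are constant.
2. **Unsupervised forward selection (UFS)** picks a subset with minimal
   multiple correlation: start with the two columns of smallest absolute
   pairwise correlation, then repeatedly add the candidate whose R² in a
   least-squares regression (with intercept) on the selected set is
   smallest, while that R² stays below `ufs_r2_max` (default 0.99; the
   main knob controlling reduced-set size).  Ties break toward the
   smallest column index, making the order deterministic.

Both steps are response-blind, so per-training-split reduction is
leakage-safe by construction.

## Linear models

* **Univariate** log K_d = a + b·log K_ow per charge class and pooled,
  by OLS; pooling heterogeneous classes destroys the correlation, which
  is the motivation for class-aware and multivariate models.
* **Leverage screening**: hat-matrix diagonals of the fitted design;
  rows with h_ii > 3p/n (multiplier configurable) are removed in a
  single pass and the model refit.
* **Stepwise regression**: forward-backward on coefficient t-test
  p-values, enter/remove thresholds 0.15/0.15 by default; perfectly
  collinear candidates get entry p-value 1.  Predicted R² for a stepwise
  model holds the selected variable set fixed across LOO folds — an
  optimistic convention matching common statistical packages, noted here
  deliberately.
* **PLS (NIPALS, single response)**: X autoscaled, y centered but not
  scaled (with one response, scaling y does not change back-transformed
  coefficients).  Each weight vector is X_residᵀy normalised (PLS1
  converges in one inner step); X is deflated per component; the sign of
  each weight vector is fixed so its largest-magnitude entry is positive,
  which makes loadings and loading-based rankings reproducible.  The
  component count is chosen by leave-one-out cross-validated R², with
  autoscaling refit inside every fold; ties resolve to the smaller count.
  The cumulative fraction of autoscaled-X variance captured by the
  selected components is reported alongside.
* **Fit statistics**: R², R²_adj = 1−(1−R²)(n−1)/(n−p−1), predicted
  R² = 1−PRESS/SST (PRESS from LOO residuals; the closed-form
  e_i/(1−h_ii) identity for OLS), LOO R²_cv, mean unsigned error, and the
  residual standard deviation.  For n ≤ p+1 the adjusted/predicted
  statistics are flagged undefined rather than silently NaN.

## Bayesian neural networks

Architecture: multilayer perceptron with one hidden tanh layer (2–5
units; 2 is the headline setting) and a single linear output predicting
centered log K_d from standardized descriptors.

Training follows the evidence framework.  The regularized error is

    E = β·E_D + Σ_g α_g·E_W(g),   E_D = ½Σ(y−ŷ)²,  E_W(g) = ½Σ_{w∈g} w²

with one prior precision α_g per weight group: each input's fan-out
weights form a group (this is automatic relevance determination, ARD),
plus one group each for hidden biases, hidden→output weights, and the
output bias.  MAP training is a deterministic conjugate-gradient
minimization (100 iterations per outer loop, gradient tolerance 1e-6)
with exact back-propagated gradients.  Hyperparameters are re-estimated
at each of 8 outer loops from the Gaussian posterior approximation:

    γ_g = |g| − α_g·tr_g(A⁻¹),  α_g ← γ_g / 2E_W(g),  β ← (N − Σγ_g) / 2E_D

where A = β·JᵀJ + diag(α) is the Gauss–Newton curvature (J the
network's weight Jacobian).  Gauss–Newton is used throughout rather than
the exact data Hessian: it is positive semidefinite, exact in the linear
test mode, and avoids saddle-point pathologies; eigenvalues are floored
at 1e-10 before inversion and log-determinants, and floored directions
contribute γ ≈ 0.  α and β are clamped to [1e-8, 1e8].  The network is
scored by the Gaussian-approximation log marginal likelihood
("evidence"):

    log Z = −βE_D − Σ α_g E_W(g) − ½log det A + ½Σ|g|log α_g + (N/2)log β − (N/2)log 2π

Initial weights are N(0, 1/√fan-in) per layer, seeded per member;
initial α_g = 0.01 and β = 1/var(y).  In the identity-activation test
mode the model is a genuinely linear map y = b + w·x (same grouping),
the MAP problem is solved in closed form, and the whole recursion
coincides with Bayesian ridge regression — the exactness oracle used in
the test suite.

**Committees.** 100 networks (configurable) differing only in
initialization seed are trained; the 10 with highest evidence are kept
and their outputs averaged.  Evidence ties break by seed order.
**ARD ranking.** Within each committee member, inputs are ranked by
ascending α (small decay → large weights → influential); descriptors are
ordered by mean rank across members, ties by name.

## Experiment protocols

* **Splits.** Five independent uniform train/test divisions (237/60 at
  the default 297 measurements), sampled without replacement and
  independently across splits (overlap between test sets is allowed, as
  "independent choices" implies).  The default split level is the
  measurement, so replicates of one compound may straddle the divide —
  this matches the 237/60 arithmetic but leaks compound identity; a
  compound-level option keeps all of a compound's measurements on one
  side at the cost of approximate test-set sizes.
* **Per-split protocol.** CV filter + UFS, standardization, PLS component
  selection and all ANN hyperparameter estimation are fit on training
  rows only; a `global_reduction` flag reproduces the simpler
  reduce-once-globally protocol.  A dedicated test corrupts test rows
  and asserts the trained models are bit-identical.
* **Production models.** After generalization error is estimated from
  the splits, final PLS and committee models are refit on the full
  dataset with the same protocols; their R²/MUE are labelled in-sample
  fit statistics, not predictive estimates.

## Determinism and numerics

All randomness flows from one master seed through named substreams
(generator / split / network-init), so a run is bit-reproducible.
Degenerate inputs (zero-variance responses or predictors, rank-deficient
designs, over-rank component requests, all-rows-flagged leverage
screens) raise informative errors rather than propagating NaNs.

## Problem sizes in tests

The test suite and the acceptance script use the generator's study-scale
defaults (297 measurements) but reduced committee sizes (20 networks,
best 5) and a single hidden-node setting for the split experiments;
these sizes were chosen so the full protocols still run comfortably on a
single CPU while preserving the committee-selection structure.

## Known limitations

* Descriptor computation (MOE/Vsurf/ParaSurf), log K_ow/log D_ow
  prediction, protomer selection and K_d data curation are out of scope;
  the package starts from a descriptor table.
* The exact data Hessian is not implemented; evidence values are those
  of the Gauss–Newton approximation.
* The stepwise predicted-R² convention (fixed variable set across folds)
  is optimistic.
* With only 60-measurement test sets, method comparisons (ANN vs PLS)
  carry seed-level variance; orderings are meaningful in aggregate, not
  per split.
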