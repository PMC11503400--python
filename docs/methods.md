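# Methods

## The model

The package predicts a count-valued attention-problem score from
resting-state network connectivity and demographic risk factors with a
group-penalized nonparametric Poisson regression. Writing the expected
count for subject i as mu_i, the model is additive on the log scale,

    log mu_i = f0 + sum_j f_j(x_ij),        y_i ~ Poisson(mu_i),

where each f_j is one predictor's effect: a per-level constant for an
unordered factor, a polynomial-contrast expansion for an ordered
factor, or a cubic spline for a numeric predictor. Because every term
contribution is centered to sample mean zero, exp(f0) is the baseline
predicted count for an average subject and exp(f_j) is the
multiplicative effect of predictor j on that baseline.

The fit minimizes

    (1/n) sum_i [mu_i - y_i log mu_i]
        + sum_g  alpha * rho(||beta_g||_2; lambda w_g, gamma)
                + (1 - alpha) * (lambda w_g / 2) * ||beta_g||_2^2,

a group elastic net: all columns belonging to one predictor form a
group g with weight w_g = sqrt(group size), so a predictor enters or
leaves the model as a whole. rho is one of three sparsity penalties
applied to the group norm:

* **LASSO** — rho(t) = lambda t; convex, but biases large effects
  toward zero and tends to admit false positives;
* **MCP** (gamma > 2) — quadratically relaxes the penalty until it is
  flat for t > gamma lambda, so large coefficient blocks are estimated
  without shrinkage;
* **SCAD** (gamma > 3) — linear near zero, then a quadratic blend, then
  flat beyond gamma lambda.

The elastic-net weight alpha in [0, 1] mixes the sparsity penalty with
a group-ridge component that stabilizes correlated groups.

## Design matrix

* Unordered factors are coded with one indicator column per level and
  no reference level dropped; the group penalty resolves the resulting
  aliasing, and the all-level coding lets per-level multiplicative
  effects be read off directly. Columns are centered.
* Ordered factors (income, education) use orthonormal polynomial
  contrasts up to degree levels-1.
* Numeric predictors are standardized and expanded in a cubic B-spline
  basis of dimension `basis_df` (default 5; the default keeps the full
  86-term model at p = 438 columns, well below the cohort sizes used).
  Interior knots sit at equally spaced quantiles; boundary knots sit at
  the 0.5% and 99.5% quantiles so the basis has no free curvature in
  the extreme tails, continuing as a constant beyond them (the same
  rationale as placing the outer knots of a restricted spline at
  trimmed quantiles). The basis is rotated onto the spectral
  coordinates of the curvature penalty (the integrated squared second
  derivative), with the constant direction projected out, and each
  column is down-weighted by sqrt(1 + d_j), where d_j is its curvature
  eigenvalue. Under a group-norm penalty this makes wiggly directions
  more expensive than smooth ones — the smoothing-spline prior
  expressed through the penalty. One block-level constant rescales each
  term so that terms remain comparable under the shared lambda.
* Every column is centered to sample mean zero (|mean| < 1e-10
  enforced), which anchors the intercept at the cohort baseline.

## Solver

The objective is minimized by a monotone accelerated proximal-gradient
method (FISTA with a descent safeguard: an accelerated step that fails
to decrease the objective is replaced by a plain backtracked proximal
step from the last accepted point, which is a guaranteed descent step).
The group proximal operator is evaluated in closed form for all three
families by solving the scalar problem in the group norm; for the
nonconvex families the candidate stationary points of each penalty
region are clamped into their region and compared on the prox
objective, which is robust where the prox could otherwise be
multi-valued. The intercept is unpenalized and initialized at its null
MLE log(mean(y)), so the largest lambda on the path reproduces the
intercept-only model exactly.

The lambda path has 100 log-spaced values (ratio 0.01) from

    lambda_max = max_g ||grad_g NLL/n at the null fit||_2 / (alpha w_g),

the smallest lambda that keeps every group at zero. Fits are
warm-started along the decreasing path. Each lambda is pre-screened
with the sequential strong rule and the solution is verified against
the full KKT conditions, enlarging the candidate set until no
violations remain; the returned points satisfy first-order
stationarity within 1e-4 for all families (checked in the test suite).
Convergence is declared when the maximum coefficient change falls
below 1e-7 (default) within 10^4 iterations. MCP and SCAD are
nonconvex, so the contract is stationarity plus monotone objective
descent, not global optimality.

## Cross-validation and selection

Hyperparameters (family-specific gamma, alpha, lambda) are tuned by
k-fold cross-validation (default k = 10) scored with mean absolute
error on the count scale. The default grid is alpha in
{0.01, 0.25, 0.5, 0.75, 1} and gamma in {3, 4, 5}; gamma values that
violate a family's concavity bound (gamma > 2 for MCP, gamma > 3 for
SCAD) are dropped from that family's grid with a warning, so the SCAD
grid has 10 cells. The lambda path of each grid cell is computed once
on the full data and shared across folds. Two selection rules are
first-class: `min` (the MAE-minimizing cell and lambda) and `1se` (the
largest lambda in the winning cell whose mean MAE is within one
standard error of the minimum — the sparser model with statistically
indistinguishable error; the default reporting rule). Ties break
toward larger lambda (the sparser model). Fold fits use a looser
tolerance (1e-5) than the final full-data refit (1e-7): MAE-based
selection is insensitive to the trailing decimals of fold
coefficients.

## Interpretation

* **Deviance R2** = 100 (1 - D_model / D_null), with the Poisson
  deviance D = 2 sum[y log(y/mu) - (y - mu)] and the null model the
  intercept-only fit mu = mean(y).
* **Variable importance** distributes the explained variation across
  terms by the covariance share of each centered term contribution
  with the linear predictor:
  VI_j = 100 sum_i f_ji (eta_i - etabar) / sum_i (eta_i - etabar)^2.
  The indices sum to exactly 100 by algebra; negative values are
  possible (terms anti-correlated with the overall prediction) and are
  reported, not clipped, because the identity requires them.
* **Effect tables/curves**: per-level exp(f_j) for factors; exp(f_j)
  evaluated on 100 equally spaced points across the observed range for
  numeric terms. No extrapolation beyond the observed range is
  permitted. The multiplicative decomposition
  mu_i = exp(f0) prod_j exp(f_j(x_ij)) is exact for every subject.

## Connectivity featureization

ROI time series are motion-censored: frames with framewise
displacement above 0.2 mm are dropped, together with any sub-threshold
run shorter than 5 contiguous frames; subjects with fewer than 350
surviving frames are excluded (with a logged reason, no imputation).
On the retained frames, Pearson correlations (means removed over
retained frames only) are Fisher z-transformed — r is clipped to
+/-0.999999 so atanh stays finite — and averaged over all distinct ROI
pairs within a network, or all cross pairs between two networks. With
the 12 canonical networks this yields 78 features, named "A_B" with
the two network labels sorted lexicographically; ROIs labelled "none"
are excluded. Features are kept on the averaged-z scale (not
back-transformed to r), matching the averaging-of-transformed-
correlations definition.

## Synthetic cohort generator

The generator emulates the study population so the pipeline is
testable without restricted data:

* factor marginals follow the published descriptive statistics of the
  cohort (site uniform over 22 levels, where no marginal is published);
  factors are sampled independently by default — site-by-sex dependence
  exists in the real cohort but no joint distribution is published;
* age is uniform on [9, 11] years (only the mean 9.94 and SD 0.63 are
  published; uniform keeps the support correct);
* the 78 connectivity features are Gaussian on the averaged-z scale
  (no distribution is published) with exchangeable correlation 0.2 by
  default, within-network means 0.45, between-network means 0.10, SD
  0.15, and the default-mode/dorsal-attention pair (column `DLA_DT`)
  centered at -0.35 with SD 0.15 so its bulk lies in [-0.8, 0.2];
* the outcome follows the log-link additive model with baseline
  exp(f0) = 1.452 and default multiplicative effects taken from the
  published MCP estimates (sex 1.17/0.85; income 1.13/0.99/0.89;
  alcohol 0.87/0.93/1.03/1.19; drugs 0.76/0.93/1.12/1.27); factor
  log-effects are mean-centered under their marginals (ratios are
  preserved, the weighted mean is absorbed into the intercept); the
  default connectivity effect is the smooth monotone curve
  0.9 tanh((z + 0.5)/0.25), rising steeply as the anticorrelation
  weakens from -0.8 to about -0.4 and then flattening;
* the outcome is uncapped Poisson by default, matching the fitted
  likelihood, although the real instrument is bounded at 14; a
  truncation-by-redraw switch exists for realism studies;
* synthetic ROI time series are latent-factor constructions (network
  factor share 0.5 by default, so within-network correlations equal
  0.5 in expectation) with an FD trace whose baseline stays below
  0.2 mm and whose spikes occur at a configurable rate.

What the generator does **not** emulate: BOLD autocorrelation, scanner
drift, site-specific acquisition effects, family/sibling structure,
site-by-demographic dependence, the hard ceiling of the instrument,
and the weak, diffusely correlated effect structure of real cohort
data. Passing recovery tests therefore demonstrates the correctness of
the estimation machinery under the assumed model, not real-data effect
sizes: with the clean synthetic signal, cross-validated deviance R2
(about 15-20% at n = 8000) is far higher than the single-digit values
typical of real behavioral prediction, and all three penalties recover
the single true connectivity feature essentially perfectly at the 1se
rule, so differences in false-positive behavior between the penalties
do not manifest under these conditions.

## Problem sizes used in the test and acceptance runs

Statistical checks run at the sizes the properties reference: marginal
and moment checks at n = 10^5 to 10^6 draws; solver-oracle instances
at n = 200-400; parameter recovery at n = 8000 with the full 86-term
design (MCP, alpha = 1, gamma = 3, 10-fold CV); the selection study at
n = 8000 with the 78 connectivity terms, 20 replicates, alpha = 1, a
50-value lambda path to ratio 0.05 and fold tolerance 1e-4 (the
sparsity-relevant corner of the grid; a full-grid probe gave identical
selections). The acceptance script uses n = 4000 with the full design.

## Known limitations

* MCP/SCAD solutions are stationary points; different warm-start paths
  can reach different local minima (observed nowhere in the test
  instances, but not excluded).
* The spectral spline parameterization fixes its smooth-to-wiggly
  trade-off a priori through the sqrt(1 + d_j) weighting rather than
  tuning a second smoothing parameter per term.
* Cross-validation reuses the full-data design (column means, knots,
  basis scaling) across folds; the mild information sharing is the
  standard path-CV compromise and does not affect fold disjointness of
  the outcome.
* The alpha = 0 corner of the elastic net has no finite lambda_max; the
  path is anchored with a large cap and flagged with a warning.
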