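# Methods

## Model and estimators

Subject *i* contributes a scalar outcome y_i and an unordered stack of p_i
tubule feature vectors in R^q. We assume the tubule vectors are draws from a
G-component mixture of latent subgroup distributions, and that the outcome
follows the bilinear model

    y_i = alpha' X_i** beta + eps_i,      eps_i ~ N(0, sigma^2),

where X_i** = diag(w^i) X_i* is the subject's matrix of subgroup-mean
features weighted by their subgroup proportions w^i. alpha in R^G carries row
(subgroup) effects, beta in R^q column (feature) effects. The pair is
identified only up to a scale/sign exchange, so estimation is constrained to
||alpha||_1 = 1 and a positive largest-magnitude beta component; the reported
quantity of scientific interest is the L1-normalized magnitude profile of
beta.

Three estimators share this model:

* **Full Information** — the structured lasso on the true (X_i**, y_i); an
  oracle available only in simulation.
* **CLUSSO** — the same lasso on estimated designs: pooled tubules are
  clustered (GMM or K-means), features are averaged within subject-by-cluster
  cells, and the observed cluster proportions supply the weights. Subjects
  lacking a tubule in some cluster have an undefined cell and are dropped
  (and reported); a majority of drops is a diagnostic that the data may have
  fewer latent subgroups than G, where the naive method is a reasonable
  fallback.
* **naive** — ordinary lasso on per-subject overall feature means; the
  baseline that ignores heterogeneity.

## The alternating solver

The objective (1/n) sum_i (y_i - alpha' X_i beta)^2 + lambda ||beta||_1 is
biconvex. With alpha fixed, z_i = X_i' alpha reduces the problem to an
ordinary lasso in beta, solved by cyclic coordinate descent with
soft-thresholding (residual-maintained; inner sweeps stop when the largest
coefficient move is < 1e-10, capped at 10 sweeps — each coordinate update is
itself a descent step, so partial convergence cannot break monotonicity).

With beta fixed, v_i = X_i beta leaves a least-squares problem in alpha, but
the constraint ||alpha||_1 = 1 couples alpha's scale to the penalty: mapping
any unconstrained a to the feasible point (a/||a||_1, beta*||a||_1) leaves
the fit unchanged and scales the penalty to lambda*||beta||_1*||a||_1. The
alpha-step therefore minimizes

    (1/n) ||y - V a||^2 + lambda ||beta||_1 ||a||_1,

a lasso in a with the constraint-induced weight, and then rescales onto the
constraint set. This makes every step a genuine descent step of the
constrained objective (the unpenalized least-squares step followed by
renormalization does not — rescaling beta rescales the penalty, and the
objective can tick upward). At lambda = 0 the step reduces to plain least
squares with an explicit rank check. Note the model still places no penalty
of its own on alpha: the alpha-step weight is induced purely by the
constraint, not a hyperparameter.

Iterations stop when the relative objective change falls below `tol`
(default 1e-6) or after `max_iter` (default 200) alternations. On exit the
sign is canonicalized (flip both vectors if the largest-|.| beta component —
lowest index on ties — is negative). If beta hits exactly zero, alpha is
unidentified and the solver returns the null fit with objective mean(y^2).

Alternating minimization reaches a stationary point, not necessarily the
global minimum, so fits restart from `n_inits` (default 5) random
initializations — alpha standard normal then L1-normalized, beta standard
normal — and keep the smallest objective. A brute-force check over the alpha
constraint set (grid of alpha = (t, +/-(1-|t|)) at step 1e-3, convex
beta-lasso at each point) confirms the restarted solver attains the global
optimum on small instances; that oracle runs in the test suite.

## Cross-validation and thresholding

lambda is chosen by K-fold (default 5) cross-validated held-out MSE over an
ascending grid ({0.5, 1, ..., 5} by default; an application-scale grid like
{0.1, ..., 20} is a config choice). Folds are a seeded shuffle of subjects;
within each fold every lambda is fit with the usual random restarts plus a
warm start from the previous lambda's solution (deterministic, and can only
lower the fold objective). Ties in mean CV error go to the smaller lambda.
The naive baseline uses the standard 100-value log-spaced path from
lambda_max = (2/n) max_j |<x_j, y>| (the smallest all-zero lambda under the
(1/n) RSS convention, matching the structured objective's scaling) down to
lambda_max * 1e-4.

After fitting, beta is L1-normalized and components below 0.001 in magnitude
are set to zero; the result is deliberately *not* renormalized after
zeroing. Selection metrics (TPR/FPR) and the bias read this thresholded
vector; predictions use the raw fitted beta, whose scale matters.

Design cells are z-scored per (cluster, feature) cell across subjects
(population SD), the outcome is centered in lieu of an intercept, and the
stored transform is re-applied to test designs. We standardize the final
weighted cells X** — the quantity entering the fit — rather than
standardizing before weighting; a zero-variance cell is a hard error naming
the cell.

## Train-to-test cluster correspondence

Cluster labels are arbitrary, so a model trained with training-cluster order
(1, 2) may meet a test cohort whose cluster "1" resembles training cluster
"2". Prediction on new data evaluates all G! row permutations of the test
designs (standardizing with the training transform after permuting) and,
when test outcomes exist, flags the permutation with the smallest MSE. By
default test tubules are labeled by the *trained* cluster model
(reproducible, no refit); independent re-clustering of the test pool is
available behind a flag, after which correspondence resolution is essential.

## The synthetic generator

The generator mirrors the study conditions the estimators are evaluated
under. Per subject: latent subgroup-mean rows (two-cluster scenario: N(2,1)
and N(5,3), read as mean/variance), a weight w1 uniform on {0.2, ..., 0.8},
outcome noise variance 1, and observed tubules formed by resampling latent
rows with probability w and adding N(0, sigma2_R) measurement error per
entry. Tubule counts are discrete-uniform over H integers centered at
mu_M = 40 with H the largest odd integer <= sqrt(12*sigma2_M + 1)
(sigma2_M = 5 gives H = 7, support {37..43}, variance 4). True coefficients
are drawn once from {1, 2, 3, 4} with round(s_beta * q) beta components
zeroed, and shared across settings and repetitions; outcome and measurement
noise are redrawn every repetition. The correlated scenario draws the latent
matrix from a matrix normal with row covariance [[1, sqrt(3)/2],
[sqrt(3)/2, 3]] (tubule correlation exactly 0.5) and identity column
covariance, via X* = mu + L Z with L the lower Cholesky factor. Three- and
one-cluster scenarios probe a misspecified G.

What the generator does *not* emulate: real cohorts have hundreds of tubules
per subject (not ~40), dozens of correlated hand-crafted features,
non-Gaussian and possibly more-than-two-component tubule populations, and
outcome noise far above variance 1. Passing tests therefore demonstrate
correctness of the machinery and the qualitative selection advantage under
the stated mixture model — not clinical performance.

Harness aggregation follows the evaluation design: medians across
repetitions for TPR/FPR/bias/MSE (their distributions are skewed), means of
per-replicate mean clustering accuracies (nearly symmetric). Replicate seeds
are spawned from the master seed with a (setting, repetition) key, so any
setting can be reproduced in isolation; failed replicates are counted and
excluded, and undefined rates (e.g., FPR when beta* has no zeros) propagate
as missing values rather than zeros.

## Numerical choices and tie-breaks

* GMM: full covariances, 5 EM restarts, tolerance 1e-6, 500-iteration cap;
  non-convergence is an error, not a silent partial fit. Features are
  column-standardized over the pooled tubules before clustering (disable
  with a flag); constant columns pass through unscaled.
* Labels come from the frozen parameter object (log-posterior argmax for
  GMM, nearest centroid for K-means, lowest index on ties) so training-time
  and test-time labeling share one code path, and archives can relabel
  without refitting.
* Best-permutation clustering accuracy uses Hungarian assignment on the
  pooled confusion matrix — equivalent to the best of all G! relabelings —
  then averages per-subject agreement across subjects.
* K-fold assignments, restart draws, and fit seeds all derive from a single
  integer seed via spawned seed sequences; every fit is bit-reproducible.
* Model archives are JSON with arrays stored flat (row-major) plus shapes;
  floats round-trip exactly.

## Problem sizes in the shipped checks

The test suite and the acceptance script run reduced replications chosen to
give stable medians at interactive cost: 20 repetitions for clustering
accuracy at n=500 (its across-replicate spread is tiny), and 50 repetitions
per sample size for the FPR comparison at n in {1100, 1500, 2000}. The
harness itself supports full-scale grids (1000 repetitions) with disk
caching and resumability.

## Known limitations

* The alternating solver's global-optimality check covers small instances
  (G = 2, q <= 3); for large q multimodality is handled only by restarts.
* Subjects dropped for an empty cluster are excluded from both fitting and
  CV; no imputation is attempted.
* Only continuous outcomes and a single matrix predictor are supported —
  no scalar covariate adjustment, binary/survival outcomes, or
  more-than-two-way arrays.
* G is fixed by the user (the application uses G = 2); the package does not
  select it.
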