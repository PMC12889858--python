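# Methods

## Model

A dataset is a collection of `M` trials, each an `N x T(m)` matrix
`Y(m)` of channels by time, carrying a label: one option per metadata
category (e.g. task difficulty, choice).  Channel identities are fixed
across trials; durations `T(m)` may differ.  Each category `k` owns a
budget of `p(k)` components, `P = sum_k p(k)` in total, and each of its
components exists in `|k|` *variants* — one per label option — stacked in
a tensor `A(k)` of shape `N x p(k) x |k|`.  A trial's loading matrix
`A_L(m)` (`N x P`) concatenates, per category, the variant slice selected
by the trial's label.  Observations are modeled as

    Y(m) = A_L(m) Phi(m) + eps,    eps ~ iid N(0, sigma^2),

with `Phi(m)` (`P x T(m)`) the per-trial temporal traces.  Trials with
equal labels share loadings exactly; traces are free per trial.  The
model therefore separates label-driven compositional structure (in the
variants) from trial-to-trial temporal variability (in the traces).

## Objective and updates

The fit minimizes, over variants and traces jointly,

* data fidelity `sum_m ||Y(m) - A_L(m) Phi(m)||_F^2` (missing cells
  excluded when masking is enabled),
* component sparsity `gamma1 * sum |A|` (entrywise L1),
* variant coupling `gamma2 * sum_{k} sum_{i<i'} lambda_{i,i'}(k)
  ||A(k)_i - A(k)_{i'}||_F^2`, with `lambda(k)` a per-category label
  similarity graph,
* temporal smoothness `gamma3 * sum_m sum_{t>=2} ||Phi_t - Phi_{t-1}||^2`,
* trace decorrelation `gamma4 * sum_m sum_{j != j'}
  |<Phi_j, Phi_j'>| / (||Phi_j|| ||Phi_j'||)`.

Summing the coupling over unordered pairs makes each variant subproblem
exactly the global objective restricted to that slice, so block descent on
the subproblems is descent on the total.

**Variant update.**  For each (category, option) pair, the update uses all
trials carrying that option, regardless of their other label entries.
Residuals remove the other categories' current contributions.  The
subproblem is separable across channels: each row solves an L1-penalized
least squares with a quadratic attraction toward the graph-weighted
sibling variants.  It is solved by cyclic coordinate descent with
(one-sided, when nonnegativity is enabled) soft-thresholding; coordinates
are visited in fixed ascending order for bit-reproducibility, stopping
when the largest coordinate change falls below 1e-13 relative to the
problem scale.  Residuals are recomputed before every variant update
(Gauss–Seidel), so attraction always pulls toward the newest siblings.  An
option with no trials degenerates gracefully: the fidelity term vanishes
and the minimizer is the soft-thresholded graph-weighted average of its
siblings (a warning is emitted).  If a variant's trace rows are entirely
zero and no graph attraction exists, the subproblem has no curvature and
the incumbent slice is kept with a warning.

**Trace update.**  Per trial, fidelity + smoothness is an exact quadratic;
the decorrelation term is non-convex and is handled by iterated quadratic
surrogates: row norms and Gram signs are frozen from the previous inner
iterate, turning the term into `gamma4 * sum_t phi_t' W phi_t` with a
fixed symmetric zero-diagonal `W`.  Each surrogate is a block-tridiagonal
system (bandwidth `P`) solved exactly with a banded LAPACK solve; 5 inner
iterations by default (1 when `gamma4 = 0`, where the solve is already
exact).  A candidate is accepted only if it does not increase its own
surrogate, and the final iterate is kept only if it does not increase the
true per-trial objective relative to the incumbent — so trace updates
never ascend.  Zero loading columns with `gamma3 = 0` make the system
singular; a 1e-8 ridge is added with a warning.

**Normalization.**  After every component sweep, each non-zero component
column is rescaled so its absolute entries sum to `norm_constant`
(default 1; for nonnegative components this is a plain sum), and the
matching trace row of every trial selecting that slice is counter-scaled,
preserving all reconstructions to floating point.  This fixes the
scale ambiguity between components and traces while leaving trial-specific
amplitudes in the traces.

**Outer loop.**  Components → normalization → traces, repeated until the
relative change of the total objective drops below `tol` (default 1e-4)
or `max_outer_iters` (default 50) is reached.  The objective after each
outer iteration is logged.  With `check_descent=True` every subproblem
asserts its own non-ascent, which the test suite exercises.

## Label similarity graphs

Categorical categories couple all option pairs uniformly (off-diagonal
weights 1).  Ordinal categories use a Gaussian kernel on the ordinal
values rescaled to `[0, 1]`: `w(i,j) = exp(-(v_i - v_j)^2 / (2 b^2))`
with bandwidth `b = 0.5` by default — chosen for smooth monotone decay
with option distance and because `b -> inf` recovers the categorical
graph.  Weights are not row-normalized; the global `gamma2` absorbs
scale.  Per-category weight matrices can be overridden by the user
(`label_graph_weights`), e.g. to match an externally defined similarity.

## Initialization

Components are seeded from the eigenvectors of the channel covariance
accumulated over all trials, partitioned across categories in declaration
order (category `k` takes the `p(k)` eigenvectors after those claimed by
earlier categories), with a fixed sign convention (dominant entry
positive) and absolute values when nonnegativity is on.  Slices within a
category start identical; the data and graph coupling differentiate them.
Traces are initialized by ridge-stabilized (1e-8) least squares against
the initial loadings.  Initialization is fully deterministic.

## Default hyperparameters

`gamma1 = gamma2 = gamma3 = 0.1`, `gamma4 = 0.01`: each term is active
but subdominant at unit data scale, since the fidelity Gram grows with
the total number of time points while the penalties do not.  All are
exposed in `ModelConfig` / the estimator constructor and should be tuned
per application scale.

## Synthetic data generator

The generator emulates the structure the model assumes, with known ground
truth: sparse nonnegative components (support `ceil(sparsity*N)`,
magnitudes uniform(0.5, 1), L1-normalized columns) whose variants differ
by a perturbation touching at most 20% of the support (half recruited
channels, half shed), scaled linearly by `variant_jitter` and
interpolated monotonically along ordinal option orders; zero-mean
Gaussian-process traces with squared-exponential kernel (1e-6 diagonal
jitter), lengthscale and amplitude drawn per (component, label option) so
trace statistics are label-tied while each trial draws a fresh GP sample;
and iid Gaussian observation noise.  Defaults: `N=100`, `M=250`, `T=500`,
categories (difficulty: 5 ordinal options, p=2; choice: 2 categorical
options, p=2), sparsity 0.15, jitter 0.2, lengthscales uniform(10, 60)
steps, amplitudes uniform(0.5, 1.5), noise sd 0.1, labels uniform over
the product space.  `N`, the GP parameter ranges and the label
distribution are not pinned down by the protocol the generator follows
and are documented defaults.

What the generator does *not* emulate: non-Gaussian and signal-dependent
noise, temporal nonstationarity within trials, correlated channels
outside components, non-uniform label frequencies, and channel identity
drift.  Passing recovery tests on this data shows the optimizer recovers
the model's own structure at realistic noise levels — not that real
recordings satisfy the model.

## Evaluation

Factorizations are identifiable only up to component permutation, so
estimated components are aligned to ground truth by linear sum assignment
with cost `1 - |pearson|` on variant-averaged compositions (a per-variant
cost is available behind a flag).  Signed correlations under the optimal
assignment, per-trial trace correlations of matched rows, and per-trial
reconstruction R² are reported.  Zero-variance components get correlation
0 with a warning.

**Permutation test.**  Significance of label structure is assessed by
shuffling the trial-to-label assignment.  Two modes:

* *rescore* (default): trials are split at random; components are fitted
  once on the training half (real labels) and held fixed; the held-out
  half is scored — traces refit per trial — under its real labels versus
  assignments permuted within the held-out set.  Scoring out of sample is
  essential: components fitted and rescored on the same trials absorb
  noise aligned with the real labeling and beat nearly every permutation
  even when labels are pure noise (measured p = 0.01 in 10/10 label-free
  pilot runs of the in-sample variant).  With the holdout, labels are
  exchangeable under the null and the test is exact.
* *refit*: the full model is refit on every permuted dataset, giving null
  scores the same in-sample flexibility as the real score; much slower.

The score is total reconstruction R²; the add-one p-value
`(1 + #{null >= real}) / (1 + n_perms)` never returns zero.

## Numerical choices and degenerate inputs

* Coordinate-descent tie-break: fixed ascending coordinate order.
* Convergence: relative total-objective change < 1e-4 over one outer
  iteration; history length capped by `max_outer_iters`.
* NaN observations are rejected unless `mask_missing` is enabled, in
  which case masked cells are excluded from every fidelity term (per-row
  Grams in the variant update, per-column Grams in the trace update).
* `P > N` initializes trailing components to zero with a warning.
* Labels with options unknown to their category raise immediately,
  naming the offending trial.
* All randomness flows through explicit integer seeds; same seed, same
  bits.

## Problem sizes used in the test suite

Solver-versus-oracle checks run on 50 random instances with `N <= 8`,
`P <= 4 (<= N)`, `T <= 12`.  Ground-truth recovery runs at `N=50, M=80,
T=200` over 3 generator seeds (mean matched component correlation
measured ≈ 0.92, mean trace correlation ≈ 0.84).  Permutation-test
calibration uses 50 label-free repetitions at `N=20, M=24, T=30` with 99
permutations; the power check uses `N=40, M=60, T=50` with variant jitter
0.5 and noise sd 0.05.  These sizes keep the full suite fast while
leaving every structural property intact.

## Known limitations

* The decorrelation term is non-convex; the surrogate scheme guarantees
  non-ascent, not global optimality, and the alternating fit converges to
  a local optimum dependent on initialization.
* Component budgets `p(k)` are user-chosen; sparsity drives redundant
  components toward zero but no explicit model-selection procedure is
  provided.
* The per-category trace-row layout is contiguous in declaration order;
  cross-session channel matching and unequal channel sets are out of
  scope.
* The rescore permutation test spends half the trials on fitting; for
  very small `M` the refit mode, though slower, uses the data more
  efficiently.
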