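# Methods

## Model and estimator

Expression of p genes is observed for n samples under each of two
conditions (matrices X, X̃ after column centering, which absorbs the
per-gene intercepts).  Each gene i is modelled by a pair of linear
neighborhood regressions, x_i = X_{−i}β_i + e_i and
x̃_i = X̃_{−i}β̃_i + ẽ_i; the nonzero coefficients define directed
edges j → i, stored as entry (j, i) of the p×p coefficient matrices
B and B̃ (column i of B is β_i; diagonals are structurally zero).  No
Gaussianity is assumed — the estimator is penalized least squares:

J(β, β̃) = ‖x_i − X_{−i}β‖² + ‖x̃_i − X̃_{−i}β̃‖²
           + λ₁(‖β‖₁ + ‖β̃‖₁) + λ₂‖β − β̃‖₁

with sum-of-squares scaling (no 1/n or 1/2 factors; λ values therefore
scale with n and with the squared data scale).  λ₁ controls network
sparsity, λ₂ the sparsity of the between-condition differences.  The
problem is convex; the fusion term couples coefficients only in pairs,
which is what makes the proximal operator closed-form.

## Solver

Proximal gradient descent on the stacked vector α = [β; β̃]:

* smooth part g₁ = the two squared errors; gradient blocks
  2(X_{−i}ᵀX_{−i}β − X_{−i}ᵀx_i) and the analogue for the second
  condition, evaluated through cached Gram matrices (O(p²) per
  iteration after an O(np²) setup);
* non-smooth part g₂ = both penalties; prox decomposes per coordinate
  pair (t_j, t̃_j) into a two-variable fused-lasso signal approximator
  solved exactly: if |t−t̃| ≤ 2λ̃₂ both coordinates move to the
  midpoint, otherwise each moves λ̃₂ toward the other; then each is
  soft-thresholded by λ̃₁ (λ̃ = λ·step).  The closed form is verified
  in the tests against a dense-grid numeric minimizer that includes the
  kink manifolds x = y, x = 0, y = 0 (a plain 2-D grid misses the fused
  valley because no grid point lies exactly on x = y).
* constant step 1/L with L = 2(γ + γ̃), γ/γ̃ the top eigenvalues of
  the two Gram matrices, computed on the smaller of the n×n / p×p Gram
  forms; a cheaper trace-based L is available (`step_mode="trace"`) and
  always yields a smaller step.
* stopping rule: relative change of the stacked coefficient vector
  ≤ tol (default 1e-6), max_iter 10,000.  Non-convergence warns and
  returns the last iterate rather than raising, so whole-network runs
  continue.  The objective path is non-increasing to 1e-9 slack on all
  tested instances, and λ₂ = 0 solutions agree with an independent
  coordinate-descent lasso to an objective gap ≤ 1e-8.

Acceleration (FISTA) and backtracking are deliberately out of scope;
warm starts along penalty paths are used instead.

Whole-network fits use an exactly equivalent matrix form: all p
regressions share the full-sample Gram matrices, the zero-diagonal
constraint is enforced inside the (separable) prox, and per-column
penalty vectors come free.  This replaces p python-level solver loops
per network with BLAS matrix products and is what makes stability
selection affordable.

The single-condition lasso (`lasso_cd`, used for the λ₂max bound's
common solution β*, and for the separate-lasso baseline) is an
in-house cycled coordinate descent on the Gram form with an explicit
KKT-residual stopping rule (≤ 1e-8), JIT-compiled with numba; it is
cross-checked against scikit-learn's `Lasso` in the tests.

## Penalty scales and grids

λ₁max = max over predictors and conditions of 2|x_jᵀx_i| zeroes the
joint solution.  λ₂max(λ₁) is an upper bound (the exact threshold is
not tractable) obtained from the subgradient conditions at the fused
optimum β*, the stacked two-condition lasso solution with penalty 2λ₁;
fusion at λ₂max is verified empirically rather than proven tight.
Grids are geometric, largest-first (warm starts then move from sparse
to dense): S₁ = {λ₁max·α₁^m} and, per λ₁, S₂(λ₁) = {λ₂max(λ₁)·α₂^m}.
Defaults: (α₁, α₂, k₁, k₂) = (0.7, 0.8, 10, 10) for stability
selection and (0.6952, 0.3728, 20, 8) for cross-validation.  Grids are
recomputed per gene; for whole-network drivers there are two options —
a shared grid anchored at the per-gene maxima's maximum
(`network_lambda_grid`), and per-gene grids with shared exponents
(`fit_network_grid` / `stability_select_grid`), in which grid point
(m₁, m₂) solves every gene at its own λ₁max·α₁^{m₁} and
λ₂max·α₂^{m₂}.  The per-gene form is the default for stability
selection: with a single global anchor, weakly connected genes sit in
the all-zero/fully-fused regime over most of the grid and contribute
nothing to the frequencies.

## Cross-validation

Five-fold CV partitions each condition's samples independently
(seeded); each training split is recentered and its column means are
applied to the held-out split, since the model is intercept-free only
after centering.  PE(λ₁, λ₂) is the held-out squared error summed over
both conditions and averaged over folds; SE is the across-fold standard
deviation divided by √folds.  The two-SE rule selects, among grid pairs
with PE ≤ PE_min + 2·SE at the minimizer and penalties at least the
minimizers, the largest λ₁ and then the largest λ₂ (explicit
tie-break).  A pooled network variant sums per-gene PE surfaces on a
shared grid and selects one pair for all genes.

## Stability selection

For each penalty setting, each condition's samples are split at random
into two halves (independently per condition — paired samples are not
assumed; with an odd count the first half takes the extra sample) and
the whole network is refit on each half; this is repeated N times
(default 50).  Edge frequencies r, r̃ count nonzero coefficients and
Δr counts changed edges over the 2NK refits, normalized by 2NK so all
frequencies are proportions in [0, 1] (with K grid settings pooled
into one frequency, as in the original recipe; normalizing by the
actual number of fits keeps thresholds like 0.6–0.9 meaningful, and
rankings are unchanged).  Changed-edge counting applies the magnitude
criteria below inside every refit (switchable); thresholding Δr ≥ c
with c in [0.6, 0.9] declares changes, and ranking by Δr orders
candidates by reliability (ties broken by |Δb|, then labels).

## Changed-edge criteria and gene filters

An entry (j, i) counts as changed only if both
|b̃_ji − b_ji| ≥ min{|b̃_ji|, |b_ji|} (at least a one-fold change
relative to the smaller magnitude) and max{|b̃_ji|, |b_ji|} ≥ T, where
T is the 20th percentile of all nonzero coefficient magnitudes pooled
from both fitted networks — recomputed per analysis, not fixed.
Identical pairs are never changed.  For real expression matrices two
filters precede inference: genes with pooled mean expression at or
below the 30th percentile are removed, then genes with pooled
CoV (sd/mean) at or below the 70th percentile.  Percentiles use linear
interpolation, and "lower q percentile removed" is implemented as
value ≤ q-th percentile.  The mean-expression reading of the first
filter is a choice (the summary statistic is not otherwise pinned
down), as is pooling both conditions for both filters.

## Simulators

*Paired regressions*: designs are i.i.d. standard normal (n = 100,
p − 1 = 200 by default); β has 20 nonzeros uniform on ±[0.5, 1.5]; β̃
rewires 10 entries (4 zeroed, 6 added); noise is N(0, σ²) with σ² =
0.01 by default (0.01–0.5 in the benchmark sweeps).  Both responses
and designs are centered before fitting, matching the estimator's
contract.

*Paired networks*: a directed topology with exactly 62 edges on p = 50
genes is drawn by a hub-biased stand-in generator — heavy-tailed
(Pareto) in/out propensities, slot weights equal to their product, and
Gumbel top-k sampling for an exact edge count — emulating the degree
heterogeneity of curated regulatory networks; an externally produced
adjacency can be supplied instead (`adjacency=` hook or the TSV
loader).  Six off-diagonal entries are flipped (additions and deletions
sampled uniformly) for the second topology.  Weights are signed-uniform
on ±(0, 1], copied between conditions wherever the topologies agree;
if the spectral radius of either B reaches 0.95 both are rescaled by a
common factor (the structural model needs I − B invertible, which the
weight recipe alone does not guarantee).  Expression solves
X = E(I − B)⁻¹ with standard-normal E, and observed data add
N(0, σ²) measurement noise (σ² = 0.05 by default).

What the generators do *not* emulate: library-size and count noise of
real RNA-seq, batch structure, feedback-free acyclicity constraints,
and kinetic/ODE-style expression dynamics.  Passing benchmarks therefore
demonstrates correct recovery under the linear structural model with
Gaussian noise, not performance on raw sequencing data.

## Benchmarks and problem sizes

`netdiff.benchmarks` fixes the two evaluation protocols.  The linear
benchmark runs 10 replicates at (n, p−1, σ²) = (100, 200, 0.01), picks
(λ₁, λ₂) per replicate by five-fold CV with the two-SE rule on the
standard CV grid, and pools detections over replicates; the
per-condition lasso baseline gets its own CV per condition.  Expected
behavior: detection power at or near 1 for both methods, with the
joint method's changed-entry FDR at or below the baseline's.

The network benchmark runs 10 replicates of the 50-gene generator at
n = 100, σ² = 0.05, ranks changed edges by stability-selection Δr, and
scores precision-recall of the ranking pooled across replicates (area
= step-wise average precision, not trapezoidal — the choice shifts
absolute values, so comparisons should hold the estimator fixed).
Stability selection here uses per-gene grids subsampling the default
grid's range with coarser spacing (α₁ = 0.7³, α₂ = 0.8³, k₁ = k₂ = 4,
so exponents 0, 3, 6, 9 of the default decay factors), N = 4 runs, and
a capped solver budget (tol 1e-4, max_iter 2500) — refits feed support
counts, not coefficient estimates, and the selection pattern is stable
well before the coefficients converge to 1e-6.  These sizes keep a
full benchmark run in minutes on one CPU; larger K and N sharpen the
frequency resolution but do not change the ordering of the methods in
our runs.

## Numerical and degenerate-input conventions

Empty detections report power 0 and FDR 0.  Precision-recall requires
at least one true positive (error otherwise); tied scores are processed
as one threshold block.  All-zero designs admit no step size (error).
Zero-variance predictors keep zero coefficients in coordinate descent.
Frequencies and masks ignore the diagonal.  All stochastic components
(simulators, fold splits, half-sample splits) take explicit seeds and
are exactly reproducible; derived seeds stay below 2³¹.

## Known limitations

Directionality is nominal: neighborhood regression recovers the
support of the precision-matrix pattern (the moralized graph), so a
strong edge j → i generally appears in both genes' neighborhoods and
single-edge orientation should not be over-interpreted.  λ₂max is an
upper bound, so grids can over-cover the fused regime.  The
stability-frequency normalization makes frequencies depend on the grid
K; comparing Δr across analyses requires the same grid.  CV selection
with the two-SE rule is conservative by design and leaves a nonzero
FDR among changed entries at small noise; stability selection with
c ≥ 0.6 is the recommended route when false changes are costly.
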