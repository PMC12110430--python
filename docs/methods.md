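# Methods

## Model and assumptions

The observed pairs (x_i, y_i), i = 1..n, follow a linear regression whose
coefficient vector is piecewise constant in time:

    y_i = x_i'(β_1 + Σ_{l≤j} δ_l) + ε_i    for a_j < i ≤ a_{j+1},

with a_0 = 0, a_{s+1} = n, unknown count s and locations a_j (each a_j is
the *last* index of its regime). The errors are assumed i.i.d. with mean
zero and finite variance, independent of the regressors; the model carries
no implicit intercept (supply a column of ones if wanted). The asymptotic
regime behind the procedure requires the change points to be separated
proportionally to n (at most one change per block for large n), every δ_j
nonzero, and enough observations on both sides of every change.

Lagged responses may appear among the regressors (the reference design uses
y_{t−1}); detection conditions on the observed design, so no stationarity
of the autoregression is required beyond the error assumptions.

## The two-stage detector

**Cutting.** `make_plan(n, m)` partitions 1..n into p_n = ⌊n/m⌋ blocks,
lengths m except the first, which absorbs the remainder (m ≤ |Q_1| < 2m).
`build_block_design` forms the n × p_n·q cumulative design Z whose column
(l, c) equals covariate c with rows before block l zeroed; on this design a
change point becomes a sparse group of nonzero coefficients. A change point
aligned with a block boundary marks exactly one block column group; one
interior to block k marks blocks k and k+1 (the straddled block's
least-squares limit differs from both neighbours).

**Selection.** After mean-centering y and the columns of Z (constant
columns flagged and excluded), the orthogonal greedy algorithm picks, per
step, the column maximizing |z_j'r|/(√n‖z_j‖), orthogonalizes it against
the previously picked ones (modified Gram–Schmidt with one
reorthogonalization pass), and deflates the residual. The path stops at the
argmin over d of HDIC(Ĵ_d) = log σ̂²_d + d·c_n·log(r_n)/n, where σ̂²_d is the
exact least-squares residual variance of the first d raw columns (the
orthogonalized residual norms compute it; the equivalence is asserted in
tests to 1e-8). Trimming keeps a column only when removing it strictly
increases HDIC; a single-pick path is kept as is, and an empty trim falls
back to the first pick so the selected set is never empty.

**Window mapping.** A block enters the active set Â if any of its q columns
survives. Maximal runs of consecutive active blocks, excluding block 1
(baseline), each signal one change point; with run-last block b the anchor
is k̂ = b − 1 and the refinement window is the 2m range covering blocks k̂
and k̂+1. This anchor puts the true change interior to the window in both
the boundary-aligned (single-block) and interior (two-block) signatures. If
only block 1 is active the series is declared change-free (ŝ = 0), a valid
outcome.

**Refinement.** Within a window starting at n_l, admissible splits are
n_l + q < h < n_r − q (h the last pre-change index, strict bounds). The
sup-Wald statistic at h equals RSS(X) − RSS(X, Z_h), and the augmented fit
decouples into separate least squares on the pre- and post-h rows; the scan
is computed from batched cumulative Gram matrices (q × q solves for all h at
once). Singular splits are skipped with a log entry; a window in which every
split is singular raises an error. Ties, including the all-zero profile,
resolve to the smallest h.

**Block-length choice.** m = ⌈c_0√n⌉ over a grid of c_0 ∈ [0.1, 1.5]
(default step 0.1); grid points whose m < 2q+3 or 2m > n are inadmissible
and skipped. The fit minimizing BIC = n·log(RSS/n) + ŝ·q·log n is returned,
ties to the smallest m. A literal variant log(RSS) + ŝ·q·log n is available
(`bic_variant="unscaled"`), but its penalty dominates the criterion at any
realistic n and degenerates the selection toward ŝ = 0, so the
conventionally scaled form is the default.

## Bootstrap confidence intervals

Residuals of the final piecewise fit are centered *within each estimated
segment* (â_{j−1}, â_j], using â_0 = 0 so every index belongs to exactly one
segment and each segment's centered residuals sum to zero exactly. A
replicate draws ε*_i i.i.d. from its own segment's centered residuals and
sets y*_i = fitted_i + ε*_i with x_i as observed (fixed-design bootstrap;
for AR designs a recursive option re-propagates lagged columns from y*).
The selection and refinement stages are rerun on y* with the segmentation
fixed at the original m̂. A bootstrap change point matches original point j
when its anchor block equals k̂_j; unmatched points are recorded absent, so
each interval uses B*_j ≤ B effective replicates.

The interval is the percentile rule
[â_j + Q_{α/2}(D_j), â_j + Q_{1−α/2}(D_j)] on the matched differences
D_j = {â*_j − â_j}, with linear-interpolation empirical quantiles, endpoints
rounded outward to integers and clipped to [1, n]. Joint statements use the
Bonferroni level α/ŝ per point. Replicate b draws from a generator seeded by
a deterministic substream of the caller's generator, so results are
independent of execution order.

## Synthetic data

`periodic_ar_spec()` encodes the reference design: n = 600, regressors
(cos(tπ/30), sin(tπ/30), y_{t−1}), first-regime coefficients (2, 2, 0.1),
increments (−3, 1, 0.2), (2, 0, −0.3), (2, 2, 0) after t = 150, 300, 450,
i.i.d. standard normal errors, and y_0 = 0 for the recursion. The generic
`SimSpec` generator accepts arbitrary exogenous designs, shift patterns and
lag maps. What the generator does *not* emulate: dependent or
heteroskedastic errors, heavy tails, trends or missing data — passing
Monte-Carlo tests therefore demonstrate correctness of the procedure under
its stated assumptions, not robustness beyond them (dependent errors would
require a block bootstrap, out of scope here).

## Monte-Carlo drivers and problem sizes

`mc_study` reports, over R replicates: the correct-call rate (ŝ = s and
every ordered |â_j − a_j| ≤ 5), per-point hit rates (nearest estimate within
5), and conditional means/SDs of the nearest estimates within 50 of each
truth. Nearest-estimate matching is used because the matching is undefined
when ŝ ≠ s. `coverage_study` draws fresh realizations, bootstraps each once,
and reads coverage of marginal intervals at α and of Bonferroni α/ŝ joint
intervals from the same matched differences; true points match the nearest
estimate, and realizations without a matched interval count as non-covered.

The packaged checks run R = 1000 for detection metrics
(`scripts/acceptance.py`) and 200 replicates in the test suite, with
coverage at 100 realizations × B = 200 — sizes chosen so the whole suite
runs on a laptop-class single core in minutes while leaving Monte-Carlo
standard errors of a few percentage points; the full 500 × 500 coverage
protocol is available through `ogacp coverage-study`.

## Numerical choices and edge cases

- Greedy ties break to the lowest column index; columns numerically inside
  the span of the current selection (norm after orthogonalization below
  1e-10 of the original) are dropped from candidacy, so perfectly collinear
  duplicates cannot be selected twice.
- σ̂² = 0 (perfect fit) is clamped at a machine floor with a warning before
  the logarithm.
- D_n, the greedy path cap, defaults to min(#usable columns,
  ⌈(n/log r_n)^{1/2}⌉·K) with K = 5, matching the theoretical growth rate
  with a practical constant.
- c_n = 2 by default (AIC-like weight in the HDIC penalty).
- The strict h-grid bounds mean a change point lying within q+1 indices of
  its window edge cannot be hit exactly at that block length; the BIC
  selection across block lengths resolves this in practice (the noiseless
  reference design is recovered exactly).
- Rank-deficient piecewise designs raise an error naming the offending
  segment; segments with fewer than two residuals cannot be resampled and
  raise a degenerate-segment error.

## Known limitations

- Errors must be (approximately) i.i.d.; dependent errors invalidate the
  residual bootstrap.
- Changes closer together than 2m, or within q+1 of the series ends, are
  not detectable by construction.
- The number of change points is not given an interval — only locations
  are; uncertainty in ŝ shows up only through B*.
- Under weak signals the anchor-block matching discards many replicates
  (small B*), widening or destabilizing intervals; near-boundary changes
  make the anchor wobble by one block between replicates.
- The intervals are conservative for the BIC-adaptive estimator: replicates
  keep the segmentation fixed at m̂, so the bootstrap reproduces the
  dispersion of the *fixed-m* location estimator (verified in the test
  suite), while the reported point estimates benefit from per-realization
  block-length adaptation and are tighter. Empirical coverage therefore
  tends to sit above the nominal level, most visibly at looser levels
  (e.g. 90%) and for boundary-aligned change points.
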