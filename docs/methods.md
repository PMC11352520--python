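# Methods

This note documents the models, numerical choices and limitations behind
`dynoc`. Everything quantitative stated here is computed by the test suite
or by `scripts/acceptance.py`; nothing is quoted from elsewhere.

## Jackknife-correlation connectivity

For signals x, y of length T, the raw edge value at time t is minus the
Pearson correlation over the T−1 retained points, with the leave-one-out
means used in both the covariance and the variances. The implementation
works from global sums (one pass) with the signals centred first, which is
algebraically identical to the textbook form but avoids catastrophic
cancellation when BOLD offsets are large; the test suite checks agreement
with a literal per-(i,j,t) `np.corrcoef` loop to 1e−10.

Sign convention: the leading minus is kept, so after per-edge z-scoring a
larger value means the time point contributed more to the edge's
correlation. Normalization is per edge across time, with the population
(divide-by-T) standard deviation — these are fixed, complete sets of T
values, not samples from a larger population — and a zero-variance edge maps
to the all-zero vector. Requirements: T ≥ 4, finite values, non-zero
variance per region (validated at load with row/column coordinates in the
error). An isolated degenerate leave-one-out subsample (a signal constant on
the retained points) yields 0 for that element with a warning rather than
aborting the subject; a region degenerate at *every* time point is a hard
error. Slice diagonals are fixed at 0: self-connectivity is undefined for
this estimator.

## Group-level dynamic network

Each edge's representative subject minimizes the summed Euclidean distance
between length-T edge trajectories, ties broken by lowest subject index (the
selection rule needs a deterministic tie-break for reproducible provenance).
The sum includes the zero self-distance, which cannot change the argmin.
Each unordered pair is computed once and mirrored. The group tensor
therefore contains only measured trajectories — its per-edge value set is a
subset of the inputs — and a provenance table records the chosen subject per
edge. Cohorts (e.g. patients vs controls) are processed by separate calls
and compared only at the metrics layer.

## Overlapping community model

Objective: `Σ_t ‖F_t − C Z_t Cᵀ‖_F² + β‖C‖₁` with C ≥ 0 (N×k, column maxima
pinned to 1) and diagonal Z_t ≥ 0. Because C is non-negative the ℓ1 term is
`β·ΣC` and enters the gradient as the constant β.

*Intensity update.* `z_p ← z_p · (c_pᵀ F_t c_p) / (c_pᵀ C Z_t Cᵀ c_p + ε)`,
ε = 1e−12 — the natural multiplicative (Lee–Seung-style) rule for this
diagonal tri-factorization, obtained from the positive/negative split of the
gradient `−2 c_pᵀ(F_t − C Z_t Cᵀ)c_p`. For non-negative F_t it never
increases the slice residual (checked numerically in the tests); z = 0 is a
fixed point.

*Membership update.* One projected-gradient step on C with Armijo
backtracking (σ = 1e−4, halving, at most 30 halvings), then negatives are
clipped and each column rescaled to maximum 1. Rescaling column p by its
maximum m_p multiplies every z_p(t) by m_p², which leaves C Z_t Cᵀ — and the
Frobenius term — exactly unchanged; without this compensation the
renormalization step would break monotone descent. The sufficient-decrease
test is evaluated on the *full* objective after clipping and renormalization
(the β term is not preserved by rescaling), so the per-sweep objective trace
is non-increasing by construction; the accepted step warms up the next
sweep's starting step (capped at 1.0) to avoid re-halving from scratch. A
column that dies to all zeros is left untouched and contributes nothing.

*Fitting.* `n_init` random restarts (default 20; uniform non-negative C with
columns normalized, uniform non-negative intensities), each sweeping
Z-then-C until the relative objective change drops below `tol` (default
1e−6) or 500 sweeps; the restart with the smallest final objective wins. A
master seed spawns one independent stream per restart, so runs are exactly
reproducible. Negative tensor entries must be clipped first
(`preprocess_nonnegative`, which logs the clipped fraction); z-scored JC
tensors are roughly half negative, and the non-negative factors can only
represent the non-negative part of the network. Min-shifting instead of
clipping was considered and rejected: it makes every pair of regions
connected at every time point, destroying the sparsity that the communities
are meant to explain.

*Model selection.* Grid search (defaults k = 2…20, β = 0…1 step 0.1) with
2-fold cross-validation over time: interleaved even/odd time-point folds,
fit on one fold, freeze C, re-estimate held-out intensities by multiplicative
updates alone, record the held-out Frobenius error, average both directions.
Interleaving keeps both folds spanning the whole scan, so slowly varying
intensity profiles are represented in each.

## Metrics

*Stability.* Runs are hardened to partitions by per-node argmax membership
(ties to the lowest community index) — the consensus construction needs
partitions, and argmax is the standard hardening for factorization-based
consensus. Co-assignment indicators are averaged over runs into a consensus
matrix; average-linkage hierarchical clustering is applied to 1 − consensus;
the cophenetic correlation between the condensed consensus distances and the
tree's cophenetic distances is the stability score. Identical runs give
exactly 1; a degenerate single-block consensus (zero distance variance) is
defined as 1 when the tree reproduces the constant distances. Average
linkage is the convention in the consensus-clustering literature this metric
comes from.

*Diversity.* At time t, `D_t = C diag(√z_t)`; each node's k weights are
normalized to a probability vector and scored by Shannon entropy (natural
log, 0·ln 0 = 0; all-zero rows give 0). Bounds 0 ≤ H ≤ ln k are property-
tested. The √z weighting means a community's influence on a node's diversity
grows with its instantaneous intensity.

*Membership threshold and activity.* Community p's members are the regions
*strictly above* mean + 1 population SD of column p — scale-invariant, and
empty for a constant column (with a warning). Activity is
`a_p(t) = z_p(t) · mean_{j∈N_p} C[j,p]`, reported both as the full series and
as its time mean: the summation in the activity definition is ambiguous
between member strengths and time, so the member-strength mean modulated by
the intensity series is computed and both views are written. The
mean-plus-SD rule is only informative when communities are sparse relative
to N; with k communities of size ~N/k it keeps roughly the upper tail of
each block, which is the intended "strongly associated" reading.

*Group comparison.* Two-sided label-permutation test on the difference of
means with the +1 identity-permutation correction; seeded; degenerate pooled
data returns p = 1 with a warning.

## Synthetic data

The generator is the package's study condition, not a tuning knob. Regions
are split into k contiguous blocks; each block's first member anchors the
column maximum at 1.0 and the rest draw strengths from U(0.4, 0.7). Overlap
nodes (⌈overlap_fraction·N⌉ of them, taken round-robin across blocks) carry
1.0 in their home community and 0.8 in the cyclically next one — both
clearly above the mean+1SD threshold on sparse networks, and above the 0.5
strength that defines "belonging" for the planted truth. Temporal
intensities are phase-shifted sinusoids `max(0.1, 1 + sin(2πt/T + 2πp/k))`:
strictly positive (floor 0.1) and distinct per community, the per-time
variation that makes the diagonal intensities identifiable. Connectivity is
the exact low-rank forward model plus symmetric Gaussian noise (upper
triangle drawn and mirrored); diagonals are zeroed, matching the brain-
network convention used throughout. BOLD simulation mixes smooth unit-
variance latent community signals (Gaussian-filtered white noise, σ = 2
samples) through the membership matrix plus independent noise.

What the simulator does *not* emulate: hemodynamic response shapes, fMRI
noise spectra (1/f, physiological), motion artifacts, inter-subject
anatomical variability. Passing tests therefore demonstrate correctness of
the algorithms under the planted model, not performance on real scans.

## Problem sizes and defaults

Default analysis settings follow the reference protocol: β = 0.1, 20
restarts for a final fit, k grid 2–20, 100 stability runs, 10 initial frames
discarded at load (a 304 s scan at TR = 2 s acquires 152 frames; 142
remain). Stability runs use single restarts with a lighter convergence
setting (tol 1e−5, 200 sweeps) — each run only needs a representative
hardened partition, not a polished optimum. The packaged acceptance run
scales the protocol to what a single CPU resolves in minutes: a planted
network with N = 90, T = 60, k = 8, noise SD 0.1, 8 subjects, and 20
stability runs per k ∈ {7, 8, 9}; the test suite exercises the same
guarantees at smaller sizes (N = 12–40). These sizes are the package's
chosen benchmark conditions and are stated here so they can be reproduced.

## Known limitations

- The factorization is non-convex; different seeds can reach different local
  minima. The stability metric exists precisely to quantify this, and
  restarts mitigate it, but global optimality is never guaranteed.
- Clipping negative standardized connectivity discards anti-correlation
  structure by design; the model explains only positive co-fluctuation.
- Zeroed diagonals bias the fit slightly (the model's reconstruction has a
  positive diagonal that the data lacks); on planted data the effect on
  membership recovery is below the 0.01 correlation level measured in the
  tests, but it is systematic.
- The held-out CV error is nearly flat in β on noise-free synthetic data;
  β matters mainly on noisy, dense tensors.
- `compare_groups` permutes units (e.g. subjects or regions) independently;
  it is not an exchangeability-aware test for spatially autocorrelated maps.
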