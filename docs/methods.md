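# Methods

This note documents the models, the numerical choices and the synthetic
data behind `pptsvm`, including what the test suite's passing results do
and do not establish.

## Twin SVM duals and surface recovery

For classes `A` (m1×n, label +1) and `B` (m2×n, label −1), with
`C = [A; B]`, `H = [K(A,Cᵀ) e1]` and `G = [K(B,Cᵀ) e2]`, the two Wolfe
duals are

```
max_α  e2ᵀα − ½ αᵀ G (HᵀH + εI)⁻¹ Gᵀ α,   0 ≤ α ≤ c1
max_β  e1ᵀβ − ½ βᵀ H (GᵀG + εI)⁻¹ Hᵀ β,   0 ≤ β ≤ c2
```

with surfaces `[u1; b1] = −(HᵀH + εI)⁻¹Gᵀα` and
`[u2; b2] = (GᵀG + εI)⁻¹Hᵀβ`. The Tikhonov term `ε` (relative default
1e−7, scaled by the mean diagonal of the normal matrix) is required:
`HᵀH` is (m1+m2+1)×(m1+m2+1) built from an m1-row factor, hence always
rank-deficient without it.

**Box-QP solver.** Each dual is a dense convex box-constrained QP. It is
solved by Cholesky-factoring the quadratic term and handing the equivalent
bounded least-squares problem to BVLS (`scipy.optimize.lsq_linear`),
followed by an active-set KKT refinement: the equality system on the
estimated free set is re-solved exactly until the active partition is
stable. The refinement matters because the surface-recovery operator
multiplies the multipliers by `(FᵀF + εI)⁻¹`, whose norm is of order
`1/ε`: a residual solver tolerance `δ` in a flat dual direction becomes a
surface error of order `sqrt(2δ/ε)`. For the same reason, duals with
*float-level* flat directions — e.g. Gaussian Gram rows saturated to 1 or
0 by extreme widths — have surfaces that are not determined to better than
~1e−3 in float64 by *any* solver; the oracle-equivalence tests therefore
draw random problems with moderate widths (`g ∈ {0.25, 0.5, 1}`) and
offsets, where solver and oracle agree to machine precision.

**Hyperparameters.** `c1, c2` (box bounds) and `g` (kernel width) default
to 0.25 each and are selected in practice by stratified k-fold grid search
(`grid_search_cv`). The default grid is the arithmetic set
{0.25, 1.25, 2.25, 3.25} — the values tuned models of this family actually
land on — with a geometric power-of-two grid available
(`GEOMETRIC_GRID`). CV selects on accuracy; ties break to the smallest
`c1`, then `c2`, then `g`. A single `(c1, c2, g)` is shared across all
pairwise models.

## Ranking continuous output

The signed score is `f(x) = sign · d_min (d_min/d_max)^γ`, where `d_±`
combine the two normalized surface responses `r_k = (K(x,Cᵀ)u_k + b_k)/n_k`
(`n_k = sqrt(u_kᵀ K(C,Cᵀ) u_k)`) with a cross-coupling term:

```
d_+ = sqrt( (r1 + r2)² + 2 u1ᵀK u2/(n1 n2) )
d_− = sqrt( (r1 − r2)² − 2 u1ᵀK u2/(n1 n2) )
```

A negative radicand (possible since the cross term is not
sign-constrained) is clamped to 0; the whole combination lives in one
function (`_coupled_distances`) so it can be revised in isolation. The
sign follows the nearer-surface rule (positive when `s1 < s2`, zero at
ties), which guarantees `sign f(x)` matches the hard label wherever the
clamped magnitude is nonzero. Far from the data both responses flatten and
the clamp can zero the magnitude; downstream code therefore relies only on
the robust properties of `f` — its sign, the bound `|f| ≤ d_min`, and its
ranking of training samples — never its exact value. `γ > 0` (default 1)
controls how strongly near-boundary points are shrunk toward 0.

**Ties.** `s1 = s2` within 1e−12 labels +1, a fixed documented convention.

## Platt calibration

`p(+1|f) = 1/(1 + e^{a f + b})` is fitted by maximum likelihood with
Platt's prior-corrected targets `t₊ = (N₊+1)/(N₊+2)`, `t₋ = 1/(N₋+2)`
(the naive fit diverges on separable scores). The objective per sample
reduces to the overflow-safe `t·z + log(1 + e^{−z})`, minimized by damped
Newton with backtracking halving, so the deviance is non-increasing by
construction; convergence at gradient ∞-norm < 1e−5 or 100 iterations.
The sigmoid is fitted on the binary model's *training* outputs (no
held-out calibration fold) — a deliberate simplification; calibrated
probabilities on training-resubstituted scores are known to be slightly
overconfident, which the coupling step tolerates well.

## Pairwise coupling

`build_Q` maps the pairwise matrix `r` to
`Q_ii = Σ_{s≠i} r_si²`, `Q_ij = −r_ji r_ij` (i≠j). The minus sign on the
off-diagonal is required for `½PᵀQP` to expand to
`½ΣΣ (r_ji p_i − r_ij p_j)²`, and makes `Q` positive semidefinite.
`solve_coupling` runs the exact coordinate-descent sweep: per class `t`,
`Δ = (−(QP)_t + PᵀQP)/Q_tt`, update, renormalize by `1+Δ`, with `QP` and
`PᵀQP` maintained incrementally; defaults `eps = 0.005/M`, `itmax = 100`
sweeps, uniform start `1/M`. The KL (iterative-scaling) solver and voting
are baselines selectable per model. Note the coupled argmax is not a
Condorcet rule: a class that narrowly wins every pairwise contest can
still lose the argmax to a class with a few decisive wins; voting, by
contrast, always returns a unanimous winner. Pair-count weights in the KL
solver default to uniform (intended for near-balanced pairs).

## OVR-CSP front-end

Band-pass: order-5 Butterworth, 7–35 Hz, applied forward–backward
(zero-phase) — phase distortion would bias variance features. Per class
`m`, spatial covariances are per-trial `XXᵀ/trace(XXᵀ)` averaged within
class (`R_m`) and over the rest (`R_rest`); the generalized eigenproblem
`R_m w = λ(R_m + R_rest) w` has `λ ∈ [0, 1]`, and `W_m` keeps the `J`
largest- plus `J` smallest-λ eigenvectors ("optimal 2J directions").
Features are `log(var(Z_p)/Σ_j var(Z_j))` per projection block,
concatenated to `2JM` dimensions (16 for M=4, J=2); the block
normalization makes them scale-invariant per trial. A rank-deficient
composite covariance is regularized by `δI`, `δ = 1e−9·trace/channels`,
with a warning; projected variances are floored at 1e−300 before the log.

## Evaluation

Kappa uses confusion-matrix marginal products for the chance agreement
`pe` (standard Cohen definition); the balanced shortcut
`(M·p0 − 1)/(M − 1)` is a separate function used only when balance is
asserted. The experiment harness draws stratified 65:35 train/test splits,
100 repetitions by default, reporting mean ± sd of accuracy and kappa; all
splits derive from one seed. A split missing a class (only possible for
pathologically small classes) is redrawn up to 100 times.

## Synthetic data

**Blobs**: isotropic Gaussian classes; automatic centers form a regular
simplex when the dimension allows, otherwise sit on a circle whose
neighboring chord equals `separation·σ` (so `separation` is the minimum
center distance in σ units). Defaults M=4, 40/class, σ=1, separation 6.

**EEG**: each trial mixes `channels` latent sources — white noise
band-passed to 7–35 Hz, unit-variance, scaled by a class-specific variance
profile — through a fixed random orthogonal matrix, plus broadband sensor
noise. Defaults mirror a standard four-class motor-imagery recording
shape: 22 channels, 250 Hz, 2 s trials, 40 trials/class; each class boosts
one source's variance to 6 over a unit background, sensor noise sd 0.5.
These defaults were fixed once as a plausible band-power contrast for
clean motor-imagery data.

What the generator does *not* emulate: event-related
desynchronization/synchronization time courses, nonstationarity, ocular or
muscular artifacts, inter-subject variability, or volume-conduction
correlation structure beyond linear mixing. Passing the end-to-end tests
(blob accuracy ≥ 0.95, synthetic-EEG kappa ≥ 0.8) therefore shows the
pipeline is implemented correctly and recovers class structure its model
family can express — it does not predict kappa on real recordings, where
scores are typically far lower.

## Problem sizes

Tests and the acceptance script use deliberately small problems — ≤ 15
points per class for oracle comparisons, 160-sample multiclass fixtures,
20 blob seeds and 10 EEG seeds end-to-end — chosen as the smallest sizes
at which each property is meaningfully exercised.

## Known limitations

- Only the Gaussian kernel family is implemented.
- One-against-rest decomposition is intentionally absent (unbalanced
  binary subproblems); only one-against-one.
- No imbalanced-class TSVM variants and no incremental/online updates.
- Real-recording ingestion (e.g. GDF) is out of scope; the epoch container
  (`.npz` + JSON sidecar) is the supported input, and any adapter must
  expose its epoch time-window as a parameter.
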