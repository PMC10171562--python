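# Methods

This note documents the statistical machinery inside `spherepace`: the
model, the estimation pipeline and its defaults, what the synthetic-data
generator does and does not emulate, and the design decisions that were
genuinely open.

## Geometry and conventions

Compositions (pCSF, pGM, pWM) live on the 2-simplex; the elementwise square
root maps them onto the closed positive segment of the unit sphere S².  All
geometry is exact sphere geometry: geodesic distance `arccos⟨p, q⟩` (inner
products clipped to [−1, 1] before `arccos`, so machine-epsilon overshoot
never yields NaN), closed-form exponential and logarithm maps, and Fréchet
means solved by fixed-point iteration with unit step (tolerance 1e−10, at
most 100 iterations, initialized at the normalized extrinsic weighted
average, which is well-defined for data inside an open hemisphere — always
the case on the positive segment).

**Fisher–Rao convention.**  The Fisher–Rao distance between compositions is
taken as `arccos Σ_d √(c_d c'_d)`, i.e. exactly the sphere geodesic
distance after the square-root map, with **no factor 2**.  Some references
scale the same metric by 2; every scaled quantity reported here (e.g. the
holdout benchmark's scaled errors) is a ratio of Fisher–Rao distances and
therefore invariant to that choice.

**Positive-segment projection.**  Fitted or predicted sphere points can
leave the positive segment.  The geodesically nearest point of the segment
maximizes `⟨p, x⟩` over unit nonnegative `x`, which is the clamped and
renormalized vector `max(p, 0)/‖max(p, 0)‖`; this projection is applied
before squaring any sphere point back into a composition, so emitted
compositions always sum to one.  Tolerances: composition sums 1e−8 (an
opt-in renormalize mode accepts raw volumes), unit norms 1e−10.

## Smoothing

Both smoothers use the Epanechnikov kernel `0.75(1 − u²)₊`.  The 1-D
smoother is local-linear (weighted least-squares line per grid point); the
2-D smoother fits a local plane (intercept + two slopes) with product
kernel weights and is used channel-wise on the nine components of the
matrix-valued covariance surface, sharing one set of weight moments across
channels.  Local-linear fits reproduce affine functions exactly; the test
suite uses this as the defining oracle.

Sparse designs (60% of children contribute a single scan) leave some
windows empty, especially near the age-range boundary, so a deficient
window doubles its local bandwidth up to three times before failing with a
diagnostic.  Bandwidth units are years.

**Defaults.**  The mean bandwidth is chosen by 5-fold cross-validation,
folds split by child (never by scan, to respect within-child correlation),
run on the ambient sphere coordinates with candidates
(0.05, 0.075, 0.11, 0.17, 0.25) × the age range; ties prefer the larger
bandwidth.  The covariance bandwidth defaults to 2.5 × the mean bandwidth:
the pair design is far thinner than the marginal design (only multi-visit
children contribute), and pilot simulations under the default scenario
showed 2–2.5× to balance surface noise against curvature attenuation;
cross-validating the surface itself is unstable at these pair counts.

## Sparse sphere FPCA

Estimation runs on a grid of 51 equally spaced ages over the observed
range:

1. **Mean.**  At each grid age, the kernel-localized Fréchet mean
   `argmin_p Σ_ij K_h(T_ij − t) d²(p, Y_ij)`, solved for all grid ages
   simultaneously by a vectorized fixed-point iteration.
2. **Log data.**  Each observation is log-mapped at the mean evaluated *at
   its exact age* (the same localized objective, not grid interpolation),
   so tangency of `L_ij` is exact by construction.
3. **Covariance.**  Raw within-child cross products `L_ij L_ilᵀ` (j ≠ l
   only — same-time products are inflated by the noise variance and are
   excluded) are smoothed channel-wise into `Γ̂(s, t)`, then symmetrized as
   `(Γ̂(s,t) + Γ̂(t,s)ᵀ)/2`.
4. **Eigendecomposition.**  The operator is discretized to a 153×153
   matrix with rectangle-rule quadrature weights.  Before decomposition it
   is projected blockwise with `P(t) = I − μ(t)μ(t)ᵀ`; every eigenfunction
   with nonzero eigenvalue is then *exactly* tangent to the mean and the
   family is exactly orthonormal — projecting eigenvectors afterwards would
   achieve the same thing only approximately.  Negative eigenvalues
   (possible after smoothing) are truncated to zero.  Sign convention: the
   coordinate with the largest |integral| is made positive, which makes
   serialized fits reproducible.
5. **Noise.**  `σ²` denotes the *total* expected squared tangent norm
   `E‖ε‖²` with isotropy across the 2-D tangent plane (σ²/2 per
   direction); it is first estimated as the average excess of the smoothed
   same-time squared norms over `trace Γ̂(t, t)` on the central half of the
   grid, floored at zero.
6. **Likelihood refinement** (default on).  The pair-based surface only
   sees multi-visit children; under the study's repeat distribution that is
   roughly a third of the cohort, and the resulting eigenvalues carry
   ~35% relative noise while the attainable floor using all children is
   ~10%.  Holding the smoothed eigenbasis fixed as a function dictionary,
   the leading three eigenvalues, σ², and a Givens rotation of the leading
   eigen-subspace are re-fitted by Gaussian marginal likelihood over *all*
   children (single-visit ones included).  Rotations preserve
   orthonormality and tangency exactly; the rotation lets the likelihood
   correct the noisy within-subspace split of variance that otherwise
   biases the second eigenvalue.  Optimization is Nelder–Mead on log
   variances and angles; the refinement is skipped when the model is
   declared noiseless.
7. **Truncation and scores.**  `K` is the smallest number of components
   whose cumulative fraction of variance explained reaches 0.90 (the
   denominator is the sum of all positive eigenvalues).  Scores are BLUPs,
   `ξ̂_i = Λ Φ_iᵀ (Φ_i Λ Φ_iᵀ + (σ²/2) I)⁻¹ vec(L_i)`: because every
   vector involved is tangent, the ambient `(σ²/2) I` acts exactly as
   σ²/2 times the identity on each 2-D tangent plane.  If σ̂² ≈ 0 a ridge
   of 1e−10 keeps the system invertible (with a warning).

Eigenfunctions are interpolated to off-grid ages coordinate-wise and
locally re-projected onto the tangent plane of the interpolated mean; the
global L² norm is *not* recomputed, keeping scores continuous in the
observation times.  Prediction at a new age interpolates the truncated
tangent sum between neighboring grid ages before the exponential map,
projects to the positive segment, and squares; ages outside the grid are
refused (no extrapolation).  A fitted model is self-contained, so
prediction evaluates the mean at history ages by grid interpolation — the
only place where interpolation substitutes for the exact-time Fréchet
objective used during fitting.

Serialization stores a JSON header (options, K, σ², bandwidths, subject
ids) plus dense numeric blocks in an `.npz` archive; round trips are
bit-exact, and refits with identical inputs and options serialize to
identical bytes.

## Synthetic cohorts

The generator reproduces the study design: two groups of 227 and 116
children; per-child visit counts drawn from the empirical repeat
distribution (207, 82, 30, 13, 10, 1 children with 1..6 visits — mean 1.66
scans per child); visit ages i.i.d. uniform on 1.5–8.0 years; a smooth mean
composition anchored at five ages with pWM rising steeply before ~4.5 years
and plateauing afterwards while pGM declines (monotone PCHIP interpolation,
mapped through the square-root transform); rank-2 Karhunen–Loève variation
with λ = (0.012, 0.004), whose modes mimic what FPCA of growth curves
typically finds — a constant "size shift" and a centered-linear "early–late
tilt" with a constant transverse component so the eigenfunctions are
genuinely trivariate; isotropic intrinsic noise with `E‖ε‖² = σ² = 0.02²`.
Scores and noise are Gaussian.  Parameters implying 5σ tangent excursions
beyond π/2 are rejected (geodesic wraparound).

The optional group contrast is a pure mean shift: the second group's pWM is
reduced by a ramp growing linearly from 0 at age 1.5 to 0.03 (absolute
proportion) at age 4.5 and constant afterwards, with the mass moved to pGM;
the eigenstructure is shared, so a two-sample test on scores targets
exactly this shift.  The 0.03 magnitude is this package's choice of a
realistic effect.

What the generator does **not** emulate: informative visit schedules or
dropout, non-Gaussian scores, measurement-batch effects, compositions near
the simplex boundary, and age-varying noise.  Passing recovery tests
therefore demonstrate correctness of the estimation machinery under the
stated design, not robustness to those real-data features.

## Inference toolkit

**Energy test.**  `ED(F,G) = 2E‖V−W‖ − E‖V−V′‖ − E‖W−W′‖`, V-statistic
convention (within-sample means over all ordered pairs including
self-pairs), so the empirical statistic is zero exactly on identical
multisets and no group-size prefactor is needed — permutation calibration
absorbs scaling.  Group labels are permuted preserving group sizes;
`p = (1 + #{perm ≥ obs})/(1 + B)` (add-one, so p is never zero and the test
is slightly conservative).  An exhaustive mode enumerates all label
assignments for exact small-sample inference.  The group comparison uses
the top-2 score vectors from a **single pooled fit** — per-group fits would
score against different bases and make the comparison meaningless.  Scores
are not standardized before the test.

**LMM baseline.**  Per tissue, `y_ij = a₀ + a₁ t_ij + b_i + e_ij` by ML:
the variance ratio is profiled out with a bounded 1-D search on the log
scale (plus the boundary r = 0), with GLS fixed effects and closed-form
residual variance at each ratio via Woodbury identities.  Random slopes are
excluded — unidentifiable with mostly 1–2 visits per child.  Prediction
uses the shrinkage BLUP `b̂_i = [σ_b² m/(σ_b² m + σ_e²)] · mean residual`.
When only proportions are available the three models are fitted on
proportions and the three predictions are floored at 1e−6 and renormalized
to a composition; with raw volumes, fit volumes and normalize predictions
the same way.

**Holdout benchmark.**  For each child with ≥ 3 scans (ties in "latest"
broken by input order), the last scan is dropped, both models are refitted
on everything else, and the dropped composition is predicted from the
child's remaining history.  Errors are Fisher–Rao distances, averaged per
method, and scaled by the maximum pairwise Fisher–Rao distance among all
observed compositions.  Bandwidths are resolved once on the full sample and
reused across refits (re-running CV per held-out child would be O(n) extra
fits for no material change).

**Bootstrap regions.**  Children are resampled with replacement 400 times;
each replicate re-estimates the *mean only* (the regions concern the mean;
re-running the eigenanalysis 400 times would change nothing for them) and
records the mean composition at each requested age (defaults 2.8, 4.1, 5.4,
6.7 years).  Per age, the bootstrap points are mapped to ternary
coordinates, a bivariate Gaussian KDE with Scott's rule is fitted, and the
region is the highest-density set whose threshold is the largest density
containing at least 95% of the bootstrap points; contours are extracted on
a 200×200 grid.  The mean bandwidth for this procedure defaults to **half**
the cross-validated bandwidth: deliberate undersmoothing, because smoothing
bias recenters the bootstrap cloud away from the truth and inference is
more bias-sensitive than point estimation.  Replicate failures are skipped
with a warning; more than 10% failures aborts.  Degenerate (zero-spread)
bootstrap clouds collapse to a point region.  Calibration caveat: this
percentile-type region is first-order accurate; simulations at n = 150
place its true coverage at roughly 0.87–0.93 rather than 0.95.

## Problem sizes used in the shipped studies

The test suite and `scripts/acceptance.py` run entirely on generated data:
parameter recovery on one 300-child single-group cohort; test calibration
on 500 null replications (n = 100 per group, 199 permutations each) and
power on 200 replications (n = 150 per group, fitted without the likelihood
refinement, which does not affect score separation); the benchmark on the
full 343-child design (~58 eligible children, each triggering a full
refit); and region coverage on 50 replications at n = 150 with 400
bootstrap replicates each.  These sizes are the package's reference study
conditions.

## Known limitations

- Eigenvalue estimates at the study's sparsity retain ~10–20% relative
  Monte-Carlo error even after refinement; that is the information floor of
  the design (≈1.66 scans per child), not an implementation artifact.
- The refinement assumes Gaussian scores and isotropic noise; it is a
  variance-reduction device, not a robustness device.
- Confidence regions under-cover mildly (see above).
- No dense-design fast path, no derivative estimation, no manifolds beyond
  S², no asymptotic bands for the mean; Aitchison log-ratio geometry is out
  of scope.
- Months-vs-years is handled by an explicit unit flag on input; internally
  everything is years and units are never guessed from magnitudes.
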