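# Methods

## Signal model

A voxel is a distribution P(**D**) of microscopic Gaussian diffusion
tensors.  The exact signal under a b-tensor **B** is the mixture average
S = S₀⟨exp(−**B**:**D**)⟩; the package fits its two-term cumulant
expansion

log S = log S₀ − **B**:⟨**D**⟩ + ½ **B**⊗²:ℂ,

linear in the 28-vector θ = [log S₀, d, c].  Second-order tensors are
stored as Voigt 6-vectors (xx, yy, zz, yz, xz, xy) with √2 on the cross
terms; fourth-order tensors as 21-vectors (the symmetric vectorization of
the 6×6 Voigt matrix: 6 diagonal entries, then the 15 √2-scaled
off-diagonal entries).  The normalization is pinned by one requirement —
vector inner products equal full tensor contractions — which makes every
formula basis-independent and lets brute-force index contraction serve as
an oracle in the tests.  The covariance c corresponds to a PSD 6×6 Voigt
matrix whenever it comes from an actual mixture.

Axisymmetric b-tensors are parametrized by (g, b, b<sub>Δ</sub>):
eigenvalues b∥ = b(1+2b<sub>Δ</sub>)/3 along g and b⊥ = b(1−b<sub>Δ</sub>)/3 twice, so
b<sub>Δ</sub> = 1 is linear, 0 spherical, −0.5 planar encoding and tr **B** = b.

**Cumulant accuracy.** The truncation error of the cumulant model relative
to the exact mixture signal grows as b³.  On the synthetic brain-like
population it is below ~4–5% of S₀ for b ≤ 1 ms/μm², but at b = 2 it
reaches ~10% (median) and up to ~40% for strongly orientation-dispersed,
highly anisotropic voxels — a known limitation of the second-order model,
not of the fitting.  The Monte-Carlo studies generate their noise-free
signals *from the cumulant model itself* (mirroring the original
simulation design), so estimator comparisons are not confounded by this
model error.

## Scalar metrics

With E_bulk/E_shear the isotropic fourth-order basis tensors (bulk
extracts squared mean diffusivity; shear extracts eigenvalue variance),
V_bulk = ⟨d⊗d, E_bulk⟩ = MD², V_shear = ⟨d⊗d, E_shear⟩, and second
moments ⟨**D**⊗²⟩ = d⊗d + c:

* FA  = √(3/2) √(V_shear / (V_bulk + V_shear))
* μFA = same contraction ratios applied to ⟨**D**⊗²⟩
* MK<sub>i</sub> = 3 ⟨c, E_bulk⟩ / MD²  (variance of isotropic diffusivities)
* MK<sub>a</sub> = (6/5) ⟨c, E_shear⟩ / MD²  (shear variance of the covariance)
* MK = MK<sub>i</sub> + MK<sub>a</sub>,  OP = √(V_shear / V_shear,₂),  C_c = FA²/μFA²

These closed forms are pinned by limit tests: a coherent prolate tensor
gives FA = μFA, OP = 1, MK<sub>i</sub> = MK<sub>a</sub> = 0; an equal mixture of isotropic
diffusivities 1 and 3 μm²/ms gives MD = 2, MK<sub>i</sub> = 0.75, μFA = 0.  With
this MK<sub>a</sub> convention (the covariance shear, not the second-moment shear)
a coherent single-tensor voxel has zero anisotropic kurtosis — dispersion
or shape heterogeneity is what generates it.

**μFA vs FA.** Orientation dispersion alone can only lower FA, so
μFA ≥ FA for mixtures of identically shaped micro-tensors.  This is *not*
an unconditional inequality under the formula above: isotropic-diffusivity
heterogeneity inflates the μFA denominator without touching FA, and a
coherent stick (2.2, 0.2, 0.2 μm²/ms) mixed with a 3 μm²/ms free-water
pool at fractions 0.05–0.2 pushes μFA below FA by up to ≈ 0.05.  The test
suite asserts the inequality only where it holds and documents this
mechanism.

MD ≤ 0 (possible for unconstrained fits of noisy data) yields NaN metrics
with a warning rather than an exception, so Monte-Carlo loops can count
failures instead of crashing.

## Estimators

All linear estimators act on log s with rows of nonpositive signal dropped
(a warning counts them).  WLLS uses inverse-variance weights: since
var(log s) = σ²/s̃², the weight matrix in the weighted objective is
diag(s)² built from the *observed* signal — the statistically motivated
reading of the printed "reciprocal-squared" weight matrix, which
reproduces the documented WLLS behaviour (overestimated MK<sub>i</sub>, positively
biased OP at SNR 25).  IWLLS starts at WLLS and rebuilds the weights from
the model prediction exp(**A**θ̂); the default of two iterations means
exactly one prediction-based reweighting.  NLS is a damped Gauss–Newton
(Levenberg–Marquardt) on the raw signal with analytic Jacobian
diag(exp(**A**θ))**A**, gradient tolerance 1e-8, step tolerance 1e-10, at
most 200 iterations, initialized with LLS.  A vectorized LM that iterates
all noise realizations simultaneously (per-realization damping, frozen on
convergence) backs the Monte-Carlo harness; its agreement with the scalar
path is asserted in the tests.

**Constraints.** PSD conditions "for any b-tensor" are discretized over a
finite antipodally symmetric direction set U (default 60 electrostatic
directions), the standard linearization that keeps each subproblem a
convex QP: variant 1 stacks D:uuᵀ ≥ 0 and ℂ:(uuᵀ)⊗² ≥ 0; variant 2 stacks
D-positivity and monotonic signal decay at b_max
(ℂ:u⊗⁴ ≤ b_max D:u⊗²); variant 3 adds the two kurtosis-numerator rows
⟨E_bulk, c⟩ ≥ 0 and ⟨E_shear, c⟩ ≥ 0 (denominator MD² > 0 for physical
fits, so constraining numerators suffices).  Monotonic decay is enforced
at b_max only — the b-derivative condition at the largest b implies it for
the quadratic exponent on [0, b_max].

Each constrained weighted solve min ‖W^½(log s − Aθ)‖² s.t. Gθ ≤ 0 is
solved exactly through its dual: with the normal matrix factored
P = LLᵀ, the dual is a nonnegative least-squares problem (Lawson–Hanson,
`scipy.optimize.nnls`), followed by an equality-constrained KKT polish on
the detected active set.  Strong duality holds (convex QP, linear
constraints), so the solution matches interior-point or SLSQP references
to solver precision; the tests certify it with a weak-duality gap bound.
If the unconstrained iterate is already feasible it is returned unchanged.

## CRLB and experimental design

For i.i.d. Gaussian noise of SD σ the Fisher information is
I = σ⁻² **A**ᵀ diag(s(θ))² **A**; the delta method propagates the bound to
metrics via J = MᵀI⁻¹M with M the 28×K matrix of central-finite-difference
metric gradients (relative step 1e-5, absolute floor 1e-8 — the metric
formulas are smooth rational/root functions, so this is accurate to well
below the CRLB comparison tolerances).

Criteria: f₂ = −log det I (a monotone transform of det CRLB chosen to
avoid underflow of 28-dimensional determinants; reported values are
comparable only under this transform) and f₃ = Σ w_j J_jj over the metric
set {MD, μFA, MK<sub>i</sub>, MK<sub>a</sub>} with default weights 1/m_j² (equal relative
precision).  The population objective averages the criterion over M prior
voxels, each pre-rotated by a seeded uniform random rotation so the
optimized scheme is not tailored to one fiber orientation.  The design
noise level defaults to σ = S₀/15 (SNR 15).

**Optimizer.** Directions are fixed to an electrostatic direction set
(antipodal Coulomb energy minimized by L-BFGS from seeded random starts,
best of 3); the 2N vector (b, b<sub>Δ</sub>) is refined by opportunistic coordinate
polling with step halving from 0.4 (box units) down to 1e-3 inside
0.1 < b < 2, −0.5 ≤ b<sub>Δ</sub> ≤ 1.  Descent is monotone, so the optimized
objective can never exceed the initialization; identical seeds give
bit-identical schemes.  Any monotone derivative-free method satisfies the
design contract — the acceptance surface is objective improvement, not a
particular search trajectory.

**Clustering.** Optimized b<sub>Δ</sub> values within 0.15 of a quintessential
shape (−0.5, 0, 1) snap to it (others are kept and reported); b-values
are clustered by deterministic 1-D k-means (farthest-point
initialization) with the smallest k ≤ 4 that reproduces the values
exactly, else the minimal-variance k = 4 solution; per-(b, b<sub>Δ</sub>) groups of
two or more samples get fresh electrostatic directions (singletons keep
their optimized direction — a one-point "shell" has no uniformity to
restore).

Clustering is near-lossless *when the raw optimum consolidates into a few
well-populated shells* — the typical outcome, where the objective changes
by ~1–3%.  It is not guaranteed to be: for some prior populations the
converged f<sub>3</sub> optimum legitimately spreads intermediate b-tensor shapes
across the top shell, and because the optimizer allocates (b, b<sub>Δ</sub>) to
*specific* fixed directions, forcing that spread onto a shell structure
(and regenerating per-shell directions) can cost tens of percent.  The
shelled scheme is what a scanner can execute; the reported objective
change quantifies what that practicality costs.

Precision gain between schemes is the ratio of reciprocal CRLB variances
(1/CRLB, variance-based as printed; an SD-based reading would be its
square root), independent of σ.

## Synthetic tissue generator

The generator replaces in-vivo priors with parametric classes, so
population-level numbers are not expected to match any particular
dataset — orderings and signs are the reproducible surface:

| class | axial D | radial D | Watson κ | iso fraction | iso D (gamma) |
|---|---|---|---|---|---|
| WM-like | 2.0–2.6 | 0.1–0.5 | 3–30 | 0–0.1 | shape 3, scale 0.8 |
| GM-like | 1.2–2.0 | 0.3–0.7 | 0.3–3 | 0.1–0.3 | shape 4, scale 0.25 |
| CSF-like | 2.8–3.1 (isotropic) | — | — | — | — |

Each voxel draws one (axial, radial) pair, disperses 50 axisymmetric
micro-tensors about a uniformly random mean axis by Watson rejection
sampling, and adds a 10-component isotropic pool (units μm²/ms; ranges
chosen to land the scalar metrics in published in-vivo windows: WM-like
median μFA ≈ 0.8, OP ≈ 0.9; GM-like μFA ≈ 0.55, FA ≈ 0.14; MD within
[0.5, 3.2] enforced by redraw).  The default population is an even
WM/GM mix.  What the generator does *not* emulate: intra-compartmental
(microscopic) kurtosis, exchange, time-dependent diffusion, spatially
correlated noise, partial-volume geometry.  Passing tests therefore
demonstrate correct estimator/design mechanics under the multi-Gaussian
DTD model, not fidelity to any specific in-vivo distribution.

Rician noise: s′ = √((s+ε₁)² + ε₂²) with ε ~ N(0, σ²); SNR is S₀/σ at
b = 0.  The generator's first two moments are validated against the
noncentral-χ closed forms.

## Monte-Carlo harness and problem sizes

For each voxel the noise-free cumulant signal is corrupted
`n_realizations` times, refit, and summarized by per-voxel bias (mean
estimate − truth), SD (ddof = 0, so RMSE² = bias² + SD² exactly), and
RMSE, with population medians/quartiles on top.  Runs are bit-for-bit
reproducible given seeds; realizations with non-finite metrics count as
failures and abort the run above a 5% rate.

Problem sizes: the acceptance tests use 200 voxels × 400 realizations at
SNR 25 (estimator study), 100 realizations at SNR 200 (consistency),
1500 Gaussian realizations at SNR 50 (CRLB efficiency), and 120-sample
design runs over 50 rotated priors capped at 30 000 objective
evaluations.  `scripts/acceptance.py` uses 120 voxels × 250 realizations
and 15 000 evaluations — sizes at which every reported ordering is stable
across seeds while the full run stays within a few minutes on one CPU.

## Known limitations

* The PSD constraints are enforced on a finite direction set; small
  residual violations between directions are possible (an eigenvalue
  check on the 3×3 and 6×6 Voigt matrices can quantify them post hoc).
  The exact semidefinite formulation is out of scope.
* The estimator of record for Rician data is still least-squares
  (Gaussian); no noncentral-χ maximum likelihood is provided.
* The WLLS-vs-IWLLS bias ordering for OP and the RMSE ranking depend on
  the tissue composition: within GM-like voxels the observed-weight
  estimator is clearly the worst performer, within coherent WM-like
  voxels differences are small, and population medians can land near the
  crossover (see the ordering tests for the quantitative statement under
  the default mix).
* Direction sets are optimized for uniformity only; no hardware (TE/TR,
  slew) constraints.
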