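# Methods

## Model and assumptions

The vessel wall is a two-dimensional isotropic elastic sheet closed into a
cylinder of relaxed radius *R* and length *L* (*R* ≪ *L*).  Its elastic
state is described by in-plane Lamé coefficients λ, μ (units force/length),
equivalently a 2D Young modulus `E₂D = 4μ(λ+μ)/(λ+2μ)` and Poisson ratio
`ν₂D = λ/(λ+2μ)`, plus a bending rigidity κ (units energy).  Loading is a
homogeneous pressure difference ΔP (positive = dilating), a homogeneous
axial stress σ_zz (negative = compression) and an optional radial
elastic-foundation coefficient *C* (force/length³) standing in for the
surrounding tissue matrix; tangential pinning is neglected, consistent with
the observed migration of endothelial cells along the vessel surface.

Key assumptions:

* **Small loads.** |ΔP·R| and |σ_zz| ≪ λ, μ.  The homogeneous pre-strain is
  linear in the loads; perturbations are treated to quadratic order.  This
  is enforced softly (a warning, not an error) because developmental
  trajectories may brush the boundary of the regime.
* **Quasi-equilibrium.** Development is modeled as a path through
  equilibrium states in the normalized load space; no dynamics.
* **Homogeneity.** Material constants do not depend on the azimuthal or
  axial coordinate.  Observed dorsoventral asymmetries are handled only by
  restricting which instabilities are considered relevant (the pinned
  environment suppresses Euler bending), not by inhomogeneous coefficients.
* **Near-incompressibility.** For the normalized phase diagram the membrane
  is taken incompressible (ν₂D → 1).  Dimensional code paths require
  ν₂D ≤ 0.999 because λ diverges in the exact limit; the incompressible
  case is served by the normalized closed forms.

## Mode analysis conventions

Perturbations are Fourier modes `u'_j = 2 Re(A_j e^{i(k z + n φ)})`; stored
modes carry n ≥ 0 and k ≥ 0, each representing its conjugate partner so the
field is real.  The per-mode energy is
`2πRL · Σ_ij M_ij A_i conj(A_j)` — note the index pairing `A_i conj(A_j)`
(= Aᵀ M conj(A)); with Hermitian **M** the energy is real either way, but
off-diagonal phases follow this convention and the quadrature oracle
verifies it entry by entry.  The self-conjugate homogeneous mode
(n = 0, k = 0) requires real amplitudes and counts twice.

Stability of a mode is `det M > 0`.  Excluded from verdicts are rigid-body
contents: the zero rows of the (0, 0) matrix and the |n| = 1, k = 0
Goldstone pair, whose determinant vanishes identically for the free tube at
any load and is lifted by any C > 0.

The energy oracle integrates the explicit quadratic density — linearized
membrane strain energy, the load integrands, the curvature-variation
bending term and the pinning term — on a periodic (φ, z) grid, with
spectral derivatives in φ and 4th-order periodic finite differences in z.
One term deserves a note: the load integrands as written miss the quadratic
cross term of the enclosed volume with the axial stretch,
`−(ΔP/2)·u_r·∂z u_z`, which arises because the volume element carries a
factor (1 + ∂z u_z).  The oracle includes it by default
(`include_volume_stretch_coupling=True`); switching it off shifts exactly
the radial–axial coupling entry by ΔP·R/2 and nothing else, so the
difference between the two integrand conventions is exposed rather than
absorbed.  With the term on, oracle and matrix agree to quadrature accuracy
(≲ 10⁻⁶ relative on a 96×512 grid) for all loads.

## Critical loads: analytic and numeric routes

* **Corrugation (n = 0).**  The axisymmetric block
  `M11 M33 − |M13|² = 0` is solved for σ_zz per k by bracketed Brent
  iteration on the bracket [−0.5 E₂D, 0] (refined to 10⁻¹² in normalized
  σ), then maximized over k via a coarse log grid (160 points spanning
  0.02–50 × the expected selection kR ≈ γ^(−1/2)) plus bounded
  minimization.  The closed form is
  `σ = −(ΔPR/2)(1 + 2(2ν₂D−1)√(κ/(E'R²))) − 2√(κE')/R` with
  `E' = E₂D + CR²`; pinning enters only through this effective modulus.
  At ΔP = 0 the exact block reduces to `σ(k) = −E'/(R²k²) − κk²`, so the
  numeric and analytic routes coincide to root-finder tolerance there, and
  differ by O(p, γ) terms under pressure — the convergence the tests assert
  on a γ ladder.
* **Corrugation-line intercept.**  The normalized boundary is
  `σ = −[p(1+2γ)/2 + 2γ]`.  The intercept −2γ is the normalized form of
  the classical axially-loaded-shell threshold 2√(κE₂D)/R (equivalently
  2√(DEh)/R in 3D shell constants) and is what the determinant root
  produces; quotations of this line with intercept −γ understate the
  threshold by exactly a factor 2 and are not reproduced by the matrix.
* **Euler (n = 1).**  det M(n = 1) is an even polynomial
  `a₁k² + a₂k⁴ + a₃k⁶ + a₄k⁸` with no free term (translation Goldstone).
  The coefficients are generated symbolically (sympy, cached per process)
  from the matrix and validated against the closed form
  `σ = −2μ((λ+μ)R² + κ)/((λ+2μ)R² + κ)·(kR)²`; the numeric route solves
  the long-wave truncation `a₁ + a₂k² = 0`, whose error vs. the closed form
  scales as (kR)² (≈ 2% at R/L = 1/50, ≈ 0.02% at 1/500).  In normalized
  variables the threshold is −(1/2)(2πR/L)² for any ν₂D once κ is small.
* **Transversal (k = 0, |n| ≥ 2).**  The block `M11 M22 − |M12|²` is linear
  in ΔP at k = 0, so its root is computed exactly from two evaluations and
  maximized over n ∈ [2, n_max] (ties resolve to the smallest |n|).  The
  closed form is `ΔP = −CR/(n²−1) − (n²−1)κ/R³`: weak pinning (CR⁴ ≤ κ)
  keeps |n| = 2 and the free-tube value −3κ/R³; strong pinning moves the
  critical mode to higher |n|.
* **Plate (single cell).**  A cell is modeled as a flat square plate of
  side a = R.  The 1D pinned-strip eigenproblem κu'''' = −σu'' with
  deflection and curvature zero at both ends is discretized with central
  differences (D4 = D2·D2 under these boundary conditions; generalized
  symmetric eigenproblem), giving the boundary coefficient l_c = ka/π = 1
  with O((a/N)²) error — 5·10⁻⁶ at the default N = 400.  The closed form
  σ = −κ(l_c π/R)² is also the R → ∞ limit of the radial diagonal entry.

## Stability scans and classification

`scan_stability` sweeps n ∈ [0, n_max] (default 10) over a log-spaced k
grid of 400 points reaching kR = max(10, 3/γ) — comfortably beyond the
corrugation selection kR ≈ γ^(−1/2) — plus the k = 0 column for
transversal modes.  `classify_state` uses the three normalized boundary
lines; when several are violated the label goes to the largest normalized
margin (threshold − value)/|threshold|, a convention chosen because the
diagram itself defines no precedence.  In a pinned environment the Euler
boundary is excluded from labeling (the surroundings suppress that mode)
but still reported.

## Synthetic data

The generator emulates what the imaging pipeline measures, not the images
themselves.  Defaults follow the study system: radius 12–16 µm (dilation
from ~24 to ~32 µm diameter), length 50 R, a single axisymmetric corrugation
mode of amplitude 2% R at the predicted wave vector, and additive Gaussian
radius noise of 1% R standing in for segmentation error.  Azimuthal
averaging attenuates that noise by 1/√Nφ; the wave-vector estimator takes
the dominant nonzero bin of the mean-profile periodogram, quantized to
2πj/L, and flags profiles whose peak does not exceed 3× the median spectral
amplitude.  With ~15 nonzero bins the false-positive rate of that flag on
pure noise is a few percent, which the Monte-Carlo test budgets for.

What this does **not** emulate: azimuthally inhomogeneous corrugation
(the real pattern is strongest dorsally), discrete cell tessellation of the
wall, imaging point-spread or segmentation bias, and any feedback of the
deformation on the loads.  Passing the closed-loop test therefore shows the
estimator recovers a known injected wave vector under realistic noise — not
that the pipeline would be unbiased on real microscopy data.

Developmental trajectories (`scenario_trajectories`) are an explicit
parametric stand-in, not a fit: p(t) = f·0.06·sin(πt),
σ(t) = −0.08·sin²(πt) over 25–65 hpf, with flow factor f = 1 (wild-type),
0.5 (reduced flow) or 0.02 (no flow, silent-heart-like).  Amplitudes were
chosen once so the wild-type loop enters and exits the corrugated region of
a γ = 1/50 tube, mirroring the observed stage sequence; mutants scale p
down, making trajectories steeper so they cross the corrugation boundary
earlier.  Stage labels I–IV attach at the first boundary crossing, the
p-maximum and the re-crossing, with crossings interpolated linearly in
time; trajectories that never cross, or cross more than twice, are flagged
rather than guessed at.

## Numerical choices and degenerate inputs

* Determinants are compared against a tolerance scaled by the cube of the
  largest matrix entry, so Goldstone zeros are not misread as instability.
* ν₂D = 1 is rejected in dimensional code (λ diverges); ν₂D ≤ 0.999.
* κ = 0 is allowed in the matrix but rejected where a threshold requires
  bending (corrugation wave vector and stress); the transversal threshold
  degrades gracefully to 0.
* The corrugation wave-vector formula raises when the radicand is
  non-positive (pressure too large for a varicose branch).
* Random seeds are explicit arguments everywhere; nothing draws from global
  state.

## Problem sizes

Default test and script sizes — 400-point k grids, 160-point coarse scans,
N = 400 strip discretization, 96×512 oracle grids, 50-seed recovery loops —
keep every check well under a minute on one CPU while leaving an order of
magnitude between numerical error and the asserted tolerances.

## Known limitations

* The quadratic form is linear-stability only: no post-buckling amplitudes,
  no mode interaction, no nonlinear strain beyond the terms listed above.
* The surrounding tissue is a scalar radial spring; anisotropic confinement
  (notochord above, muscle at the sides) is represented only through the
  free/pinned classification switch.
* Combined n ≥ 2, k > 0 critical modes are covered by the scan but have no
  dedicated closed forms.
* Estimating (p, σ) from real image data is out of scope; trajectories in
  this package are synthetic constructions.
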