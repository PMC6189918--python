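# Methods

## Model

The channel cross-section is the rectangle y ∈ [0, L], z ∈ [−h/2, h/2]
(dual-array frame).  Each wall carries an array of N strip electrodes of
width λ = L/(2N−1), separated by gaps of the same width, indexed left to
right; electrode n occupies y ∈ [2nλ, (2n+1)λ].  At DEP drive frequencies
the field is quasi-static, so the potential obeys Laplace's equation with
time entering only through the voltage amplitudes, and the potential is
linear in the voltage vector U.

For a single array (frame ζ ∈ [0, h], electrodes at ζ = 0, grounded plane
at ζ = h) the boundary potential is approximated by the prescribed
voltages on the strips, **linear interpolation across the gaps**, and
**even mirror reflection at the lateral walls** (the dielectric reflection
coefficient of the water/SU-8 interface, (εm − εw)/(εm + εw) = 74/82 ≈ 0.9,
is close enough to a perfect mirror).  The even 2L-periodic extension has
a cosine Fourier series; separation of variables gives one vertical
profile per harmonic,

    Z₀(ζ) = (h − ζ)/h,      Zₚ(ζ) = sinh(ωₚ(h − ζ)) / sinh(ωₚ h),

with ωₚ = pπ/L, so each term satisfies Laplace's equation exactly and the
truncation error lives entirely in the boundary reconstruction.  The
Fourier coefficients a_{p,n} of each electrode's unit "tent" profile are
closed-form (implemented in `fourier_coefficient`; verified in the tests
against direct quadrature of the boundary profile).  Key identities used
throughout: rows of A are even in p, row p = 0 sums to 1 and all other
rows sum to 0 — hence a uniform voltage yields the exact linear ramp and
zero DEP force.

Two facing arrays superpose by evaluating the single-array basis at
ζ⁺ = h/2 − z (top) and ζ⁻ = h/2 + z (bottom); each array's solution is
grounded on the opposite wall, so the superposition satisfies both
electrode boundary conditions.

All spatial derivatives up to second order are analytic, term by term
(∂²/∂y² = −ωₚ² and ∂²/∂z² = +ωₚ² per harmonic), feeding

    ∇(∇φ)² = 2 (φ_yy φ_y + φ_yz φ_z,  φ_yz φ_y + φ_zz φ_z),
    F_DEP = 2π ε0 εm r³ Re(β) ∇(∇φ)².

The Clausius–Mossotti factor uses relative complex permittivities with
the loss term σ/(ε0υ) (dividing the absolute ε* = ε0εr − iσ/υ through by
ε0), preserving the Maxwell–Wagner crossover.  Validation runs pin
Re(β) = −0.5 directly via `DriveCondition(cm_real_override=-0.5)`.

## Parameters

| parameter | default | meaning |
|---|---|---|
| L, h | 150 µm, 80 µm | channel width and height of the validation chip |
| N⁺, N⁻ | 8, 8 | electrodes per wall (N ≥ 2; λ = L/(2N−1)) |
| P | 2·max(N⁺, N⁻) | positive harmonics kept (2P+1 rows); orientation accuracy plateaus beyond 2N |
| r | 4 µm | particle radius (dipole approximation needs r ≪ h) |
| εm, εw | 78, 4 | medium and wall relative permittivities |
| Re(β) | −0.5 | Clausius–Mossotti real part (strong negative DEP) |
| FD spacing | 0.5 µm | reference-solver grid step (must divide L and h exactly) |
| ROI | y ∈ [L/4, 3L/4], z ∈ [−h/4, h/4] | central region where model accuracy is quantified |

## Reference solver

The validation oracle solves the *exact* boundary-value problem the
analytical model approximates: Dirichlet voltages on the electrode nodes,
zero normal flux (mirror ghost nodes, second order) on the gaps and the
lateral walls, five-point Laplacian, sparse LU factorisation reused
across voltage patterns.  Electrode edges snap to the nearest grid node
(exact for the 10 µm features of the default chip at 0.5 µm spacing; at
most half a cell otherwise).  Derivatives are central differences on the
grid, bilinearly interpolated; sample points must stay two cells clear of
the boundaries.  A `gap_bc="linear"` mode imposes the analytical model's
own approximated boundary instead, which is how the solver and the series
cross-check each other in the tests (they agree to truncation +
discretisation error; a uniform voltage is then reproduced to machine
precision).

Note the uniform-voltage linear ramp is *not* the exact solution of the
Neumann-gap problem (the ramp has non-zero flux through the gaps); it is
exact only under the linear-gap boundary.  The Neumann mode is instead
verified by the discrete maximum principle and Richardson convergence.

## Validation studies and study sizes

* **Boundary convergence** — relative RMS error between the truncated
  series at the electrode plane and the piecewise-linear boundary
  profile, 2001 y-points; non-increasing in P (L² projection), zero for
  constant patterns at any P.
* **Force error maps** — analytical (P = 2N) vs reference forces on an
  ROI grid snapped to FD nodes (2 µm step, ≈ 760 points); per-point
  relative magnitude error (%), absolute component errors (N), and
  orientation error via arctan2 wrapped to (−180°, 180°].  Points with
  reference force below 10⁻²⁰ N are excluded from relative and
  orientation statistics (the relative error diverges and the angle is
  undefined where the force vanishes) but kept in absolute statistics.
  Pooled over 10 random voltage patterns the median magnitude error is
  ≈ 15 % and the median orientation error ≈ 1°, inside the 20 % / 5°
  qualification bounds.
* **Orientation benchmark table** — mean over 50 random voltage draws of
  the RMS orientation difference over the ROI, for N ∈ {5, 9, 15} and
  P ∈ {N, 2N, 4N}.  This statistic intentionally uses the arctangent of
  the component ratio F_z/F_y (range ±90°): near-vertical forces then
  register ~180° discrepancies whenever the models disagree on the sign
  of a tiny F_y, so the RMS is dominated by isolated outliers along the
  F_y ≈ 0 bands and reads an order of magnitude above the typical
  pointwise error — this is the convention of the published benchmarks
  this study mirrors.  A quadrant-aware `statistic="atan2"` variant is
  available and reads ~4× lower.  50 draws per electrode count (the
  package's default study size; the full published benchmark used 800)
  give the mean to about ±1°.
* **Height power law** — mean ‖F‖ over 201 points on y ∈ [L/3, 2L/3],
  z = 0 for nine heights spanning 50–500 µm with L = h; the log–log slope
  is −3 (exactly, by dimensional analysis: potential values are
  scale-invariant, each derivative contributes one inverse length).

## Random inputs

Voltage patterns are drawn independently and uniformly on [−1, +1] V per
electrode from a seeded generator.  Orientation and relative-magnitude
statistics are invariant to the overall voltage scale (force direction is
unchanged under U → cU), so only the distribution shape matters; uniform
is the least-informative choice.  These synthetic drives exercise the
model across the whole input space but are idealized: real drives are
band-limited AC amplitudes subject to amplifier limits, electrode
double-layer effects are neglected, and near-wall corrections to the
dipole force law are out of scope — passing validation here demonstrates
fidelity to the stated electrostatic model, not to a physical device.

## Numerical choices

* Cosine (real) basis instead of complex exponentials, valid because the
  coefficient rows are even in p; a literal complex-sum path is kept for
  cross-checking in tests.
* Vertical profiles evaluated with non-positive exponential arguments
  only (`expm1` ratios), so high truncation orders cannot overflow.
* Evaluation outside y ∈ [0, L] follows the even periodic extension
  automatically (the basis is built from cos(ωₚy)); z outside the channel
  raises.
* The geometry matrix is cached per (N, P) and returned read-only.
* Trajectory integration is overdamped by default (micro-scale Reynolds
  and Stokes numbers make inertia negligible): v = F/(6πηr), explicit
  first-order stepping, wall contact flagged and clipped.  A Newton
  integrator is available behind `overdamped=False`.  Neutral buoyancy is
  the default particle density.

## Known limitations

* Accuracy degrades within a few λ of the electrode planes, where the
  linear-gap approximation and the dipole force law both fail; the ROI
  excludes those zones, as do negative-DEP operating regimes.
* The model is 2-D (translation-invariant along the channel axis); axial
  flow and 2-D electrode grids are out of scope.
* The reference solver is itself a discretisation; its edge-singularity
  error at Dirichlet–Neumann junctions converges slowly near the walls,
  another reason comparisons are restricted to the interior.
* Against a noisier reference (e.g. derivative fields of an unstructured
  finite-element solution), the outlier-driven ratio-arctangent benchmark
  reads substantially higher than against this smooth regular-grid
  reference; comparisons across reference implementations should fix the
  reference before comparing numbers.
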