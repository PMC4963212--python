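# Methods

`curvetracks` reconstructs faithful 2D representations of 3D cell or
particle tracks that move on hidden curved surfaces, and computes
directional statistics (bias angles, turning angles, straightness) that
naive projections distort. This note records the models, the numerical
choices, and what the synthetic validation does and does not show.

## The problem

Imaged in 3D, migrating cells frequently move on an unseen 2D surface —
an embryo's outer layer, an epidermis over a yolk, an organelle
membrane. Projecting such tracks onto the xy plane compresses steps by
the local surface tilt; a PCA projection does the same in a rotated
frame. Both distort the two statistics used to classify migration
modes:

* **bias angle** — signed angle between a step and the direction from
  its origin to an attractant (wound) position;
* **persistence (turning) angle** — signed angle between consecutive
  steps of one track;
* **straightness index** D = net displacement / total path length
  (1 = ballistic, → 0 = diffusive).

Angles live in [-π, π), counterclockwise positive. Histograms use 36
equal bins by default (10°; the binning is conventional, not inferred).

## Surface random walks (ground truth)

The simulator draws a heading angle in the local tangent plane at each
step. Attraction toward a target and alignment with the previous
heading are von Mises kernels with concentrations κ_b and κ_p; active
together they multiply, which for von Mises densities is again von
Mises with

    κ* e^{iμ*} = κ_p e^{iθ_prev} + κ_b e^{iθ_target}.

κ_b = κ_p = 0 gives a uniform heading (Brownian-type walk); the four
classic walk classes are the sign pattern of the two concentrations.

* **Stepping**: projected Euler — move the step length L along the
  sampled tangent direction, project orthogonally back to the surface.
  Exact on planes and along cylinder generators; O(L²/R) heading error
  at curvature radius R. Step lengths are chosen ≤ 2% of the dominant
  curvature radius on each preset surface; near isolated
  high-curvature spots (thin-ellipsoid tips and rim) the discretization
  error is larger and documented as a limitation.
* **Transport**: the previous heading is carried between steps by
  projecting the realized 3D step direction onto the new tangent
  plane. Persistence is meaningless without such a rule; this one is
  exact in the small-step limit.
* **Initial conditions**: positions area-uniform over the preset's
  start patch (rejection sampling from the area measure), headings
  uniform.
* **Ground truth**: the sampled intrinsic heading offsets are recorded
  per step, giving per-walk empirical truth; the analytic truth implied
  by the kernels is uniform (Brownian), von Mises (single kernel), a
  Bessel-series self-convolution (turning angles of a bias-only walk),
  or the seeded stationary Monte-Carlo chain of the combined kernel.

### Preset geometries

Six surfaces spanning zero to strong curvature, with walk conditions
fixed once:

| preset | surface | start patch | L |
|---|---|---|---|
| plane | square, side 4 | whole patch | 0.05 |
| cylinder | r=1, h=4 | ±60° band | 0.02 |
| hemisphere | sphere r=1 | 60° polar cap | 0.02 |
| sphere | sphere r=1 | 70° polar cap | 0.02 |
| ellipsoid_mild | (1.5, 1, 0.75) | whole surface | 0.04 |
| ellipsoid_thin | (5, 1, 0.2) | whole surface | 0.03 |

Walkers move freely after the start; the cap-started sphere walks
spread ~15° beyond their cap over 200 steps. The dome (hemisphere)
patch size sits deliberately in the regime where the naive projection
is measurably distorted while a single chart still covers the data —
the regime both reconstruction methods are built for. The closed
ellipsoids provide contiguous coverage (a connected neighborhood graph
needs overlapping tracks); their charts rely on per-track angular
unwinding (below).

## Method 1 — two-pass unwrapping

Pass 1 slices the cloud along one axis into equal-count slabs and
replaces each point's angular position in its cross-section by the
signed elliptic arc length from a reference meridian; pass 2 repeats
the idea orthogonally, replacing the axis coordinate by arc length
along the fitted meridian profile. On developable data (elliptic
cylinders, planes) the composite map is an exact isometric development
(machine precision in the tests); on spheres and ellipsoids the
residual is the mild shear of a sinusoidal-type chart, which vanishes
on the reference meridian and grows with angular distance from it.

Numerical design, where choices were genuinely open:

* **Ellipse fitting.** A single slab is fit by the numerically stable
  direct least-squares conic method with the ellipse constraint built
  into the eigenproblem (optionally polished by orthogonal-distance
  Gauss-Newton). But *independent* per-slab fits are not identified
  when a slab covers only a short arc smeared by the slab's thickness
  — the direct fit collapses toward small ellipses and the geometric
  fit wanders to large ones, both observed on sphere-cap fixtures.
  Pass 1 therefore fits a *smooth family*: section centers linear and
  shape-matrix entries quadratic in the axis coordinate. This family
  is exact for every quadric surface (sphere, ellipsoid, elliptic
  cylinder, cone), is initialized from a global algebraic quadric fit
  to the 3D cloud, and is refined jointly against all points
  (orthogonal distances). The per-slab fits then serve as diagnostics
  (`fit_report`). Ellipse shape is carried as the symmetric matrix
  R diag(A²,B²) Rᵀ whose entries stay smooth through circular sections
  where the orientation angle is undefined.
* **Reference meridian**: the world angle of the first slab's centroid
  about the fitted section center there, held fixed across sections;
  if the centroid coincides with the center (closed sections), a fixed
  angle is used — this only moves the chart's origin.
* **Arc lengths**: 32-node Gauss-Legendre quadrature (machine precision
  for these analytic integrands); the public `arc_coordinate` uses
  adaptive quadrature at 1e-12 absolute tolerance.
* **Foot points**: Newton iteration on the stationarity condition of
  the point-to-ellipse distance, vectorized, with a bounded fallback.
* **Anti-tearing**: along each track the foot-parameter sequence is
  phase-unwound, so a track crossing the chart cut keeps a continuous
  arc coordinate (charts of closed sections are periodic; the target
  position is branch-adjusted per point in `map_target`).
* **Pass 2**: per arc-coordinate bin, the section radius about the
  fitted centers is averaged in equal-count axis bins and interpolated
  by a cubic spline; the new axis coordinate is the arc length of that
  profile. For flat (collinear) slabs pass 1 degrades to straight-line
  development and pass 2 to the identity.
* **Slab count**: equal-count slabs (default 12) so sparse regions
  still meet the 5-point minimum; with the family fit the result is
  insensitive to the count (coordinates are Cauchy in the slab count
  on the test fixtures).
* **Axis choice**: largest data extent by default; `auto-residual`
  tries all three axes and keeps the smallest median section residual.
* Off-surface points are mapped to their foot point; the residual is
  reported per point, never silently dropped.

Limitation: the chart assumes the data's sections are convex and that
section shape varies smoothly (polynomially) along the axis; strongly
non-quadric surfaces would need a higher `family_degree`.

## Method 2 — Riemannian (metric) manifold learning

Any 2D chart of a curved surface misrepresents some lengths and
angles. The misrepresentation at a point is exactly the pullback
metric g(x), a 2×2 SPD matrix; computing inner products as uᵀ g v
recovers the true on-surface geometry on *any* smooth invertible
chart. The dual metric is estimated from data by applying a graph
approximation L of the Laplace-Beltrami operator to products of the
chart coordinate functions,

    h_kl = ½ [ L(f_k f_l) − f_k L f_l − f_l L f_k ],

and g is the eigenvalue-floored pseudo-inverse of h (floor 1e-8 ×
trace; rank recorded per point).

* **Graph Laplacian.** Heat-kernel weights exp(−d²/ε²) on a
  symmetrized k-NN graph, density-renormalized (α = 1) and
  row-normalized — required for convergence to Laplace-Beltrami under
  non-uniform sampling, and tracks oversample wherever cells dwell.
  The operator scale is calibrated *per node* from the kernel's local
  second moment (m2 = Σ_j P_ij |x_j−x_i|²/dim) rather than the nominal
  ε²/4; the two agree for an untruncated Gaussian kernel, but the
  per-node form stays calibrated under k-NN truncation. Sign
  convention: L(x²) = +2 on flat data, L annihilates constants
  exactly.
* **Bandwidth.** Default ε = median distance to the 50th neighbor.
  Track data is filamentary: the 10-NN distance measures frame spacing
  along a track, not cloud density, and underestimates the scale at
  which the surface looks flat by an order of magnitude. Pointwise
  consistency as n grows requires shrinking ε slower than the spacing
  (the circle eigenfunction test uses ε ∝ n^(−1/5)).
* **Estimator form.** The Laplacian-product estimator equals, node by
  node, the kernel second moment of coordinate differences. The
  default *centered* variant subtracts the kernel mean-shift outer
  product (a local covariance), which removes the estimator's
  first-order bias at the chart boundary; both agree in the interior.
  Points with a large normalized mean shift (> 0.2) are flagged as
  boundary; they are included in statistics by default but carry the
  flag. Optional neighborhood-averaging sweeps of the h field exist
  but default to off: on curved fixtures the bias from averaging
  across a varying Jacobian exceeded the variance reduction.
* **The chart.** Default: Laplacian eigenmaps — the two slowest
  non-trivial eigenfunctions of the package's own diffusion operator
  at twice the metric bandwidth (charts need smoothness above the
  track-filament spacing; the metric wants the smallest bandwidth the
  sampling supports). On noiseless track clouds the classic LLE
  eigenproblem produces localized spike eigenvectors (measured here:
  locally constant embeddings with vanishing co-metric), so eigenmaps
  is the robust default; standard/modified/Hessian/LTSA LLE and
  precomputed charts (including an unwrapping chart) are selectable —
  the estimator applies to any smooth invertible map, and the
  statistics are provably invariant to affine reparameterizations of
  the chart (tested).
* **Degeneracy detection.** Two guards raise a dimensionality error
  instead of returning a bogus chart: the 3D cloud being locally
  one-dimensional (sparse tracks = filaments), and the embedded cloud
  collapsing to a filament (median local SVD aspect ratio < 0.05 —
  a genuinely 2D patch at these sampling densities sits well above
  0.2, a collapsed chart well below 0.01). This is the expected
  behavior on the thinnest ellipsoid with sparse data, where the
  second surface dimension is simply not resolved.
* **Per-step convention**: a step uses g at its origin; the angle
  between consecutive steps uses g at the shared point.

Limitation: the metric corrects local geometry only. Bias angles
involve the chart direction toward a possibly distant target, which no
pointwise metric can fully undo on a strongly warped chart; the
residual is visible as a slightly elevated bias deviation for the
manifold method on the dome fixtures.

## Validation design and what it shows

The validation grid crosses the six preset geometries with three walk
models (Brownian, biased κ_b = 2, biased-persistent κ_b = 2, κ_p = 1),
50 tracks × 200 steps per cell, and scores every method's bias and
persistence distributions against the kernels' true distributions by
total-variation distance on 36 bins (`deviation_distance`; L2 and KS
variants available). Headline orderings (reconstructions never worse
than the xy projection; metric never worse than the metric-free
embedding) are enforced with paired bootstrap confidence intervals:
both distributions are resampled on the shared step set, which removes
the common sampling noise from the difference; a claim counts as
failed only when the reverse ordering holds beyond the 95% interval.
At 10⁴ steps the binned-TV sampling floor is ≈ 0.024, comparable to
the systematic differences on gently curved surfaces, so point
estimates order the methods while full CI separation is only reached
where the xy artifact is large (e.g. the dome's bias angles).

What passing does **not** show about real data: the simulator has no
tracking noise, no missing frames, no cell-cell interactions, no
time-varying attractant, and its surfaces are exact quadrics. The
unwrapping family fit and the metric estimator both tolerate small
off-surface noise by construction (orthogonal residuals; kernel
averaging), but their accuracy under realistic localization error is
not quantified here.

## Numerical details and degenerate inputs

* Frame gaps break steps by default (`max_gap = 0`); bridging is
  opt-in. Zero-length steps are excluded from angle statistics and
  counted.
* Duplicate (track, frame) rows, missing columns and non-finite
  coordinates are rejected at I/O with named errors.
* All simulation randomness flows from one integer seed; charts and
  metric fields are deterministic (fixed eigensolver start vectors and
  sign conventions), so equal commands give byte-identical outputs.
* Problem sizes in the test-suite fixtures (50×200 tracks for curved
  surfaces, 2000-point clouds for the flat-metric and development
  oracles, n ≤ 3200 for the Laplacian consistency ladder) were chosen
  as the smallest sizes at which the sampling floor sits clearly below
  the effects being measured.
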