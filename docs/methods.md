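# Methods

This note records the models, conventions, parameter defaults and numerical
choices in `visconn`, and what the synthetic phantoms do and do not emulate.

## Coordinate and grid conventions

All physical coordinates are in millimetres.  A volume of shape
`(nx, ny, nz)` with voxel size `(sx, sy, sz)` spans `[0, nx·sx) × … × [0,
nz·sz)`; the center of voxel `(i, j, k)` is at `((i+½)sx, (j+½)sy, (k+½)sz)`.
Voxel boundaries are half-open: a point lying exactly on a shared face
belongs to the higher-index voxel (`floor(p / s)`).  Linear voxel indices
follow C (row-major) order.  NIfTI affines carry voxel size on I/O; analysis
happens in this grid-aligned mm frame.

## Forward signal model (phantom)

Per voxel and unit gradient `g`, the noiseless signal is Stejskal–Tanner
attenuation `S = S0 · exp(−b · gᵀ D g)` with one leading b = 0 channel
(defaults `b = 1000 s/mm²`, `S0 = 1000`).  Rician noise adds independent
Gaussian noise of the stated σ to two quadrature channels and takes the
magnitude, matching magnitude MR reconstruction.  Gradient tables are
generated by seeded electrostatic repulsion with antipodal symmetry
(25 directions by default); the scheme is deterministic and produces a
design matrix with condition number ≈ 4, ample for least-squares fitting.

Phantoms are tube-shaped bundles around polyline centerlines: on-bundle
tensors are cylindrically anisotropic with λ₁ = 1.7×10⁻³ mm²/s along the
local tangent and λ₂ = λ₃ = 0.3×10⁻³ (FA ≈ 0.799); the background is
isotropic at 0.7×10⁻³.  Lesions (box or sphere, voxel coordinates)
overwrite contained voxels with an isotropic tensor of `md_factor` (default
2.0) times the background mean diffusivity, mimicking the elevated
diffusivity and abolished anisotropy of chronic infarcts.

What the phantoms do **not** emulate: partial-volume averaging, crossing or
kissing fibers within a voxel, susceptibility/eddy-current distortion,
physiological noise correlations, CSF, or realistic anatomy.  They exist to
exercise the pipeline's geometry and statistics, not to simulate a brain.

## Tensor estimation

Ordinary least squares on log signals: for each voxel, `ln(S_k/S0) = −b ·
B_k d` with design rows `B_k = [gx², gy², gz², 2gxgy, 2gxgz, 2gygz]` and the
six unique tensor elements `d = (dxx, dyy, dzz, dxy, dxz, dyz)`.  Multiple
b = 0 volumes are averaged.  Voxels with any non-positive signal are marked
invalid (log undefined) rather than silently clamped.  Fitting requires ≥ 6
non-collinear directions (rank check).  Eigenvalues are sorted descending;
FA = √(3/2) · ‖λ − λ̄‖ / ‖λ‖ (0 for a zero tensor), MD = mean(λ).
Negative fitted eigenvalues are retained but flagged (`nonphysical`), since
thresholded FA maps and tracking masks handle them naturally.

## Tractography

Deterministic FACT-style streamlining on the FA-weighted principal
eigenvector field `v(x) = FA(x)·e1(x)`:

- **Interpolation**: trilinear over the 8 surrounding voxel centers with
  per-corner sign alignment to the current heading (eigenvectors have
  arbitrary sign); coordinates clamp to the center lattice so the field is
  defined across the full physical extent.
- **Integration**: fixed-arc-length 4th-order Runge–Kutta, step 0.1 mm
  (one tenth of the default 1 mm voxel — small enough that per-step
  curvature is negligible against the angle criterion).
- **Stopping**: interpolated FA < 0.15 (conventional white-matter floor);
  heading turns > 60° relative to the heading one voxel-length earlier
  (a voxel-scale look-back; per-step angles at 0.1 mm are tiny, so the
  look-back is what detects sharp turns at bundle interfaces); the next
  point would leave the volume; or the half-track reaches the maximum
  length.
- **Seeding**: uniform 1 mm lattice anchored at the first voxel center,
  kept where interpolated FA strictly exceeds 0.3 (seeds should start well
  inside coherent white matter, higher than the stopping floor).
- **Filtering**: tracks are bidirectional (both ±e1 half-tracks joined at
  the seed); fibers with physical length outside [10, 140] mm are removed,
  boundaries inclusive (shorter tracks are predominantly noise; longer ones
  exceed plausible fiber lengths at brain scale).

## Connectivity and VISC

A fiber's penetrated voxels are the ordered unique voxels containing its
points (out-of-grid points skipped).  The direct matrix `X` is the union of
per-fiber cliques — binary, symmetric, zero diagonal — stored sparse (CSR);
an optional `chain` mode connecting only consecutive voxels is exposed for
sensitivity analysis.  The indirect matrix is `Y = [(X·X) > 0] − X − I`
(two hops but not one), computed by boolean sparse products; a dense
`n × n` matrix is never materialised.  Then `VISC_α(i) = (y(i)·X·1) /
(y(i)·1)^α` with α ∈ [0, 1] (default 1) and VISC = 0 where a voxel has no
indirect neighbors.  Fiber-count and mean-fiber-length maps use the same
penetration rule.

The FA-threshold sweep re-runs seeding → tracking → filtering → VISC for
stopping thresholds 0.10–0.40 in 0.05 steps (7 rows) and fits the log of
the ROI-mean VISC linearly against threshold.

## Registration

- **Affine**: nine parameters (3 translations mm, 3 rotations rad, 3
  scales) composed `T·Rz·Ry·Rx·S` about the volume center, optimised by
  central-finite-difference gradient descent with backtracking line search
  on the mean-squared intensity difference, over a coarse-to-fine schedule
  (4, 2, 1 mm; Gaussian anti-aliasing before subsampling).  Deterministic;
  returns best-so-far with a warning if the finest level does not converge.
- **Histogram matching** (for cross-contrast pairs): monotone quantile
  remap; a constant source is returned unchanged with a warning.
- **Demons**: classic fixed-image-gradient force `du = −(m(x+u) − f)∇f /
  (|∇f|² + (m(x+u) − f)²)` with 2 mm FWHM Gaussian regularisation per
  iteration.  Voxels whose current mapping lands inside the lesion mask are
  frozen (no update), and the regularisation is an edge-preserving
  normalised convolution that assigns zero weight to frozen voxels, so no
  displacement leaks across the lesion boundary while surrounding tissue
  still registers.
- **Inverse field**: demons fields are not analytically invertible.  The
  inverse is approximated iteratively: the inverse at each forward-mapped
  location `y = x + u(x)` is forced to `−u(x)` (trilinear scatter onto the
  grid; collisions averaged; out-of-domain targets clamped), then smoothed
  with a 2 mm FWHM Gaussian to fill and regularise; 10 iterations by
  default.  The returned field carries the per-voxel composition residual
  `|u(x) + u_inv(x + u(x))|` and an iteration log of its mean.  A uniform
  translation inverts exactly away from the clamped boundary; for smooth
  fields the mean residual is non-increasing across iterations.

## Statistics

- **Voxel-wise test**: per voxel, differences `d_c = control_c − subject`
  over n controls; `t = mean(d)/(sd(d)/√n)`, df = n − 1, one-tailed in the
  direction expected for the metric (controls-greater for FA and VISC,
  subject-greater for MD — lesions reduce anisotropy and connectivity and
  elevate diffusivity).  Zero-variance voxels get t = ±∞ by the sign of the
  mean (0 if the mean is also zero).  Note the statistic treats the subject
  map as fixed: it is exactly t-distributed (and the type-I rate is exactly
  α) with respect to control sampling variability.  If the subject map is
  itself regarded as a random draw from the control distribution, the
  statistic is inflated by √(n+1) and the test is anticonservative — an
  inherent property of this single-case design, verified (not hidden) by
  the test suite.
- **LDV**: natural log of the significant-voxel count; a zero count
  propagates as NaN (a missing observation, dropped from regressions)
  rather than −∞.
- **Regressions**: OLS via statsmodels; slope significance by F-test.
  Multiple regressions apply Bonferroni correction at α/m per coefficient
  (m = 3 metrics by default).  ROI analysis reports, per ROI × metric, the
  LDV regression and regional-mean regressions against Fugl-Meyer scores,
  with star flags at p < 0.05/m and p < 0.01/m and a second pair further
  corrected for the number of ROIs (both conventions are reported because
  the appropriate correction set is ambiguous).
- **Fugl-Meyer bookkeeping**: leaf sub-scores validated against their
  maxima; grand total 226 = upper-extremity 130 + lower-extremity 96;
  cross-cutting domains motor 100, balance 14, sensation 24, range of
  motion 44, pain 44.  Reference tables for a 10-subject stroke cohort and
  an 18-subject FA-correlation summary are bundled for arithmetic checks
  and examples.

## Reproducibility

Every stochastic component (noise synthesis, cohort generation, gradient
scheme) takes an explicit integer seed; per-realisation seeds derive from a
master seed through `numpy.random.SeedSequence` spawning, reduced mod 2³¹.
Tracking, registration and statistics are fully deterministic given their
inputs.

## Limitations

- The tensor model is single-fiber; crossing regions mislead both the fit
  and FACT tracking (no ODF/multi-tensor support).
- The clique rule makes direct connectivity of long fibers dense; memory
  scales with the square of per-fiber penetrated-voxel counts (fine at
  phantom scale, the intended regime here).
- The affine cost is plain MSE — cross-modality affine alignment should be
  preceded by histogram matching.
- The demons implementation is the small-deformation (additive) variant;
  large deformations would need a diffeomorphic scheme.
- The single-case t-test calibration caveat above applies to any
  interpretation of the resulting maps as subject-level inference.
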