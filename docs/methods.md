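# Methods

This note documents the models and procedures `ventmorph` implements, the
parameter choices that matter, what the synthetic cohort does and does not
emulate, and the numerical decisions a maintainer would want recorded.

## Synthetic cohort generator

**What it emulates.** Per-subject left/right lateral-ventricle surfaces,
per-vertex cortical-thickness maps, and a covariate table (group, age,
sex, ICV, K-MMSE) for an INPH/control study.  A single latent severity
s_i > 0 (truncated normal, mean 1.0, SD 0.35; exactly 0 for controls)
drives both regional ventricular expansion and regional cortical
thinning, so the cross-block correlation sparse CCA looks for exists by
construction and is recoverable as ground truth.

**Geometry.** The ventricle is an icosphere stretched to an elongated
ellipsoid (semi-axes 30 × 10 × 7.5 mm, long axis x) and bent by the
vertical shear z += 8·(x/a)² to suggest the ventricular arc; the shear
has unit Jacobian, so the enclosed volume remains the analytic ellipsoid
volume, which anchors the volume calibration.  The right side is the
mirror image across x = 0 with face orientation restored.  The cortex is
one ellipsoid per hemisphere (65 × 80 × 60 mm).  Zones are spherical caps
in the parameter domain, each a single connected patch: three expansion
zones (superior body, cap half-angle 1.3 rad; medial frontal horn and
temporal horn, 0.9 rad each), an untouched inferior body (0.55 rad), and
seven cortical thinning zones (0.4 rad each; orbitofrontal and rostral
anterior cingulate on both hemispheres, parahippocampal and temporal pole
on the left, insula, inferior temporal and fusiform on the right).

**Severity effects.** Vertices move outward along their normals by
s_i · A(v) · amplitude + N(0, σ_shape), where A is the pointwise maximum
of per-zone cos² bumps (1 at each zone center, 0 at and beyond the cap
edge, hence exactly 0 on the inferior body).  Thickness is
T(v) = 2.9 − s_i · B(v) · amplitude_T + N(0, σ_thickness), clipped below
at 0.5 mm, with B supported exactly on the seven cortical zones.  Because
real ventricular enlargement in this population nearly quadruples the
volume, the expansion zones are deliberately wide: most of the
non-inferior surface participates, with the strongest displacement at the
zone centers.

**Calibration (fixed once, before any acceptance run).**

| parameter | default | unit | rationale |
|---|---|---|---|
| base scale | 1.1983 | — | control-group mean total volume ≈ 32,360 mm³ |
| expansion amplitude | 21.8 | mm / unit severity | INPH mean total volume ≈ 119,129 mm³ across cohorts |
| thinning amplitude | 1.2 | mm / unit severity | INPH mean thickness ≈ 2.84 mm from T0 = 2.9 mm |
| shape noise σ | 0.4 | mm | per-vertex surface measurement error |
| thickness noise σ | 0.25 | mm | pre-smoothing per-vertex thickness error |
| severity | N(1.0, 0.35) truncated > 0 | — | cohort-mean volume CV ≈ the reported ~36% |

Head size couples to ventricle scale through (ICV/ICV_ref)^(1/3) with
ICV_ref = 1078.5 cm³ (the control population mean), so the ICV covariate
in the downstream ANCOVA does real adjustment work.  Demographics default
to the study population: INPH n=33, age 73.5 ± 5.0, 21/33 male, ICV
1151.5 ± 135.1 cm³, K-MMSE 19.9 ± 6.9; controls n=23, age 70.9 ± 4.3,
9/23 male, ICV 1078.5 ± 95.2 cm³, K-MMSE 27.1 ± 2.4.

**What it does not emulate.** No MRI volumes, tissue classes, skull
geometry or Evans-index measurement (the ratio is carried as metadata
only); no anatomical atlases (zones are parametric caps); no
registration error between thickness maps (they are generated in vertex
correspondence); cortical meshes default to 2,562 vertices per hemisphere
rather than the 40,962 of a production thickness pipeline — vertex counts
are configuration knobs, and every statistical operation is agnostic to
them.  Passing tests on this cohort therefore demonstrates that the
statistics recover planted, geometrically simple signals at realistic
effect sizes and noise levels — not that the pipeline is robust to
segmentation error, registration failure or atlas mismatch in real data.

## SPHARM correspondence

The spherical parameterization starts from the Gauss-style map
(vertices normalized about the centroid) and descends the area-distortion
cost Σ_f (Ω_f / t_f − 1)², where Ω_f is the signed spherical triangle
area (solid angle) and t_f the mesh face area rescaled to total 4π, using
the exact analytic gradient of the solid angle with backtracking line
search and a flip guard; it stops at relative improvement < 1e-6 or 500
iterations and guarantees an orientation-preserving map.  On a unit
icosphere the minimizer is *near* the identity but not exactly it: flat
triangle areas are not exactly proportional to solid angles, so the true
minimum cost is ≈ 1.5e-5 and the optimum deviates from the vertex
positions by O(1e-3) — tests bound both rather than asserting zero.

Real, orthonormal spherical harmonics are fitted to the three coordinate
functions by least squares (condition-number guard 1e8).  Degree 0
encodes the centroid and degree 1 the best-fit ellipsoid; for a centered
sphere or axis-aligned ellipsoid with identity parameterization the
coefficients are exactly first-order, which the tests verify against an
analytic projection oracle.  First-order alignment takes the SVD of the
degree-1 linear map M (parameter sphere → ellipsoid) and rotates the
parameter space by the right singular vectors (descending axis order,
dominant-entry-positive sign convention, determinant +1); rotation of the
full coefficient set is performed exactly by Gauss–Legendre quadrature
re-projection of the band-limited expansion.  A spherical first-order
ellipsoid (relative axis spread < 1e-6) carries no orientation and falls
back to the identity with a warning.  Defaults: L_max = 12, sampling
level 4 (2,562 vertices); both are knobs, and desk-scale runs use
L_max 10 and level 3.

## Alignment and expansion maps

Rigid Procrustes is the closed-form Kabsch solution with determinant
correction; no scaling, degenerate (collinear) point sets rejected.  The
control mean shape is a generalized-Procrustes iteration (align all to
the evolving mean until it moves < 1e-6 mm RMS; a single-pass mode
exists).  The expansion map is the *unsigned* distance, exactly as
defined for the ventricle difference; a signed variant (projection on the
mean's outward normal) is available but off by default.

**Known property: alignment leakage.** When the group contrast is as
large as it is here (~3.7× volume), rigid alignment of an expanded
subject to the control mean necessarily displaces the *unchanged* part of
the surface too (the optimal translation balances the expanded top
against the static bottom), so unsigned-distance maps show group
differences even on the untouched inferior body.  This is a property of
full-surface rigid alignment, not a bug.  For planted-signal evaluation
the package therefore also provides `synthetic.common_frame_expansion`,
which exploits the generator's shared construction frame (no re-alignment
is needed; head-size scale mismatch is left to the ICV covariate) and
yields leakage-free ground-truth maps; the Procrustes path is the right
choice for data arriving in arbitrary scanner frames.

## W-scores

Per-vertex OLS of the control maps on the configured covariates (default
age + ICV, matching the ANCOVA adjustment), residual SD with the n − p
denominator.  In-sample control W-scores then have mean 0 exactly and
sum-of-squares/(n − p) = 1; for large control samples the 95th percentile
of out-of-sample W-scores approaches +1.645.  Exact-fit degeneracy
(residual SD ≈ 0) raises an error naming the vertices.  W-scores are
computed for patients against the control model; the pipeline can feed
SCCA either raw maps (default) or W-score maps.

## Group statistics

Vertex-wise ANCOVA is vectorized OLS of the map stack on
[1, group, age, ICV] with group coded 1 = INPH; t and two-sided p per
vertex, verified against statsmodels per-vertex fits to 1e-9.
"Bonferroni at p 0.01" is read as familywise α = 0.01 with per-vertex
threshold 0.01/V, where V counts both sides when they are analyzed as one
family (the pipeline default); the per-vertex-0.01 reading is a config
option.  Surface smoothing is explicit-Euler heat diffusion with the
cotangent Laplacian and barycentric vertex areas, run to total time
t = σ²/2 with σ² = FWHM²/(8 ln 2); the scheme conserves the area-weighted
mean exactly, leaves constants fixed, and reproduces the half-maximum
radius FWHM/2 within 20% on a delta input.

## Sparse CCA and permutation inference

The SCCA is a penalized matrix decomposition of X^T Y: alternating
updates u ← argmax a·u subject to ‖u‖₂ ≤ 1, ‖u‖₁ ≤ c, u ≥ 0 (positivity
on by default), where the soft-threshold level for a given L1 budget is
solved exactly by a sorted-knot closed form.  "Sparseness ≈ half the
vertex dimension" is implemented as a target active fraction of 0.5 per
block, realised by bisecting the L1 budget on pilot fits of the actual
data (the two blocks' budgets interact, so they are calibrated
alternately); a raw-budget mode is also available.  With sparsity relaxed
the alternation maximizes covariance, which is *not* classical CCA; an
optional whitening mode (per-block inverse-sqrt covariance) makes the
relaxed, unconstrained fit coincide with classical CCA and serves as the
oracle cross-check.  Because expansion and thinning are negatively
associated while both weight vectors are constrained nonnegative, the
pipeline negates the (centered) thickness block so positive weights mark
thinning; thickness maps are smoothed at 30-mm FWHM first, mirroring
standard thickness preprocessing.

The permutation test re-pairs the blocks by uniform derangements
(rejection-sampled, so no subject ever keeps its own pairing), refits
with the identical budgets, and reports p = k/B exactly; the (k+1)/(B+1)
convention is available because k = 0 gives the statistically awkward
p = 0.  Default B = 2,000.  Under the null the full test's rejection rate
at the 0.05 threshold is calibrated (0.05 ± 0.03 over 500 replicates).

## Pipeline, sizes and reproducibility

`run_pipeline` executes generate → correspond → align → wscore → stats →
SCCA with a single seed governing every random draw; identical
configuration reproduces identical outputs bit-for-bit, and each run
writes a JSON manifest (config, seed, version, stage timings).  Meshes
are millimetres, right-handed, outward-oriented, vertex indices 0-based.
Desk-scale defaults (ventricle sampling level 3 = 642 vertices/side,
cortex 2,562/hemisphere, L_max 10) keep a full synthetic run around a
minute; test suites use the same scale, with the heavier calibration
suites (500-replicate nulls, B = 2,000 permutations) sized to finish in a
few minutes each.

## Limitations

- Parametric geometry only; no claim of anatomical fidelity of the zone
  layout, only of the statistical contracts.
- The area-preserving relaxation is a heuristic descent: it reduces
  distortion with a no-flip guarantee but does not reach the exact
  constrained optimum, and strongly non-star-shaped inputs may need the
  Tutte-style untangling fallback.
- One canonical component by default; deflation for further components is
  not implemented.
- Cluster-extent or FDR corrections are deliberately absent (Bonferroni
  only), as is any non-rigid alignment.
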