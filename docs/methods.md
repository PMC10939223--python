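# Methods

This note documents the models implemented in `stnseg`, the choices made
where the design was genuinely open, the synthetic phantoms used for
validation, and what validation on phantoms does and does not establish.

## Coordinate conventions

World coordinates are millimetres in a RAS+ frame; voxel indices are 0-based
and map to world space through the volume's 4×4 affine.  All interpolation
queries take world-mm points.  Signed distances to the STN surface are
**positive inside** the nucleus: the MER transition model needs a sign, and
with this convention the sigmoid of distance rises together with signal
energy as the electrode enters the nucleus.

## Mesh generation (shrink wrap)

A subdivided icosahedron (default 3 subdivisions, 642 vertices, 1280 faces)
is centred on the label's centre of mass with a radius exceeding the
structure's maximal extent.  Each vertex marches inward along its centre ray
in 0.1 mm steps; the first trilinear label value ≥ 0.5 is refined by linear
interpolation between the bracketing steps.  Vertices whose ray never
crosses 0.5 collapse to the centre and are flagged; more than 1 % flagged
vertices aborts the wrap.

Laplacian smoothing (default 5 passes, unweighted 1-ring mean) evens the
vertex distribution.  Plain 1-ring averaging contracts a closed surface
(~2 % radius per pass at this tessellation), which would cost ~0.1 dice
against the label, so each smoothing pass inside `shrink_wrap` is followed by
reprojection of the vertices onto the 0.5 level set along their centre rays:
smoothing then acts tangentially (redistribution) while the boundary
position is preserved.  The standalone `laplacian_smooth` operator remains
the plain 1-ring mean.

Because the seed tessellation is fixed, meshes of all subjects share vertex
indexing (point correspondence), which underlies the eigenshape model, the
surface statistics and the cross-subject mapping of electrode entry points.

Measured fidelity on analytic ellipsoids (STN-sized, 6×4×3 mm semi-axes):
dice ≥ 0.95 against the label at a 0.5 mm grid and ≥ 0.85 at the clinical
1.25 × 1.25 × 1.5 mm grid (the acceptance suite recomputes both).

## Shape–intensity model

- **Features.** x = [x_shp, x_int]; x_shp the 3N flattened vertex
  coordinates (vertex-major, xyz within vertex), x_int the 7N border
  intensities: cubic-spline samples at offsets −3…+3 mm (1 mm spacing, the
  unique evenly spaced reading of "7 samples within 3 mm in both
  directions") along outward vertex normals, minus the subject's mean
  interior intensity.  The interior mean is computed by a fixed radial
  quadrature (volume sampled at fractions 0.25/0.5/0.75 along each
  vertex→centroid ray plus the centroid) — a deterministic interior sample
  that is recomputed for every candidate mesh during fitting and used
  identically at training time, so the feature definition is consistent.
  Full voxelization per objective evaluation would be ~100× slower for no
  measurable benefit at these resolutions.
- **Dimensionality.** SVD of the demeaned sample matrix; L is the smallest
  count of eigenvectors whose cumulative variance exceeds 99.5 %.  With
  shrink-wrapped training meshes, rasterization jitter spreads a broadband
  tail over the spectrum, so L typically approaches n−1 even when the
  biological variation is low-rank; this is expected and harmless, but it is
  why robust estimation must run in the eigenspace.
- **Robust estimation.** Location and scatter of the eigencoefficients by
  minimum covariance determinant with support fraction 0.7 — i.e. up to 30 %
  of training subjects may be outliers, matching the disagreement level of
  repeated manual labelling on clinical images.  Precision is the
  pseudoinverse of the robust scatter.  Raw-space MCD over 10N dimensions is
  ill-posed at realistic n; the eigenspace route is the only estimable
  ordering.
- **Fitting.** Powell minimization of shape-Mahalanobis + intensity-
  Mahalanobis over the shape eigencoefficients; the two terms are computed
  independently and added (the independence factorization).  Bounds: each
  coefficient within ±3 standard deviations (±3·√eigenvalue — the "±3λ"
  bound read on the SD scale, the standard SSM convention; ±3 variances
  would be dimensionally inconsistent).  Five starts: the geometric-median
  training sample's coefficients, and ±1 SD steps along each of the two
  leading eigenvectors from that point.  Objective tolerance 1e-4, parameter
  tolerance 1e-2 (10 µm on mm-scale coefficients), ≤ 2000 evaluations per
  start.  The eigenspace parameterization with bounded coefficients keeps
  candidate meshes self-intersection free in practice.

## Joint STN–SN model

The STN/SN border is nearly invisible on clinical T2, so the two structures
are fitted jointly: a robust Gaussian over the concatenated shape
eigencoefficients provides, for each structure, the conditional prior
μ = μ₁ − Λ₁₁⁻¹Λ₁₂(x₂−μ₂) with precision Λ₁₁ given the other structure's
current coefficients.  Two numerical safeguards:

- Cross-structure coupling is restricted to the k = support/3 leading modes
  per structure; a full joint covariance is not estimable at typical n.
- The conditional prior precision is assembled block-diagonally (joint
  conditional block for the leading modes, the structure's own marginal
  block for the tail).  Mixing the joint block into the marginal matrix
  while keeping its leading–tail cross terms can produce an indefinite
  matrix, which the optimizer exploits catastrophically.

Segmentation alternates between the structures from their independent fits,
warm-starting each refit at the current coefficients, until the total
objective changes by < 1e-3 or 4 alternations.  With a zero cross block the
procedure reduces exactly to independent fitting.

## MER model

- **NRMS.** RMS over stationary 1 s windows (windows with variance > 3× the
  median window variance are rejected — a simple stationarity screen
  honouring the artefact-free-activity contract; if all windows are rejected
  the full-signal RMS is used with a warning), divided per trajectory by the
  mean RMS of the first five recording sites, which lie well above the STN.
  The ratio cancels electrode impedance and amplifier gain exactly.
- **Emissions.** log-normal NRMS distributions inside and outside the STN,
  fitted by the closed-form MLE of log-NRMS per expert-labelled class.
- **Border.** P(IN) = sigmoid(β₀ + β₁·d) of the signed surface distance,
  fitted by unpenalized logistic regression pooled over entries and exits
  (one mean trend; entry is empirically steeper than exit but a single
  sigmoid is used for all surface points).
- **Brain shift.** Bounded Powell minimization of Σ −ln[p(x|IN)S(d) +
  p(x|OUT)(1−S(d))] over (tx, ty, tz, sx, sy, sz); translation bounded at
  ±2 mm per axis, scaling at [0.9, 1.2]; scaling is applied about the mesh
  centroid; no rotation.  The transform is applied to the mesh and the
  electrode positions stay fixed (the electrode-side description is the
  inverse-equivalent convention).  Translation and scaling are estimated
  jointly.  Distances are recomputed from the transformed mesh at every
  evaluation; because the sites of a trajectory are colinear, the
  implementation uses an exact pruned point–triangle distance for the
  magnitude and ray-crossing parity along each trajectory line for the sign
  (verified to machine precision against the brute-force signed distance).
  Axes that rail at a constraint are reported at the bound exactly.

**Identifiability.** The ML estimator of the scaling from one session
(5 trajectories × 30 sites) has an irreducible per-axis SD of ~0.07: the
Ben-gun geometry probes the border at few effective crossings, and this is a
Fisher-information limit, not an optimizer artefact (the fitted likelihood
exceeds the truth's by ~k/2 nats, as theory predicts).  Scale estimates are
therefore validated by their mean over replicate sessions (bias ≤ 0.05),
translations by per-axis MAE ≤ 0.5 mm.  This matches the clinical
observation that fitted scalings often rail at the constraint.

## Synthetic phantoms

The generator emulates the study conditions; its defaults are fixed:

| parameter | default | rationale |
|---|---|---|
| STN template | ellipsoid 5.2×3.0×2.0 mm semi-axes | volume ≈ 130 mm³, the literature average |
| SN template | 6.0×3.5×2.5 mm, offset (1, 3.5, −6) mm | larger, antero-inferior neighbour |
| shape variation | rank 5, mode SDs 0.8…0.2 mm | smooth low-rank anatomy; modes are orthonormalized polynomial fields on the seed sphere, so draws cannot self-intersect |
| T2 levels | background 1.0, STN 0.55 | white-matter-normalized hypointensity |
| border ramp | logistic in signed distance, width 0.8 mm | partial-volume blur at clinical resolution |
| grids | 0.5 mm (fine) / 1.25×1.25×1.5 mm (clinical) | acquisition protocol |
| trajectories | 5-cannula Ben-gun, 2 mm radius | standard array |
| depth schedule | 1.0 mm steps −10…−5, then 0.5 mm to +7 | intra-operative protocol (30 sites/trajectory) |
| insertion direction | ~30° off the STN long axis | clinical approach traverses 4–6 mm of nucleus; IN prevalence ≈ 0.29, close to clinical prevalence |
| emissions | μ_in = ln 2.5, σ_in = 0.35; μ_out = 0, σ_out = 0.2 | in-STN NRMS 2–3× background with realistic spread |
| border sharpness | β₀ = 0, β₁ = 2 mm⁻¹ | smooth mean trend over ~±2 mm |
| true shift | uniform ±1.5 mm translation, 0.95–1.15 scaling | brain-shift magnitude reported intra-operatively |

Signed distance for the intensity ramp is computed from a signed Euclidean
distance transform of the rasterized mesh, accurate to ~half a voxel —
adequate for a partial-volume model and orders of magnitude faster than
exact mesh distance on the full grid.

**What the phantoms do not model:** bias fields, Rician noise, through-plane
partial-volume anisotropy beyond grid spacing, registration error, spiking
structure in MER beyond energy, and inter-rater labelling bias.  Passing the
synthetic suite therefore establishes the correctness and statistical
calibration of the machinery (segmentation recovers planted shapes,
transforms and model parameters; MER fitting improves containment), not the
clinical dice or accuracy level attainable on 1.5 T data.

## Problem sizes in the test and acceptance runs

The test suite trains on 30 phantoms and evaluates 10 held-out subjects for
the end-to-end direction check, uses 20 replicate sessions of 150 sites for
transform recovery, 5000 sites for emission recovery, and 100 replicates for
the robustness comparison.  The acceptance script uses 22 training/6 held-out
subjects and 10 transform replicates, chosen to keep a full from-scratch run
in the minutes range on one CPU while leaving every estimate comfortably
clear of its decision threshold.

## Known limitations

- MCD with L ≈ n retained dimensions is formally degenerate (support <
  dimension); the pseudoinverse precision then under-weights the tail modes.
  This is benign for segmentation (the intensity term dominates) but is why
  the joint model restricts coupling to leading modes.
- `mesh_to_mask` voxelizes by column parity of voxel centres; voxels whose
  centre lies within numerical precision of the surface follow floating-point
  rounding.
- The combined image+MER objective (adding an MER Mahalanobis term to the
  image objective) is intentionally not implemented; the two-stage procedure
  is the validated configuration.
- Tissue segmentation, brain extraction and template co-registration are
  upstream of this package and are consumed as inputs (a simple fuzzy
  c-means white-matter membership estimator is provided for convenience
  only).
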