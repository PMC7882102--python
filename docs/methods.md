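# Methods

This note documents the models, conventions, parameter choices and known
limitations of `fracdose`, in the order the pipeline uses them.

## Grid and transform conventions

All volumes are axis-aligned voxel grids indexed `[ix, iy, iz]` with array
axes equal to the patient axes (x, y, z).  A voxel center sits at
`origin + index * spacing` (0-based, mm).  Rigid transforms are
3 translations (mm) + 3 rotations (deg) applied about the fixed axes in
x → y → z order (pitch, roll, yaw) around a stated center — the plan
isocenter everywhere in this package.  At the ≤2° angles relevant here the
rotation-order effect is negligible, but a fixed convention is required for
reproducibility and is asserted by the transform round-trip tests
(inverse∘forward = identity to 1e-9 mm).

Interpolation is trilinear for continuous fields (dose, HU, density, depth)
and nearest-neighbour for masks.  Out-of-grid reads return 0 Gy for dose
(dose supports are interior by construction) and −1000 HU (air) for images.
The identity transform short-circuits to an exact copy, so null protocols
are bit-exact rather than merely close.

Limited-FOV CBCT volumes mark voxels outside their cylindrical field of view
(axis along z through the grid center) with the sentinel −3024 HU, a common
scanner convention that cannot collide with valid air.  `stitch_limited_fov`
replaces those voxels with the planning CT read through the online
registration; `apply_hu_curve` leaves sentinels unset (NaN) so an unstitched
volume cannot silently enter a dose calculation.

The portable container format is a single file: one JSON metadata line
(shape, dtype with byte order, spacing, origin, frame/name fields) followed
by the raw little-endian C-order array bytes.  Round trips are bit-exact;
masks are stored as 8-bit {0, 1}.  DICOM reading (CT series, RTDOSE,
RTSTRUCT polygon rasterization) is supported for axial identity-orientation
volumes only; DICOM writing is out of scope.

## DVH metrics

Dq% — the minimum dose received by the hottest q% of an ROI — is computed
from exact voxel ranks: with N in-ROI doses sorted descending,
`k = q/100 · N`, and Dq% linearly interpolates the order statistics at
fractional rank k (clamped to [1, N]).  This estimator is exact for ties,
recovers the ROI minimum as q → 100, is scaling-equivariant, and matches a
brute-force threshold sweep on every ROI ≤ 1000 voxels in the tests.  The
binned cumulative curve (default bin width 0.05 Gy) exists for plotting and
CSV export only; metrics never read it.

Relative differences are signed percentages normalized by the *planned*
metric, `100·(planned − delivered)/planned`, so positive values mean
underdose.  Normalizing by prescription instead is left to callers.  A voxel
is in or out of an ROI by mask value alone; no partial-volume weighting is
applied, because rasterization already decided voxel membership.

Plan acceptance uses three PTV coverage goals at prescription Rx:
V(Rx) ≥ 50%, V(0.98·Rx) ≥ 95%, V(1.10·Rx) = 0% (50.4, 49.392 and 55.44 Gy
at the 50.4 Gy default).

## Trajectory-log analysis

The reference log dialect is plain text: header comments (beam id, sampling
interval, leaf-pair count) and one sample per line in a documented column
order (time; expected/actual cumulative MU; gantry; four jaws; bank A then
bank B leaf positions, expected then actual).  Values are written at 17
significant digits so read→write→read is lossless.  Parsing is strict:
truncated or non-numeric records raise an integrity error naming the record
index, and a decreasing cumulative-MU stream is rejected outright.

MLC error statistics pool *signed* per-leaf differences (actual − expected)
over both banks and all samples; a moving-leaves-only filter is available
but off by default, since a parked leaf's tracking error is still a tracking
error.  MU error statistics default to the mean ± SD of *absolute*
cumulative-MU differences — a delivery-lag magnitude, which is what a QA
report bounds — with a signed variant behind a flag.  Pooling several beams'
logs concatenates their difference samples exactly.

Aperture parameters come from control points: per control point the area
sums, over open leaf pairs (gap > 0.5 mm closed-pair threshold) inside the
jaw window, the x-gap clipped to the jaws times the leaf width clipped to
the jaws; the gap statistic is the unclipped mean gap of open pairs; both
are averaged over control points.  The Millennium-120 layout (40 central
5-mm pairs, 2×10 outer 10-mm pairs) is a named profile; other layouts plug
in via the leaf-width table.  Tolerance checks compare |statistic| against a
caller-supplied table — no tolerance values are hard-coded.

## Setup-error blurring simulation

Residual setup error after image-guided repositioning is modeled as one
static rigid transform per simulation (a residual *systematic* error over
the course, not per-fraction noise).  The default law draws each translation
axis uniformly from [0, 2] mm and each rotation axis from [0, 2]° with
independent random signs; a vector-magnitude-uniform alternative is
selectable because the two laws differ in the tails.  The planned dose is
resampled through each transform — pure isodose-cloud motion, with no
density recomputation, consistent with evaluating geometric misses only —
and D98%/D2% are re-read on the fixed CTV mask.  Results are the
per-simulation signed deviations plus the maxima of their absolute values;
the signed value at the max-|Δ| simulation is also reported.  28 draws per
case is the default, one per fraction of the modeled course.

The mechanism that keeps deviations small is geometric: the plan's
prescription plateau extends the full PTV margin (7 mm) beyond the CTV, so
transforms smaller than the margin leave the CTV inside the plateau, and
rank-based D98% additionally ignores the worst 2% of voxels.  The tests
verify both the bound at 2 mm/2° and its failure at 10–12 mm.

## Daily-dose estimation

The clinical reference engines for CBCT-based delivered dose are full
superposition/convolution algorithms; this package instead declares a
primary-fluence path-length perturbation model, chosen so that every claim
it supports is mechanism-level:

    delivered(v) = planned(v) · Σ_b w_b exp(−μ_eff [d_daily,b(v) − d_plan,b(v)]) / Σ_b w_b

`μ_eff` defaults to 0.0035 mm⁻¹: a 10-MV photon depth-dose curve in water
falls from ~100% near 2.5 cm to ~55% near 20 cm depth, i.e. ≈3.5%/cm, which
this single effective attenuation coefficient reproduces.  The model is
exact for the two dominant anatomical perturbations — a uniform upstream
tissue slab (factor `exp(−μ_eff·t)`) and an upstream gas pocket
(`exp(+μ_eff·t)`) — and identical anatomies reproduce the planned dose
bit-for-bit.  It does not model scatter redistribution, build-up re-entry,
lateral kernel deformation or penumbra changes; accuracy claims are
therefore about direction and first-order magnitude, not engine
equivalence.

Beam geometry: coplanar equispaced gantry angles (7 by default, 9
selectable), equal weights, SAD 1000 mm; gantry 0 places the source
anteriorly.  `radiological_depth` provides the exact divergent-ray line
integral (uniform-step midpoint marching at ≤ half the minimum spacing) for
point queries; whole-volume depth maps treat each beam's rays as parallel to
its central axis — under 2% geometric error for a pelvic volume at 1000-mm
SAD — by rotating the density into the beam frame, accumulating a midpoint
cumulative sum along the ray axis, and rotating back.

Each fraction's density volume is assembled from the CBCT inside the FOV
(CBCT calibration curve) and the registered planning CT outside it
(planning-CT curve) — one HU→density curve per modality, with the CBCT
curve modeled as the planning curve shifted by the CBCT HU offset.  Dose is
recomputed only within the daily body outline (density ≥ 0.5, holes filled,
so gas pockets stay inside the body) expanded by 2 cm, which captures
weight change at the contour; outside that region the planned dose is
copied.  The daily contour is used where the FOV permits and the planning
contour implicitly elsewhere, since outside the FOV the density *is* the
planning CT.

Accumulation sums per-fraction doses in the planning frame (fraction-frame
doses are resampled through the inverse online registration).  Excluded
fractions (e.g. corrupted imaging) are omitted and the sum is rescaled by
n_planned/n_included to stay comparable with the planned course total; the
reference total is reconstituted by summing the per-fraction planned dose
with the same arithmetic, so a perfect course yields exactly zero
difference rather than float residue.  Deformable accumulation consumes
externally supplied displacement fields only (pull-back trilinear sampling,
no Jacobian/energy weighting — the upstream tools do not document one);
no deformable registration is implemented here.  Dice coefficients of
planning vs daily structures quantify geometric agreement; the paired
Student t test (two-sided, α = 0.05) compares planned and delivered metric
series, with the zero-variance case reported as degenerate instead of a
division by zero.

## Synthetic data

The phantom is deliberately minimal — ellipsoids and tubes on a 2-mm grid
(144×144×96 default; a 64×64×48 @ 3 mm variant exists for multi-course
statistics).  Body: elliptic cross-section (axial semi-axes 140×100 mm)
tapered in z, wider than the 26-cm CBCT FOV so stitching is exercised.
CTV: 30-mm sphere at the isocenter; PTV: exact 7-mm Euclidean expansion.
Bladder (r=20 mm, anterior), rectum (r=15 mm tube, posterior), femoral
heads (r=22 mm) and a sacral bone tube are placed disjoint from the CTV at
5-mm clearances.  Tissues: soft 40 HU, bone 700 HU, urine 0 HU, gas
−1000 HU.

The plan dose is `1.02·Rx / (1 + exp((s − 5 mm)/1.25 mm))` with s the
signed distance to the PTV surface: a 2% plateau overshoot keeps V(Rx) at
100% of the PTV while staying far below the 110% ceiling, and the 50% level
sits ~5 mm outside the PTV.  This satisfies all three coverage goals and
places the CTV on a flat plateau — the geometry the setup-error analysis
assumes.

Daily variation (defaults = the modeled study conditions): body semi-axes
drift +0.5 mm/fraction (≈14 mm over 28 fractions, a pronounced belly-size
change) plus N(0, 1 mm) random change; rectal gas pockets with probability
0.15/fraction and radius 8–15 mm; bladder/rectum volume scales N(1, 0.1)
clipped to [0.7, 1.3] (applied as cube-root radius scales); CBCT
degradation +15 HU offset and 20 HU Gaussian noise inside a 260-mm FOV.
Residual setup error defaults to zero in the daily series so the anatomical
component is isolated — the three error sources are analyzed separately,
and the setup-error module owns the rigid component; nonzero magnitudes
image the anatomy in the displaced fraction frame and report the transform
as the registration.  All draws come from one seeded generator, and all-zero
magnitudes reproduce the planning anatomy voxel-for-voxel, which is what
makes the null-course acceptance check exact.

What the generator does *not* emulate: CBCT scatter/cupping artifacts
(handled in reality by calibration, not correction), organ peristalsis,
tumor regression, and any deformation beyond the analytic radial warps.
Passing tests therefore demonstrate the pipeline's mechanics and mechanism
laws, not clinical accuracy on real CBCT.

Trajectory logs sample a sliding-window DMLC delivery at 20 ms, enforcing
the 2.5 cm/s leaf-speed limit on every control-point segment.  Injected MLC
errors are per-leaf Gaussian (bias + sd); the MU delivery lag is exponential
with the configured mean, held constant over 50-sample (1 s) blocks — a
servo-drift timescale that keeps the actual MU stream monotone at realistic
dose rates (~0.2 MU per sample) while preserving the law's mean for
recovery tests.  Zero-parameter models produce actual ≡ expected exactly.

Analytic deformation fields are radial Gaussian bumps
`u(r) = a·exp(−r²/2σ²)·r̂`; magnitudes with `a·e^{−1/2}/σ ≥ 0.95` are
rejected as non-invertible, and the inverse is evaluated by Newton
iteration on the scalar radial map to machine precision, providing an
independent oracle for the deformation code.

## Numerical choices and scale

* Resampling uses scipy's affine path with `prefilter=False` (pure
  trilinear); outputs are clipped at 0 Gy against rounding.
* Trilinear resampling conserves integral dose to ~1e-6 relative for
  band-limited fields with interior support; the test fixture for this
  invariant is a cos² bump chosen to be smooth at the 2-mm grid scale.
* Equal beam weights are normalized by their float sum, so a zero
  perturbation yields a multiplication by exactly 1.0.
* Depth maps step one voxel along the ray axis with midpoint weighting
  (half-voxel self-contribution), exact for piecewise-constant densities.
* The multi-course variance-contraction study runs 20 seeded 28-fraction
  courses on the 64³ phantom with 3 beams — the property (random
  per-fraction errors average out under accumulation) is scale-free, so the
  small grid is used for it.
* The adaptive-replanning report flag marks fractions whose CTV |ΔD98%|
  exceeds a configurable 2% threshold.

## Known limitations

* The dose model ignores scatter, heterogeneity kernel effects and MLC
  transmission; it must not be used for clinical dose reconstruction.
* Only axis-aligned volumes are supported; oblique acquisitions and 4D CT
  are out of scope, as are DICOM writing and treatment-plan optimization.
* Gantry-angle error statistics are not computed (static-gantry DMLC
  delivery is assumed) and no deformable registration is implemented —
  deformation fields are consumed, never produced.
* EUD/NTCP-style biological metrics are not provided.
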