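# Methods

## The model

The hip is treated as an ideal hinge. Its center of rotation is the center
of a sphere fitted to surface samples of the femoral head; its axis — the
flexion–extension axis, equal to the normal of the parasagittal plane — is
a model *input*, not an anatomical estimate. Models built in the
standardised frame (x medio-lateral, y cranial, z ventral, millimetres) use
the +x axis by default; importers of real segmented geometry must either
orient the specimen into this frame or supply `fe_axis` explicitly in the
descriptor.

Each muscle is a straight chord between the centroids of its origin and
insertion attachment patches. Centroids are unweighted vertex means; there
is no via-point routing, no wrapping surface, and no area weighting. For
the biarticular hamstrings the chord runs directly from the pelvis to the
tibial insertion — the knee does not deflect it. These simplifications
match the geometric construction the pipeline is meant to reproduce and
audit, not a physiological muscle model.

The hip extension angle θ is measured between the femur long axis and the
cranial axis within the parasagittal plane, with the 90°(hip)/90°(knee)
configuration as the reference pose. Posing rotates every femur-fixed and
shank-fixed point rigidly by (θ − 90)° about the hinge; because the shank
moves with the femur, the knee stays at 90° by construction throughout the
sweep. The default sweep runs from 20° (strongly crouched) to 160° (nearly
extended) in 10° increments — 15 poses; angles outside this range are
computed with a warning rather than refused, since the range is a
biological convention, not a mathematical limit.

Resting length L0 is the chord length at the reference pose, computed once
when the model is built and cached immutably. A zero-degree hinge rotation
is implemented as a bitwise identity, so the strain at the reference pose
is *exactly* 100% (the strain expression groups the length ratio before
scaling: `100·(L/L0)`).

## Sphere fitting

The fit minimises Σ(|pᵢ − c|² − r²)², which is linear in (2c, r² − |c|²)
and solved by least squares after centering the points for conditioning.
It is deterministic, needs no initialisation, and is exact (≤1e-9) for
noise-free spherical samples; under isotropic noise it tracks the geometric
(orthogonal-distance) fit closely, and the geometric fit is retained in the
test suite as an independent oracle only. Fewer than four points, or a
coplanar configuration, raises a degenerate-geometry error because center
and radius are then not identifiable.

## Moment arms and projection

The 3D instantaneous moment arm is the distance from the hip center to the
nearest point on the muscle's line of action. By default the nearest point
is constrained to the finite origin–insertion segment, mirroring a
nearest-point-on-curve query against the drawn muscle line; `clamp=False`
selects the infinite line, the textbook perpendicular distance. Both are
exposed because the two conventions genuinely differ in strongly flexed or
extended poses, when the perpendicular foot can leave the segment.

An obliquely running muscle contributes to several rotation axes at once.
To isolate the contribution to hip extension, the moment arm is projected
onto the flexion–extension plane. Three projection semantics are
implemented and selectable:

* `vector` (default) — project the moment-arm *vector* (center → nearest
  point) onto the plane and report its length; the most literal reading of
  projecting a measured moment arm;
* `inplane` — project the joint center and the line of action into the
  plane first, then take the 2D distance;
* `axis` — the torque-per-unit-force magnitude `|((p − c) × û)·n̂|`, which
  for a hinge equals the tendon-excursion moment arm |dL/dθ|.

All three coincide for planar configurations (regression-tested) and none
can exceed the 3D moment arm. Magnitudes are reported; the sign of the
axis scalar (extensor vs flexor action) is recoverable from the geometry
but not a column of the output.

## Normalization and strain band

Lengths and moment arms are divided by body mass^0.33 (the printed
exponent 0.33 rather than 1/3, configurable) to compare specimens of
different size; mass is stored in grams and normalization is unit-consistent
as long as every model in a comparison uses the same unit. The optimal
strain band is 85–115% of resting length, bounds inclusive; strains below
are classified `suboptimal_short`, above `suboptimal_long`.

## The synthetic generator

The generator emulates what segmentation of a stained micro-CT scan hands
to the pipeline: bone surface meshes, attachment patches, and femoral-head
surface samples — with exact ground truth. Bones are analytic solids (an
ellipsoid pelvis, capped-cylinder long bones, an icosphere head), because
the pipeline only consumes surfaces and analytic solids admit exact
oracles. Default dimensions are callitrichid-scale: pelvis 30 mm, femur
35 mm, tibia 38 mm, head radius 3.5 mm, body mass 450 g, with cohort masses
spanning 350–620 g of the roughly 120–700 g range of the family.

Each attachment is realised as a small "tuberosity" fan of mesh vertices
placed symmetrically around the designed attachment coordinate, so the
patch centroid reproduces the designed point exactly and noise-free
geometry round-trips through OBJ at full precision (meshes are written with
17 significant digits). Head samples follow a deterministic Fibonacci
sphere; optional Gaussian noise and attachment jitter are seeded.

Attachment placement encodes the qualitative anatomy the pipeline is
expected to resolve:

* The gluteals originate on the lateral iliac face and insert on a short
  trochanteric offset that points dorso-caudally at the reference pose.
  Origin and insertion share the same lateral offset, so the muscle runs in
  a lateral parasagittal plane; its projected moment arm then rises
  monotonically with extension until the perpendicular foot reaches the
  insertion, after which the moment arm equals the (constant) center-to-
  insertion distance — a rise-then-plateau curve, never decreasing.
* The hamstrings originate on the ischial region well *medial* of the
  lateral hip joint and insert on the tibia. The medio-lateral offset is
  load-bearing: for a purely planar hinge geometry, a segment-clamped
  moment arm can mathematically never decline after its maximum (it
  saturates at the center-to-endpoint distance), so the declining limb of
  the observed bell-shaped hamstring curves is a genuinely 3D effect of
  medially offset origins. With the default offsets the projected moment
  arm peaks at 110–130° and declines towards both sweep ends.
* The semitendinosus insertion slides along the tibial shaft via a
  dedicated fraction parameter (default 0.37 of tibia length from the
  knee), allowing the "insertion toward the center of the tibial shaft"
  variant.

Morphotype presets scale the trochanteric radius and the ischial reach:
`trunk_leaper` ×1.25, `generic` ×1.0, `horizontal_leaper` ×0.8 — larger
offsets mean longer moment arms (torque), smaller offsets shorter ones
(velocity). They are illustrative placements encoding that contrast, not
inferred species anatomy.

What the generator does *not* emulate: realistic bone shape, attachment
areas with anatomical outlines, curvature-following muscle paths, soft
tissue, or segmentation noise. Passing tests on synthetic models therefore
validate the *computational* pipeline — geometry, posing, measurement,
normalization, I/O — not the fidelity of any particular anatomical
reconstruction.

## Sensitivity analyses

* **Placement repeatability** — every origin and insertion centroid is
  displaced by an isotropic Gaussian offset (default σ = 0.5 mm, small
  against 30–40 mm bones; the manual re-placements being emulated have no
  published error model) and re-projected onto the bone surface by an exact
  closest-point-on-triangle query; the sweep is recomputed per replicate
  (default 5). σ = 0 leaves the model bitwise untouched, so dispersion is
  exactly zero and a single σ=0 replicate equals the baseline sweep.
* **Mass perturbation** — the sweep is recomputed with mass·(1+f) for
  f ∈ {−0.20, −0.10, +0.10, +0.20}. Geometry is untouched; normalized
  values scale by the analytic factor (1+f)^−0.33, which the implementation
  reproduces to ~1e-16 relative (asserted at 1e-12).
* **Origin shift** — the chosen origin (default biceps femoris) is
  translated along the pelvis principal axis (largest principal component
  of the pelvis vertex cloud, oriented cranially — a reproducible stand-in
  for "along the bone") by f·pelvic length, snapped back to the nearest
  pelvis surface point, and the sweep rerun. Shifts that leave the pelvis
  bounding box warn and snap anyway.

Reports carry per-(muscle, angle, quantity) mean/sd/min/max across
replicates or levels and are bit-reproducible from (model, spec, seed).

## Numerical choices

* Degrees at every interface, radians internally; millimetres throughout.
* Rotations use the Rodrigues formula; the zero-angle case returns its
  input bitwise (reference-pose exactness).
* The sphere fit centers the data before solving; rank < 4 in the linear
  system raises rather than returning a garbage sphere.
* Segment parameters are clamped to [0, 1]; coincident segment endpoints,
  coincident attachment centroids, and non-positive masses/lengths raise
  immediately with the offending entity named.
* CSV outputs store floats at 17 significant digits and carry a `#`
  provenance header (tool version, config hash, seed, fitted sphere).
  Headers contain no timestamp: equal configurations must produce
  byte-identical files.
* Descriptor vertex indices are 0-based; OBJ's on-disk 1-based indices are
  converted by the reader, and meshes are loaded with vertex order
  preserved (no merging or reprocessing), since patches address vertices
  positionally.

## Known limitations

* The hinge model ignores the other degrees of freedom of a real hip;
  abduction/adduction and long-axis rotation components are projected away
  rather than modelled.
* Straight-chord muscles underestimate lengths (and distort moment arms)
  wherever a real muscle wraps bone or passes retinacula.
* The flexion–extension axis is supplied, not estimated; misorientation of
  an imported specimen propagates directly into the projected values.
* Attachment centroids compress an attachment area to a point; the
  placement-jitter analysis quantifies, but does not remove, the resulting
  sensitivity.
* Bone "effective lengths" default to the maximum pairwise vertex distance
  when not supplied explicitly — a caliper length, which can exceed an
  axis-projected anatomical length.
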