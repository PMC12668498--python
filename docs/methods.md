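# Methods

This note documents the models, conventions, numerical choices and known
limitations of scolimorph, in the package's own terms.

## Frames, units and angle conventions

All geometry is millimetres; masses are kilograms; the osim writer converts
to metres/radians on output.  The **model frame** is +X anterior, +Y superior
(inferior→superior), +Z toward the subject's right, with the sacral apex at
the origin.  Landmark files may declare their own axis convention with a
`# axes: <code>` header, three letters from {A,P,S,I,R,L} naming the
anatomical direction of the file's +X, +Y, +Z axes (e.g. `RAS`); alignment to
the model frame is the corresponding signed-permutation rotation plus the
translation that maps the user-supplied sacral apex to the origin.  The apex
is an explicit input rather than an estimate because it is frequently outside
the imaged field of view; choosing a different fixed reference point only
shifts the global origin.

Sagittal *pitch* of a direction `v` is `atan2(v_y, v_x)`, positive above the
horizontal.  **Lumbar lordosis** is the sacral slope minus the pitch of L1's
anterior (AP) axis; positive is lordotic, a kyphotic lumbar segment yields a
negative value.  The **Cobb angle** is the frontal-plane projected angle
between the right–left axes of the two end-vertebra body frames (the
classical endplate-line definition re-expressed through body frames), always
reported ≥ 0.  A projected angle is invariant to rigid rotations *within* the
frontal plane but not to arbitrary 3-D reorientation, so models are assessed
in the model frame, which the alignment step guarantees.

## Landmark protocol

Each vertebra carries 14 landmarks — 8 scaling + 6 joint — with the mapping
S1/S2 = anterior/posterior-most point of the superior endplate, S3/S4 = the
same on the inferior endplate, S5/S6 = right/left-most of the superior
endplate, S7/S8 = right/left-most of the inferior endplate, JM1/JM2 = right
pedicle top/base, JM3/JM4 = left pedicle top/base, JM5/JM6 =
superior/inferior endplate centre.  The mapping is fixed in
`scolimorph.landmarks` and documented so users with a different palpation
protocol can remap codes before constructing a `LandmarkSet`.  The sacrum
carries SP_ANT/SP_POST on the anterior/posterior-most promontory points.

## Geometric primitives

**Sphere fitting** minimises the geometric objective Σᵢ(‖pᵢ−c‖−r)² with a
Levenberg–Marquardt refinement (`scipy.optimize.least_squares`, ftol 1e-10,
≤ 1000 function evaluations) started from the algebraic Kåsa solution.
Inputs of fewer than four points, or points whose smallest singular value is
below 1e-9 of the largest, are rejected as coplanar.  The fit is exact on
noiseless spheres and rotation/translation-equivariant to 1e-9.

**Anterior-surface selection** is an automated surrogate for manual node
picking: a vertex is selected when its AP coordinate in a hint frame exceeds
the (1−fraction) quantile over the mesh *and* its outward normal has a
positive AP component.  The fraction defaults to 0.35 and is exposed in the
API; at least 10 vertices must survive.  Selection is deterministic for a
fixed mesh and hint.

**Body frames**: IS is the unit vector from the inferior- to the
superior-endplate landmark mean; the provisional AP direction is the mean of
the two endplate midline (posterior→anterior) vectors; RL completes the
right-handed triad and AP is re-orthogonalised against IS.  IS is kept exact
because it anchors the frame hierarchy; the residual obliquity is absorbed by
AP.

**Joint poses** (6 DoF each): origin at the midpoint of the facing endplate
centres (JM5 of the caudal vertebra, JM6 of the cranial one); RL from the
unit pedicle right-minus-left vectors of the two vertebrae, averaged (an
exact bisector); AP from the mean facing-endplate midline direction projected
perpendicular to RL; IS completes the triad and its sign is chosen so it
points from the caudal toward the cranial endplate centre — an intrinsic
convention that keeps the construction rotation-equivariant.  The joint AP
axis uses the midline *scaling* landmarks of the facing endplates (S1–S2 and
S3–S4) because the joint-landmark group alone contains no anterior midline
direction.  At the lumbosacral joint the sacral plate is represented by the
promontory landmarks.  The historical alternative of intersecting the
endplate-centre lines is not used: two lines in 3-D generically do not
intersect, so the midpoint definition is the only well-posed one.

## Morphing workflow

Scaling factors per vertebra are ratios of subject-to-model Euclidean
distances between landmark means: AP between mean(S1,S3) and mean(S2,S4), IS
between the superior and inferior endplate means, RL between mean(S5,S7) and
mean(S6,S8).  Scaling acts about the body origin along the body axes on the
mesh, markers, attached muscle points and the wrap sphere; the **wrap sphere
is refit to the scaled mesh** rather than scaled analytically, because an
anisotropically scaled sphere is an ellipsoid.  The sacrum is never scaled.
All body masses are multiplied by subject mass / template total mass, so the
scaled model's total mass equals the subject mass (default 75 kg).  Muscle
attachment coordinates scale with their body — a modelling choice, flagged
here, rather than a re-derivation from muscle anatomy.

Sacrum alignment is a pure sagittal rotation (about the global RL axis,
centred on the sacral apex) matching the promontory pitch to the subject's
sacral slope; the vertebral chain follows the rotation, the pelvis does not.
The operation is idempotent.

Vertebra realignment sets each body pose so the frame computed from its own
(scaled) markers coincides with the frame computed from the palpated
landmarks.  Because the same frame construction is applied to both sides,
morphing the template with its own landmarks is exactly the identity, and
re-palpating a morphed model and morphing again is idempotent — both are
enforced as tests at 1e-6 mm / 1e-6 rad.

Bushing realignment re-seats both frames of each bushing on the final joint
pose, making all six generalised deflections zero at the constructed pose
(no stiffness preload).  Deflections are measured as child-frame translation
in parent-frame axes (converted to metres) and the rotation vector of the
relative orientation; forces follow the linear spring law per DoF, e.g. a
1 mm anterior shear with default stiffness gives 149 N and 0.01 rad of
flexion gives 0.51 N·m.

The osim writer emits OpenSim 4.x-dialect XML: each joint is a `CustomJoint`
whose spatial transform lists rotations in Z–X–Y order (flexion–extension,
lateral bending, axial rotation) followed by X/Y/Z translations, with both
joint frames at the morphed joint pose so every coordinate default is zero;
bushings are `BushingForce` elements on those frames; wrap spheres, markers
and muscle path points ride on their bodies.  Element order is deterministic
and a structural validator (`validate_osim`) checks the dialect.  The JSON
serialisation is lossless and is the round-trip format.

## Synthetic data: what it emulates and what it does not

The generator fabricates the entire study bench.  Vertebral bodies are
*barrel* meshes — a sphere zone of radius `hypot(AP/2, IS/2)` about the body
centre with flat endplate caps — plus a posterior box standing in for
pedicles and processes.  With the default circular cross-section (AP = RL)
the anterior surface is exactly spherical, so sphere-fit centres coincide
with the true body centres and centre-recovery tests measure the pipeline,
not an uncontrolled mesh-fitting bias.  Landmarks are placed analytically on
the mesh surface; endplate-rim spans equal the nominal dimensions exactly.
Default dimensions grow linearly from T1 (24×16 mm) to L5 (36×28 mm) with
disc heights of 4–8 mm — round numbers in the anatomical range.

Scoliotic subjects compose per-level rotations `R = Rz(ψ)·Rx(φ)·Ry(axial)`
(sagittal pitch, frontal tilt, axial rotation).  The frontal profile is a
sine over the main curve — end vertebrae maximally tilted (±φmax), apex
untilted — with linear decay on the flanks, which yields the classic C-curve
whose lateral displacement peaks at the apex; φmax is calibrated by scalar
root finding (`brentq`) so the *measured* projected Cobb angle between the
end-vertebra frames equals the target exactly.  The sagittal profile ramps
the lumbar pitch so L1's pitch equals (sacral slope − target lordosis),
making the measured lordosis exact by construction.  The default subject
(Cobb 75° over T12–L4 with apex L2, supine lordosis 34°, sacral slope 27.7°,
75 kg) represents a severe adult lumbar scoliosis; the template sacral slope
is 40°, so sacrum alignment performs a −12.3° rotation.  The generator
stores the achieved (measured) angles, frames, centres, rotations and scale
factors as ground truth.

Palpation panels add, per observation, a fixed per-operator bias
(SD 0.45/0.85/0.25 mm per axis), independent noise (SD 1.0/1.2/0.65 mm), and
with probability 0.02 an outlier of 5.2–10.3 mm directed with the same
anisotropy as the noise (mis-identified endplates displace mostly along IS);
the total perturbation is capped at 10.3 mm.  The free parameters (bias SD,
outlier rate) were calibrated once so that the pooled per-axis mean
displacements of a default 5-operator × 3-repeat panel centre on
0.95 / 1.19 / 0.61 mm (AP/IS/RL) with ~2 mm Euclidean spread — the scale of
variability reported for manual palpation of a severely scoliotic spine.
Because only five operator biases are drawn per panel, a single panel's mean
displacement has a sampling CV of roughly 10–30%; panel-emulation checks
therefore average six independent panels and the tolerance (15%) applies to
that average.

What passing these tests does *not* show: real vertebrae are not barrels
(sphere fits on real anterior surfaces carry a shape-dependent bias), real
palpation errors are not Gaussian or independent across landmarks, real
templates differ anatomically from subjects (the synthetic subject is a
deformation of its own template, which removes template–subject shape
mismatch, the dominant error source in practice), and supine-to-standing
posture change is not modelled.

## Variability statistics

Displacements are observation minus marker mean, per axis (signed, summing to
zero within markers) and as the Euclidean norm; summaries are reported per
operator/repeat and pooled.

**ICC(2,1)** (two-way random effects, absolute agreement, single measurement)
is computed from the ANOVA mean squares, with the standard F-based 95%
confidence interval; a zero-variance matrix raises an error instead of
silently returning 1.  The implementation is cross-checked in the tests
against both a brute-force decomposition and `pingouin.intraclass_corr`.

The **unbalanced Friedman test** is implemented as the Skillings–Mack
statistic: within each block the observed groups are mid-ranked, centred
ranks are scaled by √(12/(c+1)), summed per group, and the quadratic form
with the pseudo-inverse of the incidence covariance is referred to χ² with
df = rank of that covariance.  On balanced complete data without ties this
equals the classical Friedman statistic to machine precision.  Replicates
within a (group, block) cell are averaged before ranking.  The χ²
approximation is conservative at small panel sizes (null rejection ≈ 2–4% at
30 blocks × 5 groups), which the calibration test accounts for by asserting
the binomial 99% band around 5% rather than 5% exactly.

**One-to-many Nemenyi** comparisons standardise the summed within-block rank
difference between each group and the control over the blocks where both are
observed, z = |Σ(r_c − r_g)| / √(Σ c(c+1)/6), reducing to the classical
many-to-one z on balanced data.  Significance is z ≥ a caller-supplied
critical value (2.728 and 3.164 are the conventional inter-/intra-operator
choices for these design sizes); tier codes use the conventional p-value
brackets (*** ≤ 0.001, ** ≤ 0.01, * ≤ 0.05, . ≤ 0.1).  The omnibus test is a
warning gate, not a hard one.  The D'Agostino skewness test and Shapiro–Wilk
normality checks are available for gating reports; they never silently switch
methods — the nonparametric path is always the one used.

## Problem sizes and numerical tolerances

Default spines span T9–L5 (9 vertebrae, 128 landmarks, ~300 vertices per
body mesh); panels are 5 × 3 × 128 observations; oracle checks use 200-point
sphere clouds, 12 × 4 rating matrices, 30-block Friedman panels and 200 null
replicates — sizes at which every check runs in seconds while the estimators
are already in their asymptotic regime.  Identity and recovery checks use
1e-6 mm/rad; oracle-equality checks 1e-10; stochastic emulation 10–15% as
discussed above.  Rotation matrices are validated orthonormal to 1e-8–1e-9;
frame degeneracies (coincident means, parallel axes) raise typed errors.

## Known limitations

* The template bundled here is schematic; results on real anatomy depend on
  the user-supplied template's fidelity.
* The 6-DoF joint/bushing model is linear; no nonlinear disc behaviour.
* No rib cage, no muscle force or dynamics simulation — files are written
  for OpenSim, not executed.
* Apex detection uses frontal-plane displacement from the sacral-apex
  vertical only; double curves report the single largest-displacement level.
* The osim dialect targets OpenSim 4.x but is validated structurally, not by
  an OpenSim runtime.
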