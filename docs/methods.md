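# Methods

This note documents the models, parameters and numerical choices behind
`postop3d`, and what the synthetic phantom does and does not establish.

## Coordinate conventions

A `Volume` is a 3D scalar grid with `world = origin + axes · (spacing ⊙
index)`; indices are 0-based and address voxel **centers**. All geometry
(planes, transforms, screw axes) lives in world millimetres, so every
operator is invariant to anisotropic voxel spacing. The anatomical
convention is configurable and defaults to +x = left, +y = posterior,
+z = superior; the phantom is generated in this convention and the screw
head axis defaults to superior (+z).

Rigid transforms are 4×4 homogeneous matrices with proper rotations and
map **pre-image world coordinates into post-image world coordinates**;
resampling uses the inverse. ITK's convention (fixed → moving) is the
inverse of this, which the registration wrapper handles internally.

## Phantom generator

The phantom emulates the geometric and statistical structure the pipeline
relies on, not pelvic anatomy:

* **Body**: a union of three overlapping ellipsoids (bone, default
  700 HU) on a soft-tissue background (40 HU). The pipeline's operators
  are geometry-generic, so an anatomical shape model would add nothing to
  what the tests can show.
* **Trabecular texture**: a smooth random field (40 cosines, wavelengths
  10–40 mm, sd 200 HU) that is a function of *anatomy* coordinates — it
  moves with the fragment. Intensity-based registration needs internal
  structure to lock onto; homogeneous bone would make the normalized
  correlation degenerate. The amplitude is in the range of real
  trabecular HU variability; the wavelengths are long enough that the
  correlation basin covers the fragment displacements being simulated.
* **Cuts**: four planes forming a jittered tetrahedron of inward
  half-spaces around a fragment center; inradii 12–18 mm (scaled with the
  field of view). The fragment is the body region strictly inside all
  four half-spaces.
* **Callus**: each cut interface patch extruded symmetrically ±2 mm along
  its plane normal (4 mm total width, roughly the cut gap plus early
  callus at a ~15-week follow-up), labelled 1–4 and given bone+150 HU.
  The membership test is evaluated at the projection of each point onto
  the plane, so the labelled prism is exactly symmetric about the true
  plane: its centroid lies on the plane and its smallest principal axis
  is the plane normal up to voxel sampling. How callus intensity really
  evolves with healing is patient- and time-dependent; these values are
  configuration, not claims.
* **Transforms**: the fragment moves by 5–15° / 3–10 mm about its
  centroid, and the whole scene by an additional scanner offset of
  2–8° / 1–6 mm between pre and post acquisition — follow-up CTs are
  never acquired in the same frame. `truth.fragment_transform` is the
  full pre→post fragment map; `truth.fine_transform` the residual after
  the coarse alignment.
* **Screws**: 4 capsules (radius 2 mm, length 40–80 mm) running from
  fixed bone into the fragment within 25° of superior, with a minimum
  inter-axis distance of 6 mm (screws close together is the hard case for
  line detection). Metal is 3000 HU; with the default 20 HU noise the
  >2500 HU threshold isolates exactly the screws.
* **Masks**: the oracle pelvis masks mirror what a threshold-based bone
  segmentation yields — mineralized bone only, excluding immature callus
  and metal. This matters: callus bridges the cut and carries fixed-bone
  intensity, so including it in the fragment registration mask biases the
  metric optimum away from the true fragment transform (several mm in
  early experiments); excluding metal matters for the same reason, at
  larger amplitude.
* **Noise**: i.i.d. Gaussian, default sd 20 HU, independent between pre
  and post. Generation is bit-deterministic per seed (separate spawned
  RNG streams for scene and noise), and plane draws that fail to isolate
  a closed fragment are redrawn (error after 20 attempts).

What the phantom does **not** model: CT physics (beam hardening, metal
artifacts, partial volume), anatomical shape variability, soft-tissue
structures, and deformable anatomy changes. Passing tests therefore
demonstrate the correctness and internal consistency of the algorithms
under known geometry — not clinical segmentation or registration accuracy.

## Cut detection

The segmenter is a five-block 3D U-Net (3×3×3 convolutions, leaky ReLU
slope 0.1, 2×2×2 max pooling, filters 16→256 doubling per block,
nearest-neighbour upsampling with skip concatenation, 1×1×1 head). The
cut network uses a softmax over 5 channels and the weighted categorical
cross-entropy with default class weights [10, 270, 260, 270, 260]
(background vs the four rare cut classes); the loss index runs over
classes per voxel and is averaged over voxels (the sum-vs-mean choice
only rescales the learning rate). The binary pelvis segmenter reuses the
same architecture with a sigmoid head and the Dice-CE loss
`(1−α)·L_CE + α·(1−softDice)`, α = 0.5. Learning-rate schedules: 1e-4
for epochs 0–10 then 1e-5 (cut network); 1e-4 / 1e-5 / 1e-6 at epochs
20 and 30 (pelvis network); Adam; probabilities clipped at 1e-7.

The network, backpropagation and Adam are implemented in numpy (im2col
matmuls); the architecture is resolution-agnostic and the package trains
it at desk scale (20 cases at 32³, ~1 min/10 epochs on one CPU). The
empirical class weights were tuned on clinical data originally; they are
defaults, overridable per `SegmenterSpec`.

Because trained weights are not shipped, the geometric pipeline is fully
testable through the **oracle backend**, which replays phantom labels —
this backend is first-class, not a test shim.

Plane fitting is plain PCA (eigh of the point covariance). The normal's
sign is left unresolved at fitting time and fixed by orienting toward the
joint-center approximation (mean of the four plane centers) in the
repositioning stage. Fits with fewer than 3 voxels or rank < 2 raise a
degenerate-input error; `detect_planes` flags per-plane failures and
returns the remaining planes.

## Repositioning

Registration is ITK's framework via SimpleITK: normalized correlation
metric restricted to a fixed-image mask, regular-step gradient descent
over a versor-parameterized rigid transform. Hyperparameters (exposed in
`RegistrationParams`): coarse — 200 iterations, translation scale 1/2000,
rotation scale 1, max step 1, min step 0.001; fine — translation scale
1/500, max step 0.7, min step 0.0001. The metric uses full in-mask
sampling by default, which makes optimization deterministic; fractional
sampling is available for speed. The gradient-magnitude stop tolerance is
set effectively to zero so termination is governed by the step-size
bounds, and the rotation center is the mask centroid (required for the
stated translation scales to be meaningful). The coarse stage is
initialized by aligning the pre/post pelvis-mask centroids when a
preoperative mask is available, identity otherwise.

Design choice on mask frames: the fragment mask is built from the
**postoperative** pelvis mask intersected with the oriented-plane
half-space rule. The post mask covers the fragment where it actually is,
and the postoperative segmentation (trained to be robust to implants) is
the natural source; resampling the preoperative mask through T1 is an
alternative reading that leaves the mask centred on the fragment's *old*
position and performed worse. The voxel-on-plane boundary uses the strict
inequality `> 0`.

The reported `metric_value` is the plain Pearson correlation at the
optimum (ITK's internal value is its negative square). Convergence is
flagged from the optimizer's stop condition (step below `min_step`).

## Implant quantification

Directions are the vertices of a level-4 subdivided icosahedron restricted
to one hemisphere (1281 directions, ~1.3° resolution; the level is
configurable). Anchors are discretized with step `dx` in the plane
through the origin orthogonal to each direction; voting is a dense
`directions × anchor-cells` array rebuilt per iteration over the
remaining points. The point-to-line assignment radius reuses `dx`, which
keeps the parameter surface to the three documented knobs (`nlines`,
`minvotes`, `dx` = 6, 50, 3 mm by default). After taking the global vote
maximum, the line is refined twice by orthogonal regression
(centroid + principal eigenvector) with re-assignment; a line must reach
`minvotes` both in the voting array and in refined supporting points.
Detected directions are stored sign-canonically on one hemisphere, so
results do not depend on point order.

The entry point is the **center of the last foreground voxel** of the
contiguous run containing the start (sub-voxel refinement of the face
crossing would exceed what the detection geometry supports); rays that
exit the grid while still in foreground return the last in-grid voxel
with an `out_of_field` flag. If a line's center of mass falls on a
background voxel (possible between thread ridges), the trace starts from
the nearest cloud point instead.

## Evaluation geometry

Landmarks: P1 (most superior surface point on plane 1), P2/P3 (most
medial points on the plane-1∩2 and plane-2∩3 intersection lines), P4/P5
(most anterior / posterior surface points on planes 3 / 4). "Surface on
plane" uses a half-voxel-diagonal tolerance band (0.87 mm at 1 mm
spacing); intersection lines are clipped to the surface bounding box
before taking extrema (an infinite line has no extremum), and "medial"
is minimal |offset| from the surface's midsagittal plane along the left
axis. Near-parallel planes (|n_a × n_b| < 1e-3) and empty bands are
flagged rather than silently guessed.

P1–P4 are projected onto their least-squares plane PL (same PCA fit);
SR = angle(V1, V2) and RI = angle(V2, V3) of the connecting vectors.
Plane-normal comparisons are sign-agnostic (`acos |n_a·n_b|`).
Registration error is the mean Euclidean distance between corresponding
surface points under the two transforms (errT1 whole pelvis, errT2
fragment residual, errT12 full composition). Screw correspondence is
greedy mutual-nearest on entry points with a 10 mm gate.

## Problem sizes and determinism

Default phantom: 96³ voxels at 1 mm (a cropped hip-region field of view);
the scene scales with the field of view so smaller/larger grids remain
valid. Tests and the acceptance script use 10-seed cohorts at this size,
and train the U-Net on 20 cases at 32³ for 10 epochs — sizes chosen so
the whole suite runs in minutes on one CPU while still exercising every
code path at realistic parameter values. Oracle-backend pipeline runs are
byte-deterministic under a fixed seed (seeded RNG streams, full-sampling
registration, sorted-key JSON); training is deterministic given seed and
backend.

## Known limitations

* Clinical accuracy figures cannot be established here: phantoms are far
  cleaner than postoperative CTs (no metal artifacts, no segmentation
  noise, exact labels). Recovery errors on phantoms are accordingly much
  smaller than published clinical errors.
* The network backends are trained only at desk scale; shipped code, not
  shipped weights.
* Screw detection assumes line-like implants; plates and prosthesis heads
  would need different Hough shape features.
* `nlines` bounds the number of detectable screws; behaviour when the
  true count exceeds it is untested.
* DICOM ingestion, metal-artifact reduction and deformable registration
  are out of scope.
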