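# Methods

## Problem and pipeline

The package reconstructs a dense 3D left-atrium (LA) segmentation from a
sparse endocardial point cloud of the kind recorded point-by-point during
catheter ablation.  The reconstruction is learned: paired (cloud,
segmentation) examples are produced by a deterministic geometric pipeline,
and a 3D convolutional network maps a voxelized "partial shell" of the
cloud to the full chamber.  This note documents the models, the parameters
that matter, the numerical choices, and what the synthetic experiments do
and do not demonstrate.

## Synthetic anatomy

Clinical paired data are not redistributable, so training and evaluation
use a constructive-solid-geometry stand-in with the topology the pipeline
relies on: an ellipsoidal chamber body, four tubular pulmonary veins (PVs)
in left/right × superior/inferior configuration, and an optional
hemispheric appendage bulge.  The implicit union is evaluated at voxel
centers on an isotropic grid.

Key parameters (`SyntheticConfig`):

- `body_radii_mm` — ellipsoid semi-axes.  Default (22.5, 19.0, 15.5) mm.
  This is deliberately smaller than a typical clinical LA (~50 cm³): the
  default is sized so that the number of surface voxels at 0.625 mm
  (~12,400) makes the default point count and coverage mutually consistent
  — 3,703 points covering ≈30% of the surface, the regime the pipeline is
  designed for.  With a full-size LA, 3,703 points cannot cover 30% of a
  0.625 mm surface; coverage statistics drive the accuracy analysis, so
  they take precedence over absolute chamber size.
- `pv_radius_mm` (4 mm), `pv_length_mm` (10 mm) — vein tubes, attached at
  the ellipsoid surface along four fixed directions with a small per-seed
  random tilt (≤6°).
- `n_points` (3,703), `coverage_fraction` (0.30), `noise_sd_mm` (1.0) —
  catheter emulation: the candidate set is the `coverage_fraction` of
  surface voxels angularly closest to a random patch direction (a
  spherical-cap window, matching the contiguous blind spots of clinical
  maps); `n_points` candidates are drawn without replacement and jittered.
  Requesting more points than the window contains is an error.
- PV landmarks are placed on the surface voxel nearest each ostium center
  (the axis point itself lies inside the vein lumen and would violate the
  requirement that landmarks sit on the chamber surface).

A coarse profile (`DESK_PROFILE`: 1 mm spacing, radii (16, 13, 11) mm,
650 points) exists for CPU-scale experiments; cohort generation
(`make_cohort`) jitters radii ±10%, randomizes the appendage, and sets the
per-case point count to the target coverage times the measured surface
voxel count.

What the generator does **not** emulate: wall thickness and fibrosis,
mitral-valve anatomy, electrogram amplitudes, non-surface (interior)
points, and the irregular vein branching of real anatomy.  Passing tests
therefore demonstrate the pipeline's correctness and its coverage-accuracy
behaviour on body-plus-veins topology, not clinical-grade accuracy on
patient data.

## Registration

The four PV landmarks, matched by label, determine a similarity transform
x ↦ s·R·x + t via the closed-form least-squares solution: center both
landmark sets, take the SVD of the cross-covariance for R (with sign
correction so det R = +1; reflections are never returned), and obtain the
isotropic scale from the variance ratio.  This closed form is the global
optimum for the similarity family, replacing any sequential
center/rotate/scale search.  Collinear or coincident landmark sets leave
the rotation under-determined and raise an error (detected by the second
singular value falling below 1e-9 relative to the first).  Scale is
isotropic — a single scalar — since nothing in the problem distinguishes
axes at this stage.

## Projection

Registered clouds only approximately match the target anatomy, so each
point is replaced by the intersection of the ray from the mask's center of
mass (COM) through the point with the mask's **outer** surface.  Rays are
marched at spacing/2 steps with trilinear interpolation of the binary mask;
the outermost 0.5-crossing is located and refined by linear interpolation
within the bracketing step.  Choosing the outermost crossing puts points on
the endocardial shell even when a ray crosses a vein twice.  Points whose
ray never enters the foreground cannot be projected; they are dropped and
counted (with an interior COM this does not occur — every such ray exits
through the surface).  A COM outside the mask (e.g. a hollow or concave
shape) makes the construction ill-posed and raises an error.

## Shell building

The alpha-concave hull of a point set is the boundary triangulation of its
alpha complex: the Delaunay tetrahedralization filtered to simplices with
circumradius ≤ α.  α is a length in mm (default 5); circumradii are
computed vectorized from the 3×3 linear system for each tetrahedron's
circumcenter, with degenerate (near-zero-volume) simplices assigned
infinite radius.  If no simplex survives, the error names the smallest
circumradius found.  Note one degeneracy: points lying *exactly* on a
common sphere give every tetrahedron that sphere as circumsphere, so a
small α retains nothing; voxel-snapped or jittered surface samples (the
practical inputs) do not have this property.

Densification iterates: build the hull, insert the midpoint of every
unique edge, recurse.  "Every edge" defaults to all edges of the retained
alpha-complex simplices; measured growth on well-sampled surfaces is
~6-8× per iteration, so three iterations turn ~4,000 samples into well
over 250,000.  Using only boundary-triangulation edges is available as an
option but grows slower (~3-4× per iteration, decaying as inserted points
get buried inside the complex slab and leave the boundary), which is too
slow to reach the several-hundred-thousand-point regime in three
iterations.  `points_per_edge` > 1 inserts evenly spaced points instead of
midpoints.

Discretization maps world coordinates to voxels by floor((x − origin) /
spacing) and marks only point-containing voxels — densification, not face
rasterization, is what closes gaps.  The volume is cropped/padded about
the foreground bounding-box center to a standard shape (128×208×88 at full
resolution; 64×64×48 in the desk profile).  For training pairs the crop is
centered on the *label's* bounding box so input and label stay aligned in
one frame; an oversized bounding box is an error.

## Network

A fully convolutional residual encoder-decoder with, at the default
width 8 / 4 levels / 5×5×5 kernels:

- encoder: residual conv groups of (1, 2, 3, 3) convolutions at widths
  (8, 16, 32, 64), each convolution followed by batch normalization, PReLU
  (one learnable slope per channel, init 0.25) and channel-wise dropout;
  2×2×2 stride-2 convolutions double the width between levels;
- a bottom residual group of 3 convolutions at width 128;
- decoder: 2×2×2 stride-2 transpose convolutions, concatenation with the
  matching encoder feature at four points, residual conv groups at widths
  64 → 32 → 16 → 16;
- a final 1×1×1 convolution to 2 channels and per-voxel softmax.

That is 30 convolutional layers (12 encoder + 4 down + 4 up + 9 decoder +
1 output).  Residual skips add the group input to the group output, with a
1×1×1 projection exactly where the channel count changes (level entries
and post-concatenation groups); projections change no spatial shape.

Odd spatial extents are zero-padded by one before each down-convolution
and cropped again after the matching up-convolution, so *any* input shape
yields an equal-shaped output — including 128×208×88, whose depth (88) is
not divisible by 2⁴.

The layer library is numpy: stride-1 convolutions run as chunked im2col
(k³ strided block copies) + BLAS GEMM; the non-overlapping 2×2×2 stride-2
down/up convolutions reduce to single reshaped GEMMs; backward passes are
explicit (input gradients via convolution with the flipped, transposed
kernel).  With batch size 1, batch normalization reduces to per-sample
(instance) statistics; the same per-sample statistics are used at
inference, keeping predictions deterministic and batch-free.  Dropout is
channel-wise (spatial) dropout after each activation.  Gradient
correctness is verified against finite differences in the test suite.

## Training

Loss: the smoothed dice coefficient F(p,g) = (2Σpg + 1)/(Σp² + Σg² + 1)
with sums over all voxels and the smoothing constant fixed at 1, minimized
as 1 − F on the foreground softmax channel.  Optimizer: ADAM with lr 1e-4
and β = (0.9, 0.999) by default; batch size 1; training order reshuffled
every epoch from the seeded generator.  After each epoch the mean dice of
the thresholded (argmax) prediction on the validation set is recorded —
thresholded rather than soft, to match test-time evaluation.  Training
stops at `max_epochs` (default 1000) or after `patience` (default 50)
epochs without validation improvement, and the weights of the best
validation epoch are restored.  Non-finite losses abort with epoch/step
context.  Pre-processed pairs can be cached to HDF5 (`shells`/`labels`
uint8 datasets) with bit-exact reload.

The default profile is the full-scale configuration (128×208×88, width 8,
lr 1e-4, ≤1000 epochs) and is practical on GPU-class hardware.  The desk
profile used throughout the tests (64×64×48 at 1 mm, width 4, 3 levels,
3×3×3 kernels, no dropout, lr 1e-2, ≤8 epochs, 40 train / 8 validation
cases) was chosen as the smallest configuration that reliably reconstructs
held-out synthetic cases (mean dice ≥ 0.85 within a few epochs on one CPU
core): smaller kernels and the higher learning rate compensate for the
shallow budget, and dropout is disabled because the homogeneous synthetic
cohort does not overfit in so few epochs.

## Evaluation

- "Surface" = foreground voxels with ≥1 background 6-neighbor.
- STSD: Euclidean distance transforms of each surface set; the sum of both
  directed surface-distance sums divided by the total surface voxel count;
  reported in voxel units ("pixels"), × spacing for mm.  Verified against
  an O(n²) all-pairs oracle.
- Diameter: the maximum over all slices of the in-slice row sum along the
  anterior-posterior axis, × spacing; the A-P axis is a parameter
  (`ap_axis`, default the second array axis) so datasets with other
  orientations can remap it.  This voxel-count definition is not the
  echocardiographic A-P diameter convention.
- Volume: foreground count × spacing³ (cm³).
- Coverage: points snapped to the voxel grid, deduplicated, divided by the
  surface voxel count and capped at 1 (jittered points can land off the
  surface; deduplication keeps duplicated samples from inflating the
  ratio).
- Percent errors: |pred − truth| / truth × 100 per case.
- Error maps: per-surface-voxel distances in both directions; their pooled
  mean equals the STSD by construction.
- Coverage correlation: Pearson r with two-sided p and a least-squares
  line per metric; zero-variance metrics are flagged as degenerate rather
  than raised.

## Known limitations

- Synthetic anatomy only; no claim of clinical accuracy transfer.
- The numpy network is CPU-practical at desk scale; full-scale training
  (width 8, 128×208×88, 1000 epochs) is supported by the same code but is
  a GPU-class workload.
- The alpha complex is built from scipy's Delaunay (Qhull); pathological
  inputs (exactly cospherical dense sets) can make the filtered complex
  empty, which surfaces as the "smallest circumradius" error.
- Coverage control is approximate under jitter: voxel collisions reduce
  the realized coverage slightly below the angular-window fraction.
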