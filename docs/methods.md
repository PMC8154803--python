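# Methods

This note records the measurement model, the conventions that the pipeline
fixes where the underlying method description leaves them open, the
synthetic phantom model, and the numerical choices — in enough detail that
every number the package produces can be traced to a definition.

## Coordinates and containers

A `LabelVolume` is a 3D integer grid (0 = background, 1 = MT, 2 = cMF,
3 = LT, 4 = cLF) with anisotropic voxel spacing in mm and an axis map
assigning each grid axis (row, col, slice) to an anatomical direction
family (superior–inferior, anterior–posterior, medial–lateral) and
polarity. Physical positions are voxel centers, `index × spacing`. Two
grid presets mirror the common knee protocols: FLASH-like coronal
(0.3125 × 0.3125 mm in-plane, 1.5 mm slices; slice axis = AP) and
DESS-like sagittal (0.37 × 0.37 mm in-plane, 0.7 mm slices; slice
axis = ML). A JSON sidecar carries plane, axes, knee/visit ids, the ROI
fraction, and the femoral ROI landmarks (notch and posterior-end positions
per condyle, in mm along the AP axis); NIfTI headers alone cannot express
these unambiguously. Foreign label encodings are remapped through an
optional `label_map` in the sidecar.

## Post-processing conventions

The five clean-up steps run in the fixed order fill → connectivity →
smoothing → ROI → surface separation. Choices the step names do not
determine:

* **Gap filling.** A "small" enclosed gap is, by default, any enclosed
  background region whose entire 4-connected neighbourhood belongs to one
  plate (thin cartilage structures make enclosed regions intrinsically
  small); an optional area cap is available. Gaps bordered by two
  different plates are never filled.
* **Connectivity.** 3D 26-connectivity per plate; only the largest
  component is kept. A size tie keeps the component whose minimum voxel
  index is lexicographically smallest, making the step deterministic.
  `keep_fraction < 1` additionally retains secondary components at least
  that fraction of the largest (for atypical data).
* **Spike removal.** Iterative deletion of foreground pixels with ≤ 1
  four-connected same-plate neighbour until a fixpoint. The operator is
  monotone (never adds voxels) and idempotent.
* **ROI cut.** `cut = notch + fraction × (posterior − notch)`, signed by
  the landmark ordering so either axis polarity works. Voxels strictly
  posterior to the cut (voxel center beyond the cut position) are cleared;
  tibial plates are never touched.
* **Boundary and tracing.** Boundary pixels are foreground pixels with a
  4-connected background neighbour (other plates count as background for
  this purpose). Contours are traced with Moore neighbour following,
  clockwise in image coordinates, starting from the minimum-index boundary
  pixel.
* **Farthest pair.** Computed on physical in-plane coordinates (mm), so
  anisotropic in-plane spacing is honoured; ties are resolved toward the
  lexicographically smallest pixel-index pair. The two points belong to
  both chains.
* **tAB/AC side assignment.** The chain with the greater mean
  inferior-direction coordinate is the bone interface for tibial plates;
  the smaller for femoral plates. A per-plate flip is available for
  datasets with other conventions.
* **ROI-abutting femoral slices** (sagittal only, where the AP axis is
  in-plane): boundary pixels on the cut line whose *only* background
  exposure is across the cut — the artificial posterior face, not an
  anatomical surface — are assigned to IC; the cut line thereby bounds the
  chains. Pixels at the cut that also expose a superior/inferior face keep
  their surface role.
* **Degenerate slices** (≤ 2 boundary pixels) are not traced: both
  surfaces collapse onto those pixels (logged). A single-voxel plate
  therefore has coincident tAB and AC and zero thickness.
* **Measurement chains.** The farthest-pair split necessarily allocates
  the plate's lateral margin pixels (exposed only sideways, not toward
  bone or joint space) to one chain or the other. For *measurement* the
  chains are trimmed: terminal runs without a background face on the
  expected side (bone side for tAB, articular side for AC) are stripped;
  interior pixels are never removed, so staircase chains of curved
  interfaces stay intact. Trimming is what makes flat-slab area and
  thickness exact. Its known limit: interfaces steeper than ~45° at a
  chain end can lose a terminal vertical run; the phantom geometry keeps
  interface slopes below 1.

## Morphometry definitions

* **Volume** = plate voxel count × voxel volume. Exact by construction;
  an absent plate reports 0.
* **tAB area.** Per slice, the polyline length of the (trimmed) bone
  chain × slice spacing, summed over slices, in cm². Raw rasterised
  polylines overestimate curved interfaces by 5–30% (staircase bias), so
  chain coordinates are smoothed with an endpoint-preserving moving
  average (window 5) and the polyline is evaluated on every 2nd point
  (chord approximation); half of the first/last raw segment is appended at
  each end so an axis-aligned chain of n pixels measures exactly
  n × spacing. A quarter-circle interface of radius 10 mm at 0.5 mm
  spacing is recovered within ~2.4% (documented tolerance ≤ 3%); planar
  interfaces are exact. Through-plane tilt is *not* captured — the measure
  underestimates surfaces tilted along the slice axis (about −8% for the
  condylar arc seen across coronal slices at the default geometry). This
  is the price of a deterministic slice-wise measure without 3D meshing.
* **Thickness.** tAB and AC surface points are taken per slice at voxel
  *faces*: each boundary pixel center is offset half a voxel toward each
  in-plane 4-connected background neighbour (opposing offsets cancel, so a
  free-standing pixel stays at its center). For every tAB point the
  minimal 3D Euclidean distance to the AC point set is computed (KD-tree;
  slice position enters as the third coordinate) and the mean over tAB
  points is returned. On flat slabs this is exact (n layers measure
  n × spacing); on gently curved slabs it measures the local normal
  thickness t·cos θ. One-directional tAB→AC distance is the fixed default;
  an absent surface yields a missing value, not 0, because a mean over an
  empty set is undefined.
* **Compartments** are plate sums for all three measures — including
  thickness, so MFTC thickness is the *sum* of MT and cMF thickness. A
  compartment with a missing constituent is flagged missing; the other
  compartment is unaffected.

## Agreement metric dialect

DSC = 2|A∩B|/(|A|+|B|); VOE = 100·(1 − |A∩B|/|A∪B|), identical to
100·(1 − DSC/(2 − DSC)) to machine precision. Surface voxels are set
members with ≥ 1 six-connected neighbour outside the set (grid border
counts as outside); HD and ASSD are computed between surface voxel
*centers* in physical mm, with no sub-voxel interpolation. Conventions for
cases the definitions leave open: DSC(∅,∅) = 1, VOE(∅,∅) = 0; surface
distances involving an empty set raise (per-plate summaries report NaN so
cohort tables stay computable). The KD-tree implementation is checked
against an all-pairs brute-force oracle, which it must match exactly.

## Precision statistics

For two visits per knee with no expected true change: per-knee SD (n−1
denominator) reduces to |v₂−v₁|/√2 and per-knee CV% = 100·SD/pair-mean;
RMS SD and RMS CV% are root-mean-squares over knees. MC = mean(v₂−v₁) with
a two-sided paired *t* test (zero-variance differences resolve to the
limit t = 0, p = 1); MC% is normalised by the visit-1 mean.
SEM = SD(differences)/√2 and SDC = 1.96·√2·SEM (equivalently
1.96·SD(differences)). Bland–Altman: differences oriented first − second
(automated − manual, corFLASH − sagDESS); limits = mean ± 1.96·SD. All SDs
use n−1; no multiplicity correction. A pair with non-positive mean has an
undefined CV and raises, naming the knee.

## Synthetic phantoms

The generator produces label + grayscale volumes with analytically known
morphometry. Geometry (canonical SI/ML/AP space, then transposed to the
grid layout of the preset):

* tibial plates: slabs of prescribed thickness under a gently
  upward-convex paraboloid bone surface (default curvature 0.015 /mm,
  i.e. 1–2 mm of bow across the footprint — enough that SI voxel
  quantisation dithers out rather than acting coherently);
* femoral plates: slabs on a circular-arc condyle profile in the SI–AP
  plane (radius 0.75 × the notch-to-posterior span) with mild ML
  curvature, generated only inside the 60% ROI so the clean phantom is a
  fixed point of the post-processing chain; landmarks are recorded in the
  metadata;
* default thicknesses MT 1.7, cMF 1.8, LT 2.1, cLF 1.7 mm — typical
  healthy-knee plate means; a `flat` geometry renders axis-aligned slabs
  with exactly `round(t/spacing)` voxel layers, for which truth is exact.

Truth (thickness = footprint mean of t·cos θ from the analytic surface
gradient; volume = ∫t dA; tAB area = ∫√(1+|∇z|²) dA) is evaluated on the
voxel-column grid and recorded *before* defects are injected. The clean
truth mask is stored in post-processing normal form (the fixpoint of spike
pruning + connectivity), so "post-processing restores the clean mask
exactly" is a well-posed statement. Intensities are three-level piecewise
constant (bone 0.2, background 0.4, cartilage 0.9) with Gaussian noise
(σ = 0.05 default) and optional bright 15×15 corner artefacts.

Defects: enclosed holes (disks carved strictly inside the per-slice mask,
placement validated by erosion) and distant spurious blobs (≥ 2 slices
from the plate, in empty background). Follow-up pairs re-voxelise the same
geometry under a rigid sub-voxel shift (N(0, jitter) per axis) and apply
boundary-layer flips with probability p, with add/drop rates balanced so
the perturbation is volume-preserving in expectation — the correct model
for zero true change. Cohort splits use largest-remainder rounding
(92 knees at the reference fractions give 50/21/21) and derive per-phantom
seeds from one master seed via `SeedSequence` spawn keys; no global RNG
state anywhere.

What the phantoms do *not* emulate: MR physics (bias fields, partial
volume beyond voxelisation), osteophytes and cartilage lesions, reader
variability structure, and real anatomical shape variation. Passing tests
therefore demonstrate the correctness of the measurement and statistics
machinery under known geometry — not clinical segmentation accuracy.

## Toy U-Net stage

A 4-level encoder–decoder 2D U-Net in pure numpy (im2col convolutions,
hand-written backprop, gradient-checked), with the single architecture
departure that transpose convolutions of the up-sampling path output as
many feature maps as there are feature classes. Loss: weighted
cross-entropy with background weight 1/(1+2n) and foreground weight
2/(1+2n) for n feature classes (weighted pixel mean). Optimiser: ADAM with
initial learning rate 0.01, β₁ = 0.9, β₂ = 0.999 and decay rate 0.1
applied as an exponential staircase once at 50% of the epochs (the decay
*schedule* is not determined by the rate alone, so it is explicit config).
Weights use variance-scaling (He) initialisation from the config seed;
slices are z-scored after zeroing the four 15×15 corners (the corner
pixels enter the statistics as zeros — a documented assumption); only
slices containing a configured class are trained on; the epoch with the
best validation foreground Dice supplies the final weights (asserted
invariant of the training record). Per-compartment networks are merged by
higher softmax score, ties to the lower label id, logged.

Toy-scale defaults: base width 16, batch size 2 (with epochs capped at ~10
on synthetic contrast, batch 4 converges too slowly and batch 1 is
unstable at learning rate 0.01), 64×64 slices. A 4-class network at this
field of view cannot tell cMF from cLF — at 64×64 they differ only by
medial/lateral position, which a translation-equivariant network must
infer from border padding; the per-compartment configuration (one network
per compartment, each plate an individual feature class) resolves exactly
this ambiguity and is the configuration the segmentation demonstration
uses. The stage targets toy problem sizes; it is not intended for
full-resolution MRI training.

## Problem sizes and runtimes

Default test-suite sizes (one CPU): phantoms 112×112×20 (FLASH-like) and
96×28×110 (DESS-like); agreement oracle on 16×16×8 masks, 20 pairs;
test–retest simulation 21 pairs × 3 noise levels × 100 repeats on
48×64×10 phantoms using cartilage volume as the measure (volume needs no
surface partition, which keeps the full factorial cheap; a thickness run
through the full partition pipeline is exercised separately); U-Net
training on 40 slices of 64×64 for 10 epochs (~30 s). Full suite ≈ 2 min;
`scripts/acceptance.py` ≈ 2 min.

## Known limitations

* tAB area ignores through-plane tilt (slice-wise polyline, by design).
* The thickness definition (one-directional nearest-point tAB→AC over
  face points) is this package's explicit stand-in for the unpublished
  definition of the original analysis software; symmetric variants exist
  behind the same interface but the default is fixed for reproducibility.
* Surface-measurement trimming assumes interface slopes ≲ 1 at chain
  ends.
* The partition handles multiple in-plane 4-components (noisy masks) by
  partitioning each separately, but the two-chain identity invariant is
  only guaranteed for single-component slices.
* No regional subdivision of plates, no denuded-area or lesion measures,
  no DICOM ingestion.
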