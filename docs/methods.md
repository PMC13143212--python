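# Methods

This note documents the models, conventions and numerical choices behind
spinemetrics, in enough detail to judge what a passing test suite does and
does not establish.

## Image model and conventions

Images are single 2D planes (or maximum-intensity projections) with an
isotropic physical pixel size in µm/px; all areas are pixel counts ×
(pixel size)². Coordinates are 0-based `(row, col)` with the row axis
increasing downward. Foreground connectivity is 8, and a *border pixel* is
a foreground pixel 4-adjacent to background — the standard digital-topology
pairing; one peel iteration is therefore an erosion with the cross
structuring element.

## Spine segmentation

### Peel route (primary)

1. **Threshold.** Absolute value or `mean + k*sd` of the whole image.
   Before thresholding, a mild Gaussian smooth (σ = 0.5 px, below the
   optical PSF) suppresses per-pixel noise so the mask boundary follows
   the half-maximum contour. σ was calibrated on synthetic images: a
   heavier smooth measurably shrinks spine heads near the resolution
   limit, and a median filter clips their convex corners.
2. **Labeling.** Hoshen–Kopelman single-pass union-find with provisional
   labels and path compression, relabeled consecutively. Islands below
   `min_island_area` (default 50 px = 0.5 µm² at 0.1 µm/px) are discarded
   as disconnected noise; interior holes (single-pixel dropouts at low
   SNR) are filled — otherwise they fragment the peeled core.
3. **Peel and sever.** `peel_depth` iterations (default 2; a neck of
   width w needs ⌈w/2⌉). A convenience mode picks the earliest depth
   maximizing the peeled island count — the depth at which every neck is
   severed while the heads still survive.
4. **Channel reconstruction.** The largest surviving component is the
   channel core (the dendrite always dominates these fields of view); it
   is rebuilt by `peel_depth` geodesic dilations (cross element, each
   intersected with the original mask). Reconstruction is conservative by
   construction: channel ⊆ mask always.
5. **Spine islands.** The residual is labeled; islands below
   `min_head_area` (default 10 px = 0.1 µm², smaller than any real spine)
   are residue and dropped.

Pixels at the neck–channel junction survive peeling (they are interior to
the union of tube and neck), so the reconstructed channel extends up to
the peel depth into each neck base. Consequently the spine island begins
≈ peel-depth pixels outward of the drawn neck base; the neck reference
point inherits an outward bias of up to ~2 px. This is intrinsic to the
sever/reconstruct idea, not an implementation accident.

### Centerline route (cross-validation)

The occupied-disk fraction (occupancy) around each pixel is high on the
channel axis and low on thin protrusions. Candidate central pixels are
directional local maxima of occupancy inside the mask; they are thinned
(`skeletonize`) and the longest end-to-end path through the dominant
component, found by double breadth-first search, is the centerline.
Because thinning retracts tips by roughly the tube radius, both endpoints
are extended to the mask boundary by stepping to the deepest (most
medial) neighbour in the forward direction, ties favouring the straight
course. Path length sums 1/√2 steps × pixel size. A purely cyclic
skeleton (annulus) raises unless `allow_closed` is set.

The channel is rebuilt from the centerline with `n_layers` geodesic
dilations alternating cross and square elements (an octagonal, nearly
Euclidean profile). `n_layers` defaults to ⌈max radius⌉ + 1 = 5 at the
default scale: the discrete centerline can sit half a pixel off-axis, and
one layer too few leaves 1-px boundary strips attached to the spine
islands, while one too many is clipped by the mask and only creeps
slightly further into neck bases. Spines are matched across routes by
maximal overlap (greedy, one-to-one) and scored by Jaccard index; on
noiseless fixtures the mean is ≈ 0.93.

### Head/neck split

The split severs the neck and rebuilds the head — the same idea as the
channel sever, but executed with metric-accurate (Euclidean) peeling on a
2×-upsampled grid. The reason is resolution: with full-pixel erosion a
4×4-px head block and a 3-px neck reach the same interior depth and
cannot be told apart, while on the half-pixel grid they separate (depth
4.0 vs 3.0 in half-pixel units). Pixels deeper than
`max_neck_width + 0.5` (half-px units) form the head core; the largest
core, dilated back by the same radius inside the island, is the head.
Conventions: an island nowhere deeper than the sever radius is all neck
(thin spine); residual neck fragments below `min_neck_area` (4 px) are
opening slivers of a wide blob and merge back into the head, so a stubby
spine has an empty neck.

### Local thickness

Thickness at a point is the shortest chord that bisects the channel:
chords at 36 equally spaced directions (5° steps), traced by half-pixel
supercover stepping in both directions to the first background sample,
with the boundary taken midway between the last foreground and first
background sample (removing a +0.5 px per-side bias). The chord start is
not the single channel pixel nearest the reference point — at a spine
junction that pixel sits in the reconstruction bulge — but every interior
pixel (depth ≥ max(window max − 1.5, 2.5)) of a 9×9 window around it; the
minimum over starts and angles cannot fall below the true width (any
interior start measures a full transect) yet escapes the bulge. The
measure is exact for axis-aligned tubes and within ±1 px at arbitrary
rotation.

The per-dendrite mean local diameter is sampled at the spine reference
points by default, or at regular 1-µm arclength intervals
(`diameter_sampling="uniform"`, also the no-spines fallback); both modes
are provided because either convention is defensible and they differ by
≲ 0.02 µm on the synthetic material.

## Synthetic data

The generator emulates the study conditions the analysis assumes and is
itself first-class, tested code.

**Dendrite images** (256×256 px, 0.1 µm/px): a straight-to-gently-bent
tube of diameter 0.78 µm around a sub-pixel-jittered centerline (the
jitter makes the rasterized width average to the nominal diameter across
seeds instead of snapping to an odd pixel count); mushroom spines with
0.3 µm (3 px) necks, 0.4–0.6 µm neck lengths and 0.5–0.7 µm (5–7 px)
head disks, anchored on the centerline at ≥ 2 µm spacing on random sides;
background 100, signal 400, isotropic Gaussian PSF σ = 0.8 px (widefield
approximation at NA ≈ 1.4, 510 nm, 0.1 µm/px); additive Gaussian noise —
the recovery experiments run at SNR = signal/noise s.d. = 5, the hardest
of the stated conditions; and small random noise islands kept ≥ 2 px from
the dendrite so they can never be 8-connected to it. Ground truth records
the drawn channel mask, per-spine masks, pixel-counted head-disk areas,
neck base points, and the centerline length. Everything is bit-exactly
deterministic per seed.

What the generator does *not* emulate: 3D structure and z-stacks, uneven
illumination, photobleaching, structured (correlated) noise, dendrite
branch points, overlapping or obliquely protruding spines, and spine
shape classes beyond the mushroom/stubby/thin idealizations. Passing
recovery tests therefore demonstrate correctness of the algorithmic chain
at the stated geometry and noise, not robustness to every property of
real micrographs.

**SOCE traces** (150 frames at 2 s): flat basal ratio 0.4; thapsigargin
at frame 20 triggers a depletion transient (3-frame rise of +0.3, then an
exponential decay clamped to return exactly to basal 6 frames before
re-addition, so the pre-re-addition average is exact); Ca²⁺ re-addition
at frame 80 starts a linear rise of 0.02 ratio/s anchored at the previous
frame — making the five fit frames exactly collinear — to a peak of +0.4,
then a clamped decay to the plateau (+0.25) reached at frame 120. Noise
(s.d. 0.01) is added on the ratio scale; the 380-nm channel is held
constant so the ratio carries the variation. Truth is computed from the
noise-free curve; at zero noise every feature is recovered exactly. The
Δpeak estimator (a maximum over a noisy window) carries a small intrinsic
positive bias, ≈ 0.8 standard errors of a 200-trace mean at these
settings; all other features are unbiased.

**Colocalization pairs**: exact pixel-overlap construction with uniform
on-intensities, so M1 = overlap/n_A and M2 = overlap/n_B analytically;
counts are kept ≤ ¼ of the image so the mean + 2 s.d. threshold cleanly
separates on-pixels.

## Trace quantification choices

`n_avg` defaults to 5 frames (customary range 5–10; values outside warn
but run). The influx fit uses exactly five frames — the frame before
re-addition and the four from the event frame on; re-addition occurs
between frames, so the event frame is the first "after". AUC uses the
trapezoid rule (exactly additive over adjacent windows) with the baseline
either a supplied constant, the pre-window 5-frame mean, or zero. The
Grynkiewicz calibration requires user-supplied constants (R_min, R_max,
K_d, β); no values are assumed. Fold-change normalization divides by the
reference group's *median* (robust to the skewed per-cell distributions
typical of transient transfection). Time comes from the CSV time column
and is not assumed uniform.

## Imaging quantification choices

Manders coefficients are intensity-weighted (JACoP convention) with each
channel's own mean + 2 s.d. mask. The particle filter reads its size
range 0.01–5.00 as µm² (areas, consistent with measuring synapse areas)
— callers using different units must convert. Circularity uses the closed
Moore-traced boundary chain with √2 diagonal steps (a 1-px filament is
traced along both sides, so its circularity collapses toward zero; an
isolated pixel gets perimeter 4); a Crofton perimeter is available behind
a flag. The cluster-area histogram defaults to 0.1 µm² bins over 0–3 µm²
with overflow in the last bin. Integrated density can be computed on raw
or background-subtracted images — the choice is the caller's, both modes
exist. Nucleus/cytoplasm masks are inputs; nuclear segmentation is out of
scope.

## Splicing arithmetic

2^−ΔCq with the reference gene's Cq; inclusion fraction
variant/(variant + wild type); exon inclusion probability as the
arithmetic mean of the provided splice-border PSIs (any set of junctions
the caller deems informative). Group summaries use the n−1 s.d. and
s.e.m. = s.d./√n. Template-volume differences between assays are carried
as metadata only; no volume correction is applied by default because the
raw 2^−ΔCq values are what is conventionally reported.

## Determinism and provenance

All randomness flows through `numpy.random.default_rng(seed)`; identical
specs produce bit-identical images, traces and CSVs. Pipeline runs write
a provenance record (config hash, seed, package version) and reruns with
the same config are byte-identical.

## Problem sizes

The validation experiments use 1000 random 32×32 masks for the labeling
equivalence, 50 dendrite images (6 spines each) for recovery, 10
noiseless images for the two-route comparison, 200 traces for the
feature-bias Monte Carlo and 100 random 16×16 pairs for the Manders
oracle — sizes at which the Monte-Carlo standard errors are small
relative to every margin being tested, while the whole suite stays
interactive.

## Known limitations

- The severed-ring asymmetry biases neck reference points outward by up
  to the peel depth (see above); density and thickness are insensitive to
  this, but neck-length estimates derived from the reference point would
  not be.
- Heads smaller than ≈ 5 px across on ≈ 3 px necks sit at the binary
  resolution limit of any waist-severing split; the half-pixel grid
  pushes the limit down but cannot remove it.
- The centerline is a single path: branched dendrites yield the longest
  branch, and spine density is referred to that path only.
- `local_thickness` assumes a locally tube-like channel; at branch
  points the shortest chord underestimates the local calibre.
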