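# spinemetrics

Quantification toolkit for neuronal fluorescence microscopy and the
supporting molecular assays: dendritic-spine segmentation and morphometry
from cell-fill images, store-operated Ca²⁺ entry (SOCE) trace analysis from
ratiometric Fura-2 recordings, colocalization/cluster/synapse-particle and
NFAT-translocation measures, and the arithmetic layer of qRT-PCR and
splice-inclusion quantification. A ground-truthed synthetic-data generator
makes every stage testable without any microscope.

It is written for labs that study how proteins such as the STIM family
shape dendritic spine morphology and Ca²⁺ signalling, and who need the
image-derived numbers (spine head areas, local dendrite diameters, spine
densities, SOCE kinetics) to be reproducible and validated against known
ground truth.

## The algorithms

**Spine isolation by peeling.** A cell-fill image is thresholded and
labeled with the Hoshen–Kopelman union-find algorithm; small disconnected
islands are noise and removed. The binary structure is then *peeled*:
every foreground pixel 4-adjacent to background is removed, iteratively.
After `d` iterations every spine neck thinner than `2d` px is severed.
Isolated spine heads are discarded by relabeling; the surviving dendritic
channel core is rebuilt by `d` geodesic dilations inside the original
mask; and the residual

&nbsp;&nbsp;&nbsp;&nbsp;spines = mask − reconstructed channel

contains each spine *including its neck* as a separate island. An
independent route reconstructs the channel by dilating the dendritic
centerline (extracted from the occupied-disk fraction around each pixel)
and the two routes are compared spine-by-spine with Jaccard indices —
segmentation is trusted where they agree.

**Morphometry.** Spine area = island pixel count × (pixel size)²; head
and neck are split by severing at the neck's interior depth (a
metric-accurate version of the same peeling idea); the neck reference
point is the mean position of the island pixels facing the channel; the
local dendrite thickness at that point is the shortest chord that bisects
the channel; spine density is spines per µm of centerline.

**SOCE traces.** The background-subtracted 340/380 ratio R(t) is
summarized by the basal level (mean of the basal window), Δpeak and
Δplateau relative to the mean of the 5 frames before Ca²⁺ re-addition,
the influx rate (OLS slope over the frame before re-addition and the four
from it on), and the area under the curve during store depletion.
Absolute [Ca²⁺] comes from the Grynkiewicz relation
[Ca²⁺] = K_d·β·(R−R_min)/(R_max−R) when calibration constants are given.

**Colocalization and clusters.** Channels are thresholded at
mean + 2·s.d.; Manders coefficients are intensity-weighted:
M1 = Σ_{A∩B} I_A / Σ_A I_A (M2 symmetric). Cluster statistics (count,
mean area, integrated density, area histogram), an area/circularity
particle filter (circularity = 4π·area/perimeter², perimeter by boundary
chain tracing), rolling-ball background subtraction and the
nuclear/cytosolic NFAT ratio complete the imaging toolbox.

**Expression and splicing.** Relative expression 2^−ΔCq, exon inclusion
fraction = variant/(variant + wild type), and exon inclusion probability
as the mean of the splice-border PSI values.

## Worked example

Generate two synthetic dendrites (0.78 µm tube at 0.1 µm/px decorated
with mushroom spines, ground truth in `.truth.json` sidecars) and run the
full morphometry workflow:

```bash
$ spinemetrics simulate --kind dendrite --n 2 --seed 7 --out-dir fixtures
$ spinemetrics spines --input-dir fixtures --output-dir out --threshold 300
    image_id  n_spines  spine_density_per_um  mean_local_dendrite_diameter_um  centerline_length_um  method_mean_jaccard
dendrite_000         6              0.237209                              0.8             25.294113             0.928543
dendrite_001         6              0.240125                              0.8             24.987006             0.914787
```

Both images contain 6 drawn spines and all 6 are found; the mean local
dendrite diameter (0.80 µm) recovers the drawn 0.78 µm tube to within a
fifth of a pixel; and the peel-based and centerline-based segmentations
agree with mean Jaccard ≈ 0.92. Per-spine head areas and thicknesses are
written to `out/spine_records.csv`.

The trace workflow recovers the generator's kinetic parameters the same
way (true basal 0.4, influx rate 0.02 ratio/s, Δplateau 0.25; ratio noise
0.01):

```bash
$ spinemetrics simulate --kind trace --n 2 --seed 7 --out-dir tfix
$ spinemetrics traces --input-dir tfix --output-dir tout
  cell_id    basal    dpeak  dplateau     rate      auc
trace_000 0.398869 0.399308  0.253437 0.018754 6.364660
trace_001 0.401184 0.422428  0.251926 0.019666 6.570924
```

`coloc`, `clusters`, `nfat`, `particles` and `splice` subcommands cover
the remaining assays; every run writes a provenance JSON (config hash,
seed, version) and reruns are byte-identical.

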