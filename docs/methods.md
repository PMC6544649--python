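# Methods

`lettucescan` quantifies iceberg lettuce heads in single-channel 8-bit NDVI
orthomosaics at ~3 cm ground-sample distance (GSD): it counts individual
heads, grades each into small/medium/large, and aggregates the result into a
GPS-referenced harvest map. This note describes the models and procedures,
the synthetic testbed, the numerical choices, and the limitations.

## Pipeline

Five stages, run in order by `cli.run_pipeline`:

1. **Input** — a grey-level TIFF/PNG raster plus a user-supplied
   georeference: top-left latitude/longitude, clockwise rotation versus
   geographic north, and GSD (default 0.03 m/px).
2. **Calibration** — overflow correction followed by CLAHE
   (`calibration`).
3. **Analysis** — median denoising, sectioning, sliding-window CNN scoring,
   global non-maximum suppression (`detection`), then unsupervised size
   grading (`sizing`).
4. **Visualisation** — counts overlay, size-distribution overlay, and a
   harvest-region raster coloured per grid (`harvest`).
5. **Export** — a results CSV (field totals plus one row per grid) and a
   3D-chart table (grid row/col, total count, representative category).

## Overflow correction

NDVI sensors store one 8-bit channel; over strongly vegetated pixels the
signal can exceed 255 and wrap, so the brightest core of a head is recorded
as near-black speckle. The correction rule: a pixel below
`overflow_dark_thresh` (default 30) whose 8-neighbour median exceeds
`overflow_bright_thresh` (default 200) cannot be soil — dark soil sits in
dark neighbourhoods — and is restored to 255. Because a wrapped core wider
than ~2 px has wrapped neighbours of its own, the rule is iterated to a
fixpoint (bounded at 64 passes), eating inward from the bright rim; the
fixpoint makes the operation idempotent. The thresholds leave typical soil
(grey ~80) untouched by a wide margin.

## CLAHE

Contrast-limited adaptive histogram equalisation increases lettuce/soil
contrast before learning. The image is divided into an `clahe_tile` ×
`clahe_tile` grid of tiles (default 8, i.e. the common 8×8 tile-grid
convention) and equalised with clip limit `clahe_clip` (default 0.01),
via `skimage.exposure.equalize_adapthist`. Output is rescaled to [0, 255].
A constant image is returned unchanged (degenerate histogram).

*Limitation:* on a raster with no vegetation signal at all, CLAHE stretches
pure soil noise to the full intensity range and its bilinear tile
interpolation can synthesise occasional smooth, blob-like bumps. The
measured consequence is a false-positive density of roughly 1 per 10⁵ pixels
on lettuce-free synthetic fields — negligible against planting densities of
~5 heads per 10³ pixels, but the reason the "empty field" behaviour is
specified as a density bound rather than exactly zero detections.

## Patch classifier

A compact CNN maps a 20×20 patch to the probability that it encloses one
whole lettuce head:

    [conv 32×3×3 → BN → ReLU] ×2 → maxpool 2×2
    [conv 64×3×3 → BN → ReLU] ×2 → maxpool 2×2
    flatten → dense 512 → ReLU → dropout 0.5 → dense 1 → sigmoid

Convolutions use same-padding so the spatial sizes are exactly
20 → 20 → 10 → 10 → 5; the dense head sees 5×5×64 = 1600 features. The
network, its backpropagation and the Adam optimiser are implemented in NumPy
(`_nn`), float32 throughout, with im2col convolutions running on BLAS; the
model is small enough that a full training run takes a couple of minutes on
one CPU core.

**Training protocol.** Inputs are scaled to [0, 1]. The balanced labelled
set is split 50/50 (stratified, seeded) into train and validation halves.
Optimisation uses Adam (lr 10⁻³), batch size 32, binary cross-entropy.
Training stops at the earliest epoch where the validation accuracy is at
least the training accuracy *and* has improved by less than 0.1 percentage
points over the last two epochs, else at `epochs_max` = 10. The
validation-not-below-training condition is an anti-overfitting guard; the
plateau condition makes the rule well-defined (on its own, "validation above
training" would fire immediately or never). On the synthetic patch datasets
the model reaches >99% validation accuracy within 2–3 epochs.

**Online localisation refinement.** A classifier trained only on centred
positives and far-away negatives happily scores a window that clips a head
8–12 px off-centre at ~0.9, which floods the sliding-window detector with
near-duplicate candidates that no overlap threshold can prune cleanly (the
stride-5 lattice quantises both duplicate offsets and true 12–14 px
neighbour offsets onto the same IoU levels). The remedy is the pipeline's
online-learning step: `generate_localisation_patches` produces boxes whose
centre sits 6–12 px from a head centre, labelled background, plus fresh
jittered positives, and `online_update` continues training from the current
weights (same Adam state, validation half unchanged). After refinement the
probability field collapses outside ±4 px of a head centre and each head
contributes one dominant candidate.

**Fully-convolutional inference.** Scoring every stride-5 window
independently recomputes each convolution up to 16×, and on ordinary
hardware the im2col memory traffic dominates. Since all convolutions are
stride-1, `_fullconv` runs the conv blocks once per tile, keeps both phases
of each 2×2 pooling per axis (16 phase combinations over two pools), and
evaluates only the dense head per window. Window borders then see the true
neighbouring pixels where an isolated patch sees zero padding; the affected
band is the outer two pixels and the difference is confined to windows that
were near the decision boundary anyway (mean |Δp| ≈ 0.008; candidate sets
agree on all confident windows — asserted in the test suite).
`predict_patches` retains exact patch-wise semantics for training and
evaluation.

## Detection

The calibrated mosaic is 3×3-median filtered, sectioned into 250×250 tiles
stepped by 230 px (adjacent tiles overlap by a 20 px margin so no head is
split across a seam), and each tile is scanned by the 20×20 window on a
5 px lattice. Windows scoring ≥ `prob_min` (0.5) become candidates in the
mosaic frame. One *global* greedy NMS pass — candidates visited by
descending probability, ties broken by (y, x); a box is kept iff its IoU
with every kept box is ≤ `overlap_thresh` — both prunes per-head duplicates
and removes the doubles created in the tile-overlap zones.
Intersection-over-minimum-area is available as an alternative overlap
metric (`overlap_metric="min_area"`); IoU is the default.

**Overlap-threshold selection.** `select_overlap_param` scores a set of
truth-bearing synthetic fields once, then sweeps the threshold on a coarse
0.05 grid over [0, 1] and refines around the minimum by step halving to
~0.005, minimising the mean absolute relative counting error. On default
fields the optimum lands near 0.34: below ~1/3 genuinely adjacent heads
(12–14 px apart, IoU up to 1/3 after lattice quantisation) merge; above
~0.39 diagonal duplicates (IoU 0.39) survive.

## Size grading

Each detected box is summarised by an intensity histogram on geometric bins
whose cut-offs (64, 128, 160, 192, 208, 224, 232, 240, 244, 248, 250, 252,
253, 254 — 15 bins) get finer toward 255: soil lands in the first bins
while a head's bright pixels spread over the fine top bins, so high-bin mass
grows with head area and brightness. Histograms are clustered with k-means
(k = 3, 10 seeded restarts, Euclidean on raw counts — totals are a constant
400, so counts and frequencies are affinely equivalent). Clusters are put
into size order by the dot product between each centroid and a
non-decreasing weight vector (default wᵢ = i: near-zero weight on the soil
bins, largest weight at the bright end); smallest product → "small",
largest → "large", ties broken by cluster index. Display colours are blue /
green / red for small / medium / large. With fewer than three detections no
three-cluster structure exists and everything is labelled "medium" with a
warning.

*Limitations, quantified on synthetic fields:* at the default 12 px head
spacing, neighbouring heads bleed into the corners of a 20×20 box, and a
±25 grey-level illumination gradient moves soil mass between the two coarse
low bins; both effects swamp the class signal and per-class recall falls to
~30–80%. With well-separated classes — 20 px spacing so each box holds one
head, and no gradient — recovery is 100% across seeds. Unsupervised size
grading should therefore be read as a relative, field-scale measure, not a
per-plant one, on dense plantings.

## Harvest mapping

The mosaic is divided into square grids (default 50 px = 1.5 m at 3 cm GSD,
roughly a harvester working width; configurable). Each record is assigned
to the grid containing its box centre, so grid counts conserve the record
total. A grid's representative size is its modal category with ties
resolved toward the larger size (the larger marketable heads drive harvest
decisions); empty grids have none and render black. Grid corners are
georeferenced by the top-left pixel of the cell.

Pixel→GPS uses the equirectangular approximation (111320 m per degree
latitude, scaled by cos(lat₀) for longitude) after rotating the pixel
displacement clockwise by the image's rotation versus north; for fields of
tens of hectares the approximation error is far below one GSD. The inverse
transform round-trips to <10⁻⁶ px. GPS values are exported with 7 decimal
places (~1 cm).

## Synthetic fields

`synthetic_field` generates the testbed every stage is validated against:

- **Layout** — heads on a jittered row lattice with pitch
  `min_spacing + 2` px (default spacing 12 px ≈ 36 cm at 3 cm GSD) and ±1 px
  jitter, so pairwise spacing ≥ `min_spacing` holds by construction (and is
  re-verified). Two of every eight lattice rows are left unplanted
  (tramlines) and a 30 px headland borders the field — as in real lettuce
  beds — which also provides genuine soil for background patches.
- **Radiometry** — soil is Gaussian (mean 80, sd 8); each head is a radial
  cosine bump (peak at centre, soil level at radius). Blob radius and peak
  brightness are coupled per class: small 3–4 px / 165–190, medium 5–6 px /
  195–225, large 7–8 px / 225–250 — brighter NDVI response from bigger
  heads. A low-frequency diagonal sinusoid of amplitude ±25 grey levels
  produces distinct very-bright and very-dark regions.
- **Overflow** — with `overflow=True`, pre-clip values above 255 are stored
  as value − 256 (near-black cores inside bright heads). Peaks and gradient
  are chosen so wrapped values stay below the correction's dark threshold
  (max pre-clip ≈ 275 → wrapped ≤ 19 < 30).
- **Labelled patches** — `generate_patch_dataset` emits balanced 20×20
  patches: positives centred on heads with ±2 px jitter, negatives ≥ 15 px
  from any head centre; `generate_localisation_patches` adds the off-centre
  hard negatives described above.

What the generator does *not* emulate: overlapping canopies (post-H2
growth), within-head texture, row curvature, perspective or stitching
artefacts, multi-spectral effects, and real soil heterogeneity
(tracks, stones, residue). Passing tests therefore demonstrate the
machinery's correctness and its behaviour under the stated statistical
structure, not performance on arbitrary real imagery.

## Problem sizes and numerical choices

The shipped evaluation (`scripts/acceptance.py`, mirrored by the acceptance
tests) trains on 10,000 patches from a 2,000-head field, refines with 5,000
localisation patches, selects the NMS threshold on three 300-head fields,
and evaluates counting on 36 regions of 100–399 heads, 21 of 900–1200, 57
of 100–1200, plus one 2,000-head field with gradients and overflow — sizes
chosen so the whole evaluation runs in minutes on one CPU core, whereas
production mosaics carry 10⁵–10⁶ heads per field.
Typical results: validation accuracy >99.9%, convergence in 3 epochs,
counting R² ≥ 0.999 in all three region sets, whole-field error well under
1%.

Numerical details: float32 network arithmetic with He initialisation;
batch-norm ε = 10⁻⁵, momentum 0.9; max-pool ties share gradient equally;
all randomness flows through seeded `numpy.random.Generator` instances, so
every stage is bit-reproducible on a given platform (training histories may
differ across BLAS builds at float tolerance). Degenerate inputs: constant
images pass CLAHE unchanged; empty candidate lists pass NMS; k-means
requires ≥3 distinct histograms, otherwise the medium fallback applies.
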