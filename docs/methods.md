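# Methods

## Problem and approach

Whole-slide images (WSIs) of stained tissue are too large to segment
pixel by pixel at native resolution, and classifying a regular grid of
patches ignores the biological structure the patches cut across.
`slidecarto` implements the middle road: the slide is first
oversegmented into *superpixels* — connected clusters of visually
similar pixels — at a coarse analysis resolution, and a small random
subset of native-resolution patches inside each superpixel is classified
by a pluggable patch classifier.  Patch outputs are fused into one label
per superpixel, uncertain superpixels are rejected, and the resulting
class map drives downstream tumor endpoints (tumor area, invasive
margin, tissue composition).

## Pipeline model

**Resolution model.**  Native resolution is level 0 (nominally
0.22 µm/px for a 20× scan); all analysis rasters live on the 16×
downsampled plane (nominally 3.54 µm/px).  Missing pyramid levels are
synthesized by integer block averaging, which is exact mean pooling.
Coordinates are 0-based row-major, rectangles half-open.

**Foreground.**  A pixel is white background iff min(R, G, B) ≥ the
white threshold (default 220/255): a pixel counts as white only when all
channels are bright, so strongly stained but bright pixels remain
tissue.  The threshold value and the per-channel form are package
choices; only the existence of an intensity threshold is inherent to the
method.  The slide is cropped to the tissue bounding box before
segmentation.

**Stain-aware superpixels.**  RGB is converted to optical density
(natural log, intensities floored at 1/255 of background so the log is
finite) and unmixed with the Ruifrok–Johnston H&E basis; the third
basis vector completes the pair orthogonally (the residual channel is
discarded).  SLIC then clusters in `[H, E, x, y]` instead of
`[l, a, b, x, y]`: stain concentrations are what distinguish tissue
compartments in H&E, so boundaries follow nuclear/stromal structure.
The H and E channels are Gaussian-smoothed (σ = 5 px) *after*
deconvolution and before clustering — the method only fixes that
smoothing precedes segmentation, and smoothing the feature channels is
the variant consistent with clustering in stain space.  Channels are
scaled to unit variance per slide (the per-channel std is floored at
0.05 OD so near-uniform planes do not get quantization noise amplified
to full scale) and the spatial/stain trade-off is a single compactness
constant.  The default, 0.25, was chosen by a property scan: below
~0.25 the spatial term is so weak that the k-means clusters tile the
smoothed stain *gradient* into thin strips (the σ = 5 blur turns every
class edge into a continuum), which the connectivity cleanup then
merges asymmetrically — superpixel counts collapse and boundaries land
several pixels off the true edge; above it, boundary adherence on
multi-class mosaics degrades steadily (end-to-end recovery drops from
≈ 0.99 at 0.25 to ≈ 0.92–0.96 at 1.0).  0.25 is the lowest value that
keeps near-equal sizes on uniform planes and 1-px boundary recall on
two-region phantoms.  The underlying k-means runs
at most 10 iterations from a deterministic grid seeding, and
connectivity is enforced afterwards (orphan fragments are merged into
neighboring superpixels — standard SLIC cleanup).  The superpixel count
is `k = round(bbox_pixels / avg_size)` with `avg_size = 3600` analysis
pixels, i.e. a square superpixel covers 0.2 × 0.2 mm².  Superpixels
that are ≥ 50% white are background and never classified; the permissive
threshold deliberately keeps adipose tissue (mostly white at low
magnification) in play.

**Patching.**  224-px native patches tile the bounding box
(nonoverlapping, edge remainders dropped); each patch footprint is an
integer 14 × 14 analysis block.  A patch is assigned to the superpixel
covering the largest share of its block iff that share is ≥ 50% and the
superpixel is not background; ties at the threshold go to the lower
superpixel id.  Per superpixel at most 10 patches are classified — a
uniform sample without replacement drawn from a per-superpixel RNG
stream (seeded by `(seed, superpixel_id)`), so the selection is
reproducible and independent of iteration order.  Superpixels that end
up with zero assigned patches (very small or elongated ones) carry an
UNCLASSIFIED sentinel and are excluded from evaluation like rejected
ones.

**Fusion and rejection.**  A superpixel's distribution is the mean of
its patch softmax vectors; its label is the argmax of the mean.  The
confidence is computed from *hard* votes: `Cdiffvotes = (v1 − v2)/N`
with `v1, v2` the two largest per-class argmax counts among the N
patches (1 iff unanimous, 0 iff tied).  When the mean-softmax label and
the plurality vote disagree, the mean-softmax label wins — the two
mechanisms are deliberately separate.  Superpixels with confidence
strictly below the rejection threshold (default 0.1; 0.45 is a useful
preset for *visualizing* uncertain regions rather than for metrics) are
rejected: their pixels carry a sentinel and are excluded from the class
map and all metrics.  Argmax ties break to the lowest class index
everywhere.

**Evaluation.**  At analysis resolution only.  Pixels enter the
confusion matrix iff both ground truth and prediction carry a tissue
class; code 0 (unannotated/background) and the sentinels are excluded on
both axes.  Classwise recall/precision/F1 treat each class one-vs-rest;
zero denominators yield NaN rather than a silent 0.

**Tumor endpoints.**  Binary maps for tumor cells, necrosis, and mucus
are derived from the class map.  The tumor-cell map is closed
(disk, default radius 10 px ≈ 35 µm); necrosis/mucus connected
components in 8-connected contact with it (tested after a 1-px
dilation) are merged in; the union is closed then opened (opening
radius 5 px); finally each component's holes are filled, so the mask is
the area enclosed by each outer contour.  Kernel radii are package
defaults — the recipe fixes the operations, not the sizes — and are
exposed in config.  Morphology uses exact Euclidean disks implemented
via distance transforms (memory-safe for large radii); the structuring
element is clipped at image borders, so erosion does not eat mask pixels
that touch the edge.  Overlap uses IoU and Dice, which obey
`Dice = 2·IoU/(1 + IoU)` identically.  The invasive margin dilates the
tumor mask by the margin width w (default 500 µm, converted to pixels by
the plane's mpp), intersects with non-tumor tissue, then dilates that
band by w again and re-clips to tissue — the band therefore straddles
the boundary, reaching w into the tumor and up to 2w outward.  The
second extension reuses the same w because no separate distance is
specified by the method.  Composition reports per-class pixel ratios
against a single reference-region denominator.

## Synthetic phantoms and the oracle classifier

Phantoms emulate what the pipeline needs from an H&E slide: multi-class
tissue mosaics with stain-consistent colors, white background, and
fissures.  A class-label map is drawn at analysis resolution by a
Voronoi tessellation (class assigned per cell, first K cells cycle
through all classes) or by thresholded smoothed noise; a white frame and
1–2 straight white fissure lines emulate slide background and cracks.
The map is upsampled 16× and rendered through Beer–Lambert: each of the
seven default classes (tumor cells, muscle, connective/adipose, mucosa,
necrosis, inflammation, mucus) has a mean (H, E) optical-density pair,
chosen to be pairwise ≥ 0.2 apart in OD space and histologically
plausible (nuclear-dense classes high in H, eosinophilic ones high in
E, mucus nearly blank), plus per-pixel Gaussian texture noise
(σ = 0.03 OD).  Class boundaries are rendered as *gradual* transitions:
the per-class densities are blended with Gaussian weights
(`boundary_blur_px`, default 3 analysis px ≈ 10 µm) across region
borders, because real tissue transitions — tumor infiltration fronts,
inflammation gradients, tissue fading into a fissure — are not step
edges.  The ground-truth label map stays sharp, mirroring how manual
annotations draw crisp outlines through gradual tissue.  This is what
gives the rejection mechanism something real to detect: superpixels
straddling a transition receive genuinely mixed patch votes.  Rendering
and analysis share the stain basis, so ground truth is exact by
construction and deconvolution is consistent.

The oracle classifier mimics a trained patch CNN without training one:
it computes a patch's mean OD, deconvolves it, measures Euclidean
distance to the class (H, E) centroids, and emits
`softmax(−d/T)` with temperature T = 0.02 (pure-class patches score
≥ 0.99).  Its noise model corrupts outputs per patch: *symmetric* noise
replaces the vector, with probability ε, by a smoothed one-hot on a
uniformly drawn class (possibly the same one, so ε = 1 is chance level
1/K); *confusion* noise draws the replacement from a user confusion
row.  This emulates the error structure of a real CNN at the interface
level — what fusion and rejection actually see.

What the phantoms do **not** emulate: real nuclear/glandular texture,
stain variation between slides, scanner artifacts, out-of-focus
regions, or annotation noise.  Passing tests therefore validate the
*mechanics* (segmentation geometry, fusion arithmetic, rejection
accounting, endpoint morphology), not clinical-grade accuracy on real
tissue.

## Reference experiments and problem sizes

The experiments in `slidecarto.experiments` run at desk scale — chosen
as the package's standard verification sizes so each completes in
minutes on one CPU while exercising the real 16×/224-px resolution
plumbing:

* **Recovery** — 448 × 448 analysis plane (7168² native), Voronoi
  region scale 180 px = 3× the superpixel linear scale (√3600 = 60 px),
  noise-free oracle, 5 seeds.  Errors are confined to region
  boundaries; mean pixel accuracy ≥ 0.90 is the acceptance bar.
* **Rejection** — 320 × 320 plane, region scale 96 px, symmetric noise
  ε = 0.2, 20 seeds, threshold 0.1.  Mixed-content boundary superpixels
  produce vote ties and get rejected; the experiment reports
  mean accuracy before/after and the relative drop in true and false
  predictions.
* **Patch budget** — 384 × 384 plane, region scale 120 px, noise-free.
  With the default 3600-px superpixels the mean assigned patch count is
  ~20–24 per superpixel (the ≥ 50% coverage rule lets a superpixel own
  more patch blocks than its area alone implies), so the 10-patch limit
  roughly halves the classified-patch count.
* **Tumor phantom** — a structured 256 × 256 map (tumor disk with an
  enclosed necrotic core, an abutting mucus lobe, a distant necrosis
  island, mucosa/muscle surround).  The reference tumor mask is derived
  from the ground-truth class map by the same morphological rules, so
  IoU/Dice measure cartography errors, not morphology-recipe
  differences.

## Numerical choices and degenerate inputs

* OD floor 1/255 of background; natural log.  Negative deconvolved
  concentrations are clipped at 0 by default (`clip_negative=False`
  recovers the raw least-squares solution).
* All argmax ties: lowest index.  Coverage ties at the threshold:
  lowest superpixel id.
* `k` is floored at 1; `k = 1` short-circuits to a single superpixel.
* Empty patch grids warn rather than fail (a bounding box smaller than
  one patch is legal input).
* An empty confusion matrix (everything rejected/unannotated) raises
  rather than reporting NaN accuracy silently.
* Rejection threshold is strict `<`: confidence exactly at the
  threshold is kept.
* Areas are reported in mm² to 3 decimals using the analysis plane's
  mpp.

## Known limitations

* Small structures (a few hundred µm, e.g. comedo necrosis) are below
  the superpixel scale and get absorbed into surrounding labels; the
  rejection mechanism flags but does not fix this.
* The oracle classifier is linear in mean patch OD; it cannot model
  texture-dependent CNN failure modes (it will, e.g., never confuse two
  classes with identical mean stain but different texture).
* Stain-matrix estimation and slide-to-slide stain normalization are out
  of scope; the deconvolution basis is fixed (H&E or H-DAB presets, or a
  user 3×3 matrix).
* The tumor-area recipe is purely morphological; it merges any abutting
  necrosis/mucus component regardless of biological plausibility.
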