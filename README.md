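# slidecarto

Fast whole-slide tissue cartography for H&E histology: stain-aware
superpixel segmentation, bounded random patch classification,
confidence-based rejection, and tumor endpoints.

## Who this is for

Computational-pathology engineers and researchers who need a dense
multi-class tissue map ("cartography") of a gigapixel whole-slide image
(WSI) without the cost of classifying every patch — and who already
have (or want to plug in) a patch classifier.  The package supplies
everything *around* the classifier: resolution handling, stain
deconvolution, superpixel clustering, patch bookkeeping, label fusion,
rejection, pixelwise evaluation, and tumor-area/invasive-margin/
composition endpoints.  A synthetic phantom generator with an exact
ground truth and a configurable noisy oracle classifier make the whole
pipeline testable without clinical data.

## Method in brief

1. **Superpixels in stain space.**  At a 16× downsampled analysis plane
   (≈ 3.54 µm/px for a 0.22 µm/px scan) the slide is cropped to its
   tissue bounding box and unmixed by color deconvolution
   (Beer–Lambert: OD = −ln(I/I₀), Ruifrok–Johnston H&E basis).  SLIC
   clusters in `[H, E, x, y]` rather than `[l, a, b, x, y]`, with
   Gaussian-smoothed (σ = 5 px) unit-variance channels, ≤ 10 k-means
   iterations, and

       k = round(pixelCount(boundingBox(foreground)) / 3600)

   superpixels (a square one covers 0.2 × 0.2 mm²).  Superpixels ≥ 50%
   white are background.

2. **Bounded random patch classification.**  224-px native patches are
   assigned to the superpixel covering ≥ 50% of their footprint; at
   most 10 random patches per superpixel are classified.  The
   superpixel label is the argmax of the mean patch softmax:

       L_SP = argmax_c ( Σₙ p̂ₙ / N )

   and its confidence is the vote margin
   `Cdiffvotes = (v₁ − v₂)/N` over the patches' hard votes.
   Superpixels with `Cdiffvotes < 0.1` are rejected (excluded from the
   map and from metrics).

3. **Endpoints.**  Tumor cells + adjacent necrosis/mucus components are
   merged morphologically (close, adjacency by 1-px contact, close +
   open, fill holes) into a tumor mask scored by IoU and Dice
   (`Dice = 2·IoU/(1+IoU)`); an invasive-margin band of configurable
   width straddles the tumor boundary; composition reports class ratios
   inside a reference tumor region.

See `docs/methods.md` for assumptions, parameter rationale, and
limitations.

## Worked example

Run the pipeline on a synthetic phantom with the built-in oracle
classifier:

```python
from slidecarto import PipelineConfig
from slidecarto.experiments import run_phantom
from slidecarto.synthetic import PhantomSpec, make_phantom, oracle_classifier
from slidecarto.pipeline import run_endpoints

spec = PhantomSpec(analysis_shape=(224, 224), region_scale_px=120, seed=1)
phantom = make_phantom(spec)                      # 3584x3584 native RGB + exact GT
clf = oracle_classifier(spec, seed=1)             # noise-free nearest-centroid oracle
config = PipelineConfig(seed=1, class_names=spec.class_names)

result, accuracy = run_phantom(phantom, clf, config)
print(result.manifest["n_superpixels"], result.manifest["n_patches_classified"])
print(f"pixel accuracy {accuracy:.3f}")

report = run_endpoints(result.class_map, config, result.tissue, gt=phantom.gt_labels)
print(f"tumor IoU {report.overlap.iou:.3f}  Dice {report.overlap.dice:.3f}")
```

Output:

```
15 145
pixel accuracy 0.978
tumor IoU 0.973  Dice 0.986
```

15 superpixels were segmented and 145 patches classified (≤ 10 per
superpixel).  97.8% of jointly labeled analysis pixels received the
correct class — remaining errors sit on region boundaries, where class
transitions are rendered as gradual stain blends and the superpixel
grid quantizes the true edge.  The tumor mask derived from the
prediction overlaps the one derived from the ground truth with
IoU 0.973.  A structured lesion phantom (compact tumor disk with an
enclosed necrotic core and abutting mucus, in
`slidecarto.experiments.tumor_phantom_experiment`) scores IoU ≈ 0.90,
Dice ≈ 0.95.

The same flow is available from the shell:

```bash
slidecarto simulate --spec phantom.yaml --out sim/
slidecarto segment  --input sim/slide.tiff --classifier oracle \
                    --phantom-spec phantom.yaml --out seg/
slidecarto endpoints --classmap seg/class_map.tiff --gt sim/gt.tiff --out end/
slidecarto evaluate  --classmap seg/class_map.tiff --gt sim/gt.tiff --out metrics.json
```

Real slides: `slidecarto segment --input slide.tiff --config cfg.yaml
--classifier mymodule:make_classifier --out out/`, where the factory
returns any object with `class_names` and
`predict_proba(batch) -> (N, K)` softmax rows.

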