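# mitoscore

Quantification of mitochondrial immunohistochemistry (IHC) in brightfield
histology images. The package separates the brown DAB chromogen (here: a
mitochondrial inner-membrane marker such as COX4) from the blue
hematoxylin nuclear counterstain by windowed thresholding in HSV colour
space, counts nuclei from the apexes of a Euclidean distance map, and
reports the **Mito-score**:

    Mito-score = (# IHC-positive pixels) / (# nuclei)

a per-cell measure of mitochondrial staining abundance. Because nearly
every cell contains mitochondria, a conventional positive/negative cutoff
(or an H-score) is uninformative for this marker; normalizing the stained
area by the cell count is what makes regions, tissue compartments and
whole-slide tiles comparable.

Intended users: digital-pathology and image-analysis researchers working
with FFPE sections stained for organelle markers, who need an objective,
parameter-transparent alternative to visual scoring.

## Method in brief

* **Stain separation** — pixels are classified by inclusive HSV windows:
  DAB at hue [0°, 60°] ∪ [320°, 360°), saturation [60, 255], value
  [0, 160]; hematoxylin at hue [200°, 320°], saturation [20, 255], value
  [10, 220]. The value ceiling removes background, the saturation floor
  removes nonspecific gray staining, the disjoint hue windows split the
  stains.
* **Nucleus counting** — Otsu thresholding of brightness inside the
  hematoxylin mask, morphological denoising (speck removal, dilation,
  closing), exact Euclidean distance map (border = background), then
  counting of prominent distance-map maxima ("apexes") with plateau
  consolidation and a minimum separation. Fused nucleus pairs keep two
  maxima across a saddle, so touching cells are counted separately; a
  deterministic fallback re-counts crowded fields with stronger erosion.
* **Scoring** — region scores from Labelme-style polygon annotations
  (carcinoma vs stroma), tile scores on a 2000-px grid with heatmap
  rendering, and per-granule morphometry (circular-equivalent diameter at
  0.23 µm/px, against the 1–2 µm physical size of mitochondria).

See `docs/methods.md` for assumptions, parameter defaults and limitations.

## Worked example

```python
import numpy as np
from mitoscore import (SyntheticSpec, generate, analyze_image, mito_score,
                       extract_granules, count_positive_pixels)

# a synthetic 512x512 brightfield-like field with known ground truth
spec = SyntheticSpec(seed=1)           # 25 nuclei, 40 DAB granules
image, truth = generate(spec)

analysis = analyze_image(image)        # masks + nucleus count in one pass
ihc = count_positive_pixels(analysis.ihc_mask)
result = mito_score(ihc, analysis.nucleus_result.count)
granules = extract_granules(analysis.ihc_mask, image.pixel_size_um)

print(f"nuclei counted : {result.nuclei} (ground truth {truth.nucleus_count})")
print(f"IHC pixels     : {result.ihc_pixels} (ground truth {truth.ihc_pixel_count})")
print(f"Mito-score     : {result.score:.2f}")
diams = [g.equivalent_diameter_um for g in granules]
print(f"granules       : {len(granules)}, equivalent diameter "
      f"{min(diams):.2f}-{max(diams):.2f} um (mean {np.mean(diams):.2f})")
```

prints

```
nuclei counted : 25 (ground truth 25)
IHC pixels     : 1137 (ground truth 1137)
Mito-score     : 45.48
granules       : 40, equivalent diameter 0.94-1.82 um (mean 1.36)
```

Every one of the 25 painted nuclei is recovered as exactly one apex, the
extracted DAB mask matches the painted granule pixels exactly (the
generator draws hard edges, so 1137 is not an approximation), and the
granule diameters sit in the physical size range of mitochondria.

## Command line

```sh
mitoscore synth   --spec spec.yaml --out img.png --truth truth.json
mitoscore masks   --input img.png --profile ihc --out mask.png
mitoscore nuclei  --input img.png --out nuclei.csv --qc overlay.png
mitoscore score   --input img.png --annotations regions.json --out scores.csv
mitoscore heatmap --input img.png --tile-size 2000 --out heat.png
mitoscore run     --input img.png --annotations regions.json --out-dir out/
```

`run` executes the whole pipeline and writes per-region and per-tile score
CSVs, a heatmap PNG + CSV grid, QC overlays (apexes circled for visual
validation), the stain masks, and the fully resolved configuration for
provenance. All tabular outputs are written atomically and are
byte-identical across re-runs.

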