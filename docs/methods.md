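# Methods

## Problem and model

Brightfield immunohistochemistry (IHC) of a mitochondrial marker produces a
two-chromogen image: brown DAB granules wherever the antibody bound, and a
blue-violet hematoxylin counterstain in every nucleus. Because essentially
all cells contain mitochondria, a positivity cutoff is meaningless; the
quantity of interest is instead *per-cell staining abundance*,

    Mito-score = (# IHC-positive pixels) / (# nuclei)

computed over a region (an annotated carcinoma or stroma polygon, or a tile
of a whole-slide raster). The package implements the two measurement
problems this quotient requires — classifying pixels by stain, and counting
nuclei without segmenting them — plus region/tile bookkeeping, granule
morphometry and heatmap rendering.

## Stain classification in HSV space

The RGB image is converted with the standard hexcone transform; hue is kept
in degrees on [0, 360), saturation and value on the 8-bit 0–255 scale. A
stain class is a conjunction of inclusive windows:

| class    | hue (°)            | saturation | value  |
|----------|--------------------|------------|--------|
| IHC/DAB  | [0, 60] ∪ [320, 360) | [60, 255]  | [0, 160] |
| nucleus  | [200, 320]         | [20, 255]  | [10, 220] |

The value ceiling removes the pale background, the saturation floor removes
gray nonspecific staining, the hue windows split brown from blue. The two
default hue windows are disjoint, so the two masks are provably disjoint on
any image. Window bounds are inclusive at both ends (the convention is not
dictated by the thresholds themselves; inclusivity is the simplest reading
and is pinned by tests). Because membership is a per-pixel predicate, masks
commute with cropping, tiling and rotation — tile IHC counts partition the
whole-image count exactly.

## Nucleus counting

Nuclei are counted, not segmented:

1. **Otsu binarization.** The brightness (V) of the pixels inside the
   hematoxylin mask is thresholded by exhaustive maximization of the
   between-class variance over all 256 split points; the dark side is
   foreground. Ties take the smallest threshold, so the result is
   deterministic. A constant-intensity mask (possible on hard-edged
   synthetic input) is degenerate: a warning is issued and the colour mask
   is used as-is.
2. **Denoising.** Components smaller than `min_nucleus_area` (default
   20 px²) are removed *before* any dilation, so specks are not inflated
   into countable objects; then a disk dilation (radius 1, 1 iteration)
   smooths ragged chromatin edges and a disk closing (radius 2) fills
   intranuclear holes. All structuring elements are disks; element sizes
   are the smallest that visibly smooth/close at ~0.23 µm/px.
3. **Distance map.** Exact Euclidean distance of each foreground pixel to
   the nearest background pixel; the image border counts as background so
   the map is finite even on an all-foreground image.
4. **Apex counting.** The support is eroded (`erosion_iters`, default 1),
   maxima shallower than `apex_prominence` are merged into their
   dominating neighbour (h-maxima transform), each surviving plateau
   contributes exactly one apex (the highest pixel nearest the plateau
   centroid; remaining ties break lexicographically), and apexes closer
   than `min_apex_separation` (default 7 px, below the smallest expected
   nucleus diameter) are suppressed in decreasing height order. Each
   convex blob yields one apex; two fused nuclei form a dumbbell whose
   distance map keeps two maxima across a saddle, so touching cells are
   still counted separately. Centres of gravity are computed per apex as
   the centroid of its watershed territory on the inverted distance map.
   Both positions are returned, since either may serve as "the" nucleus
   location. The pipeline contains no randomness; connectivity is
   8-neighbour throughout.

`apex_prominence` (default 0.5) is the one parameter without an obvious
geometric anchor, and its value is bracketed from both sides: the discrete
Euclidean distance transform of a single convex blob carries ridge bumps of
less than ~0.5 px (square-root lattice artifacts), while the saddle between
two same-size nuclei overlapping by ~2 px remains more than ~1 px below the
peaks even after closing thickens the neck. 0.5 therefore suppresses all
single-blob noise while preserving every genuine pair saddle.

**Crowded-cell fallback.** When the mean foreground blob area exceeds
`crowding_area_factor` (default 3) times the median area of blobs holding
exactly one apex, the field is declared crowded and apex counting is
re-run once with one extra erosion and the separation floor lowered by 2
(floor 3); the result is flagged `fallback_used`. A single deterministic
retry keeps results reproducible.

## Scoring, granules, regions, tiles

* The score is the plain quotient; a region with zero nuclei yields a
  flagged NaN score, never a dropped record (background tiles are common).
* Granules are 8-connected components of the IHC mask; physical size is
  the circular-equivalent diameter `2·sqrt(area/π)·pixel_size_um` with
  0.23 µm/px as default calibration. Real mitochondria are 1–2 µm, which
  is the plausibility band for granule output.
* A nucleus belongs to a region or tile iff its *apex* is inside
  (boundary inclusive); apexes are single pixels, so no nucleus is counted
  twice across a partition. IHC pixels are counted by rasterizing the
  polygon with boundary-inclusive pixel-centre membership; additivity over
  regions therefore requires the regions to have disjoint interiors.
* Tiles are a row-major half-open cover (default 2000 px, the field size
  of the reference 40× whole-slide workflow); edge tiles are truncated.
  Coordinates everywhere are 0-based `(row, col)`; rectangles are
  half-open.
* Heatmaps render the per-tile score grid with undefined tiles in neutral
  grey; the numeric grid is also written as CSV at `%.17g`, which
  round-trips exactly.

## Synthetic data

The generator renders what the thresholds are designed for: hard-edged
hematoxylin-blue ellipses (radius 6–10 px, i.e. ~3–5 µm nuclei at 40×),
DAB-brown disks (radius 2–4 px ≈ 1–2 µm, the physical mitochondrion
range), near-white background (V > 220, outside both stain windows). There
is no anti-aliasing, so the painted pixel set per class *is* the ground
truth and mask extraction can be tested for byte-exact equality. Non-
touching nuclei keep an 8 px boundary gap (so dilation+closing cannot
bridge them); `overlap_fraction` converts that fraction of nuclei into
circle pairs overlapping by 2 px, producing fused dumbbell blobs with
known count. Granules never overlap nuclei or each other (unless
`allow_overlap`), so per-granule areas partition the IHC pixel count.
Rendering is fully determined by the seed (byte-identical re-runs);
infeasible packings fail loudly after bounded retries.

What the generator does **not** emulate: staining-intensity gradients,
chromatin texture, anti-aliased or blurred edges, scanner noise, touching
clusters of more than two nuclei, out-of-focus debris, and stain
colocalization (DAB over hematoxylin). Optional `color_jitter`/
`blur_sigma` knobs add Gaussian colour noise and smoothing for robustness
checks, at the cost of the exactness guarantees. Passing tests therefore
demonstrate correctness of the *algorithmic contracts* (window arithmetic,
Otsu, distance maps, apex logic, bookkeeping), and recovery under idealized
appearance — not performance on real slides, which depends on
facility-specific staining and may require re-tuned windows.

## Numerical and interface choices

* Hue from the conversion routine is rescaled to degrees before windowing;
  any 0–179 half-degree encoding never reaches the user.
* Test-fixture problem sizes: synthetic fields are 512×512 px with 25
  nuclei (separated condition) or 20 nuclei in 10 fused pairs (touching
  condition), 20 seeds per condition; oracle equivalence checks use
  32×32 rasters where the O(n²) brute force is exact and fast.
* Otsu input is assumed 8-bit; float intensities are rounded and clipped
  into [0, 255] before histogramming.
* All CSV/JSON/YAML outputs are written atomically (temp file + rename):
  a failed run leaves no partial outputs. Score CSVs serialize floats at
  `%.17g`, so identical runs are byte-identical.
* The annotation reader accepts the minimal Labelme JSON subset
  (`shapes[*].label`, `shapes[*].points` as `[x, y]` vertices), preserves
  unknown labels verbatim, reports JSON syntax errors with line/column,
  and rejects self-intersecting polygons by name.

## Known limitations

* Thresholds are calibrated to one staining protocol/scanner family;
  other facilities will need adjusted windows (exposed via profile
  config).
* Heavily crowded fields (clusters of ≥3 fused nuclei) exceed what the
  single deterministic fallback can recover; counts there are lower
  bounds.
* Pixel size is never inferred from image metadata; it is an explicit
  parameter (default 0.23 µm/px).
* Only plain raster input (PNG/TIFF) is supported; pyramidal whole-slide
  formats must be pre-exported to tiles or crops.
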