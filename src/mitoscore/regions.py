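"""Polygon annotations, whole-image tiling, and Mito-score heatmaps.

Annotations follow the Labelme JSON dialect: a top-level ``shapes`` list
whose entries carry a ``label`` and a ``points`` list of ``[x, y]`` pixel
vertices. Large images are scored on a non-overlapping grid of square tiles
(2000 px at 40x in the reference workflow) and the per-tile scores are
rendered as a heatmap of mitochondrial abundance across the section.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from shapely.geometry import Polygon
from shapely.validation import explain_validity

from .color import ChannelProfile, RGBImage, count_positive_pixels
from .errors import AnnotationParseError, AnnotationValidationError
from .nuclei import DenoiseParams
from .scoring import ImageAnalysis, MitoScoreResult, analyze_image, mito_score

__all__ = [
    "AnnotationRegion",
    "TileGrid",
    "Heatmap",
    "read_annotations",
    "tile",
    "score_tiles",
    "render_heatmap",
]

DEFAULT_TILE_SIZE = 2000  # px; 2000x2000 fields at 40x in the reference workflow


@dataclass(frozen=True)
class AnnotationRegion:
    """A labelled polygon (e.g. "carcinoma" or "stroma") in pixel coordinates."""

    label: str
    polygon: Polygon
    source_file: str = ""

    @property
    def area(self) -> float:
        return self.polygon.area


def read_annotations(path: str | Path) -> list[AnnotationRegion]:
    """Read Labelme-style polygon annotations.

    Only the minimal subset is interpreted: ``shapes[*].label`` and
    ``shapes[*].points`` (``[x, y]`` vertex pairs). Unknown labels are kept
    verbatim. Malformed JSON raises :class:`AnnotationParseError` with line
    context; a polygon with fewer than 3 vertices or a self-intersection
    raises :class:`AnnotationValidationError` naming the shape.
    """
    path = Path(path)
    try:
        payload = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise AnnotationParseError(
            f"{path}: invalid JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}") from exc
    regions: list[AnnotationRegion] = []
    for i, shape in enumerate(payload.get("shapes", [])):
        name = shape.get("label", f"shape_{i}")
        points = shape.get("points", [])
        if len(points) < 3:
            raise AnnotationValidationError(
                f"{path}: shape {i} ('{name}') has {len(points)} vertices; "
                "polygons need at least 3")
        poly = Polygon([(float(x), float(y)) for x, y in points])
        if not poly.is_valid:
            raise AnnotationValidationError(
                f"{path}: shape {i} ('{name}') is not a valid polygon: "
                f"{explain_validity(poly)}")
        regions.append(AnnotationRegion(label=name, polygon=poly,
                                        source_file=str(path)))
    return regions


@dataclass(frozen=True)
class TileGrid:
    """Row-major non-overlapping cover of an image by square tiles.

    Tiles are half-open rectangles ``(r0, r1, c0, c1)`` in 0-based pixel
    coordinates; the last row/column is truncated at the image edge.
    """

    tile_size: int
    image_shape: tuple[int, int]
    tiles: tuple[tuple[int, int, int, int], ...]

    @property
    def grid_shape(self) -> tuple[int, int]:
        h, w = self.image_shape
        return (-(-h // self.tile_size), -(-w // self.tile_size))


def tile(image: RGBImage | tuple[int, int],
         tile_size: int = DEFAULT_TILE_SIZE) -> TileGrid:
    """Partition an image into a row-major grid of ``tile_size`` squares."""
    if tile_size < 1:
        raise ValueError("tile_size must be >= 1")
    h, w = image.shape if isinstance(image, RGBImage) else image
    tiles = tuple(
        (r0, min(r0 + tile_size, h), c0, min(c0 + tile_size, w))
        for r0 in range(0, h, tile_size)
        for c0 in range(0, w, tile_size)
    )
    return TileGrid(tile_size=tile_size, image_shape=(h, w), tiles=tiles)


@dataclass(frozen=True)
class Heatmap:
    """Per-tile Mito-scores on the tile grid; NaN marks undefined tiles."""

    scores: np.ndarray            # 2D float array, grid_shape
    tile_size: int
    vmin: float
    vmax: float

    @classmethod
    def from_results(cls, grid: TileGrid,
                     results: list[MitoScoreResult]) -> "Heatmap":
        gh, gw = grid.grid_shape
        if len(results) != len(grid.tiles):
            raise ValueError("one score per tile is required")
        arr = np.full((gh, gw), np.nan)
        for k, res in enumerate(results):
            arr[k // gw, k % gw] = res.score
        finite = arr[np.isfinite(arr)]
        vmin = float(finite.min()) if finite.size else 0.0
        vmax = float(finite.max()) if finite.size else 1.0
        return cls(scores=arr, tile_size=grid.tile_size, vmin=vmin, vmax=vmax)


def score_tiles(image: RGBImage,
                tile_size: int = DEFAULT_TILE_SIZE,
                profiles: tuple[ChannelProfile, ChannelProfile] | None = None,
                params: DenoiseParams = DenoiseParams(),
                analysis: ImageAnalysis | None = None,
                ) -> tuple[TileGrid, list[MitoScoreResult]]:
    """Mito-score every tile of the image.

    Masks and apexes come from one whole-image analysis; a tile's IHC count
    is the mask restricted to the tile (mask extraction is pixelwise, so
    this equals per-tile recomputation) and a nucleus belongs to the tile
    containing its apex, so no nucleus is counted twice.
    """
    grid = tile(image, tile_size)
    if analysis is None:
        analysis = analyze_image(image, profiles, params)
    apexes = np.asarray(analysis.nucleus_result.apexes, dtype=int).reshape(-1, 2)
    results = []
    for (r0, r1, c0, c1) in grid.tiles:
        ihc = int(np.count_nonzero(analysis.ihc_mask.pixels[r0:r1, c0:c1]))
        if apexes.size:
            in_tile = ((apexes[:, 0] >= r0) & (apexes[:, 0] < r1) &
                       (apexes[:, 1] >= c0) & (apexes[:, 1] < c1))
            n = int(in_tile.sum())
        else:
            n = 0
        results.append(mito_score(
            ihc, n, region_label=f"tile_r{r0}_c{c0}",
            fallback_used=analysis.nucleus_result.fallback_used))
    return grid, results


def render_heatmap(grid: TileGrid,
                   results: list[MitoScoreResult],
                   out_path: str | Path,
                   csv_path: str | Path | None = None,
                   cmap: str = "inferno") -> Heatmap:
    """Render per-tile scores as a PNG heatmap and write the numeric grid.

    Undefined tiles (no nuclei) are drawn in a neutral grey and stored as
    NaN in the CSV. The colour bar spans the finite score range. The CSV
    path defaults to the PNG path with a ``.csv`` suffix; values round-trip
    exactly (``%.17g``).
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    heat = Heatmap.from_results(grid, results)
    out_path = Path(out_path)
    csv_path = Path(csv_path) if csv_path else out_path.with_suffix(".csv")

    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("0.8")
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(heat.scores, cmap=cm, vmin=heat.vmin, vmax=heat.vmax,
                   interpolation="nearest")
    ax.set_title(f"Mito-score per {heat.tile_size}px tile")
    ax.set_xlabel("tile column")
    ax.set_ylabel("tile row")
    fig.colorbar(im, ax=ax, label="IHC-positive pixels / nucleus")
    fig.savefig(out_path, dpi=150, bbox_inches="tight")
    plt.close(fig)

    np.savetxt(csv_path, heat.scores, delimiter=",", fmt="%.17g")
    return heat
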