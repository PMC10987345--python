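"""Otsu thresholding, denoising, distance maps, and apex counting."""

import warnings

import numpy as np
import pytest
from scipy import ndimage as ndi

from mitoscore import (BinaryMask, DenoiseParams, SyntheticSpec, analyze_image,
                       count_apexes, count_nuclei, denoise, distance_map,
                       generate, otsu_binarize, otsu_threshold)
from mitoscore.errors import DegenerateHistogramWarning

# ---------------------------------------------------------------- oracles


def otsu_oracle(counts):
    """Smallest t maximizing between-class variance of the (<=t, >t) split."""
    counts = np.asarray(counts, dtype=float)
    total = counts.sum()
    best_t, best_v = None, -1.0
    for t in range(256):
        w1 = counts[:t + 1].sum()
        w2 = total - w1
        if w1 == 0 or w2 == 0:
            continue
        m1 = (counts[:t + 1] * np.arange(t + 1)).sum() / w1
        m2 = (counts[t + 1:] * np.arange(t + 1, 256)).sum() / w2
        v = w1 * w2 * (m1 - m2) ** 2
        if v > best_v:
            best_t, best_v = t, v
    return best_t


def distance_oracle(mask):
    """O(n^2) nearest-background distance; border counts as background."""
    h, w = mask.shape
    bg = [(r, c) for r in range(-1, h + 1) for c in range(-1, w + 1)
          if not (0 <= r < h and 0 <= c < w) or not mask[r, c]]
    bg = np.asarray(bg, dtype=float)
    out = np.zeros((h, w))
    for r in range(h):
        for c in range(w):
            if mask[r, c]:
                out[r, c] = np.sqrt(((bg - (r, c)) ** 2).sum(axis=1).min())
    return out


def local_max_clusters(dist, min_sep):
    """Brute-force apex oracle: 8-neighbour maxima, clustered within min_sep."""
    h, w = dist.shape
    pts = []
    for r in range(h):
        for c in range(w):
            if dist[r, c] <= 0:
                continue
            neigh = dist[max(0, r - 1):r + 2, max(0, c - 1):c + 2]
            if dist[r, c] >= neigh.max():
                pts.append((r, c))
    n = len(pts)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            d = np.hypot(pts[i][0] - pts[j][0], pts[i][1] - pts[j][1])
            if d < min_sep:
                parent[find(i)] = find(j)
    return len({find(i) for i in range(n)})


# ------------------------------------------------------------------- Otsu


def test_otsu_bimodal_toy_histogram():
    """40 px at 30 vs 60 px at 200: the threshold isolates the dark mode."""
    intensity = np.concatenate([np.full(40, 30), np.full(60, 200)])
    intensity = intensity.reshape(10, 10).astype(np.uint8)
    counts = np.bincount(intensity.ravel(), minlength=256)
    t = otsu_threshold(counts)
    assert t == otsu_oracle(counts)
    assert 30 <= t < 200
    mask = otsu_binarize(intensity)
    assert int(mask.pixels.sum()) == 40


def test_otsu_two_level_halves():
    intensity = np.zeros((4, 8), dtype=np.uint8)
    intensity[:, 4:] = 255
    mask = otsu_binarize(intensity)
    assert (mask.pixels == (intensity == 0)).all()


def test_otsu_matches_exhaustive_oracle_on_random_histograms(rng):
    for _ in range(20):
        counts = rng.integers(0, 50, 256)
        counts[rng.integers(0, 256, 200)] = 0  # sparse, with empty bins
        if np.count_nonzero(counts) < 2:
            continue
        t = otsu_threshold(counts)
        t_oracle = otsu_oracle(counts)
        # identical partitions: same set of dark-side levels
        assert (np.arange(256) <= t).tolist() == (np.arange(256) <= t_oracle).tolist()


def test_otsu_agrees_with_skimage_on_bimodal_data(rng):
    """Independent cross-check against skimage's Otsu on a clear mixture."""
    from skimage.filters import threshold_otsu

    vals = np.concatenate([rng.normal(60, 10, 600), rng.normal(190, 12, 400)])
    vals = np.clip(np.round(vals), 0, 255).astype(np.uint8).reshape(40, 25)
    t_pkg = otsu_threshold(np.bincount(vals.ravel(), minlength=256))
    t_sk = threshold_otsu(vals)
    assert (vals <= t_pkg).sum() == (vals <= t_sk).sum()


def test_otsu_constant_input_warns_and_passes_mask_through():
    intensity = np.full((6, 6), 90, dtype=np.uint8)
    sel = np.zeros((6, 6), dtype=bool)
    sel[2:5, 2:5] = True
    with pytest.warns(DegenerateHistogramWarning):
        out = otsu_binarize(intensity, sel)
    assert (out.pixels == sel).all()


def test_otsu_empty_mask_returns_empty():
    out = otsu_binarize(np.zeros((4, 4), dtype=np.uint8),
                        np.zeros((4, 4), dtype=bool))
    assert not out.pixels.any()


# ---------------------------------------------------------------- denoise


def test_closing_fills_one_pixel_hole():
    rr, cc = np.mgrid[0:21, 0:21]
    disk_mask = (rr - 10) ** 2 + (cc - 10) ** 2 <= 49
    holey = disk_mask.copy()
    holey[10, 10] = False
    params = DenoiseParams(dilation_radius=0, closing_radius=2,
                           min_nucleus_area=0)
    out = denoise(BinaryMask(holey), params)
    assert out.pixels[10, 10]
    assert (out.pixels & disk_mask).sum() == disk_mask.sum()


def test_denoise_empty_mask_is_identity():
    out = denoise(BinaryMask(np.zeros((8, 8), dtype=bool)))
    assert not out.pixels.any()


def test_small_component_removed_before_dilation():
    """An isolated pixel (area 1 < 5) vanishes even with dilation enabled."""
    mask = np.zeros((15, 15), dtype=bool)
    mask[7, 7] = True
    labels, n = ndi.label(mask)
    assert n == 1 and (labels == 1).sum() == 1  # labeling oracle: area 1
    out = denoise(BinaryMask(mask), DenoiseParams(min_nucleus_area=5))
    assert not out.pixels.any()


# ----------------------------------------------------------- distance map


@pytest.mark.parametrize("case", ["full", "empty", "single", "random"])
def test_distance_map_matches_brute_force(case, rng):
    if case == "full":
        mask = np.ones((5, 5), dtype=bool)
    elif case == "empty":
        mask = np.zeros((5, 5), dtype=bool)
    elif case == "single":
        mask = np.zeros((7, 7), dtype=bool)
        mask[3, 4] = True
    else:
        mask = rng.random((32, 32)) < 0.6
    d = distance_map(BinaryMask(mask))
    np.testing.assert_allclose(d, distance_oracle(mask), atol=1e-12)
    if case == "full":
        assert d[2, 2] == d.max() == 3.0  # centre is farthest from the border
    if case == "single":
        assert d[3, 4] == 1.0


# ------------------------------------------------------------ apex counts


def _disk_union(shape, disks):
    rr, cc = np.mgrid[0:shape[0], 0:shape[1]]
    mask = np.zeros(shape, dtype=bool)
    for (r, c, rad) in disks:
        mask |= (rr - r) ** 2 + (cc - c) ** 2 <= rad ** 2
    return mask


def test_two_separated_disks_two_apexes_at_centres():
    mask = _disk_union((60, 80), [(30, 20, 8), (30, 60, 8)])
    dist = distance_map(BinaryMask(mask))
    res = count_apexes(dist)
    assert res.count == 2
    assert local_max_clusters(dist, 7) == 2
    apexes = sorted(res.apexes)
    assert np.hypot(*(np.subtract(apexes[0], (30, 20)))) <= 1.5
    assert np.hypot(*(np.subtract(apexes[1], (30, 60)))) <= 1.5


def test_empty_distance_map_counts_zero():
    res = count_apexes(np.zeros((10, 10)))
    assert res.count == 0 and res.apexes == [] and res.centroids == []


def test_dumbbell_of_two_fused_disks_counts_two():
    """Centres 12 px apart, radius 8: one blob, two distance-map maxima."""
    mask = _disk_union((40, 60), [(20, 24, 8), (20, 36, 8)])
    labels, n_components = ndi.label(mask)
    assert n_components == 1
    dist = distance_map(BinaryMask(mask))
    res = count_apexes(dist)
    assert res.count == 2 == local_max_clusters(dist, 7)


def test_count_matches_components_for_separated_convex_blobs(rng):
    """With convex, well separated blobs the apex count equals the
    connected-component count (labeling oracle)."""
    for _ in range(5):
        disks, mask = [], None
        for r, c in [(20, 20), (20, 70), (70, 25), (65, 70)]:
            disks.append((r + int(rng.integers(-5, 6)),
                          c + int(rng.integers(-5, 6)),
                          int(rng.integers(5, 9))))
        mask = _disk_union((96, 96), disks)
        _, n_components = ndi.label(mask)
        res = count_apexes(distance_map(BinaryMask(mask)))
        assert res.count == n_components


def test_apexes_lie_on_foreground_and_match_result_lengths():
    mask = _disk_union((50, 50), [(25, 25, 9)])
    res = count_apexes(distance_map(BinaryMask(mask)))
    assert res.count == len(res.apexes) == len(res.centroids) == 1
    for r, c in res.apexes:
        assert mask[r, c]


# ---------------------------------------------------------- full pipeline


def test_pipeline_recovers_25_separated_nuclei(scene25):
    _, image, truth = scene25
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateHistogramWarning)
        analysis = analyze_image(image)
    assert analysis.nucleus_result.count == truth.nucleus_count == 25


def test_blank_image_counts_zero():
    intensity = np.full((64, 64), 240, dtype=np.uint8)
    res = count_nuclei(intensity, np.zeros((64, 64), dtype=bool))
    assert res.count == 0


def test_touching_pairs_counted_within_tolerance():
    spec = SyntheticSpec(seed=7, n_nuclei=20, overlap_fraction=1.0)
    image, truth = generate(spec)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateHistogramWarning)
        analysis = analyze_image(image)
    # 10 fused pairs; allow +-1 per pair on average
    assert abs(analysis.nucleus_result.count - truth.nucleus_count) <= 10


def test_apex_detection_is_deterministic(scene25):
    _, image, _ = scene25
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", DegenerateHistogramWarning)
        a = analyze_image(image)
        b = analyze_image(image)
    assert a.nucleus_result.apexes == b.nucleus_result.apexes
    assert a.nucleus_result.centroids == b.nucleus_result.centroids


def test_adding_isolated_nucleus_increments_count():
    mask = _disk_union((120, 120), [(30, 30, 8), (30, 90, 7), (90, 40, 9)])
    base = count_apexes(distance_map(BinaryMask(mask))).count
    mask2 = mask | _disk_union((120, 120), [(95, 95, 8)])
    grown = count_apexes(distance_map(BinaryMask(mask2))).count
    assert grown == base + 1
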