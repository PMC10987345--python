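"""HSV colour-space separation of DAB (IHC) signal from hematoxylin nuclei.

Brightfield IHC slides carry two chromogens: DAB, a brown precipitate that
marks antibody binding (here against a mitochondrial inner-membrane protein),
and hematoxylin, the blue-purple nuclear counterstain. In HSV space the two
occupy disjoint hue ranges — brown sits near the red end of the hue circle
(wrapping through 360°), hematoxylin in the blue band — which makes a simple
windowed threshold on (H, S, V) an effective stain classifier:

* IHC (DAB):      H in [0°, 60°] ∪ [320°, 360°),  S in [60, 255],  V in [0, 160]
* nucleus:        H in [200°, 320°],              S in [20, 255],  V in [10, 220]

The value ceiling removes the pale background, the saturation floor removes
nonspecific grayish staining, and the hue windows split the two stains.
Hue is in degrees on [0, 360); saturation and value on the 8-bit 0–255 scale.
All window bounds are inclusive; the three criteria are intersected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from shapely.geometry import Polygon
from skimage.color import rgb2hsv

from .errors import ShapeError
from .geometry import polygon_mask

__all__ = [
    "RGBImage",
    "HSVImage",
    "ChannelProfile",
    "BinaryMask",
    "rgb_to_hsv",
    "default_profiles",
    "extract_mask",
    "count_positive_pixels",
]

#: physical side length of one pixel at 40x whole-slide scanning, micrometres
DEFAULT_PIXEL_SIZE_UM = 0.23


@dataclass(frozen=True)
class RGBImage:
    """An 8-bit RGB brightfield image with its physical pixel size.

    Parameters
    ----------
    pixels
        ``(height, width, 3)`` array of 8-bit intensities.
    pixel_size_um
        Physical side length of one pixel in micrometres. The default 0.23
        corresponds to a 40x whole-slide scan.
    """

    pixels: np.ndarray
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3:
            raise ShapeError(
                f"expected a (height, width, 3) RGB array, got shape {px.shape}")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ShapeError("image must be at least 1x1")
        if px.dtype != np.uint8:
            if px.min() < 0 or px.max() > 255:
                raise ValueError("channel values must lie in [0, 255]")
            px = px.astype(np.uint8)
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[:2]

    @classmethod
    def from_file(cls, path: str | Path,
                  pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM) -> "RGBImage":
        """Read a PNG or TIFF file; an alpha channel, if present, is dropped."""
        import imageio.v3 as iio

        arr = iio.imread(path)
        if arr.ndim == 3 and arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ShapeError(
                f"{path}: expected an 8-bit RGB image, got shape {arr.shape}")
        return cls(arr, pixel_size_um=pixel_size_um)


@dataclass(frozen=True)
class HSVImage:
    """Per-pixel hue (degrees, [0, 360)), saturation and value ([0, 255])."""

    hue: np.ndarray
    saturation: np.ndarray
    value: np.ndarray

    def __post_init__(self) -> None:
        if not (self.hue.shape == self.saturation.shape == self.value.shape):
            raise ShapeError("H, S, V planes must share one shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.hue.shape


Interval = tuple[float, float]


@dataclass(frozen=True)
class ChannelProfile:
    """The H/S/V windows defining one stain class.

    ``hue_windows`` is a list of closed degree intervals; a hue range that
    wraps through 0° is expressed as two intervals (e.g. ``[(0, 60),
    (320, 360)]`` for DAB brown). All bounds are inclusive.
    """

    name: str
    hue_windows: tuple[Interval, ...]
    sat_window: Interval
    val_window: Interval

    def __post_init__(self) -> None:
        object.__setattr__(self, "hue_windows",
                           tuple((float(a), float(b)) for a, b in self.hue_windows))
        object.__setattr__(self, "sat_window", tuple(map(float, self.sat_window)))
        object.__setattr__(self, "val_window", tuple(map(float, self.val_window)))
        if not self.hue_windows:
            raise ValueError("at least one hue window is required")
        for lo, hi in self.hue_windows + (self.sat_window, self.val_window):
            if lo > hi:
                raise ValueError(f"window ({lo}, {hi}) has low > high")

    def contains(self, hue: np.ndarray, sat: np.ndarray,
                 val: np.ndarray) -> np.ndarray:
        """Vectorized membership test; all three criteria intersected."""
        in_hue = np.zeros(np.shape(hue), dtype=bool)
        for lo, hi in self.hue_windows:
            in_hue |= (hue >= lo) & (hue <= hi)
        in_sat = (sat >= self.sat_window[0]) & (sat <= self.sat_window[1])
        in_val = (val >= self.val_window[0]) & (val <= self.val_window[1])
        return in_hue & in_sat & in_val


@dataclass(frozen=True)
class BinaryMask:
    """Boolean pixel-membership raster tagged with the profile that made it."""

    pixels: np.ndarray
    source_profile: str = ""

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.dtype != bool:
            raise ValueError("mask pixels must be boolean")
        object.__setattr__(self, "pixels", px)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def rgb_to_hsv(image: RGBImage) -> HSVImage:
    """Standard hexcone RGB→HSV conversion.

    Hue is reported in degrees on [0, 360); saturation and value on 0–255.
    A pure red pixel maps to (0°, 255, 255), pure blue to (240°, 255, 255).
    """
    hsv = rgb2hsv(image.pixels)
    hue = np.mod(hsv[:, :, 0] * 360.0, 360.0)
    sat = hsv[:, :, 1] * 255.0
    val = hsv[:, :, 2] * 255.0
    return HSVImage(hue=hue, saturation=sat, value=val)


def default_profiles() -> tuple[ChannelProfile, ChannelProfile]:
    """The windows separating DAB (IHC) from hematoxylin (nucleus).

    Returns the ``(ihc, nucleus)`` pair:

    * IHC: hue [0, 60] ∪ [320, 360), saturation [60, 255], value [0, 160];
    * nucleus: hue [200, 320], saturation [20, 255], value [10, 220].
    """
    ihc = ChannelProfile(
        name="ihc",
        hue_windows=((0.0, 60.0), (320.0, 360.0)),
        sat_window=(60.0, 255.0),
        val_window=(0.0, 160.0),
    )
    nucleus = ChannelProfile(
        name="nucleus",
        hue_windows=((200.0, 320.0),),
        sat_window=(20.0, 255.0),
        val_window=(10.0, 220.0),
    )
    return ihc, nucleus


def extract_mask(hsv: HSVImage, profile: ChannelProfile) -> BinaryMask:
    """Pixels whose (H, S, V) fall inside every window of ``profile``."""
    return BinaryMask(profile.contains(hsv.hue, hsv.saturation, hsv.value),
                      source_profile=profile.name)


def count_positive_pixels(mask: BinaryMask,
                          region: Polygon | Sequence[Sequence[float]] | None = None,
                          ) -> int:
    """Number of true pixels, restricted to a polygon region when given.

    ``region`` is a shapely polygon or an ``(x, y)`` vertex list in pixel
    coordinates; boundary pixels count as inside. A zero-area region raises
    :class:`~mitoscore.errors.EmptyRegionError`.
    """
    if region is None:
        return int(np.count_nonzero(mask.pixels))
    inside = polygon_mask(region, mask.shape)
    return int(np.count_nonzero(mask.pixels & inside))
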