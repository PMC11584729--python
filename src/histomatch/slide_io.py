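"""Slide access, tissue masking and patch enumeration.

Whole-slide images are modelled as plain RGB rasters at a single stated
magnification (20X-equivalent).  A :class:`SlideHandle` wraps any in-memory
array or an image file; pyramidal readers can be adapted by subclassing and
overriding :meth:`SlideHandle.read`.

Coordinates are 0-based ``(row, col)`` with half-open boxes
``[r0, r0+h) x [c0, c0+w)``.

The tissue mask rule is deliberately simple and deterministic: a thumbnail
pixel is tissue when its grayscale luminance is below 0.8 (0-1 scale) *and*
its HSV saturation exceeds 0.05, which separates stained tissue from white
slide background.  The mask is computed on a downsampled thumbnail
(factor <= 32) and patch enumeration works on the mask grid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import rgb2gray, rgb2hsv
from skimage.measure import block_reduce

__all__ = [
    "SlideHandle",
    "TissueMask",
    "PatchSpec",
    "ExpandedPatch",
    "make_thumbnail",
    "compute_tissue_mask",
    "enumerate_patches",
    "read_region",
]

LUMINANCE_THRESHOLD = 0.8
SATURATION_THRESHOLD = 0.05


class SlideHandle:
    """RGB raster access to one slide at a fixed magnification."""

    def __init__(self, slide_id: str, pixels: np.ndarray, magnification: str = "20X"):
        pixels = np.asarray(pixels)
        if pixels.ndim != 3 or pixels.shape[2] != 3:
            raise ValueError("slide pixels must be an HxWx3 RGB array")
        if pixels.shape[0] < 1 or pixels.shape[1] < 1:
            raise ValueError("slide must be at least 1x1 pixels")
        self.slide_id = slide_id
        self._pixels = pixels
        self.magnification = magnification

    @property
    def shape(self) -> tuple[int, int]:
        return self._pixels.shape[:2]

    @property
    def height(self) -> int:
        return self._pixels.shape[0]

    @property
    def width(self) -> int:
        return self._pixels.shape[1]

    def read(self, r0: int, c0: int, h: int, w: int) -> np.ndarray:
        """Read the half-open box [r0, r0+h) x [c0, c0+w)."""
        if r0 < 0 or c0 < 0 or r0 + h > self.height or c0 + w > self.width:
            raise ValueError(
                f"read box ({r0},{c0})+({h},{w}) outside slide {self.shape}"
            )
        return self._pixels[r0:r0 + h, c0:c0 + w]

    @classmethod
    def from_file(cls, slide_id: str, path, magnification: str = "20X") -> "SlideHandle":
        import imageio.v3 as iio

        pixels = iio.imread(path)
        if pixels.ndim == 3 and pixels.shape[2] == 4:  # drop alpha
            pixels = pixels[..., :3]
        return cls(slide_id, pixels, magnification)


@dataclass(frozen=True)
class TissueMask:
    """Binary tissue grid at ``downsample`` cells per slide pixel side."""

    mask: np.ndarray
    downsample: int
    slide_shape: tuple[int, int]

    def __post_init__(self):
        if self.downsample < 1:
            raise ValueError("downsample must be >= 1")
        h, w = self.slide_shape
        mh, mw = self.mask.shape
        if mh * self.downsample < h - self.downsample or mw * self.downsample < w - self.downsample:
            raise ValueError("mask does not cover the slide extent")


@dataclass(frozen=True)
class PatchSpec:
    """A located, magnification-fixed square region of a slide."""

    slide_id: str
    origin: tuple[int, int]
    base_size: int
    magnification: str = "20X"

    def __post_init__(self):
        if self.origin[0] < 0 or self.origin[1] < 0:
            raise ValueError("patch origin must be >= (0, 0)")
        if self.base_size < 1:
            raise ValueError("base_size must be >= 1")


@dataclass(frozen=True)
class ExpandedPatch:
    """A patch read at a side larger than the network input.

    Views are later cropped from ``pixels`` without any rescaling, so the
    array is at native magnification.
    """

    pixels: np.ndarray
    spec: PatchSpec

    @property
    def side(self) -> int:
        return self.pixels.shape[0]


def make_thumbnail(slide: SlideHandle, downsample: int = 32) -> np.ndarray:
    """Block-mean thumbnail at the given integer downsample factor."""
    if downsample < 1:
        raise ValueError("downsample must be >= 1")
    px = slide.read(0, 0, slide.height, slide.width).astype(np.float64)
    if downsample == 1:
        return px
    return block_reduce(px, (downsample, downsample, 1), np.mean)


def compute_tissue_mask(
    thumbnail: np.ndarray,
    method: str = "luminance_threshold",
    downsample: int = 1,
    slide_shape: tuple[int, int] | None = None,
) -> TissueMask:
    """Flag tissue pixels of a thumbnail (dark and saturated vs. white glass)."""
    thumbnail = np.asarray(thumbnail)
    if thumbnail.size == 0:
        raise ValueError("empty thumbnail")
    if method != "luminance_threshold":
        raise ValueError(f"unknown masking method: {method!r}")
    rgb = thumbnail.astype(np.float64)
    if rgb.max() > 1.0:
        rgb = rgb / 255.0
    luminance = rgb2gray(rgb)
    saturation = rgb2hsv(rgb)[..., 1]
    mask = (luminance < LUMINANCE_THRESHOLD) & (saturation > SATURATION_THRESHOLD)
    if slide_shape is None:
        slide_shape = (thumbnail.shape[0] * downsample, thumbnail.shape[1] * downsample)
    return TissueMask(mask=mask, downsample=downsample, slide_shape=slide_shape)


def enumerate_patches(
    mask: TissueMask,
    base_size: int,
    stride: int,
    min_tissue_fraction: float,
    slide_id: str = "",
    magnification: str = "20X",
) -> list[PatchSpec]:
    """Row-major grid of patch locations whose tissue fraction clears the bar.

    The tissue fraction of a candidate box is the mean of the mask cells the
    box covers (boxes are mapped onto the mask grid at the mask's downsample).
    A ``base_size`` exceeding the slide yields an empty list.
    """
    if base_size < 1 or stride < 1:
        raise ValueError("base_size and stride must be >= 1")
    H, W = mask.slide_shape
    ds = mask.downsample
    specs: list[PatchSpec] = []
    for r0 in range(0, H - base_size + 1, stride):
        for c0 in range(0, W - base_size + 1, stride):
            mr0, mc0 = r0 // ds, c0 // ds
            mr1 = min(mask.mask.shape[0], int(np.ceil((r0 + base_size) / ds)))
            mc1 = min(mask.mask.shape[1], int(np.ceil((c0 + base_size) / ds)))
            frac = float(mask.mask[mr0:mr1, mc0:mc1].mean())
            if frac >= min_tissue_fraction:
                specs.append(PatchSpec(slide_id, (r0, c0), base_size, magnification))
    return specs


def read_region(slide: SlideHandle, spec: PatchSpec, expansion: int) -> ExpandedPatch:
    """Read the patch enlarged symmetrically to side ``expansion``.

    The output is a contiguous native-magnification sub-array of the slide —
    never interpolated.  When the symmetric enlargement would overflow the
    slide, the expanded box is shifted inward so that it fits; if the slide
    itself is smaller than ``expansion`` this is an error.
    """
    if spec.slide_id and spec.slide_id != slide.slide_id:
        raise ValueError(f"spec for slide {spec.slide_id!r} applied to {slide.slide_id!r}")
    r0, c0 = spec.origin
    if r0 + spec.base_size > slide.height or c0 + spec.base_size > slide.width:
        raise ValueError("patch spec lies outside the slide")
    if expansion < spec.base_size:
        raise ValueError("expansion must be >= base_size")
    if expansion > slide.height or expansion > slide.width:
        raise ValueError("expansion exceeds slide extent")
    margin = (expansion - spec.base_size) // 2
    er0 = min(max(r0 - margin, 0), slide.height - expansion)
    ec0 = min(max(c0 - margin, 0), slide.width - expansion)
    pixels = slide.read(er0, ec0, expansion, expansion)
    return ExpandedPatch(pixels=pixels, spec=spec)
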