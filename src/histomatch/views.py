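"""Magnification-preserving multi-crop view generation.

Standard multi-crop self-distillation resizes local crops to the network
input, which changes the apparent magnification of tissue.  Here views are
instead *harmonized*: local and global crops are taken from an expanded
patch at native scale and placed centered on a fixed 224x224 canvas with
padding — never interpolated — so every view shows tissue at the same
magnification.

A view set ``V`` holds, by default, two mildly augmented global views (the
teacher's inputs) and six heavily augmented local views; the student
consumes all eight.  Crop sides are drawn uniformly from [50, 140) for
local views and [140, 224] for global views (truncated to the expanded side
when it is smaller than 224).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .slide_io import ExpandedPatch

__all__ = [
    "LOCAL_SIDE_RANGE",
    "GLOBAL_SIDE_RANGE",
    "CropBox",
    "JitterParams",
    "MILD_JITTER",
    "HYPER_JITTER",
    "ViewConfig",
    "HarmonizedView",
    "ViewSet",
    "sample_crop_box",
    "crop_without_rescale",
    "flip_view",
    "pad_to_canvas",
    "apply_augmentations",
    "build_view_set",
    "crossmodal_input_view",
]

LOCAL_SIDE_RANGE = (50, 140)   # half-open: sides 50..139
GLOBAL_SIDE_RANGE = (140, 224)  # closed: sides 140..224


@dataclass(frozen=True)
class CropBox:
    top: int
    left: int
    side: int

    def __post_init__(self):
        if self.top < 0 or self.left < 0 or self.side < 1:
            raise ValueError("invalid crop box")


@dataclass(frozen=True)
class JitterParams:
    """Color-jitter magnitudes (fractional ranges around identity)."""

    brightness: float = 0.0
    contrast: float = 0.0
    saturation: float = 0.0
    hue: float = 0.0


MILD_JITTER = JitterParams(brightness=0.1, contrast=0.1, saturation=0.05, hue=0.02)
HYPER_JITTER = JitterParams(brightness=0.4, contrast=0.4, saturation=0.2, hue=0.1)


@dataclass
class ViewConfig:
    canvas_side: int = 224
    n_mild: int = 2
    n_hyper: int = 6
    mild_view_class: str = "global"
    hyper_view_class: str = "local"
    flip_p: float = 0.5
    mild_jitter: JitterParams = field(default_factory=lambda: MILD_JITTER)
    hyper_jitter: JitterParams = field(default_factory=lambda: HYPER_JITTER)
    photometric: bool = True
    fill: tuple[int, int, int] = (0, 0, 0)


@dataclass(frozen=True)
class HarmonizedView:
    canvas: np.ndarray
    crop: CropBox
    view_class: str           # "local" | "global"
    regime: str               # "mild" (tau_M) | "hyper" (tau_H)
    pad_offsets: tuple[int, int]
    flipped: tuple[bool, bool]  # (vertical, horizontal)


@dataclass(frozen=True)
class ViewSet:
    views: tuple[HarmonizedView, ...]
    teacher_indices: tuple[int, ...]

    @property
    def student_indices(self) -> tuple[int, ...]:
        return tuple(range(len(self.views)))

    def __len__(self) -> int:
        return len(self.views)


def sample_crop_box(rng: np.random.Generator, view_class: str, expanded_side: int) -> CropBox:
    """Draw a crop side uniformly from the class range, position uniformly."""
    if expanded_side < LOCAL_SIDE_RANGE[0]:
        raise ValueError(f"expanded side {expanded_side} smaller than minimum crop")
    if view_class == "local":
        lo, hi = LOCAL_SIDE_RANGE[0], min(LOCAL_SIDE_RANGE[1] - 1, expanded_side)
    elif view_class == "global":
        lo, hi = GLOBAL_SIDE_RANGE[0], min(GLOBAL_SIDE_RANGE[1], expanded_side)
        if expanded_side < lo:
            raise ValueError(f"expanded side {expanded_side} too small for a global view")
    else:
        raise ValueError(f"unknown view class: {view_class!r}")
    side = int(rng.integers(lo, hi + 1))
    top = int(rng.integers(0, expanded_side - side + 1))
    left = int(rng.integers(0, expanded_side - side + 1))
    return CropBox(top=top, left=left, side=side)


def crop_without_rescale(expanded: ExpandedPatch, box: CropBox) -> np.ndarray:
    """Extract the crop box as an exact sub-array (no interpolation)."""
    E = expanded.side
    if box.top + box.side > E or box.left + box.side > E:
        raise ValueError(f"crop box {box} outside expanded patch of side {E}")
    return expanded.pixels[box.top:box.top + box.side,
                           box.left:box.left + box.side].copy()


def flip_view(view: np.ndarray, vertical: bool, horizontal: bool) -> np.ndarray:
    out = view
    if vertical:
        out = out[::-1]
    if horizontal:
        out = out[:, ::-1]
    return np.ascontiguousarray(out)


def _fast_rgb_to_hsv(x: np.ndarray) -> np.ndarray:
    """Vectorized RGB->HSV on float arrays in [0, 1] (single-precision)."""
    r, g, b = x[..., 0], x[..., 1], x[..., 2]
    maxc = np.maximum(np.maximum(r, g), b)
    minc = np.minimum(np.minimum(r, g), b)
    delta = maxc - minc
    safe_delta = np.where(delta == 0, 1.0, delta)
    h = np.where(maxc == r, (g - b) / safe_delta,
                 np.where(maxc == g, 2.0 + (b - r) / safe_delta,
                          4.0 + (r - g) / safe_delta))
    h = np.where(delta == 0, 0.0, (h / 6.0) % 1.0)
    s = np.where(maxc == 0, 0.0, delta / np.where(maxc == 0, 1.0, maxc))
    return np.stack([h, s, maxc], axis=-1)


def _fast_hsv_to_rgb(hsv: np.ndarray) -> np.ndarray:
    h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
    h6 = h * 6.0
    vs = v * s

    def channel(n):
        k = (n + h6) % 6.0
        return v - vs * np.clip(np.minimum(k, 4.0 - k), 0.0, 1.0)

    return np.stack([channel(5.0), channel(3.0), channel(1.0)], axis=-1)


def _color_jitter(view: np.ndarray, params: JitterParams, rng: np.random.Generator) -> np.ndarray:
    """Brightness/contrast/saturation/hue jitter; uint8 in, uint8 out."""
    x = view.astype(np.float32) / np.float32(255.0)
    fb = 1.0 + rng.uniform(-params.brightness, params.brightness)
    fc = 1.0 + rng.uniform(-params.contrast, params.contrast)
    fs = 1.0 + rng.uniform(-params.saturation, params.saturation)
    dh = rng.uniform(-params.hue, params.hue)
    x = np.clip(x * np.float32(fb), 0.0, 1.0)
    mean = x.mean(dtype=np.float32)
    x = np.clip(mean + (x - mean) * np.float32(fc), 0.0, 1.0)
    if params.saturation > 0 or params.hue > 0:
        hsv = _fast_rgb_to_hsv(x)
        hsv[..., 0] = np.mod(hsv[..., 0] + np.float32(dh), 1.0)
        hsv[..., 1] = np.clip(hsv[..., 1] * np.float32(fs), 0.0, 1.0)
        x = _fast_hsv_to_rgb(hsv)
    return np.clip(np.round(x * 255.0), 0, 255).astype(np.uint8)


def apply_augmentations(
    view: np.ndarray,
    regime: str,
    rng: np.random.Generator,
    config: ViewConfig | None = None,
) -> tuple[np.ndarray, tuple[bool, bool]]:
    """Apply flips (p = ``flip_p`` each) and regime-strength color jitter.

    Returns the augmented view and the (vertical, horizontal) flip record;
    random crop is realized upstream by :func:`sample_crop_box`, so geometry
    here is flips only and the harmonization invariant is preserved.
    """
    config = config or ViewConfig()
    if regime == "mild":
        jitter = config.mild_jitter
    elif regime == "hyper":
        jitter = config.hyper_jitter
    else:
        raise ValueError(f"unknown augmentation regime: {regime!r}")
    flip_v = bool(rng.random() < config.flip_p)
    flip_h = bool(rng.random() < config.flip_p)
    out = flip_view(view, flip_v, flip_h)
    if config.photometric:
        out = _color_jitter(out, jitter, rng)
    return out, (flip_v, flip_h)


def pad_to_canvas(
    view: np.ndarray,
    canvas_side: int = 224,
    fill: tuple[int, int, int] = (0, 0, 0),
) -> tuple[np.ndarray, tuple[int, int]]:
    """Place the view centered on a fixed canvas; fill elsewhere.

    Offsets are ``floor((canvas - side) / 2)`` per axis.
    """
    h, w = view.shape[:2]
    if h > canvas_side or w > canvas_side:
        raise ValueError(f"view {h}x{w} larger than canvas {canvas_side}")
    canvas = np.empty((canvas_side, canvas_side, 3), dtype=view.dtype)
    canvas[:] = np.asarray(fill, dtype=view.dtype)
    ro = (canvas_side - h) // 2
    co = (canvas_side - w) // 2
    canvas[ro:ro + h, co:co + w] = view
    return canvas, (ro, co)


def _make_view(expanded, view_class, regime, rng, config) -> HarmonizedView:
    box = sample_crop_box(rng, view_class, expanded.side)
    crop = crop_without_rescale(expanded, box)
    augmented, flips = apply_augmentations(crop, regime, rng, config)
    canvas, offsets = pad_to_canvas(augmented, config.canvas_side, config.fill)
    return HarmonizedView(canvas=canvas, crop=box, view_class=view_class,
                          regime=regime, pad_offsets=offsets, flipped=flips)


def build_view_set(
    expanded: ExpandedPatch,
    rng: np.random.Generator,
    config: ViewConfig | None = None,
) -> ViewSet:
    """Build the view set V: mild/teacher views first, then hyper views.

    Default configuration yields |V| = 8 with exactly 2 teacher views; the
    student set is all of V.
    """
    config = config or ViewConfig()
    views = [
        _make_view(expanded, config.mild_view_class, "mild", rng, config)
        for _ in range(config.n_mild)
    ]
    views += [
        _make_view(expanded, config.hyper_view_class, "hyper", rng, config)
        for _ in range(config.n_hyper)
    ]
    return ViewSet(views=tuple(views), teacher_indices=tuple(range(config.n_mild)))


def crossmodal_input_view(
    expanded: ExpandedPatch,
    rng: np.random.Generator | None = None,
    train: bool = False,
    side: int = 224,
    config: ViewConfig | None = None,
) -> np.ndarray:
    """Input view for the matching branch: random crop at train, center at eval.

    Training applies mild-regime augmentation; evaluation is fully
    deterministic (center crop, no flips, no jitter).
    """
    config = config or ViewConfig()
    E = expanded.side
    if E < side:
        raise ValueError(f"expanded side {E} smaller than input side {side}")
    if train:
        if rng is None:
            raise ValueError("training-mode input view requires an rng")
        top = int(rng.integers(0, E - side + 1))
        left = int(rng.integers(0, E - side + 1))
        crop = crop_without_rescale(expanded, CropBox(top, left, side))
        out, _ = apply_augmentations(crop, "mild", rng, config)
        return out
    off = (E - side) // 2
    return crop_without_rescale(expanded, CropBox(off, off, side))
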