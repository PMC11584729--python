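"""Self-contained synthetic slide/caption corpus.

Real whole-slide archives pair gigapixel stained-tissue images with
diagnosis text.  For desk-scale runs this module emulates that pairing
with class-distinct textured slides: each synthetic diagnosis class has a
base hue, a blob density and a templated caption; slides are white
backgrounds scattered with colored elliptical blobs.  The texture model is
deliberately crude — it exercises tiling geometry, masking, losses and
metrics, not histologic realism — but classes are separable by hue alone,
so a learnable retrieval signal exists by construction.

Everything is deterministic under the corpus seed, including rendered
pixels and the manifest.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage.color import hsv2rgb
from skimage.draw import ellipse

from .slide_io import SlideHandle

__all__ = [
    "SyntheticClassSpec",
    "SyntheticCorpus",
    "make_class_specs",
    "render_slide",
    "build_corpus",
]

_DENSITY_WORDS = ["sparse", "moderate", "dense"]
_PATTERN_WORDS = [
    "cribriform", "papillary", "tubular", "solid", "micropapillary",
    "mucinous", "lobular", "medullary", "apocrine", "metaplastic", "ductal",
]


@dataclass(frozen=True)
class SyntheticClassSpec:
    class_id: int
    name: str
    base_hue: float                 # [0, 1)
    hue_jitter: float
    blob_density: float             # blobs per 10^4 px^2
    blob_radius_range: tuple[int, int]
    caption: str


@dataclass
class SyntheticCorpus:
    manifest: pd.DataFrame          # slide_id, class_id, class_name, caption [, path]
    slides: dict[str, SlideHandle]
    class_specs: list[SyntheticClassSpec]
    seed: int

    @property
    def captions(self) -> list[str]:
        return [s.caption for s in self.class_specs]


def make_class_specs(n_classes: int, seed: int = 0) -> list[SyntheticClassSpec]:
    """Evenly hue-spaced class specifications with templated captions."""
    if not (2 <= n_classes <= 22):
        raise ValueError("n_classes must lie in [2, 22]")
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_classes):
        density = float(rng.uniform(1.0, 3.0))
        radius_lo = int(rng.integers(6, 10))
        radius_hi = int(rng.integers(14, 22))
        density_word = _DENSITY_WORDS[i % len(_DENSITY_WORDS)]
        pattern = _PATTERN_WORDS[i % len(_PATTERN_WORDS)]
        name = f"{pattern} carcinoma variant {i}"
        caption = (f"invasive {pattern} pattern with {density_word} clustered "
                   f"nuclei consistent with {name}")
        specs.append(SyntheticClassSpec(
            class_id=i,
            name=name,
            base_hue=i / n_classes,
            hue_jitter=0.25 / n_classes,
            blob_density=density,
            blob_radius_range=(radius_lo, radius_hi),
            caption=caption,
        ))
    return specs


def render_slide(spec: SyntheticClassSpec, side_px: int, seed: int) -> np.ndarray:
    """Render one slide: white background plus hue-coded elliptical blobs."""
    if side_px < 448:
        raise ValueError("side_px must be >= 448 so expansion-sized patches exist")
    rng = np.random.default_rng(seed)
    canvas = np.full((side_px, side_px, 3), 255, dtype=np.uint8)
    n_blobs = int(round(spec.blob_density * side_px * side_px / 1e4))
    lo, hi = spec.blob_radius_range
    for _ in range(n_blobs):
        r = rng.uniform(0, side_px)
        c = rng.uniform(0, side_px)
        r_radius = rng.uniform(lo, hi)
        c_radius = rng.uniform(lo, hi)
        rotation = rng.uniform(0, np.pi)
        hue = (spec.base_hue + rng.uniform(-spec.hue_jitter, spec.hue_jitter)) % 1.0
        sat = rng.uniform(0.55, 0.9)
        val = rng.uniform(0.35, 0.7)
        rgb = (np.asarray(hsv2rgb(np.array([[[hue, sat, val]]]))[0, 0]) * 255)
        rr, cc = ellipse(r, c, r_radius, c_radius, shape=(side_px, side_px),
                         rotation=rotation)
        canvas[rr, cc] = rgb.astype(np.uint8)
    return canvas


def build_corpus(n_classes: int, slides_per_class: int, side_px: int,
                 seed: int = 0, out_dir: str | Path | None = None) -> SyntheticCorpus:
    """Class-balanced corpus of rendered slides plus a manifest.

    With ``out_dir`` set, slides are written as PNG and the manifest as CSV
    alongside a JSON record of the class specs; otherwise everything stays
    in memory.  Regenerating with the same seed reproduces identical pixels
    and manifest rows.
    """
    if slides_per_class < 1 or side_px < 448:
        raise ValueError("invalid corpus sizes")
    specs = make_class_specs(n_classes, seed)
    rows, slides = [], {}
    for spec in specs:
        for j in range(slides_per_class):
            slide_id = f"class{spec.class_id:02d}_slide{j:02d}"
            # distinct, seed-derived stream per slide
            pixels = render_slide(spec, side_px,
                                  seed=seed * 100003 + spec.class_id * 1009 + j)
            slides[slide_id] = SlideHandle(slide_id, pixels)
            rows.append({"slide_id": slide_id, "class_id": spec.class_id,
                         "class_name": spec.name, "caption": spec.caption})
    manifest = pd.DataFrame(rows)
    if out_dir is not None:
        import imageio.v3 as iio
        import json

        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for slide_id, handle in slides.items():
            path = out_dir / f"{slide_id}.png"
            iio.imwrite(path, handle.read(0, 0, *handle.shape))
            paths.append(str(path))
        manifest = manifest.assign(path=paths)
        manifest.to_csv(out_dir / "manifest.csv", index=False)
        with open(out_dir / "class_specs.json", "w") as fh:
            json.dump([vars(s) | {"blob_radius_range": list(s.blob_radius_range)}
                       for s in specs], fh, indent=2)
    return SyntheticCorpus(manifest=manifest, slides=slides,
                           class_specs=specs, seed=seed)
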