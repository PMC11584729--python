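import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from histomatch.slide_io import ExpandedPatch, PatchSpec
from histomatch.synthetic import build_corpus, make_class_specs, render_slide


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_corpus():
    """4 classes x 2 slides of 640 px; session-scoped (rendering is ~0.5 s)."""
    return build_corpus(n_classes=4, slides_per_class=2, side_px=640, seed=7)


@pytest.fixture(scope="session")
def textured_expanded():
    """One 448-px expanded patch cut from a rendered synthetic slide."""
    spec = make_class_specs(4, seed=3)[1]
    slide = render_slide(spec, 640, seed=11)
    pixels = slide[64:512, 96:544]
    return ExpandedPatch(pixels=pixels,
                         spec=PatchSpec("s0", (64, 96), 448))


def random_expanded(rng, side=448):
    pixels = rng.integers(0, 256, (side, side, 3), dtype=np.uint8)
    return ExpandedPatch(pixels=pixels, spec=PatchSpec("rnd", (0, 0), side))
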