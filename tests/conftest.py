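import numpy as np
import pytest

from gradtex import (
    Displacement,
    GradientSpec,
    GrayImage,
    make_gradient_image,
    n_tilde,
)


def exact_period_image(ng: int, grad: int, d_mag: int, width: int = 4) -> GrayImage:
    """Smallest gradient phantom with uniform GLCM counts at displacement (0, d)."""
    height = n_tilde(ng, grad) + d_mag
    return make_gradient_image(
        GradientSpec(ng=ng, grad=grad, width=width, height=height,
                     exact_period_for=d_mag)
    )


def naive_count_pairs(img: GrayImage, disp: Displacement) -> np.ndarray:
    """Brute-force double-loop pair counter (independent oracle)."""
    h, w = img.pixels.shape
    counts = np.zeros((img.ng, img.ng), dtype=np.int64)
    for y in range(h):
        for x in range(w):
            ty, tx = y + disp.dy, x + disp.dx
            if 0 <= ty < h and 0 <= tx < w:
                counts[img.pixels[y, x], img.pixels[ty, tx]] += 1
    return counts


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20250430)


def random_image(rng: np.random.Generator, ng: int, height: int, width: int) -> GrayImage:
    return GrayImage(pixels=rng.integers(0, ng, size=(height, width)), ng=ng)


def random_glcm_prob(rng: np.random.Generator, ng: int, symmetric: bool = False):
    from gradtex import GLCMProb

    raw = rng.random((ng, ng))
    if symmetric:
        raw = raw + raw.T
    return GLCMProb(probs=raw / raw.sum(), displacement=Displacement(0, 1),
                    symmetric=symmetric)
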