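"""Haralick features: defining sums, conventions, symmetrization contract."""

import numpy as np
import pytest

from gradtex import (
    Displacement,
    GrayImage,
    SumMarginal,
    compute_feature_set,
    count_pairs,
    difference_average,
    difference_entropy,
    difference_variance,
    dist_moments,
    entropy,
    marginal_diff,
    marginal_sum,
    normalize,
    sum_average,
    sum_entropy,
    sum_variance,
    symmetrize,
)
from gradtex.features import feature_set_from_glcm
from conftest import exact_period_image, random_glcm_prob, random_image


def _gradient_prob(ng, grad, d, symmetric):
    img = exact_period_image(ng, grad, d)
    c = count_pairs(img, Displacement(0, d))
    if symmetric:
        c = symmetrize(c)
    return normalize(c)


def test_sum_average_examples():
    assert sum_average(marginal_sum(_gradient_prob(8, 2, 1, True))) == pytest.approx(6.0)
    assert sum_average(marginal_sum(_gradient_prob(256, 2, 3, True))) == pytest.approx(254.0)
    point = SumMarginal(probs=np.eye(1, 15, 0).ravel())
    assert sum_average(point) == 0.0


def test_sum_variance_examples():
    assert sum_variance(marginal_sum(_gradient_prob(8, 1, 1, True))) == pytest.approx(14.0)
    assert sum_variance(marginal_sum(_gradient_prob(8, 1, 2, True))) == pytest.approx(9.0)
    point = SumMarginal(probs=np.eye(1, 15, 4).ravel())
    assert sum_variance(point) == 0.0


def test_difference_average_examples():
    assert difference_average(marginal_diff(_gradient_prob(8, 1, 1, True))) == pytest.approx(0.0)
    # signed point mass at +3
    signed = np.zeros(15)
    signed[7 + 3] = 1.0
    from gradtex import DiffMarginal

    assert difference_average(DiffMarginal(signed=signed)) == 3.0
    # non-symmetric gradient GLCM: (7*1 + 1*(-7)) / 8 = 0
    assert difference_average(marginal_diff(_gradient_prob(8, 1, 1, False))) == pytest.approx(0.0)


def test_difference_variance_examples():
    assert difference_variance(marginal_diff(_gradient_prob(8, 1, 1, True))) == pytest.approx(7.0)
    assert difference_variance(marginal_diff(_gradient_prob(8, 2, 1, True))) == pytest.approx(12.0)
    uniform = GrayImage(pixels=np.zeros((4, 4), dtype=int), ng=4)
    fs = compute_feature_set(uniform, Displacement(0, 1))
    assert fs.f10 == 0.0


def test_difference_variance_equals_abs_second_moment_for_symmetric(rng):
    p = random_glcm_prob(rng, 8, symmetric=True)
    dm = marginal_diff(p)
    direct = float(np.dot(dm.absolute_support**2, dm.absolute))
    assert difference_variance(dm) == pytest.approx(direct)


def test_entropy_examples():
    assert entropy(_gradient_prob(8, 1, 1, False)) == pytest.approx(3.0)
    assert entropy(_gradient_prob(8, 2, 1, False)) == pytest.approx(2.0)
    uniform = GrayImage(pixels=np.full((4, 4), 2), ng=4)
    p = normalize(count_pairs(uniform, Displacement(0, 1)))
    assert entropy(p) == 0.0


def test_entropy_epsilon():
    p = _gradient_prob(8, 1, 1, False)
    with pytest.raises(ValueError):
        entropy(p, epsilon=-1e-3)
    # the legacy log(p + eps) guard biases the entropy downward
    assert entropy(p, epsilon=1e-3) < entropy(p, epsilon=0.0)


def test_sum_entropy_examples():
    sm = marginal_sum(_gradient_prob(8, 2, 1, True))  # {1/4, 1/2, 1/4}
    assert sum_entropy(sm) == pytest.approx(1.5)
    point = SumMarginal(probs=np.eye(1, 15, 4).ravel())
    assert sum_entropy(point) == 0.0
    m = 4
    probs = np.zeros(15)
    probs[:m] = 1 / m
    assert sum_entropy(SumMarginal(probs=probs)) == pytest.approx(np.log2(m))


def test_difference_entropy_examples():
    dm = marginal_diff(_gradient_prob(8, 1, 1, True))  # {7/8, 1/8}
    expected = -(7 / 8) * np.log2(7 / 8) - (1 / 8) * np.log2(1 / 8)
    assert difference_entropy(dm) == pytest.approx(expected)
    assert expected == pytest.approx(0.5436, abs=1e-4)

    from gradtex import DiffMarginal

    half = np.zeros(15)
    half[7] = half[8] = 0.5
    assert difference_entropy(DiffMarginal(signed=half)) == pytest.approx(1.0)


def test_compute_feature_set_uniform_image():
    img = GrayImage(pixels=np.full((5, 5), 3), ng=8)
    fs = compute_feature_set(img, Displacement(0, 1))
    assert fs.f6 == 6.0 and fs.f7 == fs.f9 == fs.f10 == 0.0


def test_compute_feature_set_gradient_and_entropy_shift():
    sym = compute_feature_set(exact_period_image(8, 1, 1), Displacement(0, 1))
    assert (sym.f6, sym.f7, sym.f10) == pytest.approx((7.0, 14.0, 7.0))
    nonsym = compute_feature_set(
        exact_period_image(8, 1, 1), Displacement(0, 1), symmetric=False
    )
    assert (nonsym.f6, nonsym.f7, nonsym.f10) == pytest.approx((7.0, 14.0, 7.0))
    assert sym.f9 - nonsym.f9 == pytest.approx(1.0, abs=1e-12)


def test_entropy_shift_vanishes_when_support_transpose_closed():
    """At period = 2|d| the non-symmetric support is already transpose-closed."""
    img = exact_period_image(8, 1, 4)
    sym = compute_feature_set(img, Displacement(0, 4))
    nonsym = compute_feature_set(img, Displacement(0, 4), symmetric=False)
    assert sym.f9 - nonsym.f9 == pytest.approx(0.0, abs=1e-12)


def test_marginal_features_invariant_under_symmetrization(rng):
    """Sum-marginal and absolute-difference features are transpose-addition
    invariant for any image; the signed-mean features obey the exact
    variance-shift identity f10_sym = f10_nonsym + da_nonsym**2."""
    for _ in range(10):
        img = random_image(rng, int(rng.integers(2, 10)), 12, 9)
        for disp in (Displacement(0, 1), Displacement(1, -2)):
            a = compute_feature_set(img, disp, symmetric=False)
            b = compute_feature_set(img, disp, symmetric=True)
            for name in ("f6", "f7", "f8", "f11"):
                assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-12)
            assert b.da == pytest.approx(0.0, abs=1e-12)
            assert b.f10 == pytest.approx(a.f10 + a.da**2, abs=1e-10)


def test_gradient_features_invariant_under_symmetrization():
    """On gradient phantoms the signed difference mean vanishes, so f10 and da
    are fully symmetrization-invariant too."""
    for ng, grad, d in [(8, 1, 1), (16, 3, 2), (64, 5, 3)]:
        img = exact_period_image(ng, grad, d)
        a = compute_feature_set(img, Displacement(0, d), symmetric=False)
        b = compute_feature_set(img, Displacement(0, d), symmetric=True)
        for name in ("f6", "f7", "f8", "f10", "f11", "da"):
            assert getattr(a, name) == pytest.approx(getattr(b, name), abs=1e-12)


def test_f7_f10_match_marginal_moments(rng):
    p = random_glcm_prob(rng, 9)
    fs = feature_set_from_glcm(p)
    assert fs.f7 == pytest.approx(dist_moments(marginal_sum(p))[1])
    assert fs.f10 == pytest.approx(dist_moments(marginal_diff(p))[1])


def test_nonnegativity_on_random_glcms(rng):
    for _ in range(20):
        fs = feature_set_from_glcm(random_glcm_prob(rng, int(rng.integers(2, 12))))
        assert fs.f7 >= 0 and fs.f10 >= 0
        assert fs.f8 >= 0 and fs.f9 >= 0 and fs.f11 >= 0


def test_feature_set_records_provenance():
    fs = compute_feature_set(exact_period_image(8, 1, 1), Displacement(0, 1),
                             log_base=np.e, epsilon=1e-4)
    d = fs.as_dict()
    assert d["provenance"] == {
        "symmetric": True, "log_base": np.e, "epsilon": 1e-4, "dx": 0, "dy": 1,
    }
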