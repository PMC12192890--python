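"""Closed forms, asymptotics and normalizations for gradient-image features.

For a periodic linear gradient of ``grad`` levels per pixel in an image
quantized to ``ng`` gray levels, the non-symmetrized single-period GLCM
at a vertical displacement of magnitude ``d`` has a rigid structure: all
its nonzero cells carry equal weight and sit on exactly two lines
parallel to the main diagonal,

* ``n_tilde = 1 + floor((ng - 1) / grad)`` nonzero cells in total
  (also the gradient's period in pixels),
* ``m1 = n_tilde - d`` of them on the difference line ``j - i = d*grad``,
* ``m2 = d`` on the wrap line ``j - i = -m1*grad`` created by the
  periodic restart of the ramp.

From this structure the marginal distributions and the marginal-based
Haralick features follow in closed form:

======================  =========================================================
sum average      (SA)   ``(n_tilde - 1) * grad``          ~  ``ng - 1``
sum variance     (SV)   ``grad**2 * (n_tilde**2/3 - n_tilde*d + d**2 - 1/3)``
difference var.  (DV)   ``grad**2 * d * (n_tilde - d)``
entropy                 ``log(n_tilde)``
======================  =========================================================

which yield the scaling laws SA ~ ng, SV ~ ng**2 (linear in d*grad),
DV ~ ng*d*grad, entropy ~ log(ng), and hence the quantization-invariant
normalizations SA/ng, SV/ng**2, DV/ng, entropy/log(ng).

All closed forms require ``d < n_tilde``; beyond that the displacement
exceeds the gradient period, the two-line support structure breaks down,
and the functions raise rather than extrapolate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .marginals import DiffMarginal, SumMarginal

__all__ = [
    "GradientGLCMStructure",
    "AnalyticPrediction",
    "ScalingLaw",
    "n_tilde",
    "line_counts",
    "diff_marginal_closed",
    "sum_marginal_closed",
    "sa_closed",
    "sa_approx",
    "sv_closed",
    "sv_approx",
    "dv_closed",
    "dv_approx",
    "entropy_closed",
    "predict",
    "scaling_exponents",
    "normalize_features",
    "NormalizedFeatureSet",
]


def n_tilde(ng: int, grad: int) -> int:
    """Number of nonzero GLCM cells of a linear gradient: ``1 + floor((ng-1)/grad)``.

    Also the gradient's spatial period in pixels, since the single-period
    ramp visits each of these levels exactly once.
    """
    ng = int(ng)
    grad = int(grad)
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    if not 1 <= grad <= ng - 1:
        raise ValueError(f"grad must satisfy 1 <= grad <= ng - 1, got grad={grad}, ng={ng}")
    return 1 + (ng - 1) // grad


@dataclass(frozen=True)
class GradientGLCMStructure:
    """Support structure of a gradient's non-symmetrized GLCM."""

    ng: int
    grad: int
    d_mag: int
    n_tilde: int
    m1: int
    m2: int

    def __post_init__(self) -> None:
        assert self.m1 + self.m2 == self.n_tilde
        assert self.m2 == self.d_mag
        assert self.m1 >= 1


def line_counts(ng: int, grad: int, d_mag: int) -> GradientGLCMStructure:
    """Split the ``n_tilde`` nonzero cells between the two difference lines.

    ``m1 = n_tilde - |d|`` cells lie on ``j - i = d*grad`` and
    ``m2 = |d|`` on the wrap line ``j - i = -m1*grad``.
    """
    nt = n_tilde(ng, grad)
    d_mag = int(d_mag)
    if not 1 <= d_mag < nt:
        raise ValueError(
            f"displacement magnitude must satisfy 1 <= |d| < n_tilde={nt}; "
            f"got |d|={d_mag} (displacement exceeds gradient period)"
        )
    return GradientGLCMStructure(
        ng=ng, grad=grad, d_mag=d_mag, n_tilde=nt, m1=nt - d_mag, m2=d_mag
    )


def diff_marginal_closed(s: GradientGLCMStructure) -> DiffMarginal:
    """Two-point difference marginal of a gradient GLCM.

    Signed masses: ``m1/n_tilde`` at ``k = +d*grad`` and ``m2/n_tilde``
    at ``k = -m1*grad``; in absolute value the two points merge when
    ``d = m1``.
    """
    ng = s.ng
    signed = np.zeros(2 * ng - 1)
    signed[s.d_mag * s.grad + ng - 1] += s.m1 / s.n_tilde
    signed[-s.m1 * s.grad + ng - 1] += s.m2 / s.n_tilde
    return DiffMarginal(signed=signed)


def sum_marginal_closed(s: GradientGLCMStructure) -> SumMarginal:
    """Sum marginal of a gradient GLCM.

    Mass ``1/n_tilde`` at ``s = 2*i*grad + d*grad`` for the ``m1`` cells
    on the main difference line (i = 0..m1-1) and at
    ``s = 2*i*grad - m1*grad`` for the ``m2`` wrap cells
    (i = m1..n_tilde-1); coincident sums accumulate.
    """
    ng = s.ng
    probs = np.zeros(2 * ng - 1)
    i1 = s.grad * np.arange(s.m1)
    s1 = 2 * i1 + s.d_mag * s.grad
    i2 = s.grad * np.arange(s.m1, s.n_tilde)
    s2 = 2 * i2 - s.m1 * s.grad
    np.add.at(probs, np.concatenate([s1, s2]), 1.0 / s.n_tilde)
    return SumMarginal(probs=probs)


def sa_closed(ng: int, grad: int) -> float:
    """Exact sum average: ``(n_tilde - 1) * grad = grad * floor((ng-1)/grad)``.

    Independent of the displacement magnitude.
    """
    return float((n_tilde(ng, grad) - 1) * grad)


def sa_approx(ng: int) -> float:
    """Continuous approximation of the sum average: ``ng - 1``."""
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    return float(ng - 1)


def sv_closed(ng: int, grad: int, d_mag: int) -> float:
    """Exact sum variance: ``grad**2 * (n_tilde**2/3 - n_tilde*d + d**2 - 1/3)``."""
    s = line_counts(ng, grad, d_mag)
    nt = s.n_tilde
    return float(grad**2 * (nt**2 / 3 - nt * d_mag + d_mag**2 - 1 / 3))


def sv_approx(ng: int, grad: int, d_mag: int) -> float:
    """Sum-variance asymptotics with the integer part dropped:
    ``(ng-1)**2/3 - (ng-1)*d*grad + d**2*grad**2 - grad**2/3``."""
    line_counts(ng, grad, d_mag)  # validate domain
    return float(
        (ng - 1) ** 2 / 3 - (ng - 1) * d_mag * grad + d_mag**2 * grad**2 - grad**2 / 3
    )


def dv_closed(ng: int, grad: int, d_mag: int) -> float:
    """Exact difference variance: ``grad**2 * d * (n_tilde - d)``.

    This is the algebraic reduction of
    ``(m1*(d*grad)**2 + m2*(m1*grad)**2) / n_tilde`` with
    ``m1 = n_tilde - d`` and ``m2 = d``.
    """
    s = line_counts(ng, grad, d_mag)
    return float(grad**2 * d_mag * (s.n_tilde - d_mag))


def dv_approx(ng: int, grad: int, d_mag: int, coarse: bool = False) -> float:
    """Difference-variance asymptotics: ``grad*d*(ng-1) + (1-d)*grad**2``.

    With ``coarse=True`` returns the leading-order form ``grad*d*ng``.
    """
    line_counts(ng, grad, d_mag)  # validate domain
    if coarse:
        return float(grad * d_mag * ng)
    return float(grad * d_mag * (ng - 1) + (1 - d_mag) * grad**2)


def entropy_closed(ng: int, grad: int, log_base: float = 2.0) -> float:
    """Entropy of the non-symmetrized single-period gradient GLCM: ``log(n_tilde)``.

    All ``n_tilde`` nonzero cells carry equal weight, so the joint entropy
    is the log of the support size; independent of the displacement.
    Symmetrizing adds exactly ``log 2`` whenever the support is not
    already transpose-closed (i.e. whenever ``n_tilde != 2*|d|``); that
    shift belongs to the numeric feature layer, not to this closed form.
    """
    return math.log(n_tilde(ng, grad)) / math.log(log_base)


@dataclass(frozen=True)
class AnalyticPrediction:
    """Bundle of closed-form and approximate feature values for one (ng, grad, d)."""

    structure: GradientGLCMStructure
    f6_exact: float
    f6_approx: float
    f7_exact: float
    f7_approx: float
    f9_exact: float
    f10_exact: float
    f10_approx: float
    log_base: float = 2.0


def predict(ng: int, grad: int, d_mag: int, log_base: float = 2.0) -> AnalyticPrediction:
    """All closed-form and approximate predictions for one parameter triple."""
    s = line_counts(ng, grad, d_mag)
    return AnalyticPrediction(
        structure=s,
        f6_exact=sa_closed(ng, grad),
        f6_approx=sa_approx(ng),
        f7_exact=sv_closed(ng, grad, d_mag),
        f7_approx=sv_approx(ng, grad, d_mag),
        f9_exact=entropy_closed(ng, grad, log_base),
        f10_exact=dv_closed(ng, grad, d_mag),
        f10_approx=dv_approx(ng, grad, d_mag),
        log_base=log_base,
    )


@dataclass(frozen=True)
class ScalingLaw:
    """Asymptotic dependence ``f ~ ng**alpha * d**beta * grad**gamma``.

    ``alpha`` is ``None`` for the logarithmic entropy trend.  A starred
    qualitative tag marks a weak residual dependence (the integer-part
    correction), negligible for gradients below ~10 levels/pixel.
    """

    feature: str
    alpha: float | None
    beta: float
    gamma: float
    ng_tag: str
    d_tag: str
    grad_tag: str


def scaling_exponents() -> dict[str, ScalingLaw]:
    """Asymptotic scaling-law ledger for the four gradient features."""
    return {
        "f6": ScalingLaw("f6", 1, 0, 0, "linear", "independent", "independent*"),
        "f7": ScalingLaw("f7", 2, 1, 1, "quadratic", "linear", "linear"),
        "f10": ScalingLaw("f10", 1, 1, 1, "linear", "linear", "linear"),
        "f9": ScalingLaw("f9", None, 0, 0, "logarithmic", "independent", "independent*"),
    }


@dataclass(frozen=True)
class NormalizedFeatureSet:
    """Quantization-invariant feature values and the divisors used."""

    values: dict[str, float]
    divisors: dict[str, float]
    ng: int
    log_base: float


def normalize_features(fs, ng: int, log_base: float = 2.0) -> NormalizedFeatureSet:
    """Rescale features so they become asymptotically independent of ``ng``.

    Averaged features (f6, da) divide by ``ng``; variances (f7) by
    ``ng**2`` except the difference variance f10, which scales linearly
    and divides by ``ng``; entropic features (f8, f9, f11) divide by
    ``log(ng)``.
    """
    if ng < 2:
        raise ValueError(f"ng must be >= 2, got {ng}")
    log_ng = math.log(ng) / math.log(log_base)
    divisors = {
        "f6": float(ng),
        "f7": float(ng) ** 2,
        "f8": log_ng,
        "f9": log_ng,
        "f10": float(ng),
        "f11": log_ng,
        "da": float(ng),
    }
    values = {}
    for name, div in divisors.items():
        raw = getattr(fs, name, None)
        if raw is None and isinstance(fs, dict):
            raw = fs.get(name)
        if raw is not None:
            values[name] = float(raw) / div
    return NormalizedFeatureSet(values=values, divisors=divisors, ng=ng, log_base=log_base)
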