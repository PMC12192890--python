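"""Marginal-based Haralick features: f6-f11 and the difference average.

All features are moments or entropies of the sum marginal ``p_{x+y}``,
the difference marginal ``p_{x-y}`` or the joint GLCM:

* f6  sum average          mean of ``p_{x+y}``
* f7  sum variance         variance of ``p_{x+y}`` around f6
* f8  sum entropy          entropy of ``p_{x+y}``
* f9  entropy              joint entropy of ``p(i, j)``
* f10 difference variance  variance of the *signed* difference marginal
* f11 difference entropy   entropy of the absolute difference marginal
* da  difference average   mean of the *signed* difference marginal

Two conventions deserve a note.  First, the difference average here is
the signed mean ``sum_k k * p(j - i = k)``, which vanishes identically
for symmetric GLCMs; many radiomics toolkits instead average ``|i - j|``.
Under the signed convention f10 reduces, for symmetric input, to
``sum_{k>=0} k**2 * p(|i - j| = k)``.  Second, entropies default to
``epsilon = 0`` with the ``0 * log 0 = 0`` convention; a positive
``epsilon`` reproduces legacy implementations that guard the logarithm
with ``log(p + epsilon)``, which biases every entropy downward.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .glcm import Displacement, GLCMProb, count_pairs, normalize, symmetrize
from .marginals import (
    DiffMarginal,
    SumMarginal,
    dist_moments,
    marginal_diff,
    marginal_sum,
)
from .phantoms import GrayImage

__all__ = [
    "FeatureSet",
    "sum_average",
    "sum_variance",
    "difference_average",
    "difference_variance",
    "entropy",
    "sum_entropy",
    "difference_entropy",
    "compute_feature_set",
]


def sum_average(sm: SumMarginal) -> float:
    """f6: mean gray-level sum, ``sum_s s * p_{x+y}(s)``."""
    return dist_moments(sm)[0]


def sum_variance(sm: SumMarginal) -> float:
    """f7: variance of the gray-level sum around f6 (recomputed internally)."""
    return dist_moments(sm)[1]


def difference_average(dm: DiffMarginal) -> float:
    """Signed difference average, ``sum_k k * p(j - i = k)``; 0 for symmetric GLCMs."""
    return dist_moments(dm)[0]


def difference_variance(dm: DiffMarginal) -> float:
    """f10: variance of the signed gray-level difference around its mean."""
    return dist_moments(dm)[1]


def _entropy_of(probs: np.ndarray, log_base: float, epsilon: float) -> float:
    if epsilon < 0:
        raise ValueError(f"epsilon must be >= 0, got {epsilon}")
    p = np.asarray(probs, dtype=float).ravel()
    if epsilon == 0:
        nz = p[p > 0]
        h = -float(np.dot(nz, np.log(nz)))
    else:
        h = -float(np.dot(p, np.log(p + epsilon)))
    return h / math.log(log_base)


def entropy(p: GLCMProb, log_base: float = 2.0, epsilon: float = 0.0) -> float:
    """f9: joint GLCM entropy ``-sum p(i,j) log(p(i,j) + epsilon)``.

    Base 2 yields bits.  With ``epsilon = 0`` empty cells contribute
    nothing (``0 log 0 = 0``).
    """
    return _entropy_of(p.probs, log_base, epsilon)


def sum_entropy(sm: SumMarginal, log_base: float = 2.0, epsilon: float = 0.0) -> float:
    """f8: entropy of the sum marginal."""
    return _entropy_of(sm.probs, log_base, epsilon)


def difference_entropy(
    dm: DiffMarginal, log_base: float = 2.0, epsilon: float = 0.0
) -> float:
    """f11: entropy of the absolute difference marginal."""
    return _entropy_of(dm.absolute, log_base, epsilon)


@dataclass(frozen=True)
class FeatureSet:
    """Feature values plus the provenance that shaped them."""

    f6: float
    f7: float
    f8: float
    f9: float
    f10: float
    f11: float
    da: float
    symmetric: bool
    log_base: float
    epsilon: float
    displacement: Displacement | None = None

    def as_dict(self) -> dict:
        return {
            "f6": self.f6, "f7": self.f7, "f8": self.f8, "f9": self.f9,
            "f10": self.f10, "f11": self.f11, "da": self.da,
            "provenance": {
                "symmetric": self.symmetric,
                "log_base": self.log_base,
                "epsilon": self.epsilon,
                "dx": None if self.displacement is None else self.displacement.dx,
                "dy": None if self.displacement is None else self.displacement.dy,
            },
        }


def feature_set_from_glcm(
    p: GLCMProb, log_base: float = 2.0, epsilon: float = 0.0
) -> FeatureSet:
    """All marginal-based features of one normalized GLCM."""
    sm = marginal_sum(p)
    dm = marginal_diff(p)
    return FeatureSet(
        f6=sum_average(sm),
        f7=sum_variance(sm),
        f8=sum_entropy(sm, log_base, epsilon),
        f9=entropy(p, log_base, epsilon),
        f10=difference_variance(dm),
        f11=difference_entropy(dm, log_base, epsilon),
        da=difference_average(dm),
        symmetric=p.symmetric,
        log_base=log_base,
        epsilon=epsilon,
        displacement=p.displacement,
    )


def compute_feature_set(
    img: GrayImage,
    disp: Displacement,
    symmetric: bool = True,
    log_base: float = 2.0,
    epsilon: float = 0.0,
) -> FeatureSet:
    """Full pipeline: count pairs, optionally symmetrize, normalize, reduce.

    ``symmetric`` defaults to true (the classical GLCM definition);
    symmetrization leaves every marginal-based feature unchanged and can
    only affect the joint entropy f9.
    """
    counts = count_pairs(img, disp)
    if symmetric:
        counts = symmetrize(counts)
    return feature_set_from_glcm(normalize(counts), log_base, epsilon)
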