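"""Marginal distributions of a normalized GLCM and their moments.

Four marginals are derived from the joint distribution ``p(i, j)`` of
reference level ``i`` and target level ``j``:

* ``p_x(i)`` — row sums: probability of level ``i`` at the reference pixel;
* ``p_y(j)`` — column sums: probability of level ``j`` at the target pixel;
* ``p_{x+y}(s)`` — anti-diagonal sums over ``s = i + j``;
* ``p_{x-y}(k)`` — diagonal-parallel sums over the gray-level difference.

The difference marginal is kept in two conventions.  The *absolute* form
sums the super- and sub-diagonal at ``|i - j| = k`` (the classical
definition).  The *signed* form over ``k = j - i`` is what the
difference-average and difference-variance derivations for gradients
actually use: for a symmetric GLCM its mean is exactly zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover
    from .glcm import GLCMProb

__all__ = [
    "LevelMarginal",
    "SumMarginal",
    "DiffMarginal",
    "marginal_x",
    "marginal_y",
    "marginal_sum",
    "marginal_diff",
    "dist_moments",
]

_SUM_TOL = 1e-9


def _check_normalized(probs: np.ndarray) -> np.ndarray:
    probs = np.asarray(probs, dtype=float)
    if probs.min() < 0:
        raise ValueError("marginal probabilities must be non-negative")
    if abs(probs.sum() - 1.0) > _SUM_TOL:
        raise ValueError(f"marginal must sum to 1, got {probs.sum()!r}")
    return probs


@dataclass(frozen=True)
class LevelMarginal:
    """Distribution over gray levels 0..ng-1 along one GLCM axis."""

    probs: np.ndarray
    axis: str  # "x" (reference / rows) or "y" (target / columns)

    def __post_init__(self) -> None:
        object.__setattr__(self, "probs", _check_normalized(self.probs))
        if self.axis not in ("x", "y"):
            raise ValueError(f"axis must be 'x' or 'y', got {self.axis!r}")

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))


@dataclass(frozen=True)
class SumMarginal:
    """Distribution over gray-level sums s = i + j in 0..2(ng-1)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = _check_normalized(self.probs)
        if len(probs) % 2 == 0:
            raise ValueError("sum marginal must have odd length 2*ng - 1")
        object.__setattr__(self, "probs", probs)

    @property
    def ng(self) -> int:
        return (len(self.probs) + 1) // 2

    @property
    def support(self) -> np.ndarray:
        return np.arange(len(self.probs))


@dataclass(frozen=True)
class DiffMarginal:
    """Signed and absolute distributions of the gray-level difference.

    ``signed[k + ng - 1]`` holds the mass of ``k = j - i`` for
    ``k in [-(ng-1), ng-1]``; ``absolute[k]`` holds the mass of
    ``|i - j| = k`` for ``k in [0, ng-1]``.
    """

    signed: np.ndarray

    def __post_init__(self) -> None:
        signed = _check_normalized(self.signed)
        if len(signed) % 2 == 0:
            raise ValueError("signed difference marginal must have odd length 2*ng - 1")
        object.__setattr__(self, "signed", signed)

    @property
    def ng(self) -> int:
        return (len(self.signed) + 1) // 2

    @property
    def support(self) -> np.ndarray:
        """Signed difference values k = j - i."""
        n = self.ng
        return np.arange(-(n - 1), n)

    @property
    def probs(self) -> np.ndarray:
        """Alias for the signed probabilities (moment convention)."""
        return self.signed

    @property
    def absolute(self) -> np.ndarray:
        n = self.ng
        out = np.empty(n)
        out[0] = self.signed[n - 1]
        out[1:] = self.signed[n:] + self.signed[n - 2 :: -1]
        return out

    @property
    def absolute_support(self) -> np.ndarray:
        return np.arange(self.ng)


def marginal_x(p: "GLCMProb") -> LevelMarginal:
    """Row sums of the normalized GLCM: reference-pixel level distribution."""
    return LevelMarginal(probs=p.probs.sum(axis=1), axis="x")


def marginal_y(p: "GLCMProb") -> LevelMarginal:
    """Column sums of the normalized GLCM: target-pixel level distribution."""
    return LevelMarginal(probs=p.probs.sum(axis=0), axis="y")


def marginal_sum(p: "GLCMProb") -> SumMarginal:
    """Anti-diagonal sums: distribution of s = i + j."""
    ng = p.probs.shape[0]
    i, j = np.indices((ng, ng))
    probs = np.bincount((i + j).ravel(), weights=p.probs.ravel(), minlength=2 * ng - 1)
    return SumMarginal(probs=probs)


def marginal_diff(p: "GLCMProb") -> DiffMarginal:
    """Diagonal-parallel sums: distribution of the difference k = j - i."""
    ng = p.probs.shape[0]
    i, j = np.indices((ng, ng))
    signed = np.bincount(
        (j - i + ng - 1).ravel(), weights=p.probs.ravel(), minlength=2 * ng - 1
    )
    return DiffMarginal(signed=signed)


def dist_moments(m: LevelMarginal | SumMarginal | DiffMarginal) -> tuple[float, float]:
    """Mean and variance of a marginal over its support.

    For a :class:`DiffMarginal` the *signed* convention is used, so a
    symmetric GLCM yields a mean of exactly zero.
    """
    k = m.support.astype(float)
    w = m.probs
    mean = float(np.dot(k, w))
    var = float(np.dot((k - mean) ** 2, w))
    return mean, var
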