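"""Gray-level co-occurrence counting, symmetrization and normalization.

The engine counts ordered pairs of gray levels ``(i, j)`` found at the
reference pixel and at the pixel displaced by ``d = (dx, dy)``, where
``dx`` is the column offset (rightward) and ``dy`` the row offset
(downward).  Counting never wraps around the image border: for an
``Nx x Ny`` image the number of pairs is exactly
``(Nx - |dx|) * (Ny - |dy|)``.  An optional periodic mode that does wrap
is provided for experiments with translation-invariant patterns.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .phantoms import GrayImage

__all__ = [
    "Displacement",
    "GLCMCounts",
    "GLCMProb",
    "count_pairs",
    "symmetrize",
    "normalize",
    "pair_counts_xy",
    "build_2d_gradient_map",
    "wrap_gradient_map",
    "write_glcm_csv",
    "read_glcm_csv",
    "write_glcm_json",
    "read_glcm_json",
]


@dataclass(frozen=True)
class Displacement:
    """Pixel offset between reference and target: dx = columns, dy = rows."""

    dx: int
    dy: int

    def __post_init__(self) -> None:
        if self.dx == 0 and self.dy == 0:
            raise ValueError("displacement must be nonzero")

    @property
    def magnitude(self) -> float:
        return float(np.hypot(self.dx, self.dy))

    def __neg__(self) -> "Displacement":
        return Displacement(-self.dx, -self.dy)


@dataclass(frozen=True)
class GLCMCounts:
    """Unnormalized pair-count matrix; rows = reference level i, columns = target level j."""

    counts: np.ndarray
    displacement: Displacement
    symmetric: bool = False

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.ndim != 2 or c.shape[0] != c.shape[1]:
            raise ValueError("counts must be a square matrix")
        if not np.issubdtype(c.dtype, np.integer):
            raise ValueError("counts must be integer")
        if c.min() < 0:
            raise ValueError("counts must be non-negative")
        object.__setattr__(self, "counts", c)

    @property
    def ng(self) -> int:
        return self.counts.shape[0]

    @property
    def total_pairs(self) -> int:
        return int(self.counts.sum())

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.counts))


@dataclass(frozen=True)
class GLCMProb:
    """Normalized GLCM p(i, j); entries sum to one."""

    probs: np.ndarray
    displacement: Displacement
    symmetric: bool = False

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 2 or p.shape[0] != p.shape[1]:
            raise ValueError("probs must be a square matrix")
        if p.min() < 0 or p.max() > 1:
            raise ValueError("probabilities must lie in [0, 1]")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError(f"probabilities must sum to 1, got {p.sum()!r}")
        object.__setattr__(self, "probs", p)

    @property
    def ng(self) -> int:
        return self.probs.shape[0]


def count_pairs(
    img: GrayImage, disp: Displacement, periodic: bool = False
) -> GLCMCounts:
    """Count co-occurrences of gray levels at the given displacement.

    ``counts[i, j]`` is the number of positions ``(x, y)`` such that both
    ``(x, y)`` and ``(x + dx, y + dy)`` lie inside the image,
    ``img(y, x) = i`` and ``img(y + dy, x + dx) = j``.  With
    ``periodic=True`` the target coordinate wraps modulo the image size
    and every pixel contributes a pair.
    """
    dx, dy = disp.dx, disp.dy
    h, w = img.pixels.shape
    if abs(dx) >= w or abs(dy) >= h:
        raise ValueError(
            f"displacement ({dx}, {dy}) not smaller than image extent {w}x{h}"
        )
    px = img.pixels
    if periodic:
        ref = px
        tgt = np.roll(np.roll(px, -dy, axis=0), -dx, axis=1)
    else:
        ref = px[max(0, -dy) : h - max(0, dy), max(0, -dx) : w - max(0, dx)]
        tgt = px[max(0, dy) : h + min(0, dy), max(0, dx) : w + min(0, dx)]
    ng = img.ng
    flat = ref.ravel().astype(np.int64) * ng + tgt.ravel()
    counts = np.bincount(flat, minlength=ng * ng).reshape(ng, ng)
    return GLCMCounts(counts=counts, displacement=disp, symmetric=False)


def symmetrize(c: GLCMCounts) -> GLCMCounts:
    """Add the transposed counts so (i, j) and (j, i) pairings both register.

    Doubles the total pair count.  Refuses to run twice on the same
    matrix: the operation is not idempotent on the counts.
    """
    if c.symmetric:
        raise ValueError("GLCM is already symmetric")
    return GLCMCounts(
        counts=c.counts + c.counts.T, displacement=c.displacement, symmetric=True
    )


def normalize(c: GLCMCounts) -> GLCMProb:
    """Divide the counts by the total number of pairs."""
    total = c.total_pairs
    if total == 0:
        raise ValueError("cannot normalize an empty GLCM")
    return GLCMProb(
        probs=c.counts / total, displacement=c.displacement, symmetric=c.symmetric
    )


def pair_counts_xy(width: int, height: int) -> tuple[int, int]:
    """Counts of horizontal and vertical unit-displacement pairs.

    ``R_x = (width - 1) * height`` pairs at d = (1, 0) and
    ``R_y = width * (height - 1)`` pairs at d = (0, 1).
    """
    if width < 1 or height < 1:
        raise ValueError("width and height must be >= 1")
    return (width - 1) * height, width * (height - 1)


def _stripe_column(img: GrayImage) -> np.ndarray:
    px = img.pixels
    if not (px == px[:, :1]).all():
        raise ValueError("expected a vertical-stripe image (rows of constant intensity)")
    return px[:, 0]


def build_2d_gradient_map(img: GrayImage, d_mag: int) -> np.ndarray:
    """Spatial pair-indicator map of a vertical-stripe gradient (debug/teaching aid).

    The map lives in *unwrapped intensity* coordinates: row ``y`` of the
    image is assigned the unwrapped level ``y * grad`` (no periodic
    restart), and the map has a 1 at ``(y*grad, (y+d)*grad)`` for every
    vertical pair ``(y, y+d)`` present in the image whose intensity step
    follows the gradient, i.e. ``I(y+d) - I(y) = d * grad``.  Wrap pairs,
    whose intensity restarts, are recorded at the same spatial slots so
    the full map folds onto the GLCM support (see
    :func:`wrap_gradient_map`).  Consecutive nonzero entries are spaced
    ``grad`` apart along both axes.
    """
    col = _stripe_column(img)
    h = len(col)
    if not 1 <= d_mag < h:
        raise ValueError(f"d_mag must satisfy 1 <= d_mag < height={h}")
    if h < 2 or col[1] <= col[0]:
        raise ValueError("image is not an increasing vertical gradient")
    grad = int(col[1] - col[0])
    size = (h - 1) * grad + 1
    out = np.zeros((size, size), dtype=np.uint8)
    ys = np.arange(h - d_mag)
    out[ys * grad, (ys + d_mag) * grad] = 1
    return out

def wrap_gradient_map(gmap: np.ndarray, ng: int, grad: int) -> np.ndarray:
    """Fold the unwrapped-intensity map onto gray levels, giving the GLCM support.

    The unwrapped level ``y * grad`` reduces to the stored gray level
    modulo one full ramp excursion ``n_tilde * grad`` (which equals
    ``ng`` whenever ``grad`` divides ``ng``, e.g. for grad = 1).
    """
    from .analytic import n_tilde

    period_levels = n_tilde(ng, grad) * grad
    size = gmap.shape[0]
    support = np.zeros((ng, ng), dtype=np.uint8)
    ii, jj = np.nonzero(gmap)
    support[ii % period_levels, jj % period_levels] = 1
    return support


# ---------------------------------------------------------------------------
# Dense CSV / sparse JSON round-trips


def write_glcm_csv(c: GLCMCounts | GLCMProb, path: str | Path) -> None:
    """Dense CSV with a gray-level header row and column."""
    mat = c.counts if isinstance(c, GLCMCounts) else c.probs
    ng = mat.shape[0]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["i\\j"] + list(range(ng)))
        for i in range(ng):
            w.writerow([i] + list(mat[i]))


def read_glcm_csv(path: str | Path, displacement: Displacement, symmetric: bool = False) -> GLCMCounts:
    with open(path, newline="") as fh:
        rows = list(csv.reader(fh))
    body = [[int(float(v)) for v in row[1:]] for row in rows[1:]]
    return GLCMCounts(
        counts=np.asarray(body, dtype=np.int64),
        displacement=displacement,
        symmetric=symmetric,
    )


def write_glcm_json(c: GLCMCounts, path: str | Path) -> None:
    """Sparse triplet JSON: {ng, dx, dy, symmetric, entries: [[i, j, count], ...]}."""
    ii, jj = np.nonzero(c.counts)
    payload = {
        "ng": c.ng,
        "dx": c.displacement.dx,
        "dy": c.displacement.dy,
        "symmetric": c.symmetric,
        "entries": [[int(i), int(j), int(c.counts[i, j])] for i, j in zip(ii, jj)],
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def read_glcm_json(path: str | Path) -> GLCMCounts:
    payload = json.loads(Path(path).read_text())
    counts = np.zeros((payload["ng"], payload["ng"]), dtype=np.int64)
    for i, j, v in payload["entries"]:
        counts[i, j] = v
    return GLCMCounts(
        counts=counts,
        displacement=Displacement(payload["dx"], payload["dy"]),
        symmetric=payload["symmetric"],
    )
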