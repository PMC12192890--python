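"""Periodic linear-gradient phantom images.

The phantoms are the idealized inputs of the closed-form theory: a
one-dimensional, integer-valued intensity ramp that climbs by ``grad``
gray levels per pixel, restarts at zero once the next step would leave
the representable range ``[0, ng - 1]``, and is replicated along the
orthogonal axis so the image shows stripes of constant intensity.

The ramp period equals the number of distinct gray levels it visits,
``1 + floor((ng - 1) / grad)`` pixels.  An optional *exact-period* mode
trims the image height so that, at a chosen vertical displacement, every
nonzero cell of the co-occurrence matrix receives an identical count;
on such images the numeric Haralick features equal the closed forms
exactly instead of carrying a small finite-boundary bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .analytic import n_tilde

__all__ = [
    "GradientSpec",
    "GrayImage",
    "ramp_value",
    "make_gradient_image",
    "exact_period_height",
    "save_image",
    "load_image",
]


@dataclass(frozen=True)
class GrayImage:
    """Integer 2D pixel grid with a declared gray-level count.

    Rows are indexed by ``y`` (downward), columns by ``x`` (rightward),
    both 0-based; the origin sits at the upper-left corner.  ``ng`` is
    carried as metadata (e.g. 256 for 8-bit data) and is authoritative:
    it is never inferred from the maximum pixel value.
    """

    pixels: np.ndarray
    ng: int

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 2 or px.size == 0:
            raise ValueError("pixels must form a non-empty 2D grid")
        if not np.issubdtype(px.dtype, np.integer):
            raise ValueError("pixels must be integer-valued")
        if self.ng < 2:
            raise ValueError(f"ng must be >= 2, got {self.ng}")
        if px.min() < 0 or px.max() > self.ng - 1:
            raise ValueError(
                f"pixel values must lie in [0, {self.ng - 1}], "
                f"found range [{px.min()}, {px.max()}]"
            )
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class GradientSpec:
    """Parameters of a periodic linear-gradient phantom.

    Parameters
    ----------
    ng : int
        Number of gray levels (2**b for bit depth b); >= 2.
    grad : int
        Gradient magnitude in gray levels per pixel, 1 <= grad <= ng - 1.
    width, height : int
        Image size in pixels.  The default 1024 x 1024 matches the size
        used throughout the numerical experiments the theory was
        validated on.
    orientation : {"vertical", "horizontal"}
        Axis along which intensity varies.  "vertical" yields horizontal
        stripes (the ramp runs down the rows).
    exact_period_for : int or None
        If set to a displacement magnitude ``|d|``, the height is trimmed
        to the largest ``H <= height`` with ``H - |d|`` divisible by the
        ramp period, guaranteeing uniform GLCM entry counts at that
        displacement.
    """

    ng: int
    grad: int
    width: int = 1024
    height: int = 1024
    orientation: str = "vertical"
    exact_period_for: int | None = field(default=None)

    def __post_init__(self) -> None:
        if not 1 <= self.grad <= self.ng - 1:
            raise ValueError(
                f"grad must satisfy 1 <= grad <= ng - 1, got grad={self.grad}, ng={self.ng}"
            )
        if self.width < 1 or self.height < 1:
            raise ValueError("width and height must be >= 1")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(f"unknown orientation {self.orientation!r}")
        if self.exact_period_for is not None and self.exact_period_for < 1:
            raise ValueError("exact_period_for must be a positive displacement magnitude")

    @property
    def period(self) -> int:
        """Ramp period in pixels (= number of distinct levels visited)."""
        return n_tilde(self.ng, self.grad)


def ramp_value(row_index: int, ng: int, grad: int) -> int:
    """Intensity of the periodic ramp at a given row.

    Returns ``(row_index mod P) * grad`` where ``P = 1 + floor((ng-1)/grad)``
    is the ramp period: the ramp climbs in steps of ``grad`` and restarts
    at zero as soon as the next step would reach ``ng``, so it never
    emits a value outside ``[0, ng - 1]``.
    """
    if row_index < 0:
        raise ValueError("row_index must be >= 0")
    period = n_tilde(ng, grad)  # validates grad
    return (row_index % period) * grad


def exact_period_height(requested_height: int, ng: int, grad: int, d_mag: int) -> int:
    """Largest height ``H <= requested_height`` with ``(H - d_mag)`` a multiple of the ramp period.

    At vertical displacement ``d_mag`` such an image produces ``H - d_mag``
    ordered pairs per column, spread perfectly evenly over the nonzero
    GLCM cells.
    """
    period = n_tilde(ng, grad)
    if d_mag < 1:
        raise ValueError("d_mag must be >= 1")
    h = d_mag + period * ((requested_height - d_mag) // period)
    if h < period + d_mag:
        raise ValueError(
            f"requested_height={requested_height} cannot hold one full period "
            f"({period}) plus the displacement ({d_mag})"
        )
    return h


def make_gradient_image(spec: GradientSpec) -> GrayImage:
    """Render the periodic linear-gradient phantom described by *spec*."""
    period = spec.period
    # the ramp runs down the rows for vertical stripes, across the columns
    # for horizontal ones; exact-period trimming applies along the ramp axis
    along = spec.height if spec.orientation == "vertical" else spec.width
    across = spec.width if spec.orientation == "vertical" else spec.height
    if spec.exact_period_for is not None:
        along = exact_period_height(along, spec.ng, spec.grad, spec.exact_period_for)
    if along < period:
        raise ValueError(
            f"ramp length {along} is smaller than one gradient period ({period} pixels)"
        )
    ramp = (np.arange(along, dtype=np.int64) % period) * spec.grad
    pixels = np.tile(ramp[:, None], (1, across))
    if spec.orientation == "horizontal":
        pixels = pixels.T.copy()
    return GrayImage(pixels=pixels, ng=spec.ng)


def _dtype_for(ng: int) -> np.dtype:
    if ng <= 256:
        return np.dtype(np.uint8)
    if ng <= 65536:
        return np.dtype(np.uint16)
    raise ValueError(f"ng={ng} exceeds 16-bit storage")


def save_image(img: GrayImage, path: str | Path) -> None:
    """Write a single-channel PNG or TIFF (8-bit for ng <= 256, else 16-bit)."""
    import imageio.v3 as iio

    iio.imwrite(Path(path), img.pixels.astype(_dtype_for(img.ng)))


def load_image(path: str | Path, ng: int | None = None) -> GrayImage:
    """Read a single-channel grayscale raster.

    ``ng`` defaults to the full range of the stored dtype (256 for 8-bit,
    65536 for 16-bit); pass it explicitly for images quantized to fewer
    levels than their container.
    """
    import imageio.v3 as iio

    px = np.asarray(iio.imread(Path(path)))
    if px.ndim == 3:
        if px.shape[2] != 1:
            raise ValueError("expected a single-channel grayscale image")
        px = px[:, :, 0]
    if ng is None:
        if px.dtype == np.uint8:
            ng = 256
        elif px.dtype == np.uint16:
            ng = 65536
        else:
            raise ValueError(
                f"cannot infer gray-level count from dtype {px.dtype}; pass ng explicitly"
            )
    return GrayImage(pixels=px.astype(np.int64), ng=ng)
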