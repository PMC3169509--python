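"""Digital Shepp-Logan head phantom and image-domain utilities.

The phantom is the standard numerical test object for tomographic
reconstruction: a superposition of ten ellipses emulating a transverse head
slice, with intensities chosen so that the two large dark ellipses cancel the
skull/brain background exactly, leaving large exactly-zero plateaus.  Those
plateaus are what make the phantom *sparse in the gradient domain*: the
per-pixel forward-difference gradient modulus is nonzero only on region
boundaries, which is the property the TV-constrained reconstructor exploits.

Conventions
-----------
* Pixel centers are mapped to the square [-1, 1]^2 via
  ``x_i = (i - (N-1)/2) / ((N-1)/2)`` (the Matlab ``phantom`` grid), the
  y-axis pointing up (row 0 is the top of the image).
* Ellipse membership is tested with ``<= 1``.
* Ellipse intensities of the modified (default Matlab) table are exact
  multiples of 0.1 and are accumulated in integer tenths so that overlapping
  ellipses cancel *exactly* (plain float accumulation leaves ~1e-17 dust on
  the plateaus, which would destroy the gradient-domain sparsity).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence, Union

import numpy as np

__all__ = [
    "PixelImage",
    "GradientImage",
    "EllipseSpec",
    "SHEPP_LOGAN_MODIFIED",
    "generate_shepp_logan",
    "rasterize_ellipses",
    "compute_gradient_image",
    "count_nonzero",
    "add_gaussian_noise",
    "to_byte_scale",
    "to_unit_scale",
]

#: intensity-scale labels
UNIT = "unit"
BYTE = "byte"


@dataclass(frozen=True)
class PixelImage:
    """An H x W grid of real-valued intensities.

    Parameters
    ----------
    values : ndarray of shape (H, W)
        Pixel intensities; must be finite.
    intensity_scale : {"unit", "byte"}
        Label recording whether values live on the 0-1 or the 0-255 scale.
    """

    values: np.ndarray
    intensity_scale: str = UNIT

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] < 1 or v.shape[1] < 1:
            raise ValueError("PixelImage requires a 2-D grid with H, W >= 1")
        if not np.all(np.isfinite(v)):
            raise ValueError("PixelImage values must be finite")
        if self.intensity_scale not in (UNIT, BYTE):
            raise ValueError(f"unknown intensity_scale {self.intensity_scale!r}")
        object.__setattr__(self, "values", v)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def n_pixels(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class GradientImage:
    """Per-pixel forward-difference gradient modulus of a :class:`PixelImage`."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2:
            raise ValueError("GradientImage requires a 2-D grid")
        if np.any(v < 0) or not np.all(np.isfinite(v)):
            raise ValueError("GradientImage values must be finite and >= 0")
        object.__setattr__(self, "values", v)


@dataclass(frozen=True)
class EllipseSpec:
    """One additive ellipse of a piecewise-constant phantom.

    Semi-axes and center coordinates are fractions of the image half-extent
    (so the whole image spans [-1, 1] in both axes); rotation is in degrees,
    counter-clockwise about the ellipse center.
    """

    additive_intensity: float
    semi_axis_a: float
    semi_axis_b: float
    center_x: float
    center_y: float
    rotation: float = 0.0

    def __post_init__(self):
        if self.semi_axis_a <= 0 or self.semi_axis_b <= 0:
            raise ValueError("ellipse semi-axes must be positive")


# Modified (Matlab-default) Shepp-Logan table.  Intensities are stored in
# integer tenths so the rasterizer can accumulate them exactly.
_SHEPP_LOGAN_TENTHS = (
    (10, 0.69, 0.92, 0.0, 0.0, 0.0),
    (-8, 0.6624, 0.8740, 0.0, -0.0184, 0.0),
    (-2, 0.1100, 0.3100, 0.22, 0.0, -18.0),
    (-2, 0.1600, 0.4100, -0.22, 0.0, 18.0),
    (1, 0.2100, 0.2500, 0.0, 0.35, 0.0),
    (1, 0.0460, 0.0460, 0.0, 0.1, 0.0),
    (1, 0.0460, 0.0460, 0.0, -0.1, 0.0),
    (1, 0.0460, 0.0230, -0.08, -0.605, 0.0),
    (1, 0.0230, 0.0230, 0.0, -0.606, 0.0),
    (1, 0.0230, 0.0460, 0.06, -0.605, 0.0),
)

SHEPP_LOGAN_MODIFIED: tuple[EllipseSpec, ...] = tuple(
    EllipseSpec(t / 10.0, a, b, x0, y0, phi)
    for (t, a, b, x0, y0, phi) in _SHEPP_LOGAN_TENTHS
)


def _grid(size: int) -> tuple[np.ndarray, np.ndarray]:
    if size == 1:
        ax = np.zeros(1)  # single pixel sits at the origin
    else:
        half = (size - 1) / 2.0
        ax = (np.arange(size) - half) / half
    x = ax[None, :]
    y = ax[::-1][:, None]  # row 0 at the top (y = +1)
    return x, y


def _ellipse_mask(x, y, e: EllipseSpec) -> np.ndarray:
    phi = np.deg2rad(e.rotation)
    xc = x - e.center_x
    yc = y - e.center_y
    u = xc * np.cos(phi) + yc * np.sin(phi)
    v = yc * np.cos(phi) - xc * np.sin(phi)
    return (u * u) / (e.semi_axis_a**2) + (v * v) / (e.semi_axis_b**2) <= 1.0


def rasterize_ellipses(ellipses: Sequence[EllipseSpec], size: int) -> PixelImage:
    """Rasterize an additive ellipse table onto a ``size x size`` grid.

    Intensities are accumulated in float64; for tables whose intensities are
    exact multiples of 0.1 (such as the built-in Shepp-Logan table) the sum is
    carried in integer tenths so that cancelling ellipses produce exact zeros.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    x, y = _grid(size)
    tenths = [round(e.additive_intensity * 10) for e in ellipses]
    exact = all(
        abs(t / 10.0 - e.additive_intensity) == 0.0
        for t, e in zip(tenths, ellipses)
    )
    acc = np.zeros((size, size), dtype=np.float64)
    for e, t in zip(ellipses, tenths):
        mask = _ellipse_mask(x, y, e)
        acc[mask] += t if exact else e.additive_intensity * 10.0
    return PixelImage(acc / 10.0, intensity_scale=UNIT)


def generate_shepp_logan(size: int) -> PixelImage:
    """The modified Shepp-Logan phantom on a ``size x size`` grid.

    Values lie in a small range around [0, 1]; the two large low-intensity
    ellipses cancel the background exactly, so the interior plateaus are
    exactly zero and the phantom is sparse in the gradient domain.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    return rasterize_ellipses(SHEPP_LOGAN_MODIFIED, size)


def _values(img) -> np.ndarray:
    if isinstance(img, (PixelImage, GradientImage)):
        return img.values
    return np.asarray(img, dtype=np.float64)


def compute_gradient_image(img: Union[PixelImage, np.ndarray]) -> GradientImage:
    """Forward-difference gradient modulus of an image.

    Each pixel gets ``sqrt((f[h+1,w]-f[h,w])^2 + (f[h,w+1]-f[h,w])^2)``; a
    difference whose forward neighbor falls outside the grid is treated as 0,
    so the gradient image has the same shape as the source.
    """
    f = _values(img)
    dv = np.zeros_like(f)
    dh = np.zeros_like(f)
    if f.shape[0] > 1:
        dv[:-1, :] = f[1:, :] - f[:-1, :]
    if f.shape[1] > 1:
        dh[:, :-1] = f[:, 1:] - f[:, :-1]
    return GradientImage(np.sqrt(dv * dv + dh * dh))


def count_nonzero(img) -> int:
    """Number of entries that differ from zero exactly (no epsilon)."""
    return int(np.count_nonzero(_values(img)))


def to_byte_scale(img: PixelImage) -> PixelImage:
    """Rescale a unit-scale image to the 0-255 working scale (multiply by 255)."""
    if img.intensity_scale == BYTE:
        return img
    return PixelImage(img.values * 255.0, intensity_scale=BYTE)


def to_unit_scale(img: PixelImage) -> PixelImage:
    if img.intensity_scale == UNIT:
        return img
    return PixelImage(img.values / 255.0, intensity_scale=UNIT)


def add_gaussian_noise(sino, sigma: float, seed: int):
    """Additive zero-mean Gaussian perturbation of a sinogram.

    ``sigma`` is in the sinogram's intensity units.  ``sigma = 0`` returns the
    input unchanged; the same ``(sino, sigma, seed)`` always produces the same
    output.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if sigma == 0:
        return sino
    rng = np.random.default_rng(seed)
    noisy = sino.values + rng.normal(0.0, sigma, size=sino.values.shape)
    return replace(sino, values=noisy)
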