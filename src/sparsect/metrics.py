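"""Image-quality metrics: RMSE, universal quality index, correlation.

All three compare a reconstruction ``fr`` against a reference ``f0`` pixel by
pixel over the full image, with variance and covariance normalized by N-1:

* RMSE  = sqrt(sum (fr - f0)^2 / N)            -- absolute error, in
  intensity units (so its magnitude depends on the working scale);
* UQI   = [2 Cov / (D(fr) + D(f0))] * [2 mr m0 / (mr^2 + m0^2)]
  -- a correlation factor times a luminance factor, 1 for identical images,
  degraded by mean shifts;
* CC    = Cov / sqrt(D(fr) D(f0))              -- Pearson correlation,
  invariant under positive affine rescaling of either image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .phantom import PixelImage

__all__ = ["QualityReport", "UndefinedMetricError", "rmse", "uqi", "cc", "evaluate"]


class UndefinedMetricError(ValueError):
    """Raised when a metric's denominator vanishes (e.g. constant images)."""


@dataclass(frozen=True)
class QualityReport:
    """RMSE / UQI / CC triple for one reconstruction-reference pair."""

    rmse: float
    uqi: float
    cc: float
    n_pixels: int

    def to_dict(self) -> dict:
        return {
            "rmse": self.rmse,
            "uqi": self.uqi,
            "cc": self.cc,
            "n_pixels": self.n_pixels,
        }


def _pair(fr, f0) -> tuple[np.ndarray, np.ndarray]:
    a = fr.values if isinstance(fr, PixelImage) else np.asarray(fr, dtype=np.float64)
    b = f0.values if isinstance(f0, PixelImage) else np.asarray(f0, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    return a.ravel().astype(np.float64), b.ravel().astype(np.float64)


def rmse(fr, f0) -> float:
    """Root mean squared error, in the images' intensity units."""
    a, b = _pair(fr, f0)
    return float(np.sqrt(np.mean((a - b) ** 2)))


def _moments(a, b):
    n = a.size
    ma, mb = float(np.mean(a)), float(np.mean(b))
    if n < 2:
        return ma, mb, 0.0, 0.0, 0.0
    da = a - ma
    db = b - mb
    va = float(np.dot(da, da)) / (n - 1)
    vb = float(np.dot(db, db)) / (n - 1)
    cov = float(np.dot(da, db)) / (n - 1)
    return ma, mb, va, vb, cov


def uqi(fr, f0) -> float:
    """Universal quality index in [-1, 1]; 1 iff the images are identical."""
    a, b = _pair(fr, f0)
    ma, mb, va, vb, cov = _moments(a, b)
    if va + vb == 0.0 or ma * ma + mb * mb == 0.0:
        raise UndefinedMetricError(
            "UQI undefined: zero variance sum or zero mean energy"
        )
    return float((2.0 * cov / (va + vb)) * (2.0 * ma * mb / (ma * ma + mb * mb)))


def cc(fr, f0) -> float:
    """Pearson correlation coefficient between the two images."""
    a, b = _pair(fr, f0)
    _, _, va, vb, cov = _moments(a, b)
    if va == 0.0 or vb == 0.0:
        raise UndefinedMetricError("CC undefined: an image has zero variance")
    return float(cov / np.sqrt(va * vb))


def evaluate(fr, f0) -> QualityReport:
    """Bundle RMSE, UQI and CC into one report."""
    a, b = _pair(fr, f0)
    return QualityReport(
        rmse=rmse(a.reshape(1, -1), b.reshape(1, -1)),
        uqi=uqi(a.reshape(1, -1), b.reshape(1, -1)),
        cc=cc(a.reshape(1, -1), b.reshape(1, -1)),
        n_pixels=int(a.size),
    )
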