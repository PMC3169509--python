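"""Parallel-beam scan geometry.

Coordinate conventions (shared by the projector and all reconstructors):

* the image is centered at the origin with unit pixel size, so an N x N grid
  spans [-N/2, N/2] in both axes;
* row index increases downward (row 0 has the largest y);
* a view angle theta (degrees, measured counter-clockwise from the x-axis)
  defines the ray direction (cos theta, sin theta);
* detector offsets are measured perpendicular to the ray, along
  (-sin theta, cos theta); bin ``b`` of ``B`` sits at offset
  ``(b - (B-1)/2) * bin_spacing`` so the detector is centered on the grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ScanGeometry", "make_geometry"]


@dataclass(frozen=True, eq=False)
class ScanGeometry:
    """Angular and detector sampling tying an image grid to a set of rays."""

    angles_deg: np.ndarray
    n_bins: int
    grid_size: int
    bin_spacing: float = 1.0

    def __eq__(self, other):
        if not isinstance(other, ScanGeometry):
            return NotImplemented
        return (
            self.n_bins == other.n_bins
            and self.grid_size == other.grid_size
            and self.bin_spacing == other.bin_spacing
            and np.array_equal(self.angles_deg, other.angles_deg)
        )

    def __post_init__(self):
        a = np.asarray(self.angles_deg, dtype=np.float64)
        if a.ndim != 1 or a.size < 1:
            raise ValueError("need at least one view angle")
        if np.any(a < 0) or np.any(a >= 180.0):
            raise ValueError("view angles must lie in [0, 180) degrees")
        if a.size > 1 and np.any(np.diff(a) <= 0):
            raise ValueError("view angles must be strictly increasing")
        if self.n_bins < 1 or self.grid_size < 1:
            raise ValueError("n_bins and grid_size must be >= 1")
        if self.bin_spacing <= 0:
            raise ValueError("bin_spacing must be > 0")
        object.__setattr__(self, "angles_deg", a)

    @property
    def n_views(self) -> int:
        return self.angles_deg.size

    @property
    def n_rays(self) -> int:
        return self.n_views * self.n_bins

    @property
    def bin_offsets(self) -> np.ndarray:
        """Perpendicular detector offsets of each bin, in pixel widths."""
        b = np.arange(self.n_bins, dtype=np.float64)
        return (b - (self.n_bins - 1) / 2.0) * self.bin_spacing

    def to_dict(self) -> dict:
        return {
            "angles_deg": [float(a) for a in self.angles_deg],
            "n_bins": int(self.n_bins),
            "grid_size": int(self.grid_size),
            "bin_spacing": float(self.bin_spacing),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScanGeometry":
        return cls(
            angles_deg=np.asarray(d["angles_deg"], dtype=np.float64),
            n_bins=int(d["n_bins"]),
            grid_size=int(d["grid_size"]),
            bin_spacing=float(d.get("bin_spacing", 1.0)),
        )


def make_geometry(n_views: int, n_bins: int | None = None,
                  grid_size: int = 256) -> ScanGeometry:
    """Evenly spaced parallel-beam geometry over 180 degrees.

    Angles are ``k * (180 / n_views)`` for ``k = 0 .. n_views - 1``; the
    detector has ``n_bins`` bins (default: one per image column) at unit
    spacing, centered on the grid.
    """
    if n_views < 1:
        raise ValueError("n_views must be >= 1")
    if n_bins is None:
        n_bins = grid_size
    if n_bins < 1:
        raise ValueError("n_bins must be >= 1")
    angles = np.arange(n_views, dtype=np.float64) * (180.0 / n_views)
    return ScanGeometry(angles_deg=angles, n_bins=n_bins, grid_size=grid_size)
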