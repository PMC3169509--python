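"""Exact ray-pixel intersection weights and the forward projection.

Each ray is an infinite zero-width line; its weight on a pixel is the exact
Euclidean length of the chord it cuts through that pixel (so every stored
weight lies in (0, sqrt(2)] for unit pixels).  The sparse matrix of all
T x B rays, in view-major order, is the system matrix Phi of the discrete
projection model ``g = Phi f``.

Eight-fold symmetry
-------------------
Parallel rays at angles alpha, 90-alpha, 90+alpha and 180-alpha with mirrored
detector offsets cut congruent chords: each is the image of a single ray under
a symmetry of the square pixel grid (reflections about the axes and the
diagonals).  The tracer exploits this by canonicalizing every ray into the
first octant (angle in [0, 45] degrees, offset >= 0), tracing only the
canonical ray, and mapping pixel indices back through the corresponding index
permutation.  ``build_system_matrix(..., use_symmetry=True)`` additionally
caches canonical traces so each congruence class is traced once; because both
build modes execute the identical canonical trace, their outputs are
element-wise identical.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp

from .geometry import ScanGeometry, make_geometry
from .phantom import PixelImage

__all__ = [
    "Sinogram",
    "SystemMatrix",
    "compute_ray_weights",
    "build_system_matrix",
    "forward_project",
]

_EPS_SEG = 1e-12  # discard degenerate chord segments below this length


@dataclass(frozen=True)
class Sinogram:
    """T x B grid of line-integral measurements plus its scan geometry."""

    values: np.ndarray
    geometry: ScanGeometry

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.shape != (self.geometry.n_views, self.geometry.n_bins):
            raise ValueError(
                f"sinogram shape {v.shape} does not match geometry "
                f"({self.geometry.n_views}, {self.geometry.n_bins})"
            )
        if not np.all(np.isfinite(v)):
            raise ValueError("sinogram values must be finite")
        object.__setattr__(self, "values", v)

    @property
    def n_views(self) -> int:
        return self.geometry.n_views

    @property
    def n_bins(self) -> int:
        return self.geometry.n_bins


@dataclass(frozen=True)
class SystemMatrix:
    """Sparse M x N matrix of ray-pixel intersection lengths.

    Row ``i = t * B + b`` holds the weights of the ray at view ``t``,
    detector bin ``b``; ``row_sq_norms[i]`` caches the squared Euclidean norm
    of row ``i`` (the Kaczmarz update denominator).
    """

    matrix: sp.csr_matrix
    geometry: ScanGeometry
    row_sq_norms: np.ndarray

    @property
    def n_rays(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_pixels(self) -> int:
        return self.matrix.shape[1]

    def row(self, i: int) -> tuple[np.ndarray, np.ndarray]:
        """(pixel indices, weights) of ray ``i``."""
        sl = slice(self.matrix.indptr[i], self.matrix.indptr[i + 1])
        return self.matrix.indices[sl], self.matrix.data[sl]


# --- first-octant canonicalization -----------------------------------------

_FLIPV = 0      # (r, c) -> (n-1-r, c)       ray (theta, s) <- (180-theta, s)
_TRANSPOSE = 1  # (r, c) -> (c, r)           ray (theta, s) <- (90-theta, s)
_ROT180 = 2     # (r, c) -> (n-1-r, n-1-c)   ray (theta, s) <- (theta, -s)


def _canonicalize(angle_deg: float, offset: float):
    theta = float(angle_deg) % 180.0
    s = float(offset)
    ops = []
    if theta > 90.0:
        theta = 180.0 - theta
        ops.append(_FLIPV)
    if theta > 45.0:
        theta = 90.0 - theta
        ops.append(_TRANSPOSE)
    if s < 0.0:
        s = -s
        ops.append(_ROT180)
    return theta, s, ops


def _apply_ops(rows, cols, ops, n):
    # ops were collected while reducing the ray; undo them outermost-first
    for op in reversed(ops):
        if op == _FLIPV:
            rows = n - 1 - rows
        elif op == _TRANSPOSE:
            rows, cols = cols, rows
        else:  # _ROT180
            rows, cols = n - 1 - rows, n - 1 - cols
    return rows, cols


def _trace_canonical(theta_deg: float, s: float, n: int):
    """Chords of the canonical ray (theta in [0, 45] deg, s >= 0).

    Returns (rows, cols, lengths); empty arrays when the ray misses the grid.
    """
    h = n / 2.0
    empty = (np.empty(0, np.int64), np.empty(0, np.int64), np.empty(0, np.float64))
    if theta_deg == 0.0:
        # horizontal line y = s
        if s >= h:
            return empty
        q = h - s
        r = int(np.floor(q))
        if q == np.floor(q):
            # ray lies exactly on a pixel boundary: take the positive-offset
            # (+y) side, i.e. the pixel above the line
            r -= 1
        if r < 0 or r >= n:
            return empty
        cols = np.arange(n, dtype=np.int64)
        rows = np.full(n, r, dtype=np.int64)
        return rows, cols, np.ones(n, dtype=np.float64)

    th = np.deg2rad(theta_deg)
    dx, dy = np.cos(th), np.sin(th)          # 0 < dy <= dx
    p0x, p0y = -s * dy, s * dx               # point at perpendicular offset s
    t0 = max((-h - p0x) / dx, (-h - p0y) / dy)
    t1 = min((h - p0x) / dx, (h - p0y) / dy)
    if t1 - t0 <= _EPS_SEG:
        return empty
    lines = -h + np.arange(1, n, dtype=np.float64)  # interior grid lines
    x_lo, x_hi = p0x + t0 * dx, p0x + t1 * dx
    y_lo, y_hi = p0y + t0 * dy, p0y + t1 * dy
    tx = (lines[(lines > x_lo) & (lines < x_hi)] - p0x) / dx
    ty = (lines[(lines > y_lo) & (lines < y_hi)] - p0y) / dy
    ts = np.concatenate(([t0], tx, ty, [t1]))
    ts.sort(kind="stable")
    seg = np.diff(ts)
    keep = seg > _EPS_SEG
    if not np.any(keep):
        return empty
    tm = (ts[:-1] + ts[1:])[keep] / 2.0
    xm = p0x + tm * dx
    ym = p0y + tm * dy
    cols = np.floor(xm + h).astype(np.int64)
    rows = np.floor(h - ym).astype(np.int64)
    inside = (cols >= 0) & (cols < n) & (rows >= 0) & (rows < n)
    return rows[inside], cols[inside], seg[keep][inside]


def compute_ray_weights(angle_deg: float, bin_offset: float, grid_size: int):
    """Exact intersection lengths of one ray with every pixel it crosses.

    Returns ``(pixel_indices, weights)`` with flat row-major pixel indices
    sorted ascending; a ray that misses the grid yields empty arrays.
    """
    if grid_size < 1:
        raise ValueError("grid_size must be >= 1")
    theta, s, ops = _canonicalize(angle_deg, bin_offset)
    rows, cols, w = _trace_canonical(theta, s, grid_size)
    rows, cols = _apply_ops(rows, cols, ops, grid_size)
    flat = rows * grid_size + cols
    order = np.argsort(flat, kind="stable")
    return flat[order], w[order]


def build_system_matrix(geom: ScanGeometry, use_symmetry: bool = True) -> SystemMatrix:
    """Assemble the sparse system matrix for a scan geometry.

    With ``use_symmetry`` the tracer caches canonical (first-octant) rays and
    derives symmetric rays by index permutation; without it every ray is
    traced independently.  Both paths produce element-wise identical output.
    """
    n = geom.grid_size
    offsets = geom.bin_offsets
    cache: dict[tuple[float, float], tuple] = {}
    indptr = np.zeros(geom.n_rays + 1, dtype=np.int64)
    idx_parts = []
    dat_parts = []
    i = 0
    for angle in geom.angles_deg:
        for off in offsets:
            theta, s, ops = _canonicalize(angle, off)
            if use_symmetry:
                key = (theta, s)
                traced = cache.get(key)
                if traced is None:
                    traced = _trace_canonical(theta, s, n)
                    cache[key] = traced
            else:
                traced = _trace_canonical(theta, s, n)
            rows, cols, w = traced
            rows, cols = _apply_ops(rows, cols, ops, n)
            flat = rows * n + cols
            order = np.argsort(flat, kind="stable")
            idx_parts.append(flat[order])
            dat_parts.append(w[order])
            i += 1
            indptr[i] = indptr[i - 1] + flat.size
    indices = np.concatenate(idx_parts) if idx_parts else np.empty(0, np.int64)
    data = np.concatenate(dat_parts) if dat_parts else np.empty(0, np.float64)
    mat = sp.csr_matrix(
        (data, indices.astype(np.int32), indptr), shape=(geom.n_rays, n * n)
    )
    sq = mat.copy()
    sq.data = sq.data * sq.data
    rsq = np.asarray(sq.sum(axis=1)).ravel()
    return SystemMatrix(matrix=mat, geometry=geom, row_sq_norms=rsq)


def forward_project(img: PixelImage, A: SystemMatrix) -> Sinogram:
    """Evaluate ``g_i = sum_j phi_ij f_j`` for every ray of the geometry."""
    n = A.geometry.grid_size
    if img.values.shape != (n, n):
        raise ValueError(
            f"image shape {img.values.shape} does not match grid size {n}"
        )
    g = A.matrix @ img.values.ravel()
    return Sinogram(
        values=g.reshape(A.geometry.n_views, A.geometry.n_bins),
        geometry=A.geometry,
    )


def simulate_sinogram(img: PixelImage, n_views: int,
                      n_bins: int | None = None,
                      use_symmetry: bool = True) -> tuple[Sinogram, SystemMatrix]:
    """Convenience: build the geometry and matrix for ``img`` and project it."""
    geom = make_geometry(n_views, n_bins, grid_size=img.values.shape[0])
    A = build_system_matrix(geom, use_symmetry=use_symmetry)
    return forward_project(img, A), A
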