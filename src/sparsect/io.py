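"""File I/O: images and sinograms as float TIFF/CSV with JSON sidecars,
system matrices as a versioned binary cache.

Images and sinograms carry metadata (intensity scale, scan geometry) that the
raster formats cannot hold, so every array written here gets a ``<path>.json``
sidecar; loading restores the metadata from it when present.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import scipy.sparse as sp
import tifffile

from .geometry import ScanGeometry
from .metrics import QualityReport
from .phantom import PixelImage, UNIT
from .projector import Sinogram, SystemMatrix

__all__ = [
    "save_image", "load_image",
    "save_sinogram", "load_sinogram",
    "save_system_matrix", "load_system_matrix",
    "save_report",
]

_MAGIC = b"SPCTSM\x00\x01"  # magic string + format version


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def _write_array(arr: np.ndarray, path: Path):
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, arr.astype(np.float32))
    elif path.suffix.lower() == ".csv":
        np.savetxt(path, arr, delimiter=",")
    else:
        raise ValueError(f"unsupported image format: {path.suffix!r}")


def _read_array(path: Path) -> np.ndarray:
    if path.suffix.lower() in (".tif", ".tiff"):
        return np.asarray(tifffile.imread(path), dtype=np.float64)
    if path.suffix.lower() == ".csv":
        return np.atleast_2d(np.loadtxt(path, delimiter=","))
    raise ValueError(f"unsupported image format: {path.suffix!r}")


def save_image(img: PixelImage, path) -> Path:
    """Write a PixelImage as 32-bit float TIFF (or CSV) plus a JSON sidecar."""
    path = Path(path)
    _write_array(img.values, path)
    meta = {
        "height": img.height,
        "width": img.width,
        "intensity_scale": img.intensity_scale,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))
    return path


def load_image(path) -> PixelImage:
    path = Path(path)
    values = _read_array(path)
    scale = UNIT
    sc = _sidecar(path)
    if sc.exists():
        scale = json.loads(sc.read_text()).get("intensity_scale", UNIT)
    return PixelImage(values, intensity_scale=scale)


def save_sinogram(sino: Sinogram, path) -> Path:
    """Write a sinogram (T x B float array) plus its geometry sidecar."""
    path = Path(path)
    _write_array(sino.values, path)
    _sidecar(path).write_text(
        json.dumps({"geometry": sino.geometry.to_dict()}, indent=1)
    )
    return path


def load_sinogram(path, geometry: ScanGeometry | None = None) -> Sinogram:
    """Read a sinogram; geometry comes from the sidecar unless given."""
    path = Path(path)
    values = _read_array(path)
    if geometry is None:
        sc = _sidecar(path)
        if not sc.exists():
            raise FileNotFoundError(
                f"no geometry given and sidecar {sc} is missing"
            )
        geometry = ScanGeometry.from_dict(json.loads(sc.read_text())["geometry"])
    return Sinogram(values=values, geometry=geometry)


def save_system_matrix(A: SystemMatrix, path) -> Path:
    """Cache a system matrix to a binary file.

    Layout (little-endian): 8-byte magic+version; int64 n_views, n_bins,
    grid_size; float64 bin_spacing; float64 angles[n_views]; int64 nnz;
    int64 indptr[M+1]; int32 indices[nnz]; float64 data[nnz];
    float64 row_sq_norms[M].
    """
    path = Path(path)
    g = A.geometry
    m = A.matrix
    with open(path, "wb") as fh:
        fh.write(_MAGIC)
        fh.write(struct.pack("<qqq", g.n_views, g.n_bins, g.grid_size))
        fh.write(struct.pack("<d", g.bin_spacing))
        fh.write(np.asarray(g.angles_deg, dtype="<f8").tobytes())
        fh.write(struct.pack("<q", m.nnz))
        fh.write(np.asarray(m.indptr, dtype="<i8").tobytes())
        fh.write(np.asarray(m.indices, dtype="<i4").tobytes())
        fh.write(np.asarray(m.data, dtype="<f8").tobytes())
        fh.write(np.asarray(A.row_sq_norms, dtype="<f8").tobytes())
    return path


def load_system_matrix(path) -> SystemMatrix:
    path = Path(path)
    buf = path.read_bytes()
    if buf[:8] != _MAGIC:
        raise ValueError(f"{path} is not a system-matrix cache (bad magic)")
    off = 8
    n_views, n_bins, grid_size = struct.unpack_from("<qqq", buf, off)
    off += 24
    (spacing,) = struct.unpack_from("<d", buf, off)
    off += 8
    angles = np.frombuffer(buf, "<f8", n_views, off).copy()
    off += 8 * n_views
    (nnz,) = struct.unpack_from("<q", buf, off)
    off += 8
    n_rays = n_views * n_bins
    indptr = np.frombuffer(buf, "<i8", n_rays + 1, off).copy()
    off += 8 * (n_rays + 1)
    indices = np.frombuffer(buf, "<i4", nnz, off).copy()
    off += 4 * nnz
    data = np.frombuffer(buf, "<f8", nnz, off).copy()
    off += 8 * nnz
    rsq = np.frombuffer(buf, "<f8", n_rays, off).copy()
    geom = ScanGeometry(angles_deg=angles, n_bins=n_bins,
                        grid_size=grid_size, bin_spacing=spacing)
    mat = sp.csr_matrix((data, indices, indptr),
                        shape=(n_rays, grid_size * grid_size))
    return SystemMatrix(matrix=mat, geometry=geom, row_sq_norms=rsq)


def save_report(report: QualityReport, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(report.to_dict(), indent=1))
    return path
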