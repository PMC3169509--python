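"""Reconstruction of an image from few-view parallel-beam projection data.

Three reconstructors are provided, mirroring the standard comparison for
sparse-view CT:

``FilteredBackProjection``
    The analytic reference: Ram-Lak (ramp) frequency filtering of each view
    followed by linearly interpolated backprojection, scaled by pi/(2T).
``ART``
    Plain algebraic reconstruction: relaxed Kaczmarz row-action sweeps over
    the ray equations ``<phi_i, f> = g_i`` from a zero initial image.
``CSReconstruction``
    The compressed-sensing-motivated solver: each cycle runs one full ART
    sweep (data consistency) and then a few steps of gradient descent on the
    l1-norm of the gradient image (total variation), with the TV step length
    tied to the size of the ART correction.  With zero TV sub-steps it
    reduces exactly to plain ART.

The two iterative solvers are exposed statsmodels-style: a model object is
built from the data, ``fit()`` runs the solver and returns a
:class:`ReconResult` holding the image, per-cycle convergence history and a
``summary()`` table.  Thin module-level functions (``fbp_reconstruct``,
``art_reconstruct``, ``cs_reconstruct``, ``art_sweep``, ``tv_subgradient``)
wrap the same machinery.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from ._kernels import kaczmarz_sweep
from .phantom import PixelImage
from .projector import Sinogram, SystemMatrix

logger = logging.getLogger(__name__)

__all__ = [
    "CSParams",
    "ReconResult",
    "FilteredBackProjection",
    "ART",
    "CSReconstruction",
    "fbp_reconstruct",
    "art_sweep",
    "art_reconstruct",
    "tv_subgradient",
    "cs_reconstruct",
]


@dataclass(frozen=True)
class CSParams:
    """Control parameters of the TV-constrained iterative solver.

    relaxation : Kaczmarz relaxation lambda (dimensionless, default 1.0)
    tv_step : TV descent speed alpha (dimensionless, default 0.5)
    epsilon : stabilizer added inside each radical of the TV subgradient
        (intensity^2 units, default 1e-4)
    n_tv_sub : TV gradient-descent steps per cycle (default 5)
    stop_threshold : per-pixel RMS change between successive cycles' post-sweep
        images below which iteration stops (intensity units, default 0.001)
    max_cycles : hard cap on cycles (default 1000)
    nonnegativity : clamp negative pixels after each cycle (default off)
    """

    relaxation: float = 1.0
    tv_step: float = 0.5
    epsilon: float = 1e-4
    n_tv_sub: int = 5
    stop_threshold: float = 0.001
    max_cycles: int = 1000
    nonnegativity: bool = False

    def __post_init__(self):
        if self.relaxation <= 0:
            raise ValueError("relaxation must be > 0")
        if self.tv_step <= 0:
            raise ValueError("tv_step must be > 0")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.n_tv_sub < 0:
            raise ValueError("n_tv_sub must be >= 0")
        if self.max_cycles < 1:
            raise ValueError("max_cycles must be >= 1")


@dataclass
class ReconResult:
    """Outcome of a reconstruction: the image plus convergence diagnostics."""

    image: PixelImage
    n_cycles_run: int
    per_cycle_change: list
    converged: bool
    method: str
    final_residual: float | None = None
    params: CSParams | None = None

    def summary(self) -> str:
        img = self.image.values
        lines = [
            f"{'Method':<22}{self.method}",
            f"{'Image grid':<22}{img.shape[0]} x {img.shape[1]}",
            f"{'Cycles run':<22}{self.n_cycles_run}",
            f"{'Converged':<22}{self.converged}",
        ]
        if self.per_cycle_change:
            lines.append(
                f"{'Final cycle change':<22}{self.per_cycle_change[-1]:.6g}"
            )
        if self.final_residual is not None:
            lines.append(f"{'Residual ||g - Af||':<22}{self.final_residual:.6g}")
        if self.params is not None:
            p = self.params
            lines.append(
                f"{'Parameters':<22}lambda={p.relaxation} alpha={p.tv_step} "
                f"eps={p.epsilon} tv_sub={p.n_tv_sub} "
                f"stop={p.stop_threshold} max_cycles={p.max_cycles}"
            )
        width = max(len(s) for s in lines)
        rule = "=" * width
        return "\n".join([rule, "Reconstruction Results", rule, *lines, rule])

    def plot(self, ax=None):
        """Show the reconstructed image (requires matplotlib)."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        im = ax.imshow(self.image.values, cmap="gray")
        ax.set_title(self.method)
        ax.figure.colorbar(im, ax=ax)
        return ax


# --- TV subgradient ---------------------------------------------------------

def tv_subgradient(f, epsilon: float) -> np.ndarray:
    """Gradient of the smoothed total variation sum(sqrt(eps + |grad f|^2)).

    Uses forward differences with out-of-grid differences treated as zero
    (matching the gradient-image definition), so each pixel receives the
    three-term sum of its own radical and the radicals of its upper and left
    neighbors.  Returns an array of the same shape as ``f``.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be > 0")
    a = f.values if isinstance(f, PixelImage) else np.asarray(f, dtype=np.float64)
    dv = np.zeros_like(a)
    dh = np.zeros_like(a)
    if a.shape[0] > 1:
        dv[:-1, :] = a[1:, :] - a[:-1, :]
    if a.shape[1] > 1:
        dh[:, :-1] = a[:, 1:] - a[:, :-1]
    r = np.sqrt(epsilon + dv * dv + dh * dh)
    v = (-dv - dh) / r
    v[1:, :] += dv[:-1, :] / r[:-1, :]
    v[:, 1:] += dh[:, :-1] / r[:, :-1]
    return v


# --- iterative solvers ------------------------------------------------------

def _as_flat(sino: Sinogram) -> np.ndarray:
    return sino.values.ravel().astype(np.float64)


def _check_dims(sino: Sinogram, A: SystemMatrix):
    if sino.values.size != A.n_rays:
        raise ValueError(
            f"sinogram has {sino.values.size} measurements but the system "
            f"matrix has {A.n_rays} rays"
        )


def art_sweep(f: PixelImage, sino: Sinogram, A: SystemMatrix,
              relaxation: float = 1.0) -> PixelImage:
    """One complete Kaczmarz pass over all rays, in view-major row order."""
    _check_dims(sino, A)
    n = A.geometry.grid_size
    if f.values.shape != (n, n):
        raise ValueError("image grid does not match the system matrix")
    x = f.values.ravel().copy()
    kaczmarz_sweep(
        A.matrix.indptr, A.matrix.indices, A.matrix.data,
        A.row_sq_norms, _as_flat(sino), x, float(relaxation),
    )
    return PixelImage(x.reshape(n, n), intensity_scale=f.intensity_scale)


def _iterate(sino: Sinogram, A: SystemMatrix, p: CSParams, method: str) -> ReconResult:
    """Shared ART / TV-constrained loop; f(0) = 0.

    Each cycle: one full sweep gives f(M); the cycle-to-cycle change is the
    per-pixel RMS ||f(M) - f(M)_prev|| / sqrt(N); if not yet converged and
    n_tv_sub > 0, the TV phase moves the image n_tv_sub times along the
    normalized TV subgradient with step alpha * d, where d = ||f(M) - f(0)||
    is the size of the ART correction, held fixed across the sub-steps.
    The returned image is the final post-sweep f(M).
    """
    _check_dims(sino, A)
    n = A.geometry.grid_size
    g = _as_flat(sino)
    nn = n * n
    f = np.zeros(nn, dtype=np.float64)
    fm_prev = np.zeros(nn, dtype=np.float64)
    changes: list[float] = []
    converged = False
    indptr, indices, data = A.matrix.indptr, A.matrix.indices, A.matrix.data
    for _ in range(p.max_cycles):
        f_start = f.copy()
        kaczmarz_sweep(indptr, indices, data, A.row_sq_norms, g, f,
                       float(p.relaxation))
        if p.nonnegativity:
            np.maximum(f, 0.0, out=f)
        change = float(np.linalg.norm(f - fm_prev)) / np.sqrt(nn)
        changes.append(change)
        logger.info("%s cycle %d: change %.6g", method, len(changes), change)
        fm_prev = f.copy()
        if change < p.stop_threshold:
            converged = True
            break
        if p.n_tv_sub > 0:
            d = float(np.linalg.norm(f - f_start))
            if d > 0.0:
                img = f.reshape(n, n)
                for _l in range(p.n_tv_sub):
                    v = tv_subgradient(img, p.epsilon)
                    nv = float(np.linalg.norm(v))
                    if nv == 0.0:
                        break
                    img -= (p.tv_step * d / nv) * v
                if p.nonnegativity:
                    np.maximum(f, 0.0, out=f)
    residual = float(np.linalg.norm(g - A.matrix @ fm_prev))
    return ReconResult(
        image=PixelImage(fm_prev.reshape(n, n)),
        n_cycles_run=len(changes),
        per_cycle_change=changes,
        converged=converged,
        method=method,
        final_residual=residual,
        params=p,
    )


# --- filtered back projection ----------------------------------------------

def _ramp_filter(n_bins: int) -> tuple[int, np.ndarray]:
    m = 64
    while m < 2 * n_bins:
        m *= 2
    return m, 2.0 * np.abs(np.fft.fftfreq(m))


def fbp_reconstruct(sino: Sinogram) -> PixelImage:
    """Ramp-filtered backprojection onto the geometry's pixel grid.

    Each view is zero-padded to the next power of two >= 2B, multiplied by
    the Ram-Lak response 2|nu| in the frequency domain, backprojected with
    linear interpolation, and the sum is scaled by pi / (2 T).
    """
    geom = sino.geometry
    t_views, b = geom.n_views, geom.n_bins
    m, ramp = _ramp_filter(b)
    padded = np.zeros((t_views, m), dtype=np.float64)
    padded[:, :b] = sino.values
    filtered = np.real(np.fft.ifft(np.fft.fft(padded, axis=1) * ramp, axis=1))[:, :b]

    n = geom.grid_size
    cols = np.arange(n) + 0.5 - n / 2.0          # pixel-center x
    rows = n / 2.0 - np.arange(n) - 0.5          # pixel-center y
    x = cols[None, :]
    y = rows[:, None]
    bin_axis = np.arange(b, dtype=np.float64)
    recon = np.zeros((n, n), dtype=np.float64)
    for t, angle in enumerate(geom.angles_deg):
        th = np.deg2rad(angle)
        # perpendicular detector coordinate of each pixel center
        pos = (-x * np.sin(th) + y * np.cos(th)) / geom.bin_spacing \
            + (b - 1) / 2.0
        recon += np.interp(pos, bin_axis, filtered[t], left=0.0, right=0.0)
    recon *= np.pi / (2.0 * t_views)
    return PixelImage(recon)


# --- model objects ----------------------------------------------------------

class FilteredBackProjection:
    """Analytic FBP reconstruction model for a sinogram."""

    def __init__(self, sinogram: Sinogram):
        self.sinogram = sinogram

    def fit(self) -> ReconResult:
        img = fbp_reconstruct(self.sinogram)
        return ReconResult(
            image=img, n_cycles_run=0, per_cycle_change=[],
            converged=True, method="FBP",
        )


class ART:
    """Plain algebraic reconstruction (relaxed Kaczmarz) model."""

    def __init__(self, sinogram: Sinogram, system_matrix: SystemMatrix,
                 relaxation: float = 1.0, stop_threshold: float = 0.001,
                 max_cycles: int = 1000, nonnegativity: bool = False):
        self.sinogram = sinogram
        self.system_matrix = system_matrix
        self.params = CSParams(
            relaxation=relaxation, n_tv_sub=0, stop_threshold=stop_threshold,
            max_cycles=max_cycles, nonnegativity=nonnegativity,
        )

    def fit(self) -> ReconResult:
        return _iterate(self.sinogram, self.system_matrix, self.params, "ART")


class CSReconstruction:
    """TV-constrained iterative reconstruction model (ART + l1-gradient descent)."""

    def __init__(self, sinogram: Sinogram, system_matrix: SystemMatrix,
                 params: CSParams | None = None):
        self.sinogram = sinogram
        self.system_matrix = system_matrix
        self.params = params if params is not None else CSParams()

    def fit(self) -> ReconResult:
        return _iterate(self.sinogram, self.system_matrix, self.params,
                        "CS-based iteration")


# --- functional wrappers ----------------------------------------------------

def art_reconstruct(sino: Sinogram, A: SystemMatrix, relaxation: float = 1.0,
                    stop_threshold: float = 0.001,
                    max_cycles: int = 1000,
                    nonnegativity: bool = False) -> ReconResult:
    """Repeated ART sweeps from f = 0 until the per-cycle change is small."""
    return ART(sino, A, relaxation, stop_threshold, max_cycles,
               nonnegativity).fit()


def cs_reconstruct(sino: Sinogram, A: SystemMatrix,
                   p: CSParams | None = None) -> ReconResult:
    """TV-constrained reconstruction with the default study parameters."""
    return CSReconstruction(sino, A, p).fit()
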