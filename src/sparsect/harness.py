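"""End-to-end experiment runner for the few-view phantom study.

``run_experiment`` regenerates the whole comparison from nothing but code:
phantom on the 0-255 working scale, exact-intersection sinograms at each
requested view count, reconstruction with each requested method, and
RMSE/UQI/CC against the reference, laid out as a method x view-count table.

``assemble_sinogram`` is the generic helper for building a sinogram from a
stack of measured projection images (one detector row per view), with
optional background subtraction and column cropping; ``subsample_views``
extracts evenly spaced angular subsets from a dense sinogram.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np

from .geometry import ScanGeometry, make_geometry
from .metrics import QualityReport, evaluate
from .phantom import PixelImage, add_gaussian_noise, generate_shepp_logan, to_byte_scale
from .projector import Sinogram, SystemMatrix, build_system_matrix, forward_project
from .recon import ART, CSParams, CSReconstruction, FilteredBackProjection, ReconResult

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentSpec",
    "ResultsTable",
    "run_experiment",
    "assemble_sinogram",
    "subsample_views",
]

METHODS = ("cs", "art", "fbp")


@dataclass(frozen=True)
class ExperimentSpec:
    """Configuration of one phantom study run.

    ``reference="phantom"`` scores reconstructions against the ground-truth
    phantom; ``reference="dense_fbp"`` scores them against an FBP
    reconstruction from ``dense_views`` projections, mirroring the protocol
    used when no ground truth exists and a densely sampled scan serves as
    the reference.
    """

    view_counts: tuple = (60, 30)
    methods: tuple = METHODS
    grid_size: int = 256
    noise_sigma: float = 0.0
    seed: int = 0
    cs_params: CSParams = field(default_factory=CSParams)
    output_dir: str | None = None
    use_symmetry: bool = True
    reference: str = "phantom"
    dense_views: int = 180

    def __post_init__(self):
        if not self.methods:
            raise ValueError("methods must be nonempty")
        if any(v < 1 for v in self.view_counts):
            raise ValueError("every view count must be >= 1")
        for m in self.methods:
            if m not in METHODS:
                raise ValueError(f"unknown method {m!r}")
        if self.reference not in ("phantom", "dense_fbp"):
            raise ValueError("reference must be 'phantom' or 'dense_fbp'")

    def digest(self) -> str:
        d = {k: (list(v) if isinstance(v, tuple) else v)
             for k, v in self.__dict__.items() if k != "cs_params"}
        d["cs_params"] = self.cs_params.__dict__
        return hashlib.sha1(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:10]


@dataclass
class ResultsTable:
    """Per (method, view count) quality reports, mirroring the study tables."""

    reports: dict
    images: dict
    spec: ExperimentSpec

    def report(self, method: str, n_views: int) -> QualityReport:
        return self.reports[(method, n_views)]

    def __str__(self) -> str:
        methods = list(self.spec.methods)
        lines = []
        for metric in ("rmse", "uqi", "cc"):
            lines.append(metric.upper())
            header = f"{'views':>8}" + "".join(f"{m:>12}" for m in methods)
            lines.append(header)
            for v in self.spec.view_counts:
                row = f"{v:>8}"
                for m in methods:
                    row += f"{getattr(self.reports[(m, v)], metric):>12.4g}"
                lines.append(row)
            lines.append("")
        return "\n".join(lines)

    def to_records(self) -> list[dict]:
        return [
            {"method": m, "n_views": v, **r.to_dict()}
            for (m, v), r in sorted(self.reports.items())
        ]

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tag = self.spec.digest()
        recs = self.to_records()
        (outdir / f"results_{tag}.json").write_text(json.dumps(recs, indent=1))
        cols = ["method", "n_views", "rmse", "uqi", "cc", "n_pixels"]
        csv_lines = [",".join(cols)]
        csv_lines += [",".join(str(r[c]) for c in cols) for r in recs]
        (outdir / f"results_{tag}.csv").write_text("\n".join(csv_lines) + "\n")
        from .io import save_image  # local import avoids a cycle at module load

        for (m, v), img in self.images.items():
            save_image(img, outdir / f"recon_{m}_{v}view_{tag}.tif")


def _fit_method(method: str, sino: Sinogram, A: SystemMatrix,
                p: CSParams) -> ReconResult:
    if method == "fbp":
        return FilteredBackProjection(sino).fit()
    if method == "art":
        return ART(sino, A, relaxation=p.relaxation,
                   stop_threshold=p.stop_threshold, max_cycles=p.max_cycles,
                   nonnegativity=p.nonnegativity).fit()
    return CSReconstruction(sino, A, p).fit()


def run_experiment(spec: ExperimentSpec) -> ResultsTable:
    """Run the full phantom study described by ``spec``."""
    phantom = to_byte_scale(generate_shepp_logan(spec.grid_size))
    if spec.reference == "phantom":
        reference = phantom
    else:
        geom = make_geometry(spec.dense_views, grid_size=spec.grid_size)
        dense = build_system_matrix(geom, use_symmetry=spec.use_symmetry)
        reference = FilteredBackProjection(
            forward_project(phantom, dense)).fit().image

    reports: dict = {}
    images: dict = {}
    for v in spec.view_counts:
        geom = make_geometry(v, grid_size=spec.grid_size)
        A = build_system_matrix(geom, use_symmetry=spec.use_symmetry)
        sino = forward_project(phantom, A)
        if spec.noise_sigma > 0:
            sino = add_gaussian_noise(sino, spec.noise_sigma, spec.seed)
        for m in spec.methods:
            logger.info("reconstructing %s at %d views", m, v)
            res = _fit_method(m, sino, A, spec.cs_params)
            reports[(m, v)] = evaluate(res.image, reference)
            images[(m, v)] = res.image
    table = ResultsTable(reports=reports, images=images, spec=spec)
    if spec.output_dir is not None:
        table.write(spec.output_dir)
    return table


def assemble_sinogram(projection_stack: Sequence[np.ndarray], slice_row: int,
                      background: np.ndarray | None = None,
                      crop: tuple[int, int] | None = None) -> Sinogram:
    """Build a T x B sinogram from T projection images of one scan.

    Each projection contributes the detector row ``slice_row``; an optional
    flat-field/background image is subtracted first and columns may be
    cropped to ``crop = (start, stop)``.  View angles are assumed evenly
    spaced over 180 degrees in acquisition order.
    """
    stack = [np.asarray(p, dtype=np.float64) for p in projection_stack]
    if not stack:
        raise ValueError("projection stack is empty")
    shape = stack[0].shape
    if any(p.shape != shape for p in stack):
        raise ValueError("all projections must share the same dimensions")
    if not (0 <= slice_row < shape[0]):
        raise ValueError(f"slice_row {slice_row} outside image of {shape[0]} rows")
    if background is not None:
        background = np.asarray(background, dtype=np.float64)
        if background.shape != shape:
            raise ValueError("background dimensions do not match projections")
        stack = [p - background for p in stack]
    lo, hi = (0, shape[1]) if crop is None else crop
    rows = [p[slice_row, lo:hi] for p in stack]
    values = np.stack(rows, axis=0)
    t, b = values.shape
    geom = make_geometry(t, n_bins=b, grid_size=b)
    return Sinogram(values=values, geometry=geom)


def subsample_views(sino: Sinogram, keep_every: int) -> Sinogram:
    """Keep every ``keep_every``-th view (must divide the view count evenly)."""
    t = sino.geometry.n_views
    if keep_every < 1 or t % keep_every != 0:
        raise ValueError(
            f"keep_every={keep_every} does not evenly divide {t} views"
        )
    if keep_every == 1:
        return sino
    geom = ScanGeometry(
        angles_deg=sino.geometry.angles_deg[::keep_every],
        n_bins=sino.geometry.n_bins,
        grid_size=sino.geometry.grid_size,
        bin_spacing=sino.geometry.bin_spacing,
    )
    return Sinogram(values=sino.values[::keep_every], geometry=geom)
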