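"""Independent oracles used by the test suite.

These deliberately avoid the package's own code paths: line integrals are
computed by dense sub-sampling of the ray, the smoothed-TV functional and its
gradient by direct evaluation / central differences.
"""

import numpy as np


def line_integral(values: np.ndarray, angle_deg: float, offset: float,
                  step: float = 0.002) -> float:
    """Brute-force line integral through a pixel grid by midpoint sampling."""
    n = values.shape[0]
    h = n / 2.0
    th = np.deg2rad(angle_deg)
    dx, dy = np.cos(th), np.sin(th)
    ts = np.arange(-h * 1.6, h * 1.6, step) + step / 2.0
    xs = -offset * dy + ts * dx
    ys = offset * dx + ts * dy
    c = np.floor(xs + h).astype(int)
    r = np.floor(h - ys).astype(int)
    ok = (c >= 0) & (c < n) & (r >= 0) & (r < n)
    return float(values[r[ok], c[ok]].sum() * step)


def smoothed_tv(a: np.ndarray, eps: float) -> float:
    """sum over pixels of sqrt(eps + |forward-difference gradient|^2)."""
    dv = np.zeros_like(a)
    dh = np.zeros_like(a)
    dv[:-1] = np.diff(a, axis=0)
    dh[:, :-1] = np.diff(a, axis=1)
    return float(np.sum(np.sqrt(eps + dv * dv + dh * dh)))


def numerical_tv_gradient(a: np.ndarray, eps: float, h: float = 1e-6) -> np.ndarray:
    """Central-difference gradient of :func:`smoothed_tv`."""
    out = np.zeros_like(a)
    for idx in np.ndindex(a.shape):
        ap = a.copy()
        ap[idx] += h
        am = a.copy()
        am[idx] -= h
        out[idx] = (smoothed_tv(ap, eps) - smoothed_tv(am, eps)) / (2 * h)
    return out
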