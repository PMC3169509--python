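"""Numba kernel for the sequential Kaczmarz (ART) sweep.

The sweep visits rays one at a time and each update feeds the next, so the
loop cannot be vectorized; it is compiled instead.
"""

import numba
import numpy as np


@numba.njit(cache=False)
def kaczmarz_sweep(indptr, indices, data, row_sq_norms, g, f, relaxation):
    """One full pass i = 0..M-1 of relaxed Kaczmarz updates, in place on f.

    f_j += relaxation * (g_i - <phi_i, f>) / ||phi_i||^2 * phi_ij
    Rows with zero norm are skipped.
    """
    m = g.shape[0]
    for i in range(m):
        lo = indptr[i]
        hi = indptr[i + 1]
        denom = row_sq_norms[i]
        if denom <= 0.0:
            continue
        dot = 0.0
        for k in range(lo, hi):
            dot += data[k] * f[indices[k]]
        c = relaxation * (g[i] - dot) / denom
        for k in range(lo, hi):
            f[indices[k]] += c * data[k]
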