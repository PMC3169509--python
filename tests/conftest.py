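import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import sparsect as sc

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def phantom256():
    return sc.generate_shepp_logan(256)


@pytest.fixture(scope="session")
def byte_phantom32():
    return sc.to_byte_scale(sc.generate_shepp_logan(32))


@pytest.fixture(scope="session")
def small_scan(byte_phantom32):
    """16-view scan of the 32x32 byte-scale phantom (geometry, matrix, sinogram)."""
    geom = sc.make_geometry(16, grid_size=32)
    A = sc.build_system_matrix(geom)
    sino = sc.forward_project(byte_phantom32, A)
    return geom, A, sino


def random_system(seed: int, grid: int = 4):
    """A random consistent ray system on a small grid, with its exact solution."""
    import scipy.sparse as sp

    from sparsect.projector import SystemMatrix

    rng = np.random.default_rng(seed)
    n = grid * grid
    dense = np.abs(rng.random((n, n))) * (rng.random((n, n)) < 0.4)
    mat = sp.csr_matrix(dense)
    rsq = np.asarray(mat.multiply(mat).sum(axis=1)).ravel()
    geom = sc.make_geometry(grid, grid, grid_size=grid)
    A = SystemMatrix(matrix=mat, geometry=geom, row_sq_norms=rsq)
    f_true = rng.random(n)
    sino = sc.Sinogram((dense @ f_true).reshape(grid, grid), geom)
    return A, sino, f_true
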