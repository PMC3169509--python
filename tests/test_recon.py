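"""FBP, ART sweeps, TV subgradient, and the TV-constrained solver."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparsect as sc
from conftest import random_system
from oracles import numerical_tv_gradient, smoothed_tv


class TestFBP:
    def test_zero_sinogram_gives_zero_image(self):
        g = sc.make_geometry(8, 16, grid_size=16)
        s = sc.Sinogram(np.zeros((8, 16)), g)
        assert np.array_equal(sc.fbp_reconstruct(s).values, np.zeros((16, 16)))

    def test_error_decreases_with_view_density(self):
        ph = sc.to_byte_scale(sc.generate_shepp_logan(64))
        errs = {}
        for v in (60, 720):
            sino, _ = sc.simulate_sinogram(ph, v)
            errs[v] = sc.rmse(sc.fbp_reconstruct(sino), ph)
        assert errs[720] < errs[60]

    def test_agrees_with_reference_iradon(self):
        """Our FBP and skimage's iradon implement the same analytic inverse;
        on a shared sinogram their reconstructions should be far closer to
        each other than either is to the phantom (residual differences come
        from interpolation internals).  skimage's angle convention is ours
        plus 90 degrees."""
        iradon = pytest.importorskip("skimage.transform").iradon
        ph = sc.to_byte_scale(sc.generate_shepp_logan(63))
        sino, _ = sc.simulate_sinogram(ph, 60)
        ours = sc.fbp_reconstruct(sino).values
        ref = iradon(sino.values.T, theta=sino.geometry.angles_deg + 90.0,
                     filter_name="ramp", interpolation="linear", circle=True)
        assert sc.rmse(ours, ref) < 0.5 * sc.rmse(ref, ph.values)
        assert sc.cc(ours, ref) > 0.97


class TestARTSweep:
    def test_consistent_image_is_fixed_point(self, small_scan):
        _, A, sino = small_scan
        f = sc.to_byte_scale(sc.generate_shepp_logan(32))
        out = sc.art_sweep(f, sino, A, relaxation=1.0)
        assert np.allclose(out.values, f.values, atol=1e-9)

    def test_zero_relaxation_is_identity(self, small_scan):
        _, A, sino = small_scan
        rng = np.random.default_rng(0)
        f = sc.PixelImage(rng.random((32, 32)))
        out = sc.art_sweep(f, sino, A, relaxation=0.0)
        assert np.array_equal(out.values, f.values)

    def test_converges_to_exact_solution_of_full_rank_system(self):
        import scipy.sparse as sp

        from sparsect.projector import SystemMatrix

        rng = np.random.default_rng(7)
        dense = rng.random((4, 4)) + np.eye(4)
        mat = sp.csr_matrix(dense)
        A = SystemMatrix(mat, sc.make_geometry(2, 2, grid_size=2),
                         np.asarray(mat.multiply(mat).sum(axis=1)).ravel())
        f_true = rng.random(4)
        sino = sc.Sinogram((dense @ f_true).reshape(2, 2), A.geometry)
        f = sc.PixelImage(np.zeros((2, 2)))
        for _ in range(2000):
            f = sc.art_sweep(f, sino, A, 1.0)
        assert np.allclose(f.values.ravel(), f_true, atol=1e-8)

    @pytest.mark.parametrize("relaxation", [0.3, 1.0, 1.7])
    def test_distance_to_solution_never_increases(self, relaxation):
        """Relaxed Kaczmarz projections are non-expansive toward any solution
        of a consistent system, so ||f - f*|| is monotone over sweeps.  (The
        data residual itself is not monotone and is only required to vanish
        in the limit.)"""
        for seed in (0, 1, 2):
            A, sino, f_true = random_system(seed)
            f = sc.PixelImage(np.zeros((4, 4)))
            prev = np.linalg.norm(f_true)
            for _ in range(25):
                f = sc.art_sweep(f, sino, A, relaxation)
                d = np.linalg.norm(f.values.ravel() - f_true)
                assert d <= prev + 1e-9
                prev = d

    def test_residual_vanishes_on_consistent_system(self):
        A, sino, _ = random_system(3)
        res = sc.art_reconstruct(sino, A, stop_threshold=1e-10,
                                 max_cycles=3000)
        assert res.final_residual < 1e-6


class TestTVSubgradient:
    def test_constant_image_gives_zero(self):
        assert np.array_equal(sc.tv_subgradient(np.full((4, 4), 2.0), 1e-4),
                              np.zeros((4, 4)))

    def test_center_impulse_hand_values(self):
        eps = 1e-4
        f = np.zeros((3, 3))
        f[1, 1] = 1.0
        s1 = 1.0 / np.sqrt(1.0 + eps)
        s2 = 1.0 / np.sqrt(2.0 + eps)
        expect = np.array([
            [0.0, -s1, 0.0],
            [-s1, 2.0 * s2 + 2.0 * s1, -s2],
            [0.0, -s2, 0.0],
        ])
        assert np.allclose(sc.tv_subgradient(f, eps), expect, atol=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=15)
    def test_matches_numerical_gradient_of_smoothed_tv(self, seed):
        rng = np.random.default_rng(seed)
        f = rng.random((8, 8))
        v = sc.tv_subgradient(f, 1e-4)
        num = numerical_tv_gradient(f, 1e-4)
        assert np.allclose(v, num, atol=1e-4)

    def test_small_step_descends_smoothed_tv(self):
        """Stepping along the negative normalized subgradient with a
        line-search-verified step length must not increase the smoothed TV."""
        rng = np.random.default_rng(5)
        for _ in range(5):
            f = rng.random((8, 8))
            v = sc.tv_subgradient(f, 1e-4)
            nv = np.linalg.norm(v)
            e0 = smoothed_tv(f, 1e-4)
            step = 1e-2
            for _ in range(40):
                if smoothed_tv(f - step * v / nv, 1e-4) <= e0:
                    break
                step /= 2
            assert smoothed_tv(f - step * v / nv, 1e-4) <= e0

    def test_invalid_epsilon_rejected(self):
        with pytest.raises(ValueError):
            sc.tv_subgradient(np.zeros((3, 3)), 0.0)


class TestIterativeSolvers:
    def test_zero_sinogram_converges_immediately(self, small_scan):
        _, A, _ = small_scan
        zero = sc.Sinogram(np.zeros((16, 32)), A.geometry)
        for res in (sc.art_reconstruct(zero, A), sc.cs_reconstruct(zero, A)):
            assert np.array_equal(res.image.values, np.zeros((32, 32)))
            assert res.converged and res.n_cycles_run == 1

    def test_without_tv_steps_reduces_to_art(self, small_scan):
        _, A, sino = small_scan
        p = sc.CSParams(n_tv_sub=0, max_cycles=12)
        cs = sc.cs_reconstruct(sino, A, p)
        art = sc.art_reconstruct(sino, A, max_cycles=12)
        assert np.array_equal(cs.image.values, art.image.values)
        assert cs.per_cycle_change == art.per_cycle_change

    def test_tv_constraint_improves_fewview_recovery(self, small_scan):
        """With few views and gradient-sparse truth, the TV-constrained
        solver should beat plain ART on RMSE."""
        _, A, sino = small_scan
        truth = sc.to_byte_scale(sc.generate_shepp_logan(32))
        p = sc.CSParams(max_cycles=150)
        cs = sc.cs_reconstruct(sino, A, p)
        art = sc.art_reconstruct(sino, A, max_cycles=150)
        assert sc.rmse(cs.image, truth) < sc.rmse(art.image, truth)

    def test_result_diagnostics_consistent(self, small_scan):
        _, A, sino = small_scan
        res = sc.cs_reconstruct(sino, A, sc.CSParams(max_cycles=8))
        assert res.n_cycles_run <= 8
        assert len(res.per_cycle_change) == res.n_cycles_run
        assert "Cycles run" in res.summary()

    def test_nonnegativity_flag_clamps(self, small_scan):
        _, A, sino = small_scan
        res = sc.art_reconstruct(sino, A, max_cycles=5, nonnegativity=True)
        assert res.image.values.min() >= 0.0

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            sc.CSParams(relaxation=0.0)
        with pytest.raises(ValueError):
            sc.CSParams(epsilon=-1.0)
        with pytest.raises(ValueError):
            sc.CSParams(max_cycles=0)
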