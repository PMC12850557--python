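"""Solver correctness, sketched-gradient identities and cross-checks."""

import numpy as np
import pytest

from spiralsketch.coils import build_sketch_plan
from spiralsketch.encoding import EncodingSystem, sense_forward
from spiralsketch.io import ReconConfig
from spiralsketch.regularization import RegularizerSpec
from spiralsketch.solvers import (
    SolveState,
    cg_solve,
    conventional_reconstruct,
    fista_solve,
    objective_value,
    pdhg_solve,
    sketched_gradient,
    sketched_reconstruct,
)


class TestCg:
    def test_identity_system_converges_immediately(self, rng):
        rhs = rng.standard_normal(10) + 1j * rng.standard_normal(10)
        x = cg_solve(lambda v: v, rhs, 1)
        np.testing.assert_allclose(x, rhs, atol=1e-12)

    def test_dense_spd_solved_exactly(self, rng):
        B = rng.standard_normal((8, 8))
        H = B @ B.T + 8 * np.eye(8)
        rhs = rng.standard_normal(8) + 0j
        x = cg_solve(lambda v: H @ v, rhs, 8)
        ref = np.linalg.solve(H, rhs)
        assert np.linalg.norm(x - ref) < 1e-10 * np.linalg.norm(ref)


class TestFista:
    def test_quadratic_matches_reference_momentum_descent(self, rng):
        # dense toy oracle: FISTA with identity prox == accelerated GD
        B = rng.standard_normal((12, 12))
        H = B @ B.T
        H /= np.linalg.eigvalsh(H).max()
        b = rng.standard_normal(12)
        x0 = np.zeros(12, dtype=complex)
        grad = lambda v: H @ v - b
        x, _, _ = fista_solve(grad, lambda v, t: v, x0, 60, step=1.0)
        # independent reference implementation of Nesterov's sequence
        xr = x0.copy(); z = x0.copy(); t = 1.0; xp = x0.copy()
        for _ in range(60):
            g = H @ z - b
            xn = z - g
            restart = float(np.real(np.vdot(g, xn - xr))) > 0
            if restart:
                t = 1.0; z = xn.copy()
            else:
                tn = 0.5 * (1 + np.sqrt(1 + 4 * t * t))
                z = xn + ((t - 1) / tn) * (xn - xr)
                t = tn
            xr = xn
        np.testing.assert_allclose(x, xr, atol=1e-12)

    def test_zero_data_stays_zero(self):
        grad = lambda v: v  # A^H A x - A^H y with y = 0, N = I
        x, _, _ = fista_solve(grad, lambda v, t: v,
                              np.zeros(5, complex), 10)
        assert np.abs(x).max() == 0


@pytest.fixture(scope="module")
def small_system(fixture24):
    return fixture24.system, fixture24.ys


class TestSolverCrossChecks:
    def test_fista_matches_cg_without_regularization(self, small_system):
        system, ys = small_system
        cfg_f = ReconConfig(regularizer="cgsense", solver="fista", lam=0.0,
                            n_bins=3, pad_factor=1.0)
        cfg_c = ReconConfig(regularizer="cgsense", solver="cg", lam=0.0,
                            n_bins=3, pad_factor=1.0)
        reg = RegularizerSpec(kind="none", lam=0.0)
        x_f, _ = conventional_reconstruct(ys, system, cfg_f, n_iter=120,
                                          track_objective=False)
        x_c, _ = conventional_reconstruct(ys, system, cfg_c, n_iter=40,
                                          track_objective=False)
        o_f = objective_value(x_f, ys, system, reg)
        o_c = objective_value(x_c, ys, system, reg)
        assert abs(o_f - o_c) / o_c < 1e-2

    def test_pdhg_matches_cg_without_regularization(self):
        # well-conditioned multicoil Cartesian instance: both solvers must
        # land on the same least-squares solution
        from spiralsketch.encoding import kspace_preconditioner, \
            normalize_system
        from spiralsketch.nufft import nufft_forward
        from spiralsketch.phantom import PhantomSpec, make_coil_maps, \
            make_dynamic_phantom
        n = 16
        ph = make_dynamic_phantom(PhantomSpec(grid_shape=(n, n), n_phases=1,
                                              diaphragm_amplitude=0.0,
                                              seed=1))
        maps = make_coil_maps(3, (n, n), seed=2)
        ii, jj = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                             indexing="ij")
        cart = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        rng = np.random.default_rng(0)
        k = np.stack([nufft_forward(maps[c] * ph.images[0], cart)
                      for c in range(3)])
        k = k + 0.01 * (rng.standard_normal(k.shape)
                        + 1j * rng.standard_normal(k.shape))
        w = kspace_preconditioner([cart], (n, n))
        system = EncodingSystem(maps=maps, coords=[cart], weights=w,
                                grid_shape=(n, n))
        normalize_system(system, n_iter=100, seed=0)
        ys = system.preconditioned_data([k])
        cfg_p = ReconConfig(regularizer="cgsense", solver="pdhg", lam=0.0,
                            n_bins=1, pad_factor=1.0)
        cfg_c = ReconConfig(regularizer="cgsense", solver="cg", lam=0.0,
                            n_bins=1, pad_factor=1.0)
        x_p, _ = conventional_reconstruct(ys, system, cfg_p, n_iter=60,
                                          track_objective=False)
        x_c, _ = conventional_reconstruct(ys, system, cfg_c, n_iter=30,
                                          track_objective=False)
        nrmse = np.linalg.norm(np.abs(x_p) - np.abs(x_c)) \
            / np.linalg.norm(np.abs(x_c))
        assert nrmse < 0.01

    def test_tv_smooths_under_strong_regularization(self, small_system):
        system, ys = small_system
        cfg = ReconConfig(regularizer="tv", solver="pdhg", lam=1.0,
                          n_bins=3, pad_factor=1.0)
        cfg0 = ReconConfig(regularizer="cgsense", solver="cg", lam=0.0,
                           n_bins=3, pad_factor=1.0)
        x_tv, _ = conventional_reconstruct(ys, system, cfg, n_iter=40,
                                           track_objective=False)
        x_0, _ = conventional_reconstruct(ys, system, cfg0, n_iter=40,
                                          track_objective=False)
        assert np.abs(x_tv).std() < np.abs(x_0).std()

    def test_cg_recovers_phantom_fully_sampled_single_coil(self):
        from spiralsketch.encoding import kspace_preconditioner, \
            normalize_system
        from spiralsketch.phantom import PhantomSpec, make_dynamic_phantom
        from spiralsketch.nufft import nufft_forward
        n = 24
        ph = make_dynamic_phantom(PhantomSpec(grid_shape=(n, n), n_phases=1,
                                              diaphragm_amplitude=0.0, seed=1))
        ii, jj = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                             indexing="ij")
        cart = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        maps = np.ones((1, n, n), dtype=np.complex128)
        k = nufft_forward(ph.images[0], cart)[None]
        w = kspace_preconditioner([cart], (n, n))
        system = EncodingSystem(maps=maps, coords=[cart], weights=w,
                                grid_shape=(n, n))
        normalize_system(system, seed=0)
        ys = system.preconditioned_data([k])
        cfg = ReconConfig(regularizer="cgsense", solver="cg", lam=0.0,
                          n_bins=1, pad_factor=1.0)
        x, _ = conventional_reconstruct(ys, system, cfg, n_iter=20,
                                        track_objective=False)
        nrmse = np.linalg.norm(np.abs(x[0]) - np.abs(ph.images[0])) \
            / np.linalg.norm(ph.images[0])
        assert nrmse < 0.01


class TestSketchedGradient:
    @pytest.fixture(scope="class")
    def tiny(self, rng=None):
        rng = np.random.default_rng(11)
        shape = (6, 6)
        coords = rng.uniform(-3, 2.9, size=(50, 2))
        maps = rng.standard_normal((3, 6, 6)) + 1j * rng.standard_normal((3, 6, 6))
        w = [rng.uniform(0.5, 1.5, 50)]
        system = EncodingSystem(maps=maps, coords=[coords], weights=w,
                                grid_shape=shape)
        y = [rng.standard_normal((3, 50)) + 1j * rng.standard_normal((3, 50))]
        return system, y, rng

    def test_equals_full_gradient_at_anchor_for_any_sketch(self, tiny):
        system, ys, rng = tiny
        x_t = rng.standard_normal((1, 6, 6)) + 1j * rng.standard_normal((1, 6, 6))
        full_grad = system.normal(x_t) - system.adjoint(ys)
        state = SolveState(x=x_t, x_anchor=x_t, full_grad_anchor=full_grad)
        for seed in range(5):
            q = build_sketch_plan(3, 2, 1, seed=seed).sketches[0]
            g = sketched_gradient(x_t, state, system.sketched(q))
            np.testing.assert_allclose(g, full_grad, atol=1e-10)

    def test_identity_sketch_equals_full_gradient_everywhere(self, tiny):
        system, ys, rng = tiny
        x_t = rng.standard_normal((1, 6, 6)) + 1j * rng.standard_normal((1, 6, 6))
        x = rng.standard_normal((1, 6, 6)) + 1j * rng.standard_normal((1, 6, 6))
        full_anchor = system.normal(x_t) - system.adjoint(ys)
        state = SolveState(x=x, x_anchor=x_t, full_grad_anchor=full_anchor)
        g = sketched_gradient(x, state, system.sketched(np.eye(3)))
        expected = system.normal(x) - system.adjoint(ys)
        assert np.abs(g - expected).max() < 1e-10 * np.abs(expected).max()

    def test_matches_dense_matrix_evaluation(self, tiny):
        system, ys, rng = tiny
        # assemble dense A from the forward operator applied to unit vectors
        J = 36
        A = np.zeros((3 * 50, J), dtype=np.complex128)
        for j in range(J):
            e = np.zeros((1, 6, 6), dtype=np.complex128)
            e[0].flat[j] = 1.0
            A[:, j] = system.forward(e)[0].ravel()
        q = build_sketch_plan(3, 2, 1, seed=4).sketches[0]
        Aq = np.kron(q, np.eye(50)) @ A
        x_t = rng.standard_normal((1, 6, 6)) + 1j * rng.standard_normal((1, 6, 6))
        x = rng.standard_normal((1, 6, 6)) + 1j * rng.standard_normal((1, 6, 6))
        yv = ys[0].ravel()
        dense = (Aq.conj().T @ (Aq @ (x - x_t).ravel())
                 + A.conj().T @ (A @ x_t.ravel() - yv)).reshape(x.shape)
        full_anchor = system.normal(x_t) - system.adjoint(ys)
        state = SolveState(x=x, x_anchor=x_t, full_grad_anchor=full_anchor)
        g = sketched_gradient(x, state, system.sketched(q))
        assert np.linalg.norm(g - dense) / np.linalg.norm(dense) < 1e-8

    def test_stale_anchor_rejected(self, tiny):
        system, ys, rng = tiny
        x = np.zeros((1, 6, 6), complex)
        state = SolveState(x=x, x_anchor=x, full_grad_anchor=x,
                           anchor_fresh=False)
        with pytest.raises(RuntimeError, match="stale"):
            sketched_gradient(x, state, system)


class TestSketchedReconstruct:
    @pytest.mark.parametrize("solver", ["fista", "pdhg"])
    def test_degenerate_sketch_reproduces_conventional(self, fixture24,
                                                       solver):
        system, ys = fixture24.system, fixture24.ys
        C = system.n_coils
        cfg0 = ReconConfig(regularizer="lr", solver=solver, lam=0.1,
                           sketch_coils=0, n_bins=3, pad_factor=1.0)
        cfg1 = ReconConfig(regularizer="lr", solver=solver, lam=0.1,
                           sketch_coils=C, n_bins=3, pad_factor=1.0)
        x0, tr0 = conventional_reconstruct(ys, system, cfg0)
        x1, tr1 = sketched_reconstruct(ys, system, cfg1, identity_sketch=True)
        assert np.linalg.norm(x1 - x0) / np.linalg.norm(x0) < 1e-10
        for a, b in zip(tr0, tr1):
            assert abs(a[1] - b[1]) <= 1e-9 * abs(a[1])

    def test_objective_trace_counts_schedule(self, fixture24):
        system, ys = fixture24.system, fixture24.ys
        cfg = ReconConfig(regularizer="lr", solver="fista", lam=0.1,
                          sketch_coils=2, n_bins=3, pad_factor=1.0,
                          n_initial=2, n_inner=2, n_outer=3)
        _, tr = sketched_reconstruct(ys, system, cfg, track_objective=False)
        assert len(tr) == 2 + 2 * 3
        assert [t[0] for t in tr] == list(range(1, 9))

    def test_oversized_sketch_rejected(self, fixture24):
        cfg = ReconConfig(regularizer="lr", solver="fista", lam=0.1,
                          sketch_coils=99, n_bins=3, pad_factor=1.0)
        with pytest.raises(ValueError, match="exceeds"):
            sketched_reconstruct(fixture24.ys, fixture24.system, cfg)


class TestObjective:
    def test_zero_image_gives_half_data_energy(self, fixture24):
        system, ys = fixture24.system, fixture24.ys
        reg = RegularizerSpec(kind="none", lam=0.0)
        x0 = np.zeros(system.stack_shape(), complex)
        expected = 0.5 * sum(np.linalg.norm(y) ** 2 for y in ys)
        assert objective_value(x0, ys, system, reg) == pytest.approx(expected)

    def test_monotone_after_burn_in(self, fixture24):
        system, ys = fixture24.system, fixture24.ys
        cfg = ReconConfig(regularizer="lr", solver="fista", lam=0.1,
                          sketch_coils=0, n_bins=3, pad_factor=1.0)
        _, tr = conventional_reconstruct(ys, system, cfg, n_iter=25)
        objs = np.array([t[1] for t in tr])
        assert (np.diff(objs[3:]) <= 1e-6 * objs[0]).all()
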