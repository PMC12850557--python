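"""Measurement-model operators: SENSE, Toeplitz, preconditioner, power method."""

import numpy as np
import pytest

from spiralsketch.encoding import (
    EncodingSystem,
    apply_toeplitz,
    build_toeplitz_kernel,
    kspace_preconditioner,
    normal_op,
    normalize_system,
    power_method_maxeig,
    sense_adjoint,
    sense_forward,
)
from spiralsketch.nufft import nufft_forward
from spiralsketch.phantom import make_stack_of_spirals


@pytest.fixture(scope="module")
def spiral16():
    traj = make_stack_of_spirals(8, 1, (16, 16))
    rng = np.random.default_rng(5)
    maps = rng.standard_normal((3, 16, 16)) + 1j * rng.standard_normal((3, 16, 16))
    w = kspace_preconditioner([traj.coords], (16, 16))
    return traj.coords, maps, w


class TestSenseOperators:
    def test_adjoint_identity(self, spiral16, rng):
        coords, maps, w = spiral16
        x = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        ys = sense_forward(x, maps, [coords], w)
        yr = [rng.standard_normal(ys[0].shape) + 1j * rng.standard_normal(ys[0].shape)]
        xa = sense_adjoint(yr, maps, [coords], w, (16, 16))
        ip1 = np.vdot(yr[0], ys[0])
        ip2 = np.vdot(xa, x)
        assert abs(ip1 - ip2) / abs(ip1) < 1e-6

    def test_single_uniform_coil_reduces_to_nufft(self, spiral16, rng):
        coords, _, _ = spiral16
        x = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        uni = np.ones((1, 16, 16), dtype=np.complex128)
        ys = sense_forward(x, uni, [coords], [np.ones(coords.shape[0])])
        expected = nufft_forward(x[0], coords)
        np.testing.assert_allclose(ys[0][0], expected, atol=1e-12)

    def test_zero_image_gives_zero_samples(self, spiral16):
        coords, maps, w = spiral16
        ys = sense_forward(np.zeros((1, 16, 16), complex), maps, [coords], w)
        assert np.abs(ys[0]).max() == 0

    def test_phase_count_mismatch_rejected(self, spiral16, rng):
        coords, maps, w = spiral16
        x = np.zeros((2, 16, 16), complex)
        with pytest.raises(ValueError, match="phases"):
            sense_forward(x, maps, [coords], w)

    def test_linearity(self, spiral16, rng):
        coords, maps, w = spiral16
        a = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        b = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        lhs = sense_forward(0.5 * a + 2j * b, maps, [coords], w)[0]
        rhs = 0.5 * sense_forward(a, maps, [coords], w)[0] \
            + 2j * sense_forward(b, maps, [coords], w)[0]
        assert np.abs(lhs - rhs).max() < 1e-10 * np.abs(rhs).max()


class TestNormalOperator:
    def test_batch_size_independence(self, spiral16, rng):
        coords, maps, w = spiral16
        x = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        full = normal_op(x, maps, [coords], w, coil_batch=3)
        single = normal_op(x, maps, [coords], w, coil_batch=1)
        assert np.linalg.norm(full - single) / np.linalg.norm(full) < 1e-10

    def test_matches_dense_operator(self, rng):
        # 6x6 grid, 2 coils, 40 samples: assemble A column by column
        shape = (6, 6)
        coords = rng.uniform(-3, 2.9, size=(40, 2))
        maps = rng.standard_normal((2, 6, 6)) + 1j * rng.standard_normal((2, 6, 6))
        w = [rng.uniform(0.5, 2.0, 40)]
        J = 36
        A = np.zeros((2 * 40, J), dtype=np.complex128)
        for j in range(J):
            e = np.zeros((1, *shape), dtype=np.complex128)
            e[0].flat[j] = 1.0
            A[:, j] = sense_forward(e, maps, [coords], w)[0].ravel()
        x = rng.standard_normal((1, *shape)) + 1j * rng.standard_normal((1, *shape))
        dense = (A.conj().T @ (A @ x.ravel())).reshape(x.shape)
        fast = normal_op(x, maps, [coords], w)
        assert np.linalg.norm(dense - fast) / np.linalg.norm(dense) < 1e-6


class TestToeplitz:
    def test_matches_normal_op_on_spiral(self, spiral16, rng):
        coords, maps, w = spiral16
        x = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        ref = normal_op(x, maps, [coords], w)
        ker = build_toeplitz_kernel([coords], w, (16, 16))
        fast = apply_toeplitz(x, ker, maps)
        assert np.linalg.norm(fast - ref) / np.linalg.norm(ref) < 1e-3

    def test_cartesian_fully_sampled_is_scaled_identity(self, rng):
        n = 12
        ii, jj = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                             indexing="ij")
        cart = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        ker = build_toeplitz_kernel([cart], [np.ones(n * n)], (n, n))
        x = rng.standard_normal((1, n, n)) + 1j * rng.standard_normal((1, n, n))
        tx = apply_toeplitz(x, ker, np.ones((1, n, n), complex))
        ratio = tx / x
        mean = ratio.mean()
        assert np.abs(ratio - mean).max() / np.abs(mean) < 1e-6

    def test_kernel_is_map_independent(self, spiral16, rng):
        coords, maps, w = spiral16
        ker = build_toeplitz_kernel([coords], w, (16, 16))
        sketch = rng.choice([-1.0, 1.0], size=(2, 3)) / np.sqrt(1.0)
        smaps = np.tensordot(sketch, maps, axes=(1, 0))
        x = rng.standard_normal((1, 16, 16)) + 1j * rng.standard_normal((1, 16, 16))
        ref = normal_op(x, smaps, [coords], w)
        fast = apply_toeplitz(x, ker, smaps)  # same kernel, sketched maps
        assert np.linalg.norm(fast - ref) / np.linalg.norm(ref) < 1e-3

    def test_grid_mismatch_rejected(self, spiral16):
        coords, maps, w = spiral16
        ker = build_toeplitz_kernel([coords], w, (16, 16))
        with pytest.raises(ValueError, match="grid"):
            apply_toeplitz(np.zeros((1, 8, 8), complex), ker, maps[:, :8, :8])


class TestPreconditioner:
    def test_cartesian_weights_constant(self):
        n = 8
        ii, jj = np.meshgrid(np.arange(n) - n // 2, np.arange(n) - n // 2,
                             indexing="ij")
        cart = np.stack([ii.ravel(), jj.ravel()], axis=1).astype(float)
        w = kspace_preconditioner([cart], (n, n))[0]
        assert (w.max() - w.min()) / w.mean() < 1e-6

    def test_spiral_weights_positive_finite(self):
        traj = make_stack_of_spirals(6, 1, (16, 16))
        w = kspace_preconditioner([traj.coords], (16, 16))[0]
        assert np.isfinite(w).all() and (w > 0).all()

    def test_spectrum_more_clustered_on_spiral(self):
        # dense eigenvalue oracle on a 12x12 instance
        n = 12
        traj = make_stack_of_spirals(6, 1, (n, n))
        coords = traj.coords
        j0 = np.arange(n) - n // 2
        e1 = np.exp(-2j * np.pi * coords[:, :1] * j0[None, :] / n)
        e2 = np.exp(-2j * np.pi * coords[:, 1:2] * j0[None, :] / n)
        F = (e1[:, :, None] * e2[:, None, :]).reshape(coords.shape[0], -1)
        M = F @ F.conj().T
        w = kspace_preconditioner([coords], (n, n))[0]
        Mp = np.sqrt(w)[:, None] * M * np.sqrt(w)[None, :]
        rank = n * n

        def cond(mat):
            e = np.sort(np.linalg.eigvalsh(mat))[::-1]
            return e[0] / e[rank - 1]

        assert cond(Mp) <= cond(M)

    def test_dcf_fallback_positive(self):
        traj = make_stack_of_spirals(6, 1, (16, 16))
        w = kspace_preconditioner([traj.coords], (16, 16), method="dcf")[0]
        assert (w > 0).all()


class TestPowerMethod:
    def test_known_diagonal(self):
        D = np.diag([1.0, 2.0, 3.0])
        eig = power_method_maxeig(
            lambda v: (D @ v.ravel()).reshape(v.shape), (3,), n_iter=50, seed=0
        )
        assert abs(eig - 3.0) < 1e-6

    def test_matches_dense_eigensolver(self, rng):
        B = rng.standard_normal((20, 20)) + 1j * rng.standard_normal((20, 20))
        H = B @ B.conj().T
        ref = np.linalg.eigvalsh(H).max()
        eig = power_method_maxeig(
            lambda v: (H @ v.ravel()).reshape(v.shape), (20,), n_iter=500,
            seed=1,
        )
        assert abs(eig - ref) / ref < 1e-4

    def test_zero_operator_rejected(self):
        with pytest.raises(ValueError):
            power_method_maxeig(lambda v: 0.0 * v, (4,), n_iter=5, seed=0)

    def test_normalization_idempotent(self, spiral16):
        coords, maps, w = spiral16
        system = EncodingSystem(maps=maps, coords=[coords],
                                weights=[w[0].copy()], grid_shape=(16, 16))
        normalize_system(system, n_iter=200, seed=2)
        eig = power_method_maxeig(lambda v: system.normal(v),
                                  system.stack_shape(), n_iter=200, seed=3)
        assert abs(eig - 1.0) < 1e-3
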