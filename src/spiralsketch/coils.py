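"""Coil-domain processing: SVD reordering/compression, ESPIRiT-style map
estimation, and sketch-plan construction.

Virtual coils are ranked by energy via eigendecomposition of the coil
covariance of the measured k-space.  Compression keeps the top-C' virtual
coils (a fixed linear projection); sketching instead draws, per outer
iteration, a random (C_S x C) combination matrix that keeps virtual coil 1
verbatim and mixes the remaining coils with scaled Rademacher (+-1) weights,
so the sketch Gram matrix is the identity in expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import zoom as _ndzoom

from .nufft import _centered_fft, nufft_adjoint

__all__ = ["CoilBasis", "SketchPlan", "svd_reorder", "compress",
           "estimate_maps", "build_sketch_plan", "apply_sketch"]


@dataclass
class CoilBasis:
    mixing: np.ndarray  # (C, C) unitary, columns = virtual coils
    energies: np.ndarray  # nonincreasing

    @property
    def n_coils(self) -> int:
        return self.mixing.shape[0]

    def energy_fraction(self, c_prime: int) -> float:
        return float(self.energies[:c_prime].sum() / self.energies.sum())


@dataclass
class SketchPlan:
    sketches: list  # n_outer matrices, each (C_S, C)
    kept_coils: tuple
    seed: int


def svd_reorder(kspace: np.ndarray):
    """Rank coils by energy contribution.

    Returns ``(basis, reordered)`` where ``reordered = mixing^H @ kspace``
    puts the highest-energy virtual coil first.  Accepts a single (C, K)
    block or a list of per-phase blocks (covariance pooled, each block
    transformed).
    """
    blocks = kspace if isinstance(kspace, list) else [kspace]
    C = blocks[0].shape[0]
    cov = np.zeros((C, C), dtype=np.complex128)
    total = 0
    for b in blocks:
        cov += b @ b.conj().T
        total += b.shape[1]
    if not np.any(cov):
        raise ValueError("zero k-space data; coil covariance undefined")
    cov /= total
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    energies = evals[order]
    mixing = evecs[:, order]
    reordered = [mixing.conj().T @ b for b in blocks]
    basis = CoilBasis(mixing=mixing, energies=np.maximum(energies, 0.0))
    return basis, (reordered if isinstance(kspace, list) else reordered[0])


def compress(reordered_kspace, maps: np.ndarray, c_prime: int):
    """Keep the top-``c_prime`` virtual coils of data and maps.

    ``maps`` must already be expressed in the same virtual-coil basis as the
    reordered k-space.
    """
    C = maps.shape[0]
    if not 1 <= c_prime <= C:
        raise ValueError(f"c_prime must be in [1, {C}]")
    if isinstance(reordered_kspace, list):
        data = [b[:c_prime] for b in reordered_kspace]
    else:
        data = reordered_kspace[:c_prime]
    return data, maps[:c_prime]


def _grid_lowres(kspace_blocks, coords_blocks, lowres_shape):
    """Density-compensated gridding of central k-space onto a low-res grid."""
    from .encoding import kspace_preconditioner

    C = kspace_blocks[0].shape[0]
    box = np.array(lowres_shape) / 2.0 - 0.5
    sel_k, sel_c = [], []
    for kb, cb in zip(kspace_blocks, coords_blocks):
        sel = np.all(np.abs(cb) < box[None, :], axis=1)
        if sel.any():
            sel_k.append(kb[:, sel])
            sel_c.append(cb[sel])
    if not sel_c:
        raise ValueError("no samples inside the low-resolution calibration box")
    kb = np.concatenate(sel_k, axis=1)
    cb = np.concatenate(sel_c, axis=0)
    dcf = kspace_preconditioner([cb], lowres_shape, method="dcf")[0]
    imgs = np.zeros((C, *lowres_shape), dtype=np.complex128)
    for c in range(C):
        imgs[c] = nufft_adjoint(kb[c] * dcf, cb, lowres_shape)
    return imgs


def estimate_maps(
    kspace_blocks,
    coords_blocks,
    grid_shape,
    calib_width: int = 24,
    kernel_size: int = 6,
    sv_threshold: float = 0.02,
    eig_threshold: float = 0.95,
    downscale: int = 2,
):
    """ESPIRiT-style eigenvector sensitivity maps from phase-combined data.

    The non-Cartesian measurements of all phases are gridded onto a
    ``downscale``-fold smaller Cartesian grid, a calibration Hankel matrix is
    built from the central k-space, and per-voxel eigendecomposition of the
    image-domain kernel Gram matrix yields the maps, which are then upscaled
    to the full grid.  Per-voxel root-sum-of-squares is <= 1 (unit on the
    supported region, zero where the leading eigenvalue falls below
    ``eig_threshold``); phase is referenced to coil 1.
    """
    grid_shape = tuple(grid_shape)
    d = len(grid_shape)
    low = tuple(max(8, n // downscale) for n in grid_shape)
    imgs = _grid_lowres(kspace_blocks, coords_blocks, low)
    C = imgs.shape[0]
    kspace_low = np.stack([_centered_fft(imgs[c]) for c in range(C)])

    cw = min(calib_width, *low)
    calib = np.stack([
        kspace_low[c][tuple(slice(n // 2 - cw // 2, n // 2 - cw // 2 + cw)
                            for n in low)]
        for c in range(C)
    ])
    if not np.any(calib):
        raise ValueError("empty calibration region near DC")

    k = min(kernel_size, cw)
    n_win = (cw - k + 1) ** d
    rows = np.empty((n_win, C * k**d), dtype=np.complex128)
    idx = 0
    for pos in np.ndindex(*([cw - k + 1] * d)):
        sl = tuple(slice(p, p + k) for p in pos)
        rows[idx] = calib[(slice(None),) + sl].ravel()
        idx += 1
    _, s, vh = np.linalg.svd(rows, full_matrices=False)
    keep = s > sv_threshold * s[0]
    kernels = vh[keep].conj().reshape(-1, C, *([k] * d))

    # image-domain kernels on the low-res grid
    n_k = kernels.shape[0]
    kern_img = np.zeros((n_k, C, *low), dtype=np.complex128)
    embed = tuple(slice(n // 2 - k // 2, n // 2 - k // 2 + k) for n in low)
    scale = np.sqrt(np.prod(low)) / np.sqrt(k**d)
    for q in range(n_k):
        for c in range(C):
            buf = np.zeros(low, dtype=np.complex128)
            buf[embed] = kernels[q, c][::-1, ::-1] if d == 2 else \
                kernels[q, c][::-1, ::-1, ::-1]
            kern_img[q, c] = np.conj(
                _centered_fft(buf.conj())
            ) / np.sqrt(np.prod(low)) * scale

    # per-voxel Gram eigendecomposition
    K = kern_img.reshape(n_k, C, -1).transpose(2, 0, 1)  # (J, n_k, C)
    G = np.einsum("jqc,jqe->jce", K.conj(), K)
    evals, evecs = np.linalg.eigh(G)
    lead = evals[:, -1].real
    vec = evecs[:, :, -1]
    # reference the phase to coil 1 and crop unsupported voxels
    phase0 = np.exp(-1j * np.angle(vec[:, 0]))
    vec = vec * phase0[:, None]
    support = lead > eig_threshold * np.median(lead[lead > 0.5 * lead.max()]) \
        if lead.max() > 0 else np.zeros_like(lead, dtype=bool)
    vec[~support] = 0.0
    maps_low = vec.T.reshape(C, *low)

    # upscale to the full grid
    factors = [n / l for n, l in zip(grid_shape, low)]
    maps = np.stack([
        _ndzoom(maps_low[c].real, factors, order=1)
        + 1j * _ndzoom(maps_low[c].imag, factors, order=1)
        for c in range(C)
    ])
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    nz = rss > 1.0
    maps[:, nz] /= rss[nz]
    return maps


def build_sketch_plan(
    C: int,
    C_S: int,
    n_outer: int,
    seed: int = 0,
    mode: str = "rademacher",
    identity: bool = False,
) -> SketchPlan:
    """Per-outer-iteration coil-combination matrices.

    Each sketch keeps virtual coil 1 verbatim (row 0 = e_1); the remaining
    ``C_S - 1`` rows combine coils 2..C with independent Rademacher +-1
    weights scaled by ``1/sqrt(C_S - 1)`` (``mode='rademacher'``), or select
    distinct random coils outright (``mode='select'``).  ``identity=True``
    returns identity sketches (requires C_S == C; the degenerate no-sketch
    case).
    """
    if C_S > C:
        raise ValueError(f"C_S = {C_S} exceeds available coils C = {C}")
    if identity:
        if C_S != C:
            raise ValueError("identity sketch requires C_S == C")
        return SketchPlan([np.eye(C, dtype=np.complex128)] * n_outer, (0,), seed)
    if C_S < 2:
        raise ValueError("C_S must be >= 2")
    sketches = []
    for t in range(n_outer):
        rng = np.random.default_rng(np.random.SeedSequence([seed, t]))
        q = np.zeros((C_S, C), dtype=np.complex128)
        q[0, 0] = 1.0
        if mode == "rademacher":
            s = 1.0 / np.sqrt(C_S - 1)
            q[1:, 1:] = s * rng.choice([-1.0, 1.0], size=(C_S - 1, C - 1))
        elif mode == "select":
            picks = rng.choice(np.arange(1, C), size=C_S - 1, replace=False)
            for i, p in enumerate(picks):
                q[1 + i, p] = 1.0
        else:
            raise ValueError(f"unknown sketch mode {mode!r}")
        sketches.append(q)
    return SketchPlan(sketches=sketches, kept_coils=(0,), seed=seed)


def apply_sketch(sketch: np.ndarray, arr):
    """Mix the coil axis (axis 0, or axis 0 of each list element) by a sketch."""
    if isinstance(arr, list):
        return [np.tensordot(sketch, a, axes=(1, 0)) for a in arr]
    return np.tensordot(sketch, arr, axes=(1, 0))
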