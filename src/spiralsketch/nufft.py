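"""Non-uniform FFT via Kaiser-Bessel gridding.

Implements type-2 (Cartesian image -> arbitrary k-space samples, ``nufft_forward``)
and type-1 (samples -> image, ``nufft_adjoint``) transforms on an oversampled
FFT grid with Kaiser-Bessel interpolation.  The pair is an *exact* adjoint pair
by construction (spreading is the transpose of interpolation and the centered
DFT is unitary up to a known scale); the approximation error relative to the
exact non-uniform DFT is controlled by the oversampling factor and kernel
width, set here for a relative accuracy better than 1e-6.

Conventions
-----------
* Coordinates are in grid units: axis ``d`` of a shape-``N_d`` image admits
  frequencies in ``[-N_d/2, N_d/2)``.
* The forward transform computes ``s(kappa) = sum_j x_j exp(-2i pi kappa.j / N)``
  with voxel index ``j`` centered (DC voxel at array index ``N//2``).
* The adjoint conjugate-transposes this (``+2i pi`` phase).
"""

from __future__ import annotations

import math

import numpy as np
from scipy.special import i0 as _bessel_i0

__all__ = ["nufft_forward", "nufft_adjoint", "check_coords"]

# Oversampling 2 with a width-8 Beatty-parametrized Kaiser-Bessel kernel gives
# worst-case aliasing error well below 1e-6 of the signal norm.
OVERSAMP = 2
KERNEL_WIDTH = 8


def _beta(width: int, oversamp: float) -> float:
    return math.pi * math.sqrt((width / oversamp) ** 2 * (oversamp - 0.5) ** 2 - 0.8)


def _kb_kernel(u: np.ndarray, width: int, beta: float) -> np.ndarray:
    """Kaiser-Bessel interpolation kernel sampled at offsets ``u`` (grid units)."""
    t = 1.0 - (2.0 * u / width) ** 2
    out = np.zeros_like(u, dtype=np.float64)
    inside = t > 0
    out[inside] = _bessel_i0(beta * np.sqrt(t[inside]))
    return out


def _deapod_1d(n: int, grid_n: int, width: int, beta: float) -> np.ndarray:
    """Continuous Fourier transform of the KB kernel at centered pixel positions.

    Dividing the image by this function ("deapodization") cancels the
    image-domain roll-off introduced by k-space interpolation.
    """
    j = np.arange(n) - n // 2
    arg = beta**2 - (math.pi * width * j / grid_n) ** 2
    out = np.empty(n, dtype=np.float64)
    pos = arg > 0
    sq = np.sqrt(np.abs(arg))
    # sinh branch inside the main lobe, sinc branch outside (never hit for
    # 2x oversampling, kept for completeness)
    out[pos] = np.sinh(sq[pos]) / sq[pos]
    out[~pos] = np.sinc(sq[~pos] / math.pi)
    return out * width


def check_coords(coords: np.ndarray, grid_shape: tuple[int, ...]) -> np.ndarray:
    """Validate sample coordinates against the Nyquist box of ``grid_shape``."""
    coords = np.asarray(coords, dtype=np.float64)
    if coords.ndim == 1:
        coords = coords[:, None]
    if coords.shape[1] != len(grid_shape):
        raise ValueError(
            f"coords are {coords.shape[1]}-D but grid is {len(grid_shape)}-D"
        )
    for d, n in enumerate(grid_shape):
        lo, hi = coords[:, d].min(initial=0), coords[:, d].max(initial=0)
        if lo < -n / 2 or hi >= n / 2:
            raise ValueError(
                f"coords axis {d} outside Nyquist box [-{n / 2}, {n / 2}): "
                f"range [{lo}, {hi}]"
            )
    return coords


def _interp_tables(coords: np.ndarray, grid_shape: tuple[int, ...]):
    """Per-axis integer footprints and KB weights for every sample."""
    width = KERNEL_WIDTH
    beta = _beta(width, OVERSAMP)
    idx_tables = []
    w_tables = []
    for d, n in enumerate(grid_shape):
        g = OVERSAMP * n
        u = OVERSAMP * coords[:, d]  # position on the oversampled centered grid
        start = np.floor(u).astype(np.int64) - width // 2 + 1
        offs = start[:, None] + np.arange(width)[None, :]
        w = _kb_kernel(u[:, None] - offs, width, beta)
        idx_tables.append((offs + g // 2) % g)  # centered -> array index, wrapped
        w_tables.append(w)
    return idx_tables, w_tables


def _centered_fft(x: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.fftn(np.fft.ifftshift(x)))


def _centered_fft_adjoint(X: np.ndarray) -> np.ndarray:
    return np.fft.fftshift(np.fft.ifftn(np.fft.ifftshift(X))) * X.size


def _pad_slices(grid_shape):
    return tuple(slice(n // 2, n // 2 + n) for n in grid_shape)


def nufft_forward(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    """Evaluate the non-uniform DFT of ``image`` at ``coords`` (type-2 NUFFT).

    Parameters
    ----------
    image : complex ndarray, shape ``grid_shape``
    coords : float ndarray, shape ``(K, d)``, in grid units within the
        Nyquist box ``[-N/2, N/2)`` per axis.

    Returns
    -------
    complex ndarray of shape ``(K,)``.
    """
    grid_shape = image.shape
    coords = check_coords(coords, grid_shape)
    width = KERNEL_WIDTH
    beta = _beta(width, OVERSAMP)

    deapod = np.ones((), dtype=np.float64)
    x = np.asarray(image, dtype=np.complex128)
    for d, n in enumerate(grid_shape):
        shape = [1] * len(grid_shape)
        shape[d] = n
        x = x / _deapod_1d(n, OVERSAMP * n, width, beta).reshape(shape)

    padded = np.zeros(tuple(OVERSAMP * n for n in grid_shape), dtype=np.complex128)
    padded[_pad_slices(grid_shape)] = x
    spectrum = _centered_fft(padded)

    idx_t, w_t = _interp_tables(coords, grid_shape)
    ndim = len(grid_shape)
    k = coords.shape[0]
    out = np.zeros(k, dtype=np.complex128)
    # accumulate over the separable kernel footprint (WIDTH**ndim taps)
    for taps in np.ndindex(*([KERNEL_WIDTH] * ndim)):
        w = w_t[0][:, taps[0]]
        sel = (idx_t[0][:, taps[0]],)
        for d in range(1, ndim):
            w = w * w_t[d][:, taps[d]]
            sel = sel + (idx_t[d][:, taps[d]],)
        out += w * spectrum[sel]
    return out


def nufft_adjoint(
    samples: np.ndarray, coords: np.ndarray, grid_shape: tuple[int, ...]
) -> np.ndarray:
    """Exact adjoint of :func:`nufft_forward` (type-1 NUFFT / gridding).

    Returns a complex image of shape ``grid_shape``.
    """
    grid_shape = tuple(int(n) for n in grid_shape)
    coords = check_coords(coords, grid_shape)
    samples = np.asarray(samples, dtype=np.complex128).ravel()
    if samples.shape[0] != coords.shape[0]:
        raise ValueError("samples and coords disagree on the number of points")
    width = KERNEL_WIDTH
    beta = _beta(width, OVERSAMP)

    os_shape = tuple(OVERSAMP * n for n in grid_shape)
    grid = np.zeros(os_shape, dtype=np.complex128)
    idx_t, w_t = _interp_tables(coords, grid_shape)
    ndim = len(grid_shape)
    flat = grid.ravel()
    strides = np.array(
        [int(np.prod(os_shape[d + 1 :], dtype=np.int64)) for d in range(ndim)]
    )
    for taps in np.ndindex(*([KERNEL_WIDTH] * ndim)):
        w = w_t[0][:, taps[0]]
        flat_idx = idx_t[0][:, taps[0]] * strides[0]
        for d in range(1, ndim):
            w = w * w_t[d][:, taps[d]]
            flat_idx = flat_idx + idx_t[d][:, taps[d]] * strides[d]
        np.add.at(flat, flat_idx, w * samples)
    grid = flat.reshape(os_shape)

    img = _centered_fft_adjoint(grid)[_pad_slices(grid_shape)]
    for d, n in enumerate(grid_shape):
        shape = [1] * ndim
        shape[d] = n
        img = img / _deapod_1d(n, OVERSAMP * n, width, beta).reshape(shape)
    return img
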