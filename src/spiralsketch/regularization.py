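"""Regularizers and their proximal operators.

Implements the three penalties used for respiratory-resolved reconstruction
-- spatio-temporal total variation lambda*||G x||_1, global low rank
lambda*||x||_* on the Casorati (phases x voxels) matrix, and
motion-compensated low rank lambda*||M x||_* -- together with the
forward-only proximal update for the motion-compensated case: for every
reference phase, all phases are registered *to* it, the aligned Casorati
matrix is singular-value soft-thresholded, and only the reference row is
kept.  No inverse deformation is ever applied, which keeps the update stable
under non-diffeomorphic motion fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .registration import MotionFieldSet, estimate_fields_to_reference, warp

__all__ = [
    "RegularizerSpec",
    "finite_diff",
    "finite_diff_adjoint",
    "prox_l1",
    "prox_nuclear",
    "moco_lr_prox",
    "regularizer_value",
    "estimate_moco_fields",
]


@dataclass
class RegularizerSpec:
    kind: str = "none"  # none | tv | lr | mocolr
    lam: float = 0.1
    circular_phase: bool = True
    moco_refresh: int = 0  # 0 = estimate fields once and cache

    def __post_init__(self):
        if self.kind not in ("none", "tv", "lr", "mocolr"):
            raise ValueError(f"unknown regularizer kind {self.kind!r}")
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")


def finite_diff(x: np.ndarray, circular_phase: bool = True) -> np.ndarray:
    """First differences along each spatial axis and the phase axis.

    Input is an (R, *spatial) stack; output stacks one difference volume per
    axis along a new leading axis.  Spatial axes use forward differences
    with a zero row beyond the last sample; the phase axis is circular by
    default (breathing is cyclic).
    """
    diffs = []
    for ax in range(x.ndim):
        if ax == 0 and circular_phase:
            diffs.append(np.roll(x, -1, axis=ax) - x)
        else:
            g = np.zeros_like(x)
            head = tuple(slice(None, -1) if a == ax else slice(None)
                         for a in range(x.ndim))
            tail = tuple(slice(1, None) if a == ax else slice(None)
                         for a in range(x.ndim))
            g[head] = x[tail] - x[head]
            diffs.append(g)
    return np.stack(diffs)


def finite_diff_adjoint(d: np.ndarray, circular_phase: bool = True) -> np.ndarray:
    """Exact adjoint of :func:`finite_diff` (negative divergence)."""
    ndim = d.ndim - 1
    out = np.zeros(d.shape[1:], dtype=d.dtype)
    for ax in range(ndim):
        g = d[ax]
        if ax == 0 and circular_phase:
            out += np.roll(g, 1, axis=ax) - g
        else:
            # the forward never writes the last slice along ax; its adjoint
            # must ignore whatever the dual variable carries there
            g = g.copy()
            last = tuple(slice(-1, None) if a == ax else slice(None)
                         for a in range(ndim))
            g[last] = 0
            head = tuple(slice(None, -1) if a == ax else slice(None)
                         for a in range(ndim))
            tail = tuple(slice(1, None) if a == ax else slice(None)
                         for a in range(ndim))
            shifted = np.zeros_like(g)
            shifted[tail] = g[head]
            out += shifted - g
    return out


def prox_l1(z: np.ndarray, tau: float) -> np.ndarray:
    """Elementwise complex soft-threshold ``z * max(1 - tau/|z|, 0)``."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return z.copy() if isinstance(z, np.ndarray) else z
    mag = np.abs(z)
    scale = np.maximum(1.0 - tau / np.maximum(mag, 1e-300), 0.0)
    return z * scale


def prox_nuclear(Y: np.ndarray, tau: float) -> np.ndarray:
    """Singular-value soft-thresholding: the exact proximal map of tau*||.||_*."""
    if tau < 0:
        raise ValueError("tau must be >= 0")
    if tau == 0:
        return Y.copy()
    U, s, Vh = np.linalg.svd(Y, full_matrices=False)
    s = np.maximum(s - tau, 0.0)
    return (U * s) @ Vh


def nuclear_norm(Y: np.ndarray) -> float:
    return float(np.linalg.svd(Y, compute_uv=False).sum())


def estimate_moco_fields(x: np.ndarray, **flow_kwargs) -> list:
    """All-references motion-field cache for the forward-only prox.

    Returns a list of :class:`MotionFieldSet`, entry ``ref`` holding the
    fields that register every phase of ``x`` onto phase ``ref``.
    """
    R = x.shape[0]
    return [estimate_fields_to_reference(x, ref, **flow_kwargs)
            for ref in range(R)]


def moco_lr_prox(x: np.ndarray, tau: float, fields_cache=None) -> np.ndarray:
    """Forward-only motion-compensated low-rank proximal update.

    For each reference phase: warp all phases onto it, soft-threshold the
    singular values of the aligned (R x J) Casorati matrix, and keep only the
    reference row of the result.  With identity motion (a static stack) this
    collapses exactly to :func:`prox_nuclear`.
    """
    R = x.shape[0]
    if R == 1:
        return prox_nuclear(x.reshape(1, -1), tau).reshape(x.shape)
    if fields_cache is None:
        fields_cache = estimate_moco_fields(x)
    out = np.empty_like(x)
    for ref in range(R):
        fset: MotionFieldSet = fields_cache[ref]
        if not np.isfinite(fset.fields).all():
            raise ValueError(
                f"non-finite motion field registering phases onto phase {ref}"
            )
        aligned = np.empty_like(x)
        for p in range(R):
            if p == ref:
                aligned[p] = x[p]
            else:
                aligned[p] = warp(x[p], fset.fields[p])
        Y = aligned.reshape(R, -1)
        Z = prox_nuclear(Y, tau)
        out[ref] = Z[ref].reshape(x.shape[1:])
    return out


def regularizer_value(x: np.ndarray, spec: RegularizerSpec,
                      fields_cache=None) -> float:
    """Penalty value lambda*||Gx||_1, lambda*||x||_* or lambda*||Mx||_*.

    For the motion-compensated penalty the stack is forward-aligned to phase
    0 (one fixed reference) purely as a reporting convention; the per-
    reference sweep of the prox does not define a single penalty.
    """
    if spec.kind == "none" or spec.lam == 0:
        return 0.0
    if spec.kind == "tv":
        return spec.lam * float(
            np.abs(finite_diff(x, spec.circular_phase)).sum()
        )
    if spec.kind == "lr":
        return spec.lam * nuclear_norm(x.reshape(x.shape[0], -1))
    if spec.kind == "mocolr":
        R = x.shape[0]
        if R == 1:
            return spec.lam * nuclear_norm(x.reshape(1, -1))
        if fields_cache is not None:
            fset = fields_cache[0]
        else:
            fset = estimate_fields_to_reference(x, 0)
        aligned = np.stack([
            x[p] if p == 0 else warp(x[p], fset.fields[p]) for p in range(R)
        ])
        return spec.lam * nuclear_norm(aligned.reshape(R, -1))
    raise ValueError(f"unknown regularizer kind {spec.kind!r}")
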