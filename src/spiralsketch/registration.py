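"""Motion estimation and warping: the motion operator M.

``register`` estimates a dense displacement field between two volumes with a
multi-scale (coarse-to-fine pyramid) TV-L1 optical flow on magnitude images;
``warp`` resamples a volume at ``x + u(x)`` with linear interpolation (edge
values outside the domain), so it is an exact linear operator in the image
for a fixed field.  Fields are non-diffeomorphic by design and no inverse
field is ever computed; the forward-only low-rank proximal update is built
entirely from these forward warps.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import map_coordinates
from skimage.registration import optical_flow_tvl1

__all__ = ["MotionFieldSet", "register", "warp", "estimate_fields_to_reference"]


class MotionFieldSet:
    """Per-phase displacement fields mapping each phase onto a reference phase.

    ``fields[p]`` has shape ``(d, *grid)``; the reference phase's own field
    is identically zero.
    """

    def __init__(self, fields: np.ndarray, reference: int):
        fields = np.asarray(fields)
        if not np.isfinite(fields).all():
            raise ValueError("motion fields contain non-finite values")
        self.fields = fields
        self.reference = int(reference)

    @property
    def n_phases(self) -> int:
        return self.fields.shape[0]


def register(moving: np.ndarray, fixed: np.ndarray,
             attachment: float = 10.0, tightness: float = 0.3,
             num_warp: int = 5, num_iter: int = 10,
             prefilter: bool = True) -> np.ndarray:
    """Displacement field ``u`` with ``warp(moving, u) ~= fixed``.

    Complex inputs are registered on their magnitudes.  The underlying flow
    estimator is a coarse-to-fine TV-L1 solver (intensity data term with a
    total-variation smoothness penalty); it is deterministic given its
    inputs.
    """
    if moving.shape != fixed.shape:
        raise ValueError(
            f"shape mismatch: moving {moving.shape} vs fixed {fixed.shape}"
        )
    mov = np.abs(moving).astype(np.float64)
    fix = np.abs(fixed).astype(np.float64)
    scale = max(fix.max(), mov.max())
    if scale > 0:
        mov = mov / scale
        fix = fix / scale
    flow = optical_flow_tvl1(
        fix, mov, attachment=attachment, tightness=tightness,
        num_warp=num_warp, num_iter=num_iter, prefilter=prefilter,
    )
    return np.ascontiguousarray(flow)


def warp(volume: np.ndarray, field: np.ndarray) -> np.ndarray:
    """Resample ``volume`` at ``x + field(x)`` (linear interpolation).

    Out-of-domain samples take edge values.  Complex volumes are warped by
    warping real and imaginary parts with the same field.
    """
    d = volume.ndim
    if field.shape[0] != d or field.shape[1:] != volume.shape:
        raise ValueError(
            f"field shape {field.shape} inconsistent with volume {volume.shape}"
        )
    grid = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in volume.shape],
                       indexing="ij")
    pos = [g + f for g, f in zip(grid, field)]
    if np.iscomplexobj(volume):
        re = map_coordinates(volume.real, pos, order=1, mode="nearest")
        im = map_coordinates(volume.imag, pos, order=1, mode="nearest")
        return re + 1j * im
    return map_coordinates(volume, pos, order=1, mode="nearest")


def estimate_fields_to_reference(stack: np.ndarray, reference: int,
                                 **flow_kwargs) -> MotionFieldSet:
    """Register every phase of a stack to one reference phase."""
    R = stack.shape[0]
    d = stack.ndim - 1
    fields = np.zeros((R, d) + stack.shape[1:])
    for p in range(R):
        if p == reference:
            continue
        fields[p] = register(stack[p], stack[reference], **flow_kwargs)
    return MotionFieldSet(fields, reference)
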