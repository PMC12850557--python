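"""Respiratory self-navigation: Hilbert-phase estimation and k-space binning.

The navigator trace is converted to an instantaneous respiratory phase via
the analytic signal (Hilbert transform); each readout inherits the phase
interpolated to its start time and is sorted into one of R equal-width phase
bins over ``[-pi, pi)``.  Whole readouts are assigned to a single bin (the
navigator cadence is much longer than one readout).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .phantom import RawDataset

__all__ = ["BinnedKSpace", "hilbert_phase", "assign_bins", "bin_dataset"]

log = logging.getLogger(__name__)


@dataclass
class BinnedKSpace:
    """Per-respiratory-phase non-Cartesian measurements."""

    kspace: list  # R arrays, each (C, K_r) complex
    coords: list  # R arrays, each (K_r, d)
    bin_of_readout: np.ndarray  # (n_readouts,) int
    R: int
    sample_bins: np.ndarray | None = None  # (K_total,) bin per sample

    @property
    def counts(self) -> np.ndarray:
        return np.array([c.shape[0] for c in self.coords])


def hilbert_phase(navigator: np.ndarray, invert: bool = False) -> np.ndarray:
    """Instantaneous phase in ``[-pi, pi)`` of the mean-removed navigator.

    ``invert`` flips the sign convention (inhalation direction) of the trace
    before the transform.
    """
    nav = np.asarray(navigator, dtype=np.float64)
    if nav.ndim != 1 or nav.size < 8:
        raise ValueError("navigator must be a 1-D series of length >= 8")
    nav = nav - nav.mean()
    if np.allclose(nav, 0.0):
        raise ValueError("navigator is constant; respiratory phase undefined")
    if invert:
        nav = -nav
    phase = np.angle(hilbert(nav))
    # fold the +pi endpoint back into [-pi, pi)
    phase[phase >= np.pi] -= 2.0 * np.pi
    return phase


def assign_bins(
    phases: np.ndarray,
    R: int,
    readout_times: np.ndarray,
    sample_times: np.ndarray,
) -> np.ndarray:
    """Assign each readout to a phase bin.

    The navigator phase series (at ``sample_times``) is unwrapped, linearly
    interpolated to each readout's start time, re-wrapped, and quantized into
    R equal-width bins over ``[-pi, pi)``.  Readout times outside the
    navigator span are clamped to the nearest navigator sample (logged).
    """
    if R < 1:
        raise ValueError("R must be >= 1")
    phases = np.asarray(phases, dtype=np.float64)
    readout_times = np.asarray(readout_times, dtype=np.float64)
    sample_times = np.asarray(sample_times, dtype=np.float64)
    outside = (readout_times < sample_times[0]) | (readout_times > sample_times[-1])
    if outside.any():
        log.warning(
            "%d readout(s) outside the navigator span; using nearest-neighbor "
            "extrapolation", int(outside.sum()),
        )
    unwrapped = np.unwrap(phases)
    interp = np.interp(readout_times, sample_times, unwrapped)
    wrapped = np.mod(interp + np.pi, 2.0 * np.pi) - np.pi
    bins = np.floor((wrapped + np.pi) / (2.0 * np.pi / R)).astype(np.int64)
    return np.clip(bins, 0, R - 1)


def bin_dataset(raw: RawDataset, bin_of_readout: np.ndarray, R: int) -> BinnedKSpace:
    """Partition samples and coordinates into R respiratory states.

    Raises if any bin is empty (a reconstruction with an empty phase is
    undefined).  Emits the bin-occupancy table to the log.
    """
    bin_of_readout = np.asarray(bin_of_readout)
    readout_ids = np.unique(raw.readout_id)
    if bin_of_readout.shape[0] != readout_ids.shape[0]:
        raise ValueError(
            "bin assignment does not cover all readouts: "
            f"{bin_of_readout.shape[0]} assignments for {readout_ids.shape[0]} readouts"
        )
    lookup = np.full(readout_ids.max() + 1, -1, dtype=np.int64)
    lookup[readout_ids] = bin_of_readout
    sample_bins = lookup[raw.readout_id]

    kspace, coords = [], []
    for r in range(R):
        sel = sample_bins == r
        if not sel.any():
            raise ValueError(f"respiratory bin {r} is empty")
        kspace.append(raw.kspace[:, sel].copy())
        coords.append(raw.coords[sel].copy())
    counts = [c.shape[0] for c in coords]
    log.info("bin occupancy (samples per state): %s", counts)
    return BinnedKSpace(
        kspace=kspace, coords=coords,
        bin_of_readout=bin_of_readout.copy(), R=R, sample_bins=sample_bins,
    )
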