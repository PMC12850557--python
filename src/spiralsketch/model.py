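"""Model/results front end for the reconstruction pipeline.

:class:`Reconstruction` bundles prepared data (binned k-space, sensitivity
maps, preconditioner, normalization) with a :class:`~.io.ReconConfig`;
``fit()`` runs the configured solver (conventional or coil-sketched) and
returns a :class:`ReconResults` carrying the image stack, the objective
trace and a ``summary()`` table.

Typical use::

    model = Reconstruction.from_raw(raw, config)   # bins, maps, precond
    res = model.fit()
    print(res.summary())
    res.export("recon.nii.gz")
"""

from __future__ import annotations

import numpy as np

from . import io as _io
from .binning import BinnedKSpace, assign_bins, bin_dataset, hilbert_phase
from .coils import estimate_maps, svd_reorder
from .encoding import (
    EncodingSystem,
    crop_center,
    kspace_preconditioner,
    normalize_system,
    pad_center,
    pad_grid_shape,
)
from .phantom import RawDataset
from .regularization import RegularizerSpec
from .solvers import conventional_reconstruct, sketched_reconstruct

__all__ = ["Reconstruction", "ReconResults"]


class Reconstruction:
    """A respiratory-resolved reconstruction problem ready to solve.

    Parameters
    ----------
    system : EncodingSystem
        Normalized encoding system (virtual-coil maps, per-phase coordinates,
        preconditioner weights) on the (possibly padded) reconstruction grid.
    ys : list of ndarray
        Per-phase preconditioned data blocks, virtual-coil ordered.
    config : ReconConfig
    nominal_grid : tuple
        Grid of the nominal FOV; results are cropped back to it.
    """

    def __init__(self, system: EncodingSystem, ys, config,
                 nominal_grid=None, binned: BinnedKSpace | None = None):
        self.system = system
        self.ys = ys
        self.config = config
        self.nominal_grid = tuple(nominal_grid or system.grid_shape)
        self.binned = binned
        self.max_eig_ = None

    # -- construction ------------------------------------------------------

    @classmethod
    def from_raw(cls, raw: RawDataset, config, maps: np.ndarray | None = None,
                 invert_navigator: bool = False) -> "Reconstruction":
        """Prepare a model from an unbinned acquisition.

        Runs the standard pipeline: Hilbert-phase binning into
        ``config.n_bins`` states, SVD coil-energy reordering, sensitivity-map
        estimation (unless true maps are supplied), k-space preconditioning,
        and power-method normalization, all on the ``config.pad_factor``-
        enlarged reconstruction matrix.
        """
        R = config.n_bins
        grid = tuple(raw.meta.get("grid_shape"))
        phases = hilbert_phase(raw.navigator, invert=invert_navigator)
        first = np.unique(raw.readout_id, return_index=True)[1]
        bins = assign_bins(phases, R, raw.sample_time[first],
                           raw.navigator_time)
        binned = bin_dataset(raw, bins, R)

        padded = pad_grid_shape(grid, config.pad_factor)
        scale = np.array([p / g for p, g in zip(padded, grid)])
        coords = [c * scale[None, :] for c in binned.coords]

        basis, reordered = svd_reorder(binned.kspace)
        if maps is not None:
            vmaps = np.tensordot(basis.mixing.conj().T, maps, axes=(1, 0))
            if tuple(maps.shape[1:]) != padded:
                vmaps = pad_center(vmaps, padded)
        else:
            vmaps = estimate_maps(reordered, coords, padded)

        method = getattr(config, "precond", "frobenius")
        weights = kspace_preconditioner(coords, padded, method=method)
        system = EncodingSystem(maps=vmaps, coords=coords, weights=weights,
                                grid_shape=padded)
        model = cls(system, None, config, nominal_grid=grid, binned=binned)
        model.max_eig_ = normalize_system(system, n_iter=30, seed=config.seed)
        model.ys = system.preconditioned_data(reordered)
        return model

    @classmethod
    def from_binned(cls, binned: BinnedKSpace, maps: np.ndarray, config,
                    grid_shape=None) -> "Reconstruction":
        """Prepare a model from already-binned k-space and given maps."""
        grid = tuple(grid_shape or maps.shape[1:])
        basis, reordered = svd_reorder(binned.kspace)
        vmaps = np.tensordot(basis.mixing.conj().T, maps, axes=(1, 0))
        method = getattr(config, "precond", "frobenius")
        weights = kspace_preconditioner(binned.coords, grid, method=method)
        system = EncodingSystem(maps=vmaps, coords=binned.coords,
                                weights=weights, grid_shape=grid)
        model = cls(system, None, config, nominal_grid=grid, binned=binned)
        model.max_eig_ = normalize_system(system, n_iter=30, seed=config.seed)
        model.ys = system.preconditioned_data(reordered)
        return model

    # -- fitting -----------------------------------------------------------

    def fit(self, fields_cache=None, track_objective: bool = True
            ) -> "ReconResults":
        """Run the configured reconstruction and return the results."""
        reg_kind = ("none" if self.config.regularizer == "cgsense"
                    else self.config.regularizer)
        reg = RegularizerSpec(kind=reg_kind, lam=self.config.lam)
        if self.config.sketch_coils and self.config.sketch_coils > 0:
            x, trace = sketched_reconstruct(
                self.ys, self.system, self.config, reg=reg,
                fields_cache=fields_cache, track_objective=track_objective,
            )
            mode = f"sketched (C_S={self.config.sketch_coils})"
        else:
            x, trace = conventional_reconstruct(
                self.ys, self.system, self.config, reg=reg,
                fields_cache=fields_cache, track_objective=track_objective,
            )
            mode = "conventional"
        return ReconResults(self, x, trace, mode)


class ReconResults:
    """Reconstructed image stack plus solver diagnostics."""

    def __init__(self, model: Reconstruction, x_padded: np.ndarray,
                 trace, mode: str):
        self.model = model
        self.images_padded = x_padded
        self.trace = trace
        self.mode = mode

    @property
    def images(self) -> np.ndarray:
        """(R, *nominal_grid) complex stack cropped to the nominal FOV."""
        return crop_center(self.images_padded, self.model.nominal_grid)

    @property
    def objective(self) -> float:
        return self.trace[-1][1] if self.trace else np.nan

    def nrmse(self, reference: np.ndarray, mask: np.ndarray | None = None
              ) -> float:
        from .evaluation import nrmse_masked
        return nrmse_masked(self.images, reference, mask)

    def export(self, path, voxel_size_mm: float = 1.0) -> None:
        _io.export_images(self.images, path, voxel_size_mm)

    def save_trace(self, path) -> None:
        import csv
        with open(path, "w", newline="") as f:
            w = csv.writer(f)
            w.writerow(["iteration", "objective", "elapsed_s"])
            w.writerows(self.trace)

    def summary(self) -> str:
        cfg = self.model.config
        R, *grid = self.images.shape
        lines = [
            "Respiratory-resolved reconstruction results",
            "=" * 47,
            f"mode:              {self.mode}",
            f"solver:            {cfg.solver}",
            f"regularizer:       {cfg.regularizer} (lambda={cfg.lam})",
            f"respiratory bins:  {R}",
            f"image grid:        {tuple(grid)} "
            f"(padded {self.images_padded.shape[1:]})",
            f"iterations:        {len(self.trace)} "
            f"({cfg.n_initial} initial + {cfg.n_inner} x {cfg.n_outer})"
            if cfg.sketch_coils else
            f"iterations:        {len(self.trace)}",
            f"final objective:   {self.objective:.6g}",
        ]
        if self.model.max_eig_ is not None:
            lines.append(
                f"normalization:     max eig {self.model.max_eig_:.4g} "
                "rescaled to 1"
            )
        return "\n".join(lines)

    def plot_convergence(self, ax=None, reference_objective=None):
        import matplotlib.pyplot as plt
        from .evaluation import convergence_curve
        if ax is None:
            _, ax = plt.subplots()
        its = [t[0] for t in self.trace]
        if reference_objective:
            ax.plot(its, convergence_curve(self.trace, reference_objective))
            ax.set_ylabel("objective / reference")
        else:
            ax.plot(its, [t[1] for t in self.trace])
            ax.set_ylabel("objective")
        ax.set_xlabel("iteration")
        return ax
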