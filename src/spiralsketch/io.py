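"""Raw-data container (HDF5), image export (NIfTI-1) and configuration.

HDF5 layout of the raw container::

    /kspace          (C, K_total) complex  multicoil samples
    /coords          (K_total, d) float    sample coordinates, grid units
    /navigator       (n_nav,)     float    SI navigator trace
    /navigator_time  (n_nav,)     float    navigator sample times, ms
    /readout_id      (K_total,)   int      interleaf index per sample
    /sample_time     (K_total,)   float    acquisition time per sample, ms
    /truth/bin_of_readout  (n_readouts,) int   optional generating phase
    /meta/*          attributes: grid_shape, n_coils, seed, noise_sigma, ...

Configuration files are flat YAML key-value mappings; unknown keys and
invalid values are rejected with the offending key named.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .phantom import RawDataset

__all__ = ["ReconConfig", "read_raw", "write_raw", "export_images",
           "load_config", "read_images"]

_REGULARIZERS = ("cgsense", "tv", "lr", "mocolr")
_SOLVERS = ("cg", "fista", "pdhg")


@dataclass
class ReconConfig:
    """Reconstruction settings with the pipeline's standard defaults.

    Defaults follow the standard operating point: regularization strength
    0.1, five initial coil-compressed iterations, five inner iterations per
    sketched sub-problem, six outer iterations (six sketch draws), four inner
    primal iterations for PDHG, and a 1.33x enlarged reconstruction matrix to
    prevent wrap-in from signal outside the nominal FOV.
    """

    regularizer: str = "mocolr"
    solver: str = "pdhg"
    lam: float = 0.1
    n_bins: int = 6
    sketch_coils: int = 0  # 0 = no sketching (conventional)
    n_initial: int = 5
    n_inner: int = 5
    n_outer: int = 6
    pdhg_inner: int = 4
    toeplitz: bool = False
    pad_factor: float = 1.33
    seed: int = 0
    precond: str = "frobenius"  # or "dcf"
    sketch_mode: str = "rademacher"  # or "select"

    def __post_init__(self):
        if self.regularizer not in _REGULARIZERS:
            raise ValueError(
                f"invalid value for 'regularizer': {self.regularizer!r} "
                f"(choose from {_REGULARIZERS})"
            )
        if self.solver not in _SOLVERS:
            raise ValueError(
                f"invalid value for 'solver': {self.solver!r} "
                f"(choose from {_SOLVERS})"
            )
        if self.lam < 0:
            raise ValueError("invalid value for 'lambda': must be >= 0")
        if self.pad_factor < 1:
            raise ValueError("invalid value for 'pad_factor': must be >= 1")
        for key in ("n_bins", "n_initial", "n_inner", "n_outer", "pdhg_inner"):
            if getattr(self, key) < 0:
                raise ValueError(f"invalid value for '{key}': must be >= 0")
        if self.n_bins < 1:
            raise ValueError("invalid value for 'n_bins': must be >= 1")
        if self.sketch_coils < 0:
            raise ValueError("invalid value for 'sketch_coils': must be >= 0")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["lambda"] = d.pop("lam")
        return d


_CONFIG_KEYS = {
    "regularizer", "solver", "lambda", "n_bins", "sketch_coils", "n_initial",
    "n_inner", "n_outer", "pdhg_inner", "toeplitz", "pad_factor", "seed",
    "precond", "sketch_mode",
}


def load_config(path) -> ReconConfig:
    """Parse a YAML key-value config, applying defaults for absent keys."""
    text = Path(path).read_text()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ValueError("config must be a flat key-value mapping")
    unknown = set(data) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    if "lambda" in data:
        data["lam"] = data.pop("lambda")
    try:
        return ReconConfig(**data)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ValueError(str(exc)) from exc


def write_raw(dataset: RawDataset, path) -> None:
    """Write a :class:`RawDataset` to the documented HDF5 container."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps containers byte-reproducible under a seed
        kw = dict(track_times=False)
        f.create_dataset("kspace", data=dataset.kspace, **kw)
        f.create_dataset("coords", data=dataset.coords, **kw)
        f.create_dataset("navigator", data=dataset.navigator, **kw)
        f.create_dataset("navigator_time", data=dataset.navigator_time, **kw)
        f.create_dataset("readout_id", data=dataset.readout_id, **kw)
        f.create_dataset("sample_time", data=dataset.sample_time, **kw)
        if dataset.true_bins is not None:
            f.create_dataset("truth/bin_of_readout", data=dataset.true_bins,
                             **kw)
        meta = f.create_group("meta")
        meta.attrs["noise_sigma"] = dataset.noise_sigma
        for k, v in dataset.meta.items():
            meta.attrs[k] = v


def read_raw(path) -> RawDataset:
    """Read the HDF5 raw container back, verifying required datasets."""
    required = ["kspace", "coords", "navigator", "navigator_time",
                "readout_id", "sample_time"]
    with h5py.File(path, "r") as f:
        for name in required:
            if name not in f:
                raise KeyError(f"raw container is missing dataset '/{name}'")
        kspace = f["kspace"][:]
        coords = f["coords"][:]
        if kspace.shape[1] != coords.shape[0]:
            raise ValueError(
                f"/kspace ({kspace.shape}) and /coords ({coords.shape}) "
                "disagree on the number of samples"
            )
        true_bins = f["truth/bin_of_readout"][:] if "truth" in f else None
        meta = dict(f["meta"].attrs) if "meta" in f else {}
        noise_sigma = float(meta.pop("noise_sigma", 0.0))
        if "grid_shape" in meta:
            meta["grid_shape"] = tuple(int(n) for n in meta["grid_shape"])
        for key in ("n_coils", "seed", "n_phases"):
            if key in meta:
                meta[key] = int(meta[key])
        return RawDataset(
            kspace=kspace,
            coords=coords,
            navigator=f["navigator"][:],
            navigator_time=f["navigator_time"][:],
            readout_id=f["readout_id"][:],
            sample_time=f["sample_time"][:],
            noise_sigma=noise_sigma,
            meta=meta,
            true_bins=true_bins,
        )


def export_images(images: np.ndarray, path, voxel_size_mm: float = 1.0) -> None:
    """Write an (R, *spatial) complex stack as a 4-D magnitude NIfTI.

    The output is ordered (x, y, z, phase); 2-D stacks get a singleton third
    dimension.  Non-finite voxels are rejected.
    """
    images = np.asarray(images)
    if not np.isfinite(images).all():
        raise ValueError("images contain non-finite voxels")
    mag = np.abs(images)
    mag = np.moveaxis(mag, 0, -1)  # phase last
    if mag.ndim == 3:  # (x, y, phase) -> (x, y, 1, phase)
        mag = mag[:, :, None, :]
    affine = np.diag([voxel_size_mm] * 3 + [1.0])
    nib.save(nib.Nifti1Image(mag.astype(np.float32), affine), str(path))


def read_images(path) -> np.ndarray:
    """Load a NIfTI written by :func:`export_images` back to (R, *spatial)."""
    vol = np.asanyarray(nib.load(str(path)).dataobj)
    return np.moveaxis(vol, -1, 0)
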