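"""Metrics and the experiment harness.

Provides masked NRMSE, normalized convergence curves, noise pre-whitening,
pseudo-replica SNR mapping, and desk-scale experiment scenarios comparing
conventional, coil-compressed and coil-sketched reconstructions on the
seeded synthetic fixture.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import io as _io
from .binning import assign_bins, bin_dataset, hilbert_phase
from .coils import compress, svd_reorder
from .encoding import EncodingSystem, kspace_preconditioner, normalize_system
from .phantom import (
    PhantomSpec,
    RawDataset,
    make_coil_maps,
    make_dynamic_phantom,
    make_stack_of_spirals,
    simulate_acquisition,
)
from .regularization import RegularizerSpec
from .solvers import conventional_reconstruct, sketched_reconstruct

__all__ = [
    "ReplicaSet",
    "nrmse_masked",
    "convergence_curve",
    "prewhiten",
    "pseudo_replica_snr",
    "run_experiment",
    "build_fixture",
]


@dataclass
class ReplicaSet:
    images: list  # magnitude stacks, one per replica
    n_replicas: int
    seed: int


def nrmse_masked(test: np.ndarray, reference: np.ndarray,
                 mask: np.ndarray | None = None) -> float:
    """||(|test| - |ref|) . mask||_2 / |||ref| . mask||_2 on magnitude images."""
    test = np.abs(np.asarray(test))
    reference = np.abs(np.asarray(reference))
    if test.shape != reference.shape:
        raise ValueError(
            f"shape mismatch: test {test.shape} vs reference {reference.shape}"
        )
    if mask is None:
        mask = np.ones(reference.shape, dtype=bool)
    if not mask.any():
        raise ValueError("mask is empty")
    denom = np.linalg.norm(reference[mask])
    if denom == 0:
        raise ValueError("reference has zero energy inside the mask")
    return float(np.linalg.norm(test[mask] - reference[mask]) / denom)


def convergence_curve(trace, reference_objective: float) -> np.ndarray:
    """Objective ratios obj(iter) / obj(reference) for a solver trace."""
    if reference_objective <= 0:
        raise ValueError("reference objective must be > 0")
    objs = np.array([t[1] for t in trace], dtype=np.float64)
    return objs / reference_objective


def prewhiten(raw: RawDataset, noise_cov=None, sigma: float | None = None
              ) -> RawDataset:
    """Transform coil data so the noise is unit-variance and uncorrelated.

    Either a (C, C) noise covariance or a scalar per-channel sigma must be
    given; whitening is by the inverse Cholesky factor (or 1/sigma).
    """
    if noise_cov is None:
        if sigma is None:
            sigma = raw.noise_sigma
        if sigma <= 0:
            raise ValueError("need a positive noise sigma or a covariance")
        white = raw.kspace / sigma
    else:
        noise_cov = np.asarray(noise_cov)
        try:
            L = np.linalg.cholesky(noise_cov)
        except np.linalg.LinAlgError as exc:
            raise ValueError("noise covariance is singular or not PSD") from exc
        white = np.linalg.solve(L, raw.kspace)
    out = RawDataset(
        kspace=white, coords=raw.coords, navigator=raw.navigator,
        navigator_time=raw.navigator_time, readout_id=raw.readout_id,
        sample_time=raw.sample_time, noise_sigma=1.0, meta=dict(raw.meta),
        true_bins=raw.true_bins,
    )
    return out


def pseudo_replica_snr(raw: RawDataset, recon_closure, n_replicas: int = 30,
                       seed: int = 0) -> tuple[np.ndarray, ReplicaSet]:
    """Pseudo-replica SNR map: voxelwise mean/SD over noisy re-reconstructions.

    ``raw`` should already be pre-whitened (unit noise SD); each replica adds
    fresh unit-SD complex Gaussian noise and reconstructs via
    ``recon_closure(raw_replica)``, which must return an image stack.  The
    SNR map is computed on magnitudes along the replica axis.
    """
    if n_replicas < 2:
        raise ValueError("n_replicas must be >= 2")
    rng = np.random.default_rng(seed)
    mags = []
    for _ in range(n_replicas):
        noise = rng.standard_normal(raw.kspace.shape) \
            + 1j * rng.standard_normal(raw.kspace.shape)
        replica = RawDataset(
            kspace=raw.kspace + noise, coords=raw.coords,
            navigator=raw.navigator, navigator_time=raw.navigator_time,
            readout_id=raw.readout_id, sample_time=raw.sample_time,
            noise_sigma=raw.noise_sigma, meta=dict(raw.meta),
            true_bins=raw.true_bins,
        )
        mags.append(np.abs(recon_closure(replica)))
    stack = np.stack(mags)
    sd = stack.std(axis=0, ddof=1)
    snr = stack.mean(axis=0) / np.maximum(sd, 1e-12)
    return snr, ReplicaSet(images=mags, n_replicas=n_replicas, seed=seed)


# ---------------------------------------------------------------------------
# fixture + experiment harness


@dataclass
class Fixture:
    phantom: object
    maps: np.ndarray
    raw: RawDataset
    binned: object
    system: EncodingSystem
    ys: list
    basis: object
    noise_sd: float


def build_fixture(grid: tuple = (32, 32), n_coils: int = 6, n_phases: int = 3,
                  n_readouts: int = 480, n_points: int = 48,
                  noise_sd: float = 0.01, period_ms: float = 2000.0,
                  seed: int = 0, precond: str = "frobenius") -> Fixture:
    """Seeded desk-scale test instance with the full preparation pipeline:
    simulate, bin, SVD coil-reorder, precondition, normalize.

    The defaults span two breathing cycles of golden-angle spiral readouts
    at the standard TR so every respiratory state is visited repeatedly.
    """
    spec = PhantomSpec(grid_shape=grid, n_phases=n_phases,
                       diaphragm_amplitude=max(2.0, 0.1 * grid[0]),
                       seed=seed)
    ph = make_dynamic_phantom(spec)
    maps = make_coil_maps(n_coils, grid, seed=seed + 1)
    traj = make_stack_of_spirals(n_interleaves=n_readouts,
                                 n_kz=1 if len(grid) == 2 else grid[2],
                                 grid_shape=grid, n_points=n_points)
    raw = simulate_acquisition(ph, maps, traj, noise_sd=noise_sd,
                               seed=seed + 2, period_ms=period_ms)
    phases = hilbert_phase(raw.navigator)
    first = np.unique(raw.readout_id, return_index=True)[1]
    bins = assign_bins(phases, n_phases, raw.sample_time[first],
                       raw.navigator_time)
    binned = bin_dataset(raw, bins, n_phases)
    basis, reordered = svd_reorder(binned.kspace)
    vmaps = np.tensordot(basis.mixing.conj().T, maps, axes=(1, 0))
    weights = kspace_preconditioner(binned.coords, grid, method=precond)
    system = EncodingSystem(maps=vmaps, coords=binned.coords,
                            weights=weights, grid_shape=grid)
    normalize_system(system, n_iter=150, seed=seed + 3)
    ys = system.preconditioned_data(reordered)
    return Fixture(phantom=ph, maps=maps, raw=raw, binned=binned,
                   system=system, ys=ys, basis=basis, noise_sd=noise_sd)


def _write_table(path: Path, rows: list, header: list):
    with open(path, "w", newline="") as f:
        w = csv.writer(f)
        w.writerow(header)
        w.writerows(rows)


def run_experiment(name: str, config, outdir) -> dict:
    """Run a named desk-scale scenario and write metric tables/curves/images.

    Scenarios: ``regularizer_gallery``, ``compression_vs_sketching``,
    ``convergence``, ``toeplitz_accuracy``, ``snr``.
    Returns the metric dictionary that was also written to disk.
    """
    known = ("regularizer_gallery", "compression_vs_sketching",
             "convergence", "toeplitz_accuracy", "snr")
    if name not in known:
        raise ValueError(f"unknown experiment {name!r} (choose from {known})")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fx = build_fixture(seed=config.seed)
    system, ys = fx.system, fx.ys
    C = system.n_coils
    report: dict = {"experiment": name}

    if name == "regularizer_gallery":
        rows = []
        for kind in ("cgsense", "tv", "lr", "mocolr"):
            cfg = _clone_config(config, regularizer=kind,
                                solver="cg" if kind == "cgsense" else "pdhg",
                                sketch_coils=min(3, C))
            x, trace = sketched_reconstruct(ys, system, cfg)
            _io.export_images(x, outdir / f"recon_{kind}.nii.gz")
            rows.append([kind, len(trace), trace[-1][1] if trace else np.nan])
            report[f"final_objective_{kind}"] = trace[-1][1]
        _write_table(outdir / "gallery.csv", rows,
                     ["regularizer", "iterations", "final_objective"])

    elif name == "compression_vs_sketching":
        ref_cfg = _clone_config(config, sketch_coils=0, regularizer="lr",
                                solver="fista")
        x_ref, _ = conventional_reconstruct(ys, system, ref_cfg,
                                            track_objective=False)
        rows = []
        for n in range(min(3, C), C + 1):
            cfg = _clone_config(config, sketch_coils=n, regularizer="lr",
                                solver="fista")
            x_sk, _ = sketched_reconstruct(ys, system, cfg,
                                           track_objective=False)
            data_c, maps_c = compress(ys, system.maps, n)
            sys_c = system.with_maps(maps_c)
            x_cp, _ = conventional_reconstruct(data_c, sys_c, ref_cfg,
                                               track_objective=False)
            e_sk = nrmse_masked(x_sk, x_ref)
            e_cp = nrmse_masked(x_cp, x_ref)
            rows.append([n, e_sk, e_cp])
            report[f"nrmse_sketch_{n}"] = e_sk
            report[f"nrmse_compress_{n}"] = e_cp
        _write_table(outdir / "compression_vs_sketching.csv", rows,
                     ["n_coils", "nrmse_sketched", "nrmse_compressed"])

    elif name == "convergence":
        # long reference run, then normalized curves for each arm
        total = config.n_initial + config.n_inner * config.n_outer
        ref_cfg = _clone_config(config, regularizer="lr", solver="fista",
                                sketch_coils=0)
        n_ref = max(200, total)
        _, ref_trace = conventional_reconstruct(ys, system, ref_cfg,
                                                n_iter=n_ref)
        ref_obj = ref_trace[-1][1]
        arms = {
            "conventional": lambda: conventional_reconstruct(
                ys, system, ref_cfg, n_iter=total),
            "compressed": lambda: conventional_reconstruct(
                *_compressed_args(ys, system, min(3, C)), ref_cfg,
                n_iter=total),
            "sketched": lambda: sketched_reconstruct(
                ys, system, _clone_config(config, sketch_coils=min(3, C),
                                          regularizer="lr", solver="fista")),
        }
        rows = []
        for arm, runner in arms.items():
            _, trace = runner()
            curve = convergence_curve(trace, ref_obj)
            rows.extend([[arm, i + 1, c] for i, c in enumerate(curve)])
            report[f"final_ratio_{arm}"] = float(curve[-1])
        report["reference_iterations"] = n_ref
        _write_table(outdir / "convergence.csv", rows,
                     ["arm", "iteration", "objective_ratio"])

    elif name == "toeplitz_accuracy":
        for sketch in (0, min(3, C)):
            xs = {}
            for toep in (False, True):
                cfg = _clone_config(config, sketch_coils=sketch,
                                    toeplitz=toep, regularizer="lr",
                                    solver="fista")
                if sketch == 0:
                    x, _ = conventional_reconstruct(ys, system, cfg,
                                                    track_objective=False)
                else:
                    x, _ = sketched_reconstruct(ys, system, cfg,
                                                track_objective=False)
                xs[toep] = x
            key = "conventional" if sketch == 0 else "sketched"
            report[f"toeplitz_nrmse_{key}"] = nrmse_masked(xs[True], xs[False])
        _write_table(outdir / "toeplitz.csv",
                     [[k, v] for k, v in report.items() if k != "experiment"],
                     ["arm", "nrmse"])

    elif name == "snr":
        report.update(_snr_experiment(fx, config, outdir))

    else:
        raise ValueError(f"unknown experiment {name!r}")

    with open(outdir / "report.csv", "w", newline="") as f:
        w = csv.writer(f)
        for k, v in report.items():
            w.writerow([k, v])
    return report


def _compressed_args(ys, system, n):
    data_c, maps_c = compress(ys, system.maps, n)
    return data_c, system.with_maps(maps_c)


def _clone_config(config, **overrides):
    d = config.to_dict()
    d["lam"] = d.pop("lambda")
    d.update(overrides)
    from .io import ReconConfig
    return ReconConfig(**d)


def _snr_experiment(fx: Fixture, config, outdir) -> dict:
    from .model import Reconstruction

    white = prewhiten(fx.raw, sigma=fx.noise_sd)
    lung = fx.phantom.lung_mask.any(axis=0)
    out = {}
    for arm, sketch in (("conventional", 0), ("sketched", 3)):
        cfg = _clone_config(config, sketch_coils=min(sketch, fx.system.n_coils)
                            if sketch else 0, regularizer="lr",
                            solver="fista", pad_factor=1.0)

        def closure(raw_rep, cfg=cfg):
            model = Reconstruction.from_raw(raw_rep, cfg, maps=fx.maps)
            return model.fit(track_objective=False).images

        snr, _ = pseudo_replica_snr(white, closure, n_replicas=10,
                                    seed=config.seed + 7)
        out[f"mean_lung_snr_{arm}"] = float(snr[:, lung].mean())
    out["snr_ratio_conventional_vs_sketched"] = (
        out["mean_lung_snr_conventional"] / out["mean_lung_snr_sketched"]
    )
    return out
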