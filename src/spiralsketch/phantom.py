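"""Seeded synthetic free-breathing lung acquisition.

Generates everything a respiratory-resolved reconstruction needs, with exact
ground truth: a deforming analytic lung phantom (torso + two lungs + cysts +
vessel texture), smooth surface-coil sensitivity maps, a golden-angle
stack-of-spirals trajectory, a superior-inferior (SI) navigator series, and
the simulated multicoil non-Cartesian acquisition.

Geometry and motion are analytic (rasterized ellipses/spheres; SI translation
plus uniform SI scaling of the lung region), so the deformation field mapping
every respiratory phase back to phase 0 is known exactly.  Axis 0 is the SI
axis in both 2-D (coronal) and 3-D mode.

Phase-label convention: the breathing cycle of period ``period_ms`` is split
into R equal time slots; slot ``p`` displays the phase-``p`` image whose
diaphragm is displaced by ``amplitude * sin(2*pi*p/R)``.  The emitted
navigator is the smooth (trigonometric) interpolant of the per-phase
diaphragm positions, so the instantaneous Hilbert phase of the navigator
reproduces the generating slot index exactly at zero noise (a quarter-cycle
label offset is absorbed into the schedule, see :func:`phase_schedule`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import (binary_dilation, distance_transform_edt,
                           gaussian_filter, map_coordinates)

from .nufft import nufft_forward

__all__ = [
    "PhantomSpec",
    "DynamicPhantom",
    "Trajectory",
    "RawDataset",
    "make_dynamic_phantom",
    "make_coil_maps",
    "make_stack_of_spirals",
    "simulate_navigator",
    "simulate_acquisition",
    "phase_schedule",
    "GOLDEN_ANGLE_DEG",
]

#: Rotation increment between successive interleaves (360 / golden ratio).
GOLDEN_ANGLE_DEG = 360.0 * (1.0 - 2.0 / (1.0 + np.sqrt(5.0)))  # ~222.4922

DEFAULT_PERIOD_MS = 4000.0  # quiet breathing, ~15 breaths/min
DEFAULT_TR_MS = 8.3
DEFAULT_READOUT_MS = 5.4


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the dynamic lung phantom."""

    grid_shape: tuple[int, ...] = (64, 64)
    n_phases: int = 6
    diaphragm_amplitude: float = 4.0
    lung_intensity: float = 0.25
    n_cysts: int = 3
    vessel_density: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) not in (2, 3):
            raise ValueError("grid_shape must be 2-D or 3-D")
        for d, n in enumerate(self.grid_shape):
            if n < 16:
                raise ValueError(
                    f"grid_shape axis {d} = {n} is too small to contain the "
                    "anatomy (minimum 16 voxels)"
                )
        if self.n_phases < 1:
            raise ValueError("n_phases must be >= 1")
        if not 0 < self.lung_intensity < 1:
            raise ValueError("lung_intensity must lie in (0, 1)")


@dataclass
class DynamicPhantom:
    """Per-phase complex images with exact ground-truth motion."""

    images: np.ndarray  # (R, *grid) complex
    true_fields: np.ndarray  # (R, d, *grid) displacement mapping phase p -> phase 0
    lung_mask: np.ndarray  # (R, *grid) bool
    spec: PhantomSpec = None

    @property
    def n_phases(self) -> int:
        return self.images.shape[0]


@dataclass
class Trajectory:
    """Non-Cartesian sample locations in grid units, ``[-N/2, N/2)`` per axis."""

    coords: np.ndarray  # (K, d)
    readout_id: np.ndarray  # (K,) int
    time: np.ndarray  # (K,) ms

    def __post_init__(self):
        if self.coords.shape[0] != self.readout_id.shape[0]:
            raise ValueError("coords and readout_id disagree on sample count")


@dataclass
class RawDataset:
    """Unbinned multicoil acquisition plus navigator, as written to HDF5."""

    kspace: np.ndarray  # (C, K_total) complex
    coords: np.ndarray  # (K_total, d)
    navigator: np.ndarray  # (n_nav,)
    navigator_time: np.ndarray  # (n_nav,) ms
    readout_id: np.ndarray  # (K_total,) int
    sample_time: np.ndarray  # (K_total,) ms
    noise_sigma: float
    meta: dict = field(default_factory=dict)
    true_bins: np.ndarray | None = None  # generating phase per readout (ground truth)

    def __post_init__(self):
        if self.kspace.shape[1] != self.coords.shape[0]:
            raise ValueError("kspace and coords disagree on K_total")

    @property
    def n_coils(self) -> int:
        return self.kspace.shape[0]


def _centered_axes(grid_shape):
    return np.meshgrid(
        *[np.arange(n, dtype=np.float64) - n / 2.0 for n in grid_shape],
        indexing="ij",
    )


def _ellipse_mask(grid_shape, center, semiaxes):
    ax = _centered_axes(grid_shape)
    q = sum(((a - c) / s) ** 2 for a, c, s in zip(ax, center, semiaxes))
    return q <= 1.0


def _lung_geometry(spec: PhantomSpec):
    """Phase-0 torso / lung ellipse parameters in centered voxel coordinates."""
    shape = spec.grid_shape
    d = len(shape)
    n_si, n_lr = shape[0], shape[1]
    torso_center = [0.0] * d
    torso_semi = [0.44 * n_si, 0.42 * n_lr] + ([0.42 * shape[2]] if d == 3 else [])
    lung_si_c = -0.08 * n_si  # lungs sit superior of center
    lung_si_a = 0.26 * n_si
    lung_lr_off = 0.18 * n_lr
    lung_semi = [lung_si_a, 0.14 * n_lr] + ([0.22 * shape[2]] if d == 3 else [])
    lung_centers = []
    for sgn in (-1.0, 1.0):
        c = [lung_si_c, sgn * lung_lr_off] + ([0.0] if d == 3 else [])
        lung_centers.append(c)
    return torso_center, torso_semi, lung_centers, lung_semi


def _phase_motion(spec: PhantomSpec, p: int):
    """SI displacement and scale of the lung region at phase ``p``.

    The lung apex (superior edge) is fixed; the diaphragm (inferior edge)
    moves down by ``delta_p``; hence the lung stretches by ``s_p`` about the
    apex and its volume scales by ``s_p``.
    """
    delta = spec.diaphragm_amplitude * np.sin(2.0 * np.pi * p / spec.n_phases)
    _, _, _, lung_semi = _lung_geometry(spec)
    a0 = lung_semi[0]
    s = 1.0 + delta / (2.0 * a0)
    return delta, s


def _taper(lung_mask: np.ndarray) -> np.ndarray:
    """Weight 1 on the (dilated) lung, decaying to 0 over a 4-voxel margin."""
    dist_out = distance_transform_edt(~binary_dilation(lung_mask, iterations=1))
    return np.clip(1.0 - dist_out / 4.0, 0.0, 1.0)


def _lung_mask_at(spec: PhantomSpec, p: int) -> np.ndarray:
    """Union of the two lung ellipses, stretched about the apex at phase p."""
    shape = spec.grid_shape
    _, _, lung_cs, lung_s = _lung_geometry(spec)
    apex = lung_cs[0][0] - lung_s[0]
    _, s = _phase_motion(spec, p)
    mask = np.zeros(shape, dtype=bool)
    for c in lung_cs:
        cp = list(c)
        cp[0] = apex + s * (c[0] - apex)
        sp = list(lung_s)
        sp[0] = s * lung_s[0]
        mask |= _ellipse_mask(shape, cp, sp)
    return mask


def _pair_field(s_q: float, s_ref: float, taper: np.ndarray, ax0: np.ndarray,
                apex: float) -> np.ndarray:
    """SI displacement registering phase q onto the reference phase."""
    if s_q == s_ref:
        return np.zeros_like(ax0)
    return (apex + (ax0 - apex) * (s_q / s_ref) - ax0) * taper


def make_true_fields(spec: PhantomSpec, reference: int) -> np.ndarray:
    """Exact displacement fields registering every phase onto ``reference``.

    Entry ``q`` is the field ``u`` with ``warp(image_q, u) ~= image_ref`` (up
    to the density modulation): ``x + u(x)`` is the phase-q location of the
    tissue at reference-frame position ``x``, an SI affine about the fixed
    lung apex tapered to identity outside the reference lung.
    """
    shape = spec.grid_shape
    d = len(shape)
    R = spec.n_phases
    _, _, lung_cs, lung_s = _lung_geometry(spec)
    apex = lung_cs[0][0] - lung_s[0]
    _, s_ref = _phase_motion(spec, reference)
    ax = _centered_axes(shape)
    taper = _taper(_lung_mask_at(spec, reference))
    fields = np.zeros((R, d, *shape))
    for q in range(R):
        if q == reference:
            continue
        _, s_q = _phase_motion(spec, q)
        fields[q, 0] = _pair_field(s_q, s_ref, taper, ax[0], apex)
    return fields


def make_dynamic_phantom(spec: PhantomSpec) -> DynamicPhantom:
    """Rasterize the deforming phantom and its exact motion fields.

    The lung parenchyma intensity is divided by the per-phase SI scale factor
    so total lung signal ("mass") is conserved across the cycle.
    """
    shape = spec.grid_shape
    d = len(shape)
    rng = np.random.default_rng(spec.seed)
    torso_c, torso_s, lung_cs, lung_s = _lung_geometry(spec)
    if lung_s[0] < spec.diaphragm_amplitude:
        raise ValueError(
            f"grid_shape axis 0 = {shape[0]} too small for diaphragm amplitude "
            f"{spec.diaphragm_amplitude}"
        )

    torso = _ellipse_mask(shape, torso_c, torso_s)

    # Phase-0 lung texture in phase-0 coordinates: parenchyma + bright vessels
    # + dark cysts.  Sampled through the motion map for later phases so the
    # texture moves with the tissue.
    lung0 = np.zeros(shape, dtype=bool)
    for c in lung_cs:
        lung0 |= _ellipse_mask(shape, c, lung_s)
    tex0 = np.full(shape, spec.lung_intensity)
    if spec.vessel_density > 0:
        noise = gaussian_filter(rng.standard_normal(shape), sigma=1.2)
        thresh = np.quantile(noise[lung0], 1.0 - spec.vessel_density)
        tex0[noise > thresh] = min(3.0 * spec.lung_intensity, 0.9)
    cyst_r = max(1.5, 0.05 * shape[0])
    for _ in range(spec.n_cysts):
        side = rng.integers(2)
        c = list(lung_cs[side])
        jitter = rng.uniform(-0.5, 0.5, size=d)
        center = [ci + ji * si for ci, ji, si in zip(c, jitter, lung_s)]
        tex0[_ellipse_mask(shape, center, [cyst_r] * d)] = 0.0

    # smooth low-order polynomial phase map (complex-valued anatomy)
    ax = _centered_axes(shape)
    coef = rng.uniform(-1.0, 1.0, size=(d, 2))
    pmap = np.zeros(shape)
    for dd in range(d):
        u = ax[dd] / (shape[dd] / 2.0)
        pmap += 0.4 * coef[dd, 0] * u + 0.3 * coef[dd, 1] * u**2
    phase_factor = np.exp(1j * pmap)

    R = spec.n_phases
    images = np.zeros((R, *shape), dtype=np.complex128)
    fields = np.zeros((R, d, *shape))
    lung_masks = np.zeros((R, *shape), dtype=bool)

    apex = lung_cs[0][0] - lung_s[0]  # fixed superior lung edge (SI coord)
    grid_idx = np.meshgrid(*[np.arange(n, dtype=np.float64) for n in shape],
                           indexing="ij")

    for p in range(R):
        _, s = _phase_motion(spec, p)
        lung_p = _lung_mask_at(spec, p)
        lung_masks[p] = lung_p

        # analytic map from phase-p to phase-0 coordinates: SI affine about
        # the apex inside the lung, tapered to identity over a 4-voxel margin
        # outside (weight is exactly 1 on the lung so the stored field is the
        # exact lung motion)
        u_si = _pair_field(1.0, s, _taper(lung_p), ax[0], apex)
        fields[p, 0] = u_si

        # rasterize: sample the phase-0 texture at the mapped position
        sample_pos = [grid_idx[0] + u_si] + [grid_idx[dd] for dd in range(1, d)]
        tex_p = map_coordinates(tex0, sample_pos, order=1, mode="nearest")
        img = np.where(torso, 1.0, 0.0)
        img[lung_p] = tex_p[lung_p] / s  # volume-compensating density rule
        images[p] = img * phase_factor

    return DynamicPhantom(images=images, true_fields=fields,
                          lung_mask=lung_masks, spec=spec)


def make_coil_maps(
    n_coils: int,
    grid_shape: tuple[int, ...],
    seed: int = 0,
    uniform: bool = False,
) -> np.ndarray:
    """Smooth complex surface-coil sensitivity maps around the torso.

    Returns a ``(C, *grid)`` complex array normalized so the peak per-voxel
    root-sum-of-squares is 1.  ``uniform=True`` returns all-ones maps
    (identity sensitivity, single- or multi-coil).
    """
    if n_coils < 1:
        raise ValueError("n_coils must be >= 1")
    grid_shape = tuple(grid_shape)
    if uniform:
        return np.ones((n_coils, *grid_shape), dtype=np.complex128)
    d = len(grid_shape)
    rng = np.random.default_rng(seed)
    ax = _centered_axes(grid_shape)
    radius = [0.55 * n for n in grid_shape]
    sigma = 0.6 * max(grid_shape)
    maps = np.zeros((n_coils, *grid_shape), dtype=np.complex128)
    for c in range(n_coils):
        theta = 2.0 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        center = [radius[0] * np.cos(theta), radius[1] * np.sin(theta)]
        if d == 3:
            center.append(rng.uniform(-0.25, 0.25) * grid_shape[2])
        r2 = sum((a - cc) ** 2 for a, cc in zip(ax, center))
        mag = np.exp(-r2 / (2.0 * sigma**2))
        ramp = sum(
            rng.uniform(-1.0, 1.0) * ax[dd] / grid_shape[dd] for dd in range(d)
        )
        maps[c] = mag * np.exp(1j * (rng.uniform(0, 2 * np.pi) + 1.5 * ramp))
    rss = np.sqrt((np.abs(maps) ** 2).sum(axis=0))
    maps /= rss.max()
    return maps


def make_stack_of_spirals(
    n_interleaves: int = 397,
    n_kz: int = 1,
    grid_shape: tuple[int, ...] = (64, 64),
    golden_angle: bool = True,
    n_turns: int | None = None,
    n_points: int | None = None,
    tr_ms: float = DEFAULT_TR_MS,
    readout_ms: float = DEFAULT_READOUT_MS,
) -> Trajectory:
    """Golden-angle Archimedean stack-of-spirals trajectory.

    In 2-D mode (``n_kz=1`` with a 2-D grid) a plain rotating spiral is
    produced.  Interleaf ``i`` is rotated by ``i * 222.4922...`` degrees when
    ``golden_angle`` is set, else uniformly by ``360/n_interleaves`` degrees.
    Readouts are spaced ``tr_ms`` apart in acquisition time.
    """
    if n_interleaves < 1:
        raise ValueError("n_interleaves must be >= 1")
    grid_shape = tuple(grid_shape)
    d = len(grid_shape)
    if d == 2 and n_kz != 1:
        raise ValueError("2-D grid requires n_kz=1")
    kmax = min(grid_shape[0], grid_shape[1]) / 2.0 - 0.5
    if n_turns is None:
        n_turns = max(1, int(np.ceil(kmax / n_interleaves)))
    n_pts = n_points if n_points is not None else \
        max(16, int(np.ceil(2.0 * np.pi * n_turns * kmax)))
    tau = np.sqrt(np.linspace(0.0, 1.0, n_pts + 1)[1:])  # ~uniform area coverage
    r = kmax * tau
    base_angle = 2.0 * np.pi * n_turns * tau

    if golden_angle:
        dtheta = np.deg2rad(GOLDEN_ANGLE_DEG)
    else:
        dtheta = 2.0 * np.pi / n_interleaves

    kz_list = (np.arange(n_kz) - n_kz // 2) * (grid_shape[2] / n_kz) if d == 3 \
        else [None]

    coords, rid, times = [], [], []
    readout = 0
    t_in_readout = np.linspace(0.0, readout_ms, n_pts, endpoint=False)
    for kz in kz_list:
        for i in range(n_interleaves):
            theta = base_angle + readout * dtheta
            kx = r * np.cos(theta)
            ky = r * np.sin(theta)
            if d == 3:
                c = np.stack([kx, ky, np.full(n_pts, kz)], axis=1)
            else:
                c = np.stack([kx, ky], axis=1)
            coords.append(c)
            rid.append(np.full(n_pts, readout, dtype=np.int64))
            times.append(readout * tr_ms + t_in_readout)
            readout += 1
    return Trajectory(
        coords=np.concatenate(coords),
        readout_id=np.concatenate(rid),
        time=np.concatenate(times),
    )


def phase_schedule(
    times_ms: np.ndarray, n_phases: int, period_ms: float = DEFAULT_PERIOD_MS
) -> np.ndarray:
    """Generating respiratory-phase slot for each time point.

    The quarter-cycle offset aligns the slot boundaries with the bins produced
    by Hilbert-phase binning of the emitted navigator, so retrospective
    binning of a noiseless simulation reproduces this schedule.
    """
    frac = np.mod(np.asarray(times_ms, dtype=np.float64) / period_ms + 0.25, 1.0)
    return np.minimum((frac * n_phases).astype(np.int64), n_phases - 1)


def _trig_interp_periodic(values: np.ndarray, positions: np.ndarray) -> np.ndarray:
    """Evaluate the trigonometric interpolant of a periodic sequence.

    ``values`` are R samples over one period; ``positions`` are in sample
    units (period = R).  Exact for any band-limited (e.g. sinusoidal) motion.
    """
    R = len(values)
    if R == 1:
        return np.full(positions.shape, values[0], dtype=np.float64)
    spec = np.fft.rfft(values) / R
    freqs = np.arange(spec.shape[0])
    out = np.full(positions.shape, spec[0].real)
    for m, cm in zip(freqs[1:], spec[1:]):
        w = 2.0 * np.pi * m * positions / R
        if R % 2 == 0 and m == R // 2:
            out += (cm * np.exp(1j * w)).real  # Nyquist term, not doubled
        else:
            out += 2.0 * (cm * np.exp(1j * w)).real
    return out


def simulate_navigator(
    true_motion: np.ndarray,
    duration_ms: float,
    interval_ms: float = 120.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    period_ms: float = DEFAULT_PERIOD_MS,
) -> tuple[np.ndarray, np.ndarray]:
    """Quasi-periodic SI navigator trace sampled every ``interval_ms``.

    ``true_motion`` holds the per-phase diaphragm displacement (R values over
    one breathing cycle).  The trace is the smooth periodic interpolant of
    those positions plus Gaussian noise; for sinusoidal motion it equals the
    sinusoid exactly at sample times.

    Returns ``(trace, sample_times_ms)``.
    """
    if interval_ms <= 0:
        raise ValueError("interval_ms must be > 0")
    t = np.arange(0.0, duration_ms + interval_ms, interval_ms)
    R = len(true_motion)
    pos = np.mod(t / period_ms, 1.0) * R
    trace = _trig_interp_periodic(np.asarray(true_motion, dtype=np.float64), pos)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        trace = trace + rng.normal(0.0, noise_sd, size=trace.shape)
    return trace, t


def simulate_acquisition(
    phantom: DynamicPhantom,
    maps: np.ndarray,
    traj: Trajectory,
    noise_sd: float = 0.0,
    seed: int = 0,
    period_ms: float = DEFAULT_PERIOD_MS,
    navigator_interval_ms: float = 120.0,
    navigator_noise_sd: float = 0.0,
) -> RawDataset:
    """Forward-simulate the multicoil acquisition of the deforming phantom.

    Every readout is assigned the respiratory phase active at its start time;
    its samples are the NUFFT of (phase image x coil map) plus i.i.d. complex
    Gaussian noise of standard deviation ``noise_sd`` per channel.
    """
    d = phantom.images.ndim - 1
    if traj.coords.shape[1] != d:
        raise ValueError(
            f"trajectory is {traj.coords.shape[1]}-D but phantom is {d}-D"
        )
    spec = phantom.spec
    R = phantom.n_phases
    C = maps.shape[0]
    K = traj.coords.shape[0]
    rng = np.random.default_rng(seed)

    # whole readouts follow the phase active at their start time
    first_idx = np.unique(traj.readout_id, return_index=True)[1]
    readout_start = traj.time[first_idx]
    bins_per_readout = phase_schedule(readout_start, R, period_ms)
    sample_bins = bins_per_readout[traj.readout_id]

    kspace = np.zeros((C, K), dtype=np.complex128)
    for p in range(R):
        sel = sample_bins == p
        if not sel.any():
            continue
        coords_p = traj.coords[sel]
        for c in range(C):
            kspace[c, sel] = nufft_forward(maps[c] * phantom.images[p], coords_p)
    if noise_sd > 0:
        kspace = kspace + noise_sd * (
            rng.standard_normal(kspace.shape)
            + 1j * rng.standard_normal(kspace.shape)
        )

    delta = np.array([_phase_motion(spec, p)[0] for p in range(R)]) if spec else \
        np.zeros(R)
    duration = traj.time.max()
    nav, nav_t = simulate_navigator(
        delta, duration, navigator_interval_ms, navigator_noise_sd,
        seed=seed + 1, period_ms=period_ms,
    )
    meta = {
        "grid_shape": phantom.images.shape[1:],
        "n_coils": C,
        "seed": seed,
        "period_ms": period_ms,
        "n_phases": R,
    }
    return RawDataset(
        kspace=kspace,
        coords=traj.coords.copy(),
        navigator=nav,
        navigator_time=nav_t,
        readout_id=traj.readout_id.copy(),
        sample_time=traj.time.copy(),
        noise_sigma=noise_sd,
        meta=meta,
        true_bins=bins_per_readout,
    )
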