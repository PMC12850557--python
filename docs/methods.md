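# Methods

This note records the models, conventions and numerical choices behind
`spiralsketch`, in the order data flows through the pipeline.

## Synthetic free-breathing acquisition

The generator emulates a free-breathing stack-of-spirals lung acquisition
with exact ground truth so every downstream stage can be tested against a
known answer.

**Anatomy and motion.** The phantom is analytic geometry rasterized on the
grid: a torso ellipse (intensity 1.0), two lung ellipses at
`lung_intensity` (default 0.25 relative to torso), zero-intensity spherical
cysts, and bright vessel texture covering a `vessel_density` fraction of
lung voxels (default 5%). Axis 0 is superior–inferior (SI). Breathing is
modeled as SI translation plus uniform SI stretch of the lung about a fixed
apex: at phase `p` of `R` the diaphragm is displaced by
`amplitude·sin(2πp/R)` and the lung SI semi-axis scales by `s_p`. Lung
signal density is divided by `s_p`, so total lung signal ("mass") is
conserved across the cycle to well under 2%. The displacement field
mapping any phase onto any reference phase is an SI affine about the apex,
exactly 1 on the lung and tapered to identity over a 4-voxel margin
outside; these fields are returned analytically (`make_true_fields`) and
are the ground truth for all registration tests. A low-order polynomial
phase map makes the images complex without destabilizing
magnitude-image registration. Note the degenerate case `R = 2`: the
displacement formula gives `sin(0) = sin(π) = 0`, i.e. no motion; use
`R ≥ 3` for moving phantoms.

**Acquisition.** Interleaves are Archimedean spirals reaching the Nyquist
box edge, rotated by the golden angle (≈222.4922°) between successive
readouts (uniform rotation available), replicated across kz in 3-D mode.
Readouts are spaced `TR = 8.3 ms`; the SI navigator is sampled every
120 ms. Defaults mirror the target acquisition (397 interleaves per kz, 15
coils); tests use smaller, faster instances. The breathing period defaults
to 4 s (quiet breathing); the desk-scale fixtures shorten the period to
1–2 s so a few hundred readouts span several cycles. Each readout is
assigned the respiratory phase active at its start time and its samples
are the NUFFT of (phase image × coil map) plus i.i.d. complex Gaussian
noise.

**Navigator and phase-label convention.** The navigator is the smooth
periodic (trigonometric) interpolant of the per-phase diaphragm positions
plus optional Gaussian noise; for sinusoidal motion it is exactly the
sinusoid. The generating phase schedule is defined on the same partition
that Hilbert-phase binning produces — the breathing cycle is split into R
equal slots with a quarter-cycle label offset absorbed into the schedule —
so retrospective binning of a noiseless simulation reproduces the schedule
(mis-assignments come only from finite-series Hilbert-transform edge
effects; ≥95% agreement requires the acquisition to span roughly four or
more breathing cycles). The navigator waveform model is a package choice;
inhalation is "increasing navigator value", with a configurable flip.

**Coil maps.** Gaussian-profile surface coils on the torso perimeter with
smooth random phase ramps, normalized so the peak root-sum-of-squares is 1.

## Binning

The navigator's instantaneous phase is the angle of its analytic signal
(mean removed). Whole readouts are assigned by their start time — the
navigator cadence (120 ms) is far longer than one readout (5.4 ms) — via
linear interpolation of the unwrapped phase, then quantized into R
equal-width bins over [−π, π). Equal-width (not equal-count) bins are a
package choice; readout times outside the navigator span are clamped with
a logged warning, and empty bins are an error.

## Encoding

**NUFFT.** Type-1/2 transforms are implemented by Kaiser–Bessel gridding:
oversampling 2, kernel width 8, Beatty-parametrized shape, analytic
deapodization. Measured accuracy against the brute-force DFT is ~1e-7
relative; the adjoint is the exact transpose by construction. Coordinates
are in grid units with the Nyquist box [−N/2, N/2) per axis and DC at
index N/2 after FFT shift — one stated convention avoids half-voxel drift.

**Preconditioner.** The single-channel k-space preconditioner is the
row-wise Frobenius-optimal diagonal approximation to `(F F^H)^{-1}`:
`p_i = J / Σ_j |PSF(κ_i − κ_j)|²`, computed exactly with two NUFFTs on the
doubled grid via the support-autocorrelation identity. A Pipe–Menon-style
iterative density compensation is available behind `precond: dcf`. The
preconditioner enters symmetrically as `P^{1/2}` in both the operator and
the data.

**Normalization.** The maximal eigenvalue of `A^H A` is estimated by power
iteration and divided out of the weights, pinning the spectrum to [0, 1]
so unit solver steps are stable. Power iteration converges slowly when the
spectrum is clustered (which the preconditioner deliberately causes); the
pipeline runs enough iterations that the residual scale error (well under
1%) is harmless, and verification measurements use 200 iterations.

**Toeplitz embedding.** The per-phase kernel is the adjoint NUFFT of the
preconditioner weights onto the 2×-oversampled grid (the exact
linear-convolution embedding), stored in the frequency domain. Applying
`A^H A` then costs one padded FFT/IFFT pair per coil and no k-space
interpolation. The kernel depends only on trajectory and weights, never on
the maps, so one kernel serves full, compressed and sketched operators.
The internal 2× embedding is independent of the 1.33× reconstruction
padding. Kernels are invalidated when normalization rescales the weights.

**Padding.** Reconstruction runs on a `pad_factor`-enlarged matrix
(default 1.33×, rounded to even) to prevent wrap-in from signal outside
the nominal FOV; coordinates are scaled per axis accordingly and results
are cropped back.

## Coil processing

**Virtual coils.** Eigendecomposition of the pooled coil covariance ranks
coils by energy; all downstream stages operate in this basis. Compression
keeps the top C′ virtual coils of data and maps.

**Sensitivity maps.** ESPIRiT-style estimation: density-compensated
gridding of the central k-space onto a 2×-downscaled grid, calibration
Hankel matrix (box 24, kernel 6, singular-value threshold 0.02 of max),
per-voxel eigendecomposition of the image-domain kernel Gram matrix,
support crop by leading-eigenvalue threshold, bilinear upscaling, RSS ≤ 1
normalization and phase referencing to virtual coil 1. One map set is
shared across phases (estimated from phase-combined data). Maps are
identifiable only up to the per-voxel RSS, so comparisons against known
maps are made after per-voxel normalization.

**Sketches.** Each sketch is a (C_S × C) matrix that keeps virtual coil 1
verbatim; the other C_S − 1 rows carry independent Rademacher ±1 weights
over coils 2..C scaled by `1/√(C_S−1)`, making `E[Q^H Q]` the identity on
the mixed block. "Mixing" (rather than outright subset selection, which is
available via `sketch_mode: select`) is the adopted reading of random coil
combination. A fresh sketch is drawn per outer iteration from a
per-iteration seed derived from the master seed.

## Registration and the motion operator

`register(moving, fixed)` returns the displacement `u` with
`warp(moving, u) ≈ fixed`, where `warp` resamples at `x + u(x)` with
linear interpolation and edge clamping — an exact linear operator in the
image for fixed `u`. Flow estimation delegates to the multi-scale
(coarse-to-fine pyramid) TV-L1 optical-flow solver of scikit-image on
magnitude images, normalized to a common scale; defaults
(`attachment=10, tightness=0.3, num_warp=5, num_iter=10`) recover the
phantom's breathing fields to ~0.4 voxel RMS in the lung. The
hyperparameters are package choices (no reference values exist) and live
in one place, `registration.register`. Fields are non-diffeomorphic by
design; no inverse field is ever computed.

## Regularization

* TV: first differences along each spatial axis (forward, zero beyond the
  boundary) and the phase axis (circular — breathing is cyclic;
  configurable). The adjoint is exact, including the zeroed last slice.
* LR: singular-value soft-thresholding of the Casorati (R × J) matrix —
  the exact prox of the nuclear norm.
* MoCo-LR, forward-only prox: for every reference phase, all phases are
  warped *onto* it (forward transforms only), the aligned Casorati matrix
  is SVD-soft-thresholded, and only the reference row is kept. With
  identity motion this collapses exactly to the nuclear prox; with R = 1
  it degenerates likewise. Motion fields are estimated once from the
  warm-start image after the initial compressed iterations and cached
  (`moco_refresh` controls re-estimation); callers may supply analytic
  fields. The per-reference sweep defines a prox-like mapping, not a
  single penalty; for objective reporting the value `λ‖Mx‖*` uses
  alignment to phase 0 as a fixed convention.

The `tau` passed to proxes is λ times the solver step; each solver
documents its scaling.

## Solvers

* **CG** for the unregularized normal equations (CG-SENSE).
* **FISTA** with unit step (valid after normalization), gradient-based
  momentum restart, and — when a block schedule is used — momentum state
  carried across blocks so the blocked run is the continuous accelerated
  sequence.
* **PDHG** with the data-consistency term dualized (`σ = τ = 1` after
  normalization; dual prox is exact averaging). TV adds a second dual
  block with the exact clip conjugate-prox and a halved primal step; for
  prox-friendly penalties the primal update runs `pdhg_inner` (default 4)
  inner proximal-gradient steps on the quadratic subproblem at step τ/2.
  Dual variables and the extrapolation state persist across blocks.

**Sketched driver.** Schedule: `n_initial` iterations with the top-C_S
compressed coils (warm start from zero), then `n_outer` outer iterations
of `n_inner` solver steps using the sketched gradient
`A_St^H A_St (x − x_t) + A^H (A x_t − y)`; the anchor full gradient is
recomputed once per outer iteration with coil batches of size C_S (and
through the Toeplitz kernels when enabled). For PDHG the sketched term is
dualized around the sketched data with the anchor entering the primal
update as a constant linear term that vanishes identically under the
identity sketch. Consequently the identity-sketch run reproduces the
conventional FISTA/PDHG solver to machine precision — the central internal
consistency check. CG's inner blocks solve the local quadratic by restarted
CG; restarting breaks exact trace equivalence for CG (a known property of
restarts, not a defect), so the degeneracy check is asserted for FISTA and
PDHG. Because a sketched operator's spectral norm can exceed 1 (the
Rademacher scaling is unbiased, not contractive), each inner block runs a
short power iteration and shrinks its step below 1 only when needed; on
energy-ordered virtual coils the estimate is ≈1 and the step stays exactly
1. The objective trace always evaluates the full operator, one entry per
completed solver iteration.

## Evaluation

Masked NRMSE on magnitude images; convergence curves as objective ratios
against a long reference run (the experiment harness uses a 200-iteration
reference, recorded in its report; a longer reference is a flag away);
pre-whitening by scalar sigma or inverse Cholesky of a coil covariance;
pseudo-replica SNR as voxelwise mean/SD of magnitude reconstructions over
replicas with fresh unit-SD complex noise (magnitude, not complex, images —
a stated convention). The lung mask for all lung metrics is the phantom's
ground-truth mask.

## Desk-scale study conditions

All operators are dimension-agnostic (d ∈ {2, 3}); tests and the
acceptance script run 2-D+time instances so the full pipeline executes in
seconds to minutes on one CPU. The standard fixture is a 32×32 grid, 6
coils, 3 phases, 480 golden-angle readouts (48 samples each) over two 2-s
breathing cycles at 1% complex noise; solver comparisons use the standard
35-iteration schedule (5 initial + 5 × 6). The pseudo-replica analyses use
8–10 replicas for arm ratios and 30 for the closed-form check. Problem
sizes are recorded alongside each reported number.

## What the synthetic data do and do not show

The generator reproduces the *structure* of free-breathing lung MRI —
non-Cartesian sampling, coil-weighted encoding, quasi-periodic motion with
signal-conserving density modulation, navigator self-gating — with exact
ground truth. It does not model UTE/T2* decay, B0 inhomogeneity, slab
profiles, gradient-waveform imperfections, irregular breathing, or
through-plane motion in 2-D mode. Passing tests therefore certify the
correctness of the operators, proximal updates, sketching identities and
pipeline plumbing under the stated motion model; they do not certify image
quality on scanner data, and printed patient-data error levels are not
reproducible here.

## Known limitations

* The MoCo-LR prox costs R(R−1) registrations when fields are refreshed;
  fields are cached by default.
* The phantom's R = 2 mode is motionless (see above).
* Power-method normalization is accurate to ~1% at pipeline defaults.
* CG inner blocks in the sketched driver are restarted, so CG traces are
  not bit-equivalent to continuous CG (FISTA/PDHG are).
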