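"""Iterative solvers and the coil-sketching outer/inner driver.

The sketched data-consistency gradient used throughout is

    grad_St(x) = A_St^H A_St (x - x_t) + A^H (A x_t - y),

where ``x_t`` is the outer-iteration anchor and the bracketed full gradient
is evaluated once per outer iteration (batched over coil subsets, optionally
through the Toeplitz kernels).  At the anchor the sketched gradient equals
the full gradient exactly, for any sketch; under the identity sketch it
equals the full gradient everywhere.

The standard schedule is: ``n_initial`` iterations of an SVD-coil-compressed
reconstruction (top-C_S virtual coils) to warm-start, then ``n_outer`` outer
iterations of ``n_inner`` solver steps each, with a fresh Rademacher sketch
per outer iteration.  Solver state (FISTA momentum, PDHG dual variables)
persists across the outer blocks, so with the identity sketch the driver
runs the conventional solver iteration-for-iteration: the anchor terms
cancel algebraically and the trace reproduces the plain solver's trace.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field

import numpy as np

from .coils import build_sketch_plan
from .encoding import EncodingSystem, power_method_maxeig
from .regularization import (
    RegularizerSpec,
    estimate_moco_fields,
    finite_diff,
    finite_diff_adjoint,
    moco_lr_prox,
    prox_l1,
    prox_nuclear,
    regularizer_value,
)

__all__ = [
    "SolveState",
    "cg_solve",
    "fista_solve",
    "pdhg_solve",
    "sketched_gradient",
    "sketched_reconstruct",
    "conventional_reconstruct",
    "objective_value",
]


@dataclass
class SolveState:
    """Anchor bookkeeping for the sketched gradient."""

    x: np.ndarray
    x_anchor: np.ndarray
    full_grad_anchor: np.ndarray
    anchor_fresh: bool = True
    objective_trace: list = field(default_factory=list)


def objective_value(x, ys, system: EncodingSystem, reg: RegularizerSpec,
                    fields_cache=None) -> float:
    """Full objective 0.5 * sum_r ||A x_r - y_r||^2 + g(x).

    Always evaluated with the full (unsketched) operator.
    """
    res = system.forward(x)
    dc = 0.5 * sum(
        float(np.linalg.norm(r - y) ** 2) for r, y in zip(res, ys)
    )
    return dc + regularizer_value(x, reg, fields_cache)


def cg_solve(normal_closure, rhs, n_iter: int, x0=None, callback=None):
    """Conjugate gradients on the Hermitian PSD system N x = rhs."""
    x = np.zeros_like(rhs) if x0 is None else x0.copy()
    r = rhs - normal_closure(x)
    p = r.copy()
    rs = float(np.real(np.vdot(r, r)))
    for it in range(n_iter):
        if not np.isfinite(rs):
            raise FloatingPointError("CG residual is not finite")
        if rs == 0:
            if callback is not None:
                callback(x, it)
            continue
        Np = normal_closure(p)
        alpha = rs / float(np.real(np.vdot(p, Np)))
        x = x + alpha * p
        r = r - alpha * Np
        rs_new = float(np.real(np.vdot(r, r)))
        beta = rs_new / rs
        p = r + beta * p
        rs = rs_new
        if callback is not None:
            callback(x, it)
    return x


def fista_solve(grad, prox, x0, n_iter: int, step: float = 1.0,
                objective=None, callback=None, state: dict | None = None):
    """FISTA with momentum restart on objective (or gradient-sign) increase.

    ``state`` (keys ``z``, ``t``, ``prev_obj``) carries the momentum across
    consecutive calls so a blocked schedule continues the accelerated
    sequence instead of restarting it.
    """
    x = x0.copy()
    if state is None:
        state = {}
    z = state.get("z")
    z = x0.copy() if z is None else z
    t = state.get("t", 1.0)
    prev_obj = state.get("prev_obj", np.inf)
    trace = []
    for it in range(n_iter):
        g = grad(z)
        x_new = prox(z - step * g, step)
        if objective is not None:
            obj = objective(x_new)
            if not np.isfinite(obj) or (np.isfinite(prev_obj)
                                        and obj > 10.0 * max(prev_obj, 1e-30)
                                        and it > 0):
                raise FloatingPointError("FISTA objective diverged")
            restart = obj > prev_obj
            trace.append(obj)
            prev_obj = min(prev_obj, obj)
        else:
            restart = float(np.real(np.vdot(g, x_new - x))) > 0
        if restart:
            t = 1.0
            z = x_new.copy()
        else:
            t_new = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * t * t))
            z = x_new + ((t - 1.0) / t_new) * (x_new - x)
            t = t_new
        x = x_new
        if callback is not None:
            callback(x, it)
    state.update(z=z, t=t, prev_obj=prev_obj)
    return x, trace, state


def _primal_update(x_k, q, prox, tau: float, n_steps: int):
    """Approximately solve min_u g(u) + <q, u> + ||u - x_k||^2 / (2 tau)
    with ``n_steps`` proximal-gradient steps (step tau/2 for stability)."""
    eta = tau / 2.0
    u = x_k.copy()
    for _ in range(max(1, n_steps)):
        grad_q = (u - x_k) / tau + q
        u = prox(u - eta * grad_q, eta)
    return u


def pdhg_solve(system_forward, system_adjoint, ys, reg: RegularizerSpec,
               x0, n_iter: int, pdhg_inner: int = 4, tau: float = 1.0,
               sigma: float = 1.0, lin_term=None, prox=None,
               callback=None, state: dict | None = None):
    """Preconditioned PDHG with the data-consistency term dualized.

    ``system_forward``/``system_adjoint`` map image stacks to per-phase data
    blocks and back (operator norm ~1 after normalization).  TV is handled
    with a second dual block (conjugate prox = clip to the lambda-ball); for
    prox-friendly penalties the primal update runs ``pdhg_inner`` inner
    proximal-gradient steps.  ``lin_term`` adds a constant linear gradient
    contribution (the sketched anchor term).  ``state`` carries the dual
    variables and the previous iterate across consecutive calls.
    """
    x = x0.copy()
    if state is None:
        state = {}
    x_prev = state.get("x_prev")
    x_bar = x0.copy() if x_prev is None else 2.0 * x0 - x_prev
    z = state.get("z")
    if z is None or any(zi.shape != y.shape for zi, y in zip(z, ys)):
        z = [np.zeros_like(y) for y in ys]
    use_tv = reg.kind == "tv" and reg.lam > 0
    if use_tv:
        z_tv = state.get("z_tv")
        if z_tv is None:
            z_tv = np.zeros((x.ndim, *x.shape), dtype=np.complex128)
        sigma_tv = 1.0 / (4.0 * x.ndim)
        tau_eff = tau * 0.5
    else:
        z_tv = None
        tau_eff = tau

    for it in range(n_iter):
        Ax = system_forward(x_bar)
        z = [(zi + sigma * (a - y)) / (1.0 + sigma)
             for zi, a, y in zip(z, Ax, ys)]
        q = system_adjoint(z)
        if lin_term is not None:
            q = q + lin_term
        if use_tv:
            z_tv = z_tv + sigma_tv * finite_diff(x_bar, reg.circular_phase)
            mag = np.abs(z_tv)
            z_tv = z_tv / np.maximum(1.0, mag / reg.lam)
            q = q + finite_diff_adjoint(z_tv, reg.circular_phase)
            x_new = x - tau_eff * q
        elif prox is not None:
            x_new = _primal_update(x, q, prox, tau_eff, pdhg_inner)
        else:
            x_new = x - tau_eff * q
        if not np.isfinite(x_new).all():
            raise FloatingPointError("PDHG iterate is not finite")
        x_bar = 2.0 * x_new - x
        x_prev = x
        x = x_new
        if callback is not None:
            callback(x, it)
    state.update(z=z, z_tv=z_tv, x_prev=x_prev)
    return x, state


def sketched_gradient(x, state: SolveState, sketched_system: EncodingSystem):
    """Sketched data-consistency gradient about the current anchor."""
    if not state.anchor_fresh:
        raise RuntimeError("anchor full-gradient term is stale")
    return sketched_system.normal(x - state.x_anchor) + state.full_grad_anchor


def _make_prox(reg: RegularizerSpec, fields_cache):
    """Scaled proximal map prox_{t * lambda * g}; tau passed at call time."""
    if reg.kind in ("none", "cgsense") or reg.lam == 0:
        return lambda v, t: v
    if reg.kind == "lr":
        def p(v, t):
            R = v.shape[0]
            return prox_nuclear(v.reshape(R, -1), t * reg.lam).reshape(v.shape)
        return p
    if reg.kind == "mocolr":
        def p(v, t):
            return moco_lr_prox(v, t * reg.lam, fields_cache)
        return p
    if reg.kind == "tv":
        # one dual-ascent step on the TV prox; only used outside the PDHG
        # path, which dualizes the TV term exactly instead
        def p(v, t):
            d0 = finite_diff(v, reg.circular_phase)
            d = prox_l1(d0, t * reg.lam)
            return v + finite_diff_adjoint(d - d0, reg.circular_phase) \
                / (4.0 * v.ndim)
        return p
    raise ValueError(f"no prox for regularizer {reg.kind!r}")


def _safe_step(system: EncodingSystem, seed: int, n_iter: int = 8,
               tol: float = 5e-3) -> float:
    """Step 1 when the (sketched) operator norm is ~1, else 1/norm."""
    try:
        eig = power_method_maxeig(
            lambda v: system.normal(v), system.stack_shape(),
            n_iter=n_iter, seed=seed,
        )
    except ValueError:  # zero operator (e.g. zero maps): any step works
        return 1.0
    return 1.0 if eig <= 1.0 + tol else 1.0 / eig


def _run_inner(solver: str, system: EncodingSystem, grad, prox, reg,
               x, n_iter, pdhg_inner, step, ys=None, lin_term=None,
               callback=None, solver_state: dict | None = None):
    """Dispatch ``n_iter`` inner iterations of the chosen solver."""
    if n_iter <= 0:
        return x
    if solver == "cg":
        # CG on the quadratic model around x: N delta = -grad(x)
        rhs = -grad(x)
        base = [x]

        def cb(delta, it):
            if callback is not None:
                callback(base[0] + delta, it)

        delta = cg_solve(lambda v: grad(x + v) - grad(x), rhs, n_iter,
                         callback=cb)
        return x + delta
    if solver == "fista":
        x_new, _, _ = fista_solve(grad, prox, x, n_iter, step=step,
                                  callback=callback, state=solver_state)
        return x_new
    if solver == "pdhg":
        assert ys is not None
        x_new, _ = pdhg_solve(system.forward, system.adjoint, ys, reg, x,
                              n_iter, pdhg_inner=pdhg_inner, tau=step,
                              sigma=1.0, lin_term=lin_term, prox=prox,
                              callback=callback, state=solver_state)
        return x_new
    raise ValueError(f"unknown solver {solver!r}")


def sketched_reconstruct(ys, system: EncodingSystem, config,
                         reg: RegularizerSpec | None = None,
                         fields_cache=None, identity_sketch: bool = False,
                         track_objective: bool = True):
    """Full coil-sketching reconstruction on a prepared encoding system.

    ``ys`` are the per-phase preconditioned data blocks (already multiplied
    by P^(1/2)), coil-ordered by energy (virtual coils).  The system must be
    normalized (max eigenvalue of A^H A ~ 1).  Returns ``(x, trace)`` where
    the trace holds one ``(iteration, objective, elapsed_s)`` entry per
    completed solver iteration (objective always with the full operator).
    """
    C = system.n_coils
    C_S = config.sketch_coils if config.sketch_coils > 0 else C
    if C_S > C:
        raise ValueError(f"sketch_coils = {C_S} exceeds {C} available coils")
    if reg is None:
        kind = "none" if config.regularizer == "cgsense" else config.regularizer
        reg = RegularizerSpec(kind=kind, lam=config.lam)
    solver = config.solver
    toeplitz = bool(config.toeplitz)

    trace = []
    t0 = time.perf_counter()
    counter = [0]

    ahy = system.adjoint(ys)

    def tracker(fcache):
        def cb(xi, _it):
            counter[0] += 1
            obj = objective_value(xi, ys, system, reg, fcache) \
                if track_objective else np.nan
            trace.append((counter[0], obj, time.perf_counter() - t0))
        return cb

    x = np.zeros(system.stack_shape(), dtype=np.complex128)
    solver_state: dict = {}

    # ---- phase 1: initial SVD-coil-compressed iterations (top C_S coils)
    comp = np.eye(C, dtype=np.complex128)[:C_S]
    sys_c = system.sketched(comp)
    ys_c = system.sketch_data(ys, comp)
    ahy_c = sys_c.adjoint(ys_c)
    prox = _make_prox(reg, fields_cache)
    if config.n_initial > 0:
        grad_c = lambda v: sys_c.normal(v, toeplitz=toeplitz) - ahy_c
        step_c = _safe_step(sys_c, seed=config.seed + 101)
        x = _run_inner(solver, sys_c, grad_c, prox, reg, x, config.n_initial,
                       config.pdhg_inner, step_c, ys=ys_c,
                       callback=tracker(fields_cache),
                       solver_state=solver_state)

    # ---- motion fields for the motion-compensated penalty: estimated once
    # from the warm-start image unless supplied by the caller
    if reg.kind == "mocolr" and fields_cache is None:
        fields_cache = estimate_moco_fields(np.abs(x))
        prox = _make_prox(reg, fields_cache)

    # ---- phase 2: sketched outer iterations with full-gradient anchoring
    plan = build_sketch_plan(C, C_S, config.n_outer, seed=config.seed,
                             mode=getattr(config, "sketch_mode", "rademacher"),
                             identity=identity_sketch)
    state = SolveState(x=x, x_anchor=x, full_grad_anchor=np.zeros_like(x))
    for t in range(config.n_outer):
        state.x_anchor = x.copy()
        state.full_grad_anchor = (
            system.normal(x, coil_batch=min(C_S, C), toeplitz=toeplitz) - ahy
        )
        state.anchor_fresh = True
        sys_s = system.sketched(plan.sketches[t])
        grad_s = lambda v: sketched_gradient(v, state, sys_s)
        step_s = _safe_step(sys_s, seed=config.seed + 211 + t)
        if solver == "pdhg":
            # dualize around the sketched data: the dual residual plus the
            # linear term reproduces the sketched gradient, and the linear
            # term vanishes identically for the identity sketch
            ys_s = system.sketch_data(ys, plan.sketches[t])
            lin = (state.full_grad_anchor
                   - sys_s.normal(state.x_anchor) + sys_s.adjoint(ys_s))
        else:
            ys_s, lin = None, state.full_grad_anchor
        x = _run_inner(solver, sys_s, grad_s, prox, reg, x, config.n_inner,
                       config.pdhg_inner, step_s, ys=ys_s, lin_term=lin,
                       callback=tracker(fields_cache),
                       solver_state=solver_state)
        state.anchor_fresh = False
        state.x = x
    return x, trace


def conventional_reconstruct(ys, system: EncodingSystem, config,
                             reg: RegularizerSpec | None = None,
                             fields_cache=None, n_iter: int | None = None,
                             track_objective: bool = True):
    """Plain full-operator reconstruction (no sketching, no anchoring).

    Runs the chosen solver for ``n_iter`` iterations (default: the same
    total count as the sketched schedule, n_initial + n_inner * n_outer).
    """
    if reg is None:
        kind = "none" if config.regularizer == "cgsense" else config.regularizer
        reg = RegularizerSpec(kind=kind, lam=config.lam)
    if n_iter is None:
        n_iter = config.n_initial + config.n_inner * config.n_outer
    toeplitz = bool(config.toeplitz)
    ahy = system.adjoint(ys)
    trace = []
    t0 = time.perf_counter()
    counter = [0]

    def cb(xi, _it):
        counter[0] += 1
        obj = objective_value(xi, ys, system, reg, fields_cache) \
            if track_objective else np.nan
        trace.append((counter[0], obj, time.perf_counter() - t0))

    x = np.zeros(system.stack_shape(), dtype=np.complex128)
    if reg.kind == "mocolr" and fields_cache is None:
        # warm start a few iterations to have an image to register
        grad0 = lambda v: system.normal(v, toeplitz=toeplitz) - ahy
        x0, _, _ = fista_solve(grad0, lambda v, t: v, x,
                               min(5, max(1, n_iter // 4)), step=1.0)
        fields_cache = estimate_moco_fields(np.abs(x0))
    prox = _make_prox(reg, fields_cache)
    grad = lambda v: system.normal(v, toeplitz=toeplitz) - ahy
    if config.solver == "cg":
        normal = lambda v: system.normal(v, toeplitz=toeplitz)
        x_out = cg_solve(normal, ahy, n_iter, callback=cb)
        return x_out, trace
    return (
        _run_inner(config.solver, system, grad, prox, reg, x, n_iter,
                   config.pdhg_inner, 1.0, ys=ys, callback=cb),
        trace,
    )
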