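"""Steady-state and dynamic solution of the reduced system.

Strategy: damped Newton (finite-difference Jacobian, backtracking line
search) on the scaled steady-state residual.  Potentials are solved in
log space, which enforces positivity; quasi-equilibrium fluxes and the
biomass concentration stay linear.  When Newton stalls from a cold start,
a pseudo-transient continuation (implicit Euler on the index-1 DAE with
growing steps) walks the state towards the attractor before Newton is
retried.  Wash-out (maximal growth rate below the dilution rate) is
reported as a distinct, valid outcome, not a failure.

All solves are deterministic: no randomness, fixed iteration order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .modelfile import ModelDocument
from .population import ChemostatEnv
from .system import DAESystem, SteadyState, assemble

__all__ = [
    "NewtonResult",
    "damped_newton",
    "default_guess",
    "solve_steady_state",
    "solve_closed",
    "integrate",
]

#: biomass concentrations below this (g/l) count as washed out
WASHOUT_FLOOR = 1e-6


@dataclass
class NewtonResult:
    x: np.ndarray
    converged: bool
    iterations: int
    residual_norm: float


def _fd_jacobian(fun, x, f0):
    n = len(x)
    jac = np.empty((len(f0), n))
    for i in range(n):
        h = 1e-7 * max(1.0, abs(x[i]))
        xp = x.copy()
        xp[i] += h
        jac[:, i] = (fun(xp) - f0) / h
    return jac


def damped_newton(
    fun,
    x0: np.ndarray,
    tol: float = 1e-9,
    max_iter: int = 80,
    max_step: float = 100.0,
) -> NewtonResult:
    """Newton iteration with backtracking line search on ||r||^2.

    ``max_step`` caps the infinity norm of each update; the cap is loose
    because log-space variables legitimately move by tens of e-folds,
    and the backtracking line search rejects harmful long steps anyway.

    Near-equilibrium reactions evaluate as differences of gross one-way
    rates that can exceed the net rate a hundredfold, so the residual has
    a floating-point cancellation floor that may sit above ``tol``.  An
    iterate whose residual stalls (several consecutive iterations without
    meaningful progress) within 10x ``tol`` is therefore accepted as
    converged; genuine non-solutions stall orders of magnitude higher.
    """
    x = np.asarray(x0, dtype=float).copy()
    f = fun(x)
    norm = float(np.max(np.abs(f)))
    stall = 0
    for it in range(1, max_iter + 1):
        if norm < tol:
            return NewtonResult(x, True, it - 1, norm)
        jac = _fd_jacobian(fun, x, f)
        try:
            step = np.linalg.solve(jac, -f)
        except np.linalg.LinAlgError:
            step, *_ = np.linalg.lstsq(jac, -f, rcond=None)
        smax = float(np.max(np.abs(step)))
        if not math.isfinite(smax):
            return NewtonResult(x, False, it, norm)
        if smax > max_step:
            step *= max_step / smax
        alpha = 1.0
        best = None
        phi0 = float(f @ f)
        for _ in range(40):
            x_try = x + alpha * step
            try:
                f_try = fun(x_try)
            except (FloatingPointError, OverflowError, ValueError):
                alpha *= 0.5
                continue
            if not np.all(np.isfinite(f_try)):
                alpha *= 0.5
                continue
            phi = float(f_try @ f_try)
            if phi < phi0 * (1.0 - 1e-4 * alpha) or phi < tol * tol:
                best = (x_try, f_try)
                break
            alpha *= 0.5
        if best is None:
            return NewtonResult(x, norm < 10.0 * tol, it, norm)
        x, f = best
        new_norm = float(np.max(np.abs(f)))
        stall = stall + 1 if new_norm > 0.9 * norm else 0
        norm = new_norm
        if stall >= 5 and norm < 10.0 * tol:
            return NewtonResult(x, True, it, norm)
    return NewtonResult(x, norm < 10.0 * tol, max_iter, norm)


# ---------------------------------------------------------------------------
# initial guesses


def default_guess(sys: DAESystem, env: ChemostatEnv | None = None) -> np.ndarray:
    """Default starting point: each species at its declared typical
    concentration (falling back to its capacity, i.e. potential one),
    pools distributed over their members, medium at inflow composition,
    biomass from a crude carbon yield."""
    doc = sys.doc
    c = sys.capacity.copy()  # xi = 1 where no guess is declared
    for i, mid in enumerate(sys.met_ids):
        g = doc.metabolites[mid].guess
        if g is not None and g > 0:
            c[i] = g
    # overwrite pool members with the pool distribution
    for pool in doc.moieties.pools:
        share = pool.total / len(pool.members)
        for m in pool.members:
            c[sys.met_index[m]] = share
    aer = env.aerobiosis if env is not None else (
        doc.chemostat.aerobiosis if doc.chemostat else 0.0
    )
    for q in doc.moieties.quinones:
        c[sys.met_index[q.ox]] = q.total(aer) / 2
        c[sys.met_index[q.red]] = q.total(aer) / 2
    # put the energy charge mid-ramp
    if doc.growth is not None and sys.energy_couple is not None:
        pool = doc.moieties.pool_of(sys.energy_couple[0])
        if pool is not None:
            mid = 0.5 * (doc.growth.k_lo + doc.growth.k_hi)
            rest = [m for m in pool.members if m not in sys.energy_couple]
            spare = 0.1 * pool.total if rest else 0.0
            den = (pool.total - spare) / (1.0 + mid)
            c[sys.i_num] = mid * den
            c[sys.i_den] = den
            for m in rest:
                c[sys.met_index[m]] = spare / len(rest)
    u = np.log(c[sys.int_idx] / sys.capacity[sys.int_idx])

    w = np.empty(sys.n_ext)
    if sys.mode == "chemostat":
        env = env or doc.chemostat
        for k, i_ext in enumerate(sys.ext_idx):
            met = sys.met_ids[i_ext]
            g = doc.metabolites[met].guess
            if sys.gas_mask_ext[k]:
                supply = env.gas_supply(met)
                w[k] = math.log(max(supply / env.k_out[met], 1e-9))
            elif g is not None and g > 0:
                w[k] = math.log(g)
            else:
                w[k] = math.log(max(env.c_in.get(met, 0.0) * 0.5, 1e-7))
        carbon_in = sum(
            ci * doc.metabolites[met].carbons for met, ci in env.c_in.items()
        )
        cpg = doc.biomass.carbon_per_gram(
            {m.id: m.carbons for m in doc.metabolites.values()}
        )
        c_X = max(0.4 * carbon_in * 1e3 / max(cpg, 1.0), 1e-3)
        u = _project_onto_qe(sys, u, w)
        return sys.pack(u, w, np.zeros(sys.n_qe), c_X)
    u = _project_onto_qe(sys, u, np.zeros(sys.n_ext))
    return sys.pack(u, np.zeros(sys.n_ext), np.zeros(sys.n_qe))


def _project_onto_qe(sys: DAESystem, u: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Least-norm correction of the intracellular log potentials so the
    (log-linear) quasi-equilibrium constraints hold exactly at the guess."""
    if not sys.n_qe:
        return u
    ln_xi = sys.log_xi_full(u, w)
    N_full = (sys.P_mat - sys.R_mat)[sys.n_kin : sys.n_kin + sys.n_qe]
    r = N_full @ ln_xi
    N = N_full[:, sys.int_idx]
    try:
        du = N.T @ np.linalg.solve(N @ N.T, -r)
    except np.linalg.LinAlgError:
        du, *_ = np.linalg.lstsq(N, -r, rcond=None)
    return u + du


def guess_from_state(
    sys: DAESystem, state: SteadyState, env: ChemostatEnv | None = None
) -> np.ndarray:
    c = np.array([state.concentrations[m] for m in sys.met_ids])
    u = np.log(c[sys.int_idx] / sys.capacity[sys.int_idx])
    w = np.log(np.maximum(c[sys.ext_idx], 1e-300))
    if env is not None and sys.mode == "chemostat":
        # a gas whose supply changed since the guess state may sit at a
        # vanishing concentration where its balance row is numerically
        # singular; re-seed it at the no-consumption level k_in/k_out
        for k, i_ext in enumerate(sys.ext_idx):
            if sys.gas_mask_ext[k]:
                met = sys.met_ids[i_ext]
                floor = env.gas_supply(met) / env.k_out[met]
                if floor > 0:
                    w[k] = max(w[k], math.log(floor))
    J_qe = np.array([state.J[r.id] for r in sys.qe])
    if sys.mode == "chemostat":
        return sys.pack(u, w, J_qe, max(state.c_X, WASHOUT_FLOOR))
    return sys.pack(u, w, J_qe)


# ---------------------------------------------------------------------------
# dynamics (implicit Euler)


def integrate(
    sys: DAESystem,
    y0: np.ndarray,
    t_end: float,
    env: ChemostatEnv | None = None,
    h0: float = 1e-4,
    h_max: float = 0.5,
    grow: float = 1.4,
    eps: float = 1e-3,
    # loose: transient steps only need to track the trajectory, and rows
    # carrying 1/h mass terms put the FD-Jacobian noise floor near 1e-8
    newton_tol: float = 1e-7,
    record: bool = True,
    c0: np.ndarray | None = None,
):
    """Implicit-Euler integration of the index-1 DAE.

    ``y0`` is a dynamic state vector (see ``DAESystem.pack_dynamic``).
    Returns (times, states) arrays; with ``record=False`` only the final
    state is kept.  Step size grows geometrically and halves on Newton
    failure, making the integrator usable both as a trajectory oracle and
    as pseudo-transient continuation.
    """
    t, h = 0.0, h0
    y = np.asarray(y0, dtype=float).copy()
    times = [0.0]
    states = [y.copy()]
    while t < t_end:
        h = min(h, t_end - t)
        res = damped_newton(
            lambda z: sys.dynamic_residual(z, y, h, env, eps=eps, c0=c0),
            y,
            tol=newton_tol,
            max_iter=40,
        )
        if not res.converged:
            h *= 0.25
            if h < 1e-12:
                raise RuntimeError(
                    f"implicit Euler step failed to converge at t={t:.3g} h"
                )
            continue
        y = res.x
        t += h
        h = min(h * grow, h_max)
        if record:
            times.append(t)
            states.append(y.copy())
    if not record:
        times, states = [t], [y]
    return np.array(times), np.array(states)


def _dynamic_from_steady(sys: DAESystem, y: np.ndarray, env: ChemostatEnv | None):
    if sys.mode == "closed":
        return y.copy()
    env = env or sys.doc.chemostat
    u, w, _, _ = sys.unpack(y)
    ln_xi = sys.log_xi_full(u, w)
    c = sys.concentrations(ln_xi)
    a = sys.activities(c)
    c_E = sys.enzyme_synthesis(a) / env.D
    return sys.pack_dynamic(y, c_E)


# ---------------------------------------------------------------------------
# steady states


def solve_steady_state(
    model: ModelDocument | DAESystem,
    env: ChemostatEnv | None = None,
    guess: SteadyState | np.ndarray | None = None,
    tol: float = 1e-9,
    eps: float = 1e-3,
    pseudo_time: float = 50.0,
) -> SteadyState:
    """Solve the chemostat model for a steady state.

    Tries Newton from the guess; on failure falls back to pseudo-transient
    continuation and retries.  A converged state with vanishing biomass,
    or a trajectory collapsing to vanishing biomass while mu < D, is
    reported with outcome ``washout``.  Non-convergence returns outcome
    ``failed`` carrying the best iterate in the diagnostics.
    """
    sys = model if isinstance(model, DAESystem) else assemble(model)
    if sys.mode != "chemostat":
        raise ValueError("solve_steady_state requires a chemostat model; "
                         "use solve_closed for closed networks")
    env = env or sys.doc.chemostat
    if guess is None:
        y0 = default_guess(sys, env)
    elif isinstance(guess, SteadyState):
        y0 = guess_from_state(sys, guess, env)
    else:
        y0 = np.asarray(guess, dtype=float).copy()

    def fun(y):
        return sys.steady_residual(y, env, eps=eps)

    res = damped_newton(fun, y0, tol=tol)
    path = "newton"
    if res.converged and sys.unpack(res.x)[3] > WASHOUT_FLOOR:
        return sys.build_state(
            res.x, env, res.residual_norm, "steady", eps,
            diagnostics={"iterations": res.iterations, "path": path},
        )

    # pseudo-transient continuation from the initial guess
    y_dyn = _dynamic_from_steady(sys, y0, env)
    washed = False
    try:
        _, states = integrate(
            sys, y_dyn, pseudo_time, env, h0=1e-5, h_max=2.0,
            eps=eps, record=False,
        )
        y_dyn = states[-1]
        n_s = sys.n_state
        c_X_end = sys.unpack(y_dyn[:n_s])[3]
        washed = c_X_end < WASHOUT_FLOOR
        res2 = damped_newton(fun, y_dyn[:n_s], tol=tol)
        path = "newton+pseudo-transient"
    except RuntimeError:
        res2 = res
        path = "newton (pseudo-transient failed)"

    if res2.converged:
        c_X = sys.unpack(res2.x)[3]
        if c_X > WASHOUT_FLOOR:
            return sys.build_state(
                res2.x, env, res2.residual_norm, "steady", eps,
                diagnostics={"iterations": res2.iterations, "path": path},
            )
        washed = True

    if washed:
        wash = _solve_washout(sys, env, y_dyn[: sys.n_state], tol, eps)
        if wash is not None:
            return wash

    best = res2 if res2.residual_norm < res.residual_norm else res
    return sys.build_state(
        best.x, env, best.residual_norm, "failed", eps,
        diagnostics={"iterations": best.iterations, "path": path,
                     "message": "steady-state solve did not converge"},
    )


def _solve_washout(sys, env, y_near, tol, eps):
    """Solve the trivial-biomass branch (c_X = 0, medium at inflow)."""
    n_red = sys.n_int + sys.n_ext + sys.n_qe

    def fun(z):
        y = np.concatenate([z, [0.0]])
        return sys.steady_residual(y, env, eps=eps, washout=True)

    res = damped_newton(fun, y_near[:n_red], tol=tol)
    if not res.converged:
        return None
    y = np.concatenate([res.x, [0.0]])
    state = sys.build_state(
        y, env, res.residual_norm, "washout", eps, washout=True,
        diagnostics={"iterations": res.iterations, "path": "washout branch"},
    )
    if state.mu >= env.D:
        return None  # not actually a washout situation
    return state


def solve_closed(
    model: ModelDocument | DAESystem,
    c0: dict[str, float],
    guess: np.ndarray | None = None,
    tol: float = 1e-11,
) -> SteadyState:
    """Steady state of a closed (or boundary-clamped) reaction network.

    ``c0`` gives initial concentrations (mol/l) of the balanced species;
    conserved pool totals are taken from it.  When ``c0`` is None each
    species starts at its capacity (all potentials one).
    """
    sys = model if isinstance(model, DAESystem) else assemble(model)
    if sys.mode != "closed":
        raise ValueError("solve_closed requires a model without a chemostat section")
    c0_vec = np.zeros(sys.n_met)
    for i in range(sys.n_met):
        met = sys.met_ids[i]
        if sys.fixed_mask[i]:
            c0_vec[i] = sys.fixed_conc[i]
        elif c0 is None:
            c0_vec[i] = sys.capacity[i]
        else:
            c0_vec[i] = c0[met]
    if guess is None:
        u = np.log(np.maximum(c0_vec[sys.int_idx], 1e-300)) - sys.log_capacity[sys.int_idx]
        w = np.log(np.maximum(c0_vec[sys.ext_idx], 1e-300))
        guess = sys.pack(u, w, np.zeros(sys.n_qe))

    def fun(y):
        return sys.steady_residual(y, c0=c0_vec)

    res = damped_newton(fun, guess, tol=tol, max_iter=200)
    outcome = "steady" if res.converged else "failed"
    return sys.build_state(
        res.x, None, res.residual_norm, outcome,
        diagnostics={"iterations": res.iterations, "path": "newton"},
    )
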