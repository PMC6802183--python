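"""Stiff ODE integration, steady-state detection and step protocols.

Steady states are found by chunked LSODA integration with a scaled
derivative-norm criterion ``max_i |dx_i/dt| / (1 + |x_i|) < ss_tol``
required on two consecutive checkpoints, optionally accelerated by a
bounded least-squares polish of the algebraic system.  The polish
augments ``dx/dt = 0`` with the network's conserved-moiety constraints
(anchored at the integrated state) so the root is isolated within the
trajectory's stoichiometric compatibility class, and is accepted only if
it stays close to the integrated state and meets the tolerance; on any
failure the integrator simply keeps going, so batch runs never raise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import least_squares

from .network_model import Environment, NORMOXIA, ReactionNetwork, jacobian, rhs

__all__ = [
    "SolverSettings",
    "SteadyStateResult",
    "ProtocolResult",
    "integrate_to_steady_state",
    "run_step_protocol",
    "timecourse",
]


@dataclass(frozen=True)
class SolverSettings:
    """Numerical settings shared by all integrations.

    ``rtol``/``atol`` are LSODA tolerances on the nM scale; ``ss_tol`` the
    scaled steady-state residual threshold; ``t_max`` the integration
    horizon (model time units, seconds of the source models).
    """

    rtol: float = 1e-6
    atol: float = 1e-9
    ss_tol: float = 1e-8
    t_max: float = 1e6
    t_chunk0: float = 200.0
    chunk_growth: float = 4.0
    polish: bool = True
    method: str = "LSODA"


DEFAULT_SETTINGS = SolverSettings()


@dataclass
class SteadyStateResult:
    """Final state of a steady-state search.

    ``converged`` implies ``residual < ss_tol``; ``t_elapsed`` records how
    much model time was integrated (auditable distinction between true
    steady states and slow transients at the horizon).
    """

    state: np.ndarray
    converged: bool
    residual: float
    t_elapsed: float
    message: str = ""


def _scaled_residual(net: ReactionNetwork, state: np.ndarray, env: Environment) -> float:
    dx = rhs(net, state, env)
    return float(np.max(np.abs(dx) / (1.0 + np.abs(state))))


def _conservation_rows(net: ReactionNetwork) -> np.ndarray:
    """Left null space of the full stoichiometry (float, orthonormal rows)."""
    s = net.stoichiometry.astype(float)
    if s.shape[1] == 0:
        return np.eye(s.shape[0])
    u, sing, _ = np.linalg.svd(s)
    tol = max(s.shape) * np.finfo(float).eps * (sing[0] if sing.size else 1.0)
    rank = int(np.sum(sing > tol))
    return u[:, rank:].T


def _polish(
    net: ReactionNetwork,
    state: np.ndarray,
    env: Environment,
    settings: SolverSettings,
) -> Optional[np.ndarray]:
    """Newton-style refinement of ``rhs = 0`` with conservation anchoring."""
    cons = _conservation_rows(net)
    anchor = cons @ state if cons.size else np.zeros(0)

    def fun(x: np.ndarray) -> np.ndarray:
        try:
            f = rhs(net, x, env)
        except FloatingPointError:
            return np.full(net.n_species + anchor.size, 1e6)
        extra = cons @ x - anchor if cons.size else np.zeros(0)
        return np.concatenate([f, extra])

    def jac(x: np.ndarray) -> np.ndarray:
        j = jacobian(net, x, env)
        return np.vstack([j, cons]) if cons.size else j

    try:
        sol = least_squares(
            fun,
            np.clip(state, 0.0, None),
            jac=jac,
            bounds=(0.0, np.inf),
            xtol=1e-14,
            ftol=1e-14,
            gtol=None,
            max_nfev=200 * net.n_species,
        )
    except Exception:
        return None
    x = sol.x
    # reject polishes that wandered to a different branch
    drift = np.abs(x - state) / (1.0 + np.abs(state))
    if np.max(drift) > 0.05:
        return None
    if _scaled_residual(net, x, env) >= settings.ss_tol:
        return None
    return x


def integrate_to_steady_state(
    net: ReactionNetwork,
    state0: np.ndarray,
    env: Environment = NORMOXIA,
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> SteadyStateResult:
    """Integrate until the scaled derivative norm stays below ``ss_tol``.

    Convergence requires the criterion on two consecutive checkpoints
    (geometrically growing chunks).  Solver failures and horizon
    exhaustion are reported through ``converged=False`` — never raised —
    so population batches always complete.
    """
    state = np.asarray(state0, dtype=float).copy()
    if state.shape != (net.n_species,):
        raise ValueError(
            f"state0 length {state.size} != species count {net.n_species}"
        )
    t = 0.0
    chunk = settings.t_chunk0
    hits = 0
    residual = _scaled_residual(net, state, env)
    if residual < settings.ss_tol:
        return SteadyStateResult(state, True, residual, 0.0, "initial state steady")

    def f(_t: float, y: np.ndarray) -> np.ndarray:
        return rhs(net, y, env)

    def jac(_t: float, y: np.ndarray) -> np.ndarray:
        return jacobian(net, y, env)

    while t < settings.t_max:
        chunk = min(chunk, settings.t_max - t)
        try:
            sol = solve_ivp(
                f,
                (t, t + chunk),
                state,
                method=settings.method,
                rtol=settings.rtol,
                atol=settings.atol,
                jac=jac,
                dense_output=False,
            )
        except FloatingPointError as exc:
            return SteadyStateResult(state, False, residual, t, f"rhs failure: {exc}")
        if not sol.success:
            return SteadyStateResult(
                state, False, residual, t, f"solver failure: {sol.message}"
            )
        state = np.clip(sol.y[:, -1], 0.0, None)
        t = sol.t[-1]
        residual = _scaled_residual(net, state, env)
        if residual < settings.ss_tol:
            hits += 1
            if hits >= 2:
                return SteadyStateResult(state, True, residual, t, "converged")
        else:
            hits = 0
            if settings.polish and residual < 1e-4:
                polished = _polish(net, state, env, settings)
                if polished is not None:
                    return SteadyStateResult(
                        polished,
                        True,
                        _scaled_residual(net, polished, env),
                        t,
                        "converged (polished)",
                    )
        chunk *= settings.chunk_growth
    return SteadyStateResult(
        state, residual < settings.ss_tol, residual, t, "horizon reached"
    )


@dataclass
class ProtocolResult:
    """Baseline plus per-condition steady states of one step protocol."""

    baseline: SteadyStateResult
    conditions: Dict[Environment, SteadyStateResult] = field(default_factory=dict)
    timecourses: Dict[Environment, Tuple[np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )


def run_step_protocol(
    net: ReactionNetwork,
    baseline_state: np.ndarray,
    conditions: Sequence[Environment],
    settings: SolverSettings = DEFAULT_SETTINGS,
    baseline_result: Optional[SteadyStateResult] = None,
    t_grid: Optional[np.ndarray] = None,
) -> ProtocolResult:
    """Apply each condition as a step change from the same normoxic baseline.

    Conditions are independent (no carry-over): each starts from
    ``baseline_state``.  Non-converged conditions are recorded and the
    batch continues.  If ``t_grid`` is given, a sampled trajectory is also
    stored per condition (used for maximal-transient readouts).
    """
    if baseline_result is None:
        baseline_result = integrate_to_steady_state(
            net, baseline_state, NORMOXIA, settings
        )
    out = ProtocolResult(baseline=baseline_result)
    for env in conditions:
        out.conditions[env] = integrate_to_steady_state(
            net, baseline_state, env, settings
        )
        if t_grid is not None:
            out.timecourses[env] = timecourse(net, baseline_state, env, t_grid, settings)
    return out


def timecourse(
    net: ReactionNetwork,
    state0: np.ndarray,
    env: Environment,
    t_grid: Sequence[float],
    settings: SolverSettings = DEFAULT_SETTINGS,
) -> Tuple[np.ndarray, np.ndarray]:
    """Trajectory sampled at ``t_grid``; first sample equals ``state0``.

    Returns ``(times, states)`` with ``states`` of shape
    ``(len(times), n_species)``.  On solver failure the partial trajectory
    is returned (times actually reached), flagged by its shorter length.
    """
    t_grid = np.asarray(t_grid, dtype=float)
    if t_grid.ndim != 1 or t_grid.size < 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be a strictly increasing 1-D sequence")
    state0 = np.asarray(state0, dtype=float)
    t0 = t_grid[0]
    sol = solve_ivp(
        lambda _t, y: rhs(net, y, env),
        (t0, t_grid[-1]),
        state0,
        method=settings.method,
        rtol=settings.rtol,
        atol=settings.atol,
        jac=lambda _t, y: jacobian(net, y, env),
        t_eval=t_grid,
    )
    times = sol.t
    states = sol.y.T
    if times.size == 0 or times[0] != t0:
        times = np.concatenate([[t0], times])
        states = np.vstack([state0, states]) if states.size else state0[None, :]
    else:
        states = states.copy()
        states[0] = state0
    return times, np.clip(states, 0.0, None)
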