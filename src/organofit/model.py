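"""The four-compartment interaction ODE and its forward simulation.

The model couples cancer cells (N), M2-polarized macrophages (M2),
cancer-associated fibroblasts (CAF) and cytotoxic T cells (Tc):

    dN/dt   = gamma (1 - N/K) N + q1 N M2 + q2 N CAF - k Tc N
    dM2/dt  = q3 M2 N + q4 M2 CAF - delta_M2 M2
    dCAF/dt = q5 CAF N + q6 CAF M2 - delta_CAF CAF
    dTc/dt  = q7 Tc N - q8 Tc M2 - q9 Tc CAF - delta_Tc Tc

Every term carries its own state factor, so the nonnegative orthant is
forward-invariant and the origin is an equilibrium for any parameter set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .exceptions import SimulationError, UndefinedFractionError
from .params import (
    COMPARTMENTS,
    EstimatedParameters,
    KnownParameters,
    as_state_array,
)

#: Fraction of the initial total abundance below which an integrator
#: undershoot is silently clipped to zero; larger undershoots are errors.
UNDERSHOOT_TOL = 1e-9


def rhs(state, known: KnownParameters, est: EstimatedParameters) -> np.ndarray:
    """Time derivative (dN/dt, dM2/dt, dCAF/dt, dTc/dt) at ``state``.

    Parameters
    ----------
    state : StateVector or sequence of 4 floats
        Compartment abundances (N, M2, CAF, Tc); must be finite and >= 0.
    known, est
        Fixed and estimated rate parameters.

    Returns
    -------
    numpy.ndarray, shape (4,)
        Rates of change in abundance units per day.
    """
    z = as_state_array(state)
    return _rhs(z, known, est)


def _rhs(z: np.ndarray, known: KnownParameters, est: EstimatedParameters) -> np.ndarray:
    # Unvalidated kernel shared with the IVP solver (which may probe
    # slightly negative states during stepping).
    N, M2, CAF, Tc = z
    dN = known.gamma * (1.0 - N / known.K) * N + known.q1 * N * M2 \
        + est.q2 * N * CAF - known.k * Tc * N
    dM2 = known.q3 * M2 * N + est.q4 * M2 * CAF - known.delta_M2 * M2
    dCAF = est.q5 * CAF * N + est.q6 * CAF * M2 - est.delta_CAF * CAF
    dTc = est.q7 * Tc * N - est.q8 * Tc * M2 - est.q9 * Tc * CAF \
        - known.delta_Tc * Tc
    return np.array([dN, dM2, dCAF, dTc])


@dataclass(frozen=True)
class Trajectory:
    """A simulated time course of the four compartments.

    Attributes
    ----------
    times : numpy.ndarray, shape (n,)
        Strictly increasing time grid in days.
    states : numpy.ndarray, shape (n, 4)
        Abundances at each time, column order (N, M2, CAF, Tc).
    known, est
        The parameter set that produced the trajectory (provenance).
    initial : numpy.ndarray, shape (4,)
        Initial condition at ``times[0]``.
    """

    times: np.ndarray
    states: np.ndarray
    known: KnownParameters = field(repr=False, default=KnownParameters())
    est: EstimatedParameters = field(repr=False, default=EstimatedParameters())
    initial: np.ndarray = field(repr=False, default=None)

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or s.shape != (t.size, 4):
            raise ValueError(f"inconsistent trajectory shapes {t.shape} / {s.shape}")
        if t.size > 1 and not np.all(np.diff(t) > 0):
            raise ValueError("trajectory times must be strictly increasing")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError("trajectory states must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    def component(self, name: str) -> np.ndarray:
        """Return the time series of one compartment by name (N, M2, CAF, Tc)."""
        if name not in COMPARTMENTS:
            raise ValueError(
                f"unknown compartment {name!r}; expected one of {COMPARTMENTS}"
            )
        return self.states[:, COMPARTMENTS.index(name)]


def simulate(
    initial,
    known: KnownParameters,
    est: EstimatedParameters,
    t_start: float,
    t_end: float,
    grid: float = 1.0,
    *,
    times: Sequence[float] | None = None,
    rtol: float = 1e-8,
    atol: float = 1e-6,
) -> Trajectory:
    """Solve the initial-value problem and report states on a regular grid.

    The solver (LSODA, adaptive and stiffness-switching) steps independently
    of the output grid; grid values are obtained from its dense interpolant,
    so refining ``grid`` never changes the values at shared times.

    Parameters
    ----------
    initial : StateVector or 4-sequence
        State at ``t_start``.
    t_start, t_end : float
        Integration window in days, ``t_end > t_start``.
    grid : float
        Output spacing in days (ignored when ``times`` is given).
    times : sequence of float, optional
        Explicit output times (must lie in ``[t_start, t_end]``).
    rtol, atol : float
        Local error tolerances passed to the solver.

    Raises
    ------
    SimulationError
        If the solver fails, or any state undershoots zero by more than
        ``UNDERSHOOT_TOL`` times the initial total abundance.
    """
    z0 = as_state_array(initial)
    if times is None:
        if not t_end > t_start:
            raise ValueError(f"t_end ({t_end}) must exceed t_start ({t_start})")
        if grid <= 0:
            raise ValueError("grid spacing must be positive")
        t_eval = np.arange(t_start, t_end + 0.5 * grid, grid)
        t_eval[-1] = min(t_eval[-1], t_end)
    else:
        t_eval = np.asarray(times, dtype=float)
        if t_eval.ndim != 1 or t_eval.size == 0 or not np.all(np.diff(t_eval) > 0):
            raise ValueError("output times must be a strictly increasing 1-d sequence")
        t_start, t_end = float(t_eval[0]), float(t_eval[-1])
        if t_eval.size == 1:
            return Trajectory(t_eval, z0[None, :], known, est, z0)

    sol = solve_ivp(
        lambda t, z: _rhs(z, known, est),
        (t_start, t_end),
        z0,
        method="LSODA",
        t_eval=t_eval,
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise SimulationError(
            f"IVP solver failed near t = {sol.t[-1] if sol.t.size else t_start:.4g} d: "
            f"{sol.message}"
        )
    states = sol.y.T.copy()
    undershoot = states.min(initial=0.0)
    tol = UNDERSHOOT_TOL * max(z0.sum(), 1.0)
    if undershoot < -tol:
        i, j = np.unravel_index(np.argmin(states), states.shape)
        raise SimulationError(
            f"state went negative ({COMPARTMENTS[j]} = {states[i, j]:.3e} at "
            f"t = {sol.t[i]:.4g} d) beyond the undershoot tolerance {tol:.1e}"
        )
    np.clip(states, 0.0, None, out=states)
    return Trajectory(np.asarray(t_eval), states, known, est, z0)


def composition_fractions(traj: Trajectory) -> np.ndarray:
    """Per-time fractions (N, M2, CAF, Tc) / (N + M2 + CAF + Tc).

    Raises
    ------
    UndefinedFractionError
        If all four compartments are zero at any time point.
    """
    totals = traj.states.sum(axis=1)
    zero = totals <= 0
    if np.any(zero):
        t_bad = traj.times[zero][0]
        raise UndefinedFractionError(
            f"all compartments are zero at t = {t_bad:.4g} d; fractions undefined"
        )
    return traj.states / totals[:, None]


@dataclass(frozen=True)
class Extremum:
    """An interior local extremum of one compartment's time course."""

    time: float
    value: float
    kind: str  # "max" or "min"


def find_local_extrema(traj: Trajectory, component: str) -> list[Extremum]:
    """Interior local maxima/minima of one compartment, refined by a
    three-point quadratic through the bracketing grid values.

    A grid point is a candidate when its value strictly exceeds (max) or is
    strictly below (min) both neighbors by more than a prominence floor of
    1e-9 times the component's range (so round-off jitter on flat stretches
    is not reported); endpoints are never reported.  Requires at least 3
    grid points.
    """
    v = traj.component(component)
    t = traj.times
    if t.size < 3:
        raise ValueError("extremum detection needs at least 3 grid points")
    floor = 1e-9 * max(np.ptp(v), np.max(np.abs(v)), 1e-300)
    out: list[Extremum] = []
    for i in range(1, t.size - 1):
        if v[i] > v[i - 1] + floor and v[i] > v[i + 1] + floor:
            kind = "max"
        elif v[i] < v[i - 1] - floor and v[i] < v[i + 1] - floor:
            kind = "min"
        else:
            continue
        t_ref, v_ref = _quadratic_vertex(t[i - 1 : i + 2], v[i - 1 : i + 2])
        out.append(Extremum(time=t_ref, value=v_ref, kind=kind))
    return out


def _quadratic_vertex(t3: np.ndarray, v3: np.ndarray) -> tuple[float, float]:
    """Vertex of the parabola through three (possibly non-uniform) points."""
    t0, t1, t2 = (float(x) for x in t3)
    v0, v1, v2 = (float(x) for x in v3)
    # Newton form: v0 + d1 (t - t0) + d2 (t - t0)(t - t1)
    d1 = (v1 - v0) / (t1 - t0)
    d2 = ((v2 - v1) / (t2 - t1) - d1) / (t2 - t0)
    if d2 == 0.0:  # degenerate (collinear); keep the grid point
        return t1, v1
    t_star = 0.5 * (t0 + t1 - d1 / d2)
    # Keep the refined location inside the bracket.
    t_star = min(max(t_star, t0), t2)
    v_star = v0 + d1 * (t_star - t0) + d2 * (t_star - t0) * (t_star - t1)
    return t_star, v_star
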