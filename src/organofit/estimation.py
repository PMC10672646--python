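"""Linear least-squares estimation of the eight interaction rates.

Between two measurement days the ODE is collocated by a difference quotient,

    (Z_{i+1} - Z_i) / (t_{i+1} - t_i) = F(Z_{i+1/2}),

with the mid-interval state interpolated per component by the arithmetic
mean (always defined) or the harmonic mean (strictly positive endpoints).
Because the eight unknown rates enter F linearly with measured (interpolated)
cofactors, every interval contributes four linear rows and the stacked
system A Q = B is solved by (possibly nonnegativity-constrained) least
squares.

Block structure of the unknowns, by model equation:
  N equation   -> q2                      (1 unknown)
  M2 equation  -> q4                      (1 unknown)
  CAF equation -> q5, q6, delta_CAF       (3 unknowns)
  Tc equation  -> q7, q8, q9              (3 unknowns)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

from .exceptions import (
    InsufficientDataError,
    RankDeficiencyError,
)
from .params import (
    COMPARTMENTS,
    ESTIMATED_ORDER,
    EstimatedParameters,
    KnownParameters,
    as_state_array,
)

#: Columns of the design matrix owned by each model equation.
EQUATION_BLOCKS: dict[str, tuple[str, ...]] = {
    "N": ("q2",),
    "M2": ("q4",),
    "CAF": ("q5", "q6", "delta_CAF"),
    "Tc": ("q7", "q8", "q9"),
}

_COL = {name: i for i, name in enumerate(ESTIMATED_ORDER)}


@dataclass(frozen=True)
class MeasurementSeries:
    """One sample's time-stamped compartment measurements.

    Attributes
    ----------
    patient_id : str
        Opaque sample label.
    times : numpy.ndarray, shape (n,)
        Strictly increasing measurement days, n >= 2.
    states : numpy.ndarray, shape (n, 4)
        Nonnegative abundances, column order (N, M2, CAF, Tc).
    """

    patient_id: str
    times: np.ndarray
    states: np.ndarray

    def __post_init__(self):
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or s.shape != (t.size, 4):
            raise ValueError(f"inconsistent measurement shapes {t.shape} / {s.shape}")
        if t.size < 2:
            raise ValueError(
                f"patient {self.patient_id!r}: measurements require two time points "
                f"at least, got {t.size}"
            )
        if not np.all(np.diff(t) > 0):
            raise ValueError(f"patient {self.patient_id!r}: days must strictly increase")
        if not np.all(np.isfinite(s)) or np.any(s < 0):
            raise ValueError(f"patient {self.patient_id!r}: states must be finite and >= 0")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    @property
    def n_intervals(self) -> int:
        return self.times.size - 1


@dataclass(frozen=True)
class LinearSystem:
    """The stacked collocation system A Q = B with row provenance."""

    A: np.ndarray
    B: np.ndarray
    row_provenance: tuple[tuple[str, int, str], ...]  # (patient_id, interval, equation)

    def __post_init__(self):
        A = np.asarray(self.A, dtype=float)
        B = np.asarray(self.B, dtype=float)
        if A.ndim != 2 or A.shape[1] != len(ESTIMATED_ORDER):
            raise ValueError(f"A must have {len(ESTIMATED_ORDER)} columns, got {A.shape}")
        if B.shape != (A.shape[0],) or len(self.row_provenance) != A.shape[0]:
            raise ValueError("A, B and row_provenance row counts disagree")
        if not (np.all(np.isfinite(A)) and np.all(np.isfinite(B))):
            raise ValueError("linear system contains non-finite entries")
        object.__setattr__(self, "A", A)
        object.__setattr__(self, "B", B)

    @property
    def n_rows(self) -> int:
        return self.A.shape[0]

    def block_rows(self, equation: str) -> np.ndarray:
        """Row indices contributed by one model equation."""
        return np.array(
            [i for i, (_, _, eq) in enumerate(self.row_provenance) if eq == equation],
            dtype=int,
        )


def midpoint(z_i: float, z_next: float, mode: str = "auto") -> float:
    """Mid-interval interpolation of one state component.

    ``arithmetic`` returns ``(z_i + z_next)/2``; ``harmonic`` returns
    ``2 z_i z_next / (z_i + z_next)`` and requires both endpoints > 0;
    ``auto`` uses the harmonic mean when both endpoints are strictly
    positive and falls back to the arithmetic mean otherwise.  The harmonic
    mean never exceeds the arithmetic mean, with equality iff the endpoints
    are equal.
    """
    if z_i < 0 or z_next < 0:
        raise ValueError(f"midpoint endpoints must be >= 0, got ({z_i}, {z_next})")
    if mode == "arithmetic":
        return 0.5 * (z_i + z_next)
    if mode == "harmonic":
        if z_i <= 0 or z_next <= 0:
            raise ValueError(
                f"harmonic midpoint requires strictly positive endpoints, "
                f"got ({z_i}, {z_next})"
            )
        return 2.0 * z_i * z_next / (z_i + z_next)
    if mode == "auto":
        if z_i > 0 and z_next > 0:
            return 2.0 * z_i * z_next / (z_i + z_next)
        return 0.5 * (z_i + z_next)
    raise ValueError(f"unknown midpoint mode {mode!r}")


def midpoint_state(z_i, z_next, mode: str = "auto") -> np.ndarray:
    """Componentwise mid-interval state."""
    a = as_state_array(z_i)
    b = as_state_array(z_next)
    return np.array([midpoint(a[j], b[j], mode) for j in range(4)])


def interval_rows(
    z_i,
    z_next,
    t_i: float,
    t_next: float,
    known: KnownParameters,
    mode: str = "auto",
) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Four collocation rows (one per model equation) for one interval.

    With midpoint state Z* = (N*, M2*, CAF*, Tc*) and dt = t_next - t_i,
    each equation's unknown terms populate the design columns while the
    known terms move to the right-hand side:

    =========  =======================================  ============================
    equation   A columns (coefficient)                  B entry
    =========  =======================================  ============================
    N          q2: N* CAF*                              dN/dt - [gamma(1-N*/K)N*
                                                        + q1 N* M2* - k Tc* N*]
    M2         q4: M2* CAF*                             dM2/dt - [q3 M2* N*
                                                        - delta_M2 M2*]
    CAF        q5: CAF* N*, q6: CAF* M2*,               dCAF/dt
               delta_CAF: -CAF*
    Tc         q7: Tc* N*, q8: -Tc* M2*, q9: -Tc* CAF*  dTc/dt + delta_Tc Tc*
    =========  =======================================  ============================

    Returns ``(A4, b4, equations)`` where ``A4`` is 4 x 8 in the fixed
    column order and ``equations`` names each row's model equation.
    """
    dt = float(t_next) - float(t_i)
    if dt <= 0:
        raise ValueError(f"interval length must be positive, got dt = {dt}")
    a = as_state_array(z_i)
    b = as_state_array(z_next)
    Ns, M2s, CAFs, Tcs = midpoint_state(a, b, mode)
    dzdt = (b - a) / dt

    A4 = np.zeros((4, len(ESTIMATED_ORDER)))
    b4 = np.zeros(4)

    # N equation
    A4[0, _COL["q2"]] = Ns * CAFs
    b4[0] = dzdt[0] - (
        known.gamma * (1.0 - Ns / known.K) * Ns + known.q1 * Ns * M2s - known.k * Tcs * Ns
    )
    # M2 equation
    A4[1, _COL["q4"]] = M2s * CAFs
    b4[1] = dzdt[1] - (known.q3 * M2s * Ns - known.delta_M2 * M2s)
    # CAF equation
    A4[2, _COL["q5"]] = CAFs * Ns
    A4[2, _COL["q6"]] = CAFs * M2s
    A4[2, _COL["delta_CAF"]] = -CAFs
    b4[2] = dzdt[2]
    # Tc equation
    A4[3, _COL["q7"]] = Tcs * Ns
    A4[3, _COL["q8"]] = -Tcs * M2s
    A4[3, _COL["q9"]] = -Tcs * CAFs
    b4[3] = dzdt[3] + known.delta_Tc * Tcs

    return A4, b4, COMPARTMENTS


def assemble(
    series: list[MeasurementSeries],
    known: KnownParameters,
    mode: str = "auto",
) -> LinearSystem:
    """Stack interval rows over all consecutive measurement pairs of all series.

    Raises
    ------
    InsufficientDataError
        If fewer than 8 rows (2 intervals) are available in total.
    """
    rows_A: list[np.ndarray] = []
    rows_B: list[np.ndarray] = []
    prov: list[tuple[str, int, str]] = []
    for s in series:
        for i in range(s.n_intervals):
            A4, b4, eqs = interval_rows(
                s.states[i], s.states[i + 1], s.times[i], s.times[i + 1], known, mode
            )
            rows_A.append(A4)
            rows_B.append(b4)
            prov.extend((s.patient_id, i, eq) for eq in eqs)
    n_rows = 4 * sum(s.n_intervals for s in series)
    if n_rows < len(ESTIMATED_ORDER):
        raise InsufficientDataError(
            f"need at least {len(ESTIMATED_ORDER)} rows (2 measurement intervals) to "
            f"pose the system, got {n_rows} ({len(ESTIMATED_ORDER) - n_rows} short)"
        )
    return LinearSystem(np.vstack(rows_A), np.concatenate(rows_B), tuple(prov))


@dataclass(frozen=True)
class FitResult:
    """Solution of one least-squares fit with diagnostics.

    ``q`` is the raw solution vector in the fixed parameter order (it can
    contain negative entries for the unconstrained methods); ``params``
    materializes it as :class:`EstimatedParameters` and therefore requires
    nonnegativity.
    """

    q: np.ndarray
    method: str
    residual_norm: float
    rank: int
    block_ranks: dict[str, int]
    block_cond: dict[str, float]
    warnings: tuple[str, ...] = ()
    system: LinearSystem | None = field(repr=False, default=None)

    @property
    def params(self) -> EstimatedParameters:
        return EstimatedParameters.from_array(self.q)

    def as_dict(self) -> dict[str, float]:
        return dict(zip(ESTIMATED_ORDER, (float(v) for v in self.q)))


def _block_diagnostics(system: LinearSystem) -> tuple[dict[str, int], dict[str, float]]:
    ranks: dict[str, int] = {}
    conds: dict[str, float] = {}
    for eq, cols in EQUATION_BLOCKS.items():
        rows = system.block_rows(eq)
        sub = system.A[np.ix_(rows, [_COL[c] for c in cols])] if rows.size else np.zeros((0, len(cols)))
        ranks[eq] = int(np.linalg.matrix_rank(sub)) if sub.size else 0
        if sub.size and ranks[eq] == len(cols):
            sv = np.linalg.svd(sub, compute_uv=False)
            conds[eq] = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
        else:
            conds[eq] = np.inf
    return ranks, conds


def solve(
    system: LinearSystem,
    method: str = "nonnegative",
    *,
    cond_max: float = 1e12,
    keep_system: bool = False,
) -> FitResult:
    """Solve A Q = B in the least-squares sense.

    Parameters
    ----------
    method : {"nonnegative", "pseudoinverse", "normal_equations"}
        ``normal_equations`` forms Q = (A'A)^-1 A'B literally and raises
        :class:`RankDeficiencyError` when A'A is singular beyond
        ``cond_max``; ``pseudoinverse`` returns the minimum-norm
        least-squares solution; ``nonnegative`` (default) solves the
        NNLS problem min ||AQ - B|| subject to Q >= 0, honoring the
        constraint that all rates are nonnegative.
    """
    A, B = system.A, system.B
    if method == "normal_equations":
        G = A.T @ A
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > cond_max:
            raise RankDeficiencyError(
                f"normal equations are singular beyond tolerance "
                f"(cond(A'A) = {cond:.3g} > {cond_max:.3g}); use method="
                f"'pseudoinverse' or 'nonnegative'"
            )
        q = np.linalg.solve(G, A.T @ B)
    elif method == "pseudoinverse":
        q, *_ = np.linalg.lstsq(A, B, rcond=None)
    elif method == "nonnegative":
        q, _ = nnls(A, B)
    else:
        raise ValueError(f"unknown solve method {method!r}")

    ranks, conds = _block_diagnostics(system)
    warn_msgs = []
    for eq, cols in EQUATION_BLOCKS.items():
        if ranks[eq] < len(cols):
            warn_msgs.append(
                f"{eq} equation block is rank-deficient (rank {ranks[eq]} < "
                f"{len(cols)} unknowns); its components are not uniquely determined"
            )
    return FitResult(
        q=q,
        method=method,
        residual_norm=float(np.linalg.norm(A @ q - B)),
        rank=int(np.linalg.matrix_rank(A)),
        block_ranks=ranks,
        block_cond=conds,
        warnings=tuple(warn_msgs),
        system=system if keep_system else None,
    )


def fit(
    series: list[MeasurementSeries],
    known: KnownParameters | None = None,
    pooling: str = "pooled",
    method: str = "nonnegative",
    mode: str = "auto",
    **solve_kwargs,
) -> "FitResult | dict[str, FitResult]":
    """Fit the eight interaction rates from measurement series.

    Thin wrapper over :class:`organofit.estimator.TumorCompositionModel`;
    ``pooling="pooled"`` returns a single shared :class:`FitResult`,
    ``pooling="per_patient"`` a dict keyed by patient id.  Underdetermined
    equation blocks (e.g. a lone three-time-point patient, whose CAF and Tc
    blocks have 2 rows for 3 unknowns) trigger a warning and are reported
    in the result's diagnostics.
    """
    known = known or KnownParameters()
    from .estimator import TumorCompositionModel

    est = TumorCompositionModel(
        gamma=known.gamma,
        capacity=known.K,
        q1=known.q1,
        q3=known.q3,
        delta_m2=known.delta_M2,
        kill_rate=known.k,
        delta_tc=known.delta_Tc,
        method=method,
        pooling=pooling,
        midpoint_mode=mode,
        **solve_kwargs,
    ).fit(series)
    if pooling == "pooled":
        return est.results_["pooled"]
    return est.results_


def scheme_residual(
    series: MeasurementSeries,
    known: KnownParameters,
    truth: EstimatedParameters,
    mode: str = "auto",
) -> float:
    """Relative collocation residual ||A q* - B|| / ||B|| of a known truth.

    On measurements taken from an exact trajectory this residual is the
    discretization error of the difference scheme and shrinks as the
    measurement spacing shrinks (second order in the spacing).
    """
    sys_ = assemble([series], known, mode)
    B_norm = np.linalg.norm(sys_.B)
    return float(np.linalg.norm(sys_.A @ truth.to_array() - sys_.B) / B_norm)


def parameter_uncertainty(
    series: list[MeasurementSeries],
    known: KnownParameters,
    noise_cv: float,
    mode: str = "auto",
    rel_step: float = 1e-5,
) -> np.ndarray:
    """First-order propagated standard error of the unconstrained estimate.

    Perturbs every measured abundance by a relative finite-difference step,
    maps the perturbation through assemble+pseudoinverse, and accumulates
    the per-measurement contributions assuming independent multiplicative
    noise with coefficient of variation ``noise_cv``.  Used to decide which
    components a given design can identify at a given noise level.
    """
    base_sys = assemble(series, known, mode)
    q0, *_ = np.linalg.lstsq(base_sys.A, base_sys.B, rcond=None)
    var = np.zeros(len(ESTIMATED_ORDER))
    for si, s in enumerate(series):
        for ti in range(s.times.size):
            for j in range(4):
                z = s.states[ti, j]
                if z <= 0:
                    continue
                h = rel_step * z
                pert = s.states.copy()
                pert[ti, j] += h
                pert_series = list(series)
                pert_series[si] = MeasurementSeries(s.patient_id, s.times, pert)
                sys_p = assemble(pert_series, known, mode)
                qp, *_ = np.linalg.lstsq(sys_p.A, sys_p.B, rcond=None)
                var += ((qp - q0) / h * (noise_cv * z)) ** 2
    return np.sqrt(var)
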