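"""scikit-learn-style estimator wrapping the fit/simulate pipeline.

``TumorCompositionModel`` takes tidy per-patient time-course measurements,
estimates the eight interaction rates by (constrained) linear least squares
on the collocated ODE, and predicts compartment trajectories between
arbitrary days by forward simulation from each patient's earliest measured
state.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from . import estimation as est_mod
from . import model as model_mod
from .estimation import FitResult, MeasurementSeries
from .params import ESTIMATED_ORDER, EstimatedParameters, KnownParameters

#: Tidy-frame column names for the four compartments, in model order.
FRAME_COLUMNS = ("n", "m2", "caf", "tc")


def series_from_frame(X: pd.DataFrame) -> list[MeasurementSeries]:
    """Build measurement series from a tidy frame with columns
    ``patient_id``, ``day``, ``n``, ``m2``, ``caf``, ``tc``."""
    required = {"patient_id", "day", *FRAME_COLUMNS}
    missing = required - set(X.columns)
    if missing:
        raise ValueError(f"measurement frame is missing columns: {sorted(missing)}")
    out = []
    for pid, grp in X.groupby("patient_id", sort=True):
        grp = grp.sort_values("day")
        out.append(
            MeasurementSeries(
                str(pid),
                grp["day"].to_numpy(dtype=float),
                grp[list(FRAME_COLUMNS)].to_numpy(dtype=float),
            )
        )
    return out


class TumorCompositionModel(BaseEstimator):
    """Estimate tumor-microenvironment interaction rates and forecast
    organoid cell composition.

    Parameters
    ----------
    gamma, capacity, q1, q3, delta_m2, kill_rate, delta_tc : float
        The seven literature-fixed rates (defaults: adjusted literature
        values).  ``capacity`` is the cancer-cell carrying capacity K.
    method : {"nonnegative", "pseudoinverse", "normal_equations"}
        Least-squares variant; the default enforces nonnegative rates.
    pooling : {"pooled", "per_patient"}
        Whether one shared rate vector or one per patient is fitted.
    midpoint_mode : {"auto", "arithmetic", "harmonic"}
        Mid-interval interpolation used by the collocation scheme.
    fix_delta_caf : float or None
        If set, the CAF death rate is fixed to this value instead of being
        estimated (its column is removed from the unknowns).
    rtol, atol : float
        IVP solver tolerances used by :meth:`predict`.

    Attributes
    ----------
    params_ : EstimatedParameters
        Fitted rates (pooled fit; for per-patient fits, of the first patient).
    results_ : dict[str, FitResult]
        Per fit-unit results keyed by patient id, or ``{"pooled": ...}``.
    linear_system_ : LinearSystem
        The assembled design (pooled fits only).
    initial_states_ : dict[str, tuple[float, numpy.ndarray]]
        Each patient's earliest measurement day and state, used as the
        anchor for prediction.
    """

    def __init__(
        self,
        gamma: float = 0.05,
        capacity: float = 1.0e6,
        q1: float = 4.0e-5,
        q3: float = 4.0e-8,
        delta_m2: float = 0.2,
        kill_rate: float = 1.0e-3,
        delta_tc: float = 0.1,
        method: str = "nonnegative",
        pooling: str = "pooled",
        midpoint_mode: str = "auto",
        fix_delta_caf: float | None = None,
        rtol: float = 1e-8,
        atol: float = 1e-6,
    ):
        self.gamma = gamma
        self.capacity = capacity
        self.q1 = q1
        self.q3 = q3
        self.delta_m2 = delta_m2
        self.kill_rate = kill_rate
        self.delta_tc = delta_tc
        self.method = method
        self.pooling = pooling
        self.midpoint_mode = midpoint_mode
        self.fix_delta_caf = fix_delta_caf
        self.rtol = rtol
        self.atol = atol

    # ------------------------------------------------------------------
    def known_parameters(self) -> KnownParameters:
        """The fixed-rate container implied by the constructor arguments."""
        return KnownParameters(
            gamma=self.gamma,
            K=self.capacity,
            q1=self.q1,
            q3=self.q3,
            delta_M2=self.delta_m2,
            k=self.kill_rate,
            delta_Tc=self.delta_tc,
        )

    def _coerce(self, X) -> list[MeasurementSeries]:
        if isinstance(X, pd.DataFrame):
            return series_from_frame(X)
        if isinstance(X, MeasurementSeries):
            return [X]
        X = list(X)
        if not all(isinstance(s, MeasurementSeries) for s in X):
            raise ValueError(
                "X must be a tidy DataFrame or a list of MeasurementSeries"
            )
        return X

    def _solve_one(self, series: list[MeasurementSeries], known: KnownParameters) -> FitResult:
        system = est_mod.assemble(series, known, self.midpoint_mode)
        if self.fix_delta_caf is not None:
            system = _fix_column(system, "delta_CAF", self.fix_delta_caf)
        res = est_mod.solve(system, self.method, keep_system=True)
        if self.fix_delta_caf is not None:
            q = res.q.copy()
            q[ESTIMATED_ORDER.index("delta_CAF")] = self.fix_delta_caf
            res = FitResult(
                q=q,
                method=res.method,
                residual_norm=res.residual_norm,
                rank=res.rank,
                block_ranks=res.block_ranks,
                block_cond=res.block_cond,
                warnings=res.warnings,
                system=res.system,
            )
        return res

    def fit(self, X, y=None) -> "TumorCompositionModel":
        """Estimate the interaction rates from measurements.

        ``X`` is either a tidy :class:`pandas.DataFrame` (columns
        ``patient_id``, ``day``, ``n``, ``m2``, ``caf``, ``tc``) or a list
        of :class:`MeasurementSeries`.  ``y`` is ignored (unsupervised fit).
        """
        series = self._coerce(X)
        if not series:
            raise est_mod.InsufficientDataError("no measurement series provided")
        known = self.known_parameters()

        if self.pooling == "pooled":
            res = self._solve_one(series, known)
            self.results_ = {"pooled": res}
            self.linear_system_ = res.system
            self.params_ = EstimatedParameters.from_array(np.clip(res.q, 0.0, None))
        elif self.pooling == "per_patient":
            self.results_ = {s.patient_id: self._solve_one([s], known) for s in series}
            first = next(iter(self.results_.values()))
            self.linear_system_ = None
            self.params_ = EstimatedParameters.from_array(np.clip(first.q, 0.0, None))
        else:
            raise ValueError(f"unknown pooling mode {self.pooling!r}")

        import warnings as _warnings

        for unit, res in self.results_.items():
            for msg in res.warnings:
                _warnings.warn(f"{unit}: {msg}", UserWarning, stacklevel=2)

        self.series_ = series
        self.initial_states_ = {
            s.patient_id: (float(s.times[0]), s.states[0].copy()) for s in series
        }
        self.n_rows_ = sum(4 * s.n_intervals for s in series)
        return self

    def _params_for(self, patient_id: str) -> EstimatedParameters:
        if self.pooling == "pooled":
            return self.params_
        res = self.results_[patient_id]
        return EstimatedParameters.from_array(np.clip(res.q, 0.0, None))

    def predict(self, X) -> pd.DataFrame:
        """Predict compartment abundances at the requested days.

        ``X`` is a 1-d array of days.  For every fitted patient the model is
        integrated forward from that patient's earliest measured state;
        requested days before the anchor are dropped.  Returns a tidy frame
        with columns ``patient_id``, ``day``, ``n``, ``m2``, ``caf``, ``tc``.
        """
        if not hasattr(self, "initial_states_"):
            raise RuntimeError("this TumorCompositionModel instance is not fitted yet")
        days = np.sort(np.unique(np.asarray(X, dtype=float).ravel()))
        known = self.known_parameters()
        frames = []
        for pid, (t0, z0) in self.initial_states_.items():
            t_out = days[days >= t0]
            if t_out.size == 0:
                continue
            if t_out[0] > t0:
                t_out = np.concatenate([[t0], t_out])
                drop_anchor = True
            else:
                drop_anchor = False
            traj = model_mod.simulate(
                z0, known, self._params_for(pid),
                t_out[0], t_out[-1], times=t_out,
                rtol=self.rtol, atol=self.atol,
            )
            df = pd.DataFrame(traj.states, columns=list(FRAME_COLUMNS))
            df.insert(0, "day", traj.times)
            df.insert(0, "patient_id", pid)
            if drop_anchor:
                df = df.iloc[1:]
            frames.append(df)
        return pd.concat(frames, ignore_index=True)

    def simulate_patient(self, patient_id: str, t_end: float, grid: float = 0.1):
        """Dense trajectory for one fitted patient from its anchor state."""
        t0, z0 = self.initial_states_[patient_id]
        return model_mod.simulate(
            z0, self.known_parameters(), self._params_for(patient_id),
            t0, t_end, grid=grid, rtol=self.rtol, atol=self.atol,
        )


def _fix_column(system, name: str, value: float):
    """Move one unknown's column to the right-hand side at a fixed value."""
    from .estimation import LinearSystem

    j = ESTIMATED_ORDER.index(name)
    A = system.A.copy()
    B = system.B - A[:, j] * value
    A[:, j] = 0.0
    return LinearSystem(A, B, system.row_provenance)
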