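"""Synthetic flow-cytometry-style cohorts with known ground truth.

Generates per-patient compartment time courses by forward simulation of the
interaction ODE from sampled initial states and interaction rates, reads
the trajectory at the measurement days, and corrupts each reading with
independent multiplicative lognormal noise — the positive, heteroscedastic
error structure typical of cytometry subpopulation quantification.

States are expressed in *abundance units* of order 10–100, the scale of
percentage-of-total flow readouts on which the default rate priors are
dynamically plausible (the model is scale-covariant: rescaling the state by
c rescales every per-cell rate by 1/c).  Count layouts are derived through
the per-sample total (50,000 seeded cells per gel dome by default).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import SimulationError, SpecificationError
from .estimation import MeasurementSeries
from .model import simulate
from .params import (
    COMPARTMENTS,
    ESTIMATED_ORDER,
    EstimatedParameters,
    KnownParameters,
)

#: Sampling intervals for the eight estimated rates (units: day^-1 on the
#: abundance scale); the calculated per-parameter ranges of the source study.
TRUTH_RANGES: dict[str, tuple[float, float]] = {
    "q2": (1.0e-4, 5.0e-3),
    "q4": (1.0e-4, 1.0e-3),
    "q5": (0.0, 1.0e-5),
    "q6": (1.0e-5, 1.0e-3),
    "delta_CAF": (0.1, 0.1),
    "q7": (9.0e-4, 1.5e-3),
    "q8": (0.0, 1.0e-5),
    "q9": (0.0, 1.0e-5),
}

#: Day-0 abundance ranges per compartment: a cancer-cell-dominant mix in
#: percent-of-total units (the four subpopulations cover well under 100%
#: of the seeded cells, the rest being unlabeled).
INITIAL_STATE_RANGES: dict[str, tuple[float, float]] = {
    "N": (35.0, 55.0),
    "M2": (4.0, 10.0),
    "CAF": (4.0, 10.0),
    "Tc": (2.0, 6.0),
}


@dataclass(frozen=True)
class CohortSpec:
    """Study-design description for one synthetic cohort.

    Defaults emulate the source study's conditions: 16 patients measured on
    days 7, 14 and 21, 50,000 seeded cells per sample, truth drawn from the
    published rate ranges, 5% multiplicative measurement noise.
    """

    n_patients: int = 16
    measurement_days: tuple[float, ...] = (7.0, 14.0, 21.0)
    total_cells: float = 50_000.0
    known: KnownParameters = field(default_factory=KnownParameters)
    truth_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(TRUTH_RANGES)
    )
    initial_state_ranges: dict[str, tuple[float, float]] = field(
        default_factory=lambda: dict(INITIAL_STATE_RANGES)
    )
    noise_cv: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 1:
            raise SpecificationError("n_patients must be >= 1")
        if self.noise_cv < 0:
            raise SpecificationError("noise_cv must be >= 0")
        days = tuple(float(d) for d in self.measurement_days)
        if len(days) < 2 or not all(b > a for a, b in zip(days, days[1:])):
            raise SpecificationError("measurement_days must be >= 2 strictly increasing days")
        if any(d < 0 for d in days):
            raise SpecificationError("measurement_days must be nonnegative")
        object.__setattr__(self, "measurement_days", days)
        for name, rng in {**self.truth_ranges, **self.initial_state_ranges}.items():
            lo, hi = rng
            if not (0 <= lo <= hi):
                raise SpecificationError(
                    f"range for {name!r} must satisfy 0 <= lower <= upper, got {rng}"
                )
        missing = set(ESTIMATED_ORDER) - set(self.truth_ranges)
        if missing:
            raise SpecificationError(f"truth_ranges missing parameters: {sorted(missing)}")


@dataclass(frozen=True)
class Cohort:
    """A generated cohort: measurement series plus its generating truth."""

    series: list[MeasurementSeries]
    truth: EstimatedParameters
    initial_states: np.ndarray  # (n_patients, 4), day-0 states
    spec: CohortSpec

    def to_frame(self, layout: str = "counts") -> pd.DataFrame:
        """Tabulate the cohort.

        Abundance units are percent-of-seeded-total, so one unit corresponds
        to ``spec.total_cells / 100`` cells.  ``counts`` layout: columns
        ``patient_id, day, n_cells, m2_cells, caf_cells, tc_cells`` with
        counts = state x that factor.  ``percentages`` layout: columns
        ``patient_id, day, pdl1_pct, cd206_pct, asma_pct, cd8_pct,
        total_cells`` where percentages are of the current four-compartment
        total (summing to 100) and ``total_cells`` carries that total in
        cells, so counts are reconstructed exactly on read.
        """
        rows = []
        u = self.spec.total_cells / 100.0  # cells per abundance unit
        for s in self.series:
            for ti, day in enumerate(s.times):
                z = s.states[ti]
                if layout == "counts":
                    rows.append(
                        {
                            "patient_id": s.patient_id,
                            "day": day,
                            "n_cells": z[0] * u,
                            "m2_cells": z[1] * u,
                            "caf_cells": z[2] * u,
                            "tc_cells": z[3] * u,
                        }
                    )
                elif layout == "percentages":
                    total = z.sum()
                    pct = 100.0 * z / total if total > 0 else np.zeros(4)
                    rows.append(
                        {
                            "patient_id": s.patient_id,
                            "day": day,
                            "pdl1_pct": pct[0],
                            "cd206_pct": pct[1],
                            "asma_pct": pct[2],
                            "cd8_pct": pct[3],
                            "total_cells": total * u,
                        }
                    )
                else:
                    raise ValueError(f"unknown layout {layout!r}")
        return pd.DataFrame(rows)


def _rngs(spec: CohortSpec):
    # Independent, reproducible streams so that supplying an explicit truth
    # does not shift the initial-state or noise draws.
    return (
        np.random.default_rng([spec.seed, 0]),  # truth
        np.random.default_rng([spec.seed, 1]),  # initial states
        np.random.default_rng([spec.seed, 2]),  # measurement noise
    )


def sample_truth(spec: CohortSpec) -> tuple[EstimatedParameters, np.ndarray]:
    """Draw one shared truth vector and per-patient day-0 states.

    Each rate is uniform on its range; initial states are uniform on the
    per-compartment ranges.  Pure function of ``spec`` (including its seed).
    """
    rng_truth, rng_init, _ = _rngs(spec)
    truth = EstimatedParameters(
        **{
            name: float(rng_truth.uniform(*spec.truth_ranges[name]))
            for name in ESTIMATED_ORDER
        }
    )
    initials = np.column_stack(
        [
            rng_init.uniform(*spec.initial_state_ranges[c], size=spec.n_patients)
            for c in COMPARTMENTS
        ]
    )
    return truth, initials


def generate_cohort(
    spec: CohortSpec,
    truth: EstimatedParameters | None = None,
    initial_states: np.ndarray | None = None,
) -> Cohort:
    """Simulate a cohort of measurement series under a (sampled) truth.

    Per patient: integrate the ODE from the day-0 state through the last
    measurement day, read the state at each measurement day, and multiply
    each compartment reading independently by mean-one lognormal noise with
    coefficient of variation ``spec.noise_cv``.
    """
    sampled_truth, sampled_init = sample_truth(spec)
    truth = sampled_truth if truth is None else truth
    initials = sampled_init if initial_states is None else np.asarray(initial_states, float)
    if initials.shape != (spec.n_patients, 4):
        raise SpecificationError(
            f"initial_states must have shape ({spec.n_patients}, 4), got {initials.shape}"
        )
    _, _, rng_noise = _rngs(spec)
    days = np.asarray(spec.measurement_days)
    t_grid = np.unique(np.concatenate([[0.0], days]))

    if spec.noise_cv > 0:
        sigma = float(np.sqrt(np.log1p(spec.noise_cv**2)))
    else:
        sigma = 0.0

    series = []
    for p in range(spec.n_patients):
        pid = f"P{p + 1:02d}"
        try:
            traj = simulate(
                initials[p], spec.known, truth, t_grid[0], t_grid[-1], times=t_grid
            )
        except SimulationError as err:
            raise SimulationError(f"patient {pid}: {err}") from err
        idx = np.searchsorted(t_grid, days)
        clean = traj.states[idx]
        if sigma > 0:
            factors = rng_noise.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=clean.shape)
            noisy = np.clip(clean * factors, 0.0, None)
        else:
            noisy = clean
        series.append(MeasurementSeries(pid, days, noisy))
    return Cohort(series=series, truth=truth, initial_states=initials, spec=spec)


def write_cohort(
    cohort: Cohort,
    path: str | Path,
    format: str | None = None,
    layout: str = "counts",
    truth_path: str | Path | None = None,
) -> Path:
    """Write a cohort table to CSV or Excel (sheet 1), optionally with a
    ground-truth JSON sidecar for recovery scoring.

    The written file round-trips through
    :func:`organofit.io.read_measurements`.
    """
    if not cohort.series:
        raise ValueError("cannot write an empty cohort")
    path = Path(path)
    if format is None:
        format = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    df = cohort.to_frame(layout)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        raise ValueError(f"unknown format {format!r}")
    if truth_path is not None:
        payload = {
            "truth": dict(zip(ESTIMATED_ORDER, map(float, cohort.truth.to_array()))),
            "seed": cohort.spec.seed,
            "noise_cv": cohort.spec.noise_cv,
            "measurement_days": list(cohort.spec.measurement_days),
            "initial_states": cohort.initial_states.tolist(),
        }
        Path(truth_path).write_text(json.dumps(payload, indent=2, sort_keys=True))
    return path
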