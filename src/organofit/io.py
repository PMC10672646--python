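"""Reading measurement tables and writing fit/prediction artifacts.

Two tabular layouts are accepted, from CSV or Excel (first sheet):

* counts: ``patient_id, day, n_cells, m2_cells, caf_cells, tc_cells``
* percentages: ``patient_id, day, pdl1_pct, cd206_pct, asma_pct, cd8_pct``
  plus ``total_cells`` (per row, or supplied as a default), converted on
  read via ``count = pct / 100 * total_cells``.

Biomarker-to-compartment mapping: PD-L1+ -> cancer cells (N), CD206+ ->
M2 macrophages, aSMA+ -> CAFs, CD8+ -> cytotoxic T cells.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataValidationError
from .estimation import MeasurementSeries
from .model import Trajectory, composition_fractions
from .params import COMPARTMENTS

COUNT_COLUMNS = ("n_cells", "m2_cells", "caf_cells", "tc_cells")
PCT_COLUMNS = ("pdl1_pct", "cd206_pct", "asma_pct", "cd8_pct")
DEFAULT_TOTAL_CELLS = 50_000.0


def _read_table(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise DataValidationError(f"input file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm", ".xls"):
        return pd.read_excel(path, sheet_name=0, engine="openpyxl")
    return pd.read_csv(path)


def read_measurements(
    path: str | Path,
    layout: str = "auto",
    total: float | None = None,
    cells_per_unit: float | None = None,
) -> list[MeasurementSeries]:
    """Read and validate per-patient measurement series.

    Parameters
    ----------
    layout : {"auto", "counts", "percentages"}
        ``auto`` detects the layout from the columns present.
    total : float, optional
        Default per-sample total cell count for the percentage layout when
        the table has no ``total_cells`` column (defaults to 50,000).
    cells_per_unit : float, optional
        Divide all cell counts by this factor after reading, changing the
        working scale of the state.  The model is scale-covariant and the
        default literature rates are calibrated for states of order 10-100
        (percent-of-seeded-total units), so raw counts from a 50,000-cell
        sample are typically analyzed with ``cells_per_unit=500``.

    Raises
    ------
    DataValidationError
        Missing columns, negative values, duplicated (patient, day) rows,
        or a patient with fewer than two time points.
    """
    df = _read_table(path).reset_index(drop=True)
    df.columns = [str(c).strip().lower() for c in df.columns]
    base = {"patient_id", "day"}
    if missing := base - set(df.columns):
        raise DataValidationError(f"missing required columns: {sorted(missing)}")

    if layout == "auto":
        if set(COUNT_COLUMNS) <= set(df.columns):
            layout = "counts"
        elif set(PCT_COLUMNS) <= set(df.columns):
            layout = "percentages"
        else:
            raise DataValidationError(
                f"could not detect layout: expected columns {COUNT_COLUMNS} "
                f"or {PCT_COLUMNS}"
            )

    if layout == "counts":
        cols = COUNT_COLUMNS
        if missing := set(cols) - set(df.columns):
            raise DataValidationError(f"missing count columns: {sorted(missing)}")
        values = df[list(cols)].to_numpy(dtype=float)
    elif layout == "percentages":
        cols = PCT_COLUMNS
        if missing := set(cols) - set(df.columns):
            raise DataValidationError(f"missing percentage columns: {sorted(missing)}")
        pct = df[list(cols)].to_numpy(dtype=float)
        if "total_cells" in df.columns:
            totals = df["total_cells"].to_numpy(dtype=float)
        else:
            totals = np.full(len(df), DEFAULT_TOTAL_CELLS if total is None else total)
        if np.any(~np.isfinite(totals)) or np.any(totals <= 0):
            raise DataValidationError("total_cells must be finite and > 0")
        values = pct / 100.0 * totals[:, None]
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if cells_per_unit is not None:
        if not np.isfinite(cells_per_unit) or cells_per_unit <= 0:
            raise DataValidationError("cells_per_unit must be finite and > 0")
        values = values / cells_per_unit

    if np.any(~np.isfinite(values)):
        raise DataValidationError("measurements contain non-finite values")
    if np.any(values < 0):
        raise DataValidationError("measurements contain negative values")

    days = df["day"].to_numpy(dtype=float)
    if np.any(~np.isfinite(days)):
        raise DataValidationError("day column contains non-finite values")
    series: list[MeasurementSeries] = []
    for pid, grp in df.groupby("patient_id", sort=True):
        order = np.array(sorted(grp.index, key=lambda i: days[i]), dtype=int)
        t = days[order]
        if np.unique(t).size != t.size:
            raise DataValidationError(
                f"patient {pid!r} has duplicate (patient, day) rows"
            )
        if t.size < 2:
            raise DataValidationError(
                f"patient {pid!r} has a single time point; measurements from "
                f"two time points at least are required"
            )
        series.append(MeasurementSeries(str(pid), t, values[order]))
    return series


def trajectory_frame(traj: Trajectory, patient_id: str | None = None) -> pd.DataFrame:
    """Tidy CSV-ready view of a trajectory: one row per (time, compartment)
    with both the abundance and the composition fraction."""
    frac = composition_fractions(traj)
    rows = []
    for ti, t in enumerate(traj.times):
        for j, comp in enumerate(COMPARTMENTS):
            row = {
                "time_day": float(t),
                "compartment": comp,
                "count": float(traj.states[ti, j]),
                "fraction": float(frac[ti, j]),
            }
            if patient_id is not None:
                row = {"patient_id": patient_id, **row}
            rows.append(row)
    return pd.DataFrame(rows)
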