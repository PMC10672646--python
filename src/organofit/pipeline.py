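"""End-to-end fit-and-predict workflow behind the command line.

Reads measurements, fits the interaction rates, simulates each patient's
composition forward through a prediction window anchored at its earliest
measured state, and writes a report bundle: fitted parameters with
diagnostics and provenance, tidy trajectory and extrema tables, per-patient
fraction plots, and a deterministic machine-readable JSON summary.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .estimation import FitResult
from .estimator import TumorCompositionModel
from .exceptions import OrganofitError
from .io import read_measurements, trajectory_frame
from .model import composition_fractions, find_local_extrema
from .params import COMPARTMENTS, ESTIMATED_ORDER, KnownParameters

log = logging.getLogger("organofit")

KNOWN_FIELDS = ("gamma", "K", "q1", "q3", "delta_M2", "k", "delta_Tc")


@dataclass
class RunConfig:
    """Configuration of one pipeline run (mirrors the CLI flags)."""

    input_path: str
    output_dir: str = "organofit_out"
    layout: str = "auto"
    total_cells: float | None = None
    cells_per_unit: float | None = None
    known_overrides: dict[str, float] = field(default_factory=dict)
    pooling: str = "pooled"
    method: str = "nonnegative"
    midpoint_mode: str = "auto"
    fix_delta_caf: float | None = None
    predict_from: float = 7.0
    predict_to: float = 14.0
    grid: float = 0.25
    make_plots: bool = True
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


def _known_from_config(config: RunConfig) -> tuple[KnownParameters, dict[str, str]]:
    known = KnownParameters()
    provenance = {name: "table-default" for name in KNOWN_FIELDS}
    if config.known_overrides:
        bad = set(config.known_overrides) - set(KNOWN_FIELDS)
        if bad:
            raise ValueError(f"unknown parameter overrides: {sorted(bad)}")
        known = known.replace(**config.known_overrides)
        for name in config.known_overrides:
            provenance[name] = "config"
    return known, provenance


def run_fit_predict(config: RunConfig) -> dict:
    """Run the full workflow and write the report bundle.

    One malformed patient does not abort the run: its failure is logged and
    recorded in the summary while the remaining patients are processed.
    Returns the JSON-serializable summary dict.
    """
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    _setup_logging(out_dir / "run.log", config.log_level)

    series = read_measurements(
        config.input_path, config.layout, config.total_cells,
        cells_per_unit=config.cells_per_unit,
    )
    log.info("read %d patient series from %s", len(series), config.input_path)

    known, known_prov = _known_from_config(config)
    for name in KNOWN_FIELDS:
        log.info("known parameter %s = %g (%s)", name, getattr(known, name), known_prov[name])

    measured_span = (
        min(float(s.times[0]) for s in series),
        max(float(s.times[-1]) for s in series),
    )
    window_warning = None
    if config.predict_from < measured_span[0] or config.predict_to > measured_span[1]:
        window_warning = (
            f"prediction window [{config.predict_from}, {config.predict_to}] extends "
            f"outside the measured span [{measured_span[0]}, {measured_span[1]}]; "
            f"accuracy degrades outside the measured interval"
        )
        log.warning(window_warning)

    model = TumorCompositionModel(
        gamma=known.gamma,
        capacity=known.K,
        q1=known.q1,
        q3=known.q3,
        delta_m2=known.delta_M2,
        kill_rate=known.k,
        delta_tc=known.delta_Tc,
        method=config.method,
        pooling=config.pooling,
        midpoint_mode=config.midpoint_mode,
        fix_delta_caf=config.fix_delta_caf,
    )

    summary: dict = {
        "organofit_version": __version__,
        "input": str(config.input_path),
        "pooling": config.pooling,
        "method": config.method,
        "midpoint_mode": config.midpoint_mode,
        "prediction_window": [config.predict_from, config.predict_to],
        "window_warning": window_warning,
        "parameters": {
            "known": {
                name: {"value": float(getattr(known, name)), "source": known_prov[name]}
                for name in KNOWN_FIELDS
            }
        },
        "patients": {},
        "failures": {},
    }

    if config.pooling == "pooled":
        model.fit(series)
        summary["parameters"]["fitted"] = _fitted_entry(model.results_["pooled"])
    else:
        # Fit patients one at a time so a malformed series cannot abort the rest.
        fitted_units: dict = {}
        good_series = []
        for s in series:
            try:
                sub = TumorCompositionModel(**model.get_params()).fit([s])
                fitted_units[s.patient_id] = sub.results_[s.patient_id]
                good_series.append(s)
            except OrganofitError as err:
                log.error("patient %s failed to fit: %s", s.patient_id, err)
                summary["failures"][s.patient_id] = str(err)
        if not good_series:
            raise OrganofitError("no patient could be fitted")
        model.fit(good_series)
        model.results_ = fitted_units
        summary["parameters"]["fitted"] = {
            pid: _fitted_entry(res) for pid, res in fitted_units.items()
        }

    traj_frames = []
    extrema_rows = []
    t_end = max(config.predict_to, measured_span[1])
    for s in model.series_:
        pid = s.patient_id
        try:
            traj = model.simulate_patient(pid, t_end, grid=config.grid)
        except OrganofitError as err:
            log.error("patient %s failed to simulate: %s", pid, err)
            summary["failures"][pid] = str(err)
            continue
        traj_frames.append(trajectory_frame(traj, patient_id=pid))
        patient_extrema = {}
        for comp in COMPARTMENTS:
            ext = [
                e
                for e in find_local_extrema(traj, comp)
                if config.predict_from <= e.time <= config.predict_to
            ]
            patient_extrema[comp] = [
                {"time_day": round(e.time, 6), "value": round(e.value, 6), "kind": e.kind}
                for e in ext
            ]
            extrema_rows.extend(
                {"patient_id": pid, "compartment": comp, **d} for d in patient_extrema[comp]
            )
        frac = composition_fractions(traj)
        summary["patients"][pid] = {
            "anchor_day": float(s.times[0]),
            "anchor_state": [float(v) for v in s.states[0]],
            "fractions_at_window_end": {
                comp: round(float(frac[np.searchsorted(traj.times, min(config.predict_to, traj.times[-1])), j]), 6)
                for j, comp in enumerate(COMPARTMENTS)
            },
            "extrema_in_window": patient_extrema,
        }
        if config.make_plots:
            _plot_patient(traj, pid, out_dir / f"fractions_{pid}.png", config)

    import pandas as pd

    if traj_frames:
        pd.concat(traj_frames, ignore_index=True).to_csv(
            out_dir / "trajectories.csv", index=False
        )
    pd.DataFrame(
        extrema_rows, columns=["patient_id", "compartment", "time_day", "value", "kind"]
    ).to_csv(out_dir / "extrema.csv", index=False)

    (out_dir / "params.json").write_text(
        json.dumps(summary["parameters"], indent=2, sort_keys=True) + "\n"
    )
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("wrote report bundle to %s", out_dir)
    return summary


def _fitted_entry(res: FitResult) -> dict:
    return {
        "values": {
            name: {"value": float(v), "source": "fitted"}
            for name, v in zip(ESTIMATED_ORDER, res.q)
        },
        "diagnostics": {
            "method": res.method,
            "residual_norm": float(res.residual_norm),
            "rank": res.rank,
            "block_ranks": res.block_ranks,
            "block_condition": {
                k: (None if not np.isfinite(v) else float(v))
                for k, v in res.block_cond.items()
            },
            "warnings": list(res.warnings),
        },
    }


def _plot_patient(traj, pid: str, path: Path, config: RunConfig) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = composition_fractions(traj)
    fig, ax = plt.subplots(figsize=(5, 3.5))
    labels = {"N": "PD-L1 (cancer)", "M2": "CD206 (M2)", "CAF": "aSMA (CAF)", "Tc": "CD8 (Tc)"}
    for j, comp in enumerate(COMPARTMENTS):
        ax.plot(traj.times, frac[:, j], label=labels[comp])
    ax.axvspan(config.predict_from, config.predict_to, alpha=0.08, color="gray")
    ax.set_xlabel("day")
    ax.set_ylabel("composition fraction")
    ax.set_title(f"patient {pid}")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _setup_logging(logfile: Path, level: str) -> None:
    log.setLevel(getattr(logging, level.upper(), logging.INFO))
    for h in list(log.handlers):
        log.removeHandler(h)
    fh = logging.FileHandler(logfile, mode="w")
    fh.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(fh)
    log.addHandler(logging.StreamHandler())
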