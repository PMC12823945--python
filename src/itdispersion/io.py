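"""File formats: long-format CSV for records/fields/series, JSON for results.

All tabular artifacts are plain CSV with documented headers; structured
results (estimates, fits, manifests) are JSON.  Readers validate the
schema and re-sort rows into canonical (time, position) order, so
round-trips are lossless and row order in files is immaterial.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from itdispersion.correlations import CorrelationFit, ExperimentSummary
from itdispersion.diffusion import ConcentrationField
from itdispersion.inversion import DispersionEstimate
from itdispersion.moments import MomentSeries
from itdispersion.synthetic import IntensityRecord

RECORD_COLUMNS = ["time_min", "x_cm", "intensity"]
FIELD_COLUMNS = ["time_min", "x_cm", "value"]
MOMENT_COLUMNS = ["time_min", "m1_cm", "m2_left_cm2", "total_intensity"]
SUMMARY_COLUMNS = [
    "frequency_bpm",
    "stroke_volume_ml",
    "urms_cm_s",
    "alpha",
    "pe",
    "eps_amp",
    "d_exp_cm2_min",
    "ccv_cm_min",
]


class SchemaError(ValueError):
    """A file does not conform to its documented schema."""


def _require_columns(frame: pd.DataFrame, columns, what: str) -> None:
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise SchemaError(f"{what} is missing columns: {missing}")


def write_intensity_record(record: IntensityRecord, path) -> None:
    """Write a record as long-format CSV plus a JSON metadata sidecar."""
    path = Path(path)
    times = np.repeat(record.times, record.positions.size)
    xs = np.tile(record.positions, record.times.size)
    frame = pd.DataFrame(
        {"time_min": times, "x_cm": xs, "intensity": record.intensities.ravel()}
    )
    frame.to_csv(path, index=False)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    sidecar.write_text(json.dumps(record.metadata, indent=2, default=float))


def read_intensity_record(path) -> IntensityRecord:
    """Read a long-format record CSV (and its metadata sidecar if present)."""
    path = Path(path)
    frame = pd.read_csv(path)
    _require_columns(frame, RECORD_COLUMNS, f"record {path.name}")
    if (frame["intensity"] < 0).any():
        raise SchemaError(f"record {path.name} contains negative intensities")
    frame = frame.sort_values(["time_min", "x_cm"], kind="mergesort")
    times = np.array(sorted(frame["time_min"].unique()))
    positions = np.array(sorted(frame["x_cm"].unique()))
    if len(frame) != times.size * positions.size:
        raise SchemaError(
            f"record {path.name} is not a complete time x position grid"
        )
    intensities = frame["intensity"].to_numpy().reshape(times.size, positions.size)
    sidecar = path.with_suffix(path.suffix + ".meta.json")
    metadata = json.loads(sidecar.read_text()) if sidecar.exists() else {}
    return IntensityRecord(
        times=times, positions=positions, intensities=intensities, metadata=metadata
    )


def write_concentration_field(field: ConcentrationField, path) -> None:
    times = np.repeat(field.times, field.grid.n_cells)
    xs = np.tile(field.grid.cell_centers, field.times.size)
    pd.DataFrame(
        {"time_min": times, "x_cm": xs, "value": field.values.ravel()}
    ).to_csv(path, index=False)


def write_moment_series(series: MomentSeries, path) -> None:
    pd.DataFrame(
        {
            "time_min": series.times,
            "m1_cm": series.m1,
            "m2_left_cm2": series.m2_left,
            "total_intensity": series.total_intensity,
        }
    ).to_csv(path, index=False)


def read_moment_series(path) -> MomentSeries:
    frame = pd.read_csv(path)
    _require_columns(frame, MOMENT_COLUMNS, f"moment series {Path(path).name}")
    frame = frame.sort_values("time_min", kind="mergesort")
    return MomentSeries(
        times=frame["time_min"].to_numpy(),
        m1=frame["m1_cm"].to_numpy(),
        m2_left=frame["m2_left_cm2"].to_numpy(),
        total_intensity=frame["total_intensity"].to_numpy(),
    )


def write_summaries(summaries, path) -> None:
    rows = [
        {
            "frequency_bpm": s.frequency,
            "stroke_volume_ml": s.stroke_volume,
            "urms_cm_s": s.urms,
            "alpha": s.womersley,
            "pe": s.peclet,
            "eps_amp": s.amplitude_ratio,
            "d_exp_cm2_min": s.d_exp,
            "ccv_cm_min": s.ccv,
        }
        for s in summaries
    ]
    pd.DataFrame(rows, columns=SUMMARY_COLUMNS).to_csv(path, index=False)


def read_summaries(path) -> list[ExperimentSummary]:
    frame = pd.read_csv(path)
    _require_columns(frame, SUMMARY_COLUMNS, f"summary table {Path(path).name}")
    return [
        ExperimentSummary(
            frequency=float(row.frequency_bpm),
            stroke_volume=float(row.stroke_volume_ml),
            urms=float(row.urms_cm_s),
            womersley=float(row.alpha),
            peclet=float(row.pe),
            amplitude_ratio=float(row.eps_amp),
            d_exp=float(row.d_exp_cm2_min),
            ccv=None if pd.isna(row.ccv_cm_min) else float(row.ccv_cm_min),
        )
        for row in frame.itertuples()
    ]


def estimate_to_dict(estimate: DispersionEstimate) -> dict:
    return dataclasses.asdict(estimate)


def write_estimate(estimate: DispersionEstimate, path, config_echo: dict | None = None) -> None:
    payload = estimate_to_dict(estimate)
    if config_echo is not None:
        payload["config"] = config_echo
    Path(path).write_text(json.dumps(payload, indent=2, default=float))


def fit_to_dict(fit: CorrelationFit) -> dict:
    return {
        "model": fit.model,
        "coefficients": fit.coefficients,
        "r_squared": fit.r_squared,
        "n": fit.n,
    }


def write_fit(fit: CorrelationFit, path) -> None:
    Path(path).write_text(json.dumps(fit_to_dict(fit), indent=2, default=float))
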