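"""Delimited-text readers and writers for every pipeline artefact.

All tabular interchange is CSV with a header row, decimal point, and
concentrations in ou/m^3.  Writers and readers are inverse on valid
documents (write-then-read round-trips exactly: floats are serialized with
Python's shortest-repr rule).  Sensor-log sample times are serialized as
seconds from the start of each exposure window in a ``time_s`` column.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .calibration import CalibrationResults
from .errors import ParseError
from .evaluation import EvaluationReport
from .features import ExposureWindow, FeatureVector
from .olfactometry import OlfactometrySession, build_session
from .synthetic import StudyBundle

__all__ = [
    "write_sensor_log",
    "read_sensor_log",
    "write_sessions",
    "read_sessions",
    "write_session_summary",
    "write_features",
    "read_features",
    "write_model",
    "read_model",
    "write_report",
    "write_truth",
    "read_truth",
    "write_study",
    "read_study",
]

PathLike = Union[str, Path]


def _require_columns(table: pd.DataFrame, required: Sequence[str], path: PathLike) -> None:
    missing = [c for c in required if c not in table.columns]
    if missing:
        raise ParseError(f"{path}: missing column(s) {missing}")


# -- sensor logs ------------------------------------------------------------


def write_sensor_log(windows: Sequence[ExposureWindow], path: PathLike) -> None:
    """One row per sample: window_id, time_s, one column per channel,
    clean_air flag for samples inside the flagged baseline segment."""
    frames = []
    for w in windows:
        frame = w.signals.copy()
        frame.insert(0, "window_id", w.window_id)
        frame.insert(1, "time_s", w.timestamps)
        clean = np.zeros(len(frame), dtype=bool)
        if w.baseline_segment is not None:
            clean[w.baseline_segment[0] : w.baseline_segment[1]] = True
        frame["clean_air"] = clean
        frames.append(frame)
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_sensor_log(path: PathLike) -> list[ExposureWindow]:
    table = pd.read_csv(path, float_precision="round_trip")
    _require_columns(table, ["window_id", "time_s"], path)
    channel_cols = [c for c in table.columns if c not in ("window_id", "time_s", "clean_air")]
    if not channel_cols:
        raise ParseError(f"{path}: no channel columns found")
    windows = []
    for wid, group in table.groupby("window_id", sort=False):
        clean = group["clean_air"].to_numpy(dtype=bool) if "clean_air" in group else None
        segment = None
        if clean is not None and clean.any():
            idx = np.flatnonzero(clean)
            if not np.array_equal(idx, np.arange(idx[0], idx[-1] + 1)):
                raise ParseError(
                    f"{path}: window {wid!r} clean_air flags are not contiguous"
                )
            segment = (int(idx[0]), int(idx[-1]) + 1)
        windows.append(
            ExposureWindow(
                window_id=str(wid),
                timestamps=group["time_s"].to_numpy(dtype=float),
                signals=group[channel_cols].reset_index(drop=True),
                baseline_segment=segment,
            )
        )
    return windows


# -- olfactometry sessions --------------------------------------------------

_SESSION_COLUMNS = ["session_id", "timestamp", "assessor_id", "dt_yes", "dt_no"]


def write_sessions(sessions: Sequence[OlfactometrySession], path: PathLike) -> None:
    """One row per assessor reading, with the session's annotations repeated."""
    rows = []
    for s in sessions:
        for r in s.readings:
            rows.append(
                {
                    "session_id": s.session_id,
                    "timestamp": s.timestamp,
                    "assessor_id": r.assessor_id,
                    "dt_yes": r.dt_yes,
                    "dt_no": r.dt_no,
                    "intensity": s.intensity,
                    "hedonic": s.hedonic,
                }
            )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions(path: PathLike, on_small_panel: str = "raise") -> list[OlfactometrySession]:
    table = pd.read_csv(path, float_precision="round_trip")
    _require_columns(table, _SESSION_COLUMNS, path)
    sessions = []
    for sid, group in table.groupby("session_id", sort=False):
        from .olfactometry import AssessorReading

        readings = [
            AssessorReading(str(row.assessor_id), float(row.dt_yes), float(row.dt_no))
            for row in group.itertuples()
        ]
        first = group.iloc[0]

        def _opt(name):
            if name in group.columns and pd.notna(first[name]):
                return float(first[name])
            return None

        sessions.append(
            build_session(
                readings,
                session_id=str(sid),
                timestamp=str(first["timestamp"]),
                intensity=_opt("intensity"),
                hedonic=_opt("hedonic"),
                on_small_panel=on_small_panel,
            )
        )
    return sessions


def write_session_summary(sessions: Sequence[OlfactometrySession], path: PathLike) -> None:
    """Per-session digest: number of readings, each ZITE, and the C_od."""
    rows = [
        {
            "session_id": s.session_id,
            "timestamp": s.timestamp,
            "n_assessors": len(s.readings),
            "zite_values": ";".join(repr(z) for z in s.zite_values),
            "cod": s.cod,
        }
        for s in sessions
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# -- feature tables ---------------------------------------------------------


def write_features(features: Sequence[FeatureVector], path: PathLike) -> None:
    rows = []
    for f in features:
        row = {"window_id": f.window_id, "mode": f.mode}
        row.update({c: f.values[c] for c in f.values.index})
        row.update({f"smax_raw_{c}": f.smax_raw[c] for c in f.smax_raw.index})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_features(
    path: PathLike, expected_channels: Optional[Sequence[str]] = None
) -> list[FeatureVector]:
    table = pd.read_csv(path, float_precision="round_trip")
    _require_columns(table, ["window_id", "mode"], path)
    value_cols = [
        c for c in table.columns
        if c not in ("window_id", "mode") and not c.startswith("smax_raw_")
    ]
    if expected_channels is not None:
        unknown = [c for c in value_cols if c not in expected_channels]
        missing = [c for c in expected_channels if c not in value_cols]
        if unknown or missing:
            raise ParseError(
                f"{path}: channel mismatch (unknown {unknown}, missing {missing})"
            )
    features = []
    for row in table.itertuples(index=False):
        d = row._asdict()
        features.append(
            FeatureVector(
                window_id=str(d["window_id"]),
                mode=str(d["mode"]),
                values=pd.Series({c: float(d[c]) for c in value_cols}),
                smax_raw=pd.Series(
                    {c: float(d[f"smax_raw_{c}"]) for c in value_cols
                     if f"smax_raw_{c}" in d}
                ),
            )
        )
    return features


# -- models and reports -----------------------------------------------------


def write_model(results: CalibrationResults, path: PathLike) -> None:
    Path(path).write_text(results.to_json() + "\n")


def read_model(path: PathLike) -> CalibrationResults:
    try:
        return CalibrationResults.from_json(Path(path).read_text())
    except (json.JSONDecodeError, KeyError) as exc:
        raise ParseError(f"{path}: not a valid model document ({exc})") from exc


def write_report(report: EvaluationReport, path: PathLike) -> None:
    Path(path).write_text(report.to_json() + "\n")


# -- truth sidecar and whole studies ---------------------------------------


def write_truth(truth: pd.DataFrame, path: PathLike) -> None:
    truth.to_csv(path, index=False)


def read_truth(path: PathLike) -> pd.DataFrame:
    table = pd.read_csv(path, float_precision="round_trip")
    _require_columns(table, ["session_id", "cod_true"], path)
    return table


def write_study(bundle: StudyBundle, directory: PathLike) -> None:
    """Serialize a study bundle into a ready-to-run directory:
    sensor_log.csv, sessions.csv, split.csv, truth.csv and a config echo."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_sensor_log(bundle.windows, directory / "sensor_log.csv")
    write_sessions(bundle.sessions, directory / "sessions.csv")
    write_session_summary(bundle.sessions, directory / "session_summary.csv")
    write_truth(bundle.truth, directory / "truth.csv")
    pd.DataFrame(
        {
            "session_id": [s.session_id for s in bundle.sessions],
            "split": bundle.split,
        }
    ).to_csv(directory / "split.csv", index=False)
    from dataclasses import asdict

    config = asdict(bundle.config)
    config["channels"] = [dict(c) if isinstance(c, dict) else c for c in config["channels"]]
    (directory / "config.json").write_text(json.dumps(config, indent=2) + "\n")


def read_study(directory: PathLike) -> tuple[list[OlfactometrySession], list[ExposureWindow], np.ndarray]:
    """Load sessions, windows and the split from a study directory."""
    directory = Path(directory)
    sessions = read_sessions(directory / "sessions.csv")
    windows = read_sensor_log(directory / "sensor_log.csv")
    split_table = pd.read_csv(directory / "split.csv")
    _require_columns(split_table, ["session_id", "split"], directory / "split.csv")
    order = {s.session_id: i for i, s in enumerate(sessions)}
    split = np.empty(len(sessions), dtype=object)
    for row in split_table.itertuples(index=False):
        if row.session_id not in order:
            raise ParseError(f"split.csv references unknown session {row.session_id!r}")
        split[order[row.session_id]] = row.split
    if any(s is None for s in split):
        raise ParseError("split.csv does not cover every session")
    return sessions, windows, split
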