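"""Readers and writers for the three session input conventions.

* Photometry: delimited text (CSV/TSV) with a header row, one time column and
  one column per excitation channel; an HDF5 reader covers vendor-style
  exports with configurable dataset paths.
* Events: a one-row sheet (CSV or xlsx) with ``start``/``end`` for the trial
  and ``start1``/``end1`` ... ``startN``/``endN`` per event, plus free-text
  metadata columns (``odorant``, ``hedonics``, ``condition``); an optional
  ``type`` column (or per-event ``typeN``) labels the event kind. Header
  matching is case-insensitive.
* Tracking: CSV with ``frame,x,y``; an adapter maps DeepLabCut multi-header
  CSV (scorer / bodyparts / coords rows) onto the same table.

All loaders are total on their error cases: malformed input raises a typed
error, never returns a partially filled object.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

from .core import ALL_ROLES, Event, EventTable, PhotometryRecording, TrackingTable
from .errors import FormatError, ValidationError

#: Default column names in photometry exports, keyed by channel role.
DEFAULT_CHANNEL_MAP = {
    "sensor_465": "465",
    "sensor_565": "565",
    "isosbestic_405": "405",
}

_FLOAT_FMT = "%.17g"  # round-trips float64 exactly


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","


# ---------------------------------------------------------------------------
# photometry


def read_photometry(
    path: str | Path,
    channel_map: Mapping[str, str] | None = None,
    *,
    time_column: str = "time",
    session_id: str | None = None,
    uniformity_rtol: float = 1e-6,
) -> PhotometryRecording:
    """Load a delimited-text photometry export.

    ``channel_map`` maps channel roles (``sensor_465``, ``sensor_565``,
    ``isosbestic_405``) to column names; roles absent from the map are not
    loaded. The sampling rate is inferred from the median time step.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    cmap = dict(channel_map) if channel_map is not None else dict(DEFAULT_CHANNEL_MAP)
    for role in cmap:
        if role not in ALL_ROLES:
            raise FormatError(f"unknown channel role {role!r}; expected one of {ALL_ROLES}")
    df = pd.read_csv(path, sep=_sep_for(path), float_precision="round_trip")
    cols = {c.strip().lower(): c for c in df.columns}
    if time_column.lower() not in cols:
        raise FormatError(f"{path.name}: missing time column {time_column!r}")
    channels = {}
    for role, col in cmap.items():
        key = col.strip().lower()
        if key not in cols:
            raise FormatError(f"{path.name}: missing channel column {col!r} (role {role})")
        channels[role] = df[cols[key]].to_numpy(dtype=float)
    return PhotometryRecording(
        time=df[cols[time_column.lower()]].to_numpy(dtype=float),
        channels=channels,
        session_id=session_id if session_id is not None else path.stem,
        uniformity_rtol=uniformity_rtol,
    )


def write_photometry(rec: PhotometryRecording, path: str | Path) -> None:
    """Write a recording as delimited text, columns named by the default
    export convention (roles not in the convention keep their role name)."""
    path = Path(path)
    inv = {role: col for role, col in DEFAULT_CHANNEL_MAP.items()}
    data = {"time": rec.time}
    for role, trace in rec.channels.items():
        data[inv.get(role, role)] = trace
    pd.DataFrame(data).to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


def read_photometry_hdf5(
    path: str | Path,
    *,
    time_path: str,
    channel_paths: Mapping[str, str],
    session_id: str | None = None,
    uniformity_rtol: float = 1e-6,
) -> PhotometryRecording:
    """Load photometry from an HDF5 export; dataset paths are configurable
    because vendor layouts vary."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    with h5py.File(path, "r") as f:
        if time_path not in f:
            raise FormatError(f"{path.name}: missing dataset {time_path!r}")
        time = np.asarray(f[time_path], dtype=float)
        channels = {}
        for role, dpath in channel_paths.items():
            if dpath not in f:
                raise FormatError(f"{path.name}: missing dataset {dpath!r} (role {role})")
            channels[role] = np.asarray(f[dpath], dtype=float)
    return PhotometryRecording(
        time=time,
        channels=channels,
        session_id=session_id if session_id is not None else path.stem,
        uniformity_rtol=uniformity_rtol,
    )


# ---------------------------------------------------------------------------
# event sheets

_START_RE = re.compile(r"^start(\d+)$")
_END_RE = re.compile(r"^end(\d+)$")
_TYPE_RE = re.compile(r"^type(\d+)$")


def _read_sheet_row(path: Path, sheet: int | str) -> dict[str, object]:
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df = pd.read_excel(path, sheet_name=sheet)
    else:
        df = pd.read_csv(path, sep=_sep_for(path))
    if df.empty:
        raise FormatError(f"{path.name}: sheet has no data row")
    row = df.iloc[0]
    out: dict[str, object] = {}
    for col in df.columns:
        key = str(col).strip().lower()
        if key in out:
            raise FormatError(f"{path.name}: duplicate column {col!r}")
        out[key] = row[col]
    return out


def _as_seconds(value: object, what: str, path: Path) -> float:
    try:
        v = float(value)  # type: ignore[arg-type]
    except (TypeError, ValueError):
        raise FormatError(f"{path.name}: {what} is not a number: {value!r}") from None
    if np.isnan(v):
        raise FormatError(f"{path.name}: {what} is empty")
    return v


def read_event_table(
    path: str | Path,
    *,
    sheet: int | str = 0,
    session_id: str | None = None,
    time_offset: float = 0.0,
) -> EventTable:
    """Load a behavioral event sheet.

    The sheet holds one row: ``start``/``end`` bound the trial, each event i
    contributes a matched ``starti``/``endi`` pair, in suffix order 1..N.
    ``time_offset`` (seconds) is added to every time for rigs whose sheet
    clock is not the photometry clock; the default assumes simultaneous
    device start and applies none.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    row = _read_sheet_row(path, sheet)
    if "start" not in row or "end" not in row:
        raise FormatError(f"{path.name}: sheet must contain 'start' and 'end'")
    trial_start = _as_seconds(row["start"], "'start'", path) + time_offset
    trial_end = _as_seconds(row["end"], "'end'", path) + time_offset

    starts = {int(m.group(1)): k for k in row if (m := _START_RE.match(k))}
    ends = {int(m.group(1)): k for k in row if (m := _END_RE.match(k))}
    if set(starts) != set(ends):
        odd = sorted(set(starts) ^ set(ends))
        raise FormatError(f"{path.name}: unmatched start/end pair(s) for suffix {odd}")
    suffixes = sorted(starts)
    if suffixes and suffixes != list(range(1, len(suffixes) + 1)):
        raise FormatError(f"{path.name}: event suffixes must be contiguous 1..N, got {suffixes}")

    types = {int(m.group(1)): str(row[k]).strip() for k in row if (m := _TYPE_RE.match(k))}
    default_type = str(row.get("type", "hole")).strip() or "hole"
    if default_type.lower() == "nan":
        default_type = "hole"

    events = []
    for i in suffixes:
        t0 = _as_seconds(row[starts[i]], f"'start{i}'", path) + time_offset
        t1 = _as_seconds(row[ends[i]], f"'end{i}'", path) + time_offset
        if not t1 > t0:
            raise ValidationError(f"{path.name}: event {i} has end{i} <= start{i}")
        events.append(Event(index=i, t_start=t0, t_end=t1, type=types.get(i, default_type)))

    def _label(key: str) -> str:
        v = row.get(key, "")
        s = "" if v is None else str(v).strip()
        return "" if s.lower() == "nan" else s

    return EventTable(
        trial_start=trial_start,
        trial_end=trial_end,
        events=events,
        odorant=_label("odorant"),
        hedonics=_label("hedonics"),
        condition=_label("condition"),
        session_id=session_id if session_id is not None else path.stem,
    )


def write_event_table(table: EventTable, path: str | Path) -> None:
    """Write an event sheet in the startN/endN convention (CSV or xlsx)."""
    path = Path(path)
    data: dict[str, object] = {
        "start": table.trial_start,
        "end": table.trial_end,
        "odorant": table.odorant,
        "hedonics": table.hedonics,
        "condition": table.condition,
    }
    for ev in table.events:
        data[f"start{ev.index}"] = ev.t_start
        data[f"end{ev.index}"] = ev.t_end
        data[f"type{ev.index}"] = ev.type
    df = pd.DataFrame([data])
    if path.suffix.lower() in {".xlsx", ".xlsm"}:
        df.to_excel(path, index=False)
    else:
        df.to_csv(path, sep=_sep_for(path), index=False, float_format=_FLOAT_FMT)


# ---------------------------------------------------------------------------
# tracking


def read_tracking(
    path: str | Path,
    *,
    frame_rate: float,
    reference_points: tuple[tuple[float, float], tuple[float, float]],
    session_id: str | None = None,  # noqa: ARG001 - parity with other loaders
) -> TrackingTable:
    """Load a ``frame,x,y`` tracking CSV.

    Rows with a missing coordinate are kept as NaN gaps (counted by
    ``TrackingTable.n_gaps``); duplicate or negative frame indices are format
    errors.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if frame_rate <= 0:
        raise ValidationError("frame_rate must be > 0")
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = {c.strip().lower(): c for c in df.columns}
    for need in ("frame", "x", "y"):
        if need not in cols:
            raise FormatError(f"{path.name}: missing column {need!r}")
    frames_raw = pd.to_numeric(df[cols["frame"]], errors="coerce")
    if frames_raw.isna().any():
        raise FormatError(f"{path.name}: non-numeric frame index")
    frames = frames_raw.to_numpy(dtype=np.int64)
    if np.any(frames < 0):
        raise FormatError(f"{path.name}: negative frame index")
    uniq, counts = np.unique(frames, return_counts=True)
    if np.any(counts > 1):
        raise FormatError(f"{path.name}: duplicate frame index {int(uniq[counts > 1][0])}")
    order = np.argsort(frames)
    return TrackingTable(
        frame=frames[order],
        x=pd.to_numeric(df[cols["x"]], errors="coerce").to_numpy(dtype=float)[order],
        y=pd.to_numeric(df[cols["y"]], errors="coerce").to_numpy(dtype=float)[order],
        frame_rate=frame_rate,
        reference_points=reference_points,
    )


def read_tracking_dlc(
    path: str | Path,
    *,
    bodypart: str,
    frame_rate: float,
    reference_points: tuple[tuple[float, float], tuple[float, float]],
    likelihood_cutoff: float = 0.0,
) -> TrackingTable:
    """Adapter for DeepLabCut multi-header CSV (scorer / bodyparts / coords).

    Coordinates whose likelihood falls below ``likelihood_cutoff`` are turned
    into NaN gaps.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, header=[0, 1, 2], index_col=0)
    parts = df.columns.get_level_values(1)
    if bodypart not in set(parts):
        raise FormatError(f"{path.name}: bodypart {bodypart!r} not found (have {sorted(set(parts))})")
    sub = df.loc[:, parts == bodypart]
    coords = {c.lower(): i for i, c in enumerate(sub.columns.get_level_values(2))}
    for need in ("x", "y"):
        if need not in coords:
            raise FormatError(f"{path.name}: bodypart {bodypart!r} lacks coordinate {need!r}")
    x = sub.iloc[:, coords["x"]].to_numpy(dtype=float)
    y = sub.iloc[:, coords["y"]].to_numpy(dtype=float)
    if "likelihood" in coords and likelihood_cutoff > 0:
        bad = sub.iloc[:, coords["likelihood"]].to_numpy(dtype=float) < likelihood_cutoff
        x = np.where(bad, np.nan, x)
        y = np.where(bad, np.nan, y)
    frames = pd.to_numeric(pd.Series(df.index), errors="coerce")
    if frames.isna().any():
        raise FormatError(f"{path.name}: non-numeric frame index")
    return TrackingTable(
        frame=frames.to_numpy(dtype=np.int64),
        x=x,
        y=y,
        frame_rate=frame_rate,
        reference_points=reference_points,
    )


def write_tracking(track: TrackingTable, path: str | Path) -> None:
    pd.DataFrame({"frame": track.frame, "x": track.x, "y": track.y}).to_csv(
        Path(path), index=False, float_format=_FLOAT_FMT
    )


# ---------------------------------------------------------------------------
# generic tabular outputs


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy result table as CSV with full float precision."""
    df.to_csv(Path(path), index=False, float_format=_FLOAT_FMT)


def write_matrix(matrix: np.ndarray, path: str | Path) -> None:
    """Write a 2-D map as a bare CSV matrix (NaN marks unvisited bins)."""
    np.savetxt(Path(path), np.asarray(matrix, dtype=float), delimiter=",", fmt=_FLOAT_FMT)


def read_matrix(path: str | Path) -> np.ndarray:
    return np.loadtxt(Path(path), delimiter=",", ndmin=2)


def read_processed_channel_csv(path: str | Path) -> pd.DataFrame:
    """Read back a per-channel preprocessing CSV (time, raw, filtered, fitted,
    dff, zscore)."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    df = pd.read_csv(path, float_precision="round_trip")
    missing = [c for c in ("time", "zscore") if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing column(s) {missing}")
    return df


def sorted_event_tables(tables: Sequence[EventTable]) -> list[EventTable]:
    """Stable session ordering used wherever multiple sessions are pooled."""
    return sorted(tables, key=lambda t: t.session_id)
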