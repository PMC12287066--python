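"""Board-normalized coordinates, zone-entry detection and spatial signal maps.

Two reference markers (P1, P2) placed at the bottom corners of the square
board in every video fix an affine frame (translation + rotation + uniform
scale), so trajectories from different sessions land in the same normalized
[0,1]^2 board regardless of camera placement. Convention: P1 = bottom-left ->
(0,0), P2 = bottom-right -> (1,0), y increases upward. Pixel input is
image-style by default (y down); set ``pixel_y_down=False`` for y-up sources.

Spatial maps bin the normalized board into an n x n grid: occupancy (seconds
per bin), accumulated Z-score per bin, and the occupancy-normalized mean
signal per bin which is independent of how long the animal dwelt in a bin.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import Event, TrackingTable
from .errors import AlignmentError, GeometryError, ParameterError
from .preprocess import ProcessedChannel

__all__ = [
    "BoardFrame",
    "DiscZone",
    "EdgeZone",
    "SpatialMaps",
    "board_transform",
    "detect_zone_events",
    "presence_map",
    "signal_maps",
]


@dataclass
class BoardFrame:
    """Affine map between camera pixels and the normalized board square."""

    p1: tuple[float, float]
    p2: tuple[float, float]
    pixel_y_down: bool = True

    def __post_init__(self) -> None:
        self._p1 = np.asarray(self.p1, dtype=float)
        d = np.asarray(self.p2, dtype=float) - self._p1
        self._scale = float(np.hypot(*d))
        if self._scale == 0.0:
            raise GeometryError("reference points P1 and P2 coincide")
        self._ex = d / self._scale
        # Unit vector pointing "up" on the board: rotate ex by -90 deg in
        # image coordinates (y down), +90 deg in math coordinates (y up).
        if self.pixel_y_down:
            self._ey = np.array([self._ex[1], -self._ex[0]])
        else:
            self._ey = np.array([-self._ex[1], self._ex[0]])

    @property
    def scale(self) -> float:
        """Board edge length in pixels."""
        return self._scale

    def to_board(self, points: np.ndarray) -> np.ndarray:
        """Pixel (n, 2) -> normalized board coordinates (n, 2)."""
        u = np.atleast_2d(np.asarray(points, dtype=float)) - self._p1
        return np.column_stack((u @ self._ex, u @ self._ey)) / self._scale

    def from_board(self, points: np.ndarray) -> np.ndarray:
        """Normalized board coordinates (n, 2) -> pixels (n, 2)."""
        q = np.atleast_2d(np.asarray(points, dtype=float)) * self._scale
        return self._p1 + np.outer(q[:, 0], self._ex) + np.outer(q[:, 1], self._ey)


def board_transform(
    track: TrackingTable, *, pixel_y_down: bool = True, clamp: bool = True
) -> tuple[BoardFrame, np.ndarray, int]:
    """Normalize a tracked trajectory into the board frame.

    Returns (frame, trajectory (n, 2) with NaN gaps preserved, n_clamped).
    Points outside [0,1]^2 are clamped onto the square and counted.
    """
    frame = BoardFrame(track.reference_points[0], track.reference_points[1],
                       pixel_y_down=pixel_y_down)
    traj = frame.to_board(np.column_stack((track.x, track.y)))
    finite = np.isfinite(traj).all(axis=1)
    outside = finite & ((traj < 0) | (traj > 1)).any(axis=1)
    n_clamped = int(outside.sum())
    if clamp:
        traj[finite] = np.clip(traj[finite], 0.0, 1.0)
    return frame, traj, n_clamped


@dataclass
class DiscZone:
    """Circular zone (e.g. the odorized hole) in normalized coordinates."""

    center: tuple[float, float] = (0.5, 0.5)
    radius: float = 0.08

    def contains(self, traj: np.ndarray) -> np.ndarray:
        traj = np.atleast_2d(traj)
        d2 = (traj[:, 0] - self.center[0]) ** 2 + (traj[:, 1] - self.center[1]) ** 2
        return np.where(np.isfinite(d2), d2 <= self.radius**2, False)


@dataclass
class EdgeZone:
    """Border band of the board (escape zone); width in normalized units."""

    width: float = 0.1

    def contains(self, traj: np.ndarray) -> np.ndarray:
        traj = np.atleast_2d(traj)
        x, y = traj[:, 0], traj[:, 1]
        near = (x <= self.width) | (x >= 1 - self.width) | (y <= self.width) | (y >= 1 - self.width)
        return np.where(np.isfinite(x) & np.isfinite(y), near, False)


def detect_zone_events(
    traj: np.ndarray,
    zone: DiscZone | EdgeZone,
    *,
    frame_rate: float,
    min_duration: float = 0.0,
    frames: np.ndarray | None = None,
    event_type: str = "hole",
) -> list[Event]:
    """Maximal runs of consecutive in-zone frames as frame-accurate events.

    Events use the closed-open convention: t_start = first in-zone frame /
    rate, t_end = (last in-zone frame + 1) / rate, so duration = run length /
    rate. Tracking gaps (NaN points or missing frame indices) break runs. Runs
    shorter than ``min_duration`` are discarded.
    """
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if traj.size == 0:
        return []
    if frames is None:
        frames = np.arange(traj.shape[0])
    frames = np.asarray(frames, dtype=np.int64)
    inside = zone.contains(traj)

    events: list[Event] = []
    run_start = None
    prev_frame = None
    for i in range(traj.shape[0]):
        contiguous = prev_frame is not None and frames[i] == prev_frame + 1
        if inside[i]:
            if run_start is None or not contiguous:
                if run_start is not None:
                    events.append((run_start, prev_frame))
                run_start = frames[i]
        else:
            if run_start is not None:
                events.append((run_start, prev_frame))
                run_start = None
        prev_frame = frames[i]
    if run_start is not None:
        events.append((run_start, prev_frame))

    out = []
    for f0, f1 in events:
        t0, t1 = f0 / frame_rate, (f1 + 1) / frame_rate
        if t1 - t0 >= min_duration:
            out.append(Event(index=len(out) + 1, t_start=t0, t_end=t1, type=event_type))
    return out


def _bin_indices(traj: np.ndarray, grid_n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Half-open bins, top/right edges closed: every point of [0,1]^2 falls in
    exactly one bin. Returns (valid mask, ix, iy)."""
    valid = np.isfinite(traj).all(axis=1)
    safe = np.nan_to_num(traj, nan=0.0)
    ix = np.minimum((safe[:, 0] * grid_n).astype(int), grid_n - 1)
    iy = np.minimum((safe[:, 1] * grid_n).astype(int), grid_n - 1)
    return valid, ix, iy


def presence_map(traj: np.ndarray, grid_n: int = 32, *, frame_rate: float) -> np.ndarray:
    """Occupancy-time map in seconds, indexed [iy, ix] with iy=0 the bottom row.

    The total equals (non-gap frames) / frame_rate.
    """
    if grid_n < 2:
        raise ParameterError("grid_n must be >= 2")
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    occ = np.zeros((grid_n, grid_n))
    if traj.size == 0:
        return occ
    valid, ix, iy = _bin_indices(traj, grid_n)
    np.add.at(occ, (iy[valid], ix[valid]), 1.0 / frame_rate)
    return occ


@dataclass
class SpatialMaps:
    """Gridded occupancy and signal maps over the normalized board.

    ``signal_norm`` is the per-sample mean Z-score of each visited bin
    (accumulated signal divided by the number of photometry samples spent
    there, i.e. occupancy time x sampling rate), so it does not grow with
    dwell time. Unvisited bins hold NaN, never zero.
    """

    grid_n: int
    occupancy: np.ndarray
    signal_sum: np.ndarray
    sample_count: np.ndarray
    n_samples_used: int = 0
    signal_norm: np.ndarray = field(init=False)
    visited: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.visited = self.occupancy > 0
        with np.errstate(invalid="ignore", divide="ignore"):
            norm = self.signal_sum / self.sample_count
        norm[~self.visited | (self.sample_count == 0)] = np.nan
        self.signal_norm = norm


def signal_maps(
    traj: np.ndarray,
    track: TrackingTable,
    channel: ProcessedChannel,
    grid_n: int = 32,
    *,
    time_offset: float = 0.0,
) -> SpatialMaps:
    """Map photometry Z-scores onto board locations.

    Each photometry sample is assigned to the bin of the temporally nearest
    tracking frame (both streams share the session clock; ``time_offset`` is
    added to frame times for rigs with a known constant lag). Samples nearest
    to a gap frame, or outside the tracked span by more than half a frame, are
    skipped.
    """
    if channel.zscore is None:
        raise ParameterError(f"channel {channel.role} carries no zscore trace")
    traj = np.atleast_2d(np.asarray(traj, dtype=float))
    if traj.shape[0] != track.frame.size:
        raise ParameterError("trajectory and tracking table differ in length")
    ft = track.times + time_offset
    t = channel.time
    if ft.size == 0 or t[-1] < ft[0] or t[0] > ft[-1]:
        raise AlignmentError("photometry and tracking spans do not overlap")

    # nearest tracked frame per photometry sample
    pos = np.searchsorted(ft, t)
    pos = np.clip(pos, 1, ft.size - 1) if ft.size > 1 else np.zeros_like(pos)
    left, right = ft[pos - 1], ft[pos]
    nearest = np.where(np.abs(t - left) <= np.abs(right - t), pos - 1, pos)
    half = 0.5 / track.frame_rate
    in_span = np.abs(t - ft[nearest]) <= half + 1e-12

    occ = presence_map(traj, grid_n, frame_rate=track.frame_rate)
    valid, ix, iy = _bin_indices(traj, grid_n)
    usable = in_span & valid[nearest]
    sig = np.zeros((grid_n, grid_n))
    cnt = np.zeros((grid_n, grid_n))
    bins = (iy[nearest[usable]], ix[nearest[usable]])
    np.add.at(sig, bins, channel.zscore[usable])
    np.add.at(cnt, bins, 1.0)
    return SpatialMaps(
        grid_n=grid_n,
        occupancy=occ,
        signal_sum=sig,
        sample_count=cnt,
        n_samples_used=int(usable.sum()),
    )
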