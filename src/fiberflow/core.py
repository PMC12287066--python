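"""Domain containers for one recording session.

A session couples three independently acquired streams that share a clock
(all devices are started simultaneously):

* demodulated fiber photometry — one trace per excitation channel,
* a behavioral event sheet — trial bounds plus labeled event intervals,
* a video tracking table — x/y pixel coordinates of the animal per frame.

Channel roles follow the dual-color convention: a 465 nm sensor channel
(dopamine-dependent, e.g. dLight1.2), a 565 nm sensor channel
(calcium-dependent, e.g. jRGECO1a), and a 405 nm isosbestic channel that is
insensitive to ligand binding and serves as the motion/artifact reference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

SENSOR_465 = "sensor_465"
SENSOR_565 = "sensor_565"
ISOSBESTIC = "isosbestic_405"

#: Roles that carry a ligand-dependent signal and get the full DF/F stack.
SENSOR_ROLES = (SENSOR_465, SENSOR_565)
ALL_ROLES = (SENSOR_465, SENSOR_565, ISOSBESTIC)


@dataclass
class PhotometryRecording:
    """Uniformly sampled photometry traces for one session.

    Parameters
    ----------
    time:
        Sample times in seconds, strictly increasing on a uniform grid.
    channels:
        Mapping of channel role (see module constants) to raw trace.
    session_id:
        Free-text session identifier.
    uniformity_rtol:
        Relative tolerance on the time step; a grid whose steps deviate from
        the median step by more than this fraction is rejected.
    """

    time: np.ndarray
    channels: dict[str, np.ndarray]
    session_id: str = ""
    uniformity_rtol: float = 1e-6
    sampling_rate: float = field(init=False)

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        if self.time.ndim != 1 or self.time.size < 2:
            raise ValidationError("photometry needs at least 2 samples on a 1-D time base")
        dt = np.diff(self.time)
        if np.any(dt <= 0):
            raise ValidationError("time base must be strictly increasing")
        step = float(np.median(dt))
        if np.max(np.abs(dt - step)) > self.uniformity_rtol * step:
            raise ValidationError(
                f"non-uniform time base: step deviates by more than rtol={self.uniformity_rtol}"
            )
        if not self.channels:
            raise ValidationError("recording has no channels")
        clean = {}
        for role, trace in self.channels.items():
            arr = np.asarray(trace, dtype=float)
            if arr.shape != self.time.shape:
                raise ValidationError(
                    f"channel {role!r} has length {arr.size}, expected {self.time.size}"
                )
            clean[role] = arr
        self.channels = clean
        # Inferred, never trusted from metadata: exports disagree too often.
        self.sampling_rate = 1.0 / step

    @property
    def n_samples(self) -> int:
        return int(self.time.size)

    @property
    def duration(self) -> float:
        return float(self.time[-1] - self.time[0])

    def sensor_roles(self) -> list[str]:
        return [r for r in self.channels if r != ISOSBESTIC]


@dataclass
class Event:
    """One labeled behavioral interval (e.g. an olfactory investigation of the
    odorized hole, or an escape bout at the board's edge)."""

    index: int  # 1-based ordinal, matches the startN/endN column suffix
    t_start: float
    t_end: float
    type: str = "hole"

    def __post_init__(self) -> None:
        if self.index < 1:
            raise ValidationError(f"event index must be >= 1, got {self.index}")
        if not self.t_start < self.t_end:
            raise ValidationError(
                f"event {self.index}: t_start ({self.t_start}) must be < t_end ({self.t_end})"
            )

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class EventTable:
    """Trial bounds plus the ordered event list for one session.

    Session-level metadata labels are free text and captured verbatim from the
    sheet (e.g. odorant "Citro", hedonics "plea", condition "Ctrl").
    """

    trial_start: float
    trial_end: float
    events: list[Event] = field(default_factory=list)
    odorant: str = ""
    hedonics: str = ""
    condition: str = ""
    session_id: str = ""

    def __post_init__(self) -> None:
        if not self.trial_start < self.trial_end:
            raise ValidationError(
                f"trial_start ({self.trial_start}) must be < trial_end ({self.trial_end})"
            )
        for i, ev in enumerate(self.events, start=1):
            if ev.index != i:
                raise ValidationError(
                    f"events must be indexed 1..N in order; position {i} has index {ev.index}"
                )
            if ev.t_start < self.trial_start or ev.t_end > self.trial_end:
                raise ValidationError(
                    f"event {ev.index} [{ev.t_start}, {ev.t_end}] outside trial "
                    f"bounds [{self.trial_start}, {self.trial_end}]"
                )

    @property
    def n_events(self) -> int:
        return len(self.events)


@dataclass
class TrackingTable:
    """Frame-indexed x/y pixel coordinates of the tracked animal.

    Rows with missing coordinates are retained with NaN and counted as gaps;
    missing frame indices are allowed (detection failures drop frames).
    ``reference_points`` are the two board-corner markers (P1, P2) placed at
    the bottom corners of the board in every video.
    """

    frame: np.ndarray
    x: np.ndarray
    y: np.ndarray
    frame_rate: float
    reference_points: tuple[tuple[float, float], tuple[float, float]]

    def __post_init__(self) -> None:
        self.frame = np.asarray(self.frame, dtype=np.int64)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (self.frame.shape == self.x.shape == self.y.shape):
            raise ValidationError("frame, x and y must have equal length")
        if self.frame.size and np.any(self.frame < 0):
            raise ValidationError("negative frame index")
        if self.frame.size and np.any(np.diff(self.frame) <= 0):
            raise ValidationError("frame indices must be strictly increasing")
        if self.frame_rate <= 0:
            raise ValidationError("frame_rate must be > 0")
        p1, p2 = self.reference_points
        if tuple(p1) == tuple(p2):
            raise ValidationError("reference points P1 and P2 must differ")

    @property
    def n_gaps(self) -> int:
        """Rows present in the table but with a missing coordinate."""
        return int(np.sum(np.isnan(self.x) | np.isnan(self.y)))

    @property
    def times(self) -> np.ndarray:
        """Frame times in seconds on the shared session clock."""
        return self.frame / self.frame_rate

    @property
    def duration(self) -> float:
        """Nominal span covered by the table (frames / rate)."""
        return float(self.frame.size / self.frame_rate) if self.frame.size else 0.0
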