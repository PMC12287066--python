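"""Event selection and onset-locked ensemble averaging.

Behavioral events are referenced retrospectively (the segmentation is done
after the recording), so analysis is query-driven: filter events by type,
odorant, hedonics, condition and within-session sequence, extract Z-score
segments locked to each event onset ("time point 0"), and average across
events or across animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .core import Event, EventTable
from .errors import AlignmentError, ParameterError
from .preprocess import ProcessedChannel

__all__ = [
    "EventQuery",
    "AlignedEnsemble",
    "select_events",
    "extract_aligned",
    "total_event_duration",
    "ensemble_average",
]


@dataclass
class EventQuery:
    """Metadata filter over events; None leaves a field unrestricted.

    ``sequence`` picks events within each session after the metadata filters:
    "all", "first", "last", or an explicit list of per-session positions
    (1-based, into the filtered list).
    """

    type: str | None = None
    odorant: str | None = None
    hedonics: str | None = None
    condition: str | None = None
    sequence: object = "all"


def _match(label: str, wanted: str | None) -> bool:
    return wanted is None or label == wanted


def select_events(
    tables: Sequence[EventTable], query: EventQuery | None = None
) -> list[tuple[str, Event]]:
    """Events matching every non-empty filter, in (session, event index) order.

    An empty result is valid, never an error.
    """
    query = query or EventQuery()
    out: list[tuple[str, Event]] = []
    for table in tables:
        if not (
            _match(table.odorant, query.odorant)
            and _match(table.hedonics, query.hedonics)
            and _match(table.condition, query.condition)
        ):
            continue
        hits = [ev for ev in table.events if _match(ev.type, query.type)]
        seq = query.sequence
        if seq == "all":
            pass
        elif seq == "first":
            hits = hits[:1]
        elif seq == "last":
            hits = hits[-1:]
        elif isinstance(seq, Iterable) and not isinstance(seq, str):
            wanted = {int(i) for i in seq}
            hits = [ev for pos, ev in enumerate(hits, start=1) if pos in wanted]
        else:
            raise ParameterError(f"unknown sequence selector {seq!r}")
        out.extend((table.session_id, ev) for ev in hits)
    return out


def total_event_duration(events: Sequence[tuple[str, Event]] | Sequence[Event]) -> float:
    """Summed duration (s) of the selected events; 0 for an empty selection.

    With events from a zone detector this is the total exploration duration of
    that zone (e.g. total odorized-hole investigation time).
    """
    total = 0.0
    for item in events:
        ev = item[1] if isinstance(item, tuple) else item
        total += ev.duration
    return total


@dataclass
class AlignedEnsemble:
    """Events x relative-time matrix of Z-scores locked to event onset.

    ``rel_time`` runs from -pre to +post on the channel's sample grid with 0
    at the onset sample; row i belongs to ``event_ids[i]`` = (session, event
    index). ``n_dropped`` counts selected events whose window left the
    recording.
    """

    rel_time: np.ndarray
    matrix: np.ndarray
    event_ids: list[tuple[str, int]]
    n_dropped: int = 0
    mean: np.ndarray = field(init=False)
    sem: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.rel_time = np.asarray(self.rel_time, dtype=float)
        self.matrix = np.atleast_2d(np.asarray(self.matrix, dtype=float))
        if self.matrix.shape[0] != len(self.event_ids):
            raise AlignmentError("matrix rows and event_ids disagree")
        if self.matrix.shape[1] != self.rel_time.size:
            raise AlignmentError("matrix columns and rel_time disagree")
        if not np.any(np.isclose(self.rel_time, 0.0, atol=1e-12)):
            raise AlignmentError("rel_time must contain the onset sample (0)")
        self.mean = self.matrix.mean(axis=0)
        n = self.matrix.shape[0]
        if n > 1:
            self.sem = self.matrix.std(axis=0, ddof=1) / np.sqrt(n)
        else:
            self.sem = np.zeros(self.matrix.shape[1])

    @property
    def n_events(self) -> int:
        return self.matrix.shape[0]

    @property
    def onset_index(self) -> int:
        return int(np.argmin(np.abs(self.rel_time)))


def extract_aligned(
    channel: ProcessedChannel,
    events: Sequence[tuple[str, Event]] | Sequence[Event],
    pre: float = 2.0,
    post: float = 2.0,
) -> AlignedEnsemble:
    """One ensemble row per event, sampled on the channel grid.

    The onset maps to the nearest sample at or before t_start (floor; no
    interpolation, so no post-onset information leaks into pre-onset samples).
    Events whose [onset-pre, onset+post] window leaves the recording are
    dropped and counted, not padded.
    """
    if pre < 0 or post < 0:
        raise ParameterError("pre and post must be >= 0")
    if channel.zscore is None:
        raise ParameterError(f"channel {channel.role} carries no zscore trace")
    time = channel.time
    z = channel.zscore
    fs = channel.sampling_rate
    n_pre = int(round(pre * fs))
    n_post = int(round(post * fs))
    rel_time = np.arange(-n_pre, n_post + 1) / fs

    rows, ids, dropped = [], [], 0
    for item in events:
        sid, ev = item if isinstance(item, tuple) else ("", item)
        onset = int(np.searchsorted(time, ev.t_start + 1e-12, side="right")) - 1
        if onset < 0 or onset - n_pre < 0 or onset + n_post >= time.size:
            dropped += 1
            continue
        rows.append(z[onset - n_pre : onset + n_post + 1])
        ids.append((sid, ev.index))
    if not rows:
        raise AlignmentError(
            f"all {dropped} event(s) dropped: window [-{pre}, +{post}] s leaves the recording"
        )
    return AlignedEnsemble(
        rel_time=rel_time, matrix=np.vstack(rows), event_ids=ids, n_dropped=dropped
    )


def ensemble_average(
    ensembles: Sequence[AlignedEnsemble], level: str = "event"
) -> AlignedEnsemble:
    """Pool ensembles across sessions.

    level="event" pools every row (each event weighs equally); level="animal"
    first averages within each ensemble, then across ensembles (each animal
    weighs equally). The two differ whenever animals contribute unequal event
    counts.
    """
    if not ensembles:
        raise ParameterError("no ensembles to average")
    ref = ensembles[0].rel_time
    for e in ensembles[1:]:
        if e.rel_time.shape != ref.shape or not np.allclose(e.rel_time, ref, atol=1e-9):
            raise AlignmentError("ensembles have mismatched rel_time grids")
    if level == "event":
        matrix = np.vstack([e.matrix for e in ensembles])
        ids = [eid for e in ensembles for eid in e.event_ids]
    elif level == "animal":
        matrix = np.vstack([e.mean for e in ensembles])
        ids = [(e.event_ids[0][0] if e.event_ids else "", 0) for e in ensembles]
    else:
        raise ParameterError(f"level must be 'event' or 'animal', got {level!r}")
    dropped = sum(e.n_dropped for e in ensembles)
    return AlignedEnsemble(rel_time=ref, matrix=matrix, event_ids=ids, n_dropped=dropped)
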