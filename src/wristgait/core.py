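"""Domain types and interval conventions shared by all modules.

All time intervals are half-open ``[start_s, end_s)`` in seconds from the
start of the recording.  Acceleration is expressed in units of g throughout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "Recording",
    "GaitSequence",
    "GSList",
    "StepEvents",
    "StrideIntervals",
    "assemble_gs_from_events",
    "merge_overlapping",
]


@dataclass(frozen=True)
class Recording:
    """A uniformly sampled triaxial acceleration series.

    Parameters
    ----------
    fs : float
        Sampling frequency in Hz, strictly positive.
    acc : ndarray of shape (N, 3)
        Acceleration samples in g.
    subject_id : str
        Opaque subject identifier.
    group : str
        Cohort label (free string, e.g. ``"HA"``, ``"PFF"``).
    meta : dict
        Free-form annotations (e.g. ``walking_aid: "none"|"unilateral"|"bilateral"``).
    """

    fs: float
    acc: np.ndarray
    subject_id: str = ""
    group: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        acc = np.asarray(self.acc, dtype=float)
        if acc.ndim != 2 or acc.shape[1] != 3:
            raise ValueError(f"acc must be N x 3, got shape {acc.shape}")
        if acc.shape[0] < 1:
            raise ValueError("recording must contain at least one sample")
        if not self.fs > 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if not np.all(np.isfinite(acc)):
            raise ValueError("acceleration contains non-finite values")
        object.__setattr__(self, "acc", acc)

    @property
    def n_samples(self) -> int:
        return self.acc.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def time(self) -> np.ndarray:
        """Sample timestamps in seconds from the recording start."""
        return np.arange(self.n_samples) / self.fs


@dataclass(frozen=True, order=True)
class GaitSequence:
    """A half-open gait interval ``[start_s, end_s)``."""

    start_s: float
    end_s: float

    def __post_init__(self):
        if not (0 <= self.start_s < self.end_s):
            raise ValueError(
                f"invalid gait sequence [{self.start_s}, {self.end_s})"
            )

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def contains(self, t: float) -> bool:
        return self.start_s <= t < self.end_s


@dataclass(frozen=True)
class GSList:
    """An ordered, non-overlapping list of gait sequences from one source."""

    sequences: tuple[GaitSequence, ...] = ()
    source: str = ""

    def __post_init__(self):
        seqs = tuple(self.sequences)
        for a, b in zip(seqs, seqs[1:]):
            if b.start_s <= a.end_s:
                raise ValueError(
                    f"gait sequences must be sorted and separated by a positive "
                    f"gap: [{a.start_s},{a.end_s}) then [{b.start_s},{b.end_s})"
                )
        object.__setattr__(self, "sequences", seqs)

    def __len__(self) -> int:
        return len(self.sequences)

    def __iter__(self):
        return iter(self.sequences)

    def __getitem__(self, i):
        return self.sequences[i]

    @property
    def total_duration_s(self) -> float:
        return float(sum(gs.duration_s for gs in self.sequences))

    def as_array(self) -> np.ndarray:
        """(n, 2) array of [start_s, end_s] rows."""
        if not self.sequences:
            return np.empty((0, 2))
        return np.array([[g.start_s, g.end_s] for g in self.sequences])


@dataclass(frozen=True)
class StepEvents:
    """Strictly increasing step-event timestamps in seconds."""

    times: tuple[float, ...] = ()

    def __post_init__(self):
        times = tuple(float(t) for t in self.times)
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("step event times must be strictly increasing")
        object.__setattr__(self, "times", times)

    def __len__(self) -> int:
        return len(self.times)

    def __iter__(self):
        return iter(self.times)


@dataclass(frozen=True)
class StrideIntervals:
    """Ordered ``(start_s, end_s)`` stride intervals with increasing starts."""

    strides: tuple[tuple[float, float], ...] = ()

    def __post_init__(self):
        strides = tuple((float(a), float(b)) for a, b in self.strides)
        for a, b in strides:
            if b <= a:
                raise ValueError(f"stride interval ({a}, {b}) has end <= start")
        starts = [a for a, _ in strides]
        if any(y <= x for x, y in zip(starts, starts[1:])):
            raise ValueError("stride starts must be strictly increasing")
        object.__setattr__(self, "strides", strides)

    def __len__(self) -> int:
        return len(self.strides)

    def __iter__(self):
        return iter(self.strides)


def _events_as_intervals(
    events: StepEvents | StrideIntervals | Sequence,
) -> tuple[list[tuple[float, float]], int]:
    """Normalize to (start, end) pairs; also return the per-item event count.

    A run of k strides spans k+1 stride endpoints, a run of k steps k
    events; the returned offset (0 for steps, 1 for strides) is added to
    the run length before comparing against ``min_events``.
    """
    if isinstance(events, StepEvents):
        return [(t, t) for t in events.times], 0
    if isinstance(events, StrideIntervals):
        return list(events.strides), 1
    items = list(events)
    if not items:
        return [], 0
    if np.isscalar(items[0]):
        return [(t, t) for t in StepEvents(tuple(items)).times], 0
    return list(StrideIntervals(tuple(items)).strides), 1


def assemble_gs_from_events(
    events: StepEvents | StrideIntervals | Sequence,
    max_gap_s: float = 3.0,
    min_events: int = 2,
    source: str = "",
) -> GSList:
    """Assemble step events or stride intervals into gait sequences.

    Consecutive events separated by at most ``max_gap_s`` (end-to-next-start
    for strides, time-to-time for steps) belong to the same gait sequence.
    Runs with fewer than ``min_events`` events are discarded.  Each gait
    sequence spans from the first event start to the last event end (for
    step events: the last step time).

    Parameters
    ----------
    events : StepEvents, StrideIntervals or sequence
        Sorted events.  Raw sequences are validated on conversion.
    max_gap_s : float
        Maximum tolerated separation between consecutive events, seconds.
    min_events : int
        Minimum number of events per gait sequence, at least 2.
    """
    if not max_gap_s > 0:
        raise ValueError(f"max_gap_s must be > 0, got {max_gap_s}")
    if min_events < 2:
        raise ValueError(f"min_events must be >= 2, got {min_events}")

    intervals, offset = _events_as_intervals(events)
    if not intervals:
        return GSList((), source=source)

    sequences: list[GaitSequence] = []
    run_start, run_end, run_n = intervals[0][0], intervals[0][1], 1
    for start, end in intervals[1:]:
        if start - run_end <= max_gap_s:
            run_end = max(run_end, end)
            run_n += 1
        else:
            if run_n + offset >= min_events and run_end > run_start:
                sequences.append(GaitSequence(run_start, run_end))
            run_start, run_end, run_n = start, end, 1
    if run_n + offset >= min_events and run_end > run_start:
        sequences.append(GaitSequence(run_start, run_end))

    return GSList(tuple(sequences), source=source)


def merge_overlapping(
    gs: Iterable[GaitSequence | tuple[float, float]], source: str = ""
) -> GSList:
    """Union of possibly overlapping/touching intervals, sorted.

    Total covered time is preserved; the result satisfies GSList invariants.
    """
    pairs = sorted(
        (g.start_s, g.end_s) if isinstance(g, GaitSequence) else (float(g[0]), float(g[1]))
        for g in gs
    )
    merged: list[list[float]] = []
    for start, end in pairs:
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return GSList(
        tuple(GaitSequence(a, b) for a, b in merged if b > a), source=source
    )
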