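"""Sleep-bout detection from epoch counts.

An epoch is scored "rest" when its count falls at or below a low-activity
threshold. Maximal runs of rest/wake that are shorter than a minimum
segment length are then iteratively flipped to the opposite state
(shortest run first, earlier run on ties) until a fixed point is reached,
so brief stirrings inside a sleep bout and brief lulls during the day do
not fragment the state sequence. Runs touching the record boundaries are
exempt because their true length is unknown. Bouts longer than a validity
cap (default 15 h) are discarded as device artefacts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ingest import EpochSeries

__all__ = [
    "SleepParams",
    "SleepInterval",
    "NightActivity",
    "detect_sleep",
    "filter_valid_sleep",
    "sleep_time",
    "night_slices",
    "write_intervals_csv",
]


@dataclass(frozen=True)
class SleepParams:
    low_activity_threshold: float = 10.0
    min_segment_len: int = 30
    max_sleep_len: int = 900  # 15 h of 1-min epochs

    def __post_init__(self) -> None:
        if self.low_activity_threshold <= 0 or self.min_segment_len <= 0 or self.max_sleep_len <= 0:
            raise ValueError("all sleep parameters must be positive")
        if self.min_segment_len >= self.max_sleep_len:
            raise ValueError("min_segment_len must be below max_sleep_len")


@dataclass(frozen=True)
class SleepInterval:
    """Half-open epoch-index interval [start_epoch, end_epoch)."""

    start_epoch: int
    end_epoch: int
    night_id: int = 0

    def __post_init__(self) -> None:
        if self.end_epoch <= self.start_epoch:
            raise ValueError("end_epoch must exceed start_epoch")

    @property
    def duration(self) -> int:
        return self.end_epoch - self.start_epoch


@dataclass(frozen=True)
class NightActivity:
    """Epoch counts inside one detected sleep interval."""

    night_id: int
    counts: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "counts", np.asarray(self.counts, dtype=float))

    def __len__(self) -> int:
        return len(self.counts)


def _runs(states: np.ndarray) -> list[tuple[int, int, int]]:
    """Maximal runs of a boolean sequence as (state, start, length)."""
    n = len(states)
    if n == 0:
        return []
    breaks = np.flatnonzero(np.diff(states.view(np.int8)) != 0) + 1
    starts = np.concatenate(([0], breaks))
    ends = np.concatenate((breaks, [n]))
    return [(int(states[s]), int(s), int(e - s)) for s, e in zip(starts, ends)]


def flip_to_fixed_point(states: np.ndarray, min_segment_len: int) -> np.ndarray:
    """Iteratively flip short interior runs to the opposite state.

    At each step the shortest run with length < ``min_segment_len`` that
    does not touch either record boundary is flipped (earlier run wins
    ties), merging it into its neighbours; repeats until no such run
    remains. Deterministic by construction.
    """
    states = np.asarray(states, dtype=bool).copy()
    while True:
        runs = _runs(states)
        candidates = [
            (length, start)
            for _, start, length in runs[1:-1]  # boundary runs exempt
            if length < min_segment_len
        ]
        if not candidates:
            return states
        length, start = min(candidates)
        states[start : start + length] = ~states[start]


def detect_sleep(series: EpochSeries, params: SleepParams = SleepParams()) -> list[SleepInterval]:
    """Detect sleep bouts; returns disjoint, sorted intervals.

    A bout may span midnight; ``night_id`` numbers the intervals in
    chronological order, not the calendar days.
    """
    if len(series) == 0:
        raise ValueError("empty series")
    rest = series.counts <= params.low_activity_threshold
    rest = flip_to_fixed_point(rest, params.min_segment_len)
    intervals = []
    for state, start, length in _runs(rest):
        if state:
            intervals.append(
                SleepInterval(start_epoch=start, end_epoch=start + length,
                              night_id=len(intervals))
            )
    return intervals


def filter_valid_sleep(
    intervals: list[SleepInterval], params: SleepParams = SleepParams()
) -> list[SleepInterval]:
    """Drop bouts longer than ``max_sleep_len`` epochs; keep the rest
    untouched (original night_ids preserved)."""
    return [iv for iv in intervals if iv.duration <= params.max_sleep_len]


def sleep_time(intervals: list[SleepInterval], epoch_len_s: int = 60) -> float:
    """Mean sleep-bout duration in minutes (``slp_tm``); NaN when no
    valid bout exists."""
    if not intervals:
        return float("nan")
    return float(np.mean([iv.duration for iv in intervals])) * epoch_len_s / 60.0


def night_slices(series: EpochSeries, intervals: list[SleepInterval]) -> list[NightActivity]:
    """Extract the count vector inside each interval, order preserved."""
    out = []
    for iv in intervals:
        if iv.start_epoch < 0 or iv.end_epoch > len(series):
            raise ValueError(f"interval [{iv.start_epoch}, {iv.end_epoch}) out of range")
        out.append(NightActivity(night_id=iv.night_id,
                                 counts=series.counts[iv.start_epoch : iv.end_epoch]))
    return out


def write_intervals_csv(path, subject_intervals: dict[str, list[SleepInterval]],
                        epoch_len_s: int = 60) -> None:
    rows = [
        {
            "subject_id": sid,
            "night_id": iv.night_id,
            "start_epoch": iv.start_epoch,
            "end_epoch": iv.end_epoch,
            "duration_min": iv.duration * epoch_len_s / 60.0,
        }
        for sid, ivs in subject_intervals.items()
        for iv in ivs
    ]
    pd.DataFrame(rows, columns=["subject_id", "night_id", "start_epoch",
                                "end_epoch", "duration_min"]).to_csv(path, index=False)
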