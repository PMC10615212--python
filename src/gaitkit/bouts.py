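"""Strides and walking bouts from gait-event logs.

Walking-bout rules follow the consensus definition used for free-living
digital mobility assessment: a bout needs at least two left and two right
valid strides, may internally contain rests of at most 3 s, and only bouts
lasting at least 10 s are analyzed. A stride is valid when its duration lies
in [0.2 s, 3 s] (bounds inclusive) and, when a length is available, the
stride is at least 0.15 m long; stride lengths come from an external source
(trajectory reconstruction is out of scope) and the length filter is skipped
when absent.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from gaitkit.core import EventKind, EventLog, Side

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class Stride:
    """One stride: two successive same-side initial contacts."""

    side: Side
    start: float  # IC time (s)
    end: float  # next same-side IC time (s)
    fc: float | None = None  # intervening FC, if exactly one was found
    length: float | None = None  # meters, externally supplied

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"stride must have start < end, got [{self.start}, {self.end}]")
        if self.fc is not None and not self.start < self.fc < self.end:
            raise ValueError("fc must lie strictly between the stride's ICs")

    @property
    def duration(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class WalkingBout:
    start: float
    end: float
    strides: tuple[Stride, ...]

    @property
    def duration(self) -> float:
        return self.end - self.start

    def n_strides(self, side: Side) -> int:
        return sum(1 for s in self.strides if s.side is side)


def strides_from_events(events: EventLog) -> dict[Side, list[Stride]]:
    """Build strides from consecutive same-side IC pairs.

    The FC is attached when exactly one same-side FC falls strictly between
    the two ICs; zero or multiple candidate FCs leave it unset (a warning is
    logged for the multiple case).
    """
    out: dict[Side, list[Stride]] = {Side.LEFT: [], Side.RIGHT: []}
    for side in Side:
        ics = events.select(side=side, kind=EventKind.IC).times()
        fcs = events.select(side=side, kind=EventKind.FC).times()
        for ic1, ic2 in zip(ics, ics[1:]):
            between = fcs[(fcs > ic1) & (fcs < ic2)]
            fc = float(between[0]) if between.size == 1 else None
            if between.size > 1:
                logger.warning(
                    "%d final contacts between %s ICs at %.2f and %.2f s; leaving fc unset",
                    between.size, side.value, ic1, ic2,
                )
            out[side].append(Stride(side, float(ic1), float(ic2), fc))
    return out


def filter_valid_strides(
    strides: list[Stride],
    min_duration: float = 0.2,
    max_duration: float = 3.0,
    min_length: float = 0.15,
) -> list[Stride]:
    """Keep strides with duration in [min_duration, max_duration] (inclusive)
    and, where a length is present, length >= min_length."""
    if any(s.length is None for s in strides):
        logger.debug("stride lengths absent; length filter skipped for those strides")
    return [
        s
        for s in strides
        if min_duration <= s.duration <= max_duration
        and (s.length is None or s.length >= min_length)
    ]


def form_walking_bouts(
    left: list[Stride],
    right: list[Stride],
    rest_threshold: float = 3.0,
) -> list[WalkingBout]:
    """Merge valid strides of both sides into walking bouts.

    Strides are pooled across sides in time order; a new bout starts whenever
    the gap from the end of all strides so far to the next stride's start
    exceeds ``rest_threshold`` (a rest of exactly the threshold is still
    contained). Segments with fewer than two strides per side are dropped.
    """
    pool = sorted(left + right, key=lambda s: (s.start, s.end))
    segments: list[list[Stride]] = []
    current: list[Stride] = []
    frontier = -float("inf")
    for s in pool:
        if current and s.start - frontier > rest_threshold:
            segments.append(current)
            current = []
        current.append(s)
        frontier = max(frontier, s.end)
    if current:
        segments.append(current)
    bouts = []
    for seg in segments:
        n_left = sum(1 for s in seg if s.side is Side.LEFT)
        n_right = len(seg) - n_left
        if n_left >= 2 and n_right >= 2:
            bouts.append(
                WalkingBout(min(s.start for s in seg), max(s.end for s in seg), tuple(seg))
            )
    return bouts


def filter_bouts(bouts: list[WalkingBout], min_duration: float = 10.0) -> list[WalkingBout]:
    """Keep bouts lasting at least ``min_duration`` seconds (inclusive)."""
    return [b for b in bouts if b.duration >= min_duration]
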