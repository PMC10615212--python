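"""Core domain types shared across the pipeline.

Time convention: seconds from recording start; sample indices are 0-based and
``time = index / rate``. Both feet share one clock.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd


class Side(str, enum.Enum):
    LEFT = "left"
    RIGHT = "right"


class EventKind(str, enum.Enum):
    IC = "IC"  # initial contact: foot first touches the ground
    FC = "FC"  # final contact: foot leaves the ground


#: Provenance labels for event streams.
EVENT_SOURCES = ("truth", "insole", "imu_ref", "fused", "predicted")


@dataclass(frozen=True)
class SamplingSpec:
    """Uniform sampling grid: ``rate`` samples per second over ``duration`` seconds."""

    rate: float = 100.0
    duration: float = 0.0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"sampling rate must be > 0, got {self.rate}")
        if self.duration <= 0:
            raise ValueError(f"duration must be > 0, got {self.duration}")

    @property
    def n_samples(self) -> int:
        return int(np.floor(self.rate * self.duration))

    def times(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.rate


@dataclass(frozen=True, order=True)
class GaitEvent:
    """A single timestamped gait event."""

    side: Side
    time: float
    kind: EventKind
    source: str = "truth"

    def __post_init__(self) -> None:
        if self.source not in EVENT_SOURCES:
            raise ValueError(f"unknown event source {self.source!r}")


class EventLog:
    """Ordered collection of :class:`GaitEvent`, sortable by (side, time).

    Within one (side, kind, source) stream times must strictly increase; the
    constructor sorts and validates this.
    """

    def __init__(self, events: Iterable[GaitEvent] = ()) -> None:
        self.events: list[GaitEvent] = sorted(events, key=lambda e: (e.side.value, e.time, e.kind.value))
        self._validate()

    def _validate(self) -> None:
        last: dict[tuple, float] = {}
        for e in self.events:
            key = (e.side, e.kind, e.source)
            if key in last and e.time <= last[key]:
                raise ValueError(
                    f"times must strictly increase within ({e.side.value}, {e.kind.value}, "
                    f"{e.source}): {e.time} after {last[key]}"
                )
            last[key] = e.time

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[GaitEvent]:
        return iter(self.events)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EventLog):
            return NotImplemented
        return self.events == other.events

    def select(self, side: Side | None = None, kind: EventKind | None = None, source: str | None = None) -> "EventLog":
        return EventLog(
            e
            for e in self.events
            if (side is None or e.side == side)
            and (kind is None or e.kind == kind)
            and (source is None or e.source == source)
        )

    def times(self) -> np.ndarray:
        return np.asarray([e.time for e in self.events], dtype=float)

    def with_source(self, source: str) -> "EventLog":
        return EventLog(GaitEvent(e.side, e.time, e.kind, source) for e in self.events)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": [e.time for e in self.events],
                "side": [e.side.value for e in self.events],
                "kind": [e.kind.value for e in self.events],
                "source": [e.source for e in self.events],
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "EventLog":
        return cls(
            GaitEvent(Side(r.side), float(r.time_s), EventKind(r.kind), str(r.source))
            for r in df.itertuples()
        )

    def __repr__(self) -> str:
        return f"EventLog(n={len(self.events)})"


#: Canonical channel order of one foot's 6-channel signal block.
FOOT_CHANNELS = ("acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z")


@dataclass
class BilateralRecording:
    """Synchronized 12-channel bilateral foot IMU time series.

    ``left`` and ``right`` are (n_samples, 6) arrays ordered as
    ``FOOT_CHANNELS``: accelerometer in m/s^2, gyroscope in deg/s.
    """

    sampling: SamplingSpec
    left: np.ndarray
    right: np.ndarray
    subject: str = ""

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        for name, arr in (("left", self.left), ("right", self.right)):
            if arr.ndim != 2 or arr.shape[1] != 6:
                raise ValueError(f"{name} foot signal must be (n_samples, 6), got {arr.shape}")
        if self.left.shape[0] != self.right.shape[0]:
            raise ValueError("left and right feet must share one clock (equal length)")

    @property
    def n_samples(self) -> int:
        return self.left.shape[0]

    def stacked(self) -> np.ndarray:
        """(n_samples, 12) array: left foot channels then right foot channels."""
        return np.hstack([self.left, self.right])

    def foot(self, side: Side) -> np.ndarray:
        return self.left if side is Side.LEFT else self.right


@dataclass
class InsoleLog:
    """Per-foot binary pressure-insole element activations on the sampling grid.

    ``left``/``right`` are (n_samples, n_elements) uint8 matrices;
    ``neighbors`` maps each element index to its spatially adjacent elements.
    """

    sampling: SamplingSpec
    left: np.ndarray
    right: np.ndarray
    neighbors: dict[int, tuple[int, ...]]

    def __post_init__(self) -> None:
        self.left = np.asarray(self.left)
        self.right = np.asarray(self.right)
        for name, arr in (("left", self.left), ("right", self.right)):
            if arr.ndim != 2:
                raise ValueError(f"{name} activation matrix must be 2-D, got {arr.shape}")
            vals = np.unique(arr)
            if not np.all(np.isin(vals, (0, 1))):
                raise ValueError(f"{name} activation entries must be 0/1")
        n_elem = self.left.shape[1]
        if set(self.neighbors) != set(range(n_elem)):
            raise ValueError("neighborhood map must cover all elements")

    @property
    def n_elements(self) -> int:
        return self.left.shape[1]

    def foot(self, side: Side) -> np.ndarray:
        return self.left if side is Side.LEFT else self.right


def grid_neighbors(n_elements: int = 16) -> dict[int, tuple[int, ...]]:
    """4-adjacency neighborhood map for elements laid out on a near-square grid."""
    ncol = int(np.ceil(np.sqrt(n_elements)))
    nrow = int(np.ceil(n_elements / ncol))
    out: dict[int, tuple[int, ...]] = {}
    for idx in range(n_elements):
        r, c = divmod(idx, ncol)
        nbrs = []
        for dr, dc in ((-1, 0), (1, 0), (0, -1), (0, 1)):
            rr, cc = r + dr, c + dc
            j = rr * ncol + cc
            if 0 <= rr < nrow and 0 <= cc < ncol and j < n_elements:
                nbrs.append(j)
        out[idx] = tuple(nbrs)
    return out
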