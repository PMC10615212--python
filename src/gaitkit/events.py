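"""Discrete gait events from per-timestep probability traces.

Peak extraction mirrors the detector's decision rule: a gait event is declared
wherever a class probability has a local maximum of at least ``min_probability``,
and maxima of the same class closer together than ``min_distance`` are pruned
keeping the higher one (earlier on ties). The distance constraint is applied
per class only: an IC and the following FC of the other phase may legitimately
be closer than 0.5 s (swing times are ~0.4 s), so cross-class pruning would
destroy valid events.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from gaitkit.core import EventKind, EventLog, GaitEvent, Side


@dataclass(frozen=True)
class PeakConfig:
    min_probability: float = 0.5  # minimum peak height
    min_distance: float = 0.5  # minimum same-class interpeak distance, seconds

    def __post_init__(self) -> None:
        if not 0.0 < self.min_probability <= 1.0:
            raise ValueError("min_probability must be in (0, 1]")
        if self.min_distance <= 0:
            raise ValueError("min_distance must be > 0")


#: probability-trace column -> (side, kind); column 0 is the null class
EVENT_CLASSES: dict[int, tuple[Side, EventKind]] = {
    1: (Side.LEFT, EventKind.IC),
    2: (Side.LEFT, EventKind.FC),
    3: (Side.RIGHT, EventKind.IC),
    4: (Side.RIGHT, EventKind.FC),
}


def _candidate_peaks(p: np.ndarray, height: float) -> np.ndarray:
    """Local-maximum sample indices; plateaus yield their first sample and
    boundary samples qualify when they dominate their one-sided neighborhood."""
    padded = np.concatenate([[-1.0], p, [-1.0]])
    _, props = find_peaks(padded, height=height, plateau_size=1)
    return props["left_edges"].astype(int) - 1


def _prune_min_distance(idx: np.ndarray, heights: np.ndarray, min_gap: float, rate: float) -> np.ndarray:
    """Keep-higher (earlier on ties) pruning of peaks closer than min_gap seconds."""
    order = sorted(range(len(idx)), key=lambda i: (-heights[i], idx[i]))
    kept: list[int] = []
    for i in order:
        if all(abs(idx[i] - idx[j]) / rate >= min_gap for j in kept):
            kept.append(i)
    return np.sort(idx[kept]) if kept else np.empty(0, dtype=int)


def detect_events(trace, cfg: PeakConfig = PeakConfig()) -> EventLog:
    """Extract predicted gait events from a probability trace.

    Parameters
    ----------
    trace : ProbabilityTrace
        Per-timestep class probabilities (columns: null, IC left, FC left,
        IC right, FC right).
    cfg : PeakConfig
        Peak height and same-class interpeak-distance constraints.
    """
    probs = np.asarray(trace.probabilities, dtype=float)
    if probs.ndim != 2 or probs.shape[1] < 1 + len(EVENT_CLASSES):
        raise ValueError(
            f"trace must have {1 + len(EVENT_CLASSES)} class columns, got shape {probs.shape}"
        )
    rate = trace.sampling.rate
    out: list[GaitEvent] = []
    for col, (side, kind) in EVENT_CLASSES.items():
        p = probs[:, col]
        idx = _candidate_peaks(p, cfg.min_probability)
        idx = _prune_min_distance(idx, p[idx], cfg.min_distance, rate)
        out.extend(GaitEvent(side, i / rate, kind, "predicted") for i in idx)
    return EventLog(out)
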