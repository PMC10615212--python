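"""Reference gait events from pressure insoles, fused with an external
IMU-based event stream (insole priority).

Foot-ground contact is declared while at least ``min_elements`` sensing
elements forming one spatial neighborhood — a connected component of the
element adjacency graph — are simultaneously active. Each maximal contact run
emits an initial contact at its first sample and a final contact at its last.
A 4-adjacency grid contains no 3-cliques, so "same spatial neighborhood" is
interpreted as connectivity, not mutual adjacency: three pairwise
non-adjacent active elements never qualify.
"""

from __future__ import annotations

import numpy as np

from gaitkit.core import EventKind, EventLog, GaitEvent, InsoleLog, Side
from gaitkit.metrics import greedy_pairs

#: contact runs shorter than this are discarded as sensor bounce
DEFAULT_DEBOUNCE = 0.03  # seconds


def _has_component(active: np.ndarray, neighbors: dict[int, tuple[int, ...]], k: int) -> bool:
    """True if the active elements contain a connected component of size >= k."""
    todo = set(np.flatnonzero(active))
    while todo:
        stack = [todo.pop()]
        size = 0
        while stack:
            el = stack.pop()
            size += 1
            for nb in neighbors[el]:
                if nb in todo:
                    todo.discard(nb)
                    stack.append(nb)
        if size >= k:
            return True
    return False


def _contact_mask(mat: np.ndarray, neighbors: dict[int, tuple[int, ...]], k: int) -> np.ndarray:
    """Per-sample contact condition, evaluated once per run of identical rows."""
    n = mat.shape[0]
    if n == 0:
        return np.zeros(0, dtype=bool)
    change = np.ones(n, dtype=bool)
    change[1:] = np.any(mat[1:] != mat[:-1], axis=1)
    starts = np.flatnonzero(change)
    ends = np.append(starts[1:], n)
    out = np.zeros(n, dtype=bool)
    for s, e in zip(starts, ends):
        if mat[s].sum() >= k and _has_component(mat[s], neighbors, k):
            out[s:e] = True
    return out


def insole_contacts(
    log: InsoleLog, min_elements: int = 3, debounce: float = DEFAULT_DEBOUNCE
) -> EventLog:
    """Reference IC/FC events from insole element activations.

    A contact interval opens at the first sample where >= ``min_elements``
    mutually connected elements are active and closes when the condition
    lapses; the interval start is emitted as IC and its end as FC, at
    sample/rate resolution. Runs shorter than ``debounce`` seconds are
    discarded as bounce.
    """
    rate = log.sampling.rate
    min_run = max(int(np.ceil(debounce * rate)), 1)
    events: list[GaitEvent] = []
    for side in Side:
        mask = _contact_mask(log.foot(side), log.neighbors, min_elements)
        padded = np.concatenate([[False], mask, [False]])
        edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
        for start, stop in zip(edges[::2], edges[1::2]):
            if stop - start < min_run:
                continue
            events.append(GaitEvent(side, start / rate, EventKind.IC, "insole"))
            events.append(GaitEvent(side, (stop - 1) / rate, EventKind.FC, "insole"))
    return EventLog(events)


def fuse_events(
    insole: EventLog, imu_ref: EventLog, pairing_tolerance: float = 0.25
) -> EventLog:
    """Union of insole and IMU reference events with insole priority.

    Events of the same side and kind within ``pairing_tolerance`` are paired
    one-to-one (greedy by ascending absolute difference); for each pair the
    insole timing is kept. Unpaired events from either source pass through
    unchanged. The fused log size is |insole| + |imu_ref| - #pairs.
    """
    fused: list[GaitEvent] = []
    for side in Side:
        for kind in EventKind:
            pi = sorted(insole.select(side=side, kind=kind).events, key=lambda e: e.time)
            imu = sorted(imu_ref.select(side=side, kind=kind).events, key=lambda e: e.time)
            pt = np.asarray([e.time for e in pi])
            it = np.asarray([e.time for e in imu])
            pairs = greedy_pairs(pt, it, pairing_tolerance)
            paired_imu = {j for _, j in pairs}
            fused.extend(GaitEvent(side, e.time, kind, "fused") for e in pi)
            fused.extend(
                GaitEvent(side, e.time, kind, "fused")
                for j, e in enumerate(imu)
                if j not in paired_imu
            )
    return EventLog(fused)
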