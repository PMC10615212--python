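"""CSV readers/writers, dataset splitting, and config handling.

All files are comma-separated UTF-8 with a mandatory header row; metadata
(config hash, root seed, sampling rate) travels in ``#``-prefixed comment
lines before the header. Time is seconds from recording start.

Schemas
-------
recording: ``time_s, foot, acc_x, acc_y, acc_z, gyr_x, gyr_y, gyr_z``
           (long format, one row per foot per sample; accel m/s^2, gyro deg/s)
events:    ``time_s, side, kind, source`` with kind in {IC, FC}
insole:    ``time_s, foot, element_id, active`` with active in {0, 1}
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitkit.core import (
    BilateralRecording,
    EventLog,
    InsoleLog,
    SamplingSpec,
    Side,
    grid_neighbors,
)

RATE_TOLERANCE = 1e-6  # seconds of allowed deviation of each time step


def config_hash(config: dict) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def _write_with_header(df: pd.DataFrame, path, header: dict | None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for key, value in (header or {}).items():
            fh.write(f"# {key}: {value}\n")
        df.to_csv(fh, index=False)


def read_header(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition(":")
            meta[key.strip()] = value.strip()
    return meta


# ---------------------------------------------------------------------------
# recordings

_CHANNELS = ["acc_x", "acc_y", "acc_z", "gyr_x", "gyr_y", "gyr_z"]


def write_recording(rec: BilateralRecording, path, header: dict | None = None) -> None:
    t = rec.sampling.times()
    frames = []
    for side in Side:
        df = pd.DataFrame(rec.foot(side), columns=_CHANNELS)
        df.insert(0, "foot", side.value)
        df.insert(0, "time_s", t)
        frames.append(df)
    out = pd.concat(frames).sort_values(["time_s", "foot"], kind="stable")
    meta = {"rate_hz": rec.sampling.rate, "n_samples": rec.n_samples, "subject": rec.subject}
    meta.update(header or {})
    _write_with_header(out, path, meta)


def read_recording(path) -> BilateralRecording:
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "foot", *_CHANNELS} - set(df.columns)
    if missing:
        raise ValueError(f"recording file missing columns: {sorted(missing)}")
    if df[_CHANNELS].isna().any().any():
        row = int(df[df[_CHANNELS].isna().any(axis=1)].index[0])
        raise ValueError(f"incomplete channel data at row {row}")
    feet = {}
    for side in Side:
        sub = df[df["foot"] == side.value].sort_index()
        if sub.empty:
            raise ValueError(f"recording file has no rows for the {side.value} foot")
        t = sub["time_s"].to_numpy()
        dt = np.diff(t)
        if np.any(dt <= 0):
            row = int(sub.index[1:][dt <= 0][0])
            raise ValueError(f"non-monotone time at row {row}")
        rate = 1.0 / np.median(dt)
        drift = np.abs(dt - 1.0 / rate)
        if np.any(drift > RATE_TOLERANCE):
            row = int(sub.index[1:][drift > RATE_TOLERANCE][0])
            raise ValueError(f"sampling-rate drift at row {row}: step {dt[drift > RATE_TOLERANCE][0]:.6f} s")
        feet[side] = (sub[_CHANNELS].to_numpy(), rate, len(sub))
    (left, rate_l, n_l), (right, rate_r, n_r) = feet[Side.LEFT], feet[Side.RIGHT]
    if n_l != n_r or abs(rate_l - rate_r) > RATE_TOLERANCE:
        raise ValueError("left and right feet must share one clock")
    meta = read_header(path)
    sampling = SamplingSpec(rate=round(rate_l, 6), duration=n_l / round(rate_l, 6))
    return BilateralRecording(sampling, left, right, subject=meta.get("subject", ""))


# ---------------------------------------------------------------------------
# events

def write_events(events: EventLog, path, header: dict | None = None) -> None:
    _write_with_header(events.to_frame(), path, header)


def read_events(path) -> EventLog:
    df = pd.read_csv(path, comment="#")
    missing = {"time_s", "side", "kind", "source"} - set(df.columns)
    if missing:
        raise ValueError(f"events file missing columns: {sorted(missing)}")
    return EventLog.from_frame(df)


# ---------------------------------------------------------------------------
# insole

def write_insole(log: InsoleLog, path, header: dict | None = None) -> None:
    t = log.sampling.times()
    frames = []
    for side in Side:
        mat = log.foot(side)
        sample, elem = np.nonzero(mat)
        frames.append(
            pd.DataFrame(
                {"time_s": t[sample], "foot": side.value, "element_id": elem, "active": 1}
            )
        )
    out = pd.concat(frames).sort_values(["time_s", "foot", "element_id"], kind="stable")
    meta = {
        "rate_hz": log.sampling.rate,
        "n_samples": log.sampling.n_samples,
        "n_elements": log.n_elements,
    }
    meta.update(header or {})
    _write_with_header(out, path, meta)


def read_insole(path) -> InsoleLog:
    meta = read_header(path)
    rate = float(meta["rate_hz"])
    n_samples = int(meta["n_samples"])
    n_elements = int(meta["n_elements"])
    df = pd.read_csv(path, comment="#")
    sampling = SamplingSpec(rate=rate, duration=n_samples / rate)
    mats = {}
    for side in Side:
        mat = np.zeros((n_samples, n_elements), dtype=np.uint8)
        sub = df[(df["foot"] == side.value) & (df["active"] == 1)]
        idx = np.round(sub["time_s"].to_numpy() * rate).astype(int)
        mat[idx, sub["element_id"].to_numpy(dtype=int)] = 1
        mats[side] = mat
    return InsoleLog(sampling, mats[Side.LEFT], mats[Side.RIGHT], grid_neighbors(n_elements))


# ---------------------------------------------------------------------------
# dataset splitting

@dataclass(frozen=True)
class DatasetSplit:
    """Disjoint, exhaustive assignment of subjects to training/validation/testing."""

    assignment: dict[str, str]

    def subjects(self, set_name: str) -> list[str]:
        return sorted(s for s, name in self.assignment.items() if name == set_name)

    @property
    def training(self) -> list[str]:
        return self.subjects("training")

    @property
    def validation(self) -> list[str]:
        return self.subjects("validation")

    @property
    def testing(self) -> list[str]:
        return self.subjects("testing")


def split_dataset(
    subjects: list[str],
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
    groups: dict[str, str] | None = None,
) -> DatasetSplit:
    """Randomly assign subjects to training/validation/testing.

    Validation and testing sizes are floors of their fractions (per stratum
    when ``groups`` labels are given); the remainder goes to training.
    Deterministic given the seed.
    """
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    rng = np.random.default_rng(seed)
    strata: dict[str, list[str]] = {}
    for s in subjects:
        strata.setdefault(groups.get(s, "") if groups else "", []).append(s)
    assignment: dict[str, str] = {}
    for _, members in sorted(strata.items()):
        members = sorted(members)
        rng.shuffle(members)
        n = len(members)
        n_val = int(np.floor(fractions[1] * n))
        n_test = int(np.floor(fractions[2] * n))
        n_train = n - n_val - n_test
        for i, s in enumerate(members):
            if i < n_train:
                assignment[s] = "training"
            elif i < n_train + n_val:
                assignment[s] = "validation"
            else:
                assignment[s] = "testing"
    return DatasetSplit(assignment)
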