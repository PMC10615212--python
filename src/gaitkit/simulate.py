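"""Synthetic bilateral gait: ground-truth event schedules, foot IMU signals,
and pressure-insole activations.

The generator produces quasi-periodic stride sequences with per-stride timing
variability, an approximately half-cycle contralateral phase offset, rests
between bouts, arbitrary sensor-to-segment orientation, and event-locked
signal signatures (an impact transient at each initial contact, a mid-swing
angular-velocity lobe). It supplies the training and evaluation data for the
event detector; it does not claim biomechanical fidelity beyond those
event-locked features.

Ground-truth event times are snapped to the sampling grid so that a
zero-jitter insole log round-trips exactly through the reference pipeline.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.transform import Rotation

from gaitkit.core import (
    BilateralRecording,
    EventKind,
    EventLog,
    GaitEvent,
    InsoleLog,
    SamplingSpec,
    Side,
    grid_neighbors,
)

_STANCE_FRACTION_BOUNDS = (0.05, 0.95)
_MAX_RESAMPLES = 100


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of one synthetic subject's recording.

    Defaults emulate free-living walking of older adults: stride times around
    1.3 s, stance occupying ~70% of the stride, and rests between bouts long
    enough (>3 s) that bout segmentation is exercised.
    """

    seed: int = 0
    n_bouts: int = 3
    strides_per_bout: tuple[int, int] = (8, 12)
    cadence: tuple[float, float] = (1.0 / 1.30, 0.02)  # strides/s per foot: (mean, sd)
    stance_fraction: tuple[float, float] = (0.70, 0.02)  # fraction of stride: (mean, sd)
    phase_offset: float = 0.5  # contralateral IC offset as fraction of stride
    rest_duration: tuple[float, float] = (4.0, 8.0)  # seconds, uniform range
    orientation: str | dict = "random"  # "random", "identity", or {side: rotvec (rad)}
    noise_sd_accel: float = 0.3  # m/s^2
    noise_sd_gyro: float = 3.0  # deg/s
    insole_elements: int = 16
    insole_jitter_sd: float = 0.0  # seconds
    insole_dropout_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.stance_fraction[0] < 1.0:
            raise ValueError("stance_fraction mean must be in (0, 1)")
        if self.cadence[0] <= 0:
            raise ValueError("cadence mean must be > 0")
        if self.insole_elements < 3:
            raise ValueError("insole needs at least 3 elements")
        if not 0.0 <= self.phase_offset < 1.0:
            raise ValueError("phase_offset must be in [0, 1)")

    def replace(self, **kw) -> "SimulationConfig":
        return dataclasses.replace(self, **kw)


def _rng(cfg: SimulationConfig, stream: int) -> np.random.Generator:
    # independent, reproducible streams per operation so the same config
    # yields the same schedule regardless of which signals are synthesized
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=(stream,)))


def _sample_stance_fraction(rng: np.random.Generator, mean: float, sd: float) -> float:
    lo, hi = _STANCE_FRACTION_BOUNDS
    for _ in range(_MAX_RESAMPLES):
        f = rng.normal(mean, sd)
        if lo < f < hi:
            return f
    raise RuntimeError(
        f"could not sample a stance fraction in ({lo}, {hi}) after {_MAX_RESAMPLES} tries"
    )


def _raw_schedule(cfg: SimulationConfig, rate: float) -> list[GaitEvent]:
    """Un-validated schedule; times already snapped to the sampling grid."""
    rng = _rng(cfg, stream=0)
    mean_cad, sd_cad = cfg.cadence
    events: list[GaitEvent] = []
    t = 1.0  # lead-in rest before the first bout
    for _ in range(cfg.n_bouts):
        lo, hi = cfg.strides_per_bout
        n_strides = int(rng.integers(lo, hi + 1))
        # left-foot stride durations drive both feet; the right foot walks at
        # the same rhythm, offset by phase_offset of the concurrent stride
        strides = 1.0 / np.maximum(rng.normal(mean_cad, sd_cad, size=n_strides + 1), 1e-3)
        left_ics = t + np.concatenate([[0.0], np.cumsum(strides[:-1])])
        right_ics = left_ics + cfg.phase_offset * strides
        for side, ics in ((Side.LEFT, left_ics), (Side.RIGHT, right_ics)):
            ic_next = np.append(ics[1:], ics[-1] + strides[-1])
            for ic, nxt in zip(ics, ic_next):
                frac = _sample_stance_fraction(rng, *cfg.stance_fraction)
                fc = ic + frac * (nxt - ic)
                events.append(GaitEvent(side, ic, EventKind.IC))
                events.append(GaitEvent(side, fc, EventKind.FC))
        t = max(e.time for e in events) + rng.uniform(*cfg.rest_duration)
    snapped = [
        GaitEvent(e.side, round(e.time * rate) / rate, e.kind, "truth") for e in events
    ]
    return snapped


def schedule_span(cfg: SimulationConfig, rate: float = 100.0) -> float:
    """Duration (s) that comfortably contains the schedule for this config."""
    last = max(e.time for e in _raw_schedule(cfg, rate))
    return float(np.ceil(last + 2.0))


def event_schedule(cfg: SimulationConfig, sampling: SamplingSpec) -> EventLog:
    """Ground-truth alternating IC/FC schedule for both feet.

    Stride time is 1/cadence with per-stride Gaussian variation, stance time
    is stance_fraction x stride time, and contralateral initial contacts are
    offset by phase_offset x stride time. Deterministic given the seed.
    """
    events = _raw_schedule(cfg, sampling.rate)
    last = max(e.time for e in events)
    if last >= sampling.duration:
        raise ValueError(
            f"schedule extends to {last:.2f} s but sampling covers only "
            f"{sampling.duration:.2f} s; use schedule_span() to size the recording"
        )
    return EventLog(events)


def _hann_lobe(t: np.ndarray, center: float, width: float, amplitude: float) -> np.ndarray:
    """Raised-cosine lobe supported on [center - width/2, center + width/2]."""
    x = (t - center) / width + 0.5
    lobe = np.where((x >= 0) & (x <= 1), 0.5 - 0.5 * np.cos(2 * np.pi * np.clip(x, 0, 1)), 0.0)
    return amplitude * lobe


def _foot_rotation(cfg: SimulationConfig, side: Side, rng: np.random.Generator) -> Rotation:
    if isinstance(cfg.orientation, dict):
        return Rotation.from_rotvec(np.asarray(cfg.orientation[side.value], dtype=float))
    if cfg.orientation == "identity":
        return Rotation.identity()
    if cfg.orientation == "random":
        return Rotation.random(rng=rng)
    raise ValueError(f"unknown orientation spec {cfg.orientation!r}")


# template amplitudes; typical of foot-worn sensors during comfortable walking
_SWING_GYRO_AMP = 300.0  # deg/s, mid-swing mediolateral lobe
_EVENT_GYRO_AMP = -120.0  # deg/s, short negative lobes at IC and FC
_IC_IMPACT_AMP = 8.0  # m/s^2, damped impact transient at IC
_IC_IMPACT_FREQ = 18.0  # Hz
_IC_IMPACT_TAU = 0.05  # s
_GRAVITY = 9.80665  # m/s^2


def synthesize_foot_signals(
    events: EventLog,
    side: Side,
    cfg: SimulationConfig,
    sampling: SamplingSpec,
) -> np.ndarray:
    """(n_samples, 6) accelerometer + gyroscope signal for one foot.

    Body-frame template: gravity on the accelerometer z axis plus a damped
    high-frequency transient at each IC; the mediolateral gyroscope axis
    carries a positive mid-swing lobe between each FC and the next IC and
    short negative lobes at the events themselves. The whole 3-D signal is
    then rotated by the foot's (arbitrary) sensor-to-segment orientation and
    white noise is added, so the detector cannot rely on axis alignment.
    """
    rng = _rng(cfg, stream=1 if side is Side.LEFT else 2)
    t = sampling.times()
    n = t.size
    foot_events = events.select(side=side)
    times = foot_events.times()
    if times.size and (times.min() < 0 or times.max() >= sampling.duration):
        raise ValueError("events fall outside the sampling span")

    accel = np.zeros((n, 3))
    gyro = np.zeros((n, 3))
    accel[:, 2] = _GRAVITY

    ics = foot_events.select(kind=EventKind.IC).times()
    fcs = foot_events.select(kind=EventKind.FC).times()
    # mid-swing lobe for every swing phase FC -> next IC
    for fc in fcs:
        nxt = ics[ics > fc]
        if nxt.size == 0:
            continue
        ic_next = nxt[0]
        swing = ic_next - fc
        gyro[:, 1] += _hann_lobe(t, fc + 0.5 * swing, 0.6 * swing, _SWING_GYRO_AMP)
    for ev in np.concatenate([ics, fcs]) if (ics.size or fcs.size) else []:
        gyro[:, 1] += _hann_lobe(t, ev, 0.12, _EVENT_GYRO_AMP)
    # damped impact transient at each IC on the accelerometer
    for ic in ics:
        rel = t - ic
        mask = (rel >= 0) & (rel < 6 * _IC_IMPACT_TAU)
        burst = np.zeros(n)
        burst[mask] = (
            _IC_IMPACT_AMP
            * np.exp(-rel[mask] / _IC_IMPACT_TAU)
            * np.sin(2 * np.pi * _IC_IMPACT_FREQ * rel[mask])
        )
        accel[:, 2] += burst
        accel[:, 0] += 0.5 * burst

    rot = _foot_rotation(cfg, side, rng)
    accel = rot.apply(accel)
    gyro = rot.apply(gyro)
    accel += rng.normal(0.0, cfg.noise_sd_accel, size=accel.shape)
    gyro += rng.normal(0.0, cfg.noise_sd_gyro, size=gyro.shape)
    return np.hstack([accel, gyro])


def _stance_intervals(events: EventLog, side: Side) -> list[tuple[float, float]]:
    """(IC, FC) stance intervals from an alternating ground-truth stream."""
    foot = events.select(side=side)
    ics = foot.select(kind=EventKind.IC).times()
    fcs = foot.select(kind=EventKind.FC).times()
    intervals: list[tuple[float, float]] = []
    for ic in ics:
        after = fcs[fcs > ic]
        if after.size:
            intervals.append((float(ic), float(after[0])))
    for (a0, b0), (a1, _b1) in zip(intervals, intervals[1:]):
        if a1 < b0:
            raise ValueError(
                f"overlapping stance intervals on {side.value} foot: [{a0}, {b0}] and IC at {a1}"
            )
    return intervals


def simulate_insole(cfg_events: EventLog, cfg: SimulationConfig, sampling: SamplingSpec) -> InsoleLog:
    """Binary element activations spanning each ground-truth stance phase.

    Each element switches on at IC + jitter and off at FC + jitter (Gaussian,
    independent per element and event, truncated so activation precedes
    deactivation); elements drop out whole stances with insole_dropout_prob.
    Activation covers samples round(on*rate)..round(off*rate) inclusive.
    """
    rng = _rng(cfg, stream=3)
    n = sampling.n_samples
    mats = {}
    for side in (Side.LEFT, Side.RIGHT):
        mat = np.zeros((n, cfg.insole_elements), dtype=np.uint8)
        for ic, fc in _stance_intervals(cfg_events, side):
            for el in range(cfg.insole_elements):
                dropped = rng.random() < cfg.insole_dropout_prob
                j_on = rng.normal(0.0, cfg.insole_jitter_sd)
                j_off = rng.normal(0.0, cfg.insole_jitter_sd)
                if dropped:
                    continue
                for _ in range(_MAX_RESAMPLES):
                    if ic + j_on < fc + j_off:
                        break
                    j_on = rng.normal(0.0, cfg.insole_jitter_sd)
                    j_off = rng.normal(0.0, cfg.insole_jitter_sd)
                a = int(round((ic + j_on) * sampling.rate))
                b = int(round((fc + j_off) * sampling.rate))
                a, b = max(a, 0), min(b, n - 1)
                if a <= b:
                    mat[a : b + 1, el] = 1
        mats[side] = mat
    return InsoleLog(sampling, mats[Side.LEFT], mats[Side.RIGHT], grid_neighbors(cfg.insole_elements))


def simulate_recording(
    cfg: SimulationConfig, rate: float = 100.0, subject: str = ""
) -> tuple[BilateralRecording, EventLog, InsoleLog]:
    """Convenience: schedule + both feet's signals + insole log for one subject."""
    sampling = SamplingSpec(rate=rate, duration=schedule_span(cfg, rate))
    events = event_schedule(cfg, sampling)
    left = synthesize_foot_signals(events, Side.LEFT, cfg, sampling)
    right = synthesize_foot_signals(events, Side.RIGHT, cfg, sampling)
    insole = simulate_insole(events, cfg, sampling)
    return BilateralRecording(sampling, left, right, subject=subject), events, insole
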