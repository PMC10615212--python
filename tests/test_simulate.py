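"""Synthetic gait generator: schedule timing, signal templates, insole model."""

import numpy as np
import pytest

from gaitkit.core import EventKind, SamplingSpec, Side
from gaitkit.metrics import temporal_params
from gaitkit.simulate import (
    SimulationConfig,
    event_schedule,
    schedule_span,
    simulate_insole,
    simulate_recording,
    synthesize_foot_signals,
)


def _sampling(cfg, rate=100.0):
    return SamplingSpec(rate=rate, duration=schedule_span(cfg, rate))


class TestEventSchedule:
    def test_deterministic_given_seed(self, clean_cfg):
        s = _sampling(clean_cfg)
        assert event_schedule(clean_cfg, s) == event_schedule(clean_cfg, s)

    def test_different_seed_differs(self, clean_cfg):
        s = _sampling(clean_cfg)
        other = clean_cfg.replace(seed=clean_cfg.seed + 1)
        assert event_schedule(clean_cfg, s) != event_schedule(other, _sampling(other))

    def test_constant_gait_yields_printed_stance_swing_stride(self):
        # cadence 1/1.34 strides/s with 69.4% stance -> the (0.93, 0.41, 1.34) s
        # triple of a slow-walking cohort, exact on the 100 Hz grid
        cfg = SimulationConfig(
            seed=0, n_bouts=1, strides_per_bout=(5, 5),
            cadence=(1 / 1.34, 0.0), stance_fraction=(0.694, 0.0),
        )
        events, _ = event_schedule(cfg, _sampling(cfg)), None
        params = temporal_params(event_schedule(cfg, _sampling(cfg)))
        assert params, "no strides generated"
        for p in params:
            assert p.stride == pytest.approx(1.34, abs=1e-9)
            assert p.stance == pytest.approx(0.93, abs=1e-9)
            assert p.swing == pytest.approx(0.41, abs=1e-9)

    def test_contralateral_phase_offset(self):
        cfg = SimulationConfig(
            seed=1, n_bouts=1, strides_per_bout=(4, 4),
            cadence=(1 / 1.2, 0.0), phase_offset=0.5,
        )
        ev = event_schedule(cfg, _sampling(cfg))
        left = ev.select(side=Side.LEFT, kind=EventKind.IC).times()
        right = ev.select(side=Side.RIGHT, kind=EventKind.IC).times()
        np.testing.assert_allclose(right - left, 0.6, atol=1e-9)

    def test_stance_plus_swing_equals_stride_exactly(self, schedule):
        events, _ = schedule
        for p in temporal_params(events):
            assert p.stance + p.swing == pytest.approx(p.stride, abs=1e-12)

    def test_events_alternate_ic_fc_per_foot(self, schedule):
        events, _ = schedule
        for side in Side:
            kinds = [e.kind for e in sorted(events.select(side=side).events, key=lambda e: e.time)]
            assert all(k == (EventKind.IC if i % 2 == 0 else EventKind.FC) for i, k in enumerate(kinds))

    def test_impossible_stance_fraction_raises(self):
        cfg = SimulationConfig(seed=0, stance_fraction=(0.5, 1e6))  # almost never in (0.05, 0.95)
        with pytest.raises(RuntimeError, match="stance fraction"):
            event_schedule(cfg, SamplingSpec(duration=120.0))

    def test_schedule_longer_than_recording_raises(self, clean_cfg):
        with pytest.raises(ValueError, match="schedule extends"):
            event_schedule(clean_cfg, SamplingSpec(rate=100.0, duration=2.0))


class TestFootSignals:
    def test_gravity_only_without_events(self, clean_cfg):
        from gaitkit.core import EventLog

        sampling = SamplingSpec(rate=100.0, duration=5.0)
        sig = synthesize_foot_signals(EventLog(), Side.LEFT, clean_cfg, sampling)
        np.testing.assert_allclose(np.linalg.norm(sig[:, :3], axis=1), 9.80665, atol=1e-9)
        np.testing.assert_allclose(sig[:, 3:], 0.0, atol=1e-12)

    def test_one_midswing_gyro_maximum_per_swing(self, clean_cfg, schedule):
        events, sampling = schedule
        sig = synthesize_foot_signals(events, Side.LEFT, clean_cfg, sampling)
        gyro_ml = sig[:, 4]  # identity orientation: mediolateral axis
        foot = events.select(side=Side.LEFT)
        fcs = foot.select(kind=EventKind.FC).times()
        ics = foot.select(kind=EventKind.IC).times()
        t = sampling.times()
        checked = 0
        for fc in fcs:
            nxt = ics[ics > fc]
            if nxt.size == 0:
                continue
            # interior of the swing, away from the event lobes
            win = (t > fc + 0.1) & (t < nxt[0] - 0.1)
            seg = gyro_ml[win]
            interior = seg[1:-1]
            peaks = np.sum((interior > seg[:-2]) & (interior >= seg[2:]))
            assert peaks == 1
            checked += 1
        assert checked > 0

    def test_rotation_preserves_accelerometer_norm(self, clean_cfg, schedule):
        events, sampling = schedule
        rotated = clean_cfg.replace(orientation={"left": [0.3, -1.2, 2.0], "right": [0.0, 0.0, 0.0]})
        a = synthesize_foot_signals(events, Side.LEFT, clean_cfg, sampling)
        b = synthesize_foot_signals(events, Side.LEFT, rotated, sampling)
        np.testing.assert_allclose(
            np.linalg.norm(a[:, :3], axis=1), np.linalg.norm(b[:, :3], axis=1), atol=1e-9
        )

    def test_event_outside_span_raises(self, clean_cfg, schedule):
        events, _ = schedule
        with pytest.raises(ValueError, match="outside the sampling span"):
            synthesize_foot_signals(events, Side.LEFT, clean_cfg, SamplingSpec(duration=3.0))


class TestInsole:
    def test_zero_jitter_covers_stance_samples_exactly(self):
        from gaitkit.core import EventLog, GaitEvent

        cfg = SimulationConfig(seed=0, insole_jitter_sd=0.0, insole_dropout_prob=0.0)
        sampling = SamplingSpec(rate=100.0, duration=4.0)
        events = EventLog(
            [GaitEvent(Side.LEFT, 1.00, EventKind.IC), GaitEvent(Side.LEFT, 1.93, EventKind.FC)]
        )
        log = simulate_insole(events, cfg, sampling)
        active = np.flatnonzero(log.left.all(axis=1))
        np.testing.assert_array_equal(active, np.arange(100, 194))
        assert not log.right.any()

    def test_full_dropout_gives_empty_matrix(self, clean_cfg, schedule):
        events, sampling = schedule
        log = simulate_insole(events, clean_cfg.replace(insole_dropout_prob=1.0), sampling)
        assert not log.left.any() and not log.right.any()

    def test_overlapping_stance_raises(self):
        from gaitkit.core import EventLog, GaitEvent

        events = EventLog(
            [
                GaitEvent(Side.LEFT, 1.0, EventKind.IC),
                GaitEvent(Side.LEFT, 1.5, EventKind.IC),
                GaitEvent(Side.LEFT, 2.0, EventKind.FC),
                GaitEvent(Side.LEFT, 2.5, EventKind.FC),
            ]
        )
        cfg = SimulationConfig(seed=0)
        with pytest.raises(ValueError, match="[Oo]verlapping"):
            simulate_insole(events, cfg, SamplingSpec(duration=5.0))

    def test_element_activation_jitter_is_unbiased(self):
        # ~1000 stance intervals with 10 ms jitter: the mean per-element
        # activation-onset offset from the true IC is 0 within 3 standard errors
        cfg = SimulationConfig(
            seed=7, n_bouts=8, strides_per_bout=(32, 32),
            insole_jitter_sd=0.01, insole_dropout_prob=0.0,
        )
        sampling = SamplingSpec(rate=100.0, duration=schedule_span(cfg))
        events = event_schedule(cfg, sampling)
        log = simulate_insole(events, cfg, sampling)
        offsets = []
        for side in Side:
            mat = log.foot(side)
            ics = events.select(side=side, kind=EventKind.IC).times()
            for el in range(cfg.insole_elements):
                col = np.flatnonzero(np.diff(np.concatenate([[0], mat[:, el]])) == 1)
                onsets = col / sampling.rate
                for ic in ics:
                    j = np.argmin(np.abs(onsets - ic))
                    offsets.append(onsets[j] - ic)
        offsets = np.asarray(offsets)
        se = offsets.std(ddof=1) / np.sqrt(offsets.size)
        assert abs(offsets.mean()) < 3 * se + 1e-4  # grid quantization guard

    def test_deterministic_given_seed(self, clean_cfg):
        a = simulate_recording(clean_cfg)
        b = simulate_recording(clean_cfg)
        np.testing.assert_array_equal(a[0].left, b[0].left)
        np.testing.assert_array_equal(a[2].left, b[2].left)
        assert a[1] == b[1]


def test_config_invariants_rejected():
    with pytest.raises(ValueError):
        SimulationConfig(stance_fraction=(1.2, 0.0))
    with pytest.raises(ValueError):
        SimulationConfig(cadence=(-1.0, 0.0))
    with pytest.raises(ValueError):
        SimulationConfig(insole_elements=2)
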