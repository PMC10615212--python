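"""Evaluation layer: matching (with a brute-force oracle), detection scores,
time errors, temporal parameters, and Bland-Altman agreement."""

import itertools
import math

import numpy as np
import pytest

from gaitkit.core import EventKind, EventLog, GaitEvent, Side
from gaitkit.metrics import (
    absolute_relative_errors,
    agreement,
    detection_scores,
    greedy_pairs,
    match_events,
    paired_stride_params,
    temporal_params,
    time_errors,
)


def _log(times, kind=EventKind.IC, side=Side.LEFT, source="truth"):
    return EventLog(GaitEvent(side, t, kind, source) for t in times)


def brute_force_pairs(a, b, tol):
    """Oracle: exhaustive one-to-one assignment, maximizing pair count and
    breaking ties by minimal total absolute error."""
    best = (0, 0.0, [])
    n, m = len(a), len(b)
    for k in range(min(n, m), -1, -1):
        found = False
        for ai in itertools.combinations(range(n), k):
            for bj in itertools.permutations(range(m), k):
                if all(abs(a[i] - b[j]) <= tol for i, j in zip(ai, bj)):
                    cost = sum(abs(a[i] - b[j]) for i, j in zip(ai, bj))
                    if not found or cost < best[1] - 1e-12:
                        best = (k, cost, sorted(zip(ai, bj)))
                        found = True
        if found:
            break
    return best


class TestMatching:
    def test_tolerance_is_inclusive(self):
        m = match_events(_log([5.00]), _log([5.25], source="predicted"))
        assert m.tp == 1 and m.fn == 0 and m.fp == 0

    def test_just_outside_tolerance(self):
        m = match_events(_log([5.00]), _log([5.26], source="predicted"))
        assert (m.tp, m.fn, m.fp) == (0, 1, 1)

    def test_greedy_prefers_smaller_error(self):
        m = match_events(_log([5.00]), _log([4.90, 5.05], source="predicted"))
        assert m.tp == 1 and m.fp == 1
        ref, pred = m.pairs[0]
        assert pred.time == 5.05
        assert m.unmatched_predicted[0].time == 4.90

    def test_no_matching_across_sides_or_kinds(self):
        ref = _log([1.0], side=Side.LEFT)
        pred = _log([1.0], side=Side.RIGHT, source="predicted")
        m = match_events(ref, pred)
        assert (m.tp, m.fn, m.fp) == (0, 1, 1)

    def test_count_identities(self):
        ref = _log([1.0, 2.2, 3.4, 4.6])
        pred = _log([1.05, 2.18, 7.0], source="predicted")
        m = match_events(ref, pred)
        assert m.tp + m.fn == len(ref)
        assert m.tp + m.fp == len(pred)

    def test_symmetry_negates_errors_and_swaps_fn_fp(self):
        ref = _log([1.0, 2.2, 3.4])
        pred = _log([1.05, 3.39, 5.0], source="predicted")
        a = match_events(ref, pred)
        b = match_events(pred, ref)
        np.testing.assert_allclose(np.sort(a.errors), np.sort(-b.errors))
        assert (a.fn, a.fp) == (b.fp, b.fn)

    def test_greedy_equals_brute_force_on_gait_like_streams(self):
        """1,000 random instances with detector-consistent spacing (>= 0.5 s
        within each stream, twice the 0.25 s tolerance): the greedy matching
        equals the exhaustive optimal assignment."""
        rng = np.random.default_rng(12345)
        tol = 0.25
        for _ in range(1000):
            n_ref, n_pred = rng.integers(0, 7, size=2)
            ref = np.cumsum(rng.uniform(0.5, 2.0, size=n_ref)) if n_ref else np.empty(0)
            pred = np.sort(rng.uniform(-0.5, (ref[-1] if n_ref else 2.0) + 0.5, size=n_pred))
            while pred.size > 1 and np.min(np.diff(pred)) < 0.5:  # enforce interpeak distance
                pred = np.delete(pred, np.argmin(np.diff(pred)) + 1)
            got = greedy_pairs(ref, pred, tol)
            k, cost, pairs = brute_force_pairs(ref, pred, tol)
            assert len(got) == k
            assert sum(abs(ref[i] - pred[j]) for i, j in got) == pytest.approx(cost, abs=1e-12)


class TestDetectionScores:
    def test_published_cohort_row_slow_walking(self):
        # worked example: 408 TP, 3 FN, 18 FP -> recall 99%, precision 96%
        s = detection_scores(tp=408, fn=3, fp=18)
        assert s.recall == pytest.approx(0.99270, abs=5e-6)
        assert s.precision == pytest.approx(0.95775, abs=5e-6)
        assert round(100 * s.recall) == 99 and round(100 * s.precision) == 96

    def test_published_cohort_row_f1(self):
        # worked example: 2431 TP, 23 FN, 40 FP -> F1 99%
        s = detection_scores(tp=2431, fn=23, fp=40)
        assert s.f1 == pytest.approx(0.987208, abs=5e-6)
        assert round(100 * s.f1) == 99

    def test_zero_denominators_are_flagged_nan(self):
        s = detection_scores(tp=0, fn=0, fp=0)
        assert math.isnan(s.recall) and math.isnan(s.precision) and math.isnan(s.f1)

    def test_from_match_result(self):
        m = match_events(_log([1.0, 2.2]), _log([1.01, 5.0], source="predicted"))
        s = detection_scores(m)
        assert (s.tp, s.fn, s.fp) == (1, 1, 1)


class TestTimeErrors:
    def test_identical_logs(self):
        m = match_events(_log([1.0, 2.2]), _log([1.0, 2.2], source="predicted"))
        t = time_errors(m)
        assert t.median == 0.0 and t.iqr == 0.0 and t.n == 2

    def test_hand_computed_quartiles(self):
        # eps = [-0.01, 0.00, 0.01, 0.02]: median 0.005; linear-interpolation
        # quartiles Q1 = -0.0025, Q3 = 0.0125, hence IQR = 0.015
        ref = _log([1.0, 2.2, 3.4, 4.6])
        pred = _log([1.01, 2.2, 3.39, 4.58], source="predicted")
        t = time_errors(match_events(ref, pred))
        assert t.median == pytest.approx(0.005, abs=1e-9)
        assert t.iqr == pytest.approx(0.015, abs=1e-9)

    def test_late_predictions_give_positive_median(self):
        # predictions uniformly 0.02 s early => eps = t_ref - t_pred = +0.02
        ref = _log([1.0, 2.2, 3.4])
        pred = _log([0.98, 2.18, 3.38], source="predicted")
        assert time_errors(match_events(ref, pred)).median == pytest.approx(0.02)

    def test_empty_match(self):
        t = time_errors(match_events(EventLog(), EventLog()))
        assert t.n == 0 and math.isnan(t.median)


class TestTemporalParams:
    def test_published_triple(self):
        ev = EventLog(
            [
                GaitEvent(Side.LEFT, 10.00, EventKind.IC),
                GaitEvent(Side.LEFT, 10.93, EventKind.FC),
                GaitEvent(Side.LEFT, 11.34, EventKind.IC),
            ]
        )
        (p,) = temporal_params(ev)
        assert (p.stance, p.swing, p.stride) == pytest.approx((0.93, 0.41, 1.34))

    def test_missing_fc_skips_stride(self):
        ev = EventLog(
            [
                GaitEvent(Side.LEFT, 10.0, EventKind.IC),
                GaitEvent(Side.LEFT, 11.34, EventKind.IC),
                GaitEvent(Side.LEFT, 12.68, EventKind.IC),
                GaitEvent(Side.LEFT, 12.0, EventKind.FC),
            ]
        )
        params = temporal_params(ev)
        assert len(params) == 1 and params[0].ic == 11.34

    def test_stance_plus_swing_identity(self, schedule):
        events, _ = schedule
        for p in temporal_params(events):
            assert p.stance + p.swing == p.stride or abs(p.stance + p.swing - p.stride) < 1e-12


class TestAgreement:
    def test_closed_form_loa(self):
        # differences [0.01, -0.01, 0.03, -0.03]: bias 0, sample sd 0.02582, LoA +/- 0.0506
        ref = np.array([1.0, 1.0, 1.0, 1.0])
        pred = ref + np.array([0.01, -0.01, 0.03, -0.03])
        a = agreement(ref, pred)
        assert a.mean_difference == pytest.approx(0.0, abs=1e-12)
        assert a.loa_high == pytest.approx(1.96 * 0.025819889, abs=1e-8)
        assert a.loa_low == pytest.approx(-a.loa_high, abs=1e-12)

    def test_perfect_agreement(self):
        x = np.array([1.2, 1.3, 1.4])
        a = agreement(x, x)
        assert a.mean_difference == 0.0 and a.loa_low == 0.0 and a.loa_high == 0.0

    def test_loa_undefined_below_two_pairs(self):
        a = agreement(np.array([1.0]), np.array([1.1]))
        assert math.isnan(a.loa_low) and math.isnan(a.loa_high)

    def test_loa_multiplier_configurable(self):
        ref = np.zeros(4)
        pred = np.array([0.01, -0.01, 0.03, -0.03])
        a = agreement(ref, pred, loa_multiplier=1.0)
        assert a.loa_high == pytest.approx(0.025819889, abs=1e-8)

    def test_stride_bias_is_stance_plus_swing_bias(self):
        """Additivity: on any paired stride set, stride-time bias equals
        stance-time bias + swing-time bias."""
        rng = np.random.default_rng(7)
        ref_ic2 = np.cumsum(rng.uniform(1.0, 1.5, 20))
        ref_ic1 = ref_ic2 - rng.uniform(1.0, 1.4, 20)
        ref_fc = ref_ic1 + rng.uniform(0.5, 0.9, 20)
        pred_ic1 = ref_ic1 + rng.normal(0, 0.02, 20)
        pred_fc = ref_fc + rng.normal(0, 0.02, 20)
        pred_ic2 = ref_ic2 + rng.normal(0, 0.02, 20)
        bias = {}
        for name, (r, p) in {
            "stance": (ref_fc - ref_ic1, pred_fc - pred_ic1),
            "swing": (ref_ic2 - ref_fc, pred_ic2 - pred_fc),
            "stride": (ref_ic2 - ref_ic1, pred_ic2 - pred_ic1),
        }.items():
            bias[name] = agreement(r, p).mean_difference
        assert bias["stride"] == pytest.approx(bias["stance"] + bias["swing"], abs=1e-12)

    def test_relative_error_is_per_stride_normalized(self):
        from gaitkit.metrics import StrideParams

        ref = [StrideParams(Side.LEFT, 0.0, 0.8, 0.4, 1.2), StrideParams(Side.LEFT, 1.2, 0.8, 0.2, 1.0)]
        pred = [StrideParams(Side.LEFT, 0.0, 0.8, 0.5, 1.3), StrideParams(Side.LEFT, 1.2, 0.8, 0.1, 0.9)]
        pairs = list(zip(ref, pred))
        abs_err, rel_err = absolute_relative_errors(pairs, "swing")
        assert abs_err == pytest.approx(0.1)
        assert rel_err == pytest.approx(100 * (0.1 / 0.4 + 0.1 / 0.2) / 2)
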