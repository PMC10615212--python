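"""Evaluation layer: event matching, detection scores, time agreement,
temporal gait parameters, and Bland-Altman limits of agreement.

Conventions
-----------
* A reference and a predicted event match when their absolute time difference
  is at most the tolerance (250 ms by default, i.e. a 500 ms window centered
  on the reference timing); matching is one-to-one, greedy by ascending
  absolute error.
* The time error of a matched pair is ``eps = t_ref - t_pred``; positive means
  the event was detected early (advanced detection).
* Limits of agreement are ``bias +/- 1.96 * sd`` of the paired differences
  (95% interval); the multiplier is configurable.
* All internals keep full precision; rounding to printed formats (integer
  percent, 10-ms table cells) happens only in the report layer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from gaitkit.core import EventKind, EventLog, GaitEvent, Side


# ---------------------------------------------------------------------------
# matching

def greedy_pairs(a: np.ndarray, b: np.ndarray, tolerance: float) -> list[tuple[int, int]]:
    """One-to-one pairing of two sorted time arrays, greedy by ascending |dt|.

    Among all candidate pairs with |a[i] - b[j]| <= tolerance, repeatedly
    accept the pair with the smallest absolute difference (ties broken by
    earlier indices) whose endpoints are both still free.
    """
    cand = [
        (abs(a[i] - b[j]), i, j)
        for i in range(len(a))
        for j in range(len(b))
        if abs(a[i] - b[j]) <= tolerance
    ]
    cand.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in cand:
        if i not in used_a and j not in used_b:
            pairs.append((i, j))
            used_a.add(i)
            used_b.add(j)
    return sorted(pairs)


@dataclass
class MatchResult:
    """One-to-one event correspondences within a tolerance window."""

    pairs: list[tuple[GaitEvent, GaitEvent]]
    unmatched_reference: list[GaitEvent]  # false negatives
    unmatched_predicted: list[GaitEvent]  # false positives
    tolerance: float

    @property
    def errors(self) -> np.ndarray:
        """eps = t_ref - t_pred per matched pair (seconds)."""
        return np.asarray([r.time - p.time for r, p in self.pairs], dtype=float)

    @property
    def tp(self) -> int:
        return len(self.pairs)

    @property
    def fn(self) -> int:
        return len(self.unmatched_reference)

    @property
    def fp(self) -> int:
        return len(self.unmatched_predicted)

    def merged_with(self, other: "MatchResult") -> "MatchResult":
        if other.tolerance != self.tolerance:
            raise ValueError("cannot merge matches computed at different tolerances")
        return MatchResult(
            self.pairs + other.pairs,
            self.unmatched_reference + other.unmatched_reference,
            self.unmatched_predicted + other.unmatched_predicted,
            self.tolerance,
        )


def match_events(
    reference: EventLog,
    predicted: EventLog,
    tolerance: float = 0.25,
    side: Side | None = None,
    kind: EventKind | None = None,
) -> MatchResult:
    """Match reference to predicted events per (side, kind) stream.

    With ``side``/``kind`` unset, all four streams are matched independently
    and the results pooled; events never match across sides or kinds.
    """
    sides = [side] if side is not None else list(Side)
    kinds = [kind] if kind is not None else list(EventKind)
    result = MatchResult([], [], [], tolerance)
    for s in sides:
        for k in kinds:
            ref = sorted(reference.select(side=s, kind=k).events, key=lambda e: e.time)
            pred = sorted(predicted.select(side=s, kind=k).events, key=lambda e: e.time)
            rt = np.asarray([e.time for e in ref])
            pt = np.asarray([e.time for e in pred])
            pairs = greedy_pairs(rt, pt, tolerance)
            pi = {i for i, _ in pairs}
            pj = {j for _, j in pairs}
            result = result.merged_with(
                MatchResult(
                    [(ref[i], pred[j]) for i, j in pairs],
                    [e for i, e in enumerate(ref) if i not in pi],
                    [e for j, e in enumerate(pred) if j not in pj],
                    tolerance,
                )
            )
    return result


# ---------------------------------------------------------------------------
# detection scores

@dataclass(frozen=True)
class DetectionScores:
    """Recall, precision, F1 from true-positive / false-negative /
    false-positive counts. Undefined ratios (zero denominator) are NaN."""

    tp: int
    fn: int
    fp: int

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn > 0 else math.nan

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp > 0 else math.nan

    @property
    def f1(self) -> float:
        r, p = self.recall, self.precision
        if math.isnan(r) or math.isnan(p) or r + p == 0:
            return math.nan
        return 2 * r * p / (r + p)


def detection_scores(m: MatchResult | None = None, *, tp: int | None = None, fn: int | None = None, fp: int | None = None) -> DetectionScores:
    """Detection scores from a match result or from raw counts."""
    if m is not None:
        return DetectionScores(m.tp, m.fn, m.fp)
    if tp is None or fn is None or fp is None:
        raise ValueError("provide either a MatchResult or all of tp, fn, fp")
    return DetectionScores(tp, fn, fp)


# ---------------------------------------------------------------------------
# time agreement

@dataclass(frozen=True)
class TimeErrorSummary:
    median: float  # seconds
    iqr: float  # seconds, Q3 - Q1 with linear-interpolation quantiles
    n: int


def time_errors(m: MatchResult) -> TimeErrorSummary:
    """Median and inter-quartile range of eps = t_ref - t_pred over matches."""
    eps = m.errors
    if eps.size == 0:
        return TimeErrorSummary(math.nan, math.nan, 0)
    q1, q3 = np.percentile(eps, [25, 75])
    return TimeErrorSummary(float(np.median(eps)), float(q3 - q1), int(eps.size))


# ---------------------------------------------------------------------------
# temporal gait parameters

@dataclass(frozen=True)
class StrideParams:
    """Stance, swing and stride time of one stride; stance + swing = stride."""

    side: Side
    ic: float  # first IC, identifies the stride for pairing
    stance: float
    swing: float
    stride: float


def temporal_params(events: EventLog) -> list[StrideParams]:
    """Per-stride temporal parameters from an event log.

    For each same-side IC-FC-IC triple: stance = FC - IC1, swing = IC2 - FC,
    stride = IC2 - IC1. Strides without exactly one FC strictly between the
    two ICs are skipped (both ICs and the FC in between must be present).
    """
    out: list[StrideParams] = []
    for side in Side:
        ics = events.select(side=side, kind=EventKind.IC).times()
        fcs = events.select(side=side, kind=EventKind.FC).times()
        for ic1, ic2 in zip(ics, ics[1:]):
            between = fcs[(fcs > ic1) & (fcs < ic2)]
            if between.size != 1:
                continue
            fc = float(between[0])
            out.append(StrideParams(side, float(ic1), fc - ic1, ic2 - fc, ic2 - ic1))
    return out


# ---------------------------------------------------------------------------
# agreement statistics

@dataclass
class AgreementSummary:
    """Bland-Altman agreement between predicted and reference parameters."""

    mean_difference: float  # bias, predicted - reference (s)
    loa_low: float
    loa_high: float
    n: int
    differences: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))
    averages: np.ndarray = field(repr=False, default_factory=lambda: np.empty(0))


def agreement(
    reference: np.ndarray,
    predicted: np.ndarray,
    loa_multiplier: float = 1.96,
) -> AgreementSummary:
    """Mean difference and limits of agreement for paired parameter values.

    ``loa = bias +/- loa_multiplier * sd(differences)`` with the sample
    (ddof=1) standard deviation; 1.96 corresponds to a 95% interval. The
    per-pair differences and averages are retained for Bland-Altman plots.
    """
    reference = np.asarray(reference, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if reference.shape != predicted.shape:
        raise ValueError("reference and predicted must be paired (equal length)")
    d = predicted - reference
    avg = (predicted + reference) / 2.0
    bias = float(np.mean(d)) if d.size else math.nan
    if d.size >= 2:
        spread = loa_multiplier * float(np.std(d, ddof=1))
        lo, hi = bias - spread, bias + spread
    else:
        lo = hi = math.nan
    return AgreementSummary(bias, lo, hi, int(d.size), d, avg)


def paired_stride_params(
    reference: list[StrideParams],
    predicted: list[StrideParams],
    tolerance: float = 0.25,
) -> list[tuple[StrideParams, StrideParams]]:
    """Pair reference and predicted strides by side and initial-contact time."""
    out: list[tuple[StrideParams, StrideParams]] = []
    for side in Side:
        ref = [p for p in reference if p.side is side]
        pred = [p for p in predicted if p.side is side]
        rt = np.asarray([p.ic for p in ref])
        pt = np.asarray([p.ic for p in pred])
        out.extend((ref[i], pred[j]) for i, j in greedy_pairs(rt, pt, tolerance))
    return out


def absolute_relative_errors(
    pairs: list[tuple[StrideParams, StrideParams]], attr: str
) -> tuple[float, float]:
    """Mean absolute error (s) and mean relative error (%) of one parameter.

    Relative error is normalized per stride: mean over strides of
    |predicted - reference| / reference, in percent.
    """
    ref = np.asarray([getattr(r, attr) for r, _ in pairs])
    pred = np.asarray([getattr(p, attr) for _, p in pairs])
    if ref.size == 0:
        return math.nan, math.nan
    abs_err = np.abs(pred - ref)
    return float(np.mean(abs_err)), float(np.mean(abs_err / ref) * 100.0)
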