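"""End-to-end orchestration: simulate -> reference -> bouts -> train ->
predict -> detect -> evaluate.

The pipeline emulates a multi-subject free-living study: every synthetic
subject gets their own gait statistics (cadence and stance fraction drawn
from cohort-level ranges), their own sensor orientations and noise, and a
pressure-insole log. Reference events come from the insole contacts fused
with a jittered copy of the ground truth standing in for the external
IMU-based reference detector. The network is trained on the training
subjects' reference annotations, validated for early stopping on the
validation subjects, and all reported numbers come from the held-out test
subjects' walking bouts (>= 10 s) only.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from gaitkit import bouts as bouts_mod
from gaitkit import io as io_mod
from gaitkit.core import BilateralRecording, EventKind, EventLog, GaitEvent, InsoleLog, Side
from gaitkit.events import PeakConfig, detect_events
from gaitkit.metrics import (
    absolute_relative_errors,
    agreement,
    detection_scores,
    match_events,
    paired_stride_params,
    temporal_params,
    time_errors,
)
from gaitkit.network import (
    NetworkConfig,
    TrainingConfig,
    build_model,
    predict_probabilities,
    train,
)
from gaitkit.reference import fuse_events, insole_contacts
from gaitkit.simulate import SimulationConfig, simulate_recording

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """Study-level configuration for a full synthetic experiment."""

    n_subjects: int = 30
    rate: float = 100.0
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2)
    # between-subject gait statistics: stride times ~1.18-1.43 s, stance ~66-73%
    cadence_mean_range: tuple[float, float] = (0.70, 0.85)  # strides/s
    cadence_sd: float = 0.02
    stance_mean_range: tuple[float, float] = (0.66, 0.73)
    stance_sd: float = 0.02
    n_bouts: int = 2
    strides_per_bout: tuple[int, int] = (12, 16)
    noise_sd_accel: float = 0.3  # m/s^2
    noise_sd_gyro: float = 3.0  # deg/s
    insole_jitter_sd: float = 0.005  # s
    insole_dropout_prob: float = 0.02
    imu_ref_jitter_sd: float = 0.02  # s, jitter of the stand-in IMU reference
    network: NetworkConfig = field(default_factory=NetworkConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    peaks: PeakConfig = field(default_factory=PeakConfig)
    match_tolerance: float = 0.25  # s
    min_bout_duration: float = 10.0  # s

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SubjectData:
    subject: str
    recording: BilateralRecording
    truth: EventLog
    insole: InsoleLog
    reference: EventLog  # fused insole + IMU-reference events


def _subject_sim_config(pcfg: PipelineConfig, root_seed: int, index: int) -> SimulationConfig:
    rng = np.random.default_rng([root_seed, index])
    return SimulationConfig(
        seed=int(rng.integers(0, 2**31 - 1)),
        n_bouts=pcfg.n_bouts,
        strides_per_bout=pcfg.strides_per_bout,
        cadence=(float(rng.uniform(*pcfg.cadence_mean_range)), pcfg.cadence_sd),
        stance_fraction=(float(rng.uniform(*pcfg.stance_mean_range)), pcfg.stance_sd),
        noise_sd_accel=pcfg.noise_sd_accel,
        noise_sd_gyro=pcfg.noise_sd_gyro,
        insole_jitter_sd=pcfg.insole_jitter_sd,
        insole_dropout_prob=pcfg.insole_dropout_prob,
    )


def _jittered_truth(truth: EventLog, sd: float, rng: np.random.Generator) -> EventLog:
    """Stand-in for the external IMU-based reference event stream."""
    return EventLog(
        GaitEvent(e.side, e.time + float(rng.normal(0.0, sd)), e.kind, "imu_ref")
        for e in truth
    )


def generate_subject(pcfg: PipelineConfig, root_seed: int, index: int) -> SubjectData:
    cfg = _subject_sim_config(pcfg, root_seed, index)
    name = f"subject_{index:03d}"
    rec, truth, insole = simulate_recording(cfg, rate=pcfg.rate, subject=name)
    rng = np.random.default_rng([root_seed, index, 1])
    imu_ref = _jittered_truth(truth, pcfg.imu_ref_jitter_sd, rng)
    reference = fuse_events(insole_contacts(insole), imu_ref)
    return SubjectData(name, rec, truth, insole, reference)


def analysis_bouts(events: EventLog, pcfg: PipelineConfig) -> list[bouts_mod.WalkingBout]:
    """Walking bouts eligible for analysis (valid strides, >= 10 s)."""
    strides = bouts_mod.strides_from_events(events)
    left = bouts_mod.filter_valid_strides(strides[Side.LEFT])
    right = bouts_mod.filter_valid_strides(strides[Side.RIGHT])
    wbs = bouts_mod.form_walking_bouts(left, right)
    return bouts_mod.filter_bouts(wbs, pcfg.min_bout_duration)


def _events_within(events: EventLog, spans: list[tuple[float, float]], margin: float = 0.0) -> EventLog:
    return EventLog(
        e
        for e in events
        if any(lo - margin <= e.time <= hi + margin for lo, hi in spans)
    )


def evaluate_subject(subject: SubjectData, predicted: EventLog, pcfg: PipelineConfig) -> dict:
    """Per-subject evaluation restricted to analyzable walking bouts."""
    wbs = analysis_bouts(subject.reference, pcfg)
    spans = [(b.start, b.end) for b in wbs]
    ref = _events_within(subject.reference, spans)
    pred = _events_within(predicted, spans, margin=pcfg.match_tolerance)
    out: dict = {"n_bouts": len(wbs), "matches": {}}
    for kind in EventKind:
        out["matches"][kind] = match_events(ref, pred, pcfg.match_tolerance, kind=kind)
    ref_params = temporal_params(ref)
    pred_params = temporal_params(pred)
    out["param_pairs"] = paired_stride_params(ref_params, pred_params, pcfg.match_tolerance)
    return out


def pooled_results(per_subject: list[dict], pcfg: PipelineConfig) -> dict:
    """Pool matches and stride pairs over test subjects into summary tables."""
    out: dict = {"detection": {}, "time_errors": {}, "agreement": {}, "errors": {}}
    for kind in EventKind:
        merged = per_subject[0]["matches"][kind]
        for d in per_subject[1:]:
            merged = merged.merged_with(d["matches"][kind])
        out["detection"][kind.value] = detection_scores(merged)
        out["time_errors"][kind.value] = time_errors(merged)
    pairs = [p for d in per_subject for p in d["param_pairs"]]
    for attr in ("stance", "swing", "stride"):
        ref = np.asarray([getattr(r, attr) for r, _ in pairs])
        pred = np.asarray([getattr(p, attr) for _, p in pairs])
        out["agreement"][attr] = agreement(ref, pred)
        out["errors"][attr] = absolute_relative_errors(pairs, attr)
    out["n_bouts"] = sum(d["n_bouts"] for d in per_subject)
    out["n_stride_pairs"] = len(pairs)
    return out


def run_experiment(pcfg: PipelineConfig = PipelineConfig(), seed: int = 0) -> dict:
    """Full experiment; returns summaries plus the trained model and history."""
    logger.info("simulating %d subjects", pcfg.n_subjects)
    subjects = [generate_subject(pcfg, seed, i) for i in range(pcfg.n_subjects)]
    split = io_mod.split_dataset([s.subject for s in subjects], pcfg.fractions, seed=seed)
    if not split.testing:
        raise ValueError("split produced no test subjects")
    by_name = {s.subject: s for s in subjects}
    train_data = [(by_name[n].recording, by_name[n].reference) for n in split.training]
    val_data = [(by_name[n].recording, by_name[n].reference) for n in split.validation]

    model = build_model(pcfg.network, seed=seed)
    tcfg = dataclasses.replace(pcfg.training, seed=seed)
    logger.info("training on %d subjects, validating on %d", len(train_data), len(val_data))
    history = train(model, train_data, tcfg, val_data=val_data or None)

    per_subject = []
    for name in split.testing:
        sub = by_name[name]
        trace = predict_probabilities(model, sub.recording)
        predicted = detect_events(trace, pcfg.peaks)
        per_subject.append(evaluate_subject(sub, predicted, pcfg))
    results = pooled_results(per_subject, pcfg)
    results["split"] = split
    results["model"] = model
    results["history"] = history
    return results


# ---------------------------------------------------------------------------
# report writing

def write_report(results: dict, pcfg: PipelineConfig, seed: int, out_dir) -> None:
    """Write the evaluation tables; every file carries the config hash and seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    header = {"config_hash": io_mod.config_hash(pcfg.to_dict()), "root_seed": seed}

    def pct(x: float):
        return None if np.isnan(x) else round(100 * x)

    rows = []
    for kind in ("IC", "FC"):
        s = results["detection"][kind]
        rows.append(
            {
                "event": kind, "tp": s.tp, "fn": s.fn, "fp": s.fp,
                "recall_pct": pct(s.recall), "precision_pct": pct(s.precision),
                "f1_pct": pct(s.f1),
            }
        )
    io_mod._write_with_header(pd.DataFrame(rows), out / "scores.csv", header)

    rows = []
    for kind in ("IC", "FC"):
        t = results["time_errors"][kind]
        rows.append({"event": kind, "median_ms": 1000 * t.median, "iqr_ms": 1000 * t.iqr, "n": t.n})
    io_mod._write_with_header(pd.DataFrame(rows), out / "time_errors.csv", header)

    rows, points = [], []
    for attr in ("stance", "swing", "stride"):
        a = results["agreement"][attr]
        abs_err, rel_err = results["errors"][attr]
        rows.append(
            {
                "parameter": attr, "mean_difference_s": a.mean_difference,
                "loa_low_s": a.loa_low, "loa_high_s": a.loa_high, "n": a.n,
                "mean_abs_error_s": abs_err, "mean_rel_error_pct": rel_err,
            }
        )
        points.append(
            pd.DataFrame({"parameter": attr, "average_s": a.averages, "difference_s": a.differences})
        )
    io_mod._write_with_header(pd.DataFrame(rows), out / "agreement.csv", header)
    io_mod._write_with_header(pd.concat(points), out / "bland_altman.csv", header)
    io_mod._write_with_header(results["history"].to_frame(), out / "training_log.csv", header)
    with open(out / "run.json", "w", encoding="utf-8") as fh:
        json.dump(
            {
                "root_seed": seed,
                "config_hash": header["config_hash"],
                "config": pcfg.to_dict(),
                "n_bouts": results["n_bouts"],
                "n_stride_pairs": results["n_stride_pairs"],
            },
            fh,
            indent=2,
            default=str,
        )


def run_pipeline(pcfg: PipelineConfig, out_dir, seed: int = 0) -> dict:
    """Run the full experiment and write the report directory."""
    results = run_experiment(pcfg, seed=seed)
    write_report(results, pcfg, seed, out_dir)
    return results
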