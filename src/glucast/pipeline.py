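"""End-to-end orchestration: simulate/ingest -> repair -> features -> model.

Two deliberately different pipelines exist.  The **training** pipeline uses
threshold-routed hybrid imputation, which cuts the trace at unrecoverable
gaps, fits the feature transform on training rows only, and trains one
forecaster per trace (personalized models).  The **inference** pipeline never
cuts: it spline-fills every gap so the grid stays contiguous, applies the
frozen transform, forecasts, and scores only at slots that were observed in
the original file.

All randomness flows from a single global seed via fixed per-stage offsets,
so any stage can be re-run in isolation and two identical seeded runs produce
identical artifacts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .features import FeatureMatrix, FeatureTransform, derive_features
from .impute import SegmentedSeries, impute_for_inference, impute_hybrid
from .io import GlucoseSeries, load_series
from .metrics import EvalReport, evaluate_forecasts
from .model import (
    ModelConfig,
    RNNForecaster,
    TrainResult,
    WindowSet,
    build_model,
    make_windows,
    persistence_baseline,
    predict,
    train_model,
)
from .simulate import GapSpec, SimConfig, inject_missingness, simulate_trace

logger = logging.getLogger("glucast")

# fixed per-stage seed offsets derived from the global seed
_TRACE_OFFSET, _GAP_OFFSET, _MODEL_OFFSET = 0, 1000, 2000


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class RunConfig:
    """One self-contained run description (serialized beside its outputs)."""

    seed: int = 0
    mode: str = "train"
    input_path: str | None = None  # None -> simulate
    sim: SimConfig = field(default_factory=SimConfig)
    gaps: GapSpec = field(default_factory=GapSpec)
    model: ModelConfig = field(default_factory=ModelConfig)
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("train", "inference"):
            raise ValueError("mode must be 'train' or 'inference'")
        # derive per-stage seeds from the single global seed
        self.sim = dataclasses.replace(self.sim, seed=(self.seed + _TRACE_OFFSET) % 2**31)
        self.gaps = dataclasses.replace(self.gaps, seed=(self.seed + _GAP_OFFSET) % 2**31)
        self.model = dataclasses.replace(self.model, seed=(self.seed + _MODEL_OFFSET) % 2**31)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["sim"]["t0"] = str(self.sim.t0)
        d["sim"]["meal_times"] = list(self.sim.meal_times)
        d["sim"]["meal_amplitude_range"] = list(self.sim.meal_amplitude_range)
        d["gaps"]["length_mixture"] = list(self.gaps.length_mixture)
        return d


@dataclass
class TrainArtifacts:
    """Everything needed to forecast and reproduce a training run."""

    model: RNNForecaster
    transform: FeatureTransform
    config: ModelConfig
    train_result: TrainResult
    segmented: SegmentedSeries
    report: dict

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.savez(out / "weights.npz", **self.model.params)
        (out / "transform.yaml").write_text(yaml.safe_dump(self.transform.to_dict()))
        (out / "model_config.yaml").write_text(yaml.safe_dump(self.config.to_dict()))
        (out / "train_report.json").write_text(json.dumps(self.report, indent=2))


def load_artifacts(out_dir) -> tuple[RNNForecaster, FeatureTransform, ModelConfig]:
    out = Path(out_dir)
    config = ModelConfig.from_dict(yaml.safe_load((out / "model_config.yaml").read_text()))
    transform = FeatureTransform.from_dict(yaml.safe_load((out / "transform.yaml").read_text()))
    model = build_model(config)
    with np.load(out / "weights.npz") as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    return model, transform, config


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc

        return wrapped

    return deco


@_stage("ingest")
def _ingest(config: RunConfig) -> GlucoseSeries:
    if config.input_path is not None:
        series = load_series(config.input_path)
        logger.info("ingest: read %d slots from %s", series.n, config.input_path)
    else:
        clean = simulate_trace(config.sim)
        series, truth = inject_missingness(clean, config.gaps)
        logger.info(
            "ingest: simulated %d slots, injected %d gaps (%d slots missing)",
            series.n,
            len(truth),
            int((~series.mask).sum()),
        )
    return series


@_stage("impute")
def _impute_train(series: GlucoseSeries) -> SegmentedSeries:
    seg = impute_hybrid(series)
    branches = [e["branch"] for e in seg.gap_log]
    logger.info(
        "impute: %d gaps (spline=%d arima=%d cut=%d) -> %d segments, %d slots dropped",
        len(seg.gap_log),
        sum(b.startswith("spline") for b in branches),
        sum(b.startswith("arima") for b in branches),
        sum(b.startswith("cut") for b in branches),
        len(seg.segments),
        seg.n_dropped,
    )
    return seg


@_stage("features")
def _features_train(seg: SegmentedSeries) -> tuple[list[FeatureMatrix], FeatureTransform]:
    matrices = [
        derive_features(s, segment_id=i)
        for i, (s, ok) in enumerate(zip(seg.segments, seg.usable))
        if ok
    ]
    if not matrices:
        raise ValueError("no usable segments (all shorter than the minimum window span)")
    transform = FeatureTransform().fit(matrices)
    logger.info("features: %d usable segments, transform fitted", len(matrices))
    return matrices, transform


@_stage("windows")
def _windows(matrices, transform, model_config) -> WindowSet:
    ws = make_windows(matrices, transform, model_config)
    logger.info("windows: %d supervised pairs", ws.n)
    return ws


@_stage("train")
def _train(ws: WindowSet, model_config: ModelConfig) -> TrainResult:
    result = train_model(ws, model_config)
    logger.info(
        "train: best epoch %d, validation RMSE (transformed) %.5f",
        result.best_epoch,
        result.best_val_rmse,
    )
    return result


def run_train_pipeline(config: RunConfig, out_dir=None) -> TrainArtifacts:
    """Execute ingest -> hybrid impute -> features -> windows -> train."""
    series = _ingest(config)
    artifacts = _train_on_series(series, config)
    if out_dir is not None:
        artifacts.save(out_dir)
        Path(out_dir, "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
    return artifacts


def run_eval_pipeline(
    series: GlucoseSeries,
    model: RNNForecaster,
    transform: FeatureTransform,
    model_config: ModelConfig,
) -> tuple[EvalReport, dict]:
    """Inference pipeline: spline-fill without thresholds, never cut, forecast,
    and score only at originally observed target slots.

    Returns the evaluation report and a dict with the persistence-baseline
    comparison on the same masked points."""
    try:
        filled, observed = impute_for_inference(series)
    except Exception as exc:
        raise PipelineError(f"stage 'impute' failed: {exc}") from exc
    logger.info(
        "inference impute: %d slots, %d originally observed, no cuts",
        filled.n,
        int(observed.sum()),
    )
    matrix = derive_features(filled)
    ws = make_windows([matrix], transform, model_config)
    if ws.n == 0:
        raise PipelineError("stage 'windows' failed: test trace too short for any window")
    forecasts = predict(model, ws, transform)
    baseline = persistence_baseline(ws)
    target_mask = observed[ws.end_indices + model_config.horizon]
    report = evaluate_forecasts(ws.target_glucose, forecasts, target_mask)
    base_report = evaluate_forecasts(ws.target_glucose, baseline, target_mask)
    logger.info(
        "evaluate: n=%d rmse=%.2f mg/dL (persistence %.2f)",
        report.n,
        report.rmse,
        base_report.rmse,
    )
    extras = {
        "persistence_rmse": base_report.rmse,
        "persistence_mae": base_report.mae,
        "n_windows": ws.n,
        "n_evaluated": report.n,
    }
    return report, extras


def run_study(
    seed: int,
    days: int = 14,
    test_days: int = 3,
    max_epochs: int = 200,
    gap_spec: GapSpec | None = None,
) -> dict:
    """One complete surrogate study on a simulated patient.

    Simulates ``days`` of CGM with the default mixed gap profile, trains a
    personalized forecaster on everything but the last ``test_days``
    (chronological split), then scores the held-out tail with the inference
    pipeline against the persistence baseline.  Returns a flat dict of the
    study's headline numbers."""
    config = RunConfig(
        seed=seed,
        sim=SimConfig(days=days),
        gaps=gap_spec or GapSpec(),
        model=ModelConfig(max_epochs=max_epochs),
    )
    clean = simulate_trace(config.sim)
    gapped, _ = inject_missingness(clean, config.gaps)
    split = (days - test_days) * 288
    head = GlucoseSeries(gapped.patient_id, gapped.t0, gapped.values[:split], gapped.mask[:split])
    tail = GlucoseSeries(
        gapped.patient_id,
        gapped.t0 + split * gapped.step,
        gapped.values[split:],
        gapped.mask[split:],
    )

    train_config = dataclasses.replace(config)
    artifacts = _train_on_series(head, train_config)
    report, extras = run_eval_pipeline(tail, artifacts.model, artifacts.transform, artifacts.config)
    out = {
        "rmse_mgdl": report.rmse,
        "mae_mgdl": report.mae,
        "r2": report.r2,
        "mcc": report.mcc,
        "persistence_rmse_mgdl": extras["persistence_rmse"],
        "persistence_mae_mgdl": extras["persistence_mae"],
        "skill_vs_persistence": 1.0 - report.rmse / extras["persistence_rmse"],
        "n_evaluated": report.n,
        "n_train_windows": artifacts.report["n_windows"],
        "best_epoch": artifacts.report["best_epoch"],
    }
    for zone, pct in report.ceg_percent.items():
        out[f"ceg_zone_{zone}_pct"] = pct
    for cls, m in report.per_class.items():
        for name, v in m.items():
            out[f"{cls}_{name}"] = v
    return out


def _train_on_series(series: GlucoseSeries, config: RunConfig) -> TrainArtifacts:
    """Training pipeline stages on an in-memory series (no ingest I/O)."""
    seg = _impute_train(series)
    matrices, transform = _features_train(seg)
    ws = _windows(matrices, transform, config.model)
    result = _train(ws, config.model)
    report = {
        "n_slots": series.n,
        "n_gaps": len(seg.gap_log),
        "gap_branches": [e["branch"] for e in seg.gap_log],
        "n_segments": len(seg.segments),
        "n_usable_segments": int(sum(seg.usable)),
        "n_windows": ws.n,
        "best_epoch": result.best_epoch,
        "best_val_rmse_transformed": result.best_val_rmse,
        "seed": config.seed,
    }
    return TrainArtifacts(result.model, transform, config.model, result, seg, report)
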