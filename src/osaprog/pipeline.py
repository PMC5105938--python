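"""End-to-end orchestration: extract → embed → train → graph → predict.

A :class:`PipelineConfig` holds every tunable of the pipeline; a single
:func:`run_pipeline` call takes an annotated RR series, trains the
partition, DPMG and block graph on the chronologically first part of
the record, emits per-minute onset predictions on the remainder, and
writes the full artifact bundle (feature CSV, states, models, graph,
projection coordinates, predictions, evaluation report, config) to an
output directory.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import yaml

from . import embedding, hrv_features, models, prognosis, state_graph
from .errors import ConfigurationError
from .io_formats import RRSeries
from .synthetic_data import minutes_to_onset

logger = logging.getLogger(__name__)

VERSION = "0.1.0"


@dataclass
class PipelineConfig:
    """All tunables of the pipeline, with the package defaults."""

    band_lo: float = hrv_features.BAND_LO
    band_hi: float = hrv_features.BAND_HI
    recurrence_embed_dim: int = 3
    recurrence_delay: int = 1
    recurrence_rate: float = 0.10
    recurrence_min_line: int = 2
    lags_per_feature: int = embedding.DEFAULT_LAGS
    embed_delay: int = embedding.DEFAULT_DELAY
    bins_per_dim: int = 20
    alpha: float = 1.0
    dpmg_iters: int = 500
    svm_gamma: str | float = "scale"
    svm_C: float = 1.0
    smoothing: float = 0.5
    horizon: int = prognosis.DEFAULT_HORIZON
    train_fraction: float = 0.6
    transition_mode: str = "blend"       # or "empirical" / "dpmg"
    label_mode: str = "partition"        # or "majority"
    seed: int = 0
    version: str = VERSION

    def __post_init__(self) -> None:
        if self.bins_per_dim < 1:
            raise ConfigurationError("bins_per_dim must be >= 1")
        if not (0 < self.train_fraction < 1):
            raise ConfigurationError("train_fraction must lie in (0, 1)")
        if self.horizon < 1:
            raise ConfigurationError("horizon must be >= 1")
        if self.transition_mode not in ("empirical", "dpmg", "blend"):
            raise ConfigurationError(f"unknown transition_mode {self.transition_mode!r}")
        if self.label_mode not in ("partition", "majority"):
            raise ConfigurationError(f"unknown label_mode {self.label_mode!r}")

    @classmethod
    def from_file(cls, path: str) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    """In-memory artifact bundle of one pipeline run."""

    config: PipelineConfig
    features: hrv_features.FeatureSeries
    train_states: embedding.EmbeddedStates
    test_states: embedding.EmbeddedStates
    partition: models.ApneaPartition
    dpmg: models.DPMGModel
    graph: state_graph.BlockGraph
    projection: state_graph.LaplacianProjection
    predictions: list[prognosis.OnsetDistribution]
    prediction_minutes: np.ndarray
    observed_onsets: np.ndarray
    report: prognosis.EvaluationReport | None


def run_pipeline(config: PipelineConfig, series: RRSeries,
                 output_dir: str | None = None) -> PipelineResult:
    """Run the full prognosis pipeline on one annotated RR series."""
    if series.annotations is None:
        raise ConfigurationError("pipeline needs minute-wise annotations")
    rparams = hrv_features.RecurrenceParams(
        embed_dim=config.recurrence_embed_dim, delay=config.recurrence_delay,
        epsilon_or_rate=config.recurrence_rate,
        min_line=config.recurrence_min_line)

    stage = "extract"
    try:
        features = hrv_features.extract_feature_series(
            series, rparams, config.band_lo, config.band_hi)
        logger.info("extract: %d minutes -> %d feature rows",
                    series.duration_min, len(features.minutes))

        stage = "embed"
        states = embedding.delay_embed(features, config.lags_per_feature,
                                       config.embed_delay)
        split_minute = int(series.duration_min * config.train_fraction)
        train_mask = states.timestamps < split_minute
        train_states = _subset(states, train_mask)
        test_states = _subset(states, ~train_mask)
        logger.info("embed: %d states (%d train / %d test), dim %d",
                    states.n_states, train_states.n_states,
                    test_states.n_states, states.total_dim)

        stage = "train"
        partition = models.train_partition(
            train_states.vectors, train_states.labels,
            gamma=config.svm_gamma, C=config.svm_C, seed=config.seed)
        dpmg = models.fit_dpmg(train_states, alpha=config.alpha,
                               seed=config.seed, n_iter=config.dpmg_iters)
        logger.info("train: %d clusters, CV sens %.3f spec %.3f",
                    len(dpmg.cluster_ids), partition.cv_sensitivity,
                    partition.cv_specificity)

        stage = "graph"
        graph = state_graph.build_block_graph(
            train_states.vectors, train_states.timestamps,
            partition=partition, state_labels=train_states.labels,
            bins_per_dim=config.bins_per_dim,
            dpmg=dpmg if config.transition_mode in ("dpmg", "blend") else None,
            smoothing=config.smoothing, mode=config.transition_mode,
            label_mode=config.label_mode)
        projection = state_graph.laplacian_project(graph)
        logger.info("graph: %d blocks (%d apneic)", graph.n_blocks,
                    int(graph.apneic_mask.sum()))

        stage = "predict"
        true_t = minutes_to_onset(series.annotations)
        predictions, minutes_out, observed = [], [], []
        for i in range(test_states.n_states):
            m = int(test_states.timestamps[i])
            dist = prognosis.predict_from_state(test_states.vectors[i], graph,
                                                config.horizon)
            predictions.append(dist)
            minutes_out.append(m)
            observed.append(float(true_t[m]) if true_t[m] > 0 else np.nan)
        minutes_arr = np.array(minutes_out)
        observed_arr = np.array(observed)
        logger.info("predict: %d per-minute distributions", len(predictions))

        stage = "evaluate"
        # prognosis is defined from non-apneic states: "onset now"
        # detections are excluded from the time-to-onset evaluation
        not_now = np.array([not p.onset_now for p in predictions])
        eval_mask = np.isfinite(observed_arr) & not_now
        report = None
        if eval_mask.sum() >= 10:
            report = prognosis.evaluate_predictions(
                [p for p, ok in zip(predictions, eval_mask) if ok],
                observed_arr[eval_mask])
            logger.info("evaluate: n=%d R²=%.3f coverage=%.3f", report.n,
                        report.r2, report.coverage)
    except Exception as exc:
        raise type(exc)(f"[stage {stage}] {exc}") from exc

    result = PipelineResult(config, features, train_states, test_states,
                            partition, dpmg, graph, projection, predictions,
                            minutes_arr, observed_arr, report)
    if output_dir is not None:
        write_bundle(result, output_dir)
    return result


def _subset(states: embedding.EmbeddedStates, mask: np.ndarray) -> embedding.EmbeddedStates:
    return embedding.EmbeddedStates(
        states.vectors[mask], states.timestamps[mask],
        states.per_feature_lags,
        [lab for lab, ok in zip(states.labels, mask) if ok]
        if states.labels is not None else None)


def write_bundle(result: PipelineResult, output_dir: str) -> None:
    """Write the artifact bundle; every file names the config hash."""
    os.makedirs(output_dir, exist_ok=True)
    cfg_hash = result.config.hash()

    def path(name: str) -> str:
        return os.path.join(output_dir, name)

    with open(path("config.yaml"), "w") as fh:
        yaml.safe_dump({"config_hash": cfg_hash, **result.config.to_dict()}, fh)
    df = result.features.to_frame()
    df.insert(0, "config_hash", cfg_hash)
    df.to_csv(path("features.csv"), index=False)
    np.savetxt(path("train_states.csv"), result.train_states.vectors,
               delimiter=",", header=f"config_hash={cfg_hash}")
    with open(path("graph.json"), "w") as fh:
        payload = json.loads(result.graph.to_json())
        payload["config_hash"] = cfg_hash
        json.dump(payload, fh)
    coords = result.projection.coordinates
    with open(path("projection.csv"), "w") as fh:
        fh.write(f"# config_hash={cfg_hash}\nblock," +
                 ",".join(f"V{k + 2}" for k in range(coords.shape[1])) + "\n")
        for b in range(coords.shape[0]):
            fh.write(f"{b}," + ",".join(f"{c:.8g}" for c in coords[b]) + "\n")
    with open(path("predictions.jsonl"), "w") as fh:
        for m, dist, obs in zip(result.prediction_minutes, result.predictions,
                                result.observed_onsets):
            rec = {"minute": int(m), "config_hash": cfg_hash,
                   "expected_T": None if not np.isfinite(dist.expectation)
                   else round(dist.expectation, 4),
                   "ci_low": dist.ci_low, "ci_high": dist.ci_high,
                   "onset_now": dist.onset_now,
                   "observed_T": None if not np.isfinite(obs) else obs}
            for t in range(1, 6):
                rec[f"risk_{t}"] = round(dist.risk(min(t, dist.horizon)), 4)
            fh.write(json.dumps(rec) + "\n")
    if result.report is not None:
        with open(path("evaluation.json"), "w") as fh:
            json.dump({"config_hash": cfg_hash, **result.report.as_dict()}, fh)
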