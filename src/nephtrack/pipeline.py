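"""Run orchestration: preprocess -> features -> track -> export.

:class:`RunConfig` gathers every knob of a run and serialises losslessly
to YAML; :func:`run_pipeline` executes the full chain per seed and
returns a JSON-able report with path lengths, skip usage, per-rule
rejection counts (with optional all-rules overlap accounting) and
accuracy/extent against ground truth when available.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .features import extract_features
from .ml import MoveClassifier, load_classifier
from .preprocess import PreprocessParams, SigmoidSchedule, preprocess_stack
from .stack import SliceStack
from .tracker import (
    TrackConfig,
    TrackedPath,
    evaluate_against_truth,
    reconstruct_path,
    track,
)

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "config_to_dict", "config_from_dict"]


@dataclass
class RunConfig:
    """Everything needed to reproduce one tracking run."""

    stack_dir: str | None = None
    out_prefix: str | None = None
    model_path: str | None = None
    seeds: list[tuple[float, float, int]] = field(default_factory=list)
    preprocess: PreprocessParams = field(default_factory=PreprocessParams)
    tracking: TrackConfig = field(default_factory=TrackConfig)
    ml_enabled: bool = False
    node_spacing: float = 20.0
    defective_slices: list[int] | None = None  # None = auto-detect
    residual_threshold: float = 15.0
    random_seed: int = 0


def _encode(value):
    if isinstance(value, SigmoidSchedule):
        return {"sigmoid": dataclasses.asdict(value)}
    if dataclasses.is_dataclass(value) and not isinstance(value, type):
        return {k: _encode(v) for k, v in dataclasses.asdict(value).items()}
    if isinstance(value, (list, tuple)):
        return [_encode(v) for v in value]
    if isinstance(value, np.generic):
        return value.item()
    return value


def _decode_scheduled(value):
    if isinstance(value, dict) and set(value) == {"sigmoid"}:
        return SigmoidSchedule(**value["sigmoid"])
    return value


def config_to_dict(config: RunConfig) -> dict:
    out = {}
    for f in dataclasses.fields(config):
        v = getattr(config, f.name)
        if f.name in ("preprocess", "tracking"):
            out[f.name] = {
                g.name: _encode(getattr(v, g.name)) for g in dataclasses.fields(v)
            }
        else:
            out[f.name] = _encode(v)
    return out


def config_from_dict(d: dict) -> RunConfig:
    d = dict(d)
    pp = {k: _decode_scheduled(v) for k, v in d.pop("preprocess", {}).items()}
    tc = {k: _decode_scheduled(v) for k, v in d.pop("tracking", {}).items()}
    seeds = [tuple(s) for s in d.pop("seeds", [])]
    return RunConfig(
        preprocess=PreprocessParams(**pp),
        tracking=TrackConfig(**tc),
        seeds=seeds,
        **d,
    )


def save_config(config: RunConfig, path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(config)))


def load_config(path) -> RunConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def run_pipeline(
    config: RunConfig,
    stack: SliceStack | None = None,
    truth_paths: list[TrackedPath] | None = None,
    classifier: MoveClassifier | None = None,
    correction_provider=None,
) -> dict:
    """Execute the full tracking pipeline and return the run report.

    ``stack`` may be supplied in memory; otherwise ``config.stack_dir``
    is read.  ``truth_paths`` (one per seed, or a pool matched by best
    accuracy) enables alpha/beta scoring.  When ``config.out_prefix`` is
    set, per-seed CSV + SWC paths, the JSON report and the fully resolved
    config are written next to each other.
    """
    if stack is None:
        if config.stack_dir is None:
            raise ValueError("either an in-memory stack or config.stack_dir is required")
        stack = nio.read_stack(config.stack_dir)

    binary = preprocess_stack(stack, config.preprocess, config.defective_slices)
    feats = extract_features(binary, config.node_spacing, config.random_seed)

    if classifier is None and config.ml_enabled:
        if not config.model_path:
            raise ValueError("ml_enabled requires model_path")
        classifier = load_classifier(config.model_path)
    if not config.ml_enabled:
        classifier = None

    report: dict = {"n_slices": stack.n_slices, "seeds": []}
    paths: list[TrackedPath] = []
    for si, seed in enumerate(config.seeds):
        try:
            graph = track(
                stack,
                feats,
                seed,
                config=config.tracking,
                classifier=classifier,
                correction_provider=correction_provider,
            )
        except Exception as exc:
            raise RuntimeError(f"tracking failed for seed {seed}: {exc}") from exc
        path = reconstruct_path(graph)
        paths.append(path)
        entry = {
            "seed": list(seed),
            "path_length": len(path),
            "n_nodes_linked": len(graph),
            "n_skip_moves": graph.n_skip_moves,
            "n_corrections": len(graph.corrections),
            "correction_requested": graph.correction_requested,
            "region_signal_fired": graph.region_signal_fired,
            "rejections": dict(graph.rejections),
            "rejections_total": int(sum(graph.rejections.values())),
        }
        if config.tracking.record_overlap:
            entry["rejection_overlap"] = dict(graph.overlap)
        if truth_paths:
            scored = [
                evaluate_against_truth(path, t, config.residual_threshold)
                for t in truth_paths
            ]
            alpha, beta = max(scored)
            entry["alpha"] = alpha
            entry["beta"] = beta
        report["seeds"].append(entry)

    if config.out_prefix:
        prefix = Path(config.out_prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        for si, path in enumerate(paths):
            nio.write_path_csv(path, f"{prefix}_seed{si}.csv")
            nio.write_path_swc(
                path,
                f"{prefix}_seed{si}.swc",
                slice_thickness_px=stack.slice_thickness / stack.pixel_size,
            )
        nio.write_report(report, f"{prefix}_report.json")
        save_config(config, f"{prefix}_config.yaml")

    report["paths"] = paths
    return report
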