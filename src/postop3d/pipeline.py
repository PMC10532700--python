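"""End-to-end orchestration: simulate → detect cuts → reposition → screws
→ evaluate, with a YAML-backed configuration, per-stage logging and
deterministic, serialized intermediates.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .cuts import OracleSegmenter, detect_planes
from .errors import MisuseError, PostopError
from .evaluate import (EvaluationReport, compare_solutions, dice_coefficient,
                       registration_errors, screw_errors, surface_points)
from .geometry import RigidTransform
from .phantom import PhantomConfig, make_phantom
from .registration import RegistrationParams, quantify_repositioning, resample_to
from .screws import HoughParams, quantify_screws
from .volume import read_volume, write_volume

logger = logging.getLogger("postop3d")

STAGES = ("simulate", "detect_cuts", "reposition", "screws", "evaluate")
STAGE_EXIT_CODES = {name: 10 + i for i, name in enumerate(STAGES)}


class StageError(PostopError):
    """Wraps a failure with the stage name and a machine-readable code."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.code = STAGE_EXIT_CODES.get(stage, 1)
        super().__init__(f"stage '{stage}' failed: {cause}")


def _build(cls, values: dict, context: str):
    """Instantiate a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(values) - known
    if unknown:
        raise MisuseError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**values)


@dataclass
class PipelineConfig:
    """Full pipeline configuration; all module defaults mirror the
    package's standard parameter sets and are overridable."""

    out_dir: str = "postop3d_run"
    seed: int = 0
    simulate: bool = True
    pre_path: str | None = None
    post_path: str | None = None
    cut_backend: str = "oracle"      # oracle | network
    mask_backend: str = "oracle"     # oracle | network
    head_axis: tuple = (0.0, 0.0, 1.0)
    hu_threshold: float = 2500.0
    phantom: dict = field(default_factory=dict)
    coarse: dict = field(default_factory=dict)
    fine: dict = field(default_factory=dict)
    hough: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.cut_backend not in ("oracle", "network"):
            raise MisuseError("cut_backend must be 'oracle' or 'network'")
        if self.mask_backend not in ("oracle", "network"):
            raise MisuseError("mask_backend must be 'oracle' or 'network'")
        # validate nested blocks eagerly
        self.phantom_config()
        self.coarse_params()
        self.fine_params()
        self.hough_params()

    def phantom_config(self) -> PhantomConfig:
        block = dict(self.phantom)
        block.setdefault("seed", self.seed)
        return _build(PhantomConfig, block, "phantom")

    def coarse_params(self) -> RegistrationParams:
        p = _build(RegistrationParams, dict(self.coarse), "coarse registration")
        return p

    def fine_params(self) -> RegistrationParams:
        base = dataclasses.asdict(RegistrationParams.fine_default())
        base.update(self.fine)
        return _build(RegistrationParams, base, "fine registration")

    def hough_params(self) -> HoughParams:
        return _build(HoughParams, dict(self.hough), "hough")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["head_axis"] = list(self.head_axis)
        return d

    @classmethod
    def from_dict(cls, values: dict) -> "PipelineConfig":
        return _build(cls, dict(values), "pipeline")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def _write_json(path: Path, payload: dict) -> None:
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def run_pipeline(config: PipelineConfig) -> EvaluationReport:
    """Execute all stages in order, writing each stage's outputs before the
    next begins.  With oracle backends and a fixed seed the run is fully
    deterministic.  Returns the evaluation report (also written as JSON)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    logger.info("postop3d %s, seed %d, config %s", __version__, config.seed,
                config.config_hash())
    config.to_yaml(out / "config.yaml")

    timings = {}
    truth = None
    try:
        t0 = time.perf_counter()
        stage = "simulate"
        if config.simulate:
            pre, post, truth = make_phantom(config.phantom_config())
            write_volume(pre, out / "pre.nii.gz")
            write_volume(post, out / "post.nii.gz")
            write_volume(truth.cut_labels, out / "cut_labels.nii.gz")
            write_volume(truth.fragment_label, out / "fragment_label.nii.gz")
            _write_json(out / "truth.json", truth.to_dict())
        else:
            if not config.pre_path or not config.post_path:
                raise MisuseError("pre_path and post_path are required when "
                                  "simulate is disabled")
            pre = read_volume(config.pre_path)
            post = read_volume(config.post_path)
        timings[stage] = time.perf_counter() - t0
    except Exception as exc:
        raise StageError("simulate", exc) from exc

    try:
        t0 = time.perf_counter()
        stage = "detect_cuts"
        if config.cut_backend == "oracle":
            if truth is None:
                raise MisuseError("oracle cut backend requires a simulated phantom")
            backend = OracleSegmenter(truth.cut_labels)
        else:
            raise MisuseError("network cut backend requires a trained segmenter; "
                              "train one via postop3d.cuts.train_segmenter and use "
                              "the library API")
        detection = detect_planes(post, backend)
        _write_json(out / "planes.json", {
            "planes": [p.to_dict() if p else None for p in detection.planes],
            "failed": detection.failed,
            "voxel_counts": detection.voxel_counts,
        })
        if not detection.all_ok:
            raise MisuseError(f"plane detection failed for cuts "
                              f"{[i + 1 for i, f in enumerate(detection.failed) if f]}")
        timings[stage] = time.perf_counter() - t0
    except StageError:
        raise
    except Exception as exc:
        raise StageError("detect_cuts", exc) from exc

    try:
        t0 = time.perf_counter()
        stage = "reposition"
        if config.mask_backend == "oracle":
            if truth is None:
                raise MisuseError("oracle mask backend requires a simulated phantom")
            pelvis_mask = truth.post_bone_label
            pre_mask = truth.pre_bone_label
        else:
            raise MisuseError("network mask backend requires a trained segmenter; "
                              "use the library API")
        t1, t2, rep_report = quantify_repositioning(
            pre, post, detection.planes, pelvis_mask,
            config.coarse_params(), config.fine_params(), pre_pelvis_mask=pre_mask)
        _write_json(out / "transforms.json", {
            "coarse_T": t1.to_dict(), "fine_T": t2.to_dict(),
            "total_T": t2.compose(t1).to_dict(),
            "report": rep_report.to_dict(),
        })
        timings[stage] = time.perf_counter() - t0
    except StageError:
        raise
    except Exception as exc:
        raise StageError("reposition", exc) from exc

    try:
        t0 = time.perf_counter()
        stage = "screws"
        detections = quantify_screws(post, config.hough_params(),
                                     head_axis=np.array(config.head_axis),
                                     hu_threshold=config.hu_threshold)
        _write_json(out / "screws.json", {"screws": [d.to_dict() for d in detections]})
        timings[stage] = time.perf_counter() - t0
    except StageError:
        raise
    except Exception as exc:
        raise StageError("screws", exc) from exc

    try:
        t0 = time.perf_counter()
        stage = "evaluate"
        if truth is not None:
            report = _evaluate_against_truth(pre, post, truth, detection, t1, t2,
                                             detections)
        else:
            report = EvaluationReport()
        for name, secs in timings.items():
            logger.info("stage %s: %.3f s", name, secs)
        report.extras["seed"] = config.seed
        report.extras["version"] = __version__
        report.write(out / "report.json")
        timings[stage] = time.perf_counter() - t0
    except StageError:
        raise
    except Exception as exc:
        raise StageError("evaluate", exc) from exc
    finally:
        logger.removeHandler(handler)
        handler.close()
    return report


def _evaluate_against_truth(pre, post, truth, detection, t1, t2, screw_dets
                            ) -> EvaluationReport:
    surface = surface_points(truth.post_bone_label)
    report = compare_solutions(detection.planes, truth.planes, surface)

    bone_surface = surface_points(truth.pre_bone_label)
    report.err_t1_mm = registration_errors(bone_surface, t1, truth.coarse_transform)
    frag_surface = surface_points(truth.pre_fragment_label)
    report.err_t2_mm = registration_errors(frag_surface, t2, truth.fine_transform)
    report.err_t12_mm = registration_errors(frag_surface, t2.compose(t1),
                                            truth.fragment_transform)
    moved = resample_to(truth.pre_bone_label, post, t2.compose(t1))
    report.dice_auto = dice_coefficient(moved, truth.post_bone_label)
    report.screws = screw_errors(screw_dets, truth.screws)
    return report
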