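"""End-to-end orchestration: signal -> contigs -> frame selection ->
detection/crop -> keypoints, with per-stage accounting.

Stage wiring is sequential per video (record-then-process model).  The
classifier and scorers operate on greyscale, downscaled copies; the detector
and keypoint model see unresized originals — the measurement path contains
no resampling.  Pluggable components default to ground-truth-backed mocks so
the whole flow runs offline on synthetic footage.
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
import pandas as pd

from . import detection as det
from . import keypoints as kp
from . import selection as sel
from .preprocess import downscale, to_greyscale
from .segmentation import (
    ConfidenceSignal,
    Contig,
    SmoothingChainConfig,
    detect_contigs,
)
from .synthetic import (
    SceneAnnotation,
    SignalNoiseModel,
    SyntheticVideo,
    VIEWS,
    generate_signal,
    load_video,
)

logger = logging.getLogger(__name__)

__all__ = [
    "AnimalRecord",
    "PipelineConfig",
    "RunReport",
    "MockPresenceClassifier",
    "OracleKeypointPredictor",
    "run_pipeline",
    "profile_run",
    "write_records_csv",
]


@dataclass
class AnimalRecord:
    """One output row per contig."""

    contig_id: int
    start_frame: int
    end_frame: int
    selected_frame: dict[str, int]
    class_label: str = "undetected"
    detector_confidence: float = 0.0
    keypoints: kp.KeypointSet | None = None
    crop_origin: tuple[int, int] | None = None


@dataclass
class PipelineConfig:
    """Wiring and parameters for one processing run.

    Components left as ``None`` run in mock mode backed by the video's
    ground-truth annotations.
    """

    chain: SmoothingChainConfig = field(default_factory=SmoothingChainConfig)
    classifier: object | None = None  # callable(frames_small, annotations) -> signal
    scorers: dict[str, object] | None = None  # view -> scorer
    detector: object | None = None
    crop_spec: det.CropSpec | None = None  # None -> derive from detections
    keypoint_model: object | None = None  # None -> oracle from annotations
    classifier_size: tuple[int, int] | None = None  # None -> frames as-is
    views: tuple[str, ...] = VIEWS
    underside_keypoints: bool = False  # underside frames reserved for sexing
    seed: int = 0
    signal_noise: SignalNoiseModel | None = None  # for the mock classifier


@dataclass
class RunReport:
    stage_frames: dict[str, int] = field(default_factory=dict)
    stage_seconds: dict[str, float] = field(default_factory=dict)
    n_contigs: int = 0
    n_records: int = 0
    manifest: dict = field(default_factory=dict)


class MockPresenceClassifier:
    """Stands in for the per-frame binary classifier.

    Emits a volatile confidence trace derived from ground-truth presence
    through a :class:`SignalNoiseModel`, emulating the deployed classifier's
    noisy output without trained weights.
    """

    def __init__(self, noise: SignalNoiseModel | None = None, seed: int = 0) -> None:
        self.noise = noise or SignalNoiseModel(seed=seed)

    def __call__(
        self, frames_small: list[np.ndarray], annotations: list[SceneAnnotation]
    ) -> ConfidenceSignal:
        from .synthetic import EventSchedule

        present = np.array([a.present for a in annotations], dtype=bool)
        events = []
        start = None
        for i, p in enumerate(present):
            if p and start is None:
                start = i
            elif not p and start is not None:
                events.append((start, i))
                start = None
        if start is not None:
            events.append((start, len(present)))
        schedule = EventSchedule(events, len(present))
        return generate_signal(schedule, self.noise)


class OracleKeypointPredictor:
    """Returns ground-truth keypoints translated into crop coordinates."""

    def __init__(self, annotations: list[SceneAnnotation]) -> None:
        self._annotations = annotations
        self.n_calls = 0

    def predict(
        self, crop: np.ndarray, frame_index: int, origin: tuple[int, int]
    ) -> kp.KeypointSet:
        self.n_calls += 1
        ann = self._annotations[frame_index]
        return kp.KeypointSet(ann.keypoints).translate(-origin[0], -origin[1])


def _config_hash(config: PipelineConfig) -> str:
    payload = {
        "chain": dataclasses.asdict(config.chain),
        "classifier_size": config.classifier_size,
        "views": list(config.views),
        "underside_keypoints": config.underside_keypoints,
        "seed": config.seed,
        "crop_spec": dataclasses.asdict(config.crop_spec) if config.crop_spec else None,
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]


def run_pipeline(
    video: SyntheticVideo | str | Path,
    config: PipelineConfig = PipelineConfig(),
    out_dir: str | Path | None = None,
) -> tuple[list[AnimalRecord], RunReport]:
    """Process one video into animal records.

    ``video`` is a :class:`SyntheticVideo` or a directory written by
    :func:`crustavision.synthetic.save_video`.  Zero contigs is a successful
    run with an empty record list.
    """
    if not isinstance(video, SyntheticVideo):
        video = load_video(video)
    report = RunReport()
    annotations = video.annotations

    # -- stage 0: greyscale everything once, up front
    t0 = time.perf_counter()
    grey = [
        to_greyscale(f) if f.ndim == 3 else f for f in video.frames
    ]
    report.stage_seconds["greyscale"] = time.perf_counter() - t0
    report.stage_frames["greyscale"] = len(grey)

    # -- stage 1: per-frame classifier on downscaled copies
    t0 = time.perf_counter()
    if config.classifier_size is not None:
        small = [downscale(g, config.classifier_size) for g in grey]
    else:
        small = grey
    classifier = config.classifier or MockPresenceClassifier(
        noise=config.signal_noise, seed=config.seed
    )
    signal = classifier(small, annotations)
    report.stage_seconds["classifier"] = time.perf_counter() - t0
    report.stage_frames["classifier"] = len(signal)

    # -- stage 2: temporal segmentation
    t0 = time.perf_counter()
    contigs = detect_contigs(signal, config.chain)
    contigs = [
        Contig(c.start_frame, min(c.end_frame, len(grey))) for c in contigs
    ]
    report.stage_seconds["segmentation"] = time.perf_counter() - t0
    report.stage_frames["segmentation"] = len(signal)
    report.n_contigs = len(contigs)
    if not contigs:
        logger.info("no contigs detected; emitting an empty record list")

    # -- stage 3: frame selection per contig per view
    t0 = time.perf_counter()
    scorers = config.scorers or {
        view: sel.OracleScorer(annotations) for view in config.views
    }
    all_scores: dict[tuple[int, str], list[sel.FrameScore]] = {}
    scored_frames = 0
    for cid, contig in enumerate(contigs):
        for view in config.views:
            all_scores[(cid, view)] = sel.score_frames(
                small, contig, scorers[view], view
            )
            scored_frames += len(contig)
    selected = sel.select_best(all_scores) if all_scores else {}
    report.stage_seconds["selector"] = time.perf_counter() - t0
    report.stage_frames["selector"] = scored_frames

    # -- stages 4+5: detect, crop and keypoint the selected top-view frames
    detector = config.detector or det.MockDetector(annotations, seed=config.seed)
    kp_model = config.keypoint_model or OracleKeypointPredictor(annotations)
    kp_views = (
        config.views if config.underside_keypoints else ("top",)
    )

    t0 = time.perf_counter()
    detections: dict[int, det.Detection | None] = {}
    det_frames = 0
    for cid, contig in enumerate(contigs):
        frame_idx = selected.get((cid, "top"))
        if frame_idx is None:
            detections[cid] = None
            continue
        detections[cid] = det.detect(
            video.frames[frame_idx], detector, frame_index=frame_idx
        )
        det_frames += 1
        if detections[cid] is None:
            logger.warning("detector miss on contig %d frame %d; skipping", cid, frame_idx)
    report.stage_seconds["detector"] = time.perf_counter() - t0
    report.stage_frames["detector"] = det_frames

    crop_spec = config.crop_spec
    if crop_spec is None:
        found = [d for d in detections.values() if d is not None]
        if found:
            spec = det.derive_crop_size(found)
            h, w = grey[0].shape[:2]
            crop_spec = det.CropSpec(min(spec.crop_w, w), min(spec.crop_h, h))

    t0 = time.perf_counter()
    records: list[AnimalRecord] = []
    kp_frames = 0
    for cid, contig in enumerate(contigs):
        record = AnimalRecord(
            contig_id=cid,
            start_frame=contig.start_frame,
            end_frame=contig.end_frame,
            selected_frame={
                view: selected[(cid, view)]
                for view in config.views
                if (cid, view) in selected
            },
        )
        d = detections.get(cid)
        if d is not None and crop_spec is not None:
            record.class_label = d.class_label
            record.detector_confidence = d.confidence
            frame_idx = selected[(cid, "top")]
            origin = det.crop_origin(d, crop_spec, grey[frame_idx].shape)
            record.crop_origin = origin
            if "top" in kp_views:
                crop = det.crop_fixed(grey[frame_idx], d, crop_spec)
                try:
                    if isinstance(kp_model, OracleKeypointPredictor):
                        record.keypoints = kp_model.predict(crop, frame_idx, origin)
                    else:
                        record.keypoints = kp.predict_keypoints(crop, kp_model)
                    kp_frames += 1
                except ValueError as exc:
                    logger.warning("keypoint stage skipped on contig %d: %s", cid, exc)
        records.append(record)
    report.stage_seconds["keypoints"] = time.perf_counter() - t0
    report.stage_frames["keypoints"] = kp_frames
    report.n_records = len(records)

    report.manifest = {
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "n_frames": len(grey),
        "n_contigs": len(contigs),
        "n_records": len(records),
        "n_selected_frames": len(selected),
        "stage_frames": dict(report.stage_frames),
        "crop_spec": dataclasses.asdict(crop_spec) if crop_spec else None,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_records_csv(records, out / "records.csv")
        sel.write_selection_csv(selected, all_scores, out / "selected_frames.csv")
        tmp = out / "manifest.json.tmp"
        tmp.write_text(json.dumps(report.manifest, indent=2, sort_keys=True))
        tmp.replace(out / "manifest.json")
    return records, report


def profile_run(report: RunReport) -> pd.DataFrame:
    """Per-stage frames / seconds / rate table.

    Timings are reported, never asserted: they are hardware-dependent.
    """
    rows = []
    for stage, frames in report.stage_frames.items():
        seconds = report.stage_seconds.get(stage, 0.0)
        rows.append(
            {
                "stage": stage,
                "frames": frames,
                "seconds": seconds,
                "fps": frames / seconds if seconds > 0 else float("inf"),
            }
        )
    return pd.DataFrame(rows, columns=["stage", "frames", "seconds", "fps"])


def write_records_csv(records: list[AnimalRecord], path) -> None:
    columns = [
        "contig_id",
        "start_frame",
        "end_frame",
        "selected_frame_top",
        "selected_frame_underside",
        "class",
        "detector_confidence",
    ]
    for name in kp.KEYPOINT_NAMES:
        columns += [f"{name}_x", f"{name}_y"]
    rows = []
    for r in records:
        row = {
            "contig_id": r.contig_id,
            "start_frame": r.start_frame,
            "end_frame": r.end_frame,
            "selected_frame_top": r.selected_frame.get("top", ""),
            "selected_frame_underside": r.selected_frame.get("underside", ""),
            "class": r.class_label,
            "detector_confidence": f"{r.detector_confidence:.4f}",
        }
        for name in kp.KEYPOINT_NAMES:
            if r.keypoints is None:
                row[f"{name}_x"] = row[f"{name}_y"] = ""
            else:
                x, y = r.keypoints[name]
                row[f"{name}_x"] = f"{x:.3f}"
                row[f"{name}_y"] = f"{y:.3f}"
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
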