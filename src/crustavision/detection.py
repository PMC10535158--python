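"""Animal localisation on selected frames and fixed-size ROI cropping.

The detector is a pluggable component: production wires in an off-the-shelf
object detector; tests use a mock backed by synthetic ground truth.  Crops
are pure pixel copies — translated to stay inside the frame, never scaled —
because any resampling on the measurement path would distort derived sizes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np
import pandas as pd

__all__ = [
    "Detection",
    "CropSpec",
    "Detector",
    "MockDetector",
    "detect",
    "derive_crop_size",
    "crop_fixed",
    "crop_origin",
    "iou",
    "write_detections_csv",
]

CLASS_LABELS = ("crab", "lobster")


@dataclass(frozen=True)
class Detection:
    """One localised animal: bbox (x, y, w, h), class label, confidence."""

    bbox: tuple[int, int, int, int]
    class_label: str
    confidence: float

    def __post_init__(self) -> None:
        x, y, w, h = self.bbox
        if w <= 0 or h <= 0:
            raise ValueError("bbox width and height must be positive")
        if self.class_label not in CLASS_LABELS:
            raise ValueError(f"class must be one of {CLASS_LABELS}")
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError("confidence must lie in [0, 1]")

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.bbox
        return (x + w / 2.0, y + h / 2.0)


@dataclass(frozen=True)
class CropSpec:
    """Dataset-wide fixed crop dimensions."""

    crop_w: int
    crop_h: int

    def __post_init__(self) -> None:
        if self.crop_w <= 0 or self.crop_h <= 0:
            raise ValueError("crop dimensions must be positive")


@runtime_checkable
class Detector(Protocol):
    """Contract for a pluggable frame detector."""

    def __call__(self, image: np.ndarray, frame_index: int) -> list[Detection]:
        ...


class MockDetector:
    """Ground-truth-backed detector for offline tests.

    Returns the annotated bbox (optionally jittered by ``jitter_sd`` pixels)
    with the event's class label.  ``miss_prob`` simulates detector misses.
    """

    def __init__(
        self,
        annotations,
        class_of_frame=None,
        jitter_sd: float = 0.0,
        miss_prob: float = 0.0,
        seed: int = 0,
    ) -> None:
        self._annotations = annotations
        self._class_of_frame = class_of_frame or (lambda i: "crab")
        self.jitter_sd = float(jitter_sd)
        self.miss_prob = float(miss_prob)
        self._rng = np.random.default_rng(seed)
        self.n_calls = 0

    def __call__(self, image: np.ndarray, frame_index: int) -> list[Detection]:
        self.n_calls += 1
        ann = self._annotations[frame_index]
        if not ann.present or self._rng.random() < self.miss_prob:
            return []
        x, y, w, h = ann.bbox
        if self.jitter_sd > 0:
            jx, jy = self._rng.normal(0.0, self.jitter_sd, 2)
            height, width = image.shape[:2]
            x = int(np.clip(round(x + jx), 0, width - w))
            y = int(np.clip(round(y + jy), 0, height - h))
        return [
            Detection(
                bbox=(int(x), int(y), int(w), int(h)),
                class_label=self._class_of_frame(frame_index),
                confidence=0.99,
            )
        ]


def detect(image: np.ndarray, detector: Detector, frame_index: int = 0):
    """Run the detector on a full-resolution frame.

    Returns the highest-confidence :class:`Detection`, or ``None`` when the
    detector finds nothing (the caller logs and skips the contig).
    """
    detections = detector(image, frame_index)
    if not detections:
        return None
    return max(detections, key=lambda d: d.confidence)


def derive_crop_size(detections: list[Detection]) -> CropSpec:
    """Fixed crop size = mean bbox dimensions, rounded to the nearest even
    integer (keeps downstream pooling arithmetic clean)."""
    if not detections:
        raise ValueError("cannot derive a crop size from zero detections")
    mean_w = float(np.mean([d.bbox[2] for d in detections]))
    mean_h = float(np.mean([d.bbox[3] for d in detections]))
    return CropSpec(crop_w=_round_even(mean_w), crop_h=_round_even(mean_h))


def _round_even(x: float) -> int:
    return max(2, int(2 * round(x / 2.0)))


def crop_origin(
    detection: Detection, spec: CropSpec, image_shape: tuple[int, int]
) -> tuple[int, int]:
    """Top-left corner of the crop window: centred on the bbox centre, then
    translated (never scaled) to stay fully inside the image."""
    height, width = image_shape[:2]
    if spec.crop_w > width or spec.crop_h > height:
        raise ValueError(
            f"crop {spec.crop_w}x{spec.crop_h} larger than image "
            f"{width}x{height}; downscaling is forbidden"
        )
    cx, cy = detection.center
    x0 = int(round(cx - spec.crop_w / 2.0))
    y0 = int(round(cy - spec.crop_h / 2.0))
    x0 = min(max(x0, 0), width - spec.crop_w)
    y0 = min(max(y0, 0), height - spec.crop_h)
    return x0, y0


def crop_fixed(
    image: np.ndarray, detection: Detection, spec: CropSpec
) -> np.ndarray:
    """Cut an exactly crop_w x crop_h window as a pure pixel copy."""
    x0, y0 = crop_origin(detection, spec, image.shape)
    return image[y0 : y0 + spec.crop_h, x0 : x0 + spec.crop_w].copy()


def iou(box_a: tuple[int, int, int, int], box_b: tuple[int, int, int, int]) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    ix = max(0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def write_detections_csv(rows: list[dict], path) -> None:
    """Rows: frame, x, y, w, h, class, confidence."""
    pd.DataFrame(
        rows, columns=["frame", "x", "y", "w", "h", "class", "confidence"]
    ).to_csv(path, index=False)
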