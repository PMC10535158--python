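"""Seeded synthetic deck-camera data with full ground truth.

Every downstream stage is testable without real footage: this module renders
an elongated two-tone "crustacean" blob (ellipse body, triangular tail,
brighter head disc) over a textured background, emits per-frame annotations
(presence, view, bounding box, the 7 named keypoints, a quality label), and
synthesises noisy per-frame confidence signals from an event schedule.

All randomness flows through a single integer seed per call.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .keypoints import KEYPOINT_NAMES
from .segmentation import ConfidenceSignal

__all__ = [
    "EventSchedule",
    "SignalNoiseModel",
    "Pose",
    "SceneAnnotation",
    "SyntheticVideo",
    "generate_signal",
    "generate_frame",
    "generate_video",
    "random_schedule",
    "default_pose_track",
    "save_video",
    "load_video",
]

VIEWS = ("top", "underside")


@dataclass(frozen=True)
class EventSchedule:
    """Sorted, non-overlapping half-open [start, end) presentation events."""

    events: tuple[tuple[int, int], ...]
    n_frames: int

    def __init__(self, events, n_frames: int) -> None:
        events = tuple((int(s), int(e)) for s, e in events)
        object.__setattr__(self, "events", events)
        object.__setattr__(self, "n_frames", int(n_frames))
        if self.n_frames < 0:
            raise ValueError("n_frames must be non-negative")
        prev_end = 0
        for s, e in events:
            if not 0 <= s < e <= self.n_frames:
                raise ValueError(f"event ({s}, {e}) outside [0, {self.n_frames}]")
            if s < prev_end:
                raise ValueError("events must be sorted and non-overlapping")
            prev_end = e

    @property
    def n_events(self) -> int:
        return len(self.events)

    def indicator(self) -> np.ndarray:
        """1.0 on in-event frames, 0.0 elsewhere."""
        ind = np.zeros(self.n_frames)
        for s, e in self.events:
            ind[s:e] = 1.0
        return ind

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["event_id", "start_frame", "end_frame"])
            for i, (s, e) in enumerate(self.events):
                w.writerow([i, s, e])

    @classmethod
    def from_csv(cls, path, n_frames: int) -> "EventSchedule":
        events = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                events.append((int(row["start_frame"]), int(row["end_frame"])))
        return cls(events, n_frames)


@dataclass(frozen=True)
class SignalNoiseModel:
    """Noise knobs for synthesising a volatile classifier confidence trace.

    ``dropout_prob`` is the chance an in-event frame reads low;
    ``spike_prob`` the chance an out-of-event frame reads high, at
    ``spike_amplitude``.  Gaussian jitter of ``jitter_sd`` is added on top.
    These defaults are calibration knobs, not measured statistics.
    """

    in_event_level: float = 1.0
    out_event_level: float = 0.0
    dropout_prob: float = 0.3
    spike_prob: float = 0.05
    spike_amplitude: float = 0.1
    jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.dropout_prob, self.spike_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        for lvl in (self.in_event_level, self.out_event_level, self.spike_amplitude):
            if not 0.0 <= lvl <= 1.0:
                raise ValueError("levels must lie in [0, 1]")
        if self.in_event_level <= self.out_event_level:
            raise ValueError("in_event_level must exceed out_event_level")
        if self.jitter_sd < 0:
            raise ValueError("jitter_sd must be non-negative")


def generate_signal(
    schedule: EventSchedule, noise: SignalNoiseModel
) -> ConfidenceSignal:
    """Emit a noisy confidence trace following the event schedule."""
    if schedule.n_frames == 0:
        raise ValueError("cannot generate a signal for a zero-frame schedule")
    rng = np.random.default_rng(noise.seed)
    ind = schedule.indicator().astype(bool)
    values = np.where(ind, noise.in_event_level, noise.out_event_level)

    if noise.dropout_prob > 0:
        drop = rng.random(schedule.n_frames) < noise.dropout_prob
        values = np.where(ind & drop, noise.out_event_level, values)
    if noise.spike_prob > 0:
        spike = rng.random(schedule.n_frames) < noise.spike_prob
        values = np.where(~ind & spike, noise.spike_amplitude, values)
    if noise.jitter_sd > 0:
        values = values + rng.normal(0.0, noise.jitter_sd, schedule.n_frames)
    return ConfidenceSignal(np.clip(values, 0.0, 1.0))


# -- frame rendering -------------------------------------------------------


@dataclass(frozen=True)
class Pose:
    """Blob placement: pixel center, clockwise angle in degrees (0 = head
    up), and scale = semi-minor axis in pixels."""

    center: tuple[float, float]
    angle: float = 0.0
    scale: float = 12.0
    blur: float = 0.0  # motion-blur fraction in [0, 1]


@dataclass
class SceneAnnotation:
    """Ground truth for one frame."""

    present: bool
    view: str | None = None
    bbox: tuple[int, int, int, int] | None = None  # x, y, w, h; top-left origin
    keypoints: dict[str, tuple[float, float]] | None = None
    quality: float | None = None
    partial: bool = False

    def to_dict(self) -> dict:
        d = {"present": self.present, "partial": self.partial}
        if self.present:
            d.update(
                view=self.view,
                bbox=list(self.bbox),
                keypoints={k: list(v) for k, v in self.keypoints.items()},
                quality=self.quality,
            )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneAnnotation":
        if not d["present"]:
            return cls(present=False, partial=d.get("partial", False))
        return cls(
            present=True,
            view=d["view"],
            bbox=tuple(d["bbox"]),
            keypoints={k: tuple(v) for k, v in d["keypoints"].items()},
            quality=d["quality"],
            partial=d.get("partial", False),
        )


# body-frame keypoint offsets as (along-axis, across-axis) multiples of
# (semi-major a, semi-minor b); +u points toward the head
_KP_OFFSETS: dict[str, tuple[float, float]] = {
    "crab_left": (0.0, -0.9),
    "crab_right": (0.0, 0.9),
    "left_eye": (0.8, -0.3),
    "right_eye": (0.8, 0.3),
    "carapace_end": (-0.85, 0.0),
    "tail_end": (-1.45, 0.0),
    "last_segment": (-1.2, 0.0),
}

_ASPECT = 2.0  # semi-major / semi-minor axis ratio
_TAIL_TIP = 1.5  # tail tip at -_TAIL_TIP * a along the axis


def _background(shape: tuple[int, int], rng: np.random.Generator) -> np.ndarray:
    noise = rng.normal(0.0, 1.0, shape)
    texture = ndimage.gaussian_filter(noise, sigma=3.0)
    tex = texture / (np.abs(texture).max() + 1e-12)
    return np.clip(70 + 25 * tex, 0, 255)


def _axes(angle_deg: float) -> tuple[np.ndarray, np.ndarray]:
    t = math.radians(angle_deg)
    unit_u = np.array([math.sin(t), -math.cos(t)])  # toward head; angle 0 = up
    unit_v = np.array([math.cos(t), math.sin(t)])  # to the right of the body
    return unit_u, unit_v


def generate_frame(
    present: bool,
    view: str = "top",
    pose: Pose | None = None,
    image_size: tuple[int, int] = (320, 180),
    seed: int = 0,
) -> tuple[np.ndarray, SceneAnnotation]:
    """Render one RGB frame plus its annotation.

    ``image_size`` is (width, height).  When ``present`` the blob is placed
    per ``pose``; keypoints are derived analytically from the pose, the bbox
    is fitted tightly around the rendered blob mask, and the quality label is
    the product of centrality, scale fitness and (1 - blur fraction),
    discounted when the blob is partially out of frame.
    """
    w, h = image_size
    rng = np.random.default_rng(seed)
    grey = _background((h, w), rng)

    if not present:
        rgb = _to_rgb(grey, rng)
        return rgb, SceneAnnotation(present=False)

    if view not in VIEWS:
        raise ValueError(f"view must be one of {VIEWS}")
    if pose is None:
        pose = Pose(center=(w / 2.0, h / 2.0))
    cx, cy = pose.center
    b = float(pose.scale)
    a = _ASPECT * b
    unit_u, unit_v = _axes(pose.angle)

    ys, xs = np.mgrid[0:h, 0:w]
    dx = xs - cx
    dy = ys - cy
    u = dx * unit_u[0] + dy * unit_u[1]
    v = dx * unit_v[0] + dy * unit_v[1]

    body = (u / a) ** 2 + (v / b) ** 2 <= 1.0
    # tail: triangle tapering from half-width 0.5b at u=-a to a point
    tail_span = (_TAIL_TIP - 1.0) * a
    frac = np.clip((-u - a) / tail_span, 0.0, 1.0)
    tail = (-u >= a) & (-u <= _TAIL_TIP * a) & (np.abs(v) <= 0.5 * b * (1.0 - frac))
    head = (u - 0.55 * a) ** 2 + v**2 <= (0.45 * b) ** 2
    blob = body | tail

    if view == "top":
        body_tone = np.full((h, w), 170.0)
    else:  # underside: banded texture along the body axis
        band = (np.floor(u / (0.45 * b)) % 2).astype(float)
        body_tone = 140.0 + 45.0 * band
    grey = np.where(blob, body_tone, grey)
    grey = np.where(head & body, 230.0, grey)

    if pose.blur > 0:
        grey = ndimage.gaussian_filter(grey, sigma=3.0 * pose.blur)

    rgb = _to_rgb(grey, rng)

    # analytic keypoints from the pose
    keypoints = {}
    for name, (fu, fv) in _KP_OFFSETS.items():
        p = np.array([cx, cy]) + fu * a * unit_u + fv * b * unit_v
        keypoints[name] = (float(p[0]), float(p[1]))

    # tight bbox: rendered mask extent, widened to cover the analytic
    # (sub-pixel) keypoints, clipped to the image
    if not blob.any():
        raise ValueError("pose places the blob entirely outside the frame")
    rows = np.flatnonzero(blob.any(axis=1))
    cols = np.flatnonzero(blob.any(axis=0))
    kxs = [p[0] for p in keypoints.values()]
    kys = [p[1] for p in keypoints.values()]
    x0 = min(int(cols[0]), math.floor(min(kxs)))
    x1 = max(int(cols[-1]) + 1, math.ceil(max(kxs)) + 1)
    y0 = min(int(rows[0]), math.floor(min(kys)))
    y1 = max(int(rows[-1]) + 1, math.ceil(max(kys)) + 1)
    x0, y0 = max(x0, 0), max(y0, 0)
    x1, y1 = min(x1, w), min(y1, h)
    bbox = (x0, y0, x1 - x0, y1 - y0)

    # partial visibility: analytic blob extent vs frame bounds
    reach = _TAIL_TIP * a
    partial = (
        cx - reach < 0 or cx + reach > w - 1 or cy - reach < 0 or cy + reach > h - 1
    )

    quality = _quality(pose, image_size, partial, blob)
    ann = SceneAnnotation(
        present=True,
        view=view,
        bbox=bbox,
        keypoints=keypoints,
        quality=quality,
        partial=partial,
    )
    return rgb, ann


def _to_rgb(grey: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    h, w = grey.shape
    chroma = rng.normal(0.0, 2.0, (h, w, 3))
    rgb = grey[..., None] + chroma
    return np.clip(rgb, 0, 255).astype(np.uint8)


def _quality(
    pose: Pose,
    image_size: tuple[int, int],
    partial: bool,
    blob_mask: np.ndarray,
) -> float:
    w, h = image_size
    cx, cy = pose.center
    half_diag = 0.5 * math.hypot(w, h)
    centrality = 1.0 - math.hypot(cx - w / 2.0, cy - h / 2.0) / half_diag
    ideal = 0.18 * min(w, h)
    scale_fit = max(0.0, 1.0 - abs(pose.scale - ideal) / ideal)
    q = max(0.0, centrality) * scale_fit * (1.0 - min(pose.blur, 1.0))
    if partial:
        # discount by the fraction of the nominal blob area left on screen
        nominal = math.pi * pose.scale**2 * _ASPECT + 0.25 * _ASPECT * pose.scale**2
        visible = blob_mask.sum() / max(nominal, 1.0)
        q *= min(1.0, visible) * 0.5
    return float(np.clip(q, 0.0, 1.0))


# -- video synthesis -------------------------------------------------------


def default_pose_track(
    event: tuple[int, int],
    image_size: tuple[int, int],
    seed: int = 0,
) -> list[Pose]:
    """Move the blob in from an edge, hold it near center, move it out.

    Blur is high while moving and near zero at the central hold, so the
    mid-event frame is the designated best frame.
    """
    s, e = event
    n = e - s
    w, h = image_size
    rng = np.random.default_rng(seed)
    ideal = 0.18 * min(w, h)
    scale = ideal * rng.uniform(0.85, 1.15)
    angle = rng.uniform(-30.0, 30.0)
    side = rng.integers(0, 2)  # enter from left or right, half visible at entry
    x_edge = 0.0 if side == 0 else float(w - 1)
    cx_mid, cy_mid = w / 2.0 + rng.uniform(-0.05, 0.05) * w, h / 2.0

    poses = []
    for i in range(n):
        t = i / max(n - 1, 1)
        # triangular in/out trajectory with a flat hold in the middle third
        if t < 1 / 3:
            lam = t * 3.0
        elif t > 2 / 3:
            lam = (1.0 - t) * 3.0
        else:
            lam = 1.0
        cx = x_edge + lam * (cx_mid - x_edge)
        cy = cy_mid + (1 - lam) * 0.1 * h
        # residual handling blur decays toward the mid-event still point,
        # giving each event a distinct quality optimum
        blur = 0.55 * (1.0 - lam) + 0.35 * 2.0 * abs(t - 0.5)
        poses.append(Pose(center=(cx, cy), angle=angle, scale=scale, blur=blur))
    return poses


@dataclass
class SyntheticVideo:
    """Frames plus complete ground truth for one synthetic deck video."""

    frames: list[np.ndarray]
    annotations: list[SceneAnnotation]
    schedule: EventSchedule
    best_frames: dict[int, int] = field(default_factory=dict)  # event -> frame

    @property
    def n_frames(self) -> int:
        return len(self.frames)


def generate_video(
    schedule: EventSchedule,
    pose_tracks: list[list[Pose]] | None = None,
    image_size: tuple[int, int] = (320, 180),
    seed: int = 0,
) -> SyntheticVideo:
    """Render a full video for a schedule with one pose track per event.

    Tracks default to :func:`default_pose_track`.  The ground-truth best
    frame of each event is the quality argmax over the event's frames.
    """
    if pose_tracks is None:
        pose_tracks = [
            default_pose_track(ev, image_size, seed=seed + 1000 + i)
            for i, ev in enumerate(schedule.events)
        ]
    if len(pose_tracks) != schedule.n_events:
        raise ValueError("need exactly one pose track per event")
    for ev, track in zip(schedule.events, pose_tracks):
        if len(track) != ev[1] - ev[0]:
            raise ValueError("pose track length must match event length")

    event_of_frame = np.full(schedule.n_frames, -1)
    for i, (s, e) in enumerate(schedule.events):
        event_of_frame[s:e] = i

    frames: list[np.ndarray] = []
    annotations: list[SceneAnnotation] = []
    for f in range(schedule.n_frames):
        ev = int(event_of_frame[f])
        if ev < 0:
            img, ann = generate_frame(
                present=False, image_size=image_size, seed=seed + f
            )
        else:
            s, _ = schedule.events[ev]
            view = VIEWS[ev % 2]
            pose = pose_tracks[ev][f - s]
            img, ann = generate_frame(
                present=True,
                view=view,
                pose=pose,
                image_size=image_size,
                seed=seed + f,
            )
        frames.append(img)
        annotations.append(ann)

    best = {}
    for i, (s, e) in enumerate(schedule.events):
        qualities = [annotations[f].quality for f in range(s, e)]
        best[i] = s + int(np.argmax(qualities))
    return SyntheticVideo(frames, annotations, schedule, best)


def random_schedule(
    n_frames: int,
    n_events: int,
    seed: int = 0,
    min_len: int = 30,
    max_len: int = 80,
    min_gap: int = 60,
) -> EventSchedule:
    """Draw well-separated events by placing them in a jittered grid."""
    rng = np.random.default_rng(seed)
    needed = n_events * max_len + (n_events + 1) * min_gap
    if needed > n_frames:
        raise ValueError(
            f"{n_frames} frames cannot hold {n_events} events "
            f"(need >= {needed})"
        )
    slack = n_frames - needed
    # distribute slack randomly into the n_events + 1 gaps
    cuts = np.sort(rng.integers(0, slack + 1, size=n_events))
    extra = np.diff(np.concatenate(([0], cuts, [slack])))
    events = []
    cursor = 0
    for i in range(n_events):
        cursor += min_gap + int(extra[i])
        length = int(rng.integers(min_len, max_len + 1))
        events.append((cursor, cursor + length))
        cursor += max_len  # reserve the full slot to keep gaps >= min_gap
    return EventSchedule(events, n_frames)


# -- disk I/O --------------------------------------------------------------


def save_video(video: SyntheticVideo, out_dir) -> Path:
    """Write frames as PNGs plus JSON annotations and a schedule CSV."""
    out = Path(out_dir)
    frame_dir = out / "frames"
    frame_dir.mkdir(parents=True, exist_ok=True)
    for i, frame in enumerate(video.frames):
        iio.imwrite(frame_dir / f"frame_{i:06d}.png", frame)
    sidecar = {
        "n_frames": video.n_frames,
        "annotations": [a.to_dict() for a in video.annotations],
        "best_frames": {str(k): v for k, v in video.best_frames.items()},
    }
    (out / "annotations.json").write_text(json.dumps(sidecar))
    video.schedule.to_csv(out / "schedule.csv")
    return out


def load_video(in_dir) -> SyntheticVideo:
    src = Path(in_dir)
    sidecar = json.loads((src / "annotations.json").read_text())
    n = sidecar["n_frames"]
    frames = [
        np.asarray(iio.imread(src / "frames" / f"frame_{i:06d}.png"))
        for i in range(n)
    ]
    annotations = [SceneAnnotation.from_dict(d) for d in sidecar["annotations"]]
    schedule = EventSchedule.from_csv(src / "schedule.csv", n_frames=n)
    best = {int(k): v for k, v in sidecar["best_frames"].items()}
    return SyntheticVideo(frames, annotations, schedule, best)
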