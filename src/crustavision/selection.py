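"""Representativeness scoring of in-contig frames and per-contig selection.

One scorer per camera view assigns each in-contig frame a scalar quality in
[0, 1]; the per-contig, per-view argmax becomes the shortlisted frame.
Scorers are evaluated by pairwise preference accuracy: shown a (better,
worse) pair, did the scorer rank the better frame higher?
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._nn import TinyMLP, block_pool
from .segmentation import Contig

__all__ = [
    "FrameScore",
    "ScorerSpec",
    "ConstantScorer",
    "OracleScorer",
    "FrameScorer",
    "train_scorer",
    "score_frames",
    "select_best",
    "pairwise_accuracy",
    "write_selection_csv",
]


@dataclass(frozen=True)
class FrameScore:
    frame_index: int
    view: str
    score: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.score <= 1.0:
            raise ValueError("score must lie in [0, 1]")


@dataclass(frozen=True)
class ScorerSpec:
    """Published scorer training recipe; identical architecture per view."""

    input_size: tuple[int, int] = (320, 180)  # (width, height), greyscale
    epochs: int = 200
    learning_rate: float = 1e-5
    train_size: int = 950


class ConstantScorer:
    """Returns the same score for every frame (untrained stand-in)."""

    def __init__(self, value: float = 0.5) -> None:
        self.value = float(value)

    def __call__(self, frame: np.ndarray) -> float:
        return self.value


class OracleScorer:
    """Scores frames by their ground-truth quality labels (testing aid)."""

    def __init__(self, annotations) -> None:
        self._annotations = annotations

    def score_index(self, frame_index: int) -> float:
        ann = self._annotations[frame_index]
        return float(ann.quality) if ann.present else 0.0


class FrameScorer:
    """Trainable single-output frame quality model for one view.

    Block-pooled intensity plus block-pooled gradient energy (a sharpness
    cue) feed a tiny MLP ending in one sigmoid unit, honouring the
    single-confidence-neuron output convention of the deployed scorer.
    """

    def __init__(
        self,
        input_size: tuple[int, int] = (320, 180),
        pool: int = 10,
        hidden: int = 32,
        seed: int = 0,
    ) -> None:
        w, h = input_size
        if w % pool or h % pool:
            raise ValueError(
                f"input size {input_size} must be divisible by pool={pool}"
            )
        self.input_size = (int(w), int(h))
        self.pool = int(pool)
        n_features = 2 * (w // pool) * (h // pool)
        self.net = TinyMLP(
            (n_features, hidden, 1), out_activation="sigmoid", seed=seed
        )

    def _features(self, frames: list[np.ndarray]) -> np.ndarray:
        w, h = self.input_size
        feats = []
        for f in frames:
            if f.ndim != 2 or f.shape != (h, w):
                raise ValueError(
                    f"frame shape {f.shape} does not match scorer input {(h, w)}"
                )
            g = f.astype(float) / 255.0
            gy, gx = np.gradient(g)
            grad = np.hypot(gx, gy)
            feats.append(
                np.concatenate(
                    [
                        block_pool(g, self.pool, self.pool).ravel(),
                        5.0 * block_pool(grad, self.pool, self.pool).ravel(),
                    ]
                )
            )
        return np.stack(feats)

    def __call__(self, frame: np.ndarray) -> float:
        return float(self.net(self._features([frame]))[0, 0])

    def score_batch(self, frames: list[np.ndarray]) -> np.ndarray:
        return self.net(self._features(frames))[:, 0]

    def fit(
        self,
        frames: list[np.ndarray],
        targets: np.ndarray,
        epochs: int = 200,
        learning_rate: float = 1e-3,
        batch_size: int | None = 64,
        seed: int = 0,
    ) -> list[float]:
        x = self._features(frames)
        y = np.asarray(targets, dtype=float)
        return self.net.fit(
            x,
            y,
            epochs=epochs,
            learning_rate=learning_rate,
            batch_size=batch_size,
            seed=seed,
        )

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path, input_size=(320, 180), pool: int = 10) -> "FrameScorer":
        scorer = cls(input_size, pool=pool)
        scorer.net = TinyMLP.load(path)
        return scorer


def train_scorer(
    frames: list[np.ndarray],
    quality_labels: np.ndarray,
    input_size: tuple[int, int] = (320, 180),
    epochs: int = 200,
    learning_rate: float = 1e-3,
    seed: int = 0,
) -> FrameScorer:
    """Fit a fresh view scorer on labelled greyscale frames."""
    scorer = FrameScorer(input_size=input_size, seed=seed)
    scorer.fit(
        frames, quality_labels, epochs=epochs, learning_rate=learning_rate, seed=seed
    )
    return scorer


def score_frames(
    frames: list[np.ndarray],
    contig: Contig,
    scorer,
    view: str,
) -> list[FrameScore]:
    """Score every frame inside one contig; out-of-contig frames are never
    touched.

    ``frames`` is the whole video's (preprocessed) frame list; only indices
    in ``[contig.start_frame, contig.end_frame)`` are read.  The scorer is
    either a callable on a frame array or an :class:`OracleScorer`.
    """
    if len(contig) == 0:
        raise ValueError("empty contig")
    if contig.end_frame > len(frames):
        raise ValueError("contig extends past the end of the video")
    scores = []
    for idx in range(contig.start_frame, contig.end_frame):
        if isinstance(scorer, OracleScorer):
            s = scorer.score_index(idx)
        else:
            s = float(scorer(frames[idx]))
        scores.append(FrameScore(frame_index=idx, view=view, score=s))
    return scores


def select_best(
    scores: dict[tuple[int, str], list[FrameScore]],
) -> dict[tuple[int, str], int]:
    """Argmax frame per (contig_id, view); ties resolve to the earliest frame."""
    selected: dict[tuple[int, str], int] = {}
    for key, frame_scores in scores.items():
        if not frame_scores:
            raise ValueError(f"no scores for contig/view {key}")
        best = max(frame_scores, key=lambda fs: (fs.score, -fs.frame_index))
        selected[key] = best.frame_index
    return selected


def pairwise_accuracy(scorer, pairs: list[tuple[np.ndarray, np.ndarray]]) -> float:
    """Fraction of (better, worse) frame pairs ranked correctly.

    A pair counts as correct only when score(better) is strictly greater
    than score(worse); ties count as failures.
    """
    if not pairs:
        raise ValueError("empty pair set")
    correct = 0
    for better, worse in pairs:
        if float(scorer(better)) > float(scorer(worse)):
            correct += 1
    return correct / len(pairs)


def write_selection_csv(
    selected: dict[tuple[int, str], int],
    scores: dict[tuple[int, str], list[FrameScore]],
    path,
) -> None:
    rows = []
    for (contig_id, view), frame_index in sorted(selected.items()):
        score = next(
            fs.score for fs in scores[(contig_id, view)] if fs.frame_index == frame_index
        )
        rows.append(
            {
                "contig_id": contig_id,
                "view": view,
                "frame_index": frame_index,
                "score": f"{score:.6f}",
            }
        )
    pd.DataFrame(
        rows, columns=["contig_id", "view", "frame_index", "score"]
    ).to_csv(path, index=False)
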