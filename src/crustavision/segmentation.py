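"""Temporal segmentation of a noisy per-frame presence signal into contigs.

The per-frame classifier emits a volatile confidence trace.  Two rectangular
(box) smoothing passes interleaved with hard thresholds turn that trace into
"contigs" — maximal intervals each attributed to a single presented animal.
Two box passes cheaply approximate triangular smoothing while letting the two
passes take different parameters.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ConfidenceSignal",
    "SmoothingChainConfig",
    "Contig",
    "ContigEvaluation",
    "rectangular_smooth",
    "step_threshold",
    "detect_contigs",
    "evaluate_contigs",
    "read_signal_csv",
    "write_signal_csv",
    "read_contigs_csv",
    "write_contigs_csv",
]


@dataclass
class ConfidenceSignal:
    """Per-frame presence confidence in [0, 1] over one video."""

    values: np.ndarray
    fps: float = 25.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise ValueError("signal must be one-dimensional")
        if self.values.size and (
            self.values.min() < 0.0 or self.values.max() > 1.0
        ):
            raise ValueError("confidence values must lie in [0, 1]")

    def __len__(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class SmoothingChainConfig:
    """Parameters of the smooth -> step -> smooth -> step chain."""

    window1: int = 20
    threshold1: float = 0.01
    window2: int = 10
    threshold2: float = 0.5

    def __post_init__(self) -> None:
        if self.window1 < 1 or self.window2 < 1:
            raise ValueError("window sizes must be >= 1")
        for tau in (self.threshold1, self.threshold2):
            if not 0.0 < tau <= 1.0:
                raise ValueError("thresholds must lie in (0, 1]")


@dataclass(frozen=True, order=True)
class Contig:
    """Half-open frame interval [start_frame, end_frame) for one animal."""

    start_frame: int
    end_frame: int

    def __post_init__(self) -> None:
        if self.start_frame < 0 or self.end_frame <= self.start_frame:
            raise ValueError(
                f"invalid contig [{self.start_frame}, {self.end_frame})"
            )

    def __len__(self) -> int:
        return self.end_frame - self.start_frame

    def overlaps(self, start: int, end: int) -> bool:
        return max(self.start_frame, start) < min(self.end_frame, end)


@dataclass
class ContigEvaluation:
    """Outcome of matching detected contigs against true event intervals."""

    success_rate: float
    n_missed: int
    n_merged: int
    n_spurious: int
    n_events: int = 0
    n_contigs: int = 0


def rectangular_smooth(signal: ConfidenceSignal, window: int) -> ConfidenceSignal:
    """Slide an m-wide box mean over the signal with zero padding.

    Output index ``n`` averages input indices ``n - m//2 .. n + ceil(m/2) - 1``
    (exactly m samples, so constant signals are preserved); indices outside
    the signal contribute zero.
    """
    m = int(window)
    if m < 1:
        raise ValueError("window size must be >= 1")
    x = signal.values
    if x.size == 0:
        return ConfidenceSignal(x.copy(), fps=signal.fps)
    full = np.convolve(x, np.ones(m), mode="full")
    offset = -(-m // 2) - 1  # window ends at n + ceil(m/2) - 1
    smoothed = full[offset : offset + x.size] / m
    # guard against convolution round-off drifting a hair outside [0, 1]
    return ConfidenceSignal(np.clip(smoothed, 0.0, 1.0), fps=signal.fps)


def step_threshold(signal: ConfidenceSignal, tau: float) -> ConfidenceSignal:
    """Binarise: values >= tau map to 1.0, the rest to 0.0."""
    if not 0.0 < tau <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    binary = (signal.values >= tau).astype(float)
    return ConfidenceSignal(binary, fps=signal.fps)


def _runs_of_ones(binary: np.ndarray) -> list[tuple[int, int]]:
    padded = np.concatenate(([0.0], binary, [0.0]))
    diff = np.diff(padded)
    starts = np.flatnonzero(diff == 1)
    ends = np.flatnonzero(diff == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def detect_contigs(
    raw: ConfidenceSignal,
    config: SmoothingChainConfig = SmoothingChainConfig(),
) -> list[Contig]:
    """Run the four-stage smoothing chain and extract maximal runs of ones."""
    if len(raw) == 0:
        return []
    s = rectangular_smooth(raw, config.window1)
    s = step_threshold(s, config.threshold1)
    s = rectangular_smooth(s, config.window2)
    s = step_threshold(s, config.threshold2)
    return [Contig(a, b) for a, b in _runs_of_ones(s.values)]


def evaluate_contigs(contigs: list[Contig], truth) -> ContigEvaluation:
    """Score contigs against ground-truth event intervals.

    A contig "succeeds" when it overlaps exactly one event and that event is
    overlapped by no other contig.  Overlap means any shared frame.
    ``truth`` is an :class:`~crustavision.synthetic.EventSchedule` or any
    object with an ``events`` list of (start, end) pairs.
    """
    events = list(truth.events)
    overlap_matrix = np.zeros((len(contigs), len(events)), dtype=bool)
    for i, c in enumerate(contigs):
        for j, (es, ee) in enumerate(events):
            overlap_matrix[i, j] = c.overlaps(es, ee)

    events_per_contig = overlap_matrix.sum(axis=1)
    contigs_per_event = overlap_matrix.sum(axis=0)

    n_merged = int((events_per_contig >= 2).sum())
    n_spurious = int((events_per_contig == 0).sum())
    n_missed = int((contigs_per_event == 0).sum())

    successes = 0
    for i in range(len(contigs)):
        if events_per_contig[i] != 1:
            continue
        j = int(np.flatnonzero(overlap_matrix[i])[0])
        if contigs_per_event[j] == 1:
            successes += 1
    rate = successes / len(events) if events else 1.0
    return ContigEvaluation(
        success_rate=rate,
        n_missed=n_missed,
        n_merged=n_merged,
        n_spurious=n_spurious,
        n_events=len(events),
        n_contigs=len(contigs),
    )


# -- CSV interfaces --------------------------------------------------------


def write_signal_csv(signal: ConfidenceSignal, path) -> None:
    pd.DataFrame({"confidence": signal.values}).to_csv(path, index=False)


def read_signal_csv(path, fps: float = 25.0) -> ConfidenceSignal:
    df = pd.read_csv(path)
    col = "confidence" if "confidence" in df.columns else df.columns[0]
    return ConfidenceSignal(df[col].to_numpy(dtype=float), fps=fps)


def write_contigs_csv(contigs: list[Contig], path) -> None:
    pd.DataFrame(
        {
            "contig_id": range(len(contigs)),
            "start_frame": [c.start_frame for c in contigs],
            "end_frame": [c.end_frame for c in contigs],
        }
    ).to_csv(path, index=False)


def read_contigs_csv(path) -> list[Contig]:
    df = pd.read_csv(path)
    return [
        Contig(int(r.start_frame), int(r.end_frame))
        for r in df.itertuples(index=False)
    ]
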