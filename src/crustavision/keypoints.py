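"""Keypoint regression on fixed-size crops plus the pipeline's error metrics.

Seven named anatomical landmarks are always predicted as a flat 14-vector;
species-specific subsets are used downstream for size reporting (carapace
width for crabs; eye/carapace/tail chain for lobsters).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._nn import TinyMLP, block_pool

__all__ = [
    "KEYPOINT_NAMES",
    "KeypointSet",
    "KeypointModelSpec",
    "KeypointRegressor",
    "predict_keypoints",
    "mean_euclidean_error",
    "relative_error",
    "species_keypoints",
    "import_via_annotations",
    "export_keypoints_csv",
]

# canonical landmark order; defines the layout of the flat 14-vector
KEYPOINT_NAMES: tuple[str, ...] = (
    "crab_left",
    "crab_right",
    "left_eye",
    "right_eye",
    "carapace_end",
    "tail_end",
    "last_segment",
)

_SPECIES_SUBSETS: dict[str, tuple[str, ...]] = {
    # carapace width across the widest points
    "crab": ("crab_left", "crab_right"),
    # eye-to-carapace and tail-segment chain
    "lobster": ("left_eye", "right_eye", "carapace_end", "tail_end", "last_segment"),
}


class KeypointSet:
    """Ordered map of the 7 named landmarks to (x, y) crop coordinates."""

    def __init__(self, coordinates: dict[str, tuple[float, float]]) -> None:
        missing = set(KEYPOINT_NAMES) - set(coordinates)
        extra = set(coordinates) - set(KEYPOINT_NAMES)
        if missing or extra:
            raise ValueError(
                f"keypoint name mismatch: missing {sorted(missing)}, "
                f"unexpected {sorted(extra)}"
            )
        self.coordinates = {
            name: (float(coordinates[name][0]), float(coordinates[name][1]))
            for name in KEYPOINT_NAMES
        }

    def __getitem__(self, name: str) -> tuple[float, float]:
        return self.coordinates[name]

    def __iter__(self):
        return iter(KEYPOINT_NAMES)

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, KeypointSet) and self.coordinates == other.coordinates
        )

    def __repr__(self) -> str:
        return f"KeypointSet({self.coordinates!r})"

    def to_vector(self) -> np.ndarray:
        """Flatten to the canonical 14-vector (x1, y1, x2, y2, ...)."""
        return np.array(
            [c for name in KEYPOINT_NAMES for c in self.coordinates[name]]
        )

    @classmethod
    def from_vector(cls, vector: np.ndarray) -> "KeypointSet":
        vector = np.asarray(vector, dtype=float).ravel()
        if vector.size != 2 * len(KEYPOINT_NAMES):
            raise ValueError(
                f"expected {2 * len(KEYPOINT_NAMES)} values, got {vector.size}"
            )
        coords = {
            name: (vector[2 * i], vector[2 * i + 1])
            for i, name in enumerate(KEYPOINT_NAMES)
        }
        return cls(coords)

    def translate(self, dx: float, dy: float) -> "KeypointSet":
        return KeypointSet(
            {n: (x + dx, y + dy) for n, (x, y) in self.coordinates.items()}
        )


@dataclass(frozen=True)
class KeypointModelSpec:
    """Published training recipe for the landmark regressor."""

    input_size: tuple[int, int] = (560, 540)  # (width, height) crop
    n_keypoints: int = len(KEYPOINT_NAMES)
    epochs: int = 4000
    learning_rate: float = 1e-3
    loss: str = "rmse"
    optimizer: str = "adam"

    @property
    def output_dim(self) -> int:
        return 2 * self.n_keypoints


class KeypointRegressor:
    """Landmark regressor on fixed-size single-channel crops.

    Features are block-pooled crop pixels feeding a small MLP with a linear
    14-unit head; coordinates are regressed in absolute crop pixels.  The
    input crop shape is part of the model contract — mismatched crops are
    rejected, never resized.
    """

    def __init__(
        self,
        input_size: tuple[int, int],
        pool: int = 8,
        hidden: int = 64,
        seed: int = 0,
        zero_init_head: bool = False,
    ) -> None:
        w, h = input_size
        if w % pool or h % pool:
            raise ValueError(
                f"input size {input_size} must be divisible by pool={pool}"
            )
        self.input_size = (int(w), int(h))
        self.pool = int(pool)
        n_features = (w // pool) * (h // pool)
        self.net = TinyMLP(
            (n_features, hidden, 2 * len(KEYPOINT_NAMES)),
            out_activation=None,
            seed=seed,
            zero_init_head=zero_init_head,
        )

    @property
    def output_dim(self) -> int:
        return self.net.sizes[-1]

    def _features(self, crops: np.ndarray) -> np.ndarray:
        feats = [
            block_pool(c.astype(float) / 255.0, self.pool, self.pool).ravel()
            for c in crops
        ]
        return np.stack(feats)

    def _check_shape(self, crop: np.ndarray) -> None:
        w, h = self.input_size
        if crop.ndim != 2 or crop.shape != (h, w):
            raise ValueError(
                f"crop shape {crop.shape} does not match model input "
                f"{(h, w)}; crops are never resized"
            )

    def predict_vector(self, crop: np.ndarray) -> np.ndarray:
        self._check_shape(crop)
        return self.net(self._features(crop[None]))[0]

    def fit(
        self,
        crops: list[np.ndarray],
        targets: list["KeypointSet"],
        epochs: int = 300,
        learning_rate: float = 1e-3,
        seed: int = 0,
    ) -> list[float]:
        for c in crops:
            self._check_shape(c)
        x = self._features(np.stack(crops))
        y = np.stack([t.to_vector() for t in targets])
        return self.net.fit(
            x, y, epochs=epochs, learning_rate=learning_rate, seed=seed
        )

    def save(self, path) -> None:
        self.net.save(path)

    @classmethod
    def load(cls, path, input_size: tuple[int, int], pool: int = 8):
        model = cls(input_size, pool=pool)
        model.net = TinyMLP.load(path)
        return model


def predict_keypoints(crop: np.ndarray, model: KeypointRegressor) -> KeypointSet:
    """Run the regressor on one crop and decode the named landmark map."""
    vector = model.predict_vector(crop)
    if not np.all(np.isfinite(vector)):
        raise ValueError("model emitted non-finite keypoint coordinates")
    return KeypointSet.from_vector(vector)


def mean_euclidean_error(
    predicted: list[KeypointSet], truth: list[KeypointSet]
) -> float:
    """Mean over samples and landmarks of the Euclidean prediction error (px)."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth lists must have equal length")
    if not predicted:
        raise ValueError("empty evaluation set")
    total = 0.0
    count = 0
    for p, t in zip(predicted, truth):
        for name in KEYPOINT_NAMES:
            px, py = p[name]
            tx, ty = t[name]
            total += float(np.hypot(px - tx, py - ty))
            count += 1
    return total / count


def relative_error(mee: float, mean_animal_size: float) -> float:
    """Landmark error as a percentage of mean animal size.

    ``mean_animal_size`` is the mean ground-truth bounding-box diagonal over
    the evaluation set, in pixels.
    """
    if mean_animal_size <= 0:
        raise ValueError("mean animal size must be positive")
    return 100.0 * mee / mean_animal_size


def species_keypoints(class_label: str) -> list[str]:
    """Landmark subset used for measuring a given species.

    All 7 landmarks are always predicted; this selects the subset that feeds
    size reporting.
    """
    try:
        return list(_SPECIES_SUBSETS[class_label])
    except KeyError:
        raise ValueError(
            f"unknown class {class_label!r}; expected one of "
            f"{sorted(_SPECIES_SUBSETS)}"
        ) from None


# -- annotation I/O --------------------------------------------------------


def import_via_annotations(path) -> dict[str, KeypointSet]:
    """Read a VIA point-annotation JSON export.

    Returns a map of image filename to :class:`KeypointSet`.  Points must be
    named via a region attribute called ``name`` (falling back to the first
    region attribute value).
    """
    raw = json.loads(Path(path).read_text())
    metadata = raw.get("_via_img_metadata", raw)
    out: dict[str, KeypointSet] = {}
    for entry in metadata.values():
        coords: dict[str, tuple[float, float]] = {}
        for region in entry.get("regions", []):
            shape = region["shape_attributes"]
            if shape.get("name") != "point":
                continue
            attrs = region.get("region_attributes", {})
            name = attrs.get("name") or next(iter(attrs.values()), None)
            if name is None:
                continue
            coords[name] = (float(shape["cx"]), float(shape["cy"]))
        if coords:
            out[entry["filename"]] = KeypointSet(coords)
    return out


def export_keypoints_csv(records: list[dict], path) -> None:
    """Write (contig_id, class, x/y per named point) rows."""
    columns = ["contig_id", "class"]
    for name in KEYPOINT_NAMES:
        columns += [f"{name}_x", f"{name}_y"]
    rows = []
    for rec in records:
        row = {"contig_id": rec["contig_id"], "class": rec["class"]}
        kps: KeypointSet | None = rec.get("keypoints")
        for name in KEYPOINT_NAMES:
            if kps is None:
                row[f"{name}_x"] = row[f"{name}_y"] = ""
            else:
                x, y = kps[name]
                row[f"{name}_x"] = f"{x:.3f}"
                row[f"{name}_y"] = f"{y:.3f}"
        rows.append(row)
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
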