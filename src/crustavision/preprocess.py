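"""Greyscale conversion, aspect-preserving downscaling, and the stochastic
training-time augmentation chain.

Augmentation is strictly a training-time device; nothing on the measurement
path (detector input, crops, keypoints) passes through this module except
:func:`to_greyscale` and, for the cheap models only, :func:`downscale`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["AugmentationConfig", "to_greyscale", "downscale", "augment"]

# ITU-R BT.601 luminance weights
_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class AugmentationConfig:
    """Probabilities of the four sequential augmentations.

    Intensity shift is multiplicative, uniform in [1 - intensity_range,
    1 + intensity_range], clipped to the valid pixel range.
    """

    p_hflip: float = 0.5
    p_vflip: float = 0.5
    p_blur: float = 0.3
    p_intensity: float = 0.3
    intensity_range: float = 0.2
    blur_sigma: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.p_hflip, self.p_vflip, self.p_blur, self.p_intensity):
            if not 0.0 <= p <= 1.0:
                raise ValueError("augmentation probabilities must lie in [0, 1]")
        if not 0.0 <= self.intensity_range < 1.0:
            raise ValueError("intensity_range must lie in [0, 1)")

    def all_fire_probability(self) -> float:
        """Chance that one image receives every augmentation in the chain."""
        return self.p_hflip * self.p_vflip * self.p_blur * self.p_intensity


def to_greyscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB frame to one luminance channel (same width/height).

    Cuts the stored byte count by exactly a factor of 3.  Single-channel
    input passes through unchanged with a warning.
    """
    image = np.asarray(image)
    if image.ndim == 2:
        warnings.warn("input is already single-channel; passing through")
        return image
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 image, got shape {image.shape}")
    grey = image.astype(float) @ _LUMA
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(grey), 0, np.iinfo(image.dtype).max).astype(
            image.dtype
        )
    return grey


def downscale(image: np.ndarray, target: tuple[int, int]) -> np.ndarray:
    """Area-interpolate down to ``target`` = (width, height).

    The target must preserve the source aspect ratio exactly — measurement
    images are never resized, and the cheap models must not see warped
    proportions either.
    """
    image = np.asarray(image)
    h, w = image.shape[:2]
    tw, th = target
    if tw <= 0 or th <= 0:
        raise ValueError("target dimensions must be positive")
    if tw > w or th > h:
        raise ValueError(f"target {target} exceeds source {(w, h)}; upscaling refused")
    if tw * h != th * w:
        raise ValueError(
            f"aspect mismatch: source {w}x{h} ({w / h:.6g}) vs "
            f"target {tw}x{th} ({tw / th:.6g})"
        )
    if (tw, th) == (w, h):
        return image.copy()
    if w % tw == 0 and h % th == 0:
        # exact integer factor: block mean, no interpolation artefacts
        fy, fx = h // th, w // tw
        if image.ndim == 2:
            blocks = image.reshape(th, fy, tw, fx).astype(float)
            out = blocks.mean(axis=(1, 3))
        else:
            blocks = image.reshape(th, fy, tw, fx, -1).astype(float)
            out = blocks.mean(axis=(1, 3))
    else:
        from skimage.transform import resize

        shape = (th, tw) if image.ndim == 2 else (th, tw, image.shape[2])
        out = resize(
            image.astype(float), shape, anti_aliasing=True, preserve_range=True
        )
    if np.issubdtype(image.dtype, np.integer):
        return np.clip(np.rint(out), 0, np.iinfo(image.dtype).max).astype(
            image.dtype
        )
    return out


def augment(
    image: np.ndarray,
    config: AugmentationConfig = AugmentationConfig(),
    rng: np.random.Generator | int | None = None,
) -> tuple[np.ndarray, list[str]]:
    """Apply the sequential augmentation chain for training images.

    Ops are drawn independently in the fixed order hflip, vflip, blur,
    intensity; ``applied_ops`` records exactly which fired.  Never apply to
    test or measurement images.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    image = np.asarray(image)
    out = image.copy()
    applied: list[str] = []

    if rng.random() < config.p_hflip:
        out = out[:, ::-1].copy()
        applied.append("hflip")
    if rng.random() < config.p_vflip:
        out = out[::-1, :].copy()
        applied.append("vflip")
    if rng.random() < config.p_blur:
        sigma = (config.blur_sigma, config.blur_sigma) + (0,) * (out.ndim - 2)
        out = ndimage.gaussian_filter(out.astype(float), sigma=sigma)
        applied.append("blur")
    if rng.random() < config.p_intensity:
        lo, hi = 1.0 - config.intensity_range, 1.0 + config.intensity_range
        factor = rng.uniform(lo, hi)
        out = out.astype(float) * factor
        applied.append("intensity")

    if applied and np.issubdtype(image.dtype, np.integer):
        out = np.clip(np.rint(out), 0, np.iinfo(image.dtype).max).astype(
            image.dtype
        )
    return out, applied
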