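"""Collagen highlighting, training-time augmentation and normalization.

The fixed pipeline order is highlight -> augment (training only) ->
normalize; validation and inference run the identical pipeline minus
augmentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.color import hsv2rgb, rgb2hsv

_LUMA = np.array([0.299, 0.587, 0.114])


@dataclass(frozen=True)
class HsvThresholds:
    """Red band in HSV isolating Sirius-Red collagen.

    The hue band may wrap through 0 (red straddles the hue origin).
    Defaults are tuned to the synthetic stain color model; exposed in
    config because the underlying heuristic is protocol-dependent.
    """

    hue_lo: float = 0.92
    hue_hi: float = 0.06
    sat_min: float = 0.3
    val_min: float = 0.15

    def in_band(self, hsv: np.ndarray) -> np.ndarray:
        h, s, v = hsv[..., 0], hsv[..., 1], hsv[..., 2]
        if self.hue_lo <= self.hue_hi:
            hue_ok = (h >= self.hue_lo) & (h <= self.hue_hi)
        else:  # wrapping band
            hue_ok = (h >= self.hue_lo) | (h <= self.hue_hi)
        return hue_ok & (s >= self.sat_min) & (v >= self.val_min)


@dataclass(frozen=True)
class AugmentConfig:
    """Random affine + color augmentations (one draw per call).

    Rotations are restricted to multiples of 90 degrees so that flips and
    rotations permute pixels without resampling.
    """

    rotate: bool = True
    hflip: bool = True
    vflip: bool = True
    brightness_range: tuple[float, float] = (-0.1, 0.1)  # additive, [0,1] scale
    contrast_range: tuple[float, float] = (0.85, 1.15)   # multiplicative
    gamma_range: tuple[float, float] = (0.8, 1.25)
    hue_shift: float = 0.02
    sat_shift: float = 0.1
    val_shift: float = 0.1
    color: bool = True


def collagen_highlight(
    patch_rgb: np.ndarray, thresholds: HsvThresholds | None = None,
    attenuation: float = 0.5, emphasis: float = 1.0,
) -> np.ndarray:
    """Emphasize collagen-band pixels; attenuate everything else.

    Pixels inside the HSV collagen band are pushed toward full saturation
    and value at their own hue (``emphasis`` = 1 saturates them fully, 0
    leaves them untouched); pixels outside are blended toward their
    grayscale value by ``attenuation`` (0 = no change, 1 = full
    desaturation).  Tissue context is deliberately attenuated rather than
    masked out: Kleiner staging depends on where collagen sits, not only
    on how much there is.
    """
    thresholds = thresholds or HsvThresholds()
    hsv = rgb2hsv(patch_rgb)
    band = thresholds.in_band(hsv)
    rgb = patch_rgb.astype(np.float64)
    out = rgb.copy()
    if emphasis > 0:
        boosted = hsv[band]
        boosted[:, 1] = (1 - emphasis) * boosted[:, 1] + emphasis
        boosted[:, 2] = (1 - emphasis) * boosted[:, 2] + emphasis
        out[band] = hsv2rgb(boosted[None, :, :])[0] * 255.0
    gray = rgb @ _LUMA
    out[~band] = (1.0 - attenuation) * rgb[~band] + attenuation * gray[~band][:, None]
    return np.clip(out + 0.5, 0, 255).astype(np.uint8)


def augment(
    patch_rgb: np.ndarray, config: AugmentConfig | None = None,
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """One random augmentation draw; deterministic under a fixed seed."""
    config = config or AugmentConfig()
    rng = (
        seed if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    out = patch_rgb
    if config.rotate:
        out = np.rot90(out, k=int(rng.integers(4)))
    if config.hflip and rng.random() < 0.5:
        out = out[:, ::-1]
    if config.vflip and rng.random() < 0.5:
        out = out[::-1, :]
    if config.color:
        x = out.astype(np.float64) / 255.0
        x = x * rng.uniform(*config.contrast_range)
        x = x + rng.uniform(*config.brightness_range)
        x = np.clip(x, 0.0, 1.0) ** rng.uniform(*config.gamma_range)
        # cheap HSV-ish jitter: per-channel value/sat shifts via scaling
        dh = rng.uniform(-config.hue_shift, config.hue_shift)
        dv = rng.uniform(-config.val_shift, config.val_shift)
        ds = rng.uniform(-config.sat_shift, config.sat_shift)
        mean = x.mean(axis=-1, keepdims=True)
        x = mean + (x - mean) * (1.0 + ds)          # saturation about the mean
        x = np.clip(x + dv, 0.0, 1.0)
        rot = np.array([dh, 0.0, -dh])              # mild channel tilt ~ hue
        x = np.clip(x + rot, 0.0, 1.0)
        out = (x * 255.0 + 0.5).astype(np.uint8)
    return np.ascontiguousarray(out)


def normalize(patch_rgb_uint8: np.ndarray) -> np.ndarray:
    """Scale 8-bit RGB to floats in [0, 1] (shape preserved)."""
    return patch_rgb_uint8.astype(np.float32) / np.float32(255.0)


def preprocess_for_model(
    patch_rgb: np.ndarray,
    thresholds: HsvThresholds | None = None,
    augment_config: AugmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Full pipeline: highlight -> (augment if configured) -> normalize."""
    out = collagen_highlight(patch_rgb, thresholds)
    if augment_config is not None:
        out = augment(out, augment_config, rng if rng is not None else 0)
    return normalize(out)
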