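"""Training-time augmentation: random resize/crop plus an AugMix-style
mixture of photometric effect chains.

Each call applies ONE shared geometric transform (random resize in
[0.875, 1.2] followed by a random 224x224 crop) so keypoints remain
well-defined, then mixes three photometric chains with Dirichlet(alpha=1)
weights.  Each chain applies three effects drawn from a seven-entry
catalog: histogram equalization (fires with probability 0.5 inside the
chain), posterize (2-4 bits), solarize (threshold 156-256), contrast
up/down, brightness up/down.  Effect strength in [0.2, 0.8] linearly
interpolates each sampled parameter toward its identity value.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from skimage import transform as sktransform

__all__ = [
    "AugmentSpec",
    "TransformRecord",
    "EFFECT_CATALOG",
    "apply_effect",
    "random_resize_crop",
    "augmix_compose",
]


# ---------------------------------------------------------------------------
# photometric effects (grayscale; "each color channel" degenerates to one)


def _equalize(img: np.ndarray, blend: float) -> np.ndarray:
    """Histogram equalization of the 8-bit histogram, blended by ``blend``."""
    v = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    hist = np.bincount(v.ravel(), minlength=256).astype(float)
    cdf = np.cumsum(hist)
    nonzero = cdf > 0
    if not nonzero.any():
        return img.astype(float)
    cdf_min = cdf[nonzero][0]
    denom = cdf[-1] - cdf_min
    if denom <= 0:
        eq = img.astype(float)
    else:
        lut = np.clip(np.rint((cdf - cdf_min) / denom * 255.0), 0, 255)
        eq = lut[v]
    return (1.0 - blend) * img + blend * eq


def _posterize(img: np.ndarray, bits: float) -> np.ndarray:
    b = int(round(bits))
    if not (1 <= b <= 8):
        raise ValueError(f"posterize bits must be in 1..8, got {bits}")
    mask = 256 - (1 << (8 - b))
    v = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    return (v & mask).astype(float)


def _solarize(img: np.ndarray, threshold: float) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    return np.where(img >= threshold, 255.0 - img, img)


def _contrast(img: np.ndarray, mult: float) -> np.ndarray:
    img = np.asarray(img, dtype=float)
    mean = img.mean()
    return mean + mult * (img - mean)


def _brightness(img: np.ndarray, mult: float) -> np.ndarray:
    return np.asarray(img, dtype=float) * mult


@dataclass(frozen=True)
class EffectEntry:
    name: str
    fn: callable
    param_range: tuple[float, float]  # sampling range of the raw parameter
    neutral: float  # identity parameter value
    integer: bool = False


EFFECT_CATALOG: dict[str, EffectEntry] = {
    e.name: e
    for e in (
        EffectEntry("equalize", _equalize, (1.0, 1.0), 0.0),
        EffectEntry("posterize", _posterize, (2, 4), 8.0, integer=True),
        EffectEntry("solarize", _solarize, (156.0, 256.0), 256.0),
        EffectEntry("contrast_up", _contrast, (1.0, 4.0), 1.0),
        EffectEntry("contrast_down", _contrast, (0.2, 1.0), 1.0),
        EffectEntry("brightness_up", _brightness, (1.0, 3.0), 1.0),
        EffectEntry("brightness_down", _brightness, (0.4, 1.0), 1.0),
    )
}


def apply_effect(image: np.ndarray, effect: str, magnitude: float) -> np.ndarray:
    """Apply one catalog effect at the given (already strength-scaled)
    magnitude; output is clipped to [0, 255] and keeps the input shape.
    """
    try:
        entry = EFFECT_CATALOG[effect]
    except KeyError:
        raise ValueError(f"unknown effect {effect!r}; known: {sorted(EFFECT_CATALOG)}") from None
    lo = min(entry.param_range[0], entry.neutral)
    hi = max(entry.param_range[1], entry.neutral)
    if not (lo - 1e-9 <= magnitude <= hi + 1e-9):
        raise ValueError(f"magnitude {magnitude} outside [{lo}, {hi}] for {effect!r}")
    out = entry.fn(np.asarray(image, dtype=float), magnitude)
    return np.clip(out, 0.0, 255.0)


# ---------------------------------------------------------------------------
# geometry


@dataclass(frozen=True)
class TransformRecord:
    """Invertible record of the shared resize+crop transform."""

    scale_x: float
    scale_y: float
    offset_x: int
    offset_y: int

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return pts * [self.scale_x, self.scale_y] - [self.offset_x, self.offset_y]

    def invert(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (pts + [self.offset_x, self.offset_y]) / [self.scale_x, self.scale_y]


@dataclass(frozen=True)
class AugmentSpec:
    resize_range: tuple[float, float] = (0.875, 1.2)
    crop_size: int = 224
    n_effects: int = 3
    n_chains: int = 3
    strength_range: tuple[float, float] = (0.2, 0.8)
    dirichlet_alpha: float = 1.0
    equalize_probability: float = 0.5

    def __post_init__(self) -> None:
        if self.resize_range[0] > self.resize_range[1]:
            raise ValueError("invalid resize_range")
        if self.n_effects < 1 or self.n_chains < 1:
            raise ValueError("n_effects and n_chains must be >= 1")


def random_resize_crop(
    image: np.ndarray,
    keypoints: np.ndarray | Sequence[tuple[float, float]],
    rng: np.random.Generator,
    spec: AugmentSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, TransformRecord]:
    """Random uniform rescale then random crop to ``crop_size``.

    If the rescaled image falls short of the crop size (possible for
    non-256 inputs), it is zero-padded at the bottom/right before
    cropping, which leaves keypoint coordinates untouched.
    """
    spec = spec or AugmentSpec()
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    scale = rng.uniform(*spec.resize_range)
    nh, nw = max(round(h * scale), 1), max(round(w * scale), 1)
    if (nh, nw) == (h, w):
        resized = img
    else:
        resized = np.asarray(
            sktransform.resize(img, (nh, nw), order=1, preserve_range=True, anti_aliasing=False)
        )
    if nh < spec.crop_size or nw < spec.crop_size:
        padded = np.zeros((max(nh, spec.crop_size), max(nw, spec.crop_size)))
        padded[:nh, :nw] = resized
        resized = padded
        nh, nw = resized.shape
    oy = int(rng.integers(0, nh - spec.crop_size + 1))
    ox = int(rng.integers(0, nw - spec.crop_size + 1))
    crop = resized[oy : oy + spec.crop_size, ox : ox + spec.crop_size]
    record = TransformRecord(scale_x=nw / w, scale_y=nh / h, offset_x=ox, offset_y=oy)
    kps = record.apply(np.asarray(keypoints, dtype=float).reshape(-1, 2))
    return crop, kps, record


# ---------------------------------------------------------------------------
# AugMix-style composition


def _sample_chain(spec: AugmentSpec, rng: np.random.Generator) -> list[tuple[str, float]]:
    names = rng.choice(list(EFFECT_CATALOG), size=spec.n_effects, replace=False)
    chain = []
    for name in names:
        entry = EFFECT_CATALOG[name]
        strength = rng.uniform(*spec.strength_range)
        if name == "equalize":
            if rng.uniform() >= spec.equalize_probability:
                continue  # equalize fires with p=0.5 inside the chain
            magnitude = strength  # blend fraction
        else:
            lo, hi = entry.param_range
            raw = float(rng.integers(int(lo), int(hi) + 1)) if entry.integer else rng.uniform(lo, hi)
            magnitude = entry.neutral + strength * (raw - entry.neutral)
            if entry.integer:
                magnitude = float(round(magnitude))
        chain.append((name, magnitude))
    return chain


def augmix_compose(
    image: np.ndarray,
    keypoints: np.ndarray | Sequence[tuple[float, float]],
    spec: AugmentSpec | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """One augmented sample: shared geometry, Dirichlet-mixed effect chains.

    output = sum_i w_i * chain_i(resize_crop(image)),  w ~ Dirichlet(alpha).
    Photometric effects never move keypoints, so the returned keypoints
    depend only on the shared geometric transform.
    """
    spec = spec or AugmentSpec()
    rng = rng if rng is not None else np.random.default_rng()
    base, kps, _record = random_resize_crop(image, keypoints, rng, spec)
    weights = rng.dirichlet([spec.dirichlet_alpha] * spec.n_chains)
    assert weights.min() >= 0 and abs(weights.sum() - 1.0) < 1e-9
    mixed = np.zeros_like(base)
    for wgt in weights:
        out = base
        for name, magnitude in _sample_chain(spec, rng):
            out = apply_effect(out, name, magnitude)
        mixed += wgt * out
    return np.clip(mixed, 0.0, 255.0), kps
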