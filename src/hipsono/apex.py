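"""Apex-point estimation from heatmap regression.

The apex (the point where the line from the inferior end of the ilium
meets the ilium) anchors all downstream geometry.  Estimators turn a
256x256 frame into a per-pixel heatmap in (0, 1); the estimated apex
(eAP) is the heatmap argmax with quarter-pixel refinement toward the
larger of each pair of opposing neighbors.

The reference backbone (``patchnet``) is a small two-layer perceptron
applied convolutionally to every local patch, trained with mean pixelwise
binary cross-entropy against Gaussian heatmap targets.  It is written in
plain numpy, trains on a CPU in minutes, and is translation-equivariant
by construction.  Heavier published backbones plug in through the same
``predict_heatmap`` contract via :func:`register_backbone`.
"""

from __future__ import annotations

import math
import pickle
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Protocol, Sequence

import numpy as np

from .errors import NoApexSignal

__all__ = [
    "HeatmapTarget",
    "ApexEstimate",
    "TrainConfig",
    "make_heatmap_target",
    "train_apex_estimator",
    "estimate_apex",
    "localization_error",
    "PatchNetEstimator",
    "OracleApexEstimator",
    "register_backbone",
]

EXPECTED_SHAPE = (256, 256)


@dataclass(frozen=True)
class ApexEstimate:
    """Estimated apex point with its peak-heatmap confidence."""

    x: float
    y: float
    confidence: float

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


HeatmapTarget = np.ndarray  # H x W float array in [0, 1], peak 1.0


def make_heatmap_target(
    apex: tuple[float, float], shape: tuple[int, int], sigma_px: float = 2.0
) -> HeatmapTarget:
    """Unnormalized Gaussian bump centred on the pixel nearest the apex.

    The maximum value is exactly 1.0 at that pixel; for sigma much smaller
    than the image, the grid sum approaches 2*pi*sigma^2.
    """
    if sigma_px <= 0:
        raise ValueError("sigma_px must be positive")
    h, w = shape
    ax, ay = apex
    if not (0 <= ax < w and 0 <= ay < h):
        raise ValueError(f"apex {apex} outside shape {shape}")
    cx, cy = round(ax), round(ay)
    ys = np.arange(h, dtype=float)[:, None]
    xs = np.arange(w, dtype=float)[None, :]
    d2 = (xs - cx) ** 2 + (ys - cy) ** 2
    return np.exp(-d2 / (2.0 * sigma_px**2))


def localization_error(
    estimate: tuple[float, float] | ApexEstimate,
    ground_truth: tuple[float, float],
) -> float:
    """Euclidean pixel distance between estimated and true apex."""
    if isinstance(estimate, ApexEstimate):
        estimate = estimate.as_tuple()
    return float(math.hypot(estimate[0] - ground_truth[0], estimate[1] - ground_truth[1]))


# ---------------------------------------------------------------------------
# estimators


class ApexEstimator(Protocol):
    def predict_heatmap(self, image: np.ndarray) -> np.ndarray: ...


@dataclass
class OracleApexEstimator:
    """Ground-truth pass-through used to test downstream stages in isolation."""

    apex: tuple[float, float]

    def direct_estimate(self, image: np.ndarray) -> ApexEstimate:
        return ApexEstimate(x=float(self.apex[0]), y=float(self.apex[1]), confidence=1.0)

    def predict_heatmap(self, image: np.ndarray) -> np.ndarray:
        return make_heatmap_target(self.apex, np.asarray(image).shape)


def estimate_apex(estimator, image: np.ndarray) -> ApexEstimate:
    """Decode the estimator's heatmap into a continuous apex point.

    Decoding is argmax plus a quarter-pixel shift toward the strictly
    larger of the two opposing neighbors along each axis.  A flat or
    non-positive heatmap raises :class:`NoApexSignal`.
    """
    direct = getattr(estimator, "direct_estimate", None)
    if direct is not None:
        return direct(image)
    hm = np.asarray(estimator.predict_heatmap(image), dtype=float)
    peak = float(hm.max())
    if peak <= 0 or not np.isfinite(peak):
        raise NoApexSignal("heatmap has no positive response")
    if peak - float(hm.min()) < 1e-9:
        raise NoApexSignal("heatmap is flat; no apex signal")
    py, px = np.unravel_index(int(np.argmax(hm)), hm.shape)
    h, w = hm.shape

    def _refine(idx: int, minus: float, plus: float) -> float:
        if plus > minus:
            return idx + 0.25
        if minus > plus:
            return idx - 0.25
        return float(idx)

    left = hm[py, px - 1] if px > 0 else -np.inf
    right = hm[py, px + 1] if px < w - 1 else -np.inf
    up = hm[py - 1, px] if py > 0 else -np.inf
    down = hm[py + 1, px] if py < h - 1 else -np.inf
    return ApexEstimate(x=_refine(px, left, right), y=_refine(py, up, down), confidence=peak)


# ---------------------------------------------------------------------------
# reference trainable backbone


@dataclass(frozen=True)
class TrainConfig:
    backbone: str = "patchnet"
    sigma_px: float = 2.0
    epochs: int = 30
    lr: float = 3e-3
    seed: int = 0
    patch_size: int = 15
    hidden: int = 16
    n_neg_random: int = 3000
    n_neg_hard: int = 1500

    def __post_init__(self) -> None:
        if self.patch_size % 2 == 0 or self.patch_size < 3:
            raise ValueError("patch_size must be odd and >= 3")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


class PatchNetEstimator:
    """Two-layer patch perceptron applied at every pixel (tiny FCN).

    logits(p) = w2 . relu(W1 . patch(p) + b1) + b2, heatmap = sigmoid.
    """

    def __init__(self, config: TrainConfig, rng: np.random.Generator):
        p2 = config.patch_size**2
        scale = 1.0 / math.sqrt(p2)
        self.config = config
        self.W1 = rng.normal(0.0, scale, size=(p2, config.hidden)).astype(np.float64)
        self.b1 = np.zeros(config.hidden)
        self.w2 = rng.normal(0.0, 1.0 / math.sqrt(config.hidden), size=config.hidden)
        self.b2 = np.float64(-2.0)  # start biased toward background
        self._adam: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        self._adam_t = 0

    # -- patch plumbing ----------------------------------------------------
    def _padded(self, image: np.ndarray) -> np.ndarray:
        pad = self.config.patch_size // 2
        return np.pad(np.asarray(image, dtype=np.float64) / 255.0, pad, mode="reflect")

    def _patches_at(self, padded: np.ndarray, ys: np.ndarray, xs: np.ndarray) -> np.ndarray:
        view = np.lib.stride_tricks.sliding_window_view(
            padded, (self.config.patch_size, self.config.patch_size)
        )
        return view[ys, xs].reshape(len(ys), -1)

    # -- forward -----------------------------------------------------------
    def _forward(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        hidden = np.maximum(X @ self.W1 + self.b1, 0.0)
        logits = hidden @ self.w2 + self.b2
        return hidden, logits

    def predict_heatmap(self, image: np.ndarray) -> np.ndarray:
        img = np.asarray(image)
        h, w = img.shape
        padded = self._padded(img)
        view = np.lib.stride_tricks.sliding_window_view(
            padded, (self.config.patch_size, self.config.patch_size)
        )
        X = view.reshape(h * w, -1)
        _hidden, logits = self._forward(X)
        out = 1.0 / (1.0 + np.exp(-logits))
        return out.reshape(h, w)

    # -- training ----------------------------------------------------------
    def _adam_step(self, name: str, param: np.ndarray, grad: np.ndarray) -> np.ndarray:
        beta1, beta2, eps = 0.9, 0.999, 1e-8
        m, v = self._adam.get(name, (np.zeros_like(param), np.zeros_like(param)))
        m = beta1 * m + (1 - beta1) * grad
        v = beta2 * v + (1 - beta2) * grad**2
        self._adam[name] = (m, v)
        t = self._adam_t
        mh = m / (1 - beta1**t)
        vh = v / (1 - beta2**t)
        return param - self.config.lr * mh / (np.sqrt(vh) + eps)

    def _train_step(self, X: np.ndarray, target: np.ndarray) -> float:
        hidden, logits = self._forward(X)
        prob = 1.0 / (1.0 + np.exp(-logits))
        eps = 1e-12
        loss = float(
            -np.mean(target * np.log(prob + eps) + (1 - target) * np.log(1 - prob + eps))
        )
        g = (prob - target) / len(target)
        grad_w2 = hidden.T @ g
        grad_b2 = g.sum()
        gh = np.outer(g, self.w2)
        gh[hidden <= 0] = 0.0
        grad_W1 = X.T @ gh
        grad_b1 = gh.sum(axis=0)
        self._adam_t += 1
        self.W1 = self._adam_step("W1", self.W1, grad_W1)
        self.b1 = self._adam_step("b1", self.b1, grad_b1)
        self.w2 = self._adam_step("w2", self.w2, grad_w2)
        self.b2 = self._adam_step("b2", self.b2, np.asarray(grad_b2))
        return loss

    # -- persistence -------------------------------------------------------
    def save(self, path: str | Path) -> None:
        state = {
            "config": self.config,
            "W1": self.W1,
            "b1": self.b1,
            "w2": self.w2,
            "b2": self.b2,
        }
        with open(path, "wb") as fh:
            pickle.dump(state, fh)

    @classmethod
    def load(cls, path: str | Path) -> "PatchNetEstimator":
        with open(path, "rb") as fh:
            state = pickle.load(fh)
        est = cls(state["config"], np.random.default_rng(0))
        est.W1, est.b1 = state["W1"], state["b1"]
        est.w2, est.b2 = state["w2"], state["b2"]
        return est


def _sample_training_pixels(
    image: np.ndarray,
    target: np.ndarray,
    rng: np.random.Generator,
    config: TrainConfig,
) -> tuple[np.ndarray, np.ndarray]:
    h, w = image.shape
    flat_t = target.ravel()
    pos = np.nonzero(flat_t > 0.01)[0]
    flat_i = np.asarray(image, dtype=float).ravel()
    n_hard = min(config.n_neg_hard, flat_i.size)
    hard = np.argpartition(flat_i, -n_hard)[-n_hard:]
    rand = rng.integers(0, h * w, size=config.n_neg_random)
    idx = np.unique(np.concatenate([pos, hard, rand]))
    ys, xs = np.divmod(idx, w)
    return np.stack([ys, xs]), flat_t[idx]


def _train_patchnet(dataset, config: TrainConfig) -> PatchNetEstimator:
    rng = np.random.default_rng(config.seed)
    est = PatchNetEstimator(config, rng)
    images, targets = [], []
    for image, apex in dataset:
        img = np.asarray(image, dtype=np.float64)
        if img.shape != EXPECTED_SHAPE:
            raise ValueError(f"expected {EXPECTED_SHAPE} images, got {img.shape}")
        images.append(img)
        targets.append(make_heatmap_target(apex, img.shape, config.sigma_px))
    order = np.arange(len(images))
    for _epoch in range(config.epochs):
        rng.shuffle(order)
        for i in order:
            padded = est._padded(images[i])
            (ys, xs), t = _sample_training_pixels(images[i], targets[i], rng, config)
            X = est._patches_at(padded, ys, xs)
            est._train_step(X, t)
    return est


_BACKBONES: dict[str, Callable] = {"patchnet": _train_patchnet}


def register_backbone(name: str, trainer: Callable) -> None:
    """Register an alternative trainer with signature (dataset, config)."""
    _BACKBONES[name] = trainer


def train_apex_estimator(dataset: Sequence, config: TrainConfig | None = None):
    """Fit a heatmap estimator on (image, apex) pairs.

    Deterministic given ``config.seed``.  Raises on an empty dataset or on
    images that are not 256x256.
    """
    config = config or TrainConfig()
    dataset = list(dataset)
    if not dataset:
        raise ValueError("cannot train on an empty dataset")
    try:
        trainer = _BACKBONES[config.backbone]
    except KeyError:
        raise ValueError(
            f"unknown backbone {config.backbone!r}; registered: {sorted(_BACKBONES)}"
        ) from None
    return trainer(dataset, config)
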