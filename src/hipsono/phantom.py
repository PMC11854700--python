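"""Synthetic B-mode-like hip phantom generator.

Frames contain a bright near-vertical iliac cortex terminating at an apex
point and an oblique acetabular-roof segment forming a controlled alpha
angle, corrupted by the artifact classes that plague clinical frames:
multiplicative speckle, reverberation ghost echoes below bone, soft-tissue
distractor streaks, and blur.  Every frame ships with exact ground truth,
so each downstream stage can be validated against known geometry.

Coordinate convention: origin at the top-left, x rightward, y downward,
0-based, pixel centers at integer coordinates.  Orientation angles are
measured from the +x axis in array coordinates, in [0, 180), with 90 =
vertical.  Because y points down, a segment whose orientation is slightly
below 90 leans with its top end to the *left* on screen.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
from scipy import ndimage

__all__ = [
    "PhantomParams",
    "PhantomGroundTruth",
    "scene_geometry",
    "generate_phantom",
    "generate_cohort",
    "DDH_ALPHA_CUTOFF_DEG",
    "QUALITY_GATE_DEG",
]

#: Alpha-angle threshold below which a hip is labelled dysplastic.
DDH_ALPHA_CUTOFF_DEG = 60.0

#: Inclusive iliac-verticality band for a usable (qualified) frame.
QUALITY_GATE_DEG = (87.0, 93.0)

_RAYLEIGH_MEAN = math.sqrt(math.pi / 2.0)


@dataclass(frozen=True)
class PhantomParams:
    """Generating parameters of one synthetic frame.

    ``iliac_angle_deg`` is the orientation of the iliac cortex (90 =
    vertical); ``alpha_deg`` is the angle between the ilium line and the
    acetabular-roof line.  Identical params + seed yield bit-identical
    images.
    """

    image_size: tuple[int, int] = (256, 256)  # (height, width)
    apex: tuple[float, float] = (128.0, 140.0)  # (x, y)
    iliac_angle_deg: float = 90.0
    alpha_deg: float = 65.0
    ilium_intensity: float = 235.0
    roof_intensity: float = 215.0
    line_thickness_px: float = 2.5
    speckle_scale: float = 0.4
    reverb_count: int = 2
    reverb_spacing_px: float = 12.0
    reverb_decay: float = 0.4
    distractor_count: int = 2
    blur_sigma_px: float = 0.5
    roof_side: str = "right"
    roof_offset_px: tuple[float, float] = (5.0, 3.0)
    bone_texture_amp: float = 0.2
    bone_texture_period_px: float = 3.0
    ilium_length_px: float | None = None  # None -> reach up to y ~= 12
    roof_length_px: float = 60.0
    background_level: float = 8.0
    noise_floor_sd: float = 2.0
    rater_noise_sd_qualified: float = 1.0
    rater_noise_sd_disqualified: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image_size must be at least 32x32")
        if not (0.0 < self.alpha_deg < 90.0):
            raise ValueError(f"alpha_deg must lie in (0, 90), got {self.alpha_deg}")
        if not (60.0 < self.iliac_angle_deg < 120.0):
            raise ValueError(
                f"iliac_angle_deg must lie in (60, 120), got {self.iliac_angle_deg}"
            )
        for name in ("ilium_intensity", "roof_intensity", "background_level"):
            v = getattr(self, name)
            if not (0.0 <= v <= 255.0):
                raise ValueError(f"{name} must lie in [0, 255], got {v}")
        if self.roof_side not in ("left", "right"):
            raise ValueError(f"roof_side must be 'left' or 'right', got {self.roof_side!r}")
        if self.reverb_count < 0 or self.distractor_count < 0:
            raise ValueError("reverb_count and distractor_count must be >= 0")
        if self.reverb_count and not (0.0 < self.reverb_decay < 1.0):
            raise ValueError("reverb_decay must lie in (0, 1)")
        if self.speckle_scale < 0 or self.blur_sigma_px < 0:
            raise ValueError("speckle_scale and blur_sigma_px must be >= 0")
        ax, ay = self.apex
        if not (0 <= ax < w and 0 <= ay < h):
            raise ValueError(f"apex {self.apex} lies outside the {w}x{h} frame")


@dataclass(frozen=True)
class PhantomGroundTruth:
    """Exact generating truth for one frame."""

    apex: tuple[float, float]
    iliac_angle_deg: float
    alpha_deg: float
    ddh_label: bool
    qualified_label: bool
    simulated_rater_alphas: tuple[float, ...] | None = None


def _labels(alpha_deg: float, iliac_angle_deg: float) -> tuple[bool, bool]:
    lo, hi = QUALITY_GATE_DEG
    return alpha_deg < DDH_ALPHA_CUTOFF_DEG, lo <= iliac_angle_deg <= hi


def scene_geometry(params: PhantomParams) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Noise-free endpoints of the bone segments, as {name: (p0, p1)} arrays.

    The ilium runs from its superior end down to the apex; the roof starts
    a small infero-medial offset away from the apex and descends toward
    ``roof_side``.  Rotating ``iliac_angle_deg`` by delta (roof co-rotated,
    alpha fixed) rotates these endpoints about the apex by delta.
    """
    h, w = params.image_size
    ax, ay = params.apex
    theta_i = math.radians(params.iliac_angle_deg)
    u = np.array([math.cos(theta_i), math.sin(theta_i)])  # points "down" (y+)
    length = params.ilium_length_px
    if length is None:
        # reach close to the top of the frame regardless of apex depth
        length = max(ay - 12.0, 20.0) / max(math.sin(theta_i), 1e-9)
    apex = np.array([ax, ay], dtype=float)
    top = apex - length * u

    s = 1.0 if params.roof_side == "right" else -1.0
    theta_r = math.radians(params.iliac_angle_deg - s * params.alpha_deg)
    d = np.array([math.cos(theta_r), math.sin(theta_r)])
    if s < 0:
        d = -d  # descend toward the left
    # the infero-medial offset lives in the ilium's frame: co-rotates with it
    ox, oy = params.roof_offset_px
    tilt = theta_i - math.pi / 2.0
    rot = np.array([[math.cos(tilt), -math.sin(tilt)], [math.sin(tilt), math.cos(tilt)]])
    start = apex + rot @ np.array([s * ox, oy])
    end = start + params.roof_length_px * d

    for name, p in (("ilium top", top), ("roof start", start), ("roof end", end)):
        if not (-1.0 <= p[0] <= w and -1.0 <= p[1] <= h):
            raise ValueError(f"{name} {tuple(p)} falls outside the {w}x{h} frame")
    return {"ilium": (top, apex), "roof": (start, end)}


def _draw_segment(
    canvas: np.ndarray,
    p0: np.ndarray,
    p1: np.ndarray,
    intensity: float,
    thickness: float,
    texture_amp: float = 0.0,
    texture_period: float = 4.0,
) -> None:
    """Max-blend a Gaussian-profile segment onto the canvas (in place).

    ``texture_amp`` > 0 adds a deterministic sinusoidal intensity
    modulation along the segment, emulating the granular echo texture of
    real bone so the ridge carries discrete local maxima even without
    speckle.
    """
    h, w = canvas.shape
    sigma = max(thickness / 2.0, 0.5)
    margin = int(math.ceil(4 * sigma)) + 1
    x0 = max(int(math.floor(min(p0[0], p1[0]))) - margin, 0)
    x1 = min(int(math.ceil(max(p0[0], p1[0]))) + margin + 1, w)
    y0 = max(int(math.floor(min(p0[1], p1[1]))) - margin, 0)
    y1 = min(int(math.ceil(max(p0[1], p1[1]))) + margin + 1, h)
    if x0 >= x1 or y0 >= y1:
        return
    ys, xs = np.mgrid[y0:y1, x0:x1]
    pts = np.stack([xs, ys], axis=-1).astype(float)
    v = p1 - p0
    vv = float(v @ v)
    if vv == 0.0:
        d2 = np.sum((pts - p0) ** 2, axis=-1)
        along = np.zeros(d2.shape)
    else:
        t = np.clip(((pts - p0) @ v) / vv, 0.0, 1.0)
        proj = p0 + t[..., None] * v
        d2 = np.sum((pts - proj) ** 2, axis=-1)
        along = t * math.sqrt(vv)
    profile = intensity * np.exp(-d2 / (2.0 * sigma**2))
    if texture_amp > 0:
        mod = 1.0 - texture_amp * (0.5 + 0.5 * np.sin(2.0 * math.pi * along / texture_period))
        profile = profile * mod
    np.maximum(canvas[y0:y1, x0:x1], profile, out=canvas[y0:y1, x0:x1])


def _clean_scene(params: PhantomParams, rng: np.random.Generator) -> np.ndarray:
    h, w = params.image_size
    canvas = np.full((h, w), params.background_level, dtype=float)
    geom = scene_geometry(params)
    bone = [
        (geom["ilium"], params.ilium_intensity),
        (geom["roof"], params.roof_intensity),
    ]
    amp, period = params.bone_texture_amp, params.bone_texture_period_px
    for (p0, p1), inten in bone:
        _draw_segment(canvas, p0, p1, inten, params.line_thickness_px, amp, period)
    # reverberation: attenuated ghost copies displaced deeper (+y)
    for k in range(1, params.reverb_count + 1):
        shift = np.array([0.0, k * params.reverb_spacing_px])
        gain = params.reverb_decay**k
        for (p0, p1), inten in bone:
            _draw_segment(
                canvas, p0 + shift, p1 + shift, inten * gain, params.line_thickness_px, amp, period
            )
    # soft-tissue distractor streaks, kept away from the apex neighbourhood
    apex = np.array(params.apex)
    for _ in range(params.distractor_count):
        for _attempt in range(50):
            center = rng.uniform([10, 10], [w - 10, h - 10])
            if np.linalg.norm(center - apex) >= 45.0:
                break
        ang = rng.uniform(0.0, math.pi)
        half = rng.uniform(15.0, 45.0) * np.array([math.cos(ang), math.sin(ang)])
        inten = rng.uniform(40.0, 80.0)
        _draw_segment(canvas, center - half, center + half, inten, params.line_thickness_px)
    return canvas


def generate_phantom(params: PhantomParams) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Render one frame and its exact ground truth.

    Returns an (H, W) uint8 image.  The artifact chain is: clean scene ->
    multiplicative Rayleigh speckle -> additive Gaussian floor -> Gaussian
    blur -> clip to [0, 255].
    """
    rng = np.random.default_rng(params.seed)
    img = _clean_scene(params, rng)
    if params.speckle_scale > 0:
        ray = rng.rayleigh(scale=1.0, size=img.shape) / _RAYLEIGH_MEAN
        img = img * (1.0 + params.speckle_scale * (ray - 1.0))
    if params.noise_floor_sd > 0:
        img = img + rng.normal(0.0, params.noise_floor_sd, size=img.shape)
    if params.blur_sigma_px > 0:
        img = ndimage.gaussian_filter(img, params.blur_sigma_px)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)
    ddh, qualified = _labels(params.alpha_deg, params.iliac_angle_deg)
    truth = PhantomGroundTruth(
        apex=tuple(map(float, params.apex)),
        iliac_angle_deg=params.iliac_angle_deg,
        alpha_deg=params.alpha_deg,
        ddh_label=ddh,
        qualified_label=qualified,
    )
    return img, truth


# ---------------------------------------------------------------------------
# cohorts


def _sample_params(
    base: PhantomParams,
    ranges: dict[str, tuple[float, float]],
    rng: np.random.Generator,
    seed: int,
) -> PhantomParams:
    updates: dict[str, object] = {"seed": seed}
    for name, bounds in ranges.items():
        if name == "apex":
            (xlo, xhi), (ylo, yhi) = bounds  # type: ignore[misc]
            updates["apex"] = (rng.uniform(xlo, xhi), rng.uniform(ylo, yhi))
            continue
        if not hasattr(base, name):
            raise ValueError(f"unknown PhantomParams field in ranges: {name!r}")
        lo, hi = bounds
        updates[name] = rng.uniform(lo, hi)
    return replace(base, **updates)


def generate_cohort(
    n: int,
    ranges: dict[str, tuple[float, float]] | None = None,
    seed: int = 0,
    base: PhantomParams | None = None,
    simulate_raters: bool = False,
    out_dir: str | Path | None = None,
) -> list[tuple[np.ndarray, PhantomGroundTruth, PhantomParams]]:
    """Draw ``n`` frames with per-field parameters sampled from ``ranges``.

    ``ranges`` maps PhantomParams field names to (lo, hi) uniform bounds
    ("apex" takes ((xlo, xhi), (ylo, yhi))).  With ``simulate_raters``,
    four simulated alpha readings (2 raters x 2 repeats) are drawn per
    frame, with sd ``rater_noise_sd_qualified`` for qualified frames and
    the (larger) disqualified sd otherwise.  If ``out_dir`` is given, PNGs
    plus a ``manifest.csv`` are written there.
    """
    if n < 1:
        raise ValueError(f"cohort size must be >= 1, got {n}")
    base = base if base is not None else PhantomParams()
    ranges = dict(ranges or {})
    master = np.random.default_rng(seed)
    frame_seeds = master.integers(0, 2**31 - 1, size=n)
    records = []
    for i in range(n):
        params = _sample_params(base, ranges, master, int(frame_seeds[i]))
        img, truth = generate_phantom(params)
        if simulate_raters:
            sd = (
                params.rater_noise_sd_qualified
                if truth.qualified_label
                else params.rater_noise_sd_disqualified
            )
            rater_rng = np.random.default_rng(params.seed + 1)
            alphas = tuple(float(a) for a in truth.alpha_deg + rater_rng.normal(0.0, sd, 4))
            truth = replace(truth, simulated_rater_alphas=alphas)
        records.append((img, truth, params))
    if out_dir is not None:
        _write_cohort(Path(out_dir), records)
    return records


def _write_cohort(
    out_dir: Path,
    records: Sequence[tuple[np.ndarray, PhantomGroundTruth, PhantomParams]],
) -> Path:
    from . import dataio

    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for i, (img, truth, params) in enumerate(records):
        path = out_dir / f"phantom_{i:05d}.png"
        dataio.save_image(path, img)
        row = {
            "path": path.name,
            "apex_x": truth.apex[0],
            "apex_y": truth.apex[1],
            "iliac_angle_deg": truth.iliac_angle_deg,
            "alpha_deg": truth.alpha_deg,
            "ddh_label": truth.ddh_label,
            "qualified_label": truth.qualified_label,
            "seed": params.seed,
        }
        if truth.simulated_rater_alphas is not None:
            for j, a in enumerate(truth.simulated_rater_alphas):
                row[f"rater_alpha_{j}"] = a
        rows.append(row)
    manifest = out_dir / "manifest.csv"
    dataio.write_manifest(manifest, rows)
    return manifest


def iter_phantoms(
    records: Sequence[tuple[np.ndarray, PhantomGroundTruth, PhantomParams]],
) -> Iterator[tuple[np.ndarray, PhantomGroundTruth]]:
    """Convenience: drop the params column of a cohort record list."""
    for img, truth, _params in records:
        yield img, truth
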