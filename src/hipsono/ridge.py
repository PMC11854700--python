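"""Signal-heterogeneity ridge extraction and iliac-verticality gating.

The bone ridge is traced from points of locally maximal intensity inside a
narrow column-shaped region of interest anchored at the estimated apex
point (eAP): 10 pixels wide, centred on the eAP x coordinate, open toward
the top of the frame and closing 5 pixels below the eAP.  Local maxima are
obtained by max-filtering the frame and masking the filtered image against
the original.  A total-least-squares line through the selected maxima
gives the iliac angle; frames outside the 87-93 degree verticality band
are disqualified.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import InsufficientRidgeSupport

__all__ = [
    "ROISpec",
    "LocalMaximaSet",
    "RidgeLine",
    "QualityResult",
    "build_roi",
    "detect_local_maxima",
    "select_ilium_points",
    "refine_points_subpixel",
    "fit_line",
    "assess_quality",
    "export_intensity_surface",
    "DEFAULT_GATE_DEG",
]

DEFAULT_GATE_DEG = (87.0, 93.0)

ROI_HALF_WIDTH = 5  # 10-pixel-wide column
ROI_BOTTOM_OFFSET = 5  # bottom bound sits 5 px below the eAP


@dataclass(frozen=True)
class ROISpec:
    """Half-open pixel-index rectangle [x_min, x_max) x [y_min, y_max)."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError(f"empty ROI: {self}")

    @property
    def width(self) -> int:
        return self.x_max - self.x_min

    @property
    def height(self) -> int:
        return self.y_max - self.y_min

    def contains(self, x: float, y: float) -> bool:
        return self.x_min <= x < self.x_max and self.y_min <= y < self.y_max


@dataclass(frozen=True)
class LocalMaximaSet:
    """Points (x, y, intensity) where the frame equals its max-filter output."""

    points: tuple[tuple[int, int, float], ...]
    neighborhood_px: int

    def __len__(self) -> int:
        return len(self.points)

    def xy(self) -> np.ndarray:
        return np.array([(x, y) for x, y, _ in self.points], dtype=float).reshape(-1, 2)


@dataclass(frozen=True)
class RidgeLine:
    """A fitted line: centroid anchor, unit direction, orientation angle.

    ``angle_deg`` is measured from the +x axis in array coordinates and
    folded into [0, 180); 90 = vertical.
    """

    anchor: tuple[float, float]
    direction: tuple[float, float]
    angle_deg: float
    n_points: int = 0
    rms_residual: float = 0.0


@dataclass(frozen=True)
class QualityResult:
    iliac_angle_deg: float
    qualified: bool
    n_support_points: int


def build_roi(eap: tuple[float, float], image_shape: tuple[int, int]) -> ROISpec:
    """ROI column around the eAP, clipped to the frame."""
    h, w = image_shape
    cx = int(round(eap[0]))
    cy = int(round(eap[1]))
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError(f"eAP {eap} outside {w}x{h} image")
    return ROISpec(
        x_min=max(cx - ROI_HALF_WIDTH, 0),
        x_max=min(cx + ROI_HALF_WIDTH, w),
        y_min=0,
        y_max=min(cy + ROI_BOTTOM_OFFSET, h),
    )


def detect_local_maxima(
    image: np.ndarray, roi: ROISpec, neighborhood_px: int = 5
) -> LocalMaximaSet:
    """Local maxima inside the ROI under a square max-filter footprint.

    A pixel qualifies when its value equals the maximum over the
    ``neighborhood_px`` x ``neighborhood_px`` window centred on it (window
    truncated at the frame border) and is strictly positive.  Plateaus are
    kept in full; the selection stage thins them.
    """
    if neighborhood_px < 3 or neighborhood_px % 2 == 0:
        raise ValueError("neighborhood_px must be odd and >= 3")
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    x0, x1 = max(roi.x_min, 0), min(roi.x_max, w)
    y0, y1 = max(roi.y_min, 0), min(roi.y_max, h)
    if x0 >= x1 or y0 >= y1:
        raise ValueError("ROI empty after clipping to the image")
    # filter only a padded window around the ROI; borders use the true
    # in-image neighbourhood (cval=0 never wins against positive pixels)
    pad = neighborhood_px // 2
    wy0, wy1 = max(y0 - pad, 0), min(y1 + pad, h)
    wx0, wx1 = max(x0 - pad, 0), min(x1 + pad, w)
    window = img[wy0:wy1, wx0:wx1]
    filtered = ndimage.maximum_filter(window, size=neighborhood_px, mode="constant", cval=0.0)
    sy, sx = y0 - wy0, x0 - wx0
    sub = window[sy : sy + (y1 - y0), sx : sx + (x1 - x0)]
    subf = filtered[sy : sy + (y1 - y0), sx : sx + (x1 - x0)]
    mask = (sub == subf) & (sub > 0)
    ys, xs = np.nonzero(mask)
    pts = tuple(
        (int(x + x0), int(y + y0), float(sub[y, x])) for y, x in zip(ys, xs)
    )
    return LocalMaximaSet(points=pts, neighborhood_px=neighborhood_px)


def select_ilium_points(
    maxima: LocalMaximaSet,
    k_min: int = 10,
    min_rel_intensity: float = 0.55,
) -> list[tuple[int, int]]:
    """Thin the maxima to at most one ridge point per image row.

    Dim maxima below ``min_rel_intensity`` of the brightest one (speckle
    and soft-tissue debris) are dropped first; then each remaining row
    keeps its highest-intensity maximum, ties resolved toward smaller x.
    Fewer than ``k_min`` survivors disqualify the frame.
    """
    if not maxima.points:
        raise InsufficientRidgeSupport("no local maxima in ROI")
    peak = max(p[2] for p in maxima.points)
    best: dict[int, tuple[int, float]] = {}
    for x, y, inten in maxima.points:
        if inten < min_rel_intensity * peak:
            continue
        cur = best.get(y)
        if cur is None or inten > cur[1] or (inten == cur[1] and x < cur[0]):
            best[y] = (x, inten)
    selected = [(x, y) for y, (x, _inten) in sorted(best.items())]
    if len(selected) < k_min:
        raise InsufficientRidgeSupport(
            f"only {len(selected)} ridge points survive selection (need {k_min})"
        )
    return selected


def refine_points_subpixel(
    image: np.ndarray, points, max_shift: float = 0.5
) -> list[tuple[float, float]]:
    """Parabolic sub-pixel refinement of per-row ridge points along x.

    For each (x, y), a parabola through the intensities at x-1, x, x+1
    relocates the crest; the shift is clamped to ``max_shift``.  Border
    columns and non-concave triples are left untouched.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    out: list[tuple[float, float]] = []
    for x, y in points:
        xi, yi = int(round(x)), int(round(y))
        if 0 < xi < w - 1:
            left, mid, right = img[yi, xi - 1], img[yi, xi], img[yi, xi + 1]
            denom = left - 2.0 * mid + right
            if denom < 0:  # concave triple -> valid parabolic peak
                shift = 0.5 * (left - right) / denom
                x = xi + float(np.clip(shift, -max_shift, max_shift))
        out.append((float(x), float(y)))
    return out


def fit_line(points) -> RidgeLine:
    """Orthogonal (total) least-squares line through 2D points.

    Anchor = centroid; direction = principal axis of the centered cloud,
    i.e. the minimizer of the summed squared perpendicular distances.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) < 2:
        raise ValueError("need at least 2 points to fit a line")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    if not np.any(np.abs(centered) > 1e-12):
        raise ValueError("all points coincident; line undefined")
    # principal axis via SVD of the centered cloud
    _u, s, vt = np.linalg.svd(centered, full_matrices=False)
    direction = vt[0]
    # canonical orientation in [0, 180): positive y, or positive x if horizontal
    if direction[1] < 0 or (direction[1] == 0 and direction[0] < 0):
        direction = -direction
    angle = math.degrees(math.atan2(direction[1], direction[0])) % 180.0
    resid = s[1] if len(s) > 1 else 0.0
    return RidgeLine(
        anchor=(float(centroid[0]), float(centroid[1])),
        direction=(float(direction[0]), float(direction[1])),
        angle_deg=float(angle),
        n_points=len(pts),
        rms_residual=float(resid / math.sqrt(len(pts))),
    )


def assess_quality(
    line: RidgeLine, gate: tuple[float, float] = DEFAULT_GATE_DEG
) -> QualityResult:
    """Iliac-verticality gate; bounds inclusive, boundary ties qualify."""
    lo, hi = gate
    if lo > hi:
        raise ValueError(f"invalid gate {gate}")
    angle = line.angle_deg
    return QualityResult(
        iliac_angle_deg=angle,
        qualified=bool(lo <= angle <= hi),
        n_support_points=line.n_points,
    )


def export_intensity_surface(image: np.ndarray, roi: ROISpec) -> list[tuple[int, int, float]]:
    """Lossless (x, y, intensity) triples of the ROI, sorted by (y, x)."""
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    if roi.x_min < 0 or roi.y_min < 0 or roi.x_max > w or roi.y_max > h:
        raise ValueError(f"ROI {roi} exceeds image bounds {w}x{h}")
    out = []
    for y in range(roi.y_min, roi.y_max):
        for x in range(roi.x_min, roi.x_max):
            out.append((x, y, float(img[y, x])))
    return out
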