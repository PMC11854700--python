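"""Acetabular-roof ridge extraction, alpha angle, and DDH classification.

Starting from the eAP, a search rectangle toward the roof side is scanned
for local maxima; the topmost one (minimum numeric y) marks the edge of
the acetabular roof.  Maxima inside the closed sector between the
horizontal ray and the 45-degree-below-horizontal ray emanating from that
edge are fitted with the same orthogonal least-squares line used for the
ilium.  The alpha angle is the angle between the two ridge lines, folded
into [0, 90]; a hip is classified DDH when alpha falls below 60 degrees.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InsufficientRoofSupport, RoofNotFound
from .ridge import LocalMaximaSet, RidgeLine, ROISpec, detect_local_maxima, fit_line

__all__ = [
    "RoofSearchRect",
    "AlphaResult",
    "build_roof_rect",
    "find_roof_edge",
    "select_roof_points",
    "compute_alpha",
    "classify_ddh",
    "measure_alpha",
    "DDH_ALPHA_CUTOFF_DEG",
]

DDH_ALPHA_CUTOFF_DEG = 60.0

DEFAULT_RECT_EXTENT = (40, 40)  # (toward roof side, downward)


@dataclass(frozen=True)
class RoofSearchRect:
    """Half-open rectangle anchored at the eAP, opening toward the roof."""

    x_min: int
    x_max: int
    y_min: int
    y_max: int
    roof_side: str = "right"

    def __post_init__(self) -> None:
        if self.x_min >= self.x_max or self.y_min >= self.y_max:
            raise ValueError(f"empty roof search rectangle: {self}")
        if self.roof_side not in ("left", "right"):
            raise ValueError(f"roof_side must be 'left' or 'right', got {self.roof_side!r}")

    def as_roi(self) -> ROISpec:
        return ROISpec(self.x_min, self.x_max, self.y_min, self.y_max)


@dataclass(frozen=True)
class AlphaResult:
    roof_edge: tuple[float, float]
    roof_line: RidgeLine
    alpha_deg: float
    ddh: bool
    n_roof_points: int


def build_roof_rect(
    eap: tuple[float, float],
    image_shape: tuple[int, int],
    extent: tuple[int, int] = DEFAULT_RECT_EXTENT,
    roof_side: str = "right",
) -> RoofSearchRect:
    """Rectangle from the eAP extending ``extent`` px toward the roof and down.

    The column sets of the left/right variants are exact mirror images of
    one another about any mirrored anchor, so left-right flipped frames
    give identical geometry.
    """
    h, w = image_shape
    cx = int(round(eap[0]))
    cy = int(round(eap[1]))
    ex, ey = extent
    if roof_side == "right":
        x_min, x_max = cx, min(cx + ex, w)
    else:
        x_min, x_max = max(cx - ex + 1, 0), cx + 1
    return RoofSearchRect(
        x_min=x_min,
        x_max=x_max,
        y_min=max(cy, 0),
        y_max=min(cy + ey, h),
        roof_side=roof_side,
    )


def find_roof_edge(
    maxima: LocalMaximaSet,
    rect: RoofSearchRect,
    eap_x: float | None = None,
) -> tuple[int, int]:
    """Topmost (minimum numeric y) local maximum inside the rectangle.

    Ties on y are broken toward the eAP x coordinate (then smaller x).
    """
    inside = [
        (x, y, v)
        for x, y, v in maxima.points
        if rect.x_min <= x < rect.x_max and rect.y_min <= y < rect.y_max
    ]
    if not inside:
        raise RoofNotFound("no local maxima inside the roof search rectangle")
    ref = eap_x if eap_x is not None else (rect.x_min + rect.x_max) / 2.0
    x, y, _v = min(inside, key=lambda p: (p[1], abs(p[0] - ref), p[0]))
    return (int(x), int(y))


def select_roof_points(
    edge: tuple[float, float],
    maxima: LocalMaximaSet,
    roof_side: str = "right",
) -> list[tuple[int, int]]:
    """Maxima within the closed sector between the horizontal ray and the
    45-degree descending ray, both originating at the roof edge.

    A point p survives when s*(p.x - e.x) > 0 and 0 <= p.y - e.y <=
    s*(p.x - e.x), with s = +1 for a right-side roof and -1 for left.
    """
    if roof_side not in ("left", "right"):
        raise ValueError(f"roof_side must be 'left' or 'right', got {roof_side!r}")
    s = 1.0 if roof_side == "right" else -1.0
    ex, ey = edge
    kept = []
    for x, y, _v in maxima.points:
        dx = s * (x - ex)
        dy = y - ey
        if dx > 0 and 0.0 <= dy <= dx:
            kept.append((int(x), int(y)))
    if len(kept) < 2:
        raise InsufficientRoofSupport(
            f"only {len(kept)} roof points inside the sector (need >= 2)"
        )
    return kept


def compute_alpha(ilium: RidgeLine, roof: RidgeLine) -> float:
    """Angle between the two ridge lines, folded into [0, 90] degrees."""
    d = abs(ilium.angle_deg - roof.angle_deg) % 180.0
    return float(min(d, 180.0 - d))


def classify_ddh(
    alpha_deg: float,
    cutoff_deg: float = DDH_ALPHA_CUTOFF_DEG,
    inclusive: bool = False,
) -> bool:
    """DDH iff alpha < cutoff (strict by default; ``inclusive`` uses <=)."""
    if not (0.0 <= alpha_deg <= 90.0):
        raise ValueError(f"alpha_deg must lie in [0, 90], got {alpha_deg}")
    return bool(alpha_deg <= cutoff_deg) if inclusive else bool(alpha_deg < cutoff_deg)


def measure_alpha(
    image: np.ndarray,
    eap: tuple[float, float],
    ilium_line: RidgeLine,
    roof_side: str = "right",
    extent: tuple[int, int] = DEFAULT_RECT_EXTENT,
    neighborhood_px: int = 5,
    min_rel_intensity: float = 0.55,
    ddh_inclusive: bool = False,
) -> AlphaResult:
    """Full roof stage: rectangle -> edge -> sector -> fit -> alpha -> DDH.

    Dim maxima below ``min_rel_intensity`` of the brightest maximum in the
    rectangle (speckle, decayed reverberation ghosts) are discarded before
    the edge search.
    """
    rect = build_roof_rect(eap, np.asarray(image).shape, extent, roof_side)
    maxima = detect_local_maxima(image, rect.as_roi(), neighborhood_px)
    if maxima.points:
        peak = max(v for _x, _y, v in maxima.points)
        pts = tuple(p for p in maxima.points if p[2] >= min_rel_intensity * peak)
        maxima = LocalMaximaSet(points=pts, neighborhood_px=maxima.neighborhood_px)
    edge = find_roof_edge(maxima, rect, eap_x=eap[0])
    roof_points = select_roof_points(edge, maxima, roof_side)
    roof_line = fit_line(roof_points)
    alpha = compute_alpha(ilium_line, roof_line)
    return AlphaResult(
        roof_edge=(float(edge[0]), float(edge[1])),
        roof_line=roof_line,
        alpha_deg=alpha,
        ddh=classify_ddh(alpha, inclusive=ddh_inclusive),
        n_roof_points=len(roof_points),
    )
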