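"""End-to-end per-frame orchestration.

Stages run in order — apex estimation, ridge extraction with the
iliac-verticality gate, roof/alpha measurement, DDH classification — and
any stage failure short-circuits into a status on the returned verdict
rather than an exception.  Disqualified frames still report their iliac
angle (useful feedback for the sonographer) but never carry a diagnosis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import apex as apex_mod
from . import ridge as ridge_mod
from . import roof_alpha as roof_mod
from .errors import (
    InsufficientRidgeSupport,
    InsufficientRoofSupport,
    NoApexSignal,
    RoofNotFound,
)

__all__ = ["PipelineConfig", "FrameVerdict", "run_pipeline", "run_batch", "Status"]


class Status:
    OK = "ok"
    DISQUALIFIED = "disqualified"
    INSUFFICIENT_RIDGE_SUPPORT = "insufficient_ridge_support"
    ROOF_NOT_FOUND = "roof_not_found"
    NO_APEX_SIGNAL = "no_apex_signal"

    ALL = (OK, DISQUALIFIED, INSUFFICIENT_RIDGE_SUPPORT, ROOF_NOT_FOUND, NO_APEX_SIGNAL)


@dataclass(frozen=True)
class PipelineConfig:
    gate_deg: tuple[float, float] = ridge_mod.DEFAULT_GATE_DEG
    neighborhood_px: int = 3
    k_min_ridge: int = 10
    min_rel_intensity: float = 0.55
    subpixel_refine: bool = True
    roof_side: str = "right"
    roof_extent: tuple[int, int] = roof_mod.DEFAULT_RECT_EXTENT
    ddh_cutoff_deg: float = 60.0
    ddh_inclusive: bool = False


@dataclass(frozen=True)
class FrameVerdict:
    status: str
    eap: apex_mod.ApexEstimate | None = None
    quality: ridge_mod.QualityResult | None = None
    alpha: roof_mod.AlphaResult | None = None
    detail: str = ""

    def __post_init__(self) -> None:
        if (self.status == Status.OK) != (self.alpha is not None):
            raise ValueError("AlphaResult must be present exactly when status is ok")

    @property
    def ddh(self) -> bool | None:
        return None if self.alpha is None else self.alpha.ddh

    def to_dict(self) -> dict:
        out: dict = {"status": self.status, "detail": self.detail}
        if self.eap is not None:
            out["eap"] = {"x": self.eap.x, "y": self.eap.y, "confidence": self.eap.confidence}
        if self.quality is not None:
            out["quality"] = dataclasses.asdict(self.quality)
        if self.alpha is not None:
            out["alpha"] = {
                "alpha_deg": self.alpha.alpha_deg,
                "ddh": self.alpha.ddh,
                "roof_edge": list(self.alpha.roof_edge),
                "n_roof_points": self.alpha.n_roof_points,
            }
        return out


def run_pipeline(
    image: np.ndarray,
    estimator,
    config: PipelineConfig | None = None,
) -> FrameVerdict:
    """Analyze one preprocessed 256x256 frame with the given apex estimator."""
    config = config or PipelineConfig()
    img = np.asarray(image, dtype=float)

    try:
        eap = apex_mod.estimate_apex(estimator, img)
    except NoApexSignal as exc:
        return FrameVerdict(status=Status.NO_APEX_SIGNAL, detail=str(exc))

    try:
        roi = ridge_mod.build_roi(eap.as_tuple(), img.shape)
        maxima = ridge_mod.detect_local_maxima(img, roi, config.neighborhood_px)
        points = ridge_mod.select_ilium_points(
            maxima, k_min=config.k_min_ridge, min_rel_intensity=config.min_rel_intensity
        )
        if config.subpixel_refine:
            points = ridge_mod.refine_points_subpixel(img, points)
        ilium_line = ridge_mod.fit_line(points)
        quality = ridge_mod.assess_quality(ilium_line, config.gate_deg)
    except (InsufficientRidgeSupport, ValueError) as exc:
        return FrameVerdict(
            status=Status.INSUFFICIENT_RIDGE_SUPPORT, eap=eap, detail=str(exc)
        )

    if not quality.qualified:
        return FrameVerdict(
            status=Status.DISQUALIFIED,
            eap=eap,
            quality=quality,
            detail=f"iliac angle {quality.iliac_angle_deg:.2f} outside gate {config.gate_deg}",
        )

    try:
        alpha = roof_mod.measure_alpha(
            img,
            eap.as_tuple(),
            ilium_line,
            roof_side=config.roof_side,
            extent=config.roof_extent,
            neighborhood_px=config.neighborhood_px,
            min_rel_intensity=config.min_rel_intensity,
            ddh_inclusive=config.ddh_inclusive,
        )
    except (RoofNotFound, InsufficientRoofSupport) as exc:
        return FrameVerdict(
            status=Status.ROOF_NOT_FOUND, eap=eap, quality=quality, detail=str(exc)
        )

    return FrameVerdict(status=Status.OK, eap=eap, quality=quality, alpha=alpha)


def run_batch(
    frames: Sequence[tuple[np.ndarray, object]],
    config: PipelineConfig | None = None,
) -> list[FrameVerdict]:
    """Map :func:`run_pipeline` over (image, estimator) pairs independently."""
    return [run_pipeline(img, est, config) for img, est in frames]
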