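"""Image and manifest I/O plus standard preprocessing.

All analysis runs on 256x256 single-channel frames with intensities in
[0, 255]; annotations live in the preprocessed-image pixel frame (origin
top-left, x rightward, y downward).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import imageio.v3 as iio
import numpy as np
import pandas as pd
from skimage import transform as sktransform

from .errors import ManifestSchemaError

__all__ = [
    "TARGET_SHAPE",
    "ApexAnnotation",
    "preprocess_image",
    "rescale_point",
    "load_image",
    "save_image",
    "read_manifest",
    "write_manifest",
    "write_results",
    "MANIFEST_COLUMNS",
]

TARGET_SHAPE = (256, 256)  # (height, width)

MANIFEST_COLUMNS = (
    "path",
    "apex_x",
    "apex_y",
    "iliac_angle_deg",
    "alpha_deg",
    "ddh_label",
    "qualified_label",
    "seed",
)


@dataclass(frozen=True)
class ApexAnnotation:
    """A continuous (x, y) apex landmark in the preprocessed frame."""

    x: float
    y: float
    source: str = "specialist"  # {specialist, model, oracle}

    def as_tuple(self) -> tuple[float, float]:
        return (self.x, self.y)


def _to_gray(raw: np.ndarray) -> np.ndarray:
    if raw.ndim == 2:
        return raw.astype(float)
    if raw.ndim == 3 and raw.shape[2] in (3, 4):
        rgb = raw[..., :3].astype(float)
        # ITU-R 601 luma, the conventional grayscale conversion
        return rgb @ np.array([0.299, 0.587, 0.114])
    raise ValueError(f"expected a 2D or HxWx3 image, got shape {raw.shape}")


def preprocess_image(raw: np.ndarray) -> np.ndarray:
    """Convert to luminance and stretch-resize to 256x256 (bilinear).

    Anisotropic inputs are stretched to square; coordinate sidecars must be
    rescaled with :func:`rescale_point` using the same source shape.
    """
    if raw is None or np.size(raw) == 0:
        raise ValueError("empty image")
    gray = _to_gray(np.asarray(raw))
    if gray.shape == TARGET_SHAPE:
        return gray
    out = sktransform.resize(
        gray, TARGET_SHAPE, order=1, preserve_range=True, anti_aliasing=False
    )
    return np.asarray(out, dtype=float)


def rescale_point(
    point: tuple[float, float],
    from_shape: tuple[int, int],
    to_shape: tuple[int, int] = TARGET_SHAPE,
) -> tuple[float, float]:
    """Map an (x, y) point between image frames under stretch-resize."""
    fh, fw = from_shape
    th, tw = to_shape
    x, y = point
    return (x * tw / fw, y * th / fh)


def load_image(path: str | Path) -> np.ndarray:
    """Read an image file as a float grayscale array (no resize)."""
    return _to_gray(iio.imread(path))


def save_image(path: str | Path, image: np.ndarray) -> None:
    """Write an 8-bit grayscale PNG."""
    arr = np.asarray(image)
    if arr.dtype != np.uint8:
        arr = np.clip(np.rint(arr), 0, 255).astype(np.uint8)
    iio.imwrite(path, arr)


def read_manifest(path: str | Path) -> pd.DataFrame:
    """Read a cohort manifest CSV, validating the required columns.

    An empty file yields an empty frame with the standard columns.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        return pd.DataFrame(columns=list(MANIFEST_COLUMNS))
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed CSV
        raise ManifestSchemaError(f"unreadable manifest {path}: {exc}") from exc
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing:
        raise ManifestSchemaError(
            f"manifest {path} is missing required column(s): {', '.join(missing)}"
        )
    for col in ("ddh_label", "qualified_label"):
        df[col] = df[col].astype(bool)
    return df


def write_manifest(path: str | Path, rows: Iterable[Mapping] | pd.DataFrame) -> None:
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(list(rows))
    missing = [c for c in MANIFEST_COLUMNS if c not in df.columns]
    if missing and len(df):
        raise ManifestSchemaError(
            f"refusing to write manifest without column(s): {', '.join(missing)}"
        )
    df.to_csv(path, index=False)


def write_results(path: str | Path, records: Sequence[Mapping]) -> None:
    """Write analysis records as JSON lines (one object per frame)."""
    import json

    with open(path, "w") as fh:
        for rec in records:
            fh.write(json.dumps(rec, default=_json_default) + "\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
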