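"""ROI color extraction and RGB -> CMYK / HSV channel conversion.

Implements the exact color conversions used for the plate feature matrix:

    C = 1 - R/255,  M = 1 - G/255,  Y = 1 - B/255,  K = min(C, M, Y)

    V = MAX(R, G, B)            (8-bit counts, NOT rescaled)
    S = 0 if V = 0 else 1 - MIN/V
    H = piecewise on the dominant channel, degrees in [0, 360)

Two deliberate departures from textbook conventions, kept because the
feature matrix must match the formulas as used in this workflow: K is the
plain minimum of C, M, Y with no (1-K) rescaling of the other three, and V
stays on the 0-255 scale while S is a dimensionless ratio. H is 0 by
convention when MAX = MIN (achromatic pixel, e.g. a blank plate).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from PIL import Image

__all__ = [
    "ROISpec",
    "FEATURE_COLUMNS",
    "extract_roi_mean",
    "rgb_to_cmyk",
    "rgb_to_hsv",
    "color_features",
    "build_feature_table",
    "load_image",
]

#: Fixed feature-column order of every exported table.
FEATURE_COLUMNS = ["R", "G", "B", "C", "M", "Y", "K", "H", "S", "V"]


@dataclass(frozen=True)
class ROISpec:
    """A rectangular region of interest, 0-based, origin top-left.

    The region covers rows [row, row+height) and columns [col, col+width).
    """

    row: int
    col: int
    height: int = 16
    width: int = 16

    def __post_init__(self) -> None:
        if self.height < 1 or self.width < 1:
            raise ValueError(f"ROI must have positive size, got {self.height}x{self.width}")
        if self.row < 0 or self.col < 0:
            raise ValueError(f"ROI origin must be non-negative, got ({self.row}, {self.col})")


def load_image(path: str | Path) -> np.ndarray:
    """Read a PNG or JPG as an (H, W, 3) uint8 RGB array."""
    with Image.open(path) as im:
        return np.asarray(im.convert("RGB"))


def extract_roi_mean(image: np.ndarray, roi: ROISpec) -> tuple[float, float, float]:
    """Arithmetic per-channel mean over an ROI of an 8-bit RGB image."""
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    h, w = image.shape[:2]
    if roi.row + roi.height > h:
        raise ValueError(
            f"ROI rows [{roi.row}, {roi.row + roi.height}) exceed image height {h}"
        )
    if roi.col + roi.width > w:
        raise ValueError(
            f"ROI cols [{roi.col}, {roi.col + roi.width}) exceed image width {w}"
        )
    block = image[roi.row : roi.row + roi.height, roi.col : roi.col + roi.width, :]
    means = block.reshape(-1, 3).mean(axis=0)
    return float(means[0]), float(means[1]), float(means[2])


def _check_rgb(r: float, g: float, b: float) -> None:
    for name, v in (("R", r), ("G", g), ("B", b)):
        if not 0 <= v <= 255:
            raise ValueError(f"channel {name}={v} outside [0, 255]")


def rgb_to_cmyk(rgb: tuple[float, float, float]) -> tuple[float, float, float, float]:
    """CMYK from 0-255 RGB; K = min(C, M, Y), no (1-K) rescaling."""
    r, g, b = rgb
    _check_rgb(r, g, b)
    c = 1.0 - r / 255.0
    m = 1.0 - g / 255.0
    y = 1.0 - b / 255.0
    return c, m, y, min(c, m, y)


def rgb_to_hsv(rgb: tuple[float, float, float]) -> tuple[float, float, float]:
    """HSV from 0-255 RGB; V in counts, S a ratio, H in degrees [0, 360).

    Ties in the dominant channel resolve in the order R, then G, then B;
    an achromatic input (MAX = MIN) gets H = 0 by convention.
    """
    r, g, b = rgb
    _check_rgb(r, g, b)
    mx = max(r, g, b)
    mn = min(r, g, b)
    v = mx
    s = 0.0 if v == 0 else 1.0 - mn / v
    if mx == mn:
        h = 0.0
    elif mx == r:
        h = 60.0 * (g - b) / (mx - mn)
        if g < b:
            h += 360.0
    elif mx == g:
        h = 60.0 * (b - r) / (mx - mn) + 120.0
    else:
        h = 60.0 * (r - g) / (mx - mn) + 240.0
    return h, s, v


def color_features(rgb: tuple[float, float, float]) -> dict[str, float]:
    """Expand one RGB triplet into the full 10-channel feature dict."""
    r, g, b = rgb
    c, m, y, k = rgb_to_cmyk(rgb)
    h, s, v = rgb_to_hsv(rgb)
    return {"R": r, "G": g, "B": b, "C": c, "M": m, "Y": y, "K": k, "H": h, "S": s, "V": v}


def build_feature_table(
    manifest: list[tuple[np.ndarray | str | Path, float, list[ROISpec]]],
) -> pd.DataFrame:
    """Feature table from labelled plate images.

    Each manifest entry is (image or image path, concentration, ROIs). One or
    two ROIs are allowed per plate; their channel means are averaged into a
    single RGB triplet before expansion, so each plate contributes one row.

    Returns a DataFrame with columns ``sample_id, conc_mg_per_L`` followed by
    the fixed 10-channel feature order.
    """
    if len(manifest) == 0:
        raise ValueError("manifest must contain at least one sample")
    rows = []
    for i, (image, conc, rois) in enumerate(manifest):
        if not 1 <= len(rois) <= 2:
            raise ValueError(
                f"sample {i}: expected 1 or 2 ROIs, got {len(rois)}"
            )
        if isinstance(image, (str, Path)):
            image = load_image(image)
        means = np.mean([extract_roi_mean(image, roi) for roi in rois], axis=0)
        feats = color_features((float(means[0]), float(means[1]), float(means[2])))
        rows.append({"sample_id": i, "conc_mg_per_L": float(conc), **feats})
    return pd.DataFrame(rows, columns=["sample_id", "conc_mg_per_L"] + FEATURE_COLUMNS)


def read_manifest(path: str | Path) -> list[tuple[Path, float, list[ROISpec]]]:
    """Read a calibration manifest CSV.

    Expected columns: ``image_path, conc_mg_per_L, roi_row, roi_col`` with one
    row per ROI; rows sharing an image path are grouped into one sample.
    ROI size is the 16x16 default.
    """
    df = pd.read_csv(path)
    required = {"image_path", "conc_mg_per_L", "roi_row", "roi_col"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"manifest {path} missing columns {sorted(missing)}")
    base = Path(path).parent
    manifest = []
    for img_path, group in df.groupby("image_path", sort=False):
        concs = group["conc_mg_per_L"].unique()
        if len(concs) != 1:
            raise ValueError(f"conflicting concentrations for image {img_path}")
        rois = [ROISpec(int(r), int(c)) for r, c in zip(group["roi_row"], group["roi_col"])]
        p = Path(str(img_path))
        if not p.is_absolute():
            p = base / p
        manifest.append((p, float(concs[0]), rois))
    return manifest
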