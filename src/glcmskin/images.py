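"""Loading, channel splitting, grayscale conversion, ROIs and brightness.

All rasters are 8-bit.  Coordinates are 0-based and row-major; ROIs are
half-open rectangles described by their top-left corner and size.  The
grayscale conversion uses the Rec. 601 luma weights (0.299, 0.587, 0.114),
rounded half-up — the de-facto default of common imaging toolchains.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image as _PILImage

from .glcm import GrayImage

__all__ = [
    "RGBImage",
    "ROISpec",
    "BrightnessSummary",
    "load_rgb",
    "save_rgb",
    "split_channels",
    "to_gray",
    "requantize",
    "extract_roi",
    "brightness_summary",
    "write_histogram_csv",
]

REC601_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class RGBImage:
    """8-bit RGB raster, shape (height, width, 3), with an optional physical scale.

    ``scale`` is millimetres per pixel; it is needed only when ROI
    perturbations are specified in physical units.
    """

    pixels: np.ndarray
    scale: float | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 3 or px.size == 0:
            raise ValueError("RGBImage requires a non-empty (H, W, 3) raster")
        if px.dtype != np.uint8:
            if not np.issubdtype(px.dtype, np.integer):
                raise ValueError("RGBImage pixels must be 8-bit integers")
            if px.min() < 0 or px.max() > 255:
                raise ValueError("RGBImage values must lie in 0..255")
            px = px.astype(np.uint8)
        if self.scale is not None and self.scale <= 0:
            raise ValueError("scale must be positive (mm per pixel)")
        object.__setattr__(self, "pixels", px)

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class ROISpec:
    """Rectangular region of interest: top-left corner plus size, half-open."""

    origin_row: int
    origin_col: int
    height: int
    width: int

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("ROI must be at least 2x2 pixels")
        if self.origin_row < 0 or self.origin_col < 0:
            raise ValueError("ROI origin must be non-negative")

    def validate_within(self, height: int, width: int) -> None:
        end_r = self.origin_row + self.height
        end_c = self.origin_col + self.width
        if end_r > height or end_c > width:
            raise ValueError(
                f"ROI rows {self.origin_row}..{end_r} x cols "
                f"{self.origin_col}..{end_c} exceeds image bounds {height}x{width}"
            )


@dataclass(frozen=True)
class BrightnessSummary:
    """Per-gray-value histogram and mean brightness on the 0-255 scale."""

    histogram: np.ndarray
    mean_brightness: float
    pixel_count: int


def load_rgb(path: str | Path, scale: float | None = None) -> RGBImage:
    """Read an 8-bit RGB PNG/TIFF.  16-bit inputs are rejected, not rescaled."""
    with _PILImage.open(path) as im:
        if im.mode in ("I", "I;16", "I;16B", "I;16L", "F"):
            raise ValueError(f"{path}: 16-bit/float images are not supported; provide 8-bit")
        arr = np.asarray(im.convert("RGB"), dtype=np.uint8)
    return RGBImage(arr, scale=scale)


def save_rgb(image: RGBImage, path: str | Path) -> None:
    _PILImage.fromarray(image.pixels, mode="RGB").save(path)


def split_channels(image: RGBImage) -> tuple[GrayImage, GrayImage, GrayImage]:
    """Split into R, G, B single-channel rasters with no value transformation."""
    px = image.pixels.astype(np.int64)
    return tuple(GrayImage(px[:, :, k], levels=256) for k in range(3))


def to_gray(image: RGBImage, weights: tuple[float, float, float] = REC601_WEIGHTS) -> GrayImage:
    """Weighted luminance, rounded half-up and clamped to 0-255."""
    px = image.pixels.astype(np.float64)
    lum = px[:, :, 0] * weights[0] + px[:, :, 1] * weights[1] + px[:, :, 2] * weights[2]
    gray = np.clip(np.floor(lum + 0.5), 0, 255).astype(np.int64)
    return GrayImage(gray, levels=256)


def requantize(image: GrayImage, new_levels: int) -> GrayImage:
    """Map level v to floor(v * new_levels / old_levels); monotone, surjective
    onto 0..new_levels-1 for a full-range input."""
    if not 2 <= new_levels <= image.levels:
        raise ValueError(
            f"new_levels must lie in 2..{image.levels}, got {new_levels}"
        )
    mapped = (image.pixels.astype(np.int64) * new_levels) // image.levels
    return GrayImage(mapped, levels=new_levels)


def extract_roi(image: GrayImage | RGBImage, roi: ROISpec):
    """Copy the ROI sub-raster; pairs computed afterwards never straddle the cut."""
    roi.validate_within(image.height, image.width)
    r, c = roi.origin_row, roi.origin_col
    if isinstance(image, RGBImage):
        return RGBImage(image.pixels[r : r + roi.height, c : c + roi.width].copy(),
                        scale=image.scale)
    return GrayImage(image.pixels[r : r + roi.height, c : c + roi.width].copy(),
                     levels=image.levels)


def brightness_summary(image: GrayImage) -> BrightnessSummary:
    """Exact 256-bin histogram and mean gray value of an 8-bit raster."""
    if image.levels != 256:
        raise ValueError("brightness_summary expects a full 0-255 grayscale image")
    hist = np.bincount(image.pixels.ravel(), minlength=256)
    n = int(hist.sum())
    mean = float(np.arange(256) @ hist) / n
    return BrightnessSummary(hist, mean, n)


def write_histogram_csv(summary: BrightnessSummary, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["gray_value", "count"])
        for value, count in enumerate(summary.histogram):
            w.writerow([value, int(count)])
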