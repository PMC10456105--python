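"""ROI perturbation and repeatability checks for GLCM features.

A texture measurement on a skin ROI is only meaningful if it is insensitive
to small placement errors of the ROI.  This module recomputes contrast and
homogeneity after translating the ROI by a physical distance, or after
rotating the sampling window about the ROI centre, and reports the relative
change of each feature against a repeatability threshold (1% by default).

Relative change uses the pre-perturbation value as denominator:
``|perturbed − baseline| / baseline``.  Swapping baseline and perturbed
leaves the numerator unchanged; only the denominator moves.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

from .glcm import GLCMConfig, GrayImage, TextureFeatures, texture_features
from .images import ROISpec, extract_roi

__all__ = [
    "SensitivityReport",
    "shift_roi",
    "rotate_roi_contents",
    "sensitivity_check",
    "write_report_json",
]

DEFAULT_THRESHOLD = 0.01


@dataclass(frozen=True)
class SensitivityReport:
    baseline: TextureFeatures
    perturbed: TextureFeatures
    relative_change_contrast: float
    relative_change_homogeneity: float
    perturbation: str
    threshold: float
    passes: bool
    #: True when a baseline feature is zero and its relative change is undefined.
    degenerate: bool = False


def shift_roi(roi: ROISpec, displacement_mm: float, scale: float,
              axis: str = "col", bounds: tuple[int, int] | None = None) -> ROISpec:
    """Translate *roi* by a physical distance along one image axis.

    *scale* is mm per pixel; the displacement is rounded to whole pixels.
    When *bounds* (image height, width) is given, the shifted ROI is checked
    against it.
    """
    if scale <= 0:
        raise ValueError("scale must be positive (mm per pixel)")
    if axis not in ("row", "col"):
        raise ValueError("axis must be 'row' or 'col'")
    px = round(displacement_mm / scale)
    if axis == "row":
        shifted = ROISpec(roi.origin_row + px, roi.origin_col, roi.height, roi.width)
    else:
        shifted = ROISpec(roi.origin_row, roi.origin_col + px, roi.height, roi.width)
    if bounds is not None:
        shifted.validate_within(*bounds)
    return shifted


def rotate_roi_contents(image: GrayImage, roi: ROISpec, angle_deg: float) -> GrayImage:
    """Resample the ROI after rotating its sampling grid about the ROI centre.

    Nearest-neighbour sampling: it preserves the gray-level set, where any
    interpolating kernel would smooth the image and bias GLCM features.  The
    whole rotated window must stay inside the host image.
    """
    if abs(angle_deg) > 45:
        raise ValueError("rotation angle must satisfy |angle| <= 45 degrees")
    roi.validate_within(image.height, image.width)
    theta = np.deg2rad(angle_deg)
    cr = roi.origin_row + (roi.height - 1) / 2.0
    cc = roi.origin_col + (roi.width - 1) / 2.0
    rows = np.arange(roi.origin_row, roi.origin_row + roi.height)
    cols = np.arange(roi.origin_col, roi.origin_col + roi.width)
    rg, cg = np.meshgrid(rows - cr, cols - cc, indexing="ij")
    # Rotate the sampling grid; (row, col) frame, positive angle = counter-
    # clockwise in conventional image display.
    src_r = cr + rg * np.cos(theta) - cg * np.sin(theta)
    src_c = cc + rg * np.sin(theta) + cg * np.cos(theta)
    ri = np.rint(src_r).astype(np.int64)
    ci = np.rint(src_c).astype(np.int64)
    if ri.min() < 0 or ci.min() < 0 or ri.max() >= image.height or ci.max() >= image.width:
        raise ValueError(
            f"rotated sampling window exceeds image bounds {image.height}x{image.width}"
        )
    return GrayImage(image.pixels[ri, ci], levels=image.levels)


def _relative_change(base: float, pert: float) -> tuple[float, bool]:
    if base == 0.0:
        return float("nan"), True
    return abs(pert - base) / abs(base), False


def sensitivity_check(
    image: GrayImage,
    roi: ROISpec,
    config: GLCMConfig,
    perturbation,
    threshold: float = DEFAULT_THRESHOLD,
) -> SensitivityReport:
    """Compare GLCM features of *roi* against a perturbed placement.

    *perturbation* is either a perturbed :class:`ROISpec` (a shift), a number
    (rotation angle in degrees), or a callable ``(image, roi) -> GrayImage``
    producing the perturbed contents.  A zero baseline feature makes the
    relative change undefined; the report flags it instead of dividing.
    """
    baseline = texture_features(extract_roi(image, roi), config)

    if isinstance(perturbation, ROISpec):
        perturbed_img = extract_roi(image, perturbation)
        desc = (
            f"shift to origin ({perturbation.origin_row}, {perturbation.origin_col})"
        )
    elif isinstance(perturbation, (int, float)):
        perturbed_img = rotate_roi_contents(image, roi, float(perturbation))
        desc = f"rotation by {float(perturbation)} degrees"
    else:
        perturbed_img = perturbation(image, roi)
        desc = getattr(perturbation, "__name__", "custom perturbation")
    perturbed = texture_features(perturbed_img, config)

    rc, deg_c = _relative_change(baseline.contrast, perturbed.contrast)
    rh, deg_h = _relative_change(baseline.homogeneity, perturbed.homogeneity)
    degenerate = deg_c or deg_h
    passes = (not degenerate) and max(rc, rh) <= threshold
    return SensitivityReport(
        baseline=baseline,
        perturbed=perturbed,
        relative_change_contrast=rc,
        relative_change_homogeneity=rh,
        perturbation=desc,
        threshold=threshold,
        passes=passes,
        degenerate=degenerate,
    )


def write_report_json(report: SensitivityReport, path: str | Path) -> None:
    payload = asdict(report)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, allow_nan=True)
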