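"""Measure a before/after image pair the way the cohort analysis expects.

Bridges the image side (channels, ROIs, GLCM features) and the statistics
side (PatientRecord): one call turns an RGB image, or a paired pair, into
the brightness/contrast/homogeneity values per channel that
:mod:`glcmskin.cohort` aggregates.
"""

from __future__ import annotations

import numpy as np

from .cohort import PatientRecord
from .glcm import GLCMConfig, texture_features
from .images import ROISpec, RGBImage, brightness_summary, extract_roi, split_channels, to_gray

__all__ = ["measure_image", "measure_pair"]


def measure_image(
    image: RGBImage,
    roi: ROISpec | None = None,
    config: GLCMConfig | None = None,
) -> dict[tuple[str, str], float]:
    """Brightness, GLCM contrast and homogeneity on the grayscale image and
    on each RGB channel, keyed ``(metric, channel)``."""
    if roi is not None:
        image = extract_roi(image, roi)
    if config is None:
        config = GLCMConfig()
    out: dict[tuple[str, str], float] = {}
    gray = to_gray(image)
    channels = dict(zip(("R", "G", "B"), split_channels(image)))
    channels["gray"] = gray
    for name, chan in channels.items():
        out[("brightness", name)] = brightness_summary(chan).mean_brightness
        feats = texture_features(chan, config)
        out[("contrast", name)] = feats.contrast
        out[("homogeneity", name)] = feats.homogeneity
    return out


def measure_pair(
    before: RGBImage,
    after: RGBImage,
    patient_id: int = 1,
    roi: ROISpec | None = None,
    config: GLCMConfig | None = None,
) -> PatientRecord:
    """Paired measurements of a before/after image pair as one PatientRecord."""
    if before.pixels.shape != after.pixels.shape:
        raise ValueError(
            f"before/after image dimensions differ: "
            f"{before.pixels.shape} vs {after.pixels.shape}"
        )
    m_before = measure_image(before, roi, config)
    m_after = measure_image(after, roi, config)
    rec = PatientRecord(patient_id)
    for key in m_before:
        rec.values[key] = (m_before[key], m_after[key])
    return rec
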