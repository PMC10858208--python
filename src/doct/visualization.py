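"""Pseudo-color composition and slicing of dynamics volumes.

The composite display encodes the dynamics metric in hue (red = low,
green = high by default), the temporal-mean OCT intensity in value
(brightness) and fixes saturation at 1, so bright tissue shows the metric
colour while empty, dark voxels stay black regardless of the metric.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np
from matplotlib.colors import hsv_to_rgb
from pydantic import BaseModel, model_validator

from .quantify import SegmentationMask
from .scan_io import DynamicsVolume

__all__ = [
    "ColorMapSpec",
    "DEFAULT_LIV_COLORMAP",
    "DEFAULT_OCDS_COLORMAP",
    "compose_pseudocolor",
    "extract_en_face",
    "extract_cross_section",
    "mask_center_depth",
    "mask_center_location",
]


class ColorMapSpec(BaseModel):
    """Hue/value mapping of a metric + mean-intensity pair onto RGB."""

    metric_range: Tuple[float, float]
    hue_endpoints_deg: Tuple[float, float] = (0.0, 120.0)
    intensity_range_db: Tuple[float, float]

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _check_ranges(self) -> "ColorMapSpec":
        if not self.metric_range[0] < self.metric_range[1]:
            raise ValueError("metric_range must be (low, high) with low < high")
        if not self.intensity_range_db[0] < self.intensity_range_db[1]:
            raise ValueError("intensity_range_db must be (low, high) with low < high")
        return self


# Display ranges put the viability cut-offs (3 dB^2, 2e-4 /ms) in the lower
# half of the ramp; intensity limits suit the phantom's ~30 dB SNR.
DEFAULT_LIV_COLORMAP = ColorMapSpec(metric_range=(0.0, 10.0), intensity_range_db=(-25.0, 0.0))
DEFAULT_OCDS_COLORMAP = ColorMapSpec(metric_range=(0.0, 5e-4), intensity_range_db=(-25.0, 0.0))


def _unit_clip(x: np.ndarray, lo: float, hi: float) -> np.ndarray:
    return np.clip((x - lo) / (hi - lo), 0.0, 1.0)


def compose_pseudocolor(metric: DynamicsVolume, spec: ColorMapSpec) -> np.ndarray:
    """Per-voxel HSV composition -> RGB array of shape ``metric.shape + (3,)``.

    Hue interpolates linearly between the endpoint angles over
    ``metric_range``; value maps the mean dB intensity into [0, 1];
    saturation is 1 everywhere.  Out-of-range inputs clamp to endpoints.
    """
    frac = _unit_clip(metric.values.astype(np.float64), *spec.metric_range)
    h0, h1 = spec.hue_endpoints_deg
    hue = (h0 + frac * (h1 - h0)) / 360.0
    value = _unit_clip(
        metric.mean_intensity_db.astype(np.float64), *spec.intensity_range_db
    )
    hsv = np.stack([hue, np.ones_like(hue), value], axis=-1)
    return hsv_to_rgb(hsv)


def extract_en_face(volume: np.ndarray, depth_index: int) -> np.ndarray:
    """Plane parallel to the plate at a fixed depth: ``[location, lateral]``."""
    volume = np.asarray(volume)
    if not 0 <= depth_index < volume.shape[1]:
        raise IndexError(
            f"depth index {depth_index} out of bounds for {volume.shape[1]} planes"
        )
    return volume[:, depth_index]


def extract_cross_section(volume: np.ndarray, location_index: int) -> np.ndarray:
    """Single B-scan at a fixed location: ``[depth, lateral]``."""
    volume = np.asarray(volume)
    if not 0 <= location_index < volume.shape[0]:
        raise IndexError(
            f"location index {location_index} out of bounds for "
            f"{volume.shape[0]} B-scans"
        )
    return volume[location_index]


def mask_center_depth(mask: SegmentationMask) -> int:
    """Depth index of the en face plane with the largest in-mask area."""
    areas = mask.mask.sum(axis=(0, 2))
    if areas.max() == 0:
        raise ValueError("empty segmentation mask")
    return int(np.argmax(areas))


def mask_center_location(mask: SegmentationMask) -> int:
    """Location index of the B-scan with the largest in-mask area."""
    areas = mask.mask.sum(axis=(1, 2))
    if areas.max() == 0:
        raise ValueError("empty segmentation mask")
    return int(np.argmax(areas))
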