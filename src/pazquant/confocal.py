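"""Confocal-resolution synaptic levels: Otsu presynaptic mask and mean
intensities of the protein of interest within it."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import filters

from .images import ChannelRole, ImageField, MaskImage


@dataclass
class ConfocalSummary:
    image_id: str
    mask_area_px: int
    channel_means: dict  # role name -> mean intensity within the mask
    normalized_pct: float | None = None  # % of the reference-condition mean


def otsu_threshold(image: np.ndarray) -> float:
    """Otsu's threshold over a 256-bin histogram spanning [min, max]:
    the cut maximizing between-class variance."""
    image = np.asarray(image)
    if np.ptp(image) == 0:
        raise ValueError("constant image: Otsu threshold undefined")
    return float(filters.threshold_otsu(image, nbins=256))


def presynaptic_mask(field: ImageField, exclusions=()) -> MaskImage:
    """Otsu mask of the vesicle channel minus user exclusion regions
    (somata, out-of-focus areas)."""
    field.require(ChannelRole.VESICLE_MARKER)
    ves = field[ChannelRole.VESICLE_MARKER]
    thr = otsu_threshold(ves)
    mask = ves >= thr
    for excl in exclusions:
        pixels = excl.pixels if isinstance(excl, MaskImage) else np.asarray(excl, bool)
        mask = mask & ~pixels
    if not mask.any():
        raise ValueError("empty presynaptic mask after exclusions")
    return MaskImage(mask, {"method": "otsu", "threshold": thr, "n_exclusions": len(exclusions)})


def mean_in_mask(channel: np.ndarray, mask: MaskImage) -> float:
    """Arithmetic mean of the channel over mask pixels."""
    pixels = mask.pixels if isinstance(mask, MaskImage) else np.asarray(mask, bool)
    if not pixels.any():
        raise ValueError("mask is empty")
    return float(np.asarray(channel)[pixels].mean())


def analyze_confocal(field: ImageField, image_id: str = "", exclusions=()) -> ConfocalSummary:
    """Per-image confocal quantification: one pooled mean per channel
    within the presynaptic mask."""
    mask = presynaptic_mask(field, exclusions)
    means = {role.value: mean_in_mask(img, mask) for role, img in field.channels.items()}
    return ConfocalSummary(image_id=image_id, mask_area_px=mask.area_px, channel_means=means)
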