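"""Core data model: calibrated multi-channel images, masks, and unit conversions.

All physical distances are reported in nanometers.  Pixel indices are
0-based and the physical coordinate of a pixel center is
``(index + 0.5) * nm_per_px``, so sub-pixel geometry is unambiguous.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

__all__ = [
    "ChannelRole",
    "PixelCalibration",
    "ImageField",
    "ImageVolume",
    "MaskImage",
    "nm_to_px",
    "px_to_nm",
    "load_field",
    "save_field",
]


class ChannelRole(str, Enum):
    """Biological role of one acquisition channel.

    Roles are always declared explicitly (in config or at call sites),
    never inferred from channel order: staining combinations vary
    between experiments.
    """

    VESICLE_MARKER = "vesicle_marker"
    AZ_MARKER = "az_marker"
    PSD_MARKER = "psd_marker"
    PROTEIN_OF_INTEREST = "protein_of_interest"
    BRP = "brp"
    NWK = "nwk"
    DYN = "dyn"
    ENDOA = "endoA"
    DAP160 = "dap160"
    FASII = "fasII"
    PAK = "pak"
    OTHER = "other"


def _as_role(role: ChannelRole | str) -> ChannelRole:
    return role if isinstance(role, ChannelRole) else ChannelRole(role)


@dataclass(frozen=True)
class PixelCalibration:
    """Physical pixel pitch: lateral nm/pixel and, for stacks, axial nm/slice."""

    lateral_nm_per_px: float
    axial_nm_per_px: float | None = None

    def __post_init__(self) -> None:
        if not self.lateral_nm_per_px > 0:
            raise ValueError("lateral_nm_per_px must be > 0")
        if self.axial_nm_per_px is not None and not self.axial_nm_per_px > 0:
            raise ValueError("axial_nm_per_px must be > 0")


def nm_to_px(d_nm: float, cal: PixelCalibration) -> int:
    """Convert a physical distance to a pixel count.

    Rounds to the nearest integer with ties away from zero, e.g.
    175 nm at 50 nm/px -> 4 px and 136 nm at 22.7 nm/px -> 6 px.
    """
    if cal is None:
        raise ValueError("pixel calibration is required for nm->px conversion")
    if d_nm < 0:
        raise ValueError("distance must be >= 0")
    x = d_nm / cal.lateral_nm_per_px
    return int(np.floor(x + 0.5))  # x >= 0, so ties round up = away from zero


def px_to_nm(k: int, cal: PixelCalibration) -> float:
    """Pixel count to physical distance (exact inverse of nm_to_px on integers)."""
    return k * cal.lateral_nm_per_px


def _validate_channels(channels: Mapping, ndim: int) -> dict:
    out: dict[ChannelRole, np.ndarray] = {}
    shape = None
    for role, arr in channels.items():
        a = np.asarray(arr, dtype=np.float64)
        if a.ndim != ndim:
            raise ValueError(f"channel {role} must be {ndim}D, got {a.ndim}D")
        if shape is None:
            shape = a.shape
        elif a.shape != shape:
            raise ValueError("all channels must share identical dimensions")
        if not np.isfinite(a).all():
            raise ValueError(f"channel {role} contains non-finite values")
        if (a < 0).any():
            raise ValueError(f"channel {role} contains negative intensities")
        out[_as_role(role)] = a
    if not out:
        raise ValueError("at least one channel is required")
    return out


@dataclass
class ImageField:
    """Calibrated multi-channel 2D image with channel roles bound."""

    channels: dict
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.channels = _validate_channels(self.channels, 2)

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role) -> np.ndarray:
        return self.channels[_as_role(role)]

    def __contains__(self, role) -> bool:
        return _as_role(role) in self.channels

    def require(self, *roles) -> None:
        missing = [r for r in roles if _as_role(r) not in self.channels]
        if missing:
            raise KeyError(f"required channel roles missing: {missing}")


@dataclass
class ImageVolume:
    """Calibrated multi-channel 3D stack, axis order (Z, Y, X)."""

    channels: dict
    calibration: PixelCalibration

    def __post_init__(self) -> None:
        self.channels = _validate_channels(self.channels, 3)
        if self.shape[0] < 2:
            raise ValueError("a volume needs Z >= 2 slices")

    @property
    def shape(self) -> tuple:
        return next(iter(self.channels.values())).shape

    def __getitem__(self, role) -> np.ndarray:
        return self.channels[_as_role(role)]

    def __contains__(self, role) -> bool:
        return _as_role(role) in self.channels

    def require(self, *roles) -> None:
        missing = [r for r in roles if _as_role(r) not in self.channels]
        if missing:
            raise KeyError(f"required channel roles missing: {missing}")


@dataclass
class MaskImage:
    """Binary mask (2D or 3D) plus a provenance record of how it was made."""

    pixels: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if not self.provenance:
            raise ValueError("mask provenance must be non-empty")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    def __invert__(self) -> np.ndarray:
        return ~self.pixels


def save_field(obj: ImageField | ImageVolume, path) -> None:
    """Write a field/volume to a multi-page TIFF with a JSON role/calibration tag.

    Channel pages are stored in role order; pixel data round-trips
    bit-for-bit (float64).
    """
    roles = [r.value for r in obj.channels]
    data = np.stack([obj.channels[ChannelRole(r)] for r in roles])
    meta = {
        "roles": roles,
        "lateral_nm_per_px": obj.calibration.lateral_nm_per_px,
        "axial_nm_per_px": obj.calibration.axial_nm_per_px,
        "volumetric": isinstance(obj, ImageVolume),
    }
    tifffile.imwrite(
        str(path), data, description=json.dumps(meta), photometric="minisblack"
    )


def load_field(
    path,
    channel_map=None,
    calibration: PixelCalibration | None = None,
    volumetric: bool | None = None,
):
    """Load a single- or multi-page TIFF into an ImageField or ImageVolume.

    ``channel_map`` is the list of roles for the leading (channel) axis; it
    may be omitted for files written by :func:`save_field`, whose embedded
    tag also supplies the calibration (a config-supplied calibration is
    cross-checked against the tag and wins, with a warning, on mismatch).
    """
    path = Path(path)
    if not path.is_file():
        raise FileNotFoundError(path)
    with tifffile.TiffFile(str(path)) as tf:
        data = tf.asarray()
        desc = tf.pages[0].description or ""
    meta = None
    try:
        parsed = json.loads(desc)
        if isinstance(parsed, dict) and "roles" in parsed:
            meta = parsed
    except (json.JSONDecodeError, TypeError):
        meta = None

    if channel_map is None:
        if meta is None:
            raise ValueError("channel_map required for files without an embedded role tag")
        channel_map = meta["roles"]
    roles = [_as_role(r) for r in channel_map]

    if meta is not None and calibration is None:
        calibration = PixelCalibration(meta["lateral_nm_per_px"], meta["axial_nm_per_px"])
    if calibration is None:
        raise ValueError("pixel calibration required (none embedded in file)")
    if meta is not None and volumetric is None:
        volumetric = bool(meta["volumetric"])
    if meta is not None and not np.isclose(
        meta["lateral_nm_per_px"], calibration.lateral_nm_per_px
    ):
        import warnings

        warnings.warn(
            "calibration in config disagrees with TIFF metadata; using config value",
            stacklevel=2,
        )

    data = np.asarray(data, dtype=np.float64)
    if data.ndim == 2:
        data = data[None]
    if data.ndim == 3 and volumetric and len(roles) == 1:
        data = data[None]  # plain multi-page stack: (Z, Y, X), one channel
    if data.ndim == 4 and not volumetric:
        raise ValueError("4D data must be declared volumetric")
    n_chan = data.shape[0]
    if n_chan != len(roles):
        raise ValueError(f"file has {n_chan} channels but channel_map lists {len(roles)}")
    channels = {r: data[i] for i, r in enumerate(roles)}
    if volumetric:
        return ImageVolume(channels, calibration)
    return ImageField(channels, calibration)
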