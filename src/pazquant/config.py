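"""Experiment configuration: every stage reads its parameters from here.

One :class:`ExperimentConfig` holds all tunable constants of the pipeline
(window lengths, smoothing sigmas, erosion radii, threshold methods, the
random seed) so a run is fully described by its config plus its inputs.
Configs serialize to/from YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import yaml

WINDOW_MODES = ("symmetric_68", "onesided_136")
THRESHOLD_METHODS = ("otsu", "li", "triangle", "isodata")


@dataclass
class ExperimentConfig:
    # STED side-view line profiles
    profile_length_nm: float = 750.0
    rolled_average_px: int = 5
    window_mode: str = "symmetric_68"
    symmetric_halfwidth_nm: float = 68.0
    onesided_window_nm: float = 136.0
    roi_extra_width_px: int = 5
    sideview_min_cloud_nm: float = 250.0
    bar_elongation_min: float = 2.0

    # STED en-face object detection
    enface_dilation_px: int = 6
    min_size_px: int = 1
    distance_band_nm: tuple | None = None  # e.g. (100.0, 300.0); off by default

    # NMJ bouton mask and measurement
    nmj_gaussian_sigma_px: float = 5.0
    nmj_threshold_method: str = "isodata"
    nmj_erosion_px: int = 4
    rolling_ball_radius_px: int = 50

    # Periactive-zone segmentation
    edm_edge_cutoff_px: float = 7.5
    mesh_width_nm: float = 175.0
    polarization_log_base: float = 2.0
    seed_smooth_sigma_px: float = 2.0
    minima_depth_factor: float = 0.5  # h = factor * MAD of composite within mask
    upper_half_first: bool = True  # "upper half" = first (Z+1)//2 slices
    min_pak_px: int = 1

    # Per-channel fixed intensity thresholds (role name -> intensity);
    # stages fall back to Otsu when a role is absent.
    channel_thresholds: dict = field(default_factory=dict)

    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.window_mode not in WINDOW_MODES:
            raise ValueError(f"window_mode must be one of {WINDOW_MODES}")
        if self.nmj_threshold_method not in THRESHOLD_METHODS:
            raise ValueError(f"nmj_threshold_method must be one of {THRESHOLD_METHODS}")
        for name in (
            "profile_length_nm",
            "symmetric_halfwidth_nm",
            "onesided_window_nm",
            "sideview_min_cloud_nm",
            "nmj_gaussian_sigma_px",
            "rolling_ball_radius_px",
            "mesh_width_nm",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be > 0")
        for name in ("rolled_average_px",):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        for name in ("enface_dilation_px", "roi_extra_width_px", "nmj_erosion_px"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.distance_band_nm is not None:
            lo, hi = self.distance_band_nm
            if not (0 <= lo < hi):
                raise ValueError("distance_band_nm must be an increasing pair")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        preset = data.pop("preset", None)
        base = preset_config(preset) if preset else cls()
        if data.get("distance_band_nm") is not None:
            data["distance_band_nm"] = tuple(data["distance_band_nm"])
        return base.replace(**data)

    def to_yaml(self, path) -> None:
        d = self.to_dict()
        if d["distance_band_nm"] is not None:
            d["distance_band_nm"] = list(d["distance_band_nm"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)


#: Named presets.  "default_nmj" is the standard NMJ recipe; "fig9LN" is the
#: variant used for the FasII/Pak apposition experiment (lighter smoothing
#: and erosion, Otsu thresholding).  The two differ only in
#: {nmj_gaussian_sigma_px, nmj_erosion_px, nmj_threshold_method}.
_PRESETS = {
    "default": {},
    "default_nmj": {},
    "fig9LN": {
        "nmj_gaussian_sigma_px": 4.0,
        "nmj_erosion_px": 1,
        "nmj_threshold_method": "otsu",
    },
}


def preset_config(name: str = "default") -> ExperimentConfig:
    try:
        overrides = _PRESETS[name]
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; known: {sorted(_PRESETS)}") from None
    return ExperimentConfig(**overrides)
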