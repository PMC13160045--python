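"""Side-view synapse analysis: perpendicular line profiles at the active zone.

A side-view synapse shows the active-zone (or postsynaptic-density) marker
as a bar at the edge of the vesicle cloud.  A rectangular ROI is placed
perpendicular to the bar, through its center; intensity is averaged across
the ROI width, smoothed with a centered rolled average, and the resulting
per-channel trace is aligned to the reference-marker peak.  Metrics are the
signed peak-to-peak distance of the protein of interest (positive = toward
the presynaptic bouton) and the protein maximum within the periactive-zone
window around the reference peak.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from skimage import measure

from .config import ExperimentConfig
from .images import ChannelRole, ImageField

REFERENCE_ROLES = (ChannelRole.AZ_MARKER, ChannelRole.PSD_MARKER)


@dataclass
class SideViewRoi:
    """Rectangular profile ROI at one side-view synapse.

    ``angle_rad`` is the direction of the profile axis (perpendicular to
    the marker bar), normalized to [0, pi).  ``presynaptic_sign`` (+1/-1)
    says which end of the axis points into the bouton; when None it is
    inferred from the vesicle-marker centroid.
    """

    center_px: tuple  # (y, x), may be fractional
    angle_rad: float
    length_nm: float = 750.0
    width_px: int = 11
    presynaptic_sign: int | None = None

    def __post_init__(self) -> None:
        if not self.length_nm > 0:
            raise ValueError("profile length must be > 0")
        if self.width_px < 1:
            raise ValueError("roi width must be >= 1 px")
        self.angle_rad = float(self.angle_rad) % math.pi


@dataclass
class LineProfile:
    """Intensity-vs-position trace; uniform spacing of one lateral pixel.

    Positions are in nm; positive positions point toward the presynaptic
    side.  After alignment, position 0 is the reference-marker peak.
    """

    positions_nm: np.ndarray
    intensities: dict  # role -> array
    spacing_nm: float
    reference_role: ChannelRole
    smoothing: dict = field(default_factory=dict)
    sem: dict | None = None
    n_profiles: int = 1

    def __post_init__(self) -> None:
        steps = np.diff(self.positions_nm)
        if len(steps) and not np.allclose(steps, self.spacing_nm):
            raise ValueError("profile positions must be uniformly spaced")


@dataclass
class ProfileSummary:
    peak_to_peak_nm: float  # signed, + toward the presynaptic side
    window_peak: float
    window_mode: str


def rolled_average(y: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean; the window shrinks to the valid range at the
    edges (no intensity is fabricated outside the profile)."""
    if window <= 1:
        return np.asarray(y, dtype=float)
    kernel = np.ones(window)
    sums = np.convolve(y, kernel, mode="same")
    counts = np.convolve(np.ones_like(y, dtype=float), kernel, mode="same")
    return sums / counts


def _reference_role(field: ImageField) -> ChannelRole:
    for role in REFERENCE_ROLES:
        if role in field:
            return role
    raise KeyError("field has neither an az_marker nor a psd_marker channel")


def _argmax_near_zero(positions: np.ndarray, values: np.ndarray) -> int:
    """Index of the maximum; ties broken by |position| (closest to 0), then
    by the more presynaptic (larger) position."""
    vmax = values.max()
    idx = np.flatnonzero(values == vmax)
    keys = sorted(idx, key=lambda i: (abs(positions[i]), -positions[i]))
    return int(keys[0])


def extract_profile(
    field: ImageField, roi: SideViewRoi, cfg: ExperimentConfig
) -> LineProfile:
    """Sample the ROI: bilinear sub-pixel sampling at one sample per pixel
    along the axis, mean across the ROI width, then a centered rolled
    average per channel."""
    lat = field.calibration.lateral_nm_per_px
    n_half = int(math.floor(roi.length_nm / (2 * lat)))
    t = np.arange(-n_half, n_half + 1, dtype=float)  # axis samples (px)
    w = np.arange(roi.width_px, dtype=float) - (roi.width_px - 1) / 2
    th = roi.angle_rad
    ay, ax = math.sin(th), math.cos(th)  # axis direction (y, x)
    py, px_ = math.cos(th), -math.sin(th)  # perpendicular (width) direction

    cy, cx = roi.center_px
    ys = cy + t[:, None] * ay + w[None, :] * py
    xs = cx + t[:, None] * ax + w[None, :] * px_
    H, W = field.shape
    if ys.min() < 0 or xs.min() < 0 or ys.max() > H - 1 or xs.max() > W - 1:
        raise ValueError("roi exceeds image bounds")

    raw = {}
    for role, img in field.channels.items():
        samples = ndimage.map_coordinates(img, [ys, xs], order=1, mode="nearest")
        raw[role] = samples.mean(axis=1)

    sign = roi.presynaptic_sign
    if sign is None:
        if ChannelRole.VESICLE_MARKER not in raw:
            raise KeyError(
                "presynaptic sign not given and no vesicle_marker channel to infer it"
            )
        ves = raw[ChannelRole.VESICLE_MARKER]
        if ves.sum() <= 0:
            raise ValueError("vesicle channel empty within roi")
        sign = 1 if float((t * ves).sum() / ves.sum()) >= 0 else -1
    if sign < 0:  # orient so that positive positions are presynaptic
        raw = {r: v[::-1].copy() for r, v in raw.items()}

    smoothed = {r: rolled_average(v, cfg.rolled_average_px) for r, v in raw.items()}
    return LineProfile(
        positions_nm=t * lat,
        intensities=smoothed,
        spacing_nm=lat,
        reference_role=_reference_role(field),
        smoothing={"rolled_average_px": cfg.rolled_average_px, "width_px": roi.width_px},
    )


def align_profile(profile: LineProfile) -> LineProfile:
    """Shift positions so the reference-channel argmax sits at position 0."""
    ref = profile.intensities[profile.reference_role]
    if np.ptp(ref) == 0:
        raise ValueError("reference channel is flat; no unique peak")
    k = _argmax_near_zero(profile.positions_nm, ref)
    shift = profile.positions_nm[k]
    return replace(profile, positions_nm=profile.positions_nm - shift)


def align_and_average(profiles, reference_mean: float) -> LineProfile:
    """Align each profile to its reference peak, average pointwise across
    profiles, and express the result in % of ``reference_mean``.

    Positions covered by only part of the profiles average over the
    profiles that reach them.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("at least one profile is required")
    if not reference_mean > 0:
        raise ValueError("reference_mean must be > 0")
    aligned = [align_profile(p) for p in profiles]
    spacing = aligned[0].spacing_nm
    roles = list(aligned[0].intensities)

    sums: dict = {}
    sqsums: dict = {}
    counts: dict = {}
    for p in aligned:
        offsets = np.round(p.positions_nm / spacing).astype(int)
        for role in roles:
            vals = p.intensities[role]
            for o, v in zip(offsets, vals):
                key = (role, o)
                sums[key] = sums.get(key, 0.0) + v
                sqsums[key] = sqsums.get(key, 0.0) + v * v
                counts[key] = counts.get(key, 0) + 1

    all_offsets = sorted({o for (_, o) in sums})
    positions = np.array(all_offsets, dtype=float) * spacing
    mean_i, sem_i = {}, {}
    scale = 100.0 / reference_mean
    for role in roles:
        m = np.full(len(all_offsets), np.nan)
        s = np.full(len(all_offsets), np.nan)
        for j, o in enumerate(all_offsets):
            key = (role, o)
            if key in sums:
                n = counts[key]
                mu = sums[key] / n
                m[j] = mu * scale
                if n > 1:
                    var = max(sqsums[key] / n - mu * mu, 0.0) * n / (n - 1)
                    s[j] = math.sqrt(var / n) * scale
        mean_i[role] = m
        sem_i[role] = s

    return LineProfile(
        positions_nm=positions,
        intensities=mean_i,
        spacing_nm=spacing,
        reference_role=aligned[0].reference_role,
        smoothing={"normalized_pct_of": reference_mean},
        sem=sem_i,
        n_profiles=len(aligned),
    )


def profile_metrics(
    profile: LineProfile,
    cfg: ExperimentConfig,
    protein_role: ChannelRole = ChannelRole.PROTEIN_OF_INTEREST,
) -> ProfileSummary:
    """Peak-to-peak distance and periactive-zone window peak of an aligned
    profile.

    ``symmetric_68`` takes the protein maximum over [-68, +68] nm around
    the reference peak; ``onesided_136`` over [0, +136] nm on the
    presynaptic side.  Window endpoints are inclusive.
    """
    pos = profile.positions_nm
    prot = profile.intensities[protein_role]
    k = _argmax_near_zero(pos, prot)
    peak_to_peak = float(pos[k])

    if cfg.window_mode == "symmetric_68":
        lo, hi = -cfg.symmetric_halfwidth_nm, cfg.symmetric_halfwidth_nm
    else:
        lo, hi = 0.0, cfg.onesided_window_nm
    if lo < pos.min() - 1e-9 or hi > pos.max() + 1e-9:
        raise ValueError("metric window extends past the profile ends")
    inside = (pos >= lo - 1e-9) & (pos <= hi + 1e-9)
    window_peak = float(np.nanmax(prot[inside]))
    return ProfileSummary(peak_to_peak, window_peak, cfg.window_mode)


def _channel_threshold(field: ImageField, role: ChannelRole, cfg: ExperimentConfig):
    thr = cfg.channel_thresholds.get(role.value)
    if thr is not None:
        return float(thr)
    from .confocal import otsu_threshold

    return otsu_threshold(field[role])


def screen_sideview(field: ImageField, candidate: SideViewRoi, cfg: ExperimentConfig):
    """Geometric screen for side-view synapses.

    Accept iff (a) the thresholded vesicle signal extends at least
    ``sideview_min_cloud_nm`` from the marker toward the presynaptic side
    along the profile axis, and (b) the thresholded marker object is
    bar-like (second-moment elongation >= ``bar_elongation_min``).
    Returns ``(accepted, reasons)``.
    """
    field.require(ChannelRole.VESICLE_MARKER)
    ref_role = _reference_role(field)
    lat = field.calibration.lateral_nm_per_px
    reasons = []

    marker = field[ref_role]
    m_thr = _channel_threshold(field, ref_role, cfg)
    mlab = measure.label(marker >= m_thr, connectivity=2)
    if mlab.max() == 0:
        raise ValueError("no marker object above threshold")
    cy, cx = candidate.center_px
    props = measure.regionprops(mlab)
    best = min(props, key=lambda p: (p.centroid[0] - cy) ** 2 + (p.centroid[1] - cx) ** 2)
    minor = best.axis_minor_length
    elongation = math.inf if minor == 0 else best.axis_major_length / minor
    if elongation < cfg.bar_elongation_min:
        reasons.append(
            f"marker not bar-like (elongation {elongation:.2f} < {cfg.bar_elongation_min})"
        )

    # presynaptic direction for the candidate axis
    th = candidate.angle_rad
    ay, ax = math.sin(th), math.cos(th)
    ves = field[ChannelRole.VESICLE_MARKER]
    v_thr = _channel_threshold(field, ChannelRole.VESICLE_MARKER, cfg)
    H, W = field.shape
    max_t = int(candidate.length_nm / lat)
    extents = {}
    for sgn in (+1, -1) if candidate.presynaptic_sign is None else (
        candidate.presynaptic_sign,
    ):
        run = 0
        for i in range(1, max_t + 1):
            y = cy + sgn * i * ay
            x = cx + sgn * i * ax
            if not (0 <= y <= H - 1 and 0 <= x <= W - 1):
                break
            val = ndimage.map_coordinates(ves, [[y], [x]], order=1)[0]
            if val >= v_thr:
                run = i
            else:
                break
        extents[sgn] = run * lat
    extent = max(extents.values())
    if extent < cfg.sideview_min_cloud_nm:
        reasons.append(
            f"cloud < {cfg.sideview_min_cloud_nm:.0f} nm (extent {extent:.0f} nm)"
        )
    return (not reasons), reasons
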