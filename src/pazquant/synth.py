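"""Synthetic fluorescence-microscopy scenes with exhaustive ground truth.

Two scene families are generated:

* STED-like 2D fields of cultured-neuron synapses, either *side-view*
  (an elongated active-zone marker bar at the edge of a vesicle cloud,
  with the protein of interest in a band at a known signed offset) or
  *en-face* (a marker disk ringed by protein clusters at known radii).
* Airyscan-like 3D NMJ volumes: a bouton blob whose upper surface
  carries a tiling of periactive-zone units (seeded Voronoi polygons),
  each split into a mesh band of known enrichment and a core, with
  Brp puncta in a designated fraction of units and optional Pak
  apposition under every unit.

Degradation model: isotropic Gaussian PSF blur (configurable FWHM),
then Poisson shot noise at a configurable photon scaling and additive
Gaussian read noise.  All randomness flows from one seeded generator,
so identical parameters + seed give bitwise-identical scenes.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .images import ChannelRole, ImageField, ImageVolume, PixelCalibration, nm_to_px

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


def apply_noise(
    img: np.ndarray,
    poisson_scale: float,
    read_noise_sd: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Poisson shot noise (lambda = poisson_scale photons per intensity unit)
    plus Gaussian read noise; output clipped at 0.

    With signal s the output variance is s/poisson_scale + read_noise_sd**2;
    zero parameters disable the corresponding component.
    """
    out = np.asarray(img, dtype=np.float64)
    if poisson_scale and poisson_scale > 0:
        out = rng.poisson(out * poisson_scale).astype(np.float64) / poisson_scale
    if read_noise_sd and read_noise_sd > 0:
        out = out + rng.normal(0.0, read_noise_sd, size=out.shape)
    return np.clip(out, 0.0, None)


def _blur(img: np.ndarray, fwhm_nm: float, nm_per_px: float) -> np.ndarray:
    if not fwhm_nm:
        return img
    sigma_px = fwhm_nm * FWHM_TO_SIGMA / nm_per_px
    return ndimage.gaussian_filter(img, sigma_px)


# --------------------------------------------------------------------------
# STED scenes
# --------------------------------------------------------------------------


@dataclass
class SynthStedParams:
    """Scene parameters for a synthetic STED field (22.7 nm pixels)."""

    field_px: int = 256
    lateral_nm_per_px: float = 22.7
    n_sideview: int = 1
    n_enface: int = 1

    # side-view geometry (nm)
    marker_length_nm: float = 300.0
    marker_sigma_nm: float = 25.0  # bar cross-section sd
    protein_offset_nm: float | tuple = 90.8  # signed; + = presynaptic side
    protein_sigma_nm: float = 45.0
    cloud_diameter_nm: float = 400.0  # vesicle cloud extent from the marker
    angles_rad: tuple | None = None  # profile-axis angles; random if None

    # en-face geometry
    enface_marker_radius_nm: float = 90.0
    clusters_per_synapse: int = 3
    cluster_radius_nm: float | tuple = 250.0  # distance of clusters from center
    cluster_sigma_nm: float = 40.0
    enface_cloud_radius_nm: float = 350.0

    # amplitudes (arbitrary intensity units)
    marker_amp: float = 200.0
    protein_amp: float = 150.0
    cluster_amp: float = 150.0
    vesicle_amp: float = 120.0

    # degradation
    psf_fwhm_nm: float = 60.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 3.0

    seed: int = 0

    def __post_init__(self) -> None:
        if self.field_px < 32:
            raise ValueError("field too small")
        if self.psf_fwhm_nm < 0:
            raise ValueError("PSF FWHM must be >= 0")
        for name in ("marker_amp", "protein_amp", "cluster_amp", "vesicle_amp"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass
class SideViewTruth:
    center_px: tuple  # (y, x)
    angle_rad: float  # profile-axis direction; + axis = presynaptic side
    delta_nm: float  # true protein offset along the profile axis (signed)
    cloud_diameter_nm: float


@dataclass
class EnFaceTruth:
    center_px: tuple  # (y, x) of the AZ marker center
    cluster_centers_px: list  # [(y, x), ...]
    cluster_radii_nm: list  # radial distance of each cluster from center
    cluster_amp: float


@dataclass
class StedGroundTruth:
    sideview: list
    enface: list
    params: SynthStedParams
    seed: int

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, default=str, indent=1)


def _soft_disk(r: np.ndarray, radius: float, edge_sigma: float = 25.0) -> np.ndarray:
    return np.exp(-np.maximum(r - radius, 0.0) ** 2 / (2 * edge_sigma**2))


def _place_centers(
    n: int, field_px: int, min_extent_px: float, rng: np.random.Generator
) -> list:
    """Assign scene objects to jittered grid cells so nothing crosses the border."""
    if n == 0:
        return []
    g = math.ceil(math.sqrt(n))
    cell = field_px / g
    if cell < min_extent_px:
        raise ValueError(
            f"{n} synapses with extent {min_extent_px:.0f} px do not fit a "
            f"{field_px} px field without overlapping the border"
        )
    cells = [(i, j) for i in range(g) for j in range(g)]
    order = rng.permutation(len(cells))[:n]
    centers = []
    for k in order:
        i, j = cells[k]
        jitter = rng.uniform(-0.05, 0.05, size=2) * cell
        centers.append(((i + 0.5) * cell + jitter[0], (j + 0.5) * cell + jitter[1]))
    return centers


def generate_sted_field(p: SynthStedParams):
    """Render one synthetic STED field.

    Returns ``(ImageField, StedGroundTruth)``.  Channels: ``az_marker``,
    ``protein_of_interest``, ``vesicle_marker``.
    """
    rng = np.random.default_rng(p.seed)
    lat = p.lateral_nm_per_px
    shape = (p.field_px, p.field_px)
    marker = np.zeros(shape)
    protein = np.zeros(shape)
    vesicle = np.zeros(shape)
    yy, xx = np.mgrid[0 : p.field_px, 0 : p.field_px].astype(np.float64)

    n_total = p.n_sideview + p.n_enface
    # room for the 750 nm profile plus the vesicle cloud / en-face ring
    extent_nm = max(
        800.0, p.cloud_diameter_nm * 2 + 200.0, 2 * p.enface_cloud_radius_nm + 300.0
    )
    centers = _place_centers(n_total, p.field_px, extent_nm / lat, rng)

    offsets = np.broadcast_to(
        np.atleast_1d(np.asarray(p.protein_offset_nm, dtype=float)), (p.n_sideview,)
    )
    if p.angles_rad is not None:
        angles = np.broadcast_to(np.atleast_1d(p.angles_rad), (p.n_sideview,))
    else:
        angles = rng.uniform(0.0, math.pi, size=p.n_sideview)

    sv_truth: list = []
    for k in range(p.n_sideview):
        cy, cx = centers[k]
        th = float(angles[k])
        delta = float(offsets[k])
        du, dv = math.cos(th), math.sin(th)
        # u: along the profile axis (+ = presynaptic), v: along the bar
        u = ((xx - cx) * du + (yy - cy) * dv) * lat
        v = (-(xx - cx) * dv + (yy - cy) * du) * lat
        env = np.exp(
            -np.maximum(np.abs(v) - p.marker_length_nm / 2, 0.0) ** 2 / (2 * 20.0**2)
        )
        marker += p.marker_amp * np.exp(-(u**2) / (2 * p.marker_sigma_nm**2)) * env
        protein += (
            p.protein_amp * np.exp(-((u - delta) ** 2) / (2 * p.protein_sigma_nm**2)) * env
        )
        # vesicle cloud on the presynaptic (+u) side, touching the marker
        d2 = p.cloud_diameter_nm / 2
        r = np.hypot(u - d2, v)
        vesicle += p.vesicle_amp * _soft_disk(r, d2, 30.0)
        sv_truth.append(SideViewTruth((cy, cx), th, delta, p.cloud_diameter_nm))

    radii = np.broadcast_to(
        np.atleast_1d(np.asarray(p.cluster_radius_nm, dtype=float)),
        (p.clusters_per_synapse,),
    )
    ef_truth: list = []
    for k in range(p.n_enface):
        cy, cx = centers[p.n_sideview + k]
        r = np.hypot(xx - cx, yy - cy) * lat
        marker += p.marker_amp * _soft_disk(r, p.enface_marker_radius_nm, 25.0)
        vesicle += p.vesicle_amp * _soft_disk(r, p.enface_cloud_radius_nm, 30.0)
        phase = rng.uniform(0, 2 * math.pi)
        ccenters, cradii = [], []
        for j in range(p.clusters_per_synapse):
            ang = phase + 2 * math.pi * j / p.clusters_per_synapse
            rad = float(radii[j])
            py = cy + rad / lat * math.sin(ang)
            px_ = cx + rad / lat * math.cos(ang)
            rc = np.hypot(xx - px_, yy - py) * lat
            protein += p.cluster_amp * np.exp(-(rc**2) / (2 * p.cluster_sigma_nm**2))
            ccenters.append((py, px_))
            cradii.append(rad)
        ef_truth.append(EnFaceTruth((cy, cx), ccenters, cradii, p.cluster_amp))

    channels = {}
    for role, img in (
        (ChannelRole.AZ_MARKER, marker),
        (ChannelRole.PROTEIN_OF_INTEREST, protein),
        (ChannelRole.VESICLE_MARKER, vesicle),
    ):
        img = _blur(img, p.psf_fwhm_nm, lat)
        channels[role] = apply_noise(img, p.poisson_scale, p.read_noise_sd, rng)

    fieldimg = ImageField(channels, PixelCalibration(lat))
    return fieldimg, StedGroundTruth(sv_truth, ef_truth, p, p.seed)


# --------------------------------------------------------------------------
# NMJ scenes
# --------------------------------------------------------------------------

MESH_ROLES = (
    ChannelRole.NWK,
    ChannelRole.DYN,
    ChannelRole.ENDOA,
    ChannelRole.DAP160,
    ChannelRole.FASII,
)


@dataclass
class SynthNmjParams:
    """Scene parameters for a synthetic NMJ volume (50 nm lateral pixels).

    The periactive-zone surface is painted as a piecewise-constant map on
    one slice of the upper half of the stack: each channel takes the value
    ``core_level`` in unit cores and ``R * core_level`` in the mesh band,
    where the band is the set of unit pixels closer than
    ``nm_to_px(mesh_width_nm)`` to the unit boundary -- the same geometry
    the analysis quantifies, so band statistics have exact ground truth.
    """

    shape: tuple = (9, 160, 160)  # (Z, Y, X)
    lateral_nm_per_px: float = 50.0
    axial_nm_per_px: float = 150.0

    bouton_radius_px: float = 44.0
    bouton_center: tuple | None = None  # (y, x); field center if None

    n_units: int = 20
    seed_layout: str = "random"  # or "grid"
    mesh_width_nm: float = 175.0
    mesh_enrichment: dict = field(default_factory=lambda: {"nwk": 2.5, "dyn": 2.0})
    # FasII outlines unit borders: painted as a narrow Gaussian ridge on the
    # Voronoi edges (not a flat band), giving the segmentation sharp crests
    fasII_ridge_amp: float = 300.0
    fasII_ridge_sigma_nm: float = 100.0
    core_level: float = 100.0
    fill_ratio: float = 0.6  # volumetric fill relative to core_level
    background_level: float = 20.0

    brp_fraction: float = 0.5  # fraction of units carrying a Brp punctum
    brp_amp: float = 300.0
    brp_sigma_nm: float = 80.0
    brp_fill: float = 30.0
    pak_apposed: bool = True
    pak_amp: float = 200.0
    pak_radius_px: int = 3

    roles: tuple = ("brp", "nwk", "dyn", "fasII", "pak")
    paint_paz_surface: bool = True
    paz_slice: int = 1  # slice (within the upper half) carrying the surface map

    psf_fwhm_nm: float = 0.0
    poisson_scale: float = 1.0
    read_noise_sd: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")
        for r in self.mesh_enrichment.values():
            if not r > 0:
                raise ValueError("mesh enrichment factors must be > 0")
        if not 0 <= self.brp_fraction <= 1:
            raise ValueError("brp_fraction must lie in [0, 1]")
        if self.seed_layout not in ("random", "grid"):
            raise ValueError("seed_layout must be 'random' or 'grid'")


@dataclass
class NmjGroundTruth:
    params: SynthNmjParams
    seed: int
    footprint: np.ndarray  # 2D bool, bouton footprint
    interior3d: np.ndarray  # 3D bool, true bouton interior
    labels2d: np.ndarray  # 2D int, Voronoi unit labels (1..K) on the footprint
    mesh2d: np.ndarray  # 2D bool, true mesh band (within footprint)
    unit_seeds_px: list  # [(y, x), ...] Voronoi sites, unit k -> label k+1
    brp_positive: np.ndarray  # bool per unit
    brp_centers_px: list  # punctum centers, aligned with brp-positive units
    pak_apposed: bool
    mesh_enrichment: dict  # role name -> true mesh/core ratio R
    paz_slice: int

    def to_json(self) -> str:
        d = {
            "seed": self.seed,
            "unit_seeds_px": [list(map(float, s)) for s in self.unit_seeds_px],
            "brp_positive": self.brp_positive.tolist(),
            "brp_centers_px": [list(map(float, c)) for c in self.brp_centers_px],
            "pak_apposed": self.pak_apposed,
            "mesh_enrichment": self.mesh_enrichment,
            "paz_slice": self.paz_slice,
            "params": dataclasses.asdict(self.params),
        }
        return json.dumps(d, default=str, indent=1)


def _voronoi_seeds(
    p: SynthNmjParams, footprint: np.ndarray, rng: np.random.Generator
) -> list:
    ys, xs = np.nonzero(footprint)
    cy, cx = ys.mean(), xs.mean()
    if p.seed_layout == "grid":
        g = math.ceil(math.sqrt(p.n_units))
        span = 2 * p.bouton_radius_px * 0.85
        step = span / g
        pts = []
        for i in range(g):
            for j in range(g):
                if len(pts) == p.n_units:
                    break
                pts.append(
                    (cy - span / 2 + (i + 0.5) * step, cx - span / 2 + (j + 0.5) * step)
                )
        return pts
    area = footprint.sum()
    min_sep = 1.5 * math.sqrt(area / p.n_units / math.pi)
    pts: list = []
    for _ in range(20000):
        if len(pts) == p.n_units:
            break
        i = rng.integers(len(ys))
        cand = (float(ys[i]), float(xs[i]))
        if all(math.hypot(cand[0] - a, cand[1] - b) >= min_sep for a, b in pts):
            pts.append(cand)
    if len(pts) < p.n_units:
        raise ValueError(
            f"could not place {p.n_units} periactive-zone units in the bouton footprint"
        )
    return pts


def generate_nmj_volume(p: SynthNmjParams):
    """Render one synthetic NMJ volume.

    Returns ``(ImageVolume, NmjGroundTruth)``.
    """
    from .paz import mesh_core_masks  # shared band geometry (tested independently)

    rng = np.random.default_rng(p.seed)
    Z, Y, X = p.shape
    cy, cx = p.bouton_center if p.bouton_center is not None else ((Y - 1) / 2, (X - 1) / 2)
    yy, xx = np.mgrid[0:Y, 0:X].astype(np.float64)
    r2d = np.hypot(yy - cy, xx - cx)
    footprint = r2d <= p.bouton_radius_px

    # ellipsoidal 3D interior
    zc = (Z - 1) / 2
    rz = Z / 2
    interior3d = np.zeros((Z, Y, X), dtype=bool)
    for z in range(Z):
        frac = 1.0 - ((z - zc) / rz) ** 2
        if frac > 0:
            interior3d[z] = r2d <= p.bouton_radius_px * math.sqrt(frac)

    seeds = _voronoi_seeds(p, footprint, rng)
    sy = np.array([s[0] for s in seeds])
    sx = np.array([s[1] for s in seeds])
    d2 = (yy[..., None] - sy) ** 2 + (xx[..., None] - sx) ** 2
    labels2d = np.where(footprint, np.argmin(d2, axis=-1) + 1, 0).astype(np.int32)

    cal = PixelCalibration(p.lateral_nm_per_px, p.axial_nm_per_px)
    width_px = nm_to_px(p.mesh_width_nm, cal)
    mesh2d, _core2d = mesh_core_masks(labels2d, width_px)

    # Brp-positive units: exactly round(p * K) of them, chosen at random
    n_pos = int(round(p.brp_fraction * p.n_units))
    pos_idx = rng.permutation(p.n_units)[:n_pos]
    brp_positive = np.zeros(p.n_units, dtype=bool)
    brp_positive[pos_idx] = True
    brp_centers = [seeds[i] for i in np.sort(pos_idx)]

    fill = p.fill_ratio * p.core_level
    channels = {}
    for role_name in p.roles:
        role = ChannelRole(role_name)
        vol = np.zeros((Z, Y, X))
        if role == ChannelRole.BRP:
            vol += p.brp_fill * interior3d
            surf = np.zeros((Y, X))
            sig_px = p.brp_sigma_nm / p.lateral_nm_per_px
            for by, bx in brp_centers:
                surf += p.brp_amp * np.exp(
                    -((yy - by) ** 2 + (xx - bx) ** 2) / (2 * sig_px**2)
                )
            surf *= footprint  # puncta live on the bouton surface only
            if p.paint_paz_surface:
                vol[p.paz_slice] = np.maximum(vol[p.paz_slice], surf)
        elif role == ChannelRole.PAK:
            if p.pak_apposed and p.paint_paz_surface:
                surf = np.zeros((Y, X))
                for sy_, sx_ in seeds:
                    surf[np.hypot(yy - sy_, xx - sx_) <= p.pak_radius_px] = p.pak_amp
                vol[p.paz_slice] = surf * footprint
        elif role == ChannelRole.FASII:
            vol += fill * interior3d
            if p.paint_paz_surface:
                # distance to the nearest Voronoi edge: half the gap between
                # the two smallest site distances
                dsort = np.sort(np.sqrt(d2), axis=-1)
                d_edge = (dsort[..., 1] - dsort[..., 0]) / 2 if p.n_units > 1 else (
                    np.full((Y, X), np.inf)
                )
                sig = p.fasII_ridge_sigma_nm / p.lateral_nm_per_px
                ridge = p.fasII_ridge_amp * np.exp(-(d_edge**2) / (2 * sig**2))
                surf = np.where(footprint, p.core_level + ridge, 0.0)
                vol[p.paz_slice] = np.maximum(vol[p.paz_slice], surf)
        else:  # periactive-zone mesh channels
            vol += fill * interior3d
            if p.paint_paz_surface:
                R = float(p.mesh_enrichment.get(role_name, 1.0))
                surf = np.where(
                    footprint, p.core_level * np.where(mesh2d, R, 1.0), 0.0
                )
                vol[p.paz_slice] = np.maximum(vol[p.paz_slice], surf)
        vol += p.background_level
        if p.psf_fwhm_nm:
            for z in range(Z):
                vol[z] = _blur(vol[z], p.psf_fwhm_nm, p.lateral_nm_per_px)
        channels[role] = apply_noise(vol, p.poisson_scale, p.read_noise_sd, rng)

    volume = ImageVolume(channels, cal)
    truth = NmjGroundTruth(
        params=p,
        seed=p.seed,
        footprint=footprint,
        interior3d=interior3d,
        labels2d=labels2d,
        mesh2d=mesh2d & (labels2d > 0),
        unit_seeds_px=seeds,
        brp_positive=brp_positive,
        brp_centers_px=brp_centers,
        pak_apposed=p.pak_apposed,
        mesh_enrichment={k: float(v) for k, v in p.mesh_enrichment.items()},
        paz_slice=p.paz_slice,
    )
    return volume, truth
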