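"""Periactive-zone (PAZ) unit segmentation and per-unit statistics.

The NMJ surface is analyzed on a maximum-intensity projection of the
upper half of the stack.  A composite image (mesh channels summed, AZ
and postsynaptic channels subtracted) is bright on the PAZ mesh and dark
at unit centers; units are found as regional intensity minima expanded
by seeded region growing, restricted to the 2D presynaptic mask.  Units
hugging the bouton edge (low mean Euclidean-distance-map score) are
excluded as non-planar.  Each remaining unit is split into a *mesh* band
(a fixed-width ring inward from the unit boundary) and a *core*; the
per-channel polarization is the log ratio of mesh over core mean
intensity, positive meaning mesh enrichment.  Brp objects are counted
per NMJ area, and units are classified as Brp-containing and/or
Pak-apposed.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy import ndimage
from skimage import measure, morphology

from .bouton import auto_threshold, rolling_ball_subtract
from .config import ExperimentConfig
from .images import ChannelRole, ImageField, ImageVolume, MaskImage, nm_to_px

MESH_MEASURE_ROLES = (
    ChannelRole.NWK,
    ChannelRole.DYN,
    ChannelRole.ENDOA,
    ChannelRole.DAP160,
    ChannelRole.FASII,
    ChannelRole.BRP,
)


# --------------------------------------------------------------------------
# projection, mask, composite
# --------------------------------------------------------------------------


def upper_half_projection(volume: ImageVolume, cfg: ExperimentConfig) -> ImageField:
    """Per-channel maximum projection of the upper half of the stack.

    For odd Z the middle slice is included.  Which end of the stack is
    "upper" depends on acquisition; ``cfg.upper_half_first`` (default
    True) selects the first (Z+1)//2 slices.
    """
    Z = volume.shape[0]
    n = (Z + 1) // 2
    sl = slice(0, n) if cfg.upper_half_first else slice(Z - n, Z)
    channels = {role: vol[sl].max(axis=0) for role, vol in volume.channels.items()}
    return ImageField(channels, volume.calibration)


def total_mask_2d(field: ImageField, cfg: ExperimentConfig) -> MaskImage:
    """Auto-threshold of the sum of all channels.

    The threshold is computed on the log-transformed sum: fluorescence
    sums are strongly right-skewed (background / tissue / bright mesh),
    and log compression makes the background-tissue gap the dominant one
    so the mask captures the whole presynaptic area rather than only its
    brightest structures.
    """
    total = sum(field.channels.values())
    log_thr = auto_threshold(np.log1p(total), cfg.nmj_threshold_method)
    thr = float(np.expm1(log_thr))
    return MaskImage(
        total >= thr,
        {"method": "sum+log+" + cfg.nmj_threshold_method, "threshold": thr},
    )


@dataclass
class CompositeRecipe:
    """How to combine channels into the PAZ composite: positive roles are
    summed, negative roles subtracted, each mean-normalized first (so
    staining intensities are comparable) and the result clamped at 0."""

    positive: tuple
    negative: tuple = ()
    normalize: bool = True
    clamp: bool = True

    def __post_init__(self) -> None:
        self.positive = tuple(ChannelRole(r) for r in self.positive)
        self.negative = tuple(ChannelRole(r) for r in self.negative)
        if not self.positive:
            raise ValueError("at least one positive role required")


#: Standard composites: the default mesh recipe (Nwk + Dyn - Brp), the
#: Nwk-only variant for stainings without Brp, and the FasII-based recipe
#: used with Pak apposition (FasII - Brp - Pak).
COMPOSITE_RECIPES = {
    "default": CompositeRecipe(("nwk", "dyn"), ("brp",)),
    "nwk-only": CompositeRecipe(("nwk",), ()),
    "fasII": CompositeRecipe(("fasII",), ("brp", "pak")),
}


def paz_composite(field: ImageField, recipe: CompositeRecipe) -> np.ndarray:
    field.require(*recipe.positive, *recipe.negative)

    def norm(img):
        if not recipe.normalize:
            return img
        m = img.mean()
        if not m > 0:
            raise ValueError("channel with zero mean cannot be normalized")
        return img / m

    out = sum(norm(field[r]) for r in recipe.positive)
    out = out - sum((norm(field[r]) for r in recipe.negative), np.zeros(field.shape))
    if recipe.clamp:
        out = np.clip(out, 0.0, None)
    return out


# --------------------------------------------------------------------------
# seeded region growing
# --------------------------------------------------------------------------

_NEIGHBORS8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]


def seeded_region_growing(
    image: np.ndarray, seeds: np.ndarray, mask: np.ndarray
) -> np.ndarray:
    """Priority expansion of labeled seeds in ascending image intensity,
    restricted to the mask, until every mask pixel is labeled.

    Deterministic tie-breaking: among frontier claims of equal intensity,
    the earliest-inserted claim wins (seeds are enqueued in raster order),
    so competing floods meet midway on ridge crests instead of one label
    systematically annexing them.  8-connected.
    """
    image = np.asarray(image, dtype=np.float64)
    mask = np.asarray(mask, dtype=bool)
    labels = np.asarray(seeds).astype(np.int32).copy()
    labels[~mask] = 0
    if not (labels > 0).any():
        raise ValueError("no seeds inside mask")
    H, W = image.shape
    heap: list = []
    order = 0
    ys, xs = np.nonzero(labels > 0)
    for y, x in zip(ys.tolist(), xs.tolist()):
        lab = int(labels[y, x])
        for dy, dx in _NEIGHBORS8:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and labels[ny, nx] == 0:
                heapq.heappush(heap, (image[ny, nx], order, lab, ny, nx))
                order += 1
    while heap:
        _val, _order, lab, y, x = heapq.heappop(heap)
        if labels[y, x] != 0:
            continue
        labels[y, x] = lab
        for dy, dx in _NEIGHBORS8:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and labels[ny, nx] == 0:
                heapq.heappush(heap, (image[ny, nx], order, lab, ny, nx))
                order += 1
    return labels


def detect_minima_seeds(
    composite: np.ndarray, mask: np.ndarray, cfg: ExperimentConfig
) -> tuple:
    """Regional minima of the lightly smoothed composite within the mask,
    suppressed by depth h = minima_depth_factor * MAD(composite | mask).

    Returns ``(seed_labels, smoothed_composite)``.
    """
    mask = np.asarray(mask, dtype=bool)
    # normalized convolution: smooth using in-mask values only, so the mask
    # rim is not dragged toward the background and does not grow false minima
    comp = np.where(mask, np.asarray(composite, float), 0.0)
    num = ndimage.gaussian_filter(comp, cfg.seed_smooth_sigma_px)
    den = ndimage.gaussian_filter(mask.astype(float), cfg.seed_smooth_sigma_px)
    smooth = np.divide(num, den, out=np.zeros_like(num), where=den > 1e-12)
    inside = smooth[mask]
    if inside.size == 0:
        raise ValueError("mask is empty")
    if np.ptp(inside) == 0:
        raise ValueError("flat composite: no seeds found")
    med = np.median(inside)
    mad = float(np.median(np.abs(inside - med)))
    h = cfg.minima_depth_factor * mad
    work = smooth.copy()
    work[~mask] = smooth.max() + 1.0
    if h > 0:
        # classical h-minima: fill basins shallower than h by reconstruction,
        # then take regional minima of the filled surface (robust to the
        # floating-point residue comparison inside skimage's h_minima)
        filled = morphology.reconstruction(work + h, work, method="erosion")
        minima = morphology.local_minima(filled)
    else:
        minima = morphology.local_minima(work)
    minima &= mask
    seeds = measure.label(minima, connectivity=2)
    if seeds.max() == 0:
        raise ValueError("no seeds found (composite too shallow)")
    return seeds.astype(np.int32), smooth


def segment_paz_units(
    composite: np.ndarray, mask: MaskImage, cfg: ExperimentConfig
) -> np.ndarray:
    """Full unit segmentation: minima seeds + seeded region growing on the
    smoothed composite.  Returns a label image partitioning the mask."""
    pixels = mask.pixels if isinstance(mask, MaskImage) else np.asarray(mask, bool)
    seeds, smooth = detect_minima_seeds(composite, pixels, cfg)
    return seeded_region_growing(smooth, seeds, pixels)


# --------------------------------------------------------------------------
# unit geometry and statistics
# --------------------------------------------------------------------------


def unit_edm_scores(labels: np.ndarray, mask) -> dict:
    """Mean Euclidean-distance-map score per unit: per-pixel distance to the
    nearest background pixel of the mask, averaged over unit pixels."""
    pixels = mask.pixels if isinstance(mask, MaskImage) else np.asarray(mask, bool)
    edm = ndimage.distance_transform_edt(pixels)
    out = {}
    for lab in np.unique(labels[labels > 0]):
        out[int(lab)] = float(edm[labels == lab].mean())
    return out


def boundary_pixels(labels: np.ndarray) -> np.ndarray:
    """Labeled pixels 8-adjacent to a different label, to background, or to
    the image border."""
    padded = np.pad(labels, 1, constant_values=-1)
    center = padded[1:-1, 1:-1]
    boundary = np.zeros(labels.shape, dtype=bool)
    for dy, dx in _NEIGHBORS8:
        neigh = padded[1 + dy : 1 + dy + labels.shape[0], 1 + dx : 1 + dx + labels.shape[1]]
        boundary |= neigh != center
    return boundary & (labels > 0)


def mesh_core_masks(labels: np.ndarray, width_px: int) -> tuple:
    """Split every unit into mesh (pixels strictly closer than ``width_px``
    to a boundary pixel) and core (the remainder).  Mesh and core
    partition the labeled area."""
    boundary = boundary_pixels(labels)
    if not boundary.any():
        mesh = np.zeros(labels.shape, dtype=bool)
    else:
        dist = ndimage.distance_transform_edt(~boundary)
        mesh = dist < width_px
    mesh = mesh & (labels > 0)
    core = (labels > 0) & ~mesh
    return mesh, core


@dataclass
class PazUnit:
    label: int
    n_px: int
    seed_px: tuple | None
    mean_edm_px: float
    edge_excluded: bool
    mesh_px: int
    core_px: int
    core_empty: bool
    mesh_mean: dict = dc_field(default_factory=dict)  # role name -> mean
    core_mean: dict = dc_field(default_factory=dict)
    polarization: dict = dc_field(default_factory=dict)  # None when undefined
    brp_object_labels: list = dc_field(default_factory=list)
    brp_positive: bool = False
    pak_apposed: bool = False


@dataclass
class BrpObject:
    label: int
    area_px: int
    centroid_nm: tuple
    centroid_px: tuple
    integrated: float  # area x mean on the background-subtracted projection
    owning_unit: int | None = None


@dataclass
class PazSummary:
    nmj_id: str
    n_units_total: int
    n_units_analyzed: int
    brp_density_per_um2: float | None
    mean_brp_integrated: float | None
    mesh_mean: dict  # role -> mean over analyzed units of unit mesh means
    mean_polarization: dict  # role -> mean over units with defined polarization
    pct_brp_positive: float | None
    pct_pak_apposed: float | None


def polarization(mesh_mean: float, core_mean: float, cfg: ExperimentConfig):
    """Log-ratio of mesh over core mean intensity (base
    ``polarization_log_base``); positive = mesh-enriched.  Undefined
    (None) unless both means are positive."""
    if not (mesh_mean > 0 and core_mean > 0):
        return None
    return float(np.log(mesh_mean / core_mean) / np.log(cfg.polarization_log_base))


def brp_objects_and_density(
    field: ImageField, mask: MaskImage, cfg: ExperimentConfig
) -> tuple:
    """Brp objects (thresholded connected components of the
    background-subtracted Brp projection within the mask) and their count
    per um^2 of mask area."""
    field.require(ChannelRole.BRP)
    if not mask.pixels.any():
        raise ValueError("mask is empty")
    lat = field.calibration.lateral_nm_per_px
    sub = rolling_ball_subtract(
        field[ChannelRole.BRP], cfg.rolling_ball_radius_px, presmooth=True
    )
    thr = cfg.channel_thresholds.get("brp")
    if thr is None:
        # threshold on in-mask values: outside-mask background would skew it
        thr = auto_threshold(sub[mask.pixels], "otsu")
    fg = (sub >= float(thr)) & mask.pixels
    lab = measure.label(fg, connectivity=2)
    objects = []
    for prop in measure.regionprops(lab, intensity_image=sub):
        if prop.area < cfg.min_size_px:
            continue
        cy, cx = prop.centroid
        objects.append(
            BrpObject(
                label=int(prop.label),
                area_px=int(prop.area),
                centroid_nm=((cy + 0.5) * lat, (cx + 0.5) * lat),
                centroid_px=(cy, cx),
                integrated=float(prop.area) * float(prop.intensity_mean),
            )
        )
    area_um2 = mask.area_px * lat * lat / 1e6
    return objects, len(objects) / area_um2


def classify_units(units, brp_objects, labels, pak_channel, cfg: ExperimentConfig):
    """Flag units as Brp-positive (>= 1 Brp object centroid inside) and
    Pak-apposed (>= min_pak_px thresholded Pak pixels inside)."""
    by_label = {u.label: u for u in units}
    for obj in brp_objects:
        iy = int(round(obj.centroid_px[0]))
        ix = int(round(obj.centroid_px[1]))
        if 0 <= iy < labels.shape[0] and 0 <= ix < labels.shape[1]:
            lab = int(labels[iy, ix])
            if lab in by_label:
                obj.owning_unit = lab
                by_label[lab].brp_positive = True
                by_label[lab].brp_object_labels.append(obj.label)
    if pak_channel is not None:
        thr = cfg.channel_thresholds.get("pak")
        if thr is None:
            thr = auto_threshold(np.asarray(pak_channel), cfg.nmj_threshold_method)
        pak_fg = np.asarray(pak_channel) >= float(thr)
        for u in units:
            n_pak = int((pak_fg & (labels == u.label)).sum())
            u.pak_apposed = n_pak >= cfg.min_pak_px
    return units


def analyze_paz(
    volume: ImageVolume,
    cfg: ExperimentConfig,
    recipe: CompositeRecipe | str = "default",
    measure_roles=None,
    nmj_id: str = "",
):
    """Full PAZ pipeline on one NMJ volume.

    Returns ``(units, brp_objects, summary, labels, field)``.
    """
    if isinstance(recipe, str):
        recipe = COMPOSITE_RECIPES[recipe]
    field = upper_half_projection(volume, cfg)
    mask = total_mask_2d(field, cfg)
    comp = paz_composite(field, recipe)
    labels = segment_paz_units(comp, mask, cfg)
    edm_scores = unit_edm_scores(labels, mask)
    width_px = nm_to_px(cfg.mesh_width_nm, field.calibration)
    mesh, core = mesh_core_masks(labels, width_px)

    if measure_roles is None:
        measure_roles = [r for r in MESH_MEASURE_ROLES if r in field]
    else:
        measure_roles = [ChannelRole(r) for r in measure_roles]

    # mesh/core intensities are measured after removing the extracellular
    # background, estimated as the median intensity outside the 2D mask
    measured = {}
    outside = ~mask.pixels
    for role in measure_roles:
        img = field[role]
        bg = float(np.median(img[outside])) if outside.any() else 0.0
        measured[role] = np.clip(img - bg, 0.0, None)

    units = []
    for lab, score in sorted(edm_scores.items()):
        upix = labels == lab
        umesh = upix & mesh
        ucore = upix & core
        unit = PazUnit(
            label=lab,
            n_px=int(upix.sum()),
            seed_px=None,
            mean_edm_px=score,
            edge_excluded=score < cfg.edm_edge_cutoff_px,
            mesh_px=int(umesh.sum()),
            core_px=int(ucore.sum()),
            core_empty=not ucore.any(),
        )
        for role in measure_roles:
            img = measured[role]
            mm = float(img[umesh].mean()) if unit.mesh_px else float("nan")
            cm = float(img[ucore].mean()) if unit.core_px else float("nan")
            unit.mesh_mean[role.value] = mm
            unit.core_mean[role.value] = cm
            if unit.core_empty or not (mm > 0 and cm > 0):
                unit.polarization[role.value] = None
            else:
                unit.polarization[role.value] = polarization(mm, cm, cfg)
        units.append(unit)

    brp_objs, density = ([], None)
    if ChannelRole.BRP in field:
        brp_objs, density = brp_objects_and_density(field, mask, cfg)
    pak = field[ChannelRole.PAK] if ChannelRole.PAK in field else None
    classify_units(units, brp_objs, labels, pak, cfg)

    analyzed = [u for u in units if not u.edge_excluded]
    summary = PazSummary(
        nmj_id=nmj_id,
        n_units_total=len(units),
        n_units_analyzed=len(analyzed),
        brp_density_per_um2=density,
        mean_brp_integrated=(
            float(np.mean([o.integrated for o in brp_objs])) if brp_objs else None
        ),
        mesh_mean={
            r.value: float(np.mean([u.mesh_mean[r.value] for u in analyzed]))
            for r in measure_roles
            if analyzed
        },
        mean_polarization={
            r.value: (
                float(np.mean(vals))
                if (
                    vals := [
                        u.polarization[r.value]
                        for u in analyzed
                        if u.polarization[r.value] is not None
                    ]
                )
                else None
            )
            for r in measure_roles
        },
        pct_brp_positive=(
            100.0 * sum(u.brp_positive for u in analyzed) / len(analyzed)
            if analyzed and ChannelRole.BRP in field
            else None
        ),
        pct_pak_apposed=(
            100.0 * sum(u.pak_apposed for u in analyzed) / len(analyzed)
            if analyzed and pak is not None
            else None
        ),
    )
    return units, brp_objs, summary, labels, field
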