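import numpy as np
import pytest

from pazquant import synth
from pazquant.images import ImageField, ImageVolume, MaskImage, PixelCalibration
from pazquant.paz import (
    CompositeRecipe,
    analyze_paz,
    boundary_pixels,
    brp_objects_and_density,
    mesh_core_masks,
    paz_composite,
    polarization,
    seeded_region_growing,
    segment_paz_units,
    total_mask_2d,
    unit_edm_scores,
    upper_half_projection,
)

from conftest import match_units

CAL = PixelCalibration(50.0, 150.0)
CAL25 = PixelCalibration(25.0, 150.0)


def growing_oracle(image, seeds, mask):
    """Brute-force priority expansion: a plain list of pending claims,
    scanned linearly for the minimum (value, insertion order) at every
    step.  Same growth rule as the pipeline, independent mechanics."""
    image = np.asarray(image, float)
    mask = np.asarray(mask, bool)
    labels = np.asarray(seeds).astype(int).copy()
    labels[~mask] = 0
    H, W = image.shape
    neigh = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    pending = []
    counter = 0

    def push_neighbors(y, x, lab):
        nonlocal counter
        for dy, dx in neigh:
            ny, nx = y + dy, x + dx
            if 0 <= ny < H and 0 <= nx < W and mask[ny, nx] and labels[ny, nx] == 0:
                pending.append((image[ny, nx], counter, lab, ny, nx))
                counter += 1

    ys, xs = np.nonzero(labels > 0)
    for y, x in zip(ys.tolist(), xs.tolist()):
        push_neighbors(y, x, int(labels[y, x]))
    while pending:
        i_best = min(range(len(pending)), key=lambda i: pending[i][:2])
        _v, _c, lab, y, x = pending.pop(i_best)
        if labels[y, x] != 0:
            continue
        labels[y, x] = lab
        push_neighbors(y, x, lab)
    return labels


class TestProjection:
    def _vol(self, z):
        data = np.zeros((z, 6, 6))
        return data

    def test_value_in_upper_half_included(self, cfg):
        data = self._vol(4)
        data[1, 3, 3] = 9.0
        vol = ImageVolume({"brp": data}, CAL)
        proj = upper_half_projection(vol, cfg)
        assert proj["brp"][3, 3] == 9.0

    def test_value_in_lower_half_excluded(self, cfg):
        data = self._vol(4)
        data[3, 3, 3] = 9.0
        vol = ImageVolume({"brp": data}, CAL)
        proj = upper_half_projection(vol, cfg)
        assert proj["brp"][3, 3] == 0.0

    def test_odd_z_includes_middle_slice(self, cfg):
        data = self._vol(5)
        data[2, 1, 1] = 5.0  # middle slice
        data[3, 2, 2] = 7.0  # just past the middle
        vol = ImageVolume({"brp": data}, CAL)
        proj = upper_half_projection(vol, cfg)
        assert proj["brp"][1, 1] == 5.0 and proj["brp"][2, 2] == 0.0

    def test_upper_half_flag_flips_selection(self, cfg):
        data = self._vol(4)
        data[3, 3, 3] = 9.0
        vol = ImageVolume({"brp": data}, CAL)
        proj = upper_half_projection(vol, cfg.replace(upper_half_first=False))
        assert proj["brp"][3, 3] == 9.0


class TestTotalMask:
    def test_bimodal_sum_recovers_bright_region(self, cfg):
        img = np.full((40, 40), 10.0)
        img[10:30, 10:30] = 200.0
        field = ImageField({"nwk": img, "dyn": img}, CAL)
        mask = total_mask_2d(field, cfg)
        np.testing.assert_array_equal(mask.pixels, img >= 200.0)

    def test_constant_sum_rejected(self, cfg):
        field = ImageField({"nwk": np.ones((10, 10))}, CAL)
        with pytest.raises(ValueError, match="constant"):
            total_mask_2d(field, cfg)


class TestComposite:
    def test_constants_normalize_to_two(self):
        field = ImageField(
            {"nwk": np.full((8, 8), 7.0), "dyn": np.full((8, 8), 300.0),
             "brp": np.zeros((8, 8))},
            CAL,
        )
        comp = paz_composite(field, CompositeRecipe(("nwk", "dyn")))
        np.testing.assert_allclose(comp, 2.0)

    def test_clamped_at_zero_where_negative_dominates(self):
        nwk = np.full((8, 8), 1.0)
        brp = np.full((8, 8), 1.0)
        brp[4, 4] = 50.0
        field = ImageField({"nwk": nwk, "brp": brp}, CAL)
        comp = paz_composite(field, CompositeRecipe(("nwk",), ("brp",)))
        assert comp[4, 4] == 0.0

    def test_zero_mean_channel_rejected(self):
        field = ImageField({"nwk": np.zeros((8, 8))}, CAL)
        with pytest.raises(ValueError, match="zero mean"):
            paz_composite(field, CompositeRecipe(("nwk",)))


class TestRegionGrowing:
    def test_two_basins_split_on_ridge_crest(self):
        x = np.arange(16.0)
        ridge = np.exp(-((x - 7.5) ** 2) / 4.0)
        image = np.tile(ridge, (16, 1))
        seeds = np.zeros((16, 16), int)
        seeds[8, 2], seeds[8, 13] = 1, 2
        mask = np.ones((16, 16), bool)
        labels = seeded_region_growing(image, seeds, mask)
        assert (labels[:, :8] == 1).all()
        assert (labels[:, 8:] == 2).all()

    @pytest.mark.parametrize("trial", range(6))
    def test_matches_brute_force_oracle(self, trial):
        rng = np.random.default_rng(trial)
        image = rng.uniform(0, 1, (12, 12))
        mask = rng.uniform(size=(12, 12)) > 0.15
        seeds = np.zeros((12, 12), int)
        placed = 0
        while placed < 3:
            y, x = rng.integers(12), rng.integers(12)
            if mask[y, x] and seeds[y, x] == 0:
                placed += 1
                seeds[y, x] = placed
        got = seeded_region_growing(image, seeds, mask)
        expected = growing_oracle(image, seeds, mask)
        np.testing.assert_array_equal(got, expected)

    def test_matches_watershed_on_unambiguous_basins(self):
        """On an asymmetric V-ridge where every pixel has a unique basin,
        the flood agrees with the classical marker watershed exactly."""
        from skimage.segmentation import watershed

        x = np.arange(14.0)
        image = np.tile(10.0 - np.abs(x - 7.3), (14, 1))
        seeds = np.zeros((14, 14), int)
        seeds[7, 0], seeds[7, 13] = 1, 2
        mask = np.ones((14, 14), bool)
        got = seeded_region_growing(image, seeds, mask)
        ws = watershed(image, markers=seeds, mask=mask, connectivity=2)
        np.testing.assert_array_equal(got, ws)
        assert (got[:, :8] == 1).all() and (got[:, 8:] == 2).all()

    def test_labels_partition_mask(self):
        rng = np.random.default_rng(7)
        image = rng.uniform(0, 1, (20, 20))
        mask = rng.uniform(size=(20, 20)) > 0.2
        seeds = np.zeros((20, 20), int)
        ys, xs = np.nonzero(mask)
        for i, j in enumerate(rng.choice(len(ys), 4, replace=False)):
            seeds[ys[j], xs[j]] = i + 1
        labels = seeded_region_growing(image, seeds, mask)
        assert (labels[mask] > 0).all()
        assert (labels[~mask] == 0).all()

    def test_no_seeds_rejected(self):
        with pytest.raises(ValueError, match="seed"):
            seeded_region_growing(
                np.ones((5, 5)), np.zeros((5, 5), int), np.ones((5, 5), bool)
            )

    def test_flat_composite_has_no_seeds(self, cfg):
        mask = MaskImage(np.ones((20, 20), bool), {"method": "full"})
        with pytest.raises(ValueError, match="flat"):
            segment_paz_units(np.ones((20, 20)), mask, cfg)


class TestEdgeExclusion:
    def test_edm_matches_all_pairs_oracle(self):
        mask = np.zeros((9, 9), bool)
        mask[2:7, 2:7] = True  # 5x5 square
        labels = mask.astype(int)
        from scipy import ndimage

        edm = ndimage.distance_transform_edt(mask)
        bg = np.array(np.nonzero(~mask)).T
        for y, x in np.array(np.nonzero(mask)).T:
            oracle = np.sqrt(((bg - [y, x]) ** 2).sum(axis=1)).min()
            assert edm[y, x] == pytest.approx(oracle)

    def test_edge_unit_flagged_interior_kept(self, cfg):
        mask = np.zeros((40, 40), bool)
        mask[2:38, 2:38] = True
        labels = np.zeros((40, 40), int)
        labels[2:38, 2:6] = 1  # strip hugging the border: mean EDM ~ 2
        labels[14:26, 14:26] = 2  # deep interior block
        scores = unit_edm_scores(labels, MaskImage(mask, {"m": 1}))
        assert scores[1] < cfg.edm_edge_cutoff_px
        assert scores[2] > cfg.edm_edge_cutoff_px


class TestMeshCoreSplit:
    def test_square_unit_inner_core(self):
        """A 20x20 px unit at 25 nm/px with a 175 nm mesh (7 px) keeps an
        inner 6x6 core."""
        labels = np.zeros((30, 30), int)
        labels[5:25, 5:25] = 1
        from pazquant.images import nm_to_px

        w = nm_to_px(175.0, CAL25)
        assert w == 7
        mesh, core = mesh_core_masks(labels, w)
        expected_core = np.zeros((30, 30), bool)
        expected_core[12:18, 12:18] = True
        np.testing.assert_array_equal(core, expected_core)
        # per-pixel distance oracle
        bd = boundary_pixels(labels)
        bpix = np.array(np.nonzero(bd)).T
        for y, x in np.array(np.nonzero(labels > 0)).T:
            d = np.sqrt(((bpix - [y, x]) ** 2).sum(axis=1)).min()
            assert mesh[y, x] == (d < w)

    def test_thin_unit_has_empty_core(self):
        labels = np.zeros((20, 20), int)
        labels[8:12, 2:18] = 1  # 4 px wide, mesh width 7 px
        mesh, core = mesh_core_masks(labels, 7)
        assert not core.any()
        np.testing.assert_array_equal(mesh, labels > 0)

    def test_partition_contract(self, nmj_scene_clean):
        _, _, truth = nmj_scene_clean
        mesh, core = mesh_core_masks(truth.labels2d, 4)
        assert not (mesh & core).any()
        np.testing.assert_array_equal(mesh | core, truth.labels2d > 0)


class TestPolarization:
    def test_equal_means_give_zero(self, cfg):
        assert polarization(5.0, 5.0, cfg) == 0.0

    def test_factor_two_gives_one(self, cfg):
        assert polarization(10.0, 5.0, cfg) == pytest.approx(1.0)

    def test_swap_flips_sign_exactly(self, cfg):
        a = polarization(7.3, 2.1, cfg)
        b = polarization(2.1, 7.3, cfg)
        assert a == -b

    def test_nonpositive_mean_undefined(self, cfg):
        assert polarization(0.0, 5.0, cfg) is None


class TestBrpObjects:
    def test_density_arithmetic(self, cfg, nmj_scene_clean):
        p, vol, truth = nmj_scene_clean
        field = upper_half_projection(vol, cfg)
        mask = total_mask_2d(field, cfg)
        cfg1 = cfg.replace(channel_thresholds={"brp": 100.0})
        objs, density = brp_objects_and_density(field, mask, cfg1)
        area_um2 = mask.area_px * 50 * 50 / 1e6
        assert density == pytest.approx(len(objs) / area_um2)

    def test_noise_free_puncta_recovered_exactly(self, cfg):
        p = synth.SynthNmjParams(
            n_units=20, brp_fraction=0.6, poisson_scale=0, read_noise_sd=0, seed=6
        )
        vol, truth = synth.generate_nmj_volume(p)
        field = upper_half_projection(vol, cfg)
        mask = total_mask_2d(field, cfg)
        cfg1 = cfg.replace(channel_thresholds={"brp": 100.0})
        objs, density = brp_objects_and_density(field, mask, cfg1)
        assert len(objs) == 12  # round(0.6 * 20) puncta placed
        for o in objs:
            cy, cx = o.centroid_px
            d = min(np.hypot(cy - ty, cx - tx) for ty, tx in truth.brp_centers_px)
            assert d <= 1.0 + 1e-9


class TestFullPipeline:
    def test_voronoi_scene_units_recovered(self, cfg, nmj_scene_clean):
        """K=20 noise-free scene: 20 units, label-to-truth matching gives
        per-unit Jaccard >= 0.8."""
        p, vol, truth = nmj_scene_clean
        cfg1 = cfg.replace(channel_thresholds={"brp": 100.0})
        units, objs, summary, labels, field = analyze_paz(vol, cfg1, recipe="fasII")
        assert summary.n_units_total == p.n_units
        for rec_lab, true_lab in match_units(labels, truth.labels2d):
            A = labels == rec_lab
            B = truth.labels2d == true_lab
            jac = (A & B).sum() / (A | B).sum()
            assert jac >= 0.8

    def test_classification_flags_match_truth(self, cfg, nmj_scene_clean):
        p, vol, truth = nmj_scene_clean
        cfg1 = cfg.replace(channel_thresholds={"brp": 100.0})
        units, objs, summary, labels, field = analyze_paz(vol, cfg1, recipe="fasII")
        by_label = {u.label: u for u in units}
        for rec_lab, true_lab in match_units(labels, truth.labels2d):
            u = by_label[rec_lab]
            if not u.edge_excluded:
                assert u.brp_positive == bool(truth.brp_positive[true_lab - 1])
                assert u.pak_apposed
        assert summary.pct_pak_apposed == 100.0

    def test_mesh_core_partition_on_every_unit(self, cfg, nmj_scene_clean):
        _, vol, truth = nmj_scene_clean
        cfg1 = cfg.replace(channel_thresholds={"brp": 100.0})
        units, _, _, labels, _ = analyze_paz(vol, cfg1, recipe="fasII")
        for u in units:
            assert u.mesh_px + u.core_px == u.n_px
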