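import numpy as np
import pytest

from tfkscope import (CapacityError, SynthConfig, generate_sample,
                      place_cells, place_regions, render_image)
from tfkscope.regions import rasterize_geometry
from tfkscope.synthetic import CHANNELS, MARKER_MAP


def small_config(**kw):
    defaults = dict(
        image_shape=(256, 256), n_follicles=1, follicle_radius_px=70,
        follicle_radius_sd=3,
        cell_counts={"B": 5, "GC-B": 8, "T_FH": 5, "T_FK": 3, "Treg": 4,
                     "other": 3},
        planted_contact_pairs=1, noise_sd=0.0, background_amplitude=0.0,
        seed=4,
    )
    defaults.update(kw)
    return SynthConfig(**defaults)


class TestConfigValidation:
    def test_bad_gc_fraction(self):
        with pytest.raises(ValueError):
            SynthConfig(gc_fraction=1.5)

    def test_negative_count(self):
        with pytest.raises(ValueError):
            SynthConfig(cell_counts={"B": -1})

    def test_placement_probs_must_sum_to_one(self):
        probs = SynthConfig().region_placement_probs
        probs["B"] = {"GC": 0.5, "follicle": 0.2, "extrafollicular": 0.2}
        with pytest.raises(ValueError, match="sum"):
            SynthConfig(region_placement_probs=probs)

    def test_contact_pairs_bounded_by_counts(self):
        with pytest.raises(ValueError):
            small_config(planted_contact_pairs=5)  # only 3 T_FK


class TestPlaceRegions:
    def test_zero_follicles_empty(self):
        cfg = small_config(n_follicles=0)
        regions = place_regions(cfg, np.random.default_rng(0))
        assert regions.follicles == [] and regions.gcs == []

    def test_each_gc_strictly_inside_its_follicle(self):
        cfg = small_config(n_follicles=3, image_shape=(512, 512),
                           gc_fraction=0.5)
        regions = place_regions(cfg, np.random.default_rng(1))
        assert len(regions.follicles) == 3 and len(regions.gcs) == 3
        for gc in regions.gcs:
            fol = regions.follicle(gc.parent_follicle_id)
            assert gc.geometry.area < fol.geometry.area
            assert fol.geometry.contains(gc.geometry)

    def test_follicles_pairwise_disjoint_rasterized(self):
        cfg = SynthConfig(seed=1, n_follicles=5, image_shape=(1024, 1024))
        regions = place_regions(cfg, np.random.default_rng(1))
        masks = [rasterize_geometry(f.geometry, cfg.image_shape)
                 for f in regions.follicles]
        for i in range(len(masks)):
            for j in range(i + 1, len(masks)):
                assert (masks[i] & masks[j]).sum() == 0

    def test_capacity_error_when_image_too_small(self):
        cfg = small_config(n_follicles=6, image_shape=(200, 200),
                           follicle_radius_px=80)
        with pytest.raises(CapacityError):
            place_regions(cfg, np.random.default_rng(0))


class TestPlaceCells:
    def test_zero_counts_give_empty_truth(self):
        cfg = small_config(
            cell_counts={t: 0 for t in MARKER_MAP}, planted_contact_pairs=0)
        regions = place_regions(cfg, np.random.default_rng(0))
        truth = place_cells(cfg, regions, np.random.default_rng(0))
        assert truth.cells == [] and truth.contacts == []

    def test_degenerate_placement_prob_pins_region(self):
        probs = SynthConfig().region_placement_probs
        probs["GC-B"] = {"GC": 1.0, "follicle": 0.0, "extrafollicular": 0.0}
        cfg = small_config(
            cell_counts={"B": 0, "GC-B": 10, "T_FH": 0, "T_FK": 0,
                         "Treg": 0, "other": 0},
            planted_contact_pairs=0, region_placement_probs=probs)
        rng = np.random.default_rng(2)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        assert len(truth.cells) == 10
        assert all(c.true_region == "GC" for c in truth.cells)

    def test_contact_pairs_touch_exactly(self):
        cfg = small_config(
            image_shape=(512, 512), follicle_radius_px=90,
            cell_counts={"B": 0, "GC-B": 0, "T_FH": 0, "T_FK": 8,
                         "Treg": 8, "other": 0},
            planted_contact_pairs=4)
        rng = np.random.default_rng(3)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        assert len(truth.contacts) == 4
        by_id = {c.cell_id: c for c in truth.cells}
        for tfk_id, treg_id in truth.contacts:
            tfk, treg = by_id[tfk_id], by_id[treg_id]
            assert tfk.cell_type == "T_FK" and treg.cell_type == "Treg"
            d = np.hypot(tfk.centroid_px[0] - treg.centroid_px[0],
                         tfk.centroid_px[1] - treg.centroid_px[1])
            assert d == pytest.approx(tfk.radius_px + treg.radius_px,
                                      abs=0.5)

    def test_non_contact_cells_separated_by_radius_sum(self):
        cfg = small_config()
        rng = np.random.default_rng(5)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        contact_pairs = {frozenset(p) for p in truth.contacts}
        cells = truth.cells
        for i in range(len(cells)):
            for j in range(i + 1, len(cells)):
                a, b = cells[i], cells[j]
                if frozenset((a.cell_id, b.cell_id)) in contact_pairs:
                    continue
                d = np.hypot(a.centroid_px[0] - b.centroid_px[0],
                             a.centroid_px[1] - b.centroid_px[1])
                assert d >= a.radius_px + b.radius_px

    def test_true_region_matches_rasterized_geometry(self):
        cfg = small_config(seed=6)
        rng = np.random.default_rng(6)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        gc_mask = np.zeros(cfg.image_shape, bool)
        fol_mask = np.zeros(cfg.image_shape, bool)
        for g in truth.regions.gcs:
            gc_mask |= rasterize_geometry(g.geometry, cfg.image_shape)
        for f in truth.regions.follicles:
            fol_mask |= rasterize_geometry(f.geometry, cfg.image_shape)
        for c in truth.cells:
            r, col = int(round(c.centroid_px[0])), int(round(c.centroid_px[1]))
            if c.true_region == "GC":
                assert gc_mask[r, col]
            elif c.true_region == "follicle":
                assert fol_mask[r, col] and not gc_mask[r, col]
            else:
                assert not fol_mask[r, col]


class TestRender:
    def test_zero_cells_zero_noise_all_zero(self):
        cfg = small_config(
            cell_counts={t: 0 for t in MARKER_MAP}, planted_contact_pairs=0)
        rng = np.random.default_rng(0)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        img = render_image(truth, cfg, rng)
        for name in CHANNELS:
            assert not img.channel(name).any()

    def test_single_tfk_marker_signature(self):
        cfg = small_config(
            cell_counts={"B": 0, "GC-B": 0, "T_FH": 0, "T_FK": 1,
                         "Treg": 0, "other": 0},
            planted_contact_pairs=0)
        rng = np.random.default_rng(1)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        img = render_image(truth, cfg, rng)
        r, c = (int(round(v)) for v in truth.cells[0].centroid_px)
        for name in ("CD4", "BCL6", "TIA1"):
            assert img.channel(name)[r, c] > 0
        for name in ("CD19", "FOXP3"):
            assert img.channel(name)[r, c] == 0

    def test_psf_blur_preserves_flux(self):
        cfg = small_config(
            cell_counts={"B": 0, "GC-B": 0, "T_FH": 1, "T_FK": 0,
                         "Treg": 0, "other": 0},
            planted_contact_pairs=0)
        rng = np.random.default_rng(2)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        blurred = render_image(truth, cfg, np.random.default_rng(2))
        cfg_sharp = small_config(
            cell_counts=cfg.cell_counts, planted_contact_pairs=0,
            psf_sigma_px=0.0)
        sharp = render_image(truth, cfg_sharp, np.random.default_rng(2))
        for name in ("CD4", "BCL6"):
            assert blurred.channel(name).sum() == pytest.approx(
                sharp.channel(name).sum(), rel=0.01)

    def test_planted_tfk_positive_in_exactly_its_channels(self, noise0_run):
        truth, img, _ = noise0_run
        for cell in truth.cells_of_type("T_FK")[:5]:
            r, c = (int(round(v)) for v in cell.centroid_px)
            pos = {name for name in CHANNELS if img.channel(name)[r, c]
                   > 2 * 20.0}  # above any background level
            assert pos == {"CD4", "BCL6", "TIA1"}

    def test_generation_is_deterministic(self):
        cfg = small_config(noise_sd=7.0, background_amplitude=10.0)
        t1, img1 = generate_sample(cfg)
        t2, img2 = generate_sample(cfg)
        assert [c.centroid_px for c in t1.cells] == \
               [c.centroid_px for c in t2.cells]
        for name in CHANNELS:
            np.testing.assert_array_equal(img1.channel(name),
                                          img2.channel(name))

    def test_unknown_cell_type_rejected(self):
        cfg = small_config()
        rng = np.random.default_rng(0)
        truth = place_cells(cfg, place_regions(cfg, rng), rng)
        truth.cells[0].cell_type = "mystery"
        with pytest.raises(ValueError, match="mystery"):
            render_image(truth, cfg, rng)
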