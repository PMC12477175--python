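import numpy as np
import pytest
from shapely.geometry import Point, box

from tfkscope import (RegionSet, SynthConfig, assign_cells, auto_regions,
                      export_regions, generate_sample, import_regions,
                      measure_regions)
from tfkscope.ijroi import write_roi_zip
from tfkscope.phenotype import SubtypeCall
from tfkscope.regions import Follicle, GerminalCenter, rasterize_geometry
from tfkscope.segment import threshold_channel


def square(x0, y0, side):
    """Square polygon covering pixel centers x0..x0+side-1 (area side²)."""
    return box(x0 - 0.5, y0 - 0.5, x0 + side - 0.5, y0 + side - 0.5)


def roi_coords(poly):
    xs, ys = np.asarray(poly.exterior.coords).T
    return xs, ys


class TestImportRegions:
    def test_parentage_inferred_by_containment(self, tmp_path):
        path = tmp_path / "rois.zip"
        write_roi_zip(path, {
            "follicle_a": roi_coords(square(0, 0, 40)),
            "follicle_b": roi_coords(square(60, 60, 40)),
            "gc_a": roi_coords(square(10, 10, 15)),
            "gc_b": roi_coords(square(70, 70, 15)),
        })
        regions = import_regions(path)
        assert len(regions.follicles) == 2 and len(regions.gcs) == 2
        parents = {g.gc_id: g.parent_follicle_id for g in regions.gcs}
        for g in regions.gcs:
            fol = regions.follicle(g.parent_follicle_id)
            assert fol.geometry.contains(g.geometry)
        assert len(set(parents.values())) == 2
        regions.validate_nesting()

    def test_empty_archive_gives_empty_set(self, tmp_path):
        path = tmp_path / "empty.zip"
        write_roi_zip(path, {})
        regions = import_regions(path)
        assert regions.follicles == [] and regions.gcs == []

    def test_orphan_gc_flagged_not_dropped(self, tmp_path):
        path = tmp_path / "rois.zip"
        write_roi_zip(path, {
            "follicle_1": roi_coords(square(0, 0, 30)),
            "gc_far": roi_coords(square(80, 80, 10)),
        })
        regions = import_regions(path)
        assert len(regions.gcs) == 1
        assert regions.orphan_gcs[0].parent_follicle_id is None

    def test_ambiguous_parentage_raises(self, tmp_path):
        path = tmp_path / "rois.zip"
        # two overlapping follicles both covering half of the same GC
        write_roi_zip(path, {
            "follicle_1": roi_coords(box(-0.5, -0.5, 50, 100)),
            "follicle_2": roi_coords(box(30, -0.5, 100, 100)),
            "gc_x": roi_coords(box(25, 20, 55, 50)),
        })
        with pytest.raises(ValueError, match="ambiguous"):
            import_regions(path, min_containment=0.3)

    def test_export_import_round_trip(self, tmp_path, noise0_run):
        truth, _, _ = noise0_run
        path = tmp_path / "true_regions.zip"
        export_regions(truth.regions, path)
        back = import_regions(path)
        assert len(back.follicles) == len(truth.regions.follicles)
        assert len(back.gcs) == len(truth.regions.gcs)
        # areas agree to within the 1-px vertex quantization of the format
        for orig, imported in zip(
                sorted(truth.regions.follicles,
                       key=lambda f: f.geometry.area),
                sorted(back.follicles, key=lambda f: f.geometry.area)):
            assert imported.geometry.area == pytest.approx(
                orig.geometry.area, rel=0.02)
        back.validate_nesting(min_containment=0.98)


class TestAutoRegions:
    def test_recovers_planted_geometry(self, dense_overlap_config):
        truth, img = generate_sample(dense_overlap_config)
        cd19 = threshold_channel(img, "CD19", method="otsu")
        bcl6 = threshold_channel(img, "BCL6", method="otsu")
        auto = auto_regions(cd19, bcl6)
        assert len(auto.follicles) == len(truth.regions.follicles)
        for kind, true_list, auto_list in (
                ("follicle", truth.regions.follicles, auto.follicles),
                ("gc", truth.regions.gcs, auto.gcs)):
            for r_true in true_list:
                mt = rasterize_geometry(r_true.geometry, img.shape)
                best = max(
                    ((mt & rasterize_geometry(r.geometry, img.shape)).sum()
                     / (mt | rasterize_geometry(r.geometry, img.shape)).sum()
                     for r in auto_list), default=0.0)
                assert best >= 0.8, f"{kind} IoU {best:.3f}"

    def test_empty_cd19_mask_gives_empty_set(self):
        from tfkscope.segment import SignalMask
        empty = SignalMask("CD19", np.zeros((64, 64), bool), 0.0, "manual")
        bcl6 = SignalMask("BCL6", np.zeros((64, 64), bool), 0.0, "manual")
        auto = auto_regions(empty, bcl6)
        assert auto.follicles == [] and auto.gcs == []

    def test_extrafollicular_bcl6_not_promoted_to_gc(self):
        from tfkscope.segment import SignalMask
        shape = (128, 128)
        cd19 = np.zeros(shape, bool)
        cd19[10:50, 10:50] = True
        bcl6 = np.zeros(shape, bool)
        bcl6[90:120, 90:120] = True  # far from the follicle
        auto = auto_regions(
            SignalMask("CD19", cd19, 0, "manual"),
            SignalMask("BCL6", bcl6, 0, "manual"),
            min_follicle_area_px=500, smoothing_px=3)
        assert len(auto.follicles) == 1
        assert auto.gcs == []


class TestMeasureRegions:
    def test_coverage_arithmetic(self):
        regions = RegionSet(
            follicles=[Follicle(1, square(5, 5, 10))],       # 100 px
            gcs=[GerminalCenter(1, square(7, 7, 5), 1)],     # 25 px
            pixel_size=1.0)
        m = measure_regions(regions, (40, 25))               # 1000 px image
        assert m.follicle_coverage == pytest.approx(0.10)
        assert m.gc_coverage == pytest.approx(0.025)
        assert m.mean_follicle_area_px == 100
        assert m.mean_gc_area_px == 25

    def test_empty_region_set_all_zero(self):
        m = measure_regions(RegionSet(), (64, 64))
        assert m.n_follicles == 0 and m.n_gcs == 0
        assert m.follicle_coverage == 0 and m.mean_gc_area_px == 0

    def test_overlapping_follicles_union_not_double_counted(self):
        regions = RegionSet(
            follicles=[Follicle(1, square(0, 0, 10)),
                       Follicle(2, square(5, 0, 10))],  # share 50 px
            pixel_size=1.0)
        m = measure_regions(regions, (10, 100))
        assert m.follicle_coverage == pytest.approx(150 / 1000)

    def test_order_invariant(self, noise0_run):
        truth, img, _ = noise0_run
        r = truth.regions
        rev = RegionSet(follicles=list(reversed(r.follicles)),
                        gcs=list(reversed(r.gcs)),
                        pixel_size=r.pixel_size, source=r.source)
        m1 = measure_regions(r, img.shape)
        m2 = measure_regions(rev, img.shape)
        assert m1.follicle_coverage == m2.follicle_coverage
        assert sorted(m1.follicle_areas_px) == sorted(m2.follicle_areas_px)

    def test_pixel_size_scaling(self):
        regions = RegionSet(follicles=[Follicle(1, square(0, 0, 10))],
                            pixel_size=0.5)
        m = measure_regions(regions, (20, 20))
        assert m.mean_follicle_area_um2 == pytest.approx(100 * 0.25)


def call_at(cell_id, row, col):
    return SubtypeCall(cell_id, "T_FK", (row, col), 1,
                       np.array([[int(row), int(col)]]))


class TestAssignCells:
    def regions(self):
        return RegionSet(
            follicles=[Follicle(1, square(0, 0, 40))],
            gcs=[GerminalCenter(1, square(10, 10, 15), 1)])

    def test_gc_center_assigned_gc_with_parent_follicle(self):
        locs = assign_cells([call_at(1, 17, 17)], self.regions())
        assert locs[0].compartment == "GC"
        assert locs[0].follicle_id == 1 and locs[0].gc_id == 1

    def test_outside_everything_is_extrafollicular(self):
        locs = assign_cells([call_at(1, 100, 100)], self.regions())
        assert locs[0].compartment == "extrafollicular"

    def test_boundary_resolves_inward(self):
        # exactly on the GC boundary edge (x = 9.5): inner compartment wins
        locs = assign_cells([call_at(1, 15.0, 9.5)], self.regions())
        assert locs[0].compartment == "GC"

    def test_partition_property(self, noise0_run):
        truth, _, analysis = noise0_run
        comps = [l.compartment for l in analysis.locations]
        assert len(comps) == len(analysis.calls)
        assert set(comps) <= {"GC", "follicle", "extrafollicular"}

    def test_planted_compartments_recovered(self, noise0_run):
        truth, _, analysis = noise0_run
        from scipy.spatial import cKDTree
        tree = cKDTree([c.centroid_px for c in analysis.calls])
        loc = {l.cell_id: l for l in analysis.locations}
        checked = correct = 0
        for pc in truth.cells:
            if pc.cell_type in ("B", "other"):
                continue
            d, i = tree.query(pc.centroid_px)
            if d > 3:
                continue
            checked += 1
            correct += (loc[analysis.calls[i].cell_id].compartment
                        == pc.true_region)
        assert checked > 150
        assert correct / checked >= 0.99
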