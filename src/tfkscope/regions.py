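"""Follicle / germinal-center regions: import, automatic derivation,
morphometry and cell allocation.

Regions come either from manually drawn ImageJ ROIs (the primary route for
real tissue) or from :func:`auto_regions`, an automated stand-in that
derives follicles from the CD19 mask and GCs from BCL6-dense areas so the
synthetic pipeline can run unattended.  Geometries are shapely polygons in
ImageJ axis convention (x = column, y = row); cell coordinates elsewhere in
the package are (row, col), converted at the interface.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from shapely.geometry import MultiPoint, Point, Polygon
from shapely.ops import unary_union
from skimage.draw import polygon as draw_polygon
from skimage.measure import label, regionprops

from . import ijroi
from .segment import SignalMask

logger = logging.getLogger(__name__)


@dataclass
class Follicle:
    follicle_id: int
    geometry: Polygon


@dataclass
class GerminalCenter:
    gc_id: int
    geometry: Polygon
    parent_follicle_id: int | None  # None = orphan (flagged, never dropped)


@dataclass
class RegionSet:
    """Follicle and GC regions with enforced GC ⊂ follicle nesting."""

    follicles: list[Follicle] = field(default_factory=list)
    gcs: list[GerminalCenter] = field(default_factory=list)
    pixel_size: float = 0.5
    source: str = "manual_roi"  # manual_roi | auto | synthetic

    def __post_init__(self) -> None:
        ids = [f.follicle_id for f in self.follicles]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate follicle ids")
        valid = set(ids)
        for gc in self.gcs:
            if gc.parent_follicle_id is not None and gc.parent_follicle_id not in valid:
                raise ValueError(
                    f"GC {gc.gc_id} references unknown follicle "
                    f"{gc.parent_follicle_id}"
                )

    def follicle(self, follicle_id: int) -> Follicle:
        for f in self.follicles:
            if f.follicle_id == follicle_id:
                return f
        raise KeyError(follicle_id)

    @property
    def orphan_gcs(self) -> list[GerminalCenter]:
        return [g for g in self.gcs if g.parent_follicle_id is None]

    def validate_nesting(self, min_containment: float = 0.99) -> None:
        """Check each GC lies (≥ ``min_containment`` of its area) inside
        its parent follicle; raises on violation."""
        for gc in self.gcs:
            if gc.parent_follicle_id is None:
                continue
            fol = self.follicle(gc.parent_follicle_id)
            if gc.geometry.area == 0:
                raise ValueError(f"GC {gc.gc_id} has zero area")
            frac = gc.geometry.intersection(fol.geometry).area / gc.geometry.area
            if frac < min_containment:
                raise ValueError(
                    f"GC {gc.gc_id} only {frac:.3f} contained in follicle "
                    f"{gc.parent_follicle_id}"
                )


@dataclass
class RegionMorphometry:
    """Per-sample follicle/GC size and coverage summary."""

    n_follicles: int
    n_gcs: int
    follicle_areas_px: list[float]
    gc_areas_px: list[float]
    mean_follicle_area_px: float
    mean_gc_area_px: float
    mean_follicle_area_um2: float
    mean_gc_area_um2: float
    follicle_coverage: float  # fraction of image area, union (no double count)
    gc_coverage: float


@dataclass
class CellLocation:
    cell_id: int
    compartment: str  # GC | follicle | extrafollicular
    follicle_id: int | None = None
    gc_id: int | None = None


# ---------------------------------------------------------------- import


def import_regions(
    roi_file,
    pixel_size: float = 0.5,
    follicle_prefix: str = "follicle",
    gc_prefix: str = "gc",
    min_containment: float = 0.5,
) -> RegionSet:
    """Read manually drawn follicle/GC ROIs from an ImageJ .roi or .zip.

    ROI names starting with ``follicle_prefix`` become follicles, those
    with ``gc_prefix`` become GCs (case-insensitive).  GC parentage is
    inferred by maximal containment of the GC area in a follicle; a GC
    contained ≥ ``min_containment`` in more than one follicle is ambiguous
    and raises.  GCs inside no follicle are kept as flagged orphans.
    """
    rois = ijroi.read_roi_file(roi_file)
    follicles: list[Follicle] = []
    gc_geoms: list[tuple[str, Polygon]] = []
    for name, roi in rois.items():
        xs, ys = ijroi.roi_to_xy(roi)
        if len(xs) < 3:
            raise ValueError(f"ROI {name!r} has fewer than 3 vertices")
        geom = Polygon(zip(xs, ys))
        if not geom.is_valid:
            geom = geom.buffer(0)
        lname = name.lower()
        if lname.startswith(gc_prefix.lower()):
            gc_geoms.append((name, geom))
        elif lname.startswith(follicle_prefix.lower()):
            follicles.append(Follicle(len(follicles) + 1, geom))
        else:
            logger.warning("ROI %r matches neither prefix; ignored", name)
    if not rois:
        logger.warning("empty ROI archive %s", roi_file)

    gcs: list[GerminalCenter] = []
    for i, (name, geom) in enumerate(gc_geoms, start=1):
        fractions = [
            (f.follicle_id, geom.intersection(f.geometry).area / geom.area)
            for f in follicles
        ] if geom.area else []
        inside = [(fid, fr) for fid, fr in fractions if fr >= min_containment]
        if len(inside) > 1:
            ids = [fid for fid, _ in inside]
            raise ValueError(
                f"GC ROI {name!r} ambiguously contained in follicles {ids}"
            )
        if inside:
            parent = inside[0][0]
        else:
            parent = None
            logger.warning("GC ROI %r lies in no follicle; flagged orphan", name)
        gcs.append(GerminalCenter(i, geom, parent))
    return RegionSet(follicles, gcs, pixel_size=pixel_size, source="manual_roi")


def export_regions(regions: RegionSet, path) -> None:
    """Write regions as an ImageJ RoiSet zip (names encode role/parent)."""
    rois: dict[str, tuple] = {}
    for f in regions.follicles:
        xs, ys = np.asarray(f.geometry.exterior.coords).T
        rois[f"follicle_{f.follicle_id}"] = (xs, ys)
    for g in regions.gcs:
        xs, ys = np.asarray(g.geometry.exterior.coords).T
        rois[f"gc_{g.gc_id}"] = (xs, ys)
    ijroi.write_roi_zip(path, rois)


# ------------------------------------------------------------ automatic


def _disk(radius: int) -> np.ndarray:
    yy, xx = np.mgrid[-radius:radius + 1, -radius:radius + 1]
    return (yy * yy + xx * xx) <= radius * radius


def _component_hull(coords: np.ndarray) -> Polygon | None:
    """Convex hull polygon of (row, col) pixel coordinates in (x, y) axes."""
    pts = MultiPoint([(c, r) for r, c in coords])
    hull = pts.convex_hull
    if isinstance(hull, Polygon) and hull.area > 0:
        return hull
    return None


def auto_regions(
    cd19_mask: SignalMask,
    bcl6_mask: SignalMask,
    min_follicle_area_px: float = 2000.0,
    smoothing_px: int = 15,
    min_gc_area_px: float | None = None,
    pixel_size: float = 0.5,
) -> RegionSet:
    """Derive follicle and GC regions from CD19 and BCL6 signal masks.

    Follicles: the CD19 mask is morphologically closed with a disk of
    ``smoothing_px``, hole-filled, and components above
    ``min_follicle_area_px`` become follicles via their convex hull
    (follicles are near-elliptic, so the hull is a faithful outline of a
    cloud of discrete B-cell blobs).  GCs: the BCL6 mask is closed the same
    way; components whose hull intersects a follicle are clipped to that
    follicle, ranked by intersection for parentage.  BCL6 blobs outside all
    follicles (extrafollicular cytotoxic cells) are never promoted to GC.
    """
    if cd19_mask.mask.shape != bcl6_mask.mask.shape:
        raise ValueError("CD19 and BCL6 masks differ in shape")
    if min_gc_area_px is None:
        min_gc_area_px = min_follicle_area_px / 20.0
    se = _disk(smoothing_px)

    # close to merge discrete cell blobs into a region body, open to cut
    # single-cell bridges and drop isolated extrafollicular cells
    fol_closed = ndimage.binary_fill_holes(
        ndimage.binary_closing(cd19_mask.mask, structure=se)
    )
    fol_closed = ndimage.binary_opening(fol_closed, structure=se)
    follicles: list[Follicle] = []
    for prop in regionprops(label(fol_closed, connectivity=2)):
        if prop.area < min_follicle_area_px:
            continue
        hull = _component_hull(prop.coords)
        if hull is not None:
            follicles.append(Follicle(len(follicles) + 1, hull))

    gc_closed = ndimage.binary_opening(
        ndimage.binary_closing(bcl6_mask.mask, structure=se), structure=se)
    gcs: list[GerminalCenter] = []
    for prop in regionprops(label(gc_closed, connectivity=2)):
        if prop.area < min_gc_area_px:
            continue
        hull = _component_hull(prop.coords)
        if hull is None:
            continue
        best, best_area = None, 0.0
        for f in follicles:
            inter = hull.intersection(f.geometry).area
            if inter > best_area:
                best, best_area = f, inter
        if best is None or best_area == 0:
            continue  # extrafollicular BCL6 blob: not a GC
        clipped = hull.intersection(best.geometry)
        if isinstance(clipped, Polygon) and clipped.area >= min_gc_area_px:
            gcs.append(GerminalCenter(len(gcs) + 1, clipped, best.follicle_id))
    return RegionSet(follicles, gcs, pixel_size=pixel_size, source="auto")


# ----------------------------------------------------------- morphometry


def rasterize_geometry(geom: Polygon, image_shape: tuple[int, int]) -> np.ndarray:
    """Boolean pixel mask of a polygon (x=col, y=row axes) within an image."""
    mask = np.zeros(image_shape, dtype=bool)
    polys = [geom] if isinstance(geom, Polygon) else list(geom.geoms)
    for poly in polys:
        xs, ys = np.asarray(poly.exterior.coords).T
        rr, cc = draw_polygon(ys, xs, shape=image_shape)
        mask[rr, cc] = True
        for ring in poly.interiors:
            xs, ys = np.asarray(ring.coords).T
            rr, cc = draw_polygon(ys, xs, shape=image_shape)
            mask[rr, cc] = False
    return mask


def measure_regions(regions: RegionSet,
                    image_shape: tuple[int, int]) -> RegionMorphometry:
    """Areas by pixel counting, coverage on the union (no double count)."""
    total_px = float(image_shape[0] * image_shape[1])
    px2um2 = regions.pixel_size ** 2

    fol_masks = [rasterize_geometry(f.geometry, image_shape)
                 for f in regions.follicles]
    gc_masks = [rasterize_geometry(g.geometry, image_shape)
                for g in regions.gcs]
    fol_areas = [float(m.sum()) for m in fol_masks]
    gc_areas = [float(m.sum()) for m in gc_masks]

    def union_count(masks: list[np.ndarray]) -> float:
        if not masks:
            return 0.0
        u = np.zeros(image_shape, dtype=bool)
        for m in masks:
            u |= m
        return float(u.sum())

    mean_fol = float(np.mean(fol_areas)) if fol_areas else 0.0
    mean_gc = float(np.mean(gc_areas)) if gc_areas else 0.0
    return RegionMorphometry(
        n_follicles=len(regions.follicles),
        n_gcs=len(regions.gcs),
        follicle_areas_px=fol_areas,
        gc_areas_px=gc_areas,
        mean_follicle_area_px=mean_fol,
        mean_gc_area_px=mean_gc,
        mean_follicle_area_um2=mean_fol * px2um2,
        mean_gc_area_um2=mean_gc * px2um2,
        follicle_coverage=union_count(fol_masks) / total_px,
        gc_coverage=union_count(gc_masks) / total_px,
    )


# ------------------------------------------------------------ allocation


def assign_cells(calls, regions: RegionSet) -> list[CellLocation]:
    """Allocate each call to GC / follicle / extrafollicular by centroid.

    Containment is tested innermost-first (GC before follicle) and uses
    ``covers`` so a centroid exactly on a boundary resolves inward —
    deterministic and conservative.  A GC hit also records the parent
    follicle so GC cells contribute to follicular tallies.
    """
    locations: list[CellLocation] = []
    for call in calls:
        row, col = call.centroid_px
        pt = Point(col, row)
        loc = CellLocation(call.cell_id, "extrafollicular")
        for gc in regions.gcs:
            if gc.geometry.covers(pt):
                loc = CellLocation(call.cell_id, "GC",
                                   follicle_id=gc.parent_follicle_id,
                                   gc_id=gc.gc_id)
                break
        else:
            for fol in regions.follicles:
                if fol.geometry.covers(pt):
                    loc = CellLocation(call.cell_id, "follicle",
                                       follicle_id=fol.follicle_id)
                    break
        locations.append(loc)
    return locations


def region_union(regions: RegionSet):
    return unary_union([f.geometry for f in regions.follicles])
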