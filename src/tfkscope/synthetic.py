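"""Synthetic lymphoid-tissue generator with planted ground truth.

Emulates the structure the quantification pipeline assumes: elliptical
B-cell follicles each enclosing one concentric germinal center, cells of
six phenotypes rendered as marker-specific intensity disks, Gaussian PSF
blur, a low-frequency background field and additive Gaussian noise.  The
generator returns a planted-cell table (type, position, compartment,
contact pairs) so every downstream stage can be scored against truth.

Phenotype → marker map (the imaging definitions):

==========  =============================
type        positive channels
==========  =============================
B           CD19
GC-B        CD19, BCL6
T_FH        CD4, BCL6
T_FK        CD4, BCL6, TIA1
Treg        CD4, FOXP3
other       (none of the panel markers)
==========  =============================
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely import affinity
from shapely.geometry import Point, Polygon

from .image import MultiChannelImage
from .regions import Follicle, GerminalCenter, RegionSet

CHANNELS = ("CD19", "CD4", "BCL6", "TIA1", "FOXP3")
CELL_TYPES = ("B", "GC-B", "T_FH", "T_FK", "Treg", "other")
COMPARTMENTS = ("GC", "follicle", "extrafollicular")

MARKER_MAP: dict[str, tuple[str, ...]] = {
    "B": ("CD19",),
    "GC-B": ("CD19", "BCL6"),
    "T_FH": ("CD4", "BCL6"),
    "T_FK": ("CD4", "BCL6", "TIA1"),
    "Treg": ("CD4", "FOXP3"),
    "other": (),
}

_DEFAULT_AMPLITUDE = 200.0


def _default_marker_intensity() -> dict[str, dict[str, float]]:
    return {
        t: {ch: _DEFAULT_AMPLITUDE for ch in chans}
        for t, chans in MARKER_MAP.items()
    }


def _default_cell_counts() -> dict[str, int]:
    # One acquisition's worth of cells at 20x over a 1024² field:
    # mantle-zone B cells, GC B cells, the follicular T-cell compartment
    # (T_FH outnumbering T_FK roughly 3:1), Tregs and marker-negative cells.
    return {"B": 75, "GC-B": 75, "T_FH": 60, "T_FK": 20,
            "Treg": 40, "other": 30}


def _default_placement() -> dict[str, dict[str, float]]:
    # Probabilities over (GC, follicle-non-GC, extrafollicular) per type:
    # GC-B cells are confined to GCs by definition; mantle B cells ring the
    # GC; follicular T cells skew toward the GC; Tregs sit mostly outside
    # follicles; marker-negative cells are extrafollicular filler.
    return {
        "B": {"GC": 0.05, "follicle": 0.75, "extrafollicular": 0.20},
        "GC-B": {"GC": 1.0, "follicle": 0.0, "extrafollicular": 0.0},
        "T_FH": {"GC": 0.6, "follicle": 0.3, "extrafollicular": 0.1},
        "T_FK": {"GC": 0.5, "follicle": 0.3, "extrafollicular": 0.2},
        "Treg": {"GC": 0.1, "follicle": 0.3, "extrafollicular": 0.6},
        "other": {"GC": 0.0, "follicle": 0.0, "extrafollicular": 1.0},
    }


@dataclass
class SynthConfig:
    """Parameters of one synthetic acquisition.

    Defaults describe a 1024×1024 px field at 0.5 µm/px with five
    follicles whose GC occupies 0.6 of the follicle radius (GC-dominated
    follicles, as in follicular-lymphoma-like tissue), cells of radius
    ≈ 4.5 px (area ≈ 64 px, inside the 20–200 px particle window), marker
    amplitude 200, 5 % additive noise and a 10 % low-frequency background.
    """

    image_shape: tuple[int, int] = (1024, 1024)
    pixel_size: float = 0.5
    n_follicles: int = 5
    gc_fraction: float = 0.6
    follicle_radius_px: float = 110.0
    follicle_radius_sd: float = 8.0
    cell_counts: dict[str, int] = field(default_factory=_default_cell_counts)
    region_placement_probs: dict[str, dict[str, float]] = field(
        default_factory=_default_placement)
    cell_radius_px: float = 4.5
    cell_radius_sd: float = 0.3
    cell_radius_bounds: tuple[float, float] = (3.8, 5.0)
    marker_intensity: dict[str, dict[str, float]] = field(
        default_factory=_default_marker_intensity)
    noise_sd: float = 10.0
    background_amplitude: float = 20.0
    psf_sigma_px: float = 1.0
    planted_contact_pairs: int = 4
    min_cell_gap_px: float = 5.0  # extra separation beyond radius sum
    allow_overlap: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.gc_fraction < 1:
            raise ValueError("gc_fraction must be in (0, 1)")
        if self.psf_sigma_px < 0:
            raise ValueError("psf_sigma_px must be >= 0")
        if self.n_follicles < 0:
            raise ValueError("n_follicles must be >= 0")
        for t, n in self.cell_counts.items():
            if t not in CELL_TYPES:
                raise ValueError(f"unknown cell type {t!r}")
            if n < 0:
                raise ValueError(f"negative count for {t!r}")
        for t, probs in self.region_placement_probs.items():
            tot = sum(probs.get(c, 0.0) for c in COMPARTMENTS)
            if abs(tot - 1.0) > 1e-9:
                raise ValueError(
                    f"placement probabilities for {t!r} sum to {tot}, not 1")
        if self.planted_contact_pairs > min(
                self.cell_counts.get("T_FK", 0),
                self.cell_counts.get("Treg", 0)):
            raise ValueError(
                "planted_contact_pairs exceeds available T_FK or Treg count")


@dataclass
class PlantedCell:
    cell_id: int
    cell_type: str
    centroid_px: tuple[float, float]  # (row, col)
    radius_px: float
    true_region: str  # GC | follicle | extrafollicular
    follicle_id: int | None = None
    gc_id: int | None = None


@dataclass
class GroundTruth:
    """Planted-cell table, true region geometry and planted contact pairs."""

    cells: list[PlantedCell]
    regions: RegionSet
    contacts: list[tuple[int, int]]  # (tfk_id, treg_id)

    def cells_of_type(self, cell_type: str) -> list[PlantedCell]:
        return [c for c in self.cells if c.cell_type == cell_type]

    def counts(self) -> dict[str, int]:
        out = {t: 0 for t in CELL_TYPES}
        for c in self.cells:
            out[c.cell_type] += 1
        return out

    def to_frames(self) -> dict[str, pd.DataFrame]:
        cells = pd.DataFrame([
            {
                "cell_id": c.cell_id, "type": c.cell_type,
                "row": c.centroid_px[0], "col": c.centroid_px[1],
                "radius_px": c.radius_px, "true_region": c.true_region,
                "follicle_id": c.follicle_id, "gc_id": c.gc_id,
            }
            for c in self.cells
        ])
        region_rows = [
            {"region_id": f.follicle_id, "kind": "follicle", "parent": None,
             "wkt": f.geometry.wkt}
            for f in self.regions.follicles
        ] + [
            {"region_id": g.gc_id, "kind": "gc",
             "parent": g.parent_follicle_id, "wkt": g.geometry.wkt}
            for g in self.regions.gcs
        ]
        contacts = pd.DataFrame(self.contacts,
                                columns=["tfk_id", "treg_id"])
        return {
            "cells": cells,
            "regions": pd.DataFrame(region_rows),
            "contacts": contacts,
        }

    def write_csv(self, outdir) -> None:
        from pathlib import Path
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.to_frames().items():
            df.to_csv(out / f"{name}.csv", index=False)


class CapacityError(RuntimeError):
    """Requested geometry/cells do not fit the image after bounded retries."""


# -------------------------------------------------------------- regions


def _ellipse(cx: float, cy: float, a: float, b: float, angle_deg: float
             ) -> Polygon:
    circ = Point(cx, cy).buffer(1.0, quad_segs=64)
    ell = affinity.scale(circ, a, b)
    return affinity.rotate(ell, angle_deg)


def place_regions(config: SynthConfig, rng: np.random.Generator) -> RegionSet:
    """Place non-overlapping elliptical follicles with concentric GCs.

    Follicle axis ratio is sampled in [0.7, 1.0]; the GC is the follicle
    scaled about its center by ``gc_fraction``.  Placement is rejection
    sampling with bounded retries; exhausting them raises
    :class:`CapacityError`.
    """
    h, w = config.image_shape
    follicles: list[Follicle] = []
    gcs: list[GerminalCenter] = []
    margin = 4.0
    max_tries = 300
    for fid in range(1, config.n_follicles + 1):
        placed = False
        for _ in range(max_tries):
            a = max(10.0, rng.normal(config.follicle_radius_px,
                                     config.follicle_radius_sd))
            ratio = rng.uniform(0.7, 1.0)
            b = a * ratio
            angle = rng.uniform(0.0, 180.0)
            cx = rng.uniform(a + margin, w - a - margin) if w > 2 * (a + margin) else None
            cy = rng.uniform(a + margin, h - a - margin) if h > 2 * (a + margin) else None
            if cx is None or cy is None:
                continue
            geom = _ellipse(cx, cy, a, b, angle)
            if any(geom.buffer(margin).intersects(f.geometry)
                   for f in follicles):
                continue
            follicles.append(Follicle(fid, geom))
            gc_geom = affinity.scale(geom, config.gc_fraction,
                                     config.gc_fraction, origin="centroid")
            gcs.append(GerminalCenter(fid, gc_geom, fid))
            placed = True
            break
        if not placed:
            raise CapacityError(
                f"could not place follicle {fid}/{config.n_follicles} of "
                f"radius ~{config.follicle_radius_px} in {config.image_shape} "
                f"after {max_tries} tries"
            )
    return RegionSet(follicles, gcs, pixel_size=config.pixel_size,
                     source="synthetic")


# ---------------------------------------------------------------- cells


def _sample_point_in(geom: Polygon, exclude: Polygon | None,
                     rng: np.random.Generator, shape: tuple[int, int],
                     inset: float = 1.0, max_tries: int = 2000
                     ) -> tuple[float, float]:
    """Uniform point in geom (minus exclude), ≥ inset from its boundary."""
    minx, miny, maxx, maxy = geom.bounds
    target = geom.buffer(-inset) if inset else geom
    for _ in range(max_tries):
        x = rng.uniform(minx, maxx)
        y = rng.uniform(miny, maxy)
        if not (0 <= x < shape[1] and 0 <= y < shape[0]):
            continue
        pt = Point(x, y)
        if not target.covers(pt):
            continue
        if exclude is not None and exclude.buffer(inset).covers(pt):
            continue
        return (y, x)  # (row, col)
    raise CapacityError("could not sample a point in region")


def _sample_extrafollicular(rng: np.random.Generator,
                            shape: tuple[int, int],
                            follicles: list[Follicle],
                            inset: float = 1.0,
                            max_tries: int = 2000) -> tuple[float, float]:
    h, w = shape
    for _ in range(max_tries):
        x = rng.uniform(inset, w - inset)
        y = rng.uniform(inset, h - inset)
        pt = Point(x, y)
        if any(f.geometry.buffer(inset).covers(pt) for f in follicles):
            continue
        return (y, x)
    raise CapacityError("could not sample an extrafollicular point")


def _region_of_point(row: float, col: float, regions: RegionSet
                     ) -> tuple[str, int | None, int | None]:
    pt = Point(col, row)
    for gc in regions.gcs:
        if gc.geometry.covers(pt):
            return "GC", gc.parent_follicle_id, gc.gc_id
    for fol in regions.follicles:
        if fol.geometry.covers(pt):
            return "follicle", fol.follicle_id, None
    return "extrafollicular", None, None


def place_cells(config: SynthConfig, regions: RegionSet,
                rng: np.random.Generator) -> GroundTruth:
    """Plant cells with region-consistent centroids and no overlaps.

    Cells are separated by at least the sum of their radii (plus a gap
    margin so post-blur masks stay disjoint), except planted T_FK–Treg
    contact pairs, whose center distance equals exactly the radius sum
    (touching boundaries).
    """
    placed: list[PlantedCell] = []
    contacts: list[tuple[int, int]] = []
    next_id = 1

    def radius() -> float:
        lo, hi = config.cell_radius_bounds
        return float(np.clip(rng.normal(config.cell_radius_px,
                                        config.cell_radius_sd), lo, hi))

    def overlaps(row: float, col: float, r: float,
                 ignore: set[int] = frozenset()) -> bool:
        if config.allow_overlap:
            return False
        for c in placed:
            if c.cell_id in ignore:
                continue
            d = np.hypot(c.centroid_px[0] - row, c.centroid_px[1] - col)
            if d < c.radius_px + r + config.min_cell_gap_px:
                return True
        return False

    gc_list = regions.gcs
    gc_weights = np.array([g.geometry.area for g in gc_list], float)
    fol_list = regions.follicles
    fol_weights = np.array([f.geometry.area for f in fol_list], float)

    def sample_position(compartment: str) -> tuple[float, float]:
        if compartment == "GC":
            if not gc_list:
                raise CapacityError("no GC to place a GC cell in")
            g = gc_list[rng.choice(len(gc_list),
                                   p=gc_weights / gc_weights.sum())]
            return _sample_point_in(g.geometry, None, rng, config.image_shape)
        if compartment == "follicle":
            if not fol_list:
                raise CapacityError("no follicle to place a follicular cell in")
            idx = rng.choice(len(fol_list), p=fol_weights / fol_weights.sum())
            f = fol_list[idx]
            child = next((g.geometry for g in gc_list
                          if g.parent_follicle_id == f.follicle_id), None)
            return _sample_point_in(f.geometry, child, rng, config.image_shape)
        return _sample_extrafollicular(rng, config.image_shape, fol_list)

    def plant(cell_type: str, compartment: str) -> PlantedCell:
        nonlocal next_id
        for _ in range(1000):
            r = radius()
            row, col = sample_position(compartment)
            if overlaps(row, col, r):
                continue
            region, fid, gid = _region_of_point(row, col, regions)
            if region != compartment:
                continue  # e.g. follicle draw landed on GC-excluded sliver
            cell = PlantedCell(next_id, cell_type, (row, col), r,
                               region, fid, gid)
            placed.append(cell)
            next_id += 1
            return cell
        raise CapacityError(
            f"region too small to place {cell_type} in {compartment}")

    # Deterministic type order keeps the stream reproducible.
    for cell_type in CELL_TYPES:
        n = config.cell_counts.get(cell_type, 0)
        if cell_type == "Treg":
            n = n - config.planted_contact_pairs  # contact partners placed below
        probs = config.region_placement_probs[cell_type]
        pvec = np.array([probs.get(c, 0.0) for c in COMPARTMENTS])
        for _ in range(max(0, n)):
            compartment = COMPARTMENTS[rng.choice(3, p=pvec)]
            plant(cell_type, compartment)

    # Planted touching T_FK–Treg pairs.
    tfk_cells = [c for c in placed if c.cell_type == "T_FK"]
    if config.planted_contact_pairs > len(tfk_cells):
        raise CapacityError("fewer T_FK cells placed than contact pairs requested")
    h, w = config.image_shape
    candidates = list(rng.permutation(len(tfk_cells)))
    for _ in range(config.planted_contact_pairs):
        planted_pair = False
        while candidates and not planted_pair:
            tfk = tfk_cells[int(candidates.pop(0))]
            r = radius()
            dist = tfk.radius_px + r
            for _ in range(400):
                theta = rng.uniform(0, 2 * np.pi)
                row = tfk.centroid_px[0] + dist * np.sin(theta)
                col = tfk.centroid_px[1] + dist * np.cos(theta)
                if not (r < row < h - r and r < col < w - r):
                    continue
                if overlaps(row, col, r, ignore={tfk.cell_id}):
                    continue
                region, fid, gid = _region_of_point(row, col, regions)
                treg = PlantedCell(next_id, "Treg", (row, col), r,
                                   region, fid, gid)
                placed.append(treg)
                contacts.append((tfk.cell_id, treg.cell_id))
                next_id += 1
                planted_pair = True
                break
        if not planted_pair:
            raise CapacityError("could not place contact-pair Treg")

    return GroundTruth(placed, regions, contacts)


# -------------------------------------------------------------- render


def render_image(truth: GroundTruth, config: SynthConfig,
                 rng: np.random.Generator) -> MultiChannelImage:
    """Forward model: marker disks → PSF blur → background → noise → clip.

    Each planted cell adds a hard disk of its type's amplitude to every
    channel its marker map lists; all five panel channels are rendered so
    both staining panels can be analyzed from one synthetic acquisition.
    """
    h, w = config.image_shape
    channels = {ch: np.zeros((h, w), dtype=np.float64) for ch in CHANNELS}

    for cell in truth.cells:
        if cell.cell_type not in MARKER_MAP:
            raise ValueError(f"unknown cell type {cell.cell_type!r}")
        amps = config.marker_intensity.get(cell.cell_type, {})
        if not amps:
            continue
        row, col = cell.centroid_px
        r = cell.radius_px
        r0, r1 = max(0, int(row - r - 1)), min(h, int(row + r + 2))
        c0, c1 = max(0, int(col - r - 1)), min(w, int(col + r + 2))
        yy, xx = np.mgrid[r0:r1, c0:c1]
        disk = ((yy - row) ** 2 + (xx - col) ** 2) <= r * r
        for ch, amp in amps.items():
            channels[ch][r0:r1, c0:c1][disk] += amp

    for ch in CHANNELS:
        arr = channels[ch]
        if config.psf_sigma_px > 0:
            arr = ndimage.gaussian_filter(arr, config.psf_sigma_px)
        if config.background_amplitude > 0:
            arr = arr + config.background_amplitude * _background_field(
                (h, w), rng)
        if config.noise_sd > 0:
            arr = arr + rng.normal(0.0, config.noise_sd, size=(h, w))
        channels[ch] = np.clip(arr, 0.0, None)

    return MultiChannelImage(
        channels=channels,
        pixel_size=config.pixel_size,
        sample_id=f"synthetic_seed{config.seed}",
        group_label="other",
        provenance=["synthetic render"],
    )


def _background_field(shape: tuple[int, int],
                      rng: np.random.Generator) -> np.ndarray:
    """Smooth low-frequency field in [0, 1] from a coarse random grid."""
    from skimage.transform import resize
    coarse = rng.uniform(0.0, 1.0, size=(4, 4))
    return resize(coarse, shape, order=3, mode="edge", anti_aliasing=False)


def generate_sample(config: SynthConfig
                    ) -> tuple[GroundTruth, MultiChannelImage]:
    """Regions → cells → rendered image, all from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    regions = place_regions(config, rng)
    truth = place_cells(config, regions, rng)
    img = render_image(truth, config, rng)
    return truth, img


def config_with(config: SynthConfig, **kwargs) -> SynthConfig:
    """Functional update helper (dataclasses.replace re-export)."""
    return replace(config, **kwargs)
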