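"""Treg identification and T_FK–Treg direct-contact detection.

Tregs are CD4 cell objects with at least 25 % of their own area overlapped
by FOXP3 signal.  Direct contact between a T_FK call and a Treg is a
boundary gap of at most ``max_gap_px``, where the gap is the minimum
Chebyshev (8-connectivity) distance between the two pixel sets minus one —
so touching or diagonally adjacent pixel sets have gap 0, and the default
``max_gap_px = 1`` additionally admits one empty pixel between outlines.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .phenotype import SubtypeCall
from .segment import CellObject, SignalMask


@dataclass
class ContactPair:
    tfk_id: int
    treg_id: int
    boundary_gap_px: float


@dataclass
class ContactResult:
    tregs: list[CellObject]
    tfk_cells: list[SubtypeCall]
    pairs: list[ContactPair] = field(default_factory=list)

    @property
    def n_tfk_total(self) -> int:
        return len(self.tfk_cells)

    @property
    def pct_tfk_in_contact(self) -> float | None:
        """Percentage of T_FK with ≥1 Treg contact; None when no T_FK."""
        if self.n_tfk_total == 0:
            return None
        in_contact = {p.tfk_id for p in self.pairs}
        return 100.0 * len(in_contact) / self.n_tfk_total


def identify_tregs(
    cd4_cells: list[CellObject],
    foxp3_mask: SignalMask,
    min_overlap_frac: float = 0.25,
) -> list[CellObject]:
    """CD4 cells whose FOXP3 overlap fraction reaches the threshold.

    The fraction is |cell pixels ∩ FOXP3 mask| / cell area — the cell's
    own area is the denominator — and the threshold is inclusive
    ("at least 25 % overlay").
    """
    mask = foxp3_mask.mask
    tregs = []
    for cell in cd4_cells:
        rr, cc = cell.pixels[:, 0], cell.pixels[:, 1]
        frac = float(mask[rr, cc].mean())
        if frac >= min_overlap_frac:
            tregs.append(cell)
    return tregs


def chebyshev_gap(pixels_a: np.ndarray, pixels_b: np.ndarray) -> float:
    """Boundary gap: min Chebyshev distance between pixel sets, minus 1,
    floored at 0 (overlapping or 8-adjacent sets touch)."""
    if len(pixels_a) == 0 or len(pixels_b) == 0:
        return np.inf
    # chunked broadcast keeps memory bounded for big cells
    best = np.inf
    a = pixels_a[:, None, :]
    for start in range(0, len(pixels_b), 4096):
        b = pixels_b[None, start:start + 4096, :]
        d = np.abs(a - b).max(axis=2).min()
        best = min(best, float(d))
    return max(0.0, best - 1.0)


def detect_contacts(
    tfk: list[SubtypeCall],
    tregs: list[CellObject],
    max_gap_px: float = 1.0,
    image_shape: tuple[int, int] | None = None,
) -> ContactResult:
    """All (T_FK, Treg) pairs whose boundary gap is ≤ ``max_gap_px``.

    Implemented as dilation-overlap: each Treg's pixel set is expanded by a
    Chebyshev ball of radius ``max_gap_px + 1`` via a distance transform
    and tested against T_FK pixels, which is symmetric in which set is
    dilated.  Per-pair gaps are reported for audit.
    """
    result = ContactResult(tregs=list(tregs), tfk_cells=list(tfk))
    if not tfk or not tregs:
        return result
    reach = int(np.floor(max_gap_px)) + 1

    if image_shape is not None and len(tregs) > 8:
        # One distance transform per Treg would be wasteful; label all
        # tregs and use a single Chebyshev EDT to prefilter candidates.
        treg_lab = np.zeros(image_shape, dtype=np.int32)
        for t in tregs:
            treg_lab[t.pixels[:, 0], t.pixels[:, 1]] = t.cell_id
        dist = ndimage.distance_transform_cdt(
            treg_lab == 0, metric="chessboard")
        for call in tfk:
            rr, cc = call.pixels[:, 0], call.pixels[:, 1]
            if dist[rr, cc].min() > reach:
                continue
            for t in tregs:
                gap = chebyshev_gap(call.pixels, t.pixels)
                if gap <= max_gap_px:
                    result.pairs.append(
                        ContactPair(call.cell_id, t.cell_id, gap))
        return result

    for call in tfk:
        for t in tregs:
            gap = chebyshev_gap(call.pixels, t.pixels)
            if gap <= max_gap_px:
                result.pairs.append(ContactPair(call.cell_id, t.cell_id, gap))
    return result
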