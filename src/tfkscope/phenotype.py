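"""Multi-marker cell phenotyping by pairwise colocalization.

A double-positive cell is a connected component of the pixelwise AND of
two thresholded marker channels, kept only if its area lies inside the
inclusive 20–200 px window.  CD4⁺BCL6⁺ components are split into T_FH and
T_FK by TIA-1 co-occurrence at the component, and T_FK candidates can be
confirmed with intensity line profiles through their centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

from .image import MultiChannelImage
from .segment import MAX_AREA_PX, MIN_AREA_PX, SignalMask

LOCALIZATION_CHANNELS = ("CD19", "CD4", "BCL6", "TIA1")
TREG_CONTACT_CHANNELS = ("FOXP3", "CD4", "BCL6", "TIA1")


@dataclass
class PhenotypeROI:
    """One connected overlap region of a marker pair."""

    roi_id: int
    marker_set: frozenset[str]
    pixels: np.ndarray  # (n, 2) (row, col)
    area_px: int
    centroid_px: tuple[float, float]
    retained: bool
    discard_reason: str | None = None  # too_small | too_large


@dataclass
class IntensityProfile:
    candidate_id: int
    positions: np.ndarray  # column indices sampled along the line
    values: dict[str, np.ndarray]
    passed: bool


@dataclass
class SubtypeCall:
    cell_id: int
    subtype: str  # GC-B | T_FH | T_FK | Treg | other
    centroid_px: tuple[float, float]
    area_px: int
    pixels: np.ndarray
    evidence: dict = field(default_factory=dict)


def colocalize(
    mask_a: SignalMask,
    mask_b: SignalMask,
    min_area_px: int = MIN_AREA_PX,
    max_area_px: int = MAX_AREA_PX,
    connectivity: int = 8,
) -> list[PhenotypeROI]:
    """Connected components of ``mask_a AND mask_b`` with the area filter.

    Components with area in the inclusive [min, max] window are retained;
    the rest are returned with ``retained=False`` and a reason, so
    retained + discarded always equals the component total.
    """
    if mask_a.mask.shape != mask_b.mask.shape:
        raise ValueError(
            f"mask shapes differ: {mask_a.mask.shape} vs {mask_b.mask.shape}")
    overlap = mask_a.mask & mask_b.mask
    lab = label(overlap, connectivity=1 if connectivity == 4 else 2)
    marker_set = frozenset((mask_a.channel, mask_b.channel))
    rois: list[PhenotypeROI] = []
    for prop in regionprops(lab):
        area = int(prop.area)
        if area < min_area_px:
            retained, reason = False, "too_small"
        elif area > max_area_px:
            retained, reason = False, "too_large"
        else:
            retained, reason = True, None
        rois.append(PhenotypeROI(
            roi_id=int(prop.label),
            marker_set=marker_set,
            pixels=np.asarray(prop.coords, dtype=int),
            area_px=area,
            centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
            retained=retained,
            discard_reason=reason,
        ))
    return rois


def call_subtypes(
    panel: dict[str, SignalMask],
    panel_kind: str = "localization",
    min_area_px: int = MIN_AREA_PX,
    max_area_px: int = MAX_AREA_PX,
    tia1_overlap_frac: float = 0.5,
    foxp3_overlap_frac: float = 0.25,
) -> list[SubtypeCall]:
    """Subtype calls from a thresholded panel.

    localization panel (CD19/CD4/BCL6/TIA1):
      GC-B from colocalize(CD19, BCL6); CD4⁺BCL6⁺ components are T_FK when
      at least ``tia1_overlap_frac`` of their pixels are TIA-1-positive,
      else T_FH.
    treg_contact panel (FOXP3/CD4/BCL6/TIA1):
      same T_FH/T_FK split, but CD4⁺BCL6⁺ components whose FOXP3 overlap
      reaches ``foxp3_overlap_frac`` are T_FR-like — excluded from the
      T_FH/T_FK tally and returned as subtype "other" with an evidence tag.

    Each retained component yields exactly one call, so
    ``#T_FH + #T_FK (+ #foxp3-excluded)`` equals the retained CD4⁺BCL6⁺
    component count.
    """
    required = (LOCALIZATION_CHANNELS if panel_kind == "localization"
                else TREG_CONTACT_CHANNELS)
    if panel_kind not in ("localization", "treg_contact"):
        raise ValueError(f"unknown panel_kind {panel_kind!r}")
    for ch in required:
        if ch not in panel:
            raise ValueError(f"panel is missing required channel {ch!r}")

    calls: list[SubtypeCall] = []
    next_id = 1

    def add(subtype: str, roi: PhenotypeROI, **evidence) -> None:
        nonlocal next_id
        calls.append(SubtypeCall(
            cell_id=next_id,
            subtype=subtype,
            centroid_px=roi.centroid_px,
            area_px=roi.area_px,
            pixels=roi.pixels,
            evidence={"roi_id": roi.roi_id,
                      "marker_set": sorted(roi.marker_set), **evidence},
        ))
        next_id += 1

    if panel_kind == "localization":
        for roi in colocalize(panel["CD19"], panel["BCL6"],
                              min_area_px, max_area_px):
            if roi.retained:
                add("GC-B", roi)

    tia1 = panel["TIA1"].mask
    foxp3 = panel["FOXP3"].mask if panel_kind == "treg_contact" else None
    for roi in colocalize(panel["CD4"], panel["BCL6"],
                          min_area_px, max_area_px):
        if not roi.retained:
            continue
        rr, cc = roi.pixels[:, 0], roi.pixels[:, 1]
        if foxp3 is not None:
            fol_frac = float(foxp3[rr, cc].mean())
            if fol_frac >= foxp3_overlap_frac:
                add("other", roi, excluded="foxp3_overlap",
                    foxp3_frac=fol_frac)
                continue
        tia_frac = float(tia1[rr, cc].mean())
        subtype = "T_FK" if tia_frac >= tia1_overlap_frac else "T_FH"
        add(subtype, roi, tia1_frac=tia_frac)
    return calls


def profile_candidate(
    img: MultiChannelImage,
    call: SubtypeCall,
    half_length_px: int = 15,
    thresholds: dict[str, float] | None = None,
) -> IntensityProfile:
    """Horizontal intensity profile through a T_FK candidate's centroid.

    The candidate passes when every required channel (CD4, BCL6, TIA1)
    peaks inside the candidate's own pixel span along the line and that
    peak exceeds the channel threshold, while CD19 (when present) does not
    peak above threshold inside the span — i.e. the cytotoxic-T signature
    without a B-cell signal.  Lines at image borders are clipped, never
    rejected.
    """
    if call.subtype != "T_FK":
        raise ValueError("intensity profiles confirm T_FK candidates only")
    thresholds = thresholds or {}
    h, w = img.shape
    row = int(round(call.centroid_px[0]))
    row = min(max(row, 0), h - 1)
    c0 = max(0, int(round(call.centroid_px[1])) - half_length_px)
    c1 = min(w, int(round(call.centroid_px[1])) + half_length_px + 1)
    positions = np.arange(c0, c1)
    values = {name: arr[row, c0:c1].copy()
              for name, arr in img.channels.items()}

    # Columns of the candidate's own pixels on this row band define the span.
    span_cols = call.pixels[:, 1]
    span_lo, span_hi = int(span_cols.min()), int(span_cols.max())
    in_span = (positions >= span_lo) & (positions <= span_hi)

    def peak_in_span(name: str, want_inside: bool) -> bool:
        vals = values[name]
        thr = thresholds.get(name, 0.0)
        if not in_span.any():
            return not want_inside
        inside_max = vals[in_span].max()
        if want_inside:
            return inside_max >= vals.max() and inside_max > thr
        return not (inside_max >= vals.max() and inside_max > thr)

    passed = all(
        peak_in_span(ch, True)
        for ch in ("CD4", "BCL6", "TIA1") if ch in values
    )
    if "CD19" in values:
        passed = passed and peak_in_span("CD19", False)
    return IntensityProfile(call.cell_id, positions, values, passed)
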