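"""Thresholding marker channels and detecting single-marker cell objects.

Because laser gain was tuned per tissue in the source acquisitions,
thresholds are per channel and per sample: Otsu by default with a manual
override.  Detected objects are connected components of the binary mask,
area-filtered with an inclusive [min, max] window; discarded components are
kept in a ledger so retained + discarded always equals the component total.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_multiotsu, threshold_otsu
from skimage.measure import label, regionprops

from .image import MultiChannelImage

logger = logging.getLogger(__name__)

#: Inclusive particle-area window (pixels) used throughout the pipeline.
MIN_AREA_PX = 20
MAX_AREA_PX = 200


@dataclass
class SignalMask:
    """Binary signal mask for one channel with its threshold for audit."""

    channel: str
    mask: np.ndarray
    threshold_value: float
    method: str  # otsu | manual | quantile

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if not np.isfinite(self.threshold_value):
            raise ValueError("threshold_value must be finite")


@dataclass
class CellObject:
    """One connected component treated as a candidate single cell."""

    cell_id: int
    channel_or_subtype: str
    pixels: np.ndarray  # (n, 2) array of (row, col)
    area_px: int
    centroid_px: tuple[float, float]
    mean_intensity: dict[str, float] = field(default_factory=dict)

    @property
    def outline(self) -> np.ndarray:
        """Boundary pixels: members with at least one non-member 8-neighbour."""
        pix = set(map(tuple, self.pixels))
        border = [
            p for p in pix
            if any((p[0] + dr, p[1] + dc) not in pix
                   for dr in (-1, 0, 1) for dc in (-1, 0, 1)
                   if (dr, dc) != (0, 0))
        ]
        return np.array(border, dtype=int).reshape(-1, 2)


@dataclass
class DiscardRecord:
    component_id: int
    area_px: int
    reason: str  # too_small | too_large


def threshold_channel(
    img: MultiChannelImage,
    channel: str,
    method: str = "otsu",
    manual_value: float | None = None,
    quantile: float = 0.99,
) -> SignalMask:
    """Binarize one channel: ``mask = intensity > threshold``.

    method
        ``otsu`` (default), ``multi_otsu`` (upper cut of a 3-class Otsu —
        robust when the stained fraction is tiny and classic Otsu would
        split the background mode), ``manual`` (requires ``manual_value``)
        or ``quantile`` (threshold at the given intensity quantile).
    An all-equal channel under Otsu yields an empty mask with a warning
    rather than an error, so degenerate blank acquisitions flow through.
    """
    arr = img.channel(channel)
    if method == "manual":
        if manual_value is None:
            raise ValueError("manual method requires manual_value")
        thr = float(manual_value)
    elif method in ("otsu", "multi_otsu"):
        if manual_value is not None:
            raise ValueError("manual_value given but method is not 'manual'")
        if np.ptp(arr) == 0:
            logger.warning(
                "channel %s is constant; Otsu undefined, returning empty mask",
                channel,
            )
            return SignalMask(channel, np.zeros(arr.shape, bool),
                              float(arr.flat[0]), method)
        if method == "otsu":
            thr = float(threshold_otsu(arr))
        else:
            try:
                thr = float(threshold_multiotsu(arr, classes=3)[-1])
            except ValueError:  # fewer than 3 distinct grey levels
                thr = float(threshold_otsu(arr))
    elif method == "quantile":
        thr = float(np.quantile(arr, quantile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return SignalMask(channel, arr > thr, thr, method)


def detect_cells(
    mask: SignalMask,
    min_area_px: int = MIN_AREA_PX,
    max_area_px: int = MAX_AREA_PX,
    connectivity: int = 8,
    intensity_image: MultiChannelImage | None = None,
) -> tuple[list[CellObject], list[DiscardRecord]]:
    """Connected components of a mask, area-filtered to cell objects.

    Components with area strictly below ``min_area_px`` or strictly above
    ``max_area_px`` are excluded but reported in the returned discard
    ledger (bounds inclusive).  Connectivity is 8 by default, matching
    particle-analysis convention.
    """
    if not (0 < min_area_px <= max_area_px):
        raise ValueError("need 0 < min_area_px <= max_area_px")
    if connectivity not in (4, 8):
        raise ValueError("connectivity must be 4 or 8")
    lab = label(mask.mask, connectivity=1 if connectivity == 4 else 2)
    cells: list[CellObject] = []
    discards: list[DiscardRecord] = []
    for prop in regionprops(lab):
        area = int(prop.area)
        if area < min_area_px:
            discards.append(DiscardRecord(prop.label, area, "too_small"))
            continue
        if area > max_area_px:
            discards.append(DiscardRecord(prop.label, area, "too_large"))
            continue
        pixels = np.asarray(prop.coords, dtype=int)
        means: dict[str, float] = {}
        if intensity_image is not None:
            rr, cc = pixels[:, 0], pixels[:, 1]
            means = {
                name: float(arr[rr, cc].mean())
                for name, arr in intensity_image.channels.items()
            }
        cells.append(CellObject(
            cell_id=int(prop.label),
            channel_or_subtype=mask.channel,
            pixels=pixels,
            area_px=area,
            centroid_px=(float(prop.centroid[0]), float(prop.centroid[1])),
            mean_intensity=means,
        ))
    return cells, discards
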