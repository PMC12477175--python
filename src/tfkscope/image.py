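"""Multi-channel image container and TIFF I/O.

A single acquisition is held as an ordered mapping of channel name to a 2-D
float intensity array, together with the pixel calibration and sample
metadata.  Images travel between stages of the pipeline in this container;
on disk they are multi-page TIFFs with one page per channel and the channel
name recorded in each page description.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import tifffile

#: Channel roles used by the two staining panels.
LOCALIZATION_PANEL = ("CD19", "CD4", "BCL6", "TIA1")
TREG_CONTACT_PANEL = ("FOXP3", "CD4", "BCL6", "TIA1")

GROUP_LABELS = ("LN", "FL_1-2", "FL_2-3A", "other")

MAX_CHANNELS = 5  # 4 markers + optional nuclear channel


@dataclass
class MultiChannelImage:
    """Named 2-D intensity channels of one acquisition.

    Parameters
    ----------
    channels
        Ordered mapping channel name -> 2-D non-negative float array.
        All channels must share one shape; at most 5 channels.
    pixel_size
        Pixel calibration in micrometres per pixel.
    sample_id
        Identifier of the tissue sample the acquisition belongs to.
    group_label
        Cohort label, one of ``LN``, ``FL_1-2``, ``FL_2-3A`` or ``other``.
    provenance
        Free-text acquisition / processing notes, appended to by the
        preprocessing steps for audit.
    """

    channels: dict[str, np.ndarray]
    pixel_size: float = 0.5
    sample_id: str = "sample"
    group_label: str = "other"
    provenance: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= len(self.channels) <= MAX_CHANNELS:
            raise ValueError(
                f"expected 1..{MAX_CHANNELS} channels, got {len(self.channels)}"
            )
        shapes = {arr.shape for arr in self.channels.values()}
        if len(shapes) != 1:
            raise ValueError(f"channels disagree on shape: {sorted(shapes)}")
        for name, arr in self.channels.items():
            if arr.ndim != 2:
                raise ValueError(f"channel {name!r} is not 2-D")
            if np.any(arr < 0):
                raise ValueError(f"channel {name!r} has negative intensities")
        if self.group_label not in GROUP_LABELS:
            raise ValueError(
                f"group_label {self.group_label!r} not in {GROUP_LABELS}"
            )
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def channel_names(self) -> list[str]:
        return list(self.channels)

    def channel(self, name: str) -> np.ndarray:
        if name not in self.channels:
            raise KeyError(
                f"channel {name!r} not present (have {self.channel_names})"
            )
        return self.channels[name]

    def with_channels(self, channels: dict[str, np.ndarray],
                      note: str | None = None) -> "MultiChannelImage":
        """Copy of this image with replaced channel data (metadata kept)."""
        prov = list(self.provenance)
        if note:
            prov.append(note)
        return MultiChannelImage(
            channels=channels,
            pixel_size=self.pixel_size,
            sample_id=self.sample_id,
            group_label=self.group_label,
            provenance=prov,
        )


def read_image(
    path,
    channel_names: list[str] | None = None,
    pixel_size: float | None = None,
    sample_id: str = "sample",
    group_label: str = "other",
) -> MultiChannelImage:
    """Read a multi-page TIFF / OME-TIFF into a :class:`MultiChannelImage`.

    Pages are bound to ``channel_names`` in order.  When ``channel_names``
    is None the per-page descriptions written by :func:`write_image` are
    used instead.  Pixel size is taken from TIFF resolution metadata when
    present (resolution unit micron/centimetre), else from the
    ``pixel_size`` argument, else the 0.5 µm/px default.
    """
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.pages
        n_pages = len(pages)
        arrays = [p.asarray() for p in pages]
        descriptions = [p.description or "" for p in pages]
        meta_pixel_size = _pixel_size_from_tags(pages[0]) if n_pages else None

    if channel_names is None:
        channel_names = [
            d.strip() if d.strip() else f"ch{i}"
            for i, d in enumerate(descriptions)
        ]
    if len(channel_names) != n_pages:
        raise ValueError(
            f"page count ({n_pages}) does not match channel-name count "
            f"({len(channel_names)})"
        )
    if pixel_size is None:
        pixel_size = meta_pixel_size if meta_pixel_size else 0.5
    channels = {
        name: np.asarray(arr, dtype=np.float64)
        for name, arr in zip(channel_names, arrays)
    }
    return MultiChannelImage(
        channels=channels,
        pixel_size=pixel_size,
        sample_id=sample_id,
        group_label=group_label,
        provenance=[f"read from {path}"],
    )


def write_image(img: MultiChannelImage, path, dtype=np.uint16) -> None:
    """Write as a multi-page TIFF, one page per channel.

    Float data are quantized to the requested integer dtype (default
    16-bit); values outside the dtype range are clipped.  The channel name
    is stored in each page description and the pixel size in the TIFF
    resolution tags (micron unit), so :func:`read_image` round-trips both.
    """
    info = np.iinfo(dtype)
    res = 1.0 / img.pixel_size  # pixels per micron
    with tifffile.TiffWriter(str(path)) as tw:
        for name, arr in img.channels.items():
            data = np.clip(np.rint(arr), info.min, info.max).astype(dtype)
            tw.write(
                data,
                description=name,
                resolution=(res, res),
                resolutionunit="MICROMETER",
                contiguous=False,
            )


def _pixel_size_from_tags(page) -> float | None:
    try:
        unit = page.tags["ResolutionUnit"].value
        xres = page.tags["XResolution"].value
    except KeyError:
        return None
    num, den = xres if isinstance(xres, tuple) else (xres, 1)
    if not num:
        return None
    px_per_unit = num / den
    # RESUNIT: 3 = centimetre; tifffile writes MICROMETER as unit 9
    if getattr(unit, "value", unit) == 3:
        return 1e4 / px_per_unit  # µm per px from px per cm
    return 1.0 / px_per_unit
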