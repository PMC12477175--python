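"""Per-sample aggregation of counts, percentages and morphometry.

A sample may span several acquisitions; counts are summed across images
before any percentage is formed.  Percentages with an empty denominator
are None (an explicit undefined flag), never silently zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .contacts import ContactResult
from .phenotype import SubtypeCall
from .regions import CellLocation, RegionMorphometry

SUBTYPES = ("GC-B", "T_FH", "T_FK", "Treg", "other")


@dataclass
class ImageAnalysis:
    """Bundle of one acquisition's analysis results."""

    sample_id: str
    calls: list[SubtypeCall]
    locations: list[CellLocation]
    morphometry: RegionMorphometry | None = None
    contact_result: ContactResult | None = None


@dataclass
class SampleSummary:
    sample_id: str
    group_label: str
    n_images: int
    counts: dict[str, int]  # per subtype, totals over images
    counts_in_follicles: dict[str, int]  # compartment follicle or GC
    counts_in_gcs: dict[str, int]
    pct_tfk_of_tfh: float | None  # 100·T_FK/(T_FH+T_FK)
    pct_tfk_in_follicles: float | None  # of all detected T_FK
    pct_tfk_in_gcs: float | None
    pct_tfk_in_contact: float | None
    morphometry: RegionMorphometry | None = None
    notes: list[str] = field(default_factory=list)


def _pct(numerator: float, denominator: float) -> float | None:
    if denominator == 0:
        return None
    value = 100.0 * numerator / denominator
    if not 0.0 <= value <= 100.0:
        raise AssertionError(f"percentage {value} outside [0, 100]")
    return value


def summarize_sample(
    analyses: list[ImageAnalysis],
    group_label: str,
) -> SampleSummary:
    """Aggregate one sample's acquisitions into a :class:`SampleSummary`.

    All analyses must share one sample_id (mixed ids raise).  Counts are
    summed across images first; percentages are computed on the pooled
    counts.  Morphometry is pooled by concatenating region areas and
    averaging coverages over images.
    """
    if not analyses:
        raise ValueError("no analyses given")
    ids = {a.sample_id for a in analyses}
    if len(ids) != 1:
        raise ValueError(f"mixed sample_ids: {sorted(ids)}")
    sample_id = ids.pop()

    counts = {s: 0 for s in SUBTYPES}
    in_fol = {s: 0 for s in SUBTYPES}
    in_gc = {s: 0 for s in SUBTYPES}
    tfk_contact_ids = 0
    tfk_contact_total = 0
    notes: list[str] = []

    for a in analyses:
        loc_by_id = {loc.cell_id: loc for loc in a.locations}
        for call in a.calls:
            if call.subtype not in counts:
                continue
            counts[call.subtype] += 1
            loc = loc_by_id.get(call.cell_id)
            if loc is None:
                continue
            if loc.compartment in ("GC", "follicle"):
                in_fol[call.subtype] += 1  # GC cells count follicular too
            if loc.compartment == "GC":
                in_gc[call.subtype] += 1
        if a.contact_result is not None:
            tfk_contact_total += a.contact_result.n_tfk_total
            tfk_contact_ids += len(
                {p.tfk_id for p in a.contact_result.pairs})

    morpho = _pool_morphometry([a.morphometry for a in analyses
                                if a.morphometry is not None])

    n_tfh, n_tfk = counts["T_FH"], counts["T_FK"]
    pct_of_tfh = _pct(n_tfk, n_tfh + n_tfk)
    if pct_of_tfh is None:
        notes.append("pct_tfk_of_tfh undefined: no T_FH or T_FK detected")
    pct_fol = _pct(in_fol["T_FK"], n_tfk)
    pct_gc = _pct(in_gc["T_FK"], n_tfk)
    if n_tfk == 0:
        notes.append("T_FK compartment percentages undefined: 0 T_FK")
    pct_contact = (_pct(tfk_contact_ids, tfk_contact_total)
                   if tfk_contact_total else None)

    return SampleSummary(
        sample_id=sample_id,
        group_label=group_label,
        n_images=len(analyses),
        counts=counts,
        counts_in_follicles=in_fol,
        counts_in_gcs=in_gc,
        pct_tfk_of_tfh=pct_of_tfh,
        pct_tfk_in_follicles=pct_fol,
        pct_tfk_in_gcs=pct_gc,
        pct_tfk_in_contact=pct_contact,
        morphometry=morpho,
        notes=notes,
    )


def _pool_morphometry(parts: list[RegionMorphometry]
                      ) -> RegionMorphometry | None:
    if not parts:
        return None
    if len(parts) == 1:
        return parts[0]
    fol = [a for p in parts for a in p.follicle_areas_px]
    gc = [a for p in parts for a in p.gc_areas_px]
    import numpy as np
    px2um2 = None
    mean_fol = float(np.mean(fol)) if fol else 0.0
    mean_gc = float(np.mean(gc)) if gc else 0.0
    # per-image µm² means are consistent across images of one sample
    scale = (parts[0].mean_follicle_area_um2 / parts[0].mean_follicle_area_px
             if parts[0].mean_follicle_area_px else 1.0)
    return RegionMorphometry(
        n_follicles=sum(p.n_follicles for p in parts),
        n_gcs=sum(p.n_gcs for p in parts),
        follicle_areas_px=fol,
        gc_areas_px=gc,
        mean_follicle_area_px=mean_fol,
        mean_gc_area_px=mean_gc,
        mean_follicle_area_um2=mean_fol * scale,
        mean_gc_area_um2=mean_gc * scale,
        follicle_coverage=float(np.mean([p.follicle_coverage for p in parts])),
        gc_coverage=float(np.mean([p.gc_coverage for p in parts])),
    )


def summaries_to_frame(summaries: list[SampleSummary]) -> pd.DataFrame:
    """Flat per-sample table of the quantities fed to group statistics."""
    rows = []
    for s in summaries:
        row = {
            "sample_id": s.sample_id,
            "group_label": s.group_label,
            "n_images": s.n_images,
            "pct_tfk_of_tfh": s.pct_tfk_of_tfh,
            "pct_tfk_in_follicles": s.pct_tfk_in_follicles,
            "pct_tfk_in_gcs": s.pct_tfk_in_gcs,
            "pct_tfk_in_contact": s.pct_tfk_in_contact,
        }
        for sub in SUBTYPES:
            row[f"n_{sub}"] = s.counts[sub]
            row[f"n_{sub}_follicular"] = s.counts_in_follicles[sub]
            row[f"n_{sub}_gc"] = s.counts_in_gcs[sub]
        if s.morphometry:
            row["n_follicles"] = s.morphometry.n_follicles
            row["n_gcs"] = s.morphometry.n_gcs
            row["mean_follicle_area_um2"] = s.morphometry.mean_follicle_area_um2
            row["mean_gc_area_um2"] = s.morphometry.mean_gc_area_um2
            row["follicle_coverage"] = s.morphometry.follicle_coverage
            row["gc_coverage"] = s.morphometry.gc_coverage
        rows.append(row)
    return pd.DataFrame(rows)
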