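"""End-to-end orchestration: image → calls → locations → contacts → summary.

One acquisition flows through preprocessing, per-channel thresholding,
colocalization subtype calling, Treg identification, region allocation and
contact detection.  `run_pipeline` drives a whole synthetic sample and
writes deterministic CSV outputs (same config + seed ⇒ bit-identical
files), which is also how reproducibility is audited.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .contacts import ContactResult, detect_contacts, identify_tregs
from .image import MultiChannelImage
from .phenotype import SubtypeCall, call_subtypes, profile_candidate
from .preprocess import preprocess
from .regions import (RegionSet, assign_cells, auto_regions, measure_regions)
from .segment import (MAX_AREA_PX, MIN_AREA_PX, SignalMask, detect_cells,
                      threshold_channel)
from .summary import ImageAnalysis, SampleSummary, summarize_sample
from .synthetic import SynthConfig, generate_sample


@dataclass
class AnalysisParams:
    """Tunable knobs of the acquisition-analysis chain."""

    background_radius_px: float = 50.0
    do_background: bool = True
    do_deconvolve: bool = False
    psf_sigma_px: float = 2.0
    deconvolve_iterations: int = 10
    threshold_method: str = "multi_otsu"
    manual_thresholds: dict[str, float] = field(default_factory=dict)
    min_area_px: int = MIN_AREA_PX
    max_area_px: int = MAX_AREA_PX
    connectivity: int = 8
    tia1_overlap_frac: float = 0.5
    foxp3_overlap_frac: float = 0.25
    treg_min_overlap_frac: float = 0.25
    max_gap_px: float = 1.0
    profile_half_length_px: int = 15
    profile_filter: bool = False  # profiles always recorded; gating optional
    region_source: str = "given"  # given | auto


def threshold_panel(img: MultiChannelImage,
                    params: AnalysisParams) -> dict[str, SignalMask]:
    """Binarize every channel (Otsu default, per-channel manual override)."""
    masks = {}
    for name in img.channel_names:
        if name in params.manual_thresholds:
            masks[name] = threshold_channel(
                img, name, method="manual",
                manual_value=params.manual_thresholds[name])
        else:
            masks[name] = threshold_channel(
                img, name, method=params.threshold_method)
    return masks


def analyze_image(
    img: MultiChannelImage,
    params: AnalysisParams | None = None,
    regions: RegionSet | None = None,
) -> ImageAnalysis:
    """Full single-acquisition analysis.

    With all five panel channels present, subtype calling runs the
    localization logic (GC-B / T_FH / T_FK) plus FOXP3-based Treg
    identification and contact detection; regions come from the caller
    (manual/true ROIs) or are derived automatically from the CD19 and BCL6
    masks when ``params.region_source == "auto"``.
    """
    params = params or AnalysisParams()
    pre = preprocess(
        img,
        background_radius_px=params.background_radius_px,
        psf_sigma_px=params.psf_sigma_px,
        iterations=params.deconvolve_iterations,
        do_background=params.do_background,
        do_deconvolve=params.do_deconvolve,
    )
    masks = threshold_panel(pre, params)
    has_cd19 = "CD19" in masks
    has_foxp3 = "FOXP3" in masks

    calls: list[SubtypeCall] = []
    if has_cd19:
        calls = call_subtypes(
            masks, panel_kind="localization",
            min_area_px=params.min_area_px, max_area_px=params.max_area_px,
            tia1_overlap_frac=params.tia1_overlap_frac)
    elif has_foxp3:
        calls = call_subtypes(
            masks, panel_kind="treg_contact",
            min_area_px=params.min_area_px, max_area_px=params.max_area_px,
            tia1_overlap_frac=params.tia1_overlap_frac,
            foxp3_overlap_frac=params.foxp3_overlap_frac)

    # Intensity-profile confirmation of T_FK candidates (audit record;
    # optionally a hard filter).
    thresholds = {name: m.threshold_value for name, m in masks.items()}
    for call in calls:
        if call.subtype != "T_FK":
            continue
        prof = profile_candidate(pre, call,
                                 half_length_px=params.profile_half_length_px,
                                 thresholds=thresholds)
        call.evidence["profile_passed"] = prof.passed
    if params.profile_filter:
        calls = [c for c in calls
                 if c.subtype != "T_FK" or c.evidence.get("profile_passed")]

    # Treg identification from CD4 cell objects and the FOXP3 mask.
    contact_result: ContactResult | None = None
    if has_foxp3:
        cd4_cells, _ = detect_cells(
            masks["CD4"], params.min_area_px, params.max_area_px,
            connectivity=params.connectivity, intensity_image=pre)
        tregs = identify_tregs(cd4_cells, masks["FOXP3"],
                               min_overlap_frac=params.treg_min_overlap_frac)
        next_id = max((c.cell_id for c in calls), default=0) + 1
        for t in tregs:
            calls.append(SubtypeCall(
                cell_id=next_id, subtype="Treg",
                centroid_px=t.centroid_px, area_px=t.area_px,
                pixels=t.pixels,
                evidence={"cd4_component": t.cell_id,
                          "source": "foxp3_overlap"}))
            next_id += 1
        tfk_calls = [c for c in calls if c.subtype == "T_FK"]
        contact_result = detect_contacts(tfk_calls, tregs,
                                         max_gap_px=params.max_gap_px,
                                         image_shape=img.shape)

    if regions is None:
        if params.region_source == "auto" and has_cd19:
            regions = auto_regions(masks["CD19"], masks["BCL6"],
                                   pixel_size=img.pixel_size)
        else:
            regions = RegionSet(pixel_size=img.pixel_size, source="auto")
    locations = assign_cells(calls, regions)
    morphometry = measure_regions(regions, img.shape)

    return ImageAnalysis(
        sample_id=img.sample_id,
        calls=calls,
        locations=locations,
        morphometry=morphometry,
        contact_result=contact_result,
    )


def analyze_synthetic(
    config: SynthConfig,
    params: AnalysisParams | None = None,
    use_true_regions: bool = True,
):
    """Generate one synthetic sample and analyze it.

    ``use_true_regions`` feeds the planted follicle/GC geometry to the
    allocation step, mirroring the manually drawn ROIs of the real
    workflow; set it False to exercise automatic region derivation.
    """
    truth, img = generate_sample(config)
    regions = truth.regions if use_true_regions else None
    params = params or AnalysisParams()
    if not use_true_regions:
        params = AnalysisParams(**{**params.__dict__, "region_source": "auto"})
    analysis = analyze_image(img, params=params, regions=regions)
    return truth, img, analysis


# ------------------------------------------------------------ CSV output


def calls_frame(analysis: ImageAnalysis) -> pd.DataFrame:
    loc = {l.cell_id: l for l in analysis.locations}
    rows = []
    for c in analysis.calls:
        l = loc.get(c.cell_id)
        rows.append({
            "cell_id": c.cell_id,
            "subtype": c.subtype,
            "row": round(c.centroid_px[0], 3),
            "col": round(c.centroid_px[1], 3),
            "area_px": c.area_px,
            "compartment": l.compartment if l else "",
            "follicle_id": l.follicle_id if l else None,
            "gc_id": l.gc_id if l else None,
            "profile_passed": c.evidence.get("profile_passed", ""),
        })
    return pd.DataFrame(rows)


def contacts_frame(analysis: ImageAnalysis) -> pd.DataFrame:
    if analysis.contact_result is None:
        return pd.DataFrame(columns=["tfk_id", "treg_id", "boundary_gap_px"])
    return pd.DataFrame([
        {"tfk_id": p.tfk_id, "treg_id": p.treg_id,
         "boundary_gap_px": p.boundary_gap_px}
        for p in analysis.contact_result.pairs
    ], columns=["tfk_id", "treg_id", "boundary_gap_px"])


def morphometry_frame(analysis: ImageAnalysis) -> pd.DataFrame:
    m = analysis.morphometry
    if m is None:
        return pd.DataFrame()
    return pd.DataFrame([{
        "n_follicles": m.n_follicles,
        "n_gcs": m.n_gcs,
        "mean_follicle_area_px": round(m.mean_follicle_area_px, 4),
        "mean_gc_area_px": round(m.mean_gc_area_px, 4),
        "mean_follicle_area_um2": round(m.mean_follicle_area_um2, 4),
        "mean_gc_area_um2": round(m.mean_gc_area_um2, 4),
        "follicle_coverage": round(m.follicle_coverage, 6),
        "gc_coverage": round(m.gc_coverage, 6),
    }])


def run_pipeline(config: SynthConfig, out_dir,
                 params: AnalysisParams | None = None,
                 use_true_regions: bool = True) -> SampleSummary:
    """Synthetic sample → analysis → CSVs under ``out_dir``.

    Writes ground truth (cells/regions/contacts), subtype calls with
    compartments, contact pairs, morphometry and the per-sample summary.
    Outputs are a pure function of the config (including its seed).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    truth, img, analysis = analyze_synthetic(
        config, params=params, use_true_regions=use_true_regions)
    truth.write_csv(out / "ground_truth")
    calls_frame(analysis).to_csv(out / "calls.csv", index=False)
    contacts_frame(analysis).to_csv(out / "contacts.csv", index=False)
    morphometry_frame(analysis).to_csv(out / "morphometry.csv", index=False)
    summary = summarize_sample([analysis], group_label=img.group_label)
    from .summary import summaries_to_frame
    summaries_to_frame([summary]).to_csv(out / "summary.csv", index=False)
    return summary
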