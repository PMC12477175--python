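# Methods

## Quantification model

The pipeline treats a multiplex immunofluorescence acquisition as an
ordered set of 2-D marker channels (CD19, CD4, BCL6, TIA-1 and, in the
Treg panel, FOXP3) over one pixel grid. All downstream quantities are
derived from binary signal masks per channel, so the chain is:

    intensities → background subtraction → (optional deconvolution)
                → per-channel threshold → masks
                → colocalization components → subtype calls
                → region allocation / contacts → per-sample summary
                → group statistics

**Background subtraction** estimates each channel's background as a grey
opening with a flat disk (default radius 50 px, ≥ 5× the default cell
radius) and subtracts it, clipping at zero. The estimate is computed on
a 3×3-mean smoothed copy (tempering the downward bias of the erosion
under noise) and, for radii above 16 px, on a block-minimum downscaled
copy with the opening at reduced scale — the standard shrink
acceleration of rolling-ball correction. The image is edge-padded by the
ball radius before the opening so monotone illumination ramps are
reconstructed up to the border. A constant channel maps exactly to zero.

**Deconvolution** is Richardson–Lucy with a normalized Gaussian PSF
(default σ = 2 px, 10 iterations); σ = 0 is defined as the identity. It
is off by default: on synthetic data the thresholding chain recovers
ground truth without it, and no vendor PSF is available for the real
acquisitions. Background correction strictly precedes deconvolution;
running them reversed requires an explicit override flag.

**Thresholding** is per channel and per sample (laser gain differed
between tissues in the source acquisitions, so no global calibration is
assumed). `threshold_channel` defaults to classic Otsu with a manual
override. The *pipeline* default is the upper cut of a 3-class
multi-Otsu: rare markers such as TIA-1 occupy ≪ 1 % of the field, and
two-class Otsu then splits the background mode instead of separating
signal — a standard failure for strongly unbalanced histograms. The
3-class variant keeps an objective, parameter-free criterion while
remaining robust in exactly that regime; classic Otsu, quantile and
manual values remain available per channel, and every threshold is
recorded for audit.

**Cell objects and colocalization.** Single-marker cells are 8-connected
components of a mask; double-positive cells are components of the
pixelwise AND of two masks. Components with area outside the inclusive
[20, 200] px window are discarded but retained in a ledger, so retained
plus discarded always equals the component total. The bounds are
inclusive because the discard rule applies only to regions *strictly*
smaller than 20 or larger than 200 px.

**T_FH / T_FK split.** A retained CD4⁺BCL6⁺ component is T_FK iff at
least `tia1_overlap_frac` (default 0.5) of its pixels are TIA-1
positive, else T_FH. The source procedure overlays the channels without
stating a fraction; 0.5 makes the call majority-based and symmetric, and
the fraction is configurable. In the FOXP3 panel, a CD4⁺BCL6⁺ component
whose FOXP3 overlap reaches 0.25 is a T_FR-like cell: it is excluded
from the T_FH/T_FK tally (avoiding double counting against the Treg
logic) and returned tagged `foxp3_overlap`.

**Intensity-profile confirmation.** Each T_FK candidate gets a
horizontal line profile through its centroid (half-length 15 px, clipped
at borders). It passes when CD4, BCL6 and TIA-1 all attain their maxima
inside the candidate's own pixel span, above the channel threshold, and
CD19 (when present) does not. Profiles are always computed and recorded
with the call; by default they are an audit record rather than a hard
filter, because the colocalization + TIA-1 split already encodes the
same evidence — `profile_filter=True` turns them into a gate.

**Regions and allocation.** Follicle/GC geometry comes first-class from
manually drawn ImageJ ROIs (`.roi`/RoiSet `.zip`; names prefixed
`follicle`/`gc`; GC parentage by maximal containment, ambiguity is an
error, orphan GCs are flagged, never dropped). `auto_regions` is an
automated extension for unattended runs: the CD19 mask is closed with a
disk (default 15 px), hole-filled, then opened with the same disk (the
opening cuts single-cell bridges between follicles and removes isolated
extrafollicular cells), and each large component's convex hull becomes a
follicle — follicles are near-elliptic, so the hull is a faithful
outline of a cloud of discrete cell blobs. BCL6-dense components
intersecting a follicle are clipped to it and become its GC. Cells are
allocated by centroid containment, innermost first (GC before follicle,
boundary points resolve inward), so the allocation is deterministic and
every GC cell also contributes to its follicle's tally. Morphometry
counts rasterized pixels (×(µm/px)² for areas); coverage is computed on
the union so overlapping regions are not double-counted.

**Tregs and contacts.** A CD4 cell object is a Treg iff
|pixels ∩ FOXP3 mask| / area ≥ 0.25, inclusive, with the cell's own area
as denominator. "Direct contact" — manual in the source workflow —
is formalized as a boundary gap of at most `max_gap_px` (default 1),
where the gap is the minimum Chebyshev (8-connectivity) distance between
the two pixel sets minus one, floored at zero. Touching or diagonally
adjacent sets therefore have gap 0, and the default additionally admits
one empty pixel between outlines; Chebyshev is the digital adjacency
that makes diagonal touching count, and the tolerance supports
sensitivity analyses. Detection is symmetric in which set is dilated.

**Statistics.** Per-sample summaries pool counts over a sample's images
*before* forming percentages; a percentage with an empty denominator is
`None` (an explicit undefined flag), never silently zero, and such
samples are excluded from comparisons with the exclusion reported.
Mann–Whitney U uses full enumeration of the C(n, n₁) group assignments
whenever the combined n is at most 12 — the midrank U statistic makes
the enumeration valid with ties — and the normal approximation with tie
and continuity correction (scipy) above. Kruskal–Wallis uses the
chi-square approximation with tie correction (scipy), with an explicit
degenerate branch (all values identical → H = 0, p = 1, warning). Stars
follow `* p<0.05, ** p<0.005, *** p<0.001, **** p<0.0001` — note the
second tier is 0.005, not the conventional 0.01, matching the annotation
convention of the source figures exactly. Only the nonparametric tests
are the default (cohort sizes are small counts/percentages); a Welch
t-test and Benjamini–Hochberg adjustment exist behind flags but are not
part of the standard workflow, which applies no multiplicity correction.

## Synthetic tissue generator

The generator emulates the statistical structure the analysis assumes,
not histology. Defaults (one acquisition):

| parameter | default | rationale |
|---|---|---|
| field | 1024×1024 px @ 0.5 µm/px | 20× confocal field; calibration nominal |
| follicles | 5 ellipses, semi-axis 110 ± 8 px, axis ratio 0.7–1.0 | round-to-oval follicles, no mantle asymmetry |
| GC | concentric, 0.6 × follicle radius | GC-dominated follicles as in FL-like tissue |
| cells | 75 B, 75 GC-B, 60 T_FH, 20 T_FK, 40 Treg, 30 other | one field's worth; T_FH:T_FK ≈ 3:1 |
| cell radius | 4.5 ± 0.3 px, clipped to [3.8, 5.0] | area ≈ 45–80 px, mid particle window |
| marker amplitude | 200 per positive channel | hard disks; marker map B→CD19; GC-B→CD19,BCL6; T_FH→CD4,BCL6; T_FK→CD4,BCL6,TIA-1; Treg→CD4,FOXP3 |
| PSF | Gaussian σ = 1 px | flux-preserving blur |
| background | amplitude 20, smooth 4×4 random field | 10 % low-frequency shading |
| noise | additive Gaussian σ = 10, clipped at 0 | 5 % of amplitude; recovery also tested at σ = 40 |
| contact pairs | 4 T_FK–Treg placed with center distance = radius sum | touching boundaries |

Placement probabilities over (GC, follicle-non-GC, extrafollicular) per
type: GC-B (1, 0, 0); B (0.05, 0.75, 0.20); T_FH (0.6, 0.3, 0.1); T_FK
(0.5, 0.3, 0.2); Treg (0.1, 0.3, 0.6); other (0, 0, 1). Non-contact
cells are kept at center distance ≥ radius sum + 5 px so that, after PSF
blur and thresholding, masks of distinct cells stay disjoint and
ground-truth counts are unambiguous; `allow_overlap=True` lifts this for
stress tests (the dense region-recovery fixtures use it, since real
follicles are packed with B cells far beyond what unambiguous counting
permits). Placement is rejection sampling with bounded retries; requests
exceeding capacity raise an explicit error rather than degrading
silently. Everything is driven by one seed: identical configs produce
bit-identical ground truth, images and pipeline CSVs.

What the generator does **not** emulate: spectral bleed-through, nuclear
vs membranous stain texture, mantle-zone asymmetry, light/dark GC
zonation, 3-D structure, Poisson photon statistics (additive Gaussian
only), or cell-shape variation beyond disks. Consequently, passing
recovery tests shows the chain is correct under its stated assumptions
(separable cells, per-channel thresholds meaningful, regions
near-elliptic) — not that it is robust to every real-tissue artifact.

## Validation problem sizes

The test suite and `scripts/acceptance.py` exercise: exact phenotype
recovery on the default 1024² sample at σ_noise = 0; per-subtype count
error ≤ 5 % over 10 replicate seeds at σ_noise = 40 (0.2 × amplitude);
allocation of all 300 planted cells to their true compartment (≥ 99 %);
contact precision = recall = 1 on the 4 planted pairs with the pair set
equal to an all-pairs minimum-distance oracle; colocalization equal to a
flood-fill oracle on 200 random 64² mask pairs; Mann–Whitney exact p
equal to the enumeration oracle on every no-tie rank pattern up to
combined n = 10; Kruskal–Wallis H equal to the textbook rank formula to
1e-10 on 100 random instances; ≥ 90 % power for a 20-point shift
(sd 5, n = 8/group) with ≤ 10 % null rejections over 100 replicates; and
byte-identical CSVs across repeated runs.

## Known limitations

- Touching same-panel cells are not split (no watershed by default, as
  in the source pipeline); a planted contact pair appears as one CD4
  component, which is counted once as a Treg by FOXP3 fraction — correct
  for counts, but its centroid is the pair midpoint.
- Area calibration in µm² is nominal: the acquisition's true
  magnification-to-pixel mapping is not public; 0.5 µm/px is a plausible
  setting and configurable.
- `auto_regions` assumes convex (elliptic) follicles; strongly concave
  or merging follicles would need the manual-ROI route.
- The exact deconvolution settings of the original Fiji macro are not
  published; Richardson–Lucy with a Gaussian PSF is a standard,
  testable stand-in and is disabled by default.
- Whether per-sample averages in the source figures pool per image or
  per region is not always stated; the summary layer pools counts per
  sample and reports per-image morphometry lists so either aggregation
  can be formed.
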