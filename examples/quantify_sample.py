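"""Run the full quantification chain on a synthetic sample.

The pipeline sees only the rendered image (plus the follicle/GC ROIs, as
in the real workflow where they are drawn manually): background
subtraction, per-channel thresholding, colocalization subtype calling,
Treg identification, compartment allocation and contact detection.  The
printout compares recovered numbers with the planted ground truth.
"""

from collections import Counter

from tfkscope import SynthConfig, analyze_synthetic, summarize_sample

config = SynthConfig(seed=1)
truth, image, analysis = analyze_synthetic(config)

got = Counter(call.subtype for call in analysis.calls)
want = truth.counts()
print("subtype counts (recovered / planted):")
for subtype in ("GC-B", "T_FH", "T_FK", "Treg"):
    print(f"  {subtype:5s}  {got[subtype]:3d} / {want[subtype]:3d}")

summary = summarize_sample([analysis], group_label="other")
print(f"pct_tfk_of_tfh       = {summary.pct_tfk_of_tfh:.1f}  "
      "(T_FK share of the CD4+BCL6+ follicular T compartment)")
print(f"pct_tfk_in_follicles = {summary.pct_tfk_in_follicles:.1f}  "
      "(T_FK located in follicles, GC included)")
print(f"pct_tfk_in_gcs       = {summary.pct_tfk_in_gcs:.1f}")
print(f"pct_tfk_in_contact   = {summary.pct_tfk_in_contact:.1f}  "
      "(T_FK with a Treg touching their boundary)")
m = summary.morphometry
print(f"morphometry: {m.n_follicles} follicles "
      f"(mean {m.mean_follicle_area_um2:.0f} um^2), {m.n_gcs} GCs "
      f"(mean {m.mean_gc_area_um2:.0f} um^2), "
      f"follicle coverage {100 * m.follicle_coverage:.1f}% of the field")
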