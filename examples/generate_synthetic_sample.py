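"""Generate one synthetic lymphoid-tissue acquisition with ground truth.

Builds the default 1024x1024 px sample (five follicles with germinal
centers, 300 cells of six phenotypes, four planted T_FK-Treg contact
pairs), renders the five marker channels and prints what was planted.
"""

from tfkscope import SynthConfig, generate_sample, write_image

config = SynthConfig(seed=1)
truth, image = generate_sample(config)

print("channels:", ", ".join(image.channel_names))
print("follicles:", len(truth.regions.follicles),
      "| germinal centers:", len(truth.regions.gcs))
print("planted cells per phenotype:", truth.counts())
print("planted T_FK-Treg contact pairs:", len(truth.contacts))

by_region = {}
for cell in truth.cells_of_type("T_FK"):
    by_region[cell.true_region] = by_region.get(cell.true_region, 0) + 1
print("T_FK compartments (ground truth):", by_region)

write_image(image, "scratch_example_image.tif")
truth.write_csv("scratch_example_truth")
print("wrote scratch_example_image.tif (one TIFF page per channel) and "
      "scratch_example_truth/{cells,regions,contacts}.csv")
# The counts above are the ground truth that the quantification pipeline
# (see quantify_sample.py) must recover from the rendered image alone.
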