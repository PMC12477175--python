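"""Import manually drawn follicle/GC ROIs and allocate cells to them.

The real workflow draws follicle and GC outlines in ImageJ (saved as a
RoiSet zip, names prefixed "follicle"/"gc").  Here we write such a file
ourselves, read it back, check the GC-inside-follicle nesting, and
allocate a few cells by centroid containment.
"""

import numpy as np
from shapely.geometry import box

from tfkscope import assign_cells, import_regions, measure_regions
from tfkscope.ijroi import write_roi_zip
from tfkscope.phenotype import SubtypeCall


def coords(poly):
    xs, ys = np.asarray(poly.exterior.coords).T
    return xs, ys


write_roi_zip("scratch_example_rois.zip", {
    "follicle_1": coords(box(10, 10, 120, 100)),
    "gc_1": coords(box(40, 30, 90, 80)),
    "follicle_2": coords(box(150, 40, 240, 130)),
    "gc_2": coords(box(170, 60, 215, 110)),
})

regions = import_regions("scratch_example_rois.zip", pixel_size=0.5)
regions.validate_nesting()
print("follicles:", len(regions.follicles), "| GCs:", len(regions.gcs),
      "| orphan GCs:", len(regions.orphan_gcs))

morpho = measure_regions(regions, image_shape=(256, 256))
print(f"mean follicle area {morpho.mean_follicle_area_um2:.0f} um^2, "
      f"mean GC area {morpho.mean_gc_area_um2:.0f} um^2")

cells = [SubtypeCall(i, "T_FK", pos, 1, np.array([[int(pos[0]),
                                                   int(pos[1])]]))
         for i, pos in enumerate([(50, 60), (20, 15), (5, 200)], start=1)]
for call, loc in zip(cells, assign_cells(cells, regions)):
    print(f"cell at (row, col) = {call.centroid_px} -> {loc.compartment}")
# GC-resident cells also count toward their follicle's tally downstream,
# so follicular counts are always >= GC counts per follicle.
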