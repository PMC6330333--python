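"""Detect labeled somata in a synthetic section and check against truth.

Runs the full single-section chain: median filter, automatic cell threshold
from the correlation curve, connected-component grouping, and area/roundness
filters, then matches detections to the generator's ground-truth centroids.
"""

import numpy as np

from mctrace import correlation_curve, find_cells, transition_thresholds
from mctrace.segmentation import median_filter
from mctrace.synthetic import RegionSpec, SyntheticBrainSpec, generate

spec = SyntheticBrainSpec(
    n_sections=1, section_shape=(256, 256), axes=(90.0, 70.0),
    regions=[RegionSpec(name="tissue", label=1, n_cells=25,
                        min_spacing_px=7.0)],
    seed=9,
)
sections, _, truth = generate(spec)
section = sections[0]

curve = correlation_curve(median_filter(section.pixels, 3), section.bit_depth)
sel = transition_thresholds(curve)
cells = find_cells(section, sel.cell_threshold)

true_pts = truth.cells[["row", "col"]].to_numpy()
got = np.array([c.centroid_px for c in cells])
dists = [np.sqrt(((got - p) ** 2).sum(axis=1)).min() for p in true_pts]

print(f"true somata:      {len(true_pts)}")
print(f"detected somata:  {len(cells)}  (threshold {sel.cell_threshold})")
print(f"worst centroid error: {max(dists):.2f} px")
print(f"mean area: {np.mean([c.area_px for c in cells]):.1f} px, "
      f"mean roundness: {np.mean([c.roundness for c in cells]):.2f}")
print()
print("At this low density every soma is recovered with sub-pixel to")
print("few-pixel centroid accuracy; the roundness is near 1 because the")
print("median filter rounds the rendered cell bodies.")
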