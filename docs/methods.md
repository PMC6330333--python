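# Methods

## Scope and model

`mctrace` reconstructs a brain from an ordered stack of coronal fluorescence
sections and maps retrogradely labeled somata to named regions. The model of
the data is deliberately minimal: each section is a 2D grayscale raster
containing up to three intensity populations — near-black off-section
background, dim tissue autofluorescence, and bright labeled somata — whose
means drift smoothly along the rostro-caudal axis; anatomy is supplied as
per-section integer label masks with a name table rather than inferred.
Coordinates are 0-based `(row, col)`, row 0 at the top; physical position is
`index × pixel_size`, and the rostro-caudal coordinate is
`section index × thickness`. Axis semantics used by every report:
dorsal–ventral = rows, medial–lateral = columns, rostral–caudal = section
order.

## Maximum correlation thresholding

For threshold `i` the binary indicator is `yₙ = 1` iff `xₙ > i` — strictly
greater, one convention used everywhere. The correlation curve is the Pearson
correlation between the image and that indicator, evaluated for every gray
level through the histogram closed form (suffix sums over the histogram; no
masks are materialized). The curve is undefined where the mask is empty or
full (`Nᵢ ∈ {0, Nₘ}`); those entries are flagged NaN, never silently zero,
and a constant image raises a degenerate-input error. Correctness is pinned
by an independent oracle test: on random small images the closed form equals
the literal mask-and-correlate computation at every threshold to 1e-9, and
the argmax agrees. Argmax ties are broken toward the lowest threshold
(deterministic, favors inclusion).

**Transitions.** The derivative (first finite difference) of the curve shows
one sharp excursion per intensity population the threshold sweeps through.
The gray value at which an excursion *begins* is the useful threshold: just
below the tissue population it reproduces the whole tissue silhouette, just
below the soma population it keeps only labeled cells. Detection smooths
|derivative| with a 5-point moving average, finds local maxima at least 5
gray levels apart, accepts them in magnitude order, and reports each
excursion's left base — the first gray value of a sustained (≥ 3 levels) run
below 5% of the peak height, so single-level noise dips inside a broad
excursion are stepped over. Peaks sharing a base collapse to one transition,
preventing a ragged excursion from consuming both slots. With two
transitions requested the lower is the tissue-edge threshold and the higher
the cell threshold; if fewer distinct excursions exist the found subset is
returned and the shortfall flagged. Per-section manual overrides are
accepted through the run configuration, mirroring how an experimenter would
pick values off the plotted curve. Curves are computed on the
median-filtered image, matching the processing order used for segmentation.

## Segmentation

* **Median filter:** 3×3 by default (smallest window that removes isolated
  saturated pixels, the stated purpose), edge-replicated borders,
  configurable.
* **Grouping:** 8-connectivity by default (exposed in config); components
  partition the foreground exactly.
* **Morphology filters:** area within [64, 6400] µm² (converted to pixels
  via the pixel size; at 4 µm/px that is 4–400 px, accepting single somata
  and rejecting specks and large clumps) and circularity
  `4πA/P² ≥ 0.4`. The perimeter comes from the hand-implemented
  Moore-Neighbor contour trace (clockwise from the top-left-most pixel;
  termination on repeated walk state, which is Jacob's stopping criterion);
  digital circularity can exceed 1 for few-pixel blobs because the traced
  perimeter under-measures, so the stored statistic is capped at 1.
* **Merged somata are not split.** Touching cells become one component that
  is either counted once or rejected by the area/roundness filters. This is
  a documented property of the method, not a defect to engineer away: it
  produces the density-dependent undercount that the validation module
  measures (negative mean signed error in the densest decile, negative
  Spearman correlation of error against density).

Tissue boundaries are the outer contours only (silhouettes); holes are
ignored. Boundaries are rasterized and convolved with an isotropic Gaussian
(σ = 2 px by default, kernel truncated at 4σ) before alignment so the match
score is insensitive to single-pixel contour noise.

## Alignment

Rigid integer translation only, chain-aligned: section 0 is fixed and each
subsequent section takes the shift (exhaustive search over a square window,
default radius 50 px at the working resolution, 10 px in the pipeline
defaults) maximizing Pearson correlation between its smoothed boundary
raster and the previous aligned section. Score ties break toward the
smaller shift. Sections with no usable boundary inherit the previous
transform and are flagged. For large sections the search can run at pyramid
level 2 with shifts rescaled ×4 to level 0. Validation dilates each aligned
boundary with a disc of radius t (the edge-thickness tolerance) and reports
the full pairwise correlation matrix per t; on a smoothly varying stack
adjacent-section correlation exceeds the lag-5 correlation at every
thickness. Rotation, scaling, and nonrigid deformation are out of scope.

## Quantification conventions

Cells are assigned the region label under their centroid pixel in the
section's native frame (label masks and detections live in the same frame,
so the rigid transform cancels; no area voting — deterministic point
counting). Label 0 is "unassigned" and reported separately; percentages are
over assigned cells and sum to 100. Injection-site precision treats a layer
label nested inside an organ label: the organ's cells are those on either
label, the center of mass is their arithmetic mean in micrometers, and
"normalized to injection site" density maps subtract that center before
binning. Cells outside their section's traced tissue boundary are flagged by
a point-in-polygon test, never dropped.

## The synthetic generator

The generator is the package's ground-truth engine and defines its study
conditions. Tissue is an ellipse per section (axes may vary linearly along
the stack); regions are radial/angular sectors of the normalized ellipse, so
nested rings (granule cell layer inside the bulb) and wedge partitions are
exact and non-overlapping. Somata render as flat-core blobs (core radius
1.3 px, Gaussian edge σ 0.5 px) composited by per-pixel maximum, so blobs
placed within touching distance merge exactly as clumped cells do. Default
intensity model (8-bit): background 0, tissue 50 ± 5, soma peak 200 ± 10,
multiplicative per-section decay `exp(−rate × rc)` on tissue and soma,
shot noise as isolated saturated pixels at rate 1e-4. Desk scale is
512×512 px at 4 µm/px with 100 µm section thickness; all algorithms are
resolution-agnostic. A single seed fixes every draw; identical specs render
bit-identical stacks.

Packaged fixtures and their conditions:

* **fig2_gradient** — 10 sections, decay 0.04/section: per-section curves
  and monotonically declining optimal thresholds.
* **fig3_density_sweep** — 100 sections, true counts geometric from 10 to
  2,000, overlap fraction (cells placed deliberately touching a neighbor)
  rising linearly with density to 0.25. Grounds the count-agreement R² and
  the undercount analysis.
* **fig4_example** — granule-layer ring nested in a 20-section bulb, 1,500
  cells, 84% placed in-layer. The nine-replicate suite fixes in-layer
  proportions (0.84, 0.99, 0.93, 0.55, 0.62, 0.71, 0.95, 0.86, 0.75):
  mean exactly 0.80, spread matching the reported 80 ± 19% across
  experiments.
* **fig5_distribution** — 11 labeled regions over 16 sections. The named
  percentages of the reference feedback accounting (ipsilateral AON 58,
  contralateral AON 5, piriform+nLOT 27.9, HDB 3.5, amygdala 1.4, zona
  incerta 0.001, piriform–entorhinal transition 0.001, hypothalamus 0.08,
  entorhinal cortex 0.3, CA1 0.75) total 96.93, not 100; the remainder
  (3.068%) is carried by an explicit "Unattributed" label flagged
  non-olfactory rather than silently renormalizing, making the
  non-olfactory total ≈ 9.1%. Wedge widths are proportional to region
  share, so expected cell density is equal everywhere and density-dependent
  merge losses cancel in recovered percentages. Per-region counts are one
  multinomial draw from the proportions, recorded exactly.
* **fig6_injection** — adjacent main and accessory olfactory bulb
  granule-layer masks across 26 sections, 3,000 injection cells. The
  reference accounting lists compartment shares of 99.3% and 0.07%, which
  cannot both be exact for a two-compartment split; the fixture reads the
  minority share as 0.7% so placement totals 100% and the majority share of
  the pair is exactly the quoted 99.3%.
* **alignment_shifts** — smoothly growing ellipses with known integer
  per-section shifts for exact recovery.

**What the generator does not emulate:** optical point-spread functions,
vignetting and flat-field structure, autofluorescent anatomy (fiber tracts,
ventricles), dendritic processes, multi-channel crosstalk, and real
atlas-shaped region geometry. Passing tests therefore demonstrate that the
algorithms recover what they assume — two separable intensity populations
and label masks consistent with cell placement — not that segmentation is
robust to structured artifacts absent from the model.

## Numerical choices and degenerate inputs

Pyramid levels are non-overlapping 2×2 block means (stride 2), odd
dimensions edge-replicated, values kept in floating point until export, and
levels stop early at 1×1. Blank sections yield flagged (None) curves without
aborting a stack; empty masks yield empty boundary/group lists; both-empty
compartments flag an undefined ratio; zero-variance count lists flag a
degenerate comparison. All randomness flows from explicit seeds; the
detection path itself contains none.

## Known limitations

* Counting accuracy degrades with label density by design (no watershed
  splitting); the top-decile mean error on the density sweep is strongly
  negative.
* Thin wedge stand-in regions (CA1 occupies ≈ 2.7° of every section in the
  distribution fixture) sit closer than one merge distance to their
  neighbors, which measurably depresses rare-region recovery at high
  density (≈ −0.1 to −0.2 percentage points on CA1 at 20,000 cells) while
  remaining within the stated tolerance.
* Alignment is translation-only; rotated or nonrigidly distorted sections
  will align imperfectly and depress boundary correlations.
* Region assignment trusts the label masks; misdrawn masks propagate
  directly into percentages.

## Problem sizes

The test suite and the acceptance script run entire stacks at desk scale:
100 × 512² sections for the density sweep, 16–26 × 512² for the
distribution/injection fixtures (5,000–20,000 cells), 9 × 20-section
replicates, all seeded. A full acceptance run is ~1 minute on one CPU; the
full test suite ~1 minute.
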