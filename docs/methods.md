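# Methods

## Data model and conventions

All images are 2-D arrays indexed `[row, col]`, 0-based. Intensities are
raw counts (IMC ion counts or equivalent) and are never rescaled on
read; the binarization threshold below is defined on raw values.
Distances are Euclidean in pixel units and converted to µm by
`pixel_size_um` (1.0 by default, the nominal IMC resolution). Cell label
masks are integer images with 0 as background; label ids need not be
consecutive and are never renumbered, because segmentation tools may
drop labels.

## Single-cell quantification and statistics

`quantify_cells` measures each labelled object: the centroid is the
unweighted mean of member-pixel coordinates and the per-marker intensity
is the mean over member pixels (the CellProfiler
`MeasureObjectIntensity` convention). A cell is called *positive* for a
marker when its mean intensity is strictly greater than that marker's
threshold; by default every marker inherits the global binary threshold
of 60 counts, overridable per marker (`positivity_threshold`). Strict
inequality was chosen so the threshold value itself is never counted as
expression, the same convention as the pixel mask.

The *percentage count* of a marker is its positive-cell count divided by
the number of cells positive for at least one marker; it is undefined
(an error, not 0) when no cell expresses anything. Pearson correlations
are computed over all cells without positivity gating, matching how
whole-ROI single-cell scatter correlations are usually reported; the
two-condition comparison uses the Fisher Z statistic
`z = (atanh r1 − atanh r2)/sqrt(1/(n1−3) + 1/(n2−3))` with a two-sided
normal p. Distribution comparisons use the asymptotic two-sample
Kolmogorov–Smirnov test — appropriate because cell counts are in the
10^4–10^5 range in the intended use. Box-plot summaries use linear
interpolation for quartiles and the 1.5·IQR outlier fences, with min/max
reported after excluding outliers.

## Anatomy clustering

Marker masks come from strict thresholding (`intensity > 60` counts; the
value is the toolkit's fixed default, exposed in `AnalysisConfig`). The
*area ratio* is the positive-pixel fraction of the image. Anatomy
discovery flattens each marker's boolean mask to a pixel vector and runs
k-means with markers as observations — an n_markers × n_pixels matrix —
so the clusters group markers by spatial co-occupancy, never pixels by
intensity. K-means uses Lloyd's algorithm with 10 restarts, 300 max
iterations and tolerance 1e-4 (the common library defaults), keeping the
best inertia; K defaults to 6, the number of distinct spatial patterns
the toolkit targets in tonsil-scale tissue, with no automatic selection.
Markers are sorted by name before clustering so the assignment is
invariant to input order for a given seed. A stride option subsamples
pixels for very large ROIs; it is off by default since boolean masks
keep the exact path affordable.

Cluster visualization: each cluster's member images are averaged
pixel-wise, contrast-stretched between the 2nd and 98th intensity
percentiles (a constant image maps to all-zero — no contrast), tinted
with the colour at position i/K on the `gist_rainbow` colormap, and
combined by per-pixel maximum so each anatomical region retains its own
hue.

## Spatial distances

For marker pair (a, b), each a-positive cell contributes the distances
to its k nearest b-positive cells (k = 10 by default, the ten-neighbor
convention; Euclidean metric); the directed mean pools over all query
cells and neighbors. k clamps to the reference-set size rather than
erroring, because sparse markers are routine. When query and reference
are the same marker the exact self-pair is excluded. Directed entries
are stored asymmetrically; undirected summaries (intra-cluster edges)
average the two directions, and the inter-cluster distance averages all
directed entries between two clusters' marker sets. The *proximity
fraction* is the k = 1 case: the mean nearest-neighbor distance and the
share of distances strictly below a 30 µm cutoff — roughly three cell
diameters, the scale at which two cell populations read as intermingled.

Proximity maps link every origin cell to its single nearest destination
cell (ties broken by lowest index for determinism) and histogram the
link distances into 20 equal-width bins over [0, max] as proportions.
When every distance is zero the range is degenerate and the whole mass
is placed in a single bin at 0. Nearest-neighbor rather than all-pairs
distances keep the map unbiased by the destination marker's area and
density.

## Topography

A marker image is Gaussian-smoothed (default sigma 5 px, reflect
boundary — reflection avoids edge dimming that would shift border
peaks), downsampled by a stride (default 4) and given evenly spaced
contour levels between its min and max. Peaks are local maxima above a
height floor, kept greedily in descending height under a minimum
separation constraint; coordinates are reported at full resolution
(grid indices × stride). The peak distance between two markers matches
each peak of the first to its nearest peak of the second and averages,
in µm. Nearest-neighbor matching (not optimal assignment) is the
simplest defensible reading of an "average distance between the peaks";
both the matching rule and the peak definition are explicit knobs.

## Networks and the reference framework

Graph nodes are markers, sized by area ratio and coloured by anatomical
cluster; edge weights are mean k-NN distances, min-max normalized over
the edge set so a red-to-blue colormap spans close-to-distant. A graph
with one edge (or all-equal weights) normalizes to 0, the "close" end —
avoiding 0/0. Layouts use the Fruchterman–Reingold spring embedding
(k = 0.3, 30 iterations for cluster maps; k = 3.0, 5 iterations for the
reference map), deterministic given a seed.

The reference framework pins landmark markers — seven nuclear/core
lymphocyte markers expected in every dataset — at evenly spaced
positions on a unit circle, in list order; any fixed documented
arrangement serves, since only cross-dataset comparability matters.
Every marker gets directed edges to its five spatially closest markers
(smallest mean k-NN distance; the arrow points at the close marker),
clamped to n−1 when fewer markers exist. Fixed nodes are returned
bit-identically by the layout.

## Synthetic phantoms

`TissuePhantomSpec` plants geometric anatomical regions (discs, annuli,
bands, half-planes; first-listed region wins where shapes overlap), a
marker panel with per-region enrichment weights over a low baseline, and
non-overlapping circular cells placed by rejection sampling (≤ 1000
attempts per cell, then a generation error suggesting lower density).
Defaults emulate the study conditions at desk scale: 500×500 px ROIs
(the full 2500×2500 scale is configurable), baseline 5 counts and
enrichment amplitudes of ~90–120 counts so the fixed 60-count threshold
cleanly separates background from expression, 4 cells per 100×100 px,
cell radius 3 px. A cell is positive for every marker enriched in its
region; optional pairwise coexpression probabilities convert
single-positive cells to double-positive. Rendering: the tissue field is
`baseline + region weight`; each positive cell is a flat disc at
`baseline + amplitude + N(0, noise_sd)` clipped at zero, with noise
drawn once per cell and marker. Cell-level (not pixel-level) noise keeps
per-cell means exact, so quantification correctness is testable to
machine precision; the emitted cell table is always re-measured from the
rendered images and mask, never copied from ground truth.

`generate_point_pattern` plants a fixed-magnitude nearest-neighbor
offset: each of the first min(n_a, n_b) B points is its A partner plus
the offset in a random direction plus isotropic Gaussian jitter; surplus
B points are uniform. The default frame scales as
`max(500, 20·offset·sqrt(max(n_a, n_b)))` µm, which keeps the
probability that a bystander point intercepts the nearest-neighbor
search below ~1%, so the mean A→B nearest distance estimates the
planted offset.

What the phantoms do **not** emulate: IMC noise physics (plume
spillover, isotope impurity, Poisson counting), irregular cell shapes
and nucleus/membrane structure, intensity gradients within regions, and
3-D tissue. Passing tests therefore demonstrate algorithmic correctness
on idealized tissue geometry — recovery of planted anatomy, offsets and
groupings — not robustness to real acquisition noise.

## Problem sizes and determinism

Test and acceptance runs use 150–500 px phantoms with 4–8 markers and
tens to hundreds of cells, and point patterns of up to 500 points —
sizes at which brute-force oracles (full pairwise distance matrices,
exhaustive partition search up to 6 markers) are exact and fast.
All randomness flows from explicit seeds; the pipeline derives per-stage
seeds by hashing the stage name into the global seed (CRC32, folded
below 2^31), so adding a stage never shifts another stage's stream. Two
runs of the full pipeline with one seed produce byte-identical CSVs.

## Known limitations

* Positivity is a hard threshold on mean intensity; no per-marker
  automatic thresholding (e.g. Otsu) is provided.
* The k-means assignment is a local optimum; with 10 restarts on
  planted-structure phantoms recovery is empirically ≥ 95/100 seeds, but
  no global guarantee exists.
* Peak matching is directional nearest-neighbor, so `peak_distance(a, b)`
  and `peak_distance(b, a)` can differ for multi-peak sets.
* The inter-cluster graph connects cluster supernodes only; marker nodes
  are carried for colouring but not linked to their supernode.
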