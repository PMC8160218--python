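# spatialviz

Spatial analysis and visualization of highly multiplexed tissue protein
images — imaging mass cytometry (IMC) and similar modalities that produce
one ~1 µm/pixel intensity image per protein marker plus a cell
segmentation mask.

The toolkit links two views of the same tissue:

* **bottom-up (single cells):** per-cell mean intensities and centroids
  from a label mask, marker positivity, percentage counts
  (cells positive for a marker / cells positive for any marker), Pearson
  correlations between markers with a Fisher Z two-sample comparison
  across conditions, and two-sample Kolmogorov–Smirnov tests;
* **top-down (anatomy):** each marker image binarized at a fixed raw-count
  threshold (60), area ratios (positive pixels / all pixels), and k-means
  over the flattened binary masks — markers are the observations, pixels
  the features — which groups markers into anatomical clusters
  (crypt, surface epithelium, germinal centre, ...).

The two views meet in spatial statistics on marker-positive cell sets:
mean k-nearest-neighbor distances between every marker pair (k = 10 by
default), intra-/inter-cluster distance networks, per-cell
nearest-neighbor proximity maps with distance histograms, topographic
(contour/surface) maps of smoothed marker intensity with peak-to-peak
distances, and a fixed-landmark reference network in which seven shared
markers (DNA1, DNA2, Histone3, CD3, CD4, CD8a, CD20) are pinned on a
circle so that force-directed layouts of different datasets are directly
comparable.

Key statistics, in the field's notation:

* Fisher Z comparison of two correlations:
  `z = (atanh r1 − atanh r2) / sqrt(1/(n1−3) + 1/(n2−3))`, two-sided
  normal p;
* mean k-NN distance from marker *a* to marker *b*: average over every
  *a*-positive cell of its k nearest *b*-positive cell distances (µm);
* proximity fraction: share of nearest-neighbor distances strictly below
  30 µm.

No real data is required anywhere: `spatialviz.synthetic_fixtures`
generates tissue phantoms — geometric anatomical regions, markers
enriched per region, non-overlapping circular cells — with full ground
truth, and every analysis stage is tested against that truth or an
independent brute-force oracle.

## Worked example

```python
from spatialviz.synthetic_fixtures import (
    Band, MarkerProfile, Region, TissuePhantomSpec, generate_phantom)
from spatialviz import anatomy_clustering as anat, single_cell_quant as scq
from spatialviz import spatial_distance as sd
from spatialviz.io_formats import AnalysisConfig

spec = TissuePhantomSpec(
    image_size=(500, 500),
    regions=[Region(1, Band("col", 0, 230)),      # T-cell zone
             Region(2, Band("col", 270, 500))],   # crypt-like zone
    marker_profiles=[
        MarkerProfile("CD3", 5, {1: 100}), MarkerProfile("CD4", 5, {1: 90}),
        MarkerProfile("GranzymeB", 5, {2: 110}), MarkerProfile("CD68", 5, {2: 95}),
    ],
    cell_density={1: 4, 2: 4},
    rng_seed=1,
)
stack, mask, cells, truth = generate_phantom(spec)
config = AnalysisConfig(kmeans_k=2, rng_seed=0)

masks = anat.binarize_stack(stack, config.binary_threshold)
assignment = anat.cluster_markers_kmeans(masks, config, k=2)
print(assignment.labels)

pos = scq.call_positivity(cells, config)
print(round(scq.percentage_count(pos, "GranzymeB"), 4))

pts = sd.points_by_marker(cells, pos)
s = sd.knn_mean_distance(pts["GranzymeB"], pts["CD68"], k=10)
print(round(s.mean_knn_distance_um, 2))

z, p = scq.compare_correlations_fisher(0.24448, 56421, 0.57199, 56421)
print(round(z, 2), p < 0.001)
```

prints

```
{'CD3': 1, 'CD4': 1, 'CD68': 0, 'GranzymeB': 0}
0.5
59.87
-67.34 True
```

— the mask k-means recovers the planted two-compartment anatomy (CD3/CD4
vs GranzymeB/CD68, cluster ids are arbitrary); half of the expressing
cells are GranzymeB-positive, matching the phantom's half-and-half cell
split; GranzymeB and CD68 cells, planted in the same region, sit a mean
59.87 µm from their ten nearest partners; and the correlation pair
r = 0.24448 vs r = 0.57199 at n = 56,421 cells each differs with
|z| ≈ 67.3, far beyond the p < 0.001 level.

The same pipeline runs from the shell:

```sh
spatialviz run --config config.yaml --out results/
spatialviz stats counts --cells results/cells.csv --out counts.csv
```

writing the phantom stack (OME-TIFF), mask, cell table, anatomy
assignment, pairwise distance matrix, network graphs (GraphML/JSON) and
a JSON run manifest.

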