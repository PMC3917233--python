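# quanthisto

Automated quantitative histology for radial plant-organ cross-sections.

Secondary growth — the radial thickening of stems, roots and hypocotyls
driven by the vascular cambium — produces a concentric tissue pattern of
xylem, cambium and phloem comprising thousands of cells per cross-section.
Because the process can only be observed invasively, through stained
histological sections, a quantitative cellular-level description requires
segmenting and classifying every cell in hundreds of tiled bright-field
micrographs. `quanthisto` implements that pipeline end to end for anyone
analyzing toluidine-blue-stained cross-sections of radially organized
organs (hypocotyls, roots, tree-stem sections):

1. **imaging** — stitch 1024×1024 tiles, adjust gamma/contrast/brightness,
   extract the dark cell-wall network with an adaptive Gaussian threshold,
   clean it with binary morphology, and split the enclosed lumina into
   cells with an automatically seeded, marker-controlled watershed on the
   distance transform.
2. **descriptors** — a 16-component vector per cell: 10 geometric features
   (area, perimeter, moment-ellipse axes, eccentricity, orientation,
   boundary-radius statistics) and 6 positional features (centroid, polar
   coordinates about the section center, incline angle). The incline angle

   θ = | arccos( **x**·**r** / (‖**x**‖‖**r**‖) ) − π/2 |

   measures the deviation of a cell's major axis **x** from the radius
   **r** through its centroid: θ = 0 is orthoradial (periclinal), θ = π/2
   radial (anticlinal).
3. **classify** — per-(genotype × timepoint) RBF-SVM classifiers over five
   cell-type categories (xylem vessels/parenchyma, xylem fibers, cambium,
   phloem bundles, phloem parenchyma), with a 2/3–1/3 stratified split,
   greedy forward feature selection under 5-fold permuted cross-validation,
   and in-fold standardization.
4. **qc** — mask-based quality control: drop objects outside the section
   mask, reconcile xylem/phloem-parenchyma confusions with the xylem-area
   mask.
5. **phenotype** — 8-component "phenoprints" per condition (cell count,
   transverse area, the five class proportions, median incline), unit-range
   scaling, and correlation-matrix PCA for cross-condition comparison.
6. **morphodynamics** — Hartigans' dip test for incline bimodality
   (implemented in-package, bootstrap p-values), lowess trends of incline
   vs normalized radial position, per-class radial profiles, and
   fixed-radius cell counts.
7. **poles** — phloem-pole patterning: kernel density maps of bundle
   cells, circular-ROI intensity profiles of reporter-stained sections,
   Bayesian single-sinusoid estimation of the arc period between poles,
   and a Bayesian PDF of the inter-spike distance whose concentration
   distinguishes patterned from stochastic pole placement.
8. **synthdata** — a synthetic-section generator (anisotropic Voronoi
   cells on jittered polar lattices, dark walls on bright lumina, full
   ground truth) so every stage is testable without any image downloads.
9. **pipeline / CLI** — YAML-configured end-to-end runs
   (`quanthisto run`), plus one subcommand per stage
   (`synth`, `segment`, `features`, `train`, `classify`, `qc`,
   `phenoprint`, `pca`, `morpho`, `poles`).

## Worked example

```python
from quanthisto.synthdata import SectionSpec, generate_section
from quanthisto import imaging, descriptors
from quanthisto.morphodynamics import dip_test

spec = SectionSpec(seed=42, image_shape=(3072, 3072))   # defaults: ~1000 cells
image, truth, masks = generate_section(spec)
labels = imaging.segment_section(image)
rate, _ = imaging.segmentation_error_rate(labels, truth.label_map)
table = descriptors.build_feature_table(labels, image.center)
dip, p = dip_test(table["incline"].dropna(), n_boot=1000, seed=0)
```

prints, step by step:

```
synthetic section: 3072x3072 px, 1081 ground-truth cells
segmented 1124 cells; mis-segmentation rate 0.00%
feature table: 1124 cells x 16 descriptors
incline dip = 0.0890, bootstrap p = 0.000999 (bimodal: radial xylem vs orthoradial phloem)
```

The mis-segmentation rate counts ground-truth cells not recovered
one-to-one (best IoU ≤ 0.5, covering merges, splits and misses); the
extra predicted labels are background slivers outside the section that the
QC stage removes. The dip test rejects unimodality of the pooled incline
distribution because the synthetic section — like a late-stage organ —
contains a radial (xylem) and an orthoradial (cambium + phloem) cell
population.

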