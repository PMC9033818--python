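# mitoplex

Single-cell OXPHOS-deficiency profiling for multiplex immunofluorescence
imaging. The package implements a complete, testable pipeline for
quantifying mitochondrial respiratory-chain protein abundance (NDUFB8,
MTCO1, TOMM20) in tissue sections:

1. **simgen** — synthetic cohorts: cell populations drawn from a log-log
   regression model with planted deficiency phenotypes, Gaussian-emission
   spectral libraries, and rendered multispectral tissue cubes with ground
   truth (so every downstream stage is testable without any data download).
2. **unmix** — spectral library construction from single-stain reference
   cubes and per-pixel nonnegative least-squares unmixing with joint
   autofluorescence estimation (the autofluorescence plane is excluded from
   marker quantification).
3. **segquant** — DAPI nucleus detection (smoothing, thresholding,
   distance-transform watershed), cytoplasm expansion bounded by the
   cytokeratin support, epithelial/stromal classification, and the per-cell
   mean-intensity table. Ground-truth masks can replace segmentation.
4. **mrc** — the core statistic: fit the control model (mean/SD of
   log10-TOMM20; OLS of log10-NDUFB8 and log10-MTCO1 on log10-TOMM20) on
   young-benign epithelial cells, compute per-cell Z-scores, and classify
   cells into abundance categories (very_low / low / normal / high;
   deficient ⇔ z < −3).
5. **cohort** — pooled category proportions, percentage-point deltas,
   Pearson chi-square comparisons (no continuity correction) and
   Kruskal–Wallis tests on ROI-level mean Z-scores.
6. **report** — MRC scatter graphs (spot area ∝ cell area), pseudo-colour
   per-cell Z-score images, and ROI × marker heatmaps. Every figure has a
   machine-readable CSV twin; tests assert on the twins, never on pixels.

## Command line

```sh
# end-to-end on the default synthetic cohort (3 groups x 2 patients x 4 ROIs)
mitoplex pipeline run --seed 1 --out-dir out/

# individual stages
mitoplex simulate --out-dir sim/ --seed 1 --render
mitoplex build-library --singleplex DAPI=dapi.tif ... --af af.tif --out lib.yaml
mitoplex unmix --cube cube.tif --library lib.yaml --out components/
mitoplex quantify --components components/ --mask mask.tif \
    --annotations patient_id=P1,group=tumour,roi_id=r1,region=tumour --out cells.csv
mitoplex score --cells cells.csv --controls-group young_benign --out z.csv
mitoplex compare --z z.csv --contrast group:tumour,vs,group:aged_benign --marker ndufb8
mitoplex report --z z.csv --out-dir figs/
```

File formats: multispectral cubes are multi-page TIFFs (one band per page,
wavelength in the page description); masks are integer TIFFs; spectral
libraries and control models are YAML; cell tables and figure twins are CSV.

## Tests

```sh
python -m pytest -q tests/
```

The suite contains unit tests per module, property tests for the pipeline
invariants (determinism, nonnegativity, category partition, proportion
conservation), and `tests/test_acceptance.py` with the acceptance criteria
(printed-delta checks, threshold boundary sweep, unmixing oracle, parameter
and phenotype recovery, statistics oracles, end-to-end run).

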