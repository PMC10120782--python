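# smequant

Quantification of the breast-cancer **stromal microenvironment (SME)** from
H&E-stained histology images, with an epidemiological association engine for
relating the resulting tissue phenotypes to patient risk factors.

The SME — the connective-tissue compartment of a tumor and its resident
nucleated cells (lymphocytes, macrophages, fibroblasts, endothelial cells) —
carries information about tumor biology that plain tumor-cell pathology does
not. `smequant` implements a complete, testable version of an H&E-based SME
pipeline:

1. **Tissue classification** — a random forest over local colour/texture
   window features, trained from sparse labelled points (default budget:
   94 tumor + 67 stroma "datapoints"), segments each slide into tumor,
   stroma and background and quantifies per-class areas in mm².
2. **Stromal cell detection** — hematoxylin-weighted optical-density
   thresholding, watershed splitting, and gates on size, shape, local
   contrast and optical density count nucleated cells confined to the
   stroma; contiguous dark regions too large to be single nuclei are
   treated as infiltrating epithelial nests and excluded.
3. **SME metrics** — per slide,

   - tumor-stroma ratio: `TSR (%) = 100 · A_stroma / (A_tumor + A_stroma)`
   - tumor-associated stromal cellular density, in standard form
     `Ta-SCD = N_cells / A_stroma` (cells/mm²) and percent form
     `Ta-SCD (%) = 100 · N_cells · a_nuc / A_stroma` with the fixed
     single-nucleus area `a_nuc = 2.0×10⁻⁴ mm²`. The two forms are exact
     rescalings of one another (Pearson r = 1 across slides).

4. **Association analysis** — Kruskal–Wallis comparisons; partially and
   mutually adjusted linear models (age, study site, tissue area, plus the
   other exposures) with dummy coding against stated reference levels;
   ordinal trend tests; joint Wald tests for multiplicative effect
   modification; and chained-equation multiple imputation (MICE, m = 5) of
   missing tumor markers with Rubin's-rules pooling
   (`T = W + (1 + 1/m)·B`, Barnard–Rubin degrees of freedom).

Because patient-level slide archives of this kind are not publicly
deposited, the package ships two first-class synthetic generators that make
every stage testable by parameter recovery:

- `synthslide` renders H&E-like scenes (dark basophilic tumor nests,
  eosinophilic fibrous stroma, hematoxylin-dark nuclei seeded by a Poisson
  process at a controllable density) with exact ground-truth masks and
  nucleus coordinates;
- `synthcohort` simulates patient tables with realistic covariate marginals
  (reproductive history, body size, family history, ER/PR/HER2, grade,
  size), injectable linear effects on the SME outcomes, and calibrated
  missing-at-random gaps in the tumor variables.

## Worked example

```python
from smequant import synthslide as ss, tissue_classifier as tc
from smequant import cell_detect as cd, metrics as mx

slide, gt = ss.generate_slide(ss.SceneParams(seed=1), slide_id="demo")
ann = ss.sample_annotation_points(gt, seed=2, slide_id="demo")   # 94 + 67 points
model = tc.train_tissue_classifier(slide, ann)
seg = tc.segment_slide(model, slide)
det = cd.detect_stromal_cells(slide, seg)
m = mx.compute_metrics(seg, det)
print(f"TSR {m.tsr_percent:.1f}%  Ta-SCD {m.tascd_standard:.0f} cells/mm2 = {m.tascd_percent:.1f}%")
```

prints

```
TSR 76.9%  Ta-SCD 1551 cells/mm2 = 31.0%
```

against a seeded truth of TSR 78.0% and 361 nuclei (374 detected): the
classifier reaches out-of-bag accuracy 1.000 on the 161 training points and
the detector recovers the seeded count within a few percent. Downstream, an
injected parity effect is recovered through the full missing-data path:

```python
from smequant import synthcohort as sc, assoc

cohort = sc.generate_cohort(2000, effects=sc.default_effects(), seed=3)
spec = assoc.ModelSpec(outcome="tascd_percent", exposure="parity_status",
                       adjustment="mutual",
                       mutual_exposures=("menarche_cat", "parity_status",
                                         "body_size", "fhbc", "grade"))
pooled = assoc.pooled_fit(cohort, spec, m=5, seed=4)
r = pooled["parity_status[parous]"]
print(assoc.format_beta_ci(r.beta, r.ci_low, r.ci_high), f"p={r.p_value:.3g}")
```

prints `2.30 (1.29, 3.32) p=9.54e-06` for a cohort generated with a true
parous effect of +2.92 Ta-SCD percentage points — the 95% CI covers the
injected truth, and over repeated cohorts the coverage is ~95% (see
`tests/test_acceptance.py`).

A `smequant` command-line interface wraps the same stages
(`simulate-slide`, `train-tissue`, `segment`, `detect-cells`, `metrics`,
`simulate-cohort`, `analyze`); run `smequant --help` for details.

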