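# Methods

This note documents the models, parameter choices and numerical behaviour
of `smequant`, and what the synthetic-data experiments do and do not show.

## Synthetic slide model (`synthslide`)

A scene is a white-background canvas with an interior tissue box split into
tumor and stroma. Tumor is rendered as a set of elliptical "nests" with a
high-frequency dark-purple blotch texture; stroma as a pale pink field with
low-frequency fibre texture; both receive additive Gaussian stain noise
(`stain_noise_sd`, default 3 grey levels). Nest radii are drawn once from
`nest_radius_um` (default 55 ± 12 µm) and a common scale factor is iterated
so the realised tumor pixel count matches the target TSR; the contract is
±5 percentage points, and a `GeometryError` is raised when the requested
geometry cannot realise it (e.g. a non-trivial tumor fraction with zero
nests). The texture model is intentionally simple — its purpose is that
colour/texture window statistics separate the classes, since the feature
set of the commercial system this emulates is undocumented.

Stromal nuclei are seeded by a homogeneous Poisson process: the count is
`Poisson(density × stroma area)` with the full stromal area, so counts are
unbiased for the requested density; centres are placed uniformly on the
stroma eroded by roughly one nucleus diameter so rendered nuclei stay clear
of tumor and background (a small inhomogeneity at stromal margins that does
not affect counts). Nuclei are filled ellipses, radius `nucleus_radius_um`
(default 3.6 ± 0.5 µm, clipped at ±2 SD), axis ratio uniform on [0.6, 1],
dark blue-purple with per-nucleus colour jitter. The defaults — 576×576 px
at 1.0 µm/px, target TSR 76%, density 1550 cells/mm² — correspond to the
population scale of the cohort this emulates (mean TSR ≈ 76%, mean Ta-SCD
≈ 31% ≙ ≈1550 cells/mm²).

With `epithelial_nest_infiltration` enabled, two tight 5×4 grids of
overlapping malignant nuclei are rendered inside the stroma as single
connected blobs. Their coordinates are recorded separately
(`epithelial_nest_centers`) and are *not* part of the ground-truth stromal
count — they exist to exercise nest exclusion in the detector.

Ground truth stores the label raster, nucleus centres, and TSR/density
computed from the same pixel counts and area conversion
(`pixels × mpp² / 10⁶`) used everywhere else, so the metric stage can be
checked for exact identity.

Annotation sampling draws labelled points uniformly without replacement
from class interiors (≥2 px from any boundary). The default budget is 94
tumor + 67 stroma points, mirroring the reference protocol; that protocol
describes the combined set as "160-datapoint" although the stated per-class
counts sum to 161 — both numbers are surfaced as-is and the per-class
counts are used.

## Tissue classifier (`tissue_classifier`)

Features per window (length 13): mean and SD of the three RGB channels and
of the hematoxylin and eosin optical-density channels (Ruifrok–Johnston
deconvolution via `skimage.color.rgb2hed`), mean and SD of the Sobel
gradient magnitude, and the Shannon entropy of an 8-bin grey-level
histogram. Window statistics are computed from per-pixel transform maps
through integral images with reflective padding, so any number of query
points costs O(1) each. The window is 32 µm (32 px at 1.0 µm/px, scaled by
mpp) — large enough to capture texture, small enough for sparse-point
training.

The classifier is a 100-tree random forest (unlimited depth, fixed seed,
out-of-bag score reported). Segmentation assigns background first by a
luminance threshold (grey level ≥ 0.9 of maximum — the reference protocol
never states how non-tissue is removed), classifies the remaining pixels on
a stride-4 grid, and upsamples by nearest neighbour so that area accounting
is exact; any `excluded_mask` (QC negative annotations) is applied last.
Whether the reference pipeline classified at full resolution or on a grid
is unknown; the stride is exposed, and TSR moves by <2 percentage points
between stride 1 and stride 4 on default scenes. Duplicating every
annotation point leaves predictions essentially unchanged (documented as
approximate: bootstrap resampling differs, agreement ≥95% in tests).

`reproducibility_check` mirrors a two-annotator design: two forests trained
on independently sampled annotation sets segment the same slides, and the
per-slide tumor and stroma area vectors are compared by Spearman's rho.

## Cell detector (`cell_detect`)

Per-channel optical density is `OD = −log10((I+1)/256)`. The detection
channel blends the hematoxylin concentration from fixed-vector colour
deconvolution (Ruifrok–Johnston H&E vectors, residual = normalised cross
product) with the mean total OD by `nuclear_detection_weight` (default
0.8). Candidates are connected regions of detection OD above
`min_optical_density` (0.30) inside the stroma mask, split by
distance-transform watershed (peaks ≥2 µm apart; raster-order marker ids
for deterministic tie-breaking), then gated on:

- area within [10, 120] µm²,
- circularity `4πA/P² ≥ 0.4`,
- mean OD ≥ `min_optical_density`,
- local contrast: candidate mean OD minus the mean OD of a 3 µm surrounding
  annulus ≥ 0.05. The annulus excludes other dark objects, so the contrast
  is measured against stroma — touching nuclei do not suppress each other.
  (The named knobs mirror a commercial cell-detection script whose actual
  parameter values are not published; these defaults were fixed once
  against synthetic scenes and kept.)

Epithelial-nest exclusion then removes every candidate whose centroid lies
in a connected dark region larger than `nest_area_threshold_um2` (default
300 µm² ≈ several nucleus areas: larger than any plausible touching pair,
smaller than any rendered nest). With an infinite threshold the filter is
the identity. Detections are deterministic, stroma-confined by
construction, and monotone in the gating thresholds.

`count_in_region` counts centroids in half-open 500×500 µm² frames (the
counting-frame convention of the reference validation); frames tile
additively. `concordance_vs_reference` is the Pearson correlation between
automated and reference frame counts — in this package the reference is
the seeded ground truth, standing in for a manual pathologist count.

One interpretation point: the reference validation reports intra- and
peri-tumoral stromal counts separately, but the density formula pools all
stroma; the pooled interpretation is implemented.

## Metrics (`metrics`)

`TSR (%) = 100 · stroma / (tumor + stroma)`, where "total fibroglandular
tissue area" is interpreted as the classified tumor + stroma area (the
only decomposition the pipeline produces; background and excluded pixels
contribute to nothing). `Ta-SCD` standard = cells per mm² of stroma;
percent = standard × (2.0×10⁻⁴ mm² × 100). The provenance of the
2.0×10⁻⁴ mm² single-nucleus constant is not given by the protocol that
uses it; it is treated as a fixed, configurable conversion constant. The
percent form is the analysis variable downstream; the standard form is
retained for audit, and their ratio is the constant on every slide, which
is why the cross-slide correlation between the two forms is exactly 1.

## Cohort generator (`synthcohort`)

Category marginals default to a published frequency table shipped as
`data/reference_cohort_margins.csv` (e.g. parous 91.0%, positive family
history 7.0%, grade 3 69.7%) — realistic covariate imbalance matters for
the power of recovery tests. Parity consistency is enforced (nulliparous ⇒
zero children, age-at-first-birth and breastfeeding "n/a"). ER/PR/HER2 are
drawn from an 8-cell joint distribution constructed to match the published
marker and subtype marginals simultaneously (ER+ 53%, PR+ 52%, HER2+ 26%;
subtypes ≈30/34/8/28%). Age in years is uniform within its category band;
tissue area is Gamma(4, 7.5) mm² (mean 30, right-skewed); study site is a
three-hospital categorical not reported in the source table (0.40/0.35/0.25).

The subtype rule — luminal A-like ER+/PR+/HER2−, HER2-enriched
ER−/PR−/HER2+, TNBC ER−/PR−/HER2− — does not name ER−/PR+/HER2−; it is
mapped to luminal B-like (hormone-receptor-positive, HER2−, not luminal A)
so the derivation is total over all 8 marker combinations.

Outcomes are linear in the injected `EffectSpec`: Ta-SCD % = 28.5 +
Σ effects + interactions + N(0, 7.0), clipped to (5, 95) (the observed
population range is 10.7–58.7, so clipping is essentially inactive at the
defaults); TSR = 76 + effects + N(0, 14), clipped to (5, 99.9). The default
effect sizes are at the scale of the published mutually-adjusted estimates
(parous +2.92, family history +2.36, body-size gradient −1.02/−2.42, grade
+3.53/+5.22, late menarche −1.78).

Missingness is missing-at-random only: the per-record probability of
masking a tumor variable is modulated by observed site and age group and
rescaled so the marginal rate equals the configured rate (defaults at the
published unknown fractions: ER 25%, PR 25%, HER2 29%, grade 14%, size 5%).
MNAR mechanisms are out of scope, matching the validity assumption of the
imputation engine.

## Association engine (`assoc`)

- **Kruskal–Wallis**: ties-corrected H with a chi-square reference; the
  all-tied degenerate case returns H = 0 rather than the 0/0 of the ties
  correction. "n/a" and missing categories are excluded from distribution
  tables.
- **Linear models**: OLS with dummy coding against the stated reference
  level. Partial adjustment = exposure + age + site + tissue area; mutual
  adjustment adds the other exposures. Age enters as its 4-level category
  by default (matching the presentation of the emulated analysis;
  continuous age is a flag). Tissue area enters untransformed (no
  transform is stated by the source analysis). Rank-deficient designs
  raise with the aliased column names (QR diagnostic). A single-level
  exposure contributes no terms (intercept-plus-covariates fit).
- **Trend tests** replace the dummies with consecutive integer scores
  0, 1, 2, … in category order (configurable, e.g. category medians);
  "n/a" levels are excluded; the score coefficient's two-sided p is
  `p_trend`.
- **Effect modification**: full model with exposure × modifier products;
  `p_heterogeneity` from a joint Wald chi-square on all product terms (the
  emulated analysis reports a single p per modifier without naming the
  test); stratum-specific effects by linear combination of coefficients
  with delta-method SEs. Empty exposure × modifier cells raise with the
  offending cells listed.
- **MICE**: chained equations over the incomplete tumor variables in
  ascending-missingness order; binary variables use logistic draws,
  ≥3-level variables multinomial draws. Each conditional model is fitted
  on a bootstrap resample of the observed rows and imputed values are
  drawn from the predicted class probabilities — an approximately proper
  imputation that preserves between-imputation variance without explicit
  posterior sampling. Five chained iterations per stream by default (the
  convention of the R `mice` package; convergence on these low-dimensional
  categorical models is fast), m = 5 independent streams, observed values
  never altered, fully seeded. Predictors: the two SME outcomes, tissue
  area, site, age group, parity, body size, family history, menarche, and
  the other imputation variables at their current values. No installed
  library provides chained categorical imputation with posterior draws,
  hence this implementation; ordinary model fits, tests and descriptive
  statistics go through statsmodels/scipy/sklearn.
- **Rubin's rules**: pooled β = mean; W = mean SE²; B = sample variance of
  the β's; T = W + (1 + 1/m)B; degrees of freedom by Barnard–Rubin when
  the complete-data df is available (it is, from the per-imputation fits),
  classical (m−1)/λ² otherwise. With B = 0 the pooled result collapses
  exactly to the complete-data fit. All p-values are two-sided;
  significance is conventionally α = 0.05.
- **Reports**: per-exposure blocks with "1.00 (reference)" rows and
  "β (95% CI)" rendered to two decimals using decimal half-up rounding
  (floating-point bankers' rounding would turn 2.915 into "2.91");
  distribution tables show mean (SD), median (range) and the
  Kruskal–Wallis p per characteristic.

## Problem sizes used by the test suite

Unit tests run on 128–288 px scenes and cohorts of 200–6000. The
end-to-end checks use: 20 default 576 px scenes for segmentation Dice
(≥0.85 per class) and count recovery (±10% of seeded truth); 30 scenes
spanning 500–4000 cells/mm² for counting-frame concordance (r ≥ 0.9); 200
simulated cohorts of n = 2000 with default effects and missingness for the
~95% CI coverage of the pooled parity effect; 2000 permutation replicates
(Kruskal–Wallis) and 1000 null simulations (heterogeneity Wald) for test
size. The coverage experiment's mutually-adjusted model includes histologic
grade along with the risk-factor set so that the imputed tumor variables
genuinely enter the monitored estimate. The acceptance script uses 24
slides of 384 px across the same density range.

## What passing tests do and do not show

The synthetic scenes have piecewise-stationary textures, elliptical nests,
no staining-physics variation, no pyramid/whole-slide formats, and no
artifacts beyond a rectangular exclusion mask; classifier and detector
accuracies on them bound nothing about real H&E material, where stain
variability, necrosis, crush artifact and nuclear pleomorphism dominate.
Likewise the cohort generator draws covariates independently (apart from
parity consistency and the marker joint), so mutual adjustment is easier
than in real data with correlated exposures. What the experiments do
establish is internal validity: the formulas are implemented as stated,
the estimators are calibrated (test size, CI coverage, MAR unbiasedness)
under their own assumptions, and every stage recovers injected truth at
the configured signal scale. Reproducing the published cohort's actual
coefficient estimates is out of scope — the underlying patient data are
not deposited.
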