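# Methods notes

This note documents the models, numerical choices and known limitations of
`deprimap`. It is the design record of the package; nothing here states a
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## The statistical model

The analysis couples two variable sets observed on census tracts, the
smallest census enumeration unit:

| set | variable | meaning | transform |
|-----|----------|---------|-----------|
| socioeconomic | BA | proportion of households without a bathroom | arcsine-sqrt |
| | WA | proportion with piped water | arcsine-sqrt |
| | GA | proportion with garbage thrown on lot/street | arcsine-sqrt |
| | IN | mean monthly income of heads of household | natural log |
| | CR | proportion of households with > 6 residents | arcsine-sqrt |
| land cover | CO, WP, TR, PA | percent of impervious pixels that are corrugated-roof / white-painted-roof / tile-roof / pavement | percent ÷ 100, then arcsine-sqrt |
| | TX | population SD of the 3×3 high-pass-filtered red band over the tract | identity |

The arcsine-square-root transform is the standard variance stabiliser for
0- and 1-inflated proportions; it is monotone on [0, 1] so ranks are
preserved. The log base for income is irrelevant to any correlation-based
quantity; natural log is used. Both tables are then column-standardized
with *population* (divide-by-n) standard deviations — a descriptive
convention used consistently for all SDs in the package — and the
standardization constants are stored in a `TransformSpec` so that per-pixel
features can later be projected onto exactly the fitting scale.

Canonical correlation analysis is computed from first principles: with
within-set correlation matrices `Rxx`, `Ryy` and cross-correlation `Rxy`,
the singular value decomposition

    Rxx^{-1/2} Rxy Ryy^{-1/2} = U diag(r) V'

yields the canonical correlations `r` and standardized weights
`A = Rxx^{-1/2} U`, `B = Ryy^{-1/2} V`. The symmetric inverse square roots
come from eigendecompositions; a matrix whose smallest eigenvalue is below
`1e-10` times the largest raises an error suggesting the optional ridge
(`Rxx + λI`), which defaults to 0 so that exact CCA is never silently
regularized. Loadings (variable-variate correlations) are `Rxx A` and
`Ryy B`; a separate code path recomputes them as direct Pearson
correlations on scores, and the two are asserted equal in tests. The
implementation is cross-checked against an independent library
implementation and, on tiny instances, against exhaustive unit-vector grid
search.

**Sign convention.** Canonical directions are sign-indeterminate, so an
anchor rule fixes orientation: dimension 1 is flipped (jointly in `a₁`,
`b₁`, which leaves `r₁` unchanged) so that the income loading is negative —
deprivation loads positive — and each later dimension so that its
largest-magnitude socioeconomic loading is positive. The anchor variable is
configurable.

**Dimensionality.** The sequential test uses Wilks'
`Λ_k = Π_{j≥k}(1 − r_j²)` with Bartlett's multiplier
`−[N − 1 − (p+q+1)/2]`, referred to chi-squared with
`(p−k+1)(q−k+1)` degrees of freedom. Dimensions are counted significant
sequentially from the first and counting stops at the first
non-significant test, respecting the nested structure of the hypotheses.
Each dimension's eigenvalue is reported as `r²/(1−r²)`.

## Feature extraction

* **High-pass filter**: the common 3×3 kernel (center 8, neighbours −1).
  Border cells use the shrunken-window analogue — center weighted by the
  number of in-grid neighbours, each neighbour −1 — so constants and linear
  ramps are still annihilated and no off-grid pixels are fabricated.
* **Compositions**: CO/WP/TR/PA divide by the *impervious* pixel count
  (the four built classes), at both tract and window support, so the four
  percentages sum to 100 wherever defined. A window (or tract) without
  impervious pixels has undefined composition: windows are masked, tracts
  flagged and excluded from the CCA with a logged count. An all-pixels
  denominator is available (`denominator="all"`) for sensitivity analyses.
* **Windows**: 3×3, shrunken at borders, never wrapped. For a tract that
  coincides with one 3×3 block, the center pixel's window features equal
  the tract features exactly (tested).
* **Classifier**: Gaussian maximum likelihood with per-class mean,
  covariance and prior; pixel score `log prior − ½(Mahalanobis + log det +
  d·log 2π)`; ties broken by declared class order for determinism; a
  singular class covariance raises an error naming the class.

## Mapping

Dimension 1 uses the fitted first-dimension *land-cover* loadings on the
window feature stack; dimension 2 uses the second-dimension *socioeconomic*
loadings per tract, broadcast to the tract's pixels (the raster analogue of
a polygon fill — deliberately not window-smoothed). The combined score
weights the two dimension grids by their canonical correlations. The final
map is masked to impervious pixels; cloud and nodata are also excluded.

Two modes:

* `standardized` (default): loadings are applied to
  transformed-and-standardized values using fit-time constants — the scale
  on which loadings were estimated, hence the internally consistent map.
* `raw`: loadings are applied to raw percent / raw-variable values,
  reproducing the published map-algebra equations literally. On raw scales
  income (hundreds of currency units) numerically dominates the dimension-2
  sum; the mode exists for replication and hand-checking (the high-income
  reference community row gives −29.14 on dimension 1).

Loadings always come from a fitted model or an explicit reference vector —
they are arguments, never hard-coded. The published Salvador loadings ship
in `deprimap.reference` as data. Note the published dimension-1 equation
prints the white-painted-roof term with a positive sign while the published
loading table gives −0.348; the reference module follows the loading table,
and a fitted model always uses its own signed loadings. Similarly the
published equation legend describes BA as households *with* a bathroom; the
variable-definition table (households *without*) is authoritative here.
Dimension 3, though typically significant, is deliberately not mapped.

## The synthetic-city generator

The generator emulates the statistical structure the analysis assumes — a
single latent deprivation field expressed in both data sets — not any real
city's geometry.

* **Latent field**: Gaussian white noise smoothed by a uniform moving
  average of radius `smoothing_radius` (reflected borders), then rescaled
  to the configured mean and SD so the marginal scale is
  radius-independent. Default mean 0, SD 1, radius 2–3: smooth
  neighbourhood-scale gradients at desk-scale cost, without a full
  Gaussian-process simulator.
* **Tracts**: seeded region growth (first-passage competition from random
  seed pixels with log-normal per-tract growth rates, σ = 1.2). This gives
  exhaustive, 4-connected tracts whose pixel counts span orders of
  magnitude, mimicking real census geography where tract areas range from a
  few pixels to thousands.
* **Land cover**: per-pixel multinomial whose class log-odds shift linearly
  in the latent value. Base probabilities (corrugated 0.20, white 0.05,
  tile 0.10, pavement 0.15, water 0.05, vegetation 0.25, sand 0.05, soil
  0.10, cloud 0.05) describe a mixed coastal city.
* **Red band**: class-dependent base reflectance plus white noise of
  amplitude `red_noise_base · exp(−texture_contrast_slope · latent)`, so
  high-deprivation areas are more homogeneous (less 3×3 texture), the
  pattern seen in real imagery of informal settlements.
* **Census**: tract-mean latent `L̄` drives income
  `exp(a − b·L̄ + ε)` and the proportions through logits
  `invlogit(c ± s·L̄ + ε)` (piped water with a negative slope), with noise
  ε added on the transformed scale so back-transformed values stay in
  range. Intercepts are set so the null-coupling marginals approximate a
  real census profile (BA ≈ 0.02, WA ≈ 0.92, GA ≈ 0.04, CR ≈ 0.15, median
  income a few hundred currency units).
* **Reproducibility**: all stages draw from sub-streams derived from the
  master seed via seed sequences with fixed per-stage spawn keys, so every
  stage is independently re-runnable and the whole bundle is bit-stable.

Two presets define the study conditions used throughout the tests:

* `SimConfig.null_coupling()` — all coupling slopes zero, census noise 0.4:
  land cover and census are independent. Used to calibrate the
  dimensionality test's false-positive rate.
* `SimConfig.strong_coupling()` — one strong latent factor
  (corrugated log-odds slope +1.5, pavement −1.0, income slope 0.8, census
  noise 0.35 on 120×120 grids with 500 tracts). The effect sizes were
  calibrated once, against a pooled many-city fit, so that the *population*
  first canonical correlation under this condition is ≈ 0.70
  (`calibration.population_canonical_r1` recomputes it; the pooled estimate
  over 25k tracts is 0.705). The per-city estimate at ~400–500 defined
  tracts carries a small upward bias (~0.01), visible in the recovery
  statistics.

What the generator does **not** emulate: real tract polygon shapes,
spatially correlated census noise, multi-band spectra, mixed pixels,
georeferencing error, or any specific city's marginal distributions. Tests
passing on synthetic cities therefore validate the estimator and the
pipeline plumbing, not the real-world accuracy of any particular map.

## Fuzzy accuracy assessment

Validation sites are 2×2-pixel windows scored 1–5 by the presence fraction
of the *classified* class in the reference window: 1 no match; 2 below
50 %; 3 at least 50 % and below 75 %; 4 at least 75 % and at most 90 %; 5
above 90 %. The bracket boundaries are closed exactly as stated (the
verbal scale leaves them ambiguous). Sites too heterogeneous to carry a
dominant reference class enter a dedicated confusion-matrix column.

Summaries: overall fuzzy accuracy = percent of sites scoring at or above
the match threshold (default 3 — majority presence — and configurable,
since the graded-scale literature does not fix a single cut); weighted
fuzzy accuracy = mean of the linear score-to-weight map (s−1)/4 (the
simplest monotone weighting; the weight vector is configurable); user's /
producer's accuracies condition on rows / columns; kappa is Cohen's
unweighted kappa on the hard count matrix padded with an all-zero
heterogeneous row, so heterogeneous reference sites count against
agreement.

## Problem sizes and tolerances

The test-suite study conditions are: null calibration on 200 cities of
48×48 pixels / 100 tracts; recovery on 50 cities of 120×120 pixels / 500
tracts plus a 30-city pooled population fit; oracle comparisons on 50
instances with n ≤ 10 and a 2000-point angle grid (r₁ agreement within
1e-3); orthogonality and loading identities at 1e-8; exact arithmetic
identities at printed precision. These sizes keep the whole suite under
a minute while leaving the stochastic checks' Monte-Carlo error well inside
their acceptance bands (binomial 3·SE for rates, ±0.05 for the recovery
mean whose seed-to-seed SD is ≈ 0.024).

## Known limitations

* Grids are plain ESRI ASCII with nominal 30 m cells; there is no
  projection or geodesy support, by design.
* The Bartlett chi-squared approximation is asymptotic in the tract count;
  below ~20 tracts per variable its calibration degrades (the null suite
  runs at ~80–100 defined tracts for 10 variables, where it is adequate).
* Near-collinear within-set variables (e.g. compositions before the
  arcsine transform, which sum to 100 exactly) make `Rxx` singular; the
  transform breaks the exact constraint, and the ridge option exists for
  residual near-singularity.
* The weighted fuzzy accuracy uses an explicit, configurable weighting; the
  historical variants it generalises are not uniquely defined in the
  graded-accuracy literature.
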