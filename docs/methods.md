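# Methods

This note records the models the package implements, the defaults it ships,
and the design choices made where the literature leaves the construction
open. Nothing here states an empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Variogram estimation and fitting

The empirical semivariogram uses the Matheron estimator,
γ̂(h_b) = (1/2N_b) Σ (Z(xᵢ) − Z(xⱼ))², over distance bins; the
cross-variogram replaces the squared increment with the product of the two
variables' increments over co-located pairs. Defaults: 12 lags, maximum
distance half the largest pairwise distance, lag centers at the mean pair
distance of each bin. Zero-separation pairs are excluded (they carry no lag
information; duplicate locations are the kriging module's concern, where
conflicting values are averaged with a warning). Isotropy is assumed
throughout; no directional variograms.

Models are the standard trio — spherical, exponential, Gaussian — in the
form nugget + partial-sill·g(h/range) with γ(0) = 0. Exponential and
Gaussian use the practical-range convention (g reaches ≈0.95 at h = range),
the spherical sill is exact at the range. Fitting minimizes the
Cressie-weighted SSE with weights N_b/γ_model(h_b)², the model value
floored at 1e−12 against division by zero; L-BFGS-B from four starting
points, bounds nugget/psill ∈ [0, 3·max γ̂] and range ∈ (0, 2·max lag].
`family="auto"` picks the family with the lowest weighted SSE. An all-zero
empirical variogram short-circuits to the degenerate nugget-0/psill-0 model.

The linear model of coregionalization shares a fixed set of structures
(a nugget plus one or more bounded structures at fixed ranges) across all
direct and cross variograms: each (co-)variogram's coefficients are fitted
by weighted linear least squares, the per-structure coefficient matrices
are then projected to the nearest positive semidefinite matrix by
eigenvalue clipping. This is the simplest construction that guarantees a
valid co-kriging system; the price is that diagonals can move slightly off
the independently fitted direct sills when the raw cross fit is too
aggressive (the projection tolerance is −1e−8 on eigenvalues).

## Kriging

Systems are assembled in semivariance form (usable even for models without
a finite sill) with the unbiasedness constraints appended: OK weights sum
to 1; ordinary co-kriging adds the traditional second constraint that
covariate weights sum to 0. Heterotopic data are supported — each variable
contributes rows at the sites where it is observed. The left-hand matrix
depends only on the data configuration, so it is LU-factorized once and
reused for all prediction targets; exactly singular systems get 1e−10
jitter on the data diagonal. Kriging variances in (−1e−9, 0) are numerical
noise and are clamped to zero; anything lower raises.

Grids are row-major with row 0 at the north (max-y) edge, values at cell
centers, written as ESRI ASCII with 17-significant-digit formatting so
write → read → write round-trips bit-exact. GeoTIFF is not produced; the
workflow's raster interchange is the plain-text grid. The default search
neighborhood is all samples when n ≤ 200 (the survey sizes this package
targets), else the 16 nearest target-variable samples per cell; under COK
the neighborhood restricts the target variable only.

## Indicator kriging and MVIK

Indicators code exceedance: I(x; z) = 1 when Z(x) ≥ z. The kriged indicator
surface is read as the probability of exceeding the threshold, and high
composite values mean high multi-metal pollution risk. (Formulations that
write the kriged indicator as an estimate of Prob[Z ≤ z] with the same
coding appear in the applied literature; the exceedance orientation is the
internally consistent one and is documented here for users.) Probabilities
are clamped to [0, 1] after kriging, since OK on 0/1 data can overshoot.
The indicator data get their own auto-family variogram fit, falling back to
a pure-nugget model (at the indicator variance) with a warning if the fit
degenerates; a single-class indicator vector returns the constant 0 or 1
field with a warning.

The composite surface is Σ wᵢ Iᵢ(x) with wᵢ = rᵢ/Σrⱼ from toxicity response
coefficients (defaults Cd 30, As 10, Pb 5, Cr 2, Ni 5, hence Cd weight
30/52). One threshold per metal; multi-cutoff indicator co-kriging is out
of scope.

In the pipeline the kriged indicator is SPI ≥ 1 rather than a raw
concentration threshold. The two are equivalent when the threshold equals
the regulatory standard — and the SPI form stays well-defined when the
standard varies with the sample's pH class, where no single concentration
threshold exists.

## Pollution indices

SPI = C/S; NCPI = √((max P² + mean P²)/2); SPI grades on the half-open bins
(≤1, 1–2, 2–3, 3–5, >5]; NCPI grades Safety ≤ 0.7 < Alert ≤ 1 < Slight ≤ 2
< Moderate ≤ 3 < Severe — the standard Nemerow breakpoints. Percentages in
summary tables are rounded (not truncated) to two decimals.

Reference standards are configuration. The shipped defaults are the
GB 15618-2018 agricultural-soil risk screening values (farmland other than
paddy), which step with pH class (≤5.5, 5.5–6.5, 6.5–7.5, >7.5); they are
externally sourced regulatory constants supplied for convenience and can be
overridden per metal, including as a single pH-independent value.

## Getis-Ord Gi*

Binary distance-band weights with self-inclusion (the star convention);
z_i = (Σⱼ wᵢⱼxⱼ − X̄Wᵢ) / (S·√((nΣⱼwᵢⱼ² − Wᵢ²)/(n−1))) with global mean X̄
and population standard deviation S. A zero denominator (constant field, or
a neighborhood spanning all points) yields z = 0 by convention. Classes use
the two-sided normal critical values 1.645/1.960/2.576. No multiple-testing
correction is applied by default. The pipeline's default band is the fitted
variogram range of the index being analyzed, linking the hotspot scale to
the spatial-dependence scale; it can be fixed by configuration. Gi* runs on
sample points in the pipeline, but accepts any coordinate/value table,
including grid cells.

## Validation metrics

R² is the squared Pearson correlation (the reading that accompanies
scatter-against-identity plots); the 1 − SSE/SST form is computed as a
diagnostic but not reported. RMSE and signed mean bias
(mean(pred − obs) — the sign convention is a documented choice) measure
accuracy; Lin's concordance correlation coefficient, computed with
population moments, penalizes dispersion and location shift and is bounded
by |r|. Percent changes between methods are rounded to two decimals in
report output.

## Synthetic survey generator

What it emulates: a 351-site survey over a ~40 × 45 km rectangle with
uniformly random site locations; five cross-correlated metal fields with
right-skewed positive margins (lognormal, matched to mean/SD targets of
Cr 43.79/16.86, Pb 22.68/14.64, Cd 0.37/0.24, As 12.59/6.77,
Ni 20.31/8.27 mg/kg); a spatially smooth pH field (mean 5.8, SD 1.1);
a linear-plus-noise sensor whose noise variance is set analytically so the
expected squared correlation with truth equals the per-metal targets
(Cr 0.66, Pb 0.55, Cd 0.60, Ni 0.65, As 0.44); and a random 97/254
calibration/validation split in which only the calibration subset keeps
sensor values.

Construction: each metal's Gaussian field has site correlation
(sill − γ(h))/sill from its variogram, factorized by Cholesky (with 1e−10
diagonal regularization); cross-correlation is imposed by mixing shared
standard-normal innovations with the Cholesky factor of the metal
correlation matrix before the spatial factor is applied — the intrinsic
correlation model, exact when all metals share one variogram shape, which
the defaults do (spherical, nugget 0.3 / partial sill 0.7 on the unit
scale, range 12 km — chosen once as plausible for a regional survey; the
true spatial parameters of the emulated study were never published). The
lognormal transform exp(μ + σZ) matches the target mean and SD exactly in
expectation. A zero-sill variogram degenerates to a field constant at its
target mean. The default metal cross-correlation is a uniform 0.5,
reflecting the moderate inter-metal correlations typical of mixed
lithogenic/anthropogenic sources. Sensor outputs are clamped at
0.001 mg/kg.

What it does not emulate — and therefore what passing tests do not show
about real data: the real sampling pattern (roads, river valleys,
clustered farmland), land-use-driven nonstationarity, instrument physics
(detection limits, matrix and moisture effects, censoring), anisotropy,
and any relationship between pH and the metals. Results on the generator
demonstrate correctness of the estimators and the qualitative value of a
dense moderate-fidelity covariate, not the absolute accuracy attainable on
any particular real survey.

## Problem sizes in the test suite

Distribution-level checks use medians over 30 replicate surveys (n = 1000
sites) and 30-seed experiments at n = 2000 for variogram parameter
recovery; the indicator-calibration experiment pools 32 × 32 grids over 30
seeds; end-to-end pipeline tests run 15 × 15 to 20 × 20 grids on the
default 351-site design. These sizes give stable medians while keeping the
full suite around a minute of compute; all are the package's own choices
and can be scaled up freely.

## Known limitations

* The LMC is fitted per-variogram then projected; a simultaneous
  constrained fit (e.g. Goulard–Voltz iteration) would reproduce direct
  sills more faithfully when cross-structure is strong.
* No anisotropy, trend (universal kriging), block support, or conditional
  simulation.
* Indicator kriging uses one cutoff per metal; probability surfaces near 0
  and 1 are clamped rather than order-corrected.
* The sensor surrogate is homoscedastic in absolute terms; real field
  sensors are typically heteroscedastic.
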