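# soilkrige

Geostatistical analysis of soil heavy-metal surveys: kriging and co-kriging
of point-sampled concentrations with a cheap field-sensor covariate,
pollution-index assessment, hotspot detection, and indicator-kriging risk
mapping.

## The problem

Regional soil surveys measure metal concentrations (here Cr, Pb, Cd, As, Ni)
at a few hundred point locations with an accurate but expensive laboratory
assay (ICP-AES), and increasingly also with a cheap, rapid field sensor
(portable X-ray fluorescence, PXRF) that correlates only moderately with the
reference assay (per-metal R² roughly 0.4–0.7). The analytical questions this
package answers are the standard ones of spatial exposure assessment:

* **Where is the pollution?** Interpolate concentrations between samples by
  **ordinary kriging (OK)**, and sharpen the map by **ordinary co-kriging
  (COK)** that borrows strength from the dense sensor covariate.
* **How polluted is each sample?** The **single pollution index**
  SPI = Cᵢ/Sᵢ (concentration over a regulatory screening value, pH-class
  dependent) and the **Nemerow composite index**
  NCPI = √((max P² + mean P²)/2), with the usual five-grade
  classifications.
* **Where are the statistically significant clusters?** The **Getis-Ord Gi\***
  z-score within a distance band, with hot/cold-spot classes at the
  90/95/99% levels.
* **Where is multi-metal risk high?** **Multi-variable indicator kriging
  (MVIK)**: per-metal exceedance indicators I(x) = 1{Z(x) ≥ z} are kriged
  into probability surfaces and combined as Σ wᵢ Iᵢ(x) with weights from
  toxicity response coefficients (Cd 30, As 10, Pb 5, Cr 2, Ni 5,
  normalized).

Spatial structure is modeled through the semivariogram
γ(h) = ½E[(Z(x) − Z(x+h))²] estimated by the Matheron binned estimator,
fitted by Cressie-weighted least squares (weights N(h)/γ(h)²) over the
spherical/exponential/Gaussian families, and extended to a **linear model of
coregionalization** (positive-semidefinite coefficient matrices on shared
structures) so the co-kriging system is always valid.

Because survey datasets of this kind are rarely redistributable, the package
ships a **synthetic survey generator**: cross-correlated Gaussian random
fields with configurable variograms, transformed to lognormal margins
matching published summary statistics, plus a sensor surrogate whose noise
level is set analytically to hit a target R². Every downstream stage is
exercised end-to-end against it.

## Worked example

A default synthetic survey (351 sites, 97-site calibration subset carrying
the sensor measurement) for Cd, with the sensor available at every site and
the laboratory assay only on the calibration subset:

```python
import numpy as np
import soilkrige as sk
from soilkrige.variogram import empirical_cross_variogram, fit_lmc

survey = sk.simulate_fields(sk.SyntheticConfig(seed=1))
cal, val = sk.split_calibration_validation(survey, 97, seed=1)
full = survey.copy()
full.loc[~full.id.isin(cal.id), "Cd_lab"] = np.nan   # assay on 97 sites only

emp = sk.empirical_semivariogram(full, "Cd_lab")
model = sk.fit_model(emp)                             # auto family selection
lmc = fit_lmc(
    {("Cd_lab", "Cd_lab"): emp,
     ("Cd_pxrf", "Cd_pxrf"): sk.empirical_semivariogram(full, "Cd_pxrf"),
     ("Cd_lab", "Cd_pxrf"): empirical_cross_variogram(full, "Cd_lab", "Cd_pxrf")},
    [("nugget", 1.0), (model.family, model.range_)],
)
pts = val[["x", "y"]].to_numpy()
obs = survey.set_index("id").loc[val.id, "Cd_lab"].to_numpy()
ok = sk.ok_predict(full, "Cd_lab", model, pts)[0]
cok = sk.cok_predict(full, "Cd_lab", "Cd_pxrf", lmc, pts)[0]
print("OK  R2 %.3f RMSE %.4f" % (sk.r_squared(obs, ok), sk.rmse(obs, ok)))
print("COK R2 %.3f RMSE %.4f" % (sk.r_squared(obs, cok), sk.rmse(obs, cok)))
```

prints

```
OK  R2 0.283 RMSE 0.1759
COK R2 0.654 RMSE 0.1275
```

i.e. on the 254 held-out sites the sensor covariate more than doubles the
validation R² and cuts the RMSE by more than a quarter — kriging with only
97 reference measurements is data-starved, and the covariate supplies the
missing local information. Pollution assessment of the calibration subset
of the same survey:

```python
a = sk.assess(cal, ("Cr", "Pb", "Cd", "As", "Ni"))
print({m: round(a.table[f"{m}_spi"].mean(), 2) for m in ("Cr", "Pb", "Cd", "As", "Ni")})
print(round(a.table["ncpi"].mean(), 2))
```

```
{'Cr': 0.23, 'Pb': 0.23, 'Cd': 1.09, 'As': 0.3, 'Ni': 0.26}
0.83
```

Cd sits at the screening value (mean SPI ≈ 1) while the other metals are
well below theirs, and the mean composite index (0.83) is in the Alert band
(0.7 < NCPI ≤ 1) — the synthetic margins are built to emulate a survey
whose dominant pollutant is Cd.

The same workflow is available from the shell:

```sh
soilkrige run-all --seed 1 --out results_run --grid-size 100x100
```

which writes, per metal, the fitted variogram, OK and COK rasters
(ESRI ASCII) and a validation report, plus SPI/NCPI tables, Gi* hotspot
CSVs, the MVIK composite-risk raster and a deterministic JSON manifest.

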