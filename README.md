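# spastab

Woody-plant diversity and the **spatial stability of forest productivity**
(SSFP): community statistics from stem-level forest censuses, and
geographically weighted regression (GWR) to map how the
diversity–stability relationship varies across a landscape and with
elevation.

The package is aimed at forest and community ecologists working with
plot/subplot census designs: plots of 1200 m² tiled into 12 subplots of
10 m × 10 m, every woody stem with DBH ≥ 3 cm recorded with species, DBH
and height.

## What it computes

Per plot, from the stem table:

- species richness *S* and the Shannon–Wiener index
  *H′* = −Σ *pᵢ* ln *pᵢ* (stem-count shares, nats);
- functional dispersion *FDis* = Σ *aᵢzᵢ* / Σ *aᵢ*, the abundance-weighted
  mean distance *zᵢ* of species trait values to the abundance-weighted
  centroid, computed on one trait: species maximum height (99th percentile
  of all measured heights of the species);
- Berger–Parker dominance *N*max / *N*;
- **SSFP** = *μ*/*σ* of total basal area (π(DBH/2)²) across the 12
  subplots — the inverse coefficient of variation of productivity in
  space;
- the dominant species (largest total basal area) and its own *μ*/*σ*
  stability over its zero-filled subplot row;
- spatial species **asynchrony** = 1 − *σ*² / (Σᵢ *σᵢ*)², where *σ*² is
  the variance of subplot totals and *σᵢ* the SD of each species'
  zero-filled row (0 = perfect synchrony, 1 = perfect compensation).

Across plots, the pipeline log₁₀-transforms the model variables (all but
*FDis*), then fits GWR models of SSFP and its mediators against the
diversity measures:

> β̂(*i*) = (XᵀW*ᵢ*X)⁻¹ XᵀW*ᵢ*y,  *wᵢⱼ* = exp(−½ (*dᵢⱼ*/*bᵢ*)²)

with an adaptive bandwidth *bᵢ* = distance to the *k*-th nearest plot,
*k* = max(2, round(*q*(n−1))), the fraction *q* chosen by leave-one-out
cross-validation (golden-section search; AICc selection optional).
Reported diagnostics: local slopes and local R², global R² = 1 − RSS/TSS,
RSS, and the GWR-style corrected AIC from the exact hat-matrix trace.
Elevation effects are assessed with Kruskal–Wallis tests of local R²
across four elevation classes (≤200 / 201–400 / 401–600 / >600 m) and by
refitting after replacing each response with its OLS residuals on
elevation.

Because real censuses of this kind are rarely public, the package ships a
**synthetic study generator** (`spastab.synthetic_data`) that reproduces
the survey design (43 sites × 3 plots × 12 subplots, 15.48 ha, richness
4–49, elevations 25–819 m, ~200 stems/plot) with a *known*, spatially
varying diversity–stability coupling, so every stage of the pipeline can
be validated against ground truth.

## Worked example

```bash
spastab simulate --seed 3 --out simout
spastab gwr --response ssfp --predictor shannon \
    --trees simout/trees.csv --plots simout/plots.csv --out gwrout
```

prints

```
ssfp ~ shannon: q*=0.183 R2=0.426 AICc=-100.35 RSS=3.0522
```

i.e. the cross-validated adaptive kernel uses ~18% of the plots per local
fit, and the Shannon index explains ~43% of the variance in log₁₀ SSFP.
The full pipeline (here on a one-model suite) adds the
elevation-controlled refit:

```bash
spastab pipeline --config cfg.yaml --seed 2
```

```
response predictor  elevation_controlled   n        q        aicc       r2      rss  n_negative  n_positive
    ssfp   shannon                 False 129 0.175513 -151.246605 0.520792 2.062660         129           0
    ssfp   shannon                  True 129 0.925604 -157.866740 0.323244 2.104156         129           0
```

All 129 local slopes are negative (higher diversity, lower spatial
stability — the structure the default generator encodes), and the global
R² drops from 0.52 to 0.32 once elevation is controlled for, showing that
part of the association is carried by the elevation gradient. The same
tables are written as CSV (plot summaries, global and per-plot local
diagnostics, Kruskal–Wallis tests) together with a JSON manifest.

The same analysis runs on your own data by pointing the config's `input`
block at a tree table
(`site_id,plot_id,subplot_id,species,dbh_cm,height_m`) and a plot table
(`plot_id,site_id,x_km,y_km` or `longitude,latitude`, `elevation_m`).

## Layout

- `spastab.census_io` — read/validate/write the delimited census tables
- `spastab.community_metrics` — diversity, dominance, traits, imputation
- `spastab.stability_metrics` — subplot matrices, stability, asynchrony
- `spastab.gwr` — the GWR engine (kernel, bandwidths, CV, diagnostics)
- `spastab.pipeline` — transforms, model suite, elevation inference
- `spastab.synthetic_data` — study generator with known ground truth
- `docs/methods.md` — models, assumptions, numerical choices, limitations
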