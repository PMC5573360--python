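# Methods

This note documents the statistical models, the synthetic-data generator,
the numerical choices, and the known limitations of `spastab`.

## Community and stability statistics

All abundance-based indices use **stem counts** (relative individual
densities), not basal-area shares. Productivity is proxied by stem basal
area π(DBH/2)² in cm²; the stability and asynchrony statistics are
unitless ratios, so the unit cancels.

- **Shannon–Wiener H′** uses the natural logarithm; output is in nats.
- **Functional dispersion** is implemented for a single trait — species
  maximum height, defined as the 99th percentile of all measured heights
  of that species pooled over the whole study — with absolute-value
  distance to the abundance-weighted centroid. The general multi-trait
  Gower machinery is deliberately out of scope. Percentiles interpolate
  linearly between order statistics; the convention is pinned because the
  trait value feeds directly into FDis.
- **SSFP** is μ/σ of total basal area across a plot's 12 subplots, with
  the sample (n−1) standard deviation; likewise for the dominant species'
  stability, computed on its zero-filled 12-entry row. σ = 0 sets a
  `degenerate` flag instead of emitting an infinity, and degenerate plots
  are excluded from model fitting with a logged warning.
- **Spatial asynchrony** is 1 − σ²/(Σσᵢ)² over the zero-filled species ×
  subplot matrix ("every species is assumed present in every subplot,
  with zero productivity where it has no stem"). It is exactly 0 for a
  monoculture and lies in [0, 1] by the triangle inequality for standard
  deviations; values outside by rounding are clipped. A matrix whose rows
  are all constant has a zero denominator and raises an explicit error
  rather than guessing a value.
- Dominant-species ties are broken lexicographically so output is
  deterministic.

**Missing heights** are filled by single stochastic regression
imputation: a per-species linear fit of height on ln(DBH) (a pooled fit
backs up species with fewer than 3 observed heights) plus a residual
resampled from the fitting set; a deterministic mode suppresses the
residual so tests can pin exact values. Full chained-equations multiple
imputation is not warranted at the per-mille missingness this workflow
targets; imputed heights only enter the per-species 99th-percentile
trait, where their influence is negligible.

## The GWR engine

Local weighted least squares at every plot location with a **Gaussian
kernel**, w = exp(−½(d/b)²), and an **adaptive k-nearest-neighbour
bandwidth**: b at plot *i* is the distance to its k-th nearest other
plot, k = max(2, round(q·(n−1))). Gaussian weights never vanish, so every
local system uses all observations; q ∈ (0, 1] is the single smoothing
parameter.

- **Bandwidth selection**: leave-one-out cross-validation (the focal
  observation's weight set to zero), minimised by golden-section search
  on q ∈ [0.02, 1] to a tolerance of 10⁻³, with the evaluation trace
  returned. AICc minimisation is available behind `criterion="aicc"`.
  A numerically flat score curve returns the upper bound with a warning.
  Note that with this kernel the CV curve is typically very flat for
  q ≳ 0.4 on spatially homogeneous data — local fits there are already
  near-global — so the *selected* q can sit anywhere in the flat region;
  what is stable, and what the tests assert, is the fitted model itself
  (local slopes collapse onto the global OLS solution).
- **Diagnostics**: RSS, global R² = 1 − RSS/TSS, and
  AICc = n ln(σ̂²) + n ln(2π) + n(n + tr S)/(n − 2 − tr S) with
  σ̂² = RSS/n and tr S from the exact hat matrix (no approximation is
  needed at these problem sizes; the batched implementation is
  O(n²p²)). Global R² is defined as 1 − RSS/TSS rather than an aggregate
  of local R² — the two conventions differ and one must be pinned.
- **Local R²** at plot *i* uses the same kernel weights as estimation,
  with the weighted mean ȳ₍w,i₎; numerically negative values are clipped
  to 0 with a warning.
- **Distances**: Euclidean on planar km by default; great-circle
  (haversine, Earth radius 6371 km) when the plot table carries
  longitude/latitude. Both appear in field practice; the synthetic
  generator can emit either.
- Ordinary least squares (statsmodels under the hood) provides the
  global-model limit and the elevation-control residuals, with the same
  diagnostic definitions at tr S = p.

## Analysis pipeline

- **Transforms**: the default policy log₁₀-transforms every model
  variable except functional dispersion. A screening policy
  (Shapiro–Wilk at α = 0.05 per variable) is provided as the procedural
  alternative; decisions are logged either way. Rows with non-positive
  values of a variable being transformed (e.g. a zero asynchrony from a
  monoculture) are dropped with a logged warning — they cannot be
  log-transformed and flagging beats silently shifting.
- **Model suite**: stability, asynchrony, dominance and dominant-species
  stability each against richness, Shannon and FDis, plus stability
  against the three mediators (15 models); each model selects its own
  bandwidth. A failing model is recorded with its error and does not
  abort the suite. Identical response and predictor is a guard-rail
  error.
- **Elevation**: classes 1–4 break at 200/400/600 m (values below the
  survey floor fall in class 1; above the ceiling, class 4 with a
  warning). Trends are tested by tie-corrected Kruskal–Wallis on local
  R² across classes. Elevation control replaces each response by its OLS
  residuals on elevation in metres (linear control; no functional form
  beyond that is assumed), with each mediator response residualised on
  its own account. Per-plot correlation signs are classified by the sign
  of the local slope (equivalent to the local correlation sign for
  single-predictor models); an exactly zero slope counts as positive
  with a warning. No multiple-testing correction is applied by default;
  Holm across the Kruskal–Wallis family is available as a flag.

### A caveat on the Kruskal–Wallis elevation test

Local R² values are *spatially smooth by construction*: neighbouring
local fits share most of their effective data. Elevation classes are
themselves spatially structured, so the KW test's independence assumption
is violated and its P-values are anticonservative for this statistic —
simulations with all elevation couplings switched off still reject
essentially always. The test is therefore best read as a descriptive
ordering device, not a calibrated test; under random (spatially
unstructured) relabelling of plots its level is correct, which is how the
implementation is validated.

## The synthetic study generator

The generator emulates the survey design: 43 sites on a 100 × 150 km
planar extent, 3 plots per site within 1 km of the site centre and at
least 100 m apart, 12 subplots per plot, elevations 25–819 m following a
smooth south–north gradient plus site noise (so elevation classes are
spatially coherent, as on a mountain flank), per-plot richness 4–49, all
stems DBH ≥ 3 cm.

Per plot, in order:

1. **Community.** Richness is drawn around the range midpoint, optionally
   correlated with elevation (default r = 0.5). The expected total stem
   count is fixed at 200 per plot (Poisson) *independent of richness* —
   stem density in closed-canopy forest is set by space, not by how many
   species share it — and divided among species by a lognormal
   composition whose shape parameter is itself drawn per plot
   (σ ~ U(0.2, 2.5)), so evenness varies between equally rich stands and
   the Shannon index carries information beyond richness. A log-series
   composition is available as an alternative. Every sampled species
   keeps at least one stem.
2. **Latent stability target.**
   η = η₀ + g·z_elev + s(x, y)·(1 + e·r_elev)·z_H + ε,
   where z_H is the plot's standardised Shannon index, z_elev its
   standardised elevation, r_elev its elevation rank in (0, 1], s(x, y)
   the configured coefficient surface (constant, linear gradient, or an
   east/west sign split), e ≥ 0 makes the relationship strengthen with
   elevation, and ε ~ N(0, 0.25²). Defaults: η₀ = 0.3, g = −0.3,
   s ≡ −0.35, e = 1 — a negative diversity–stability relationship that
   grows stronger with elevation, with elevation also depressing
   stability directly and enriching diversity, so that controlling for
   elevation genuinely removes shared signal.
3. **Stem placement.** Stems of each species are scattered over the 12
   subplots by a Dirichlet–multinomial; the concentration is solved per
   plot so the *expected* CV of subplot basal-area totals matches the
   target exp(−η), using the variance decomposition
   CV² = (k−1)/N² · (N + ρ Σnᵢ(nᵢ−1)) + k·(v/m²)/N,
   with ρ the Dirichlet intra-class correlation and v/m² the relative
   basal-area variance implied by the lognormal DBH distribution. The
   second and ρ-free terms are an irreducible sampling floor — targets
   above the floor's ceiling clamp to near-uniform scattering. The
   formula was validated against direct simulation (within ~8%; DBH
   truncation at the census threshold makes it slightly conservative).
4. **Stem attributes.** DBH is lognormal (ln-mean 2.0, ln-SD 0.4)
   truncated below 3 cm; height = 1.5·DBH^0.66 + N(0, 1), floored at
   breast height (1.3 m); a fraction 7 × 10⁻⁴ of heights (the per-mille
   regime of real inventories) is blanked completely at random.

The generator returns, besides the stem and plot tables, a per-plot truth
table (true slope, latent η, realised Dirichlet aggregation) for
parameter-recovery tests.

**What the generator does and does not emulate.** It reproduces the
design geometry, the census protocol, realistic abundance and size
distributions, and a controllable spatially varying diversity–stability
coupling with elevation structure. It does not simulate climate,
disturbance, dispersal or species–habitat associations; subplot layout
within a plot is an index only (no statistic in the pipeline uses
within-plot geometry, and the field design's 3×4 vs 2×6 tiling is
immaterial for them). Consequently, passing recovery tests demonstrates
that the *pipeline* estimates what it claims under known structure — not
that any particular ecological mechanism holds in real forests.

## Problem sizes and determinism

Simulation-backed tests use the study's own scale — 129 plots,
~2.6 × 10⁴ stems — with 20 replicate seeds for recovery properties and 50
for bandwidth-selection properties; the 500-plot slope-sign recovery
check uses 6 seeds. All randomness flows through `numpy` Generators
seeded explicitly; identical (design, truth, seed) inputs reproduce
byte-identical output tables.

## Known limitations

- Single-trait FDis only; no rarefaction, Hill numbers or phylogenetic
  diversity.
- Spatial (not temporal) stability only — the design has one census.
- The KW elevation test inherits the anticonservativeness described
  above; treat its P-values comparatively.
- GWR here is the standard single-scale form: Gaussian kernel, one
  bandwidth for all terms; no bisquare/tricube kernels, mixed or
  multiscale GWR, and no spatial-autocorrelation diagnostics.
- Elevation control is linear; a strongly non-linear elevation signal
  would leave structure in the residuals.
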