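# Methods

## The interpolation model

Onset dates are assumed locally linear in elevation, longitude and
latitude: within each interpolation circle,
`DOY = a0 + a1·h + a2·lon + a3·lat + ε`, with ε i.i.d. Gaussian observer
noise. The circle lattice (default five rows by six columns, radius
1.95°, outermost centers on the bounding box of the observations) makes
the linearity assumption local: coefficients may drift smoothly across
the region, and the overlap between neighbouring circles — each grid
cell typically sits inside two to four — lets inverse-distance weighting
(power 1) blend them into continuous coefficient surfaces. A cell
coinciding with a circle center copies that circle's coefficients
exactly (the limit of 1/d weighting); cells inside no fitted circle are
masked and counted.

Assumptions worth keeping in mind:

- **Homoscedastic noise.** The least-squares fits and the LOOCV error
  treat observer noise as constant across sites and years.
- **Degree-space distances.** Circle membership and IDW weights use
  Euclidean distance in degrees, because the circle radius is specified
  in degrees. At mid-latitudes a degree of longitude is shorter on the
  ground than a degree of latitude; the resulting anisotropy is accepted
  rather than corrected, keeping one distance metric everywhere.
- **Elevation cut-off.** Cells at or above 1000 m a.s.l. are masked
  (strict: exactly 1000 m is excluded). Observer networks barely sample
  high terrain, and a linear elevation term extrapolated upward is not
  trustworthy.

## Parameters that matter

| parameter | default | units | why |
|---|---|---|---|
| circle radius | 1.95 | degrees | large enough for stable 4-parameter fits, small enough to stay local |
| circle lattice | 5 × 6 | — | standard layout for a country-scale domain |
| `min_fit_n` | 8 | observations | twice the parameter count; smaller circles are skipped, not force-fitted |
| IDW power | 1 | — | gentle blending across overlapping circles |
| elevation mask | 1000 | m a.s.l. | network does not constrain higher terrain |
| condition threshold | 1e10 | — | design matrices beyond this are flagged rank-deficient and excluded from IDW |
| LOESS span | 0.25 | fraction of 23 within-year composites | ≈ six nearest composites, a ±48-day window |
| minimum NDVI amplitude | 0.1 | NDVI | below this no season is declared |
| station trend filter | ≥ 30 (≥ 15 winter) | years | short records produce unstable slopes |

## Uncertainty machinery

`RMSE_LOOCV` per circle is computed with the PRESS identity
`e_i / (1 − h_ii)` from a single OLS fit; observations whose leverage is
numerically one fall back to an explicit refit, and a refit whose
reduced design is rank-deficient drops that observation with a log
entry. The explicit refit-every-observation path is kept in the code
(`loocv_refit`) purely as the independent oracle the fast path is tested
against.

Note the estimand: LOOCV measures *out-of-sample prediction error*, not
the noise sd alone. Its expectation is approximately
`σ·(1 + p/(2·n_c))` for circles of size `n_c` with `p = 4` parameters,
so recovered values sit a tenth of a day or two above the generating σ
at realistic circle sizes. This is a property of cross-validation, not
a bias to remove.

The thinning experiment draws `floor(p·n/100)` observations globally
without replacement — no spatial balancing, mimicking uncontrolled
observer attrition — recomputes every circle's RMSE_LOOCV, and averages
over the circles that remain fittable (circles that fall below the
minimum size are excluded from that repetition's average; zero-filling
would bias the curve downward). At 100% retention the draw is
deterministic and equals the full-data value. Per-repetition RNG streams
are spawned from one master seed.

## Trends and temperature sensitivity

Theil–Sen slopes (median of pairwise slopes, via `scipy.stats.theilslopes`)
are paired with the Mann–Kendall test, its conventional significance
companion: tie-corrected variance, continuity correction, normal
approximation for n > 10 and the exact tail otherwise. Duplicate years
are averaged before fitting. No multiple-testing correction is applied
across cells or stations — reported significant-trend proportions are raw
p < 0.05 rates by design.

The preseason of an onset is its calendar month plus the two preceding
months (reaching into the previous year for January/February onsets).
Two window modes exist:

- **per-year** (default): the window follows each year's onset;
- **climatological**: the window is fixed at the month of the cell's
  multi-year mean onset.

The per-year window has a subtle property: for cells whose onsets
straddle a calendar-month boundary, warm and cold years are measured
against windows with *different seasonal baselines* (April is several °C
warmer than March climatologically), which dilutes the measured
correlation toward zero for those cells. Correlation-recovery
experiments therefore use the climatological window, which measures the
generating coupling cleanly; the per-year mode is retained as the
default behaviour and verified for its sign structure.

## The synthetic world

The generator emulates exactly the structure the method assumes:

- DEM: smooth random cosine-series surface clipped to [0, 1800] m on a
  Bavaria-sized domain (lat 47.3–50.5°, lon 9.0–13.9°).
- Onsets: `DOY = a0* + a1*·h + a2*·lon + a3*·lat + β·(year−year0) + N(0, σ²)`,
  defaults a1* = 0.03 d/m (3 days per 100 m), a2* = 1.5 d/°E,
  a3* = 3 d/°N, σ = 6 days (the magnitude of a good spring-phase
  interpolation uncertainty), β = −0.25 d/yr (a typical spring advance).
  DOY is rounded to whole days after noise and clipped to [1, 366]
  (`round_doy=False` keeps the exact plane for exactness checks — day
  rounding would otherwise dominate 1e-9-level comparisons). Optional
  per-year dropout mimics observer attrition.
- Temperature: seasonal cycle (mean 9 °C, amplitude 9 °C, peak July)
  + lapse −6.5 °C/km + warming 0.03 °C/yr + an interannual anomaly with
  an annual component (sd 1.2 °C) shared by all months of a year and an
  independent monthly component (sd 0.8 °C) — monthly anomalies in
  nature are temporally autocorrelated, and this structure keeps the
  preseason mean stable under one-month window shifts.
- Temperature coupling: onset anomaly `ρ·Z + √(1−ρ²)·ε` with Z the
  standardised preseason anomaly at the cell's climatological onset
  month. ρ is a Pearson correlation; the implied Spearman is
  `(6/π)·asin(ρ/2)`, the quantity recovery tests compare against.
  Negative ρ encodes a spring phase, positive an autumn phase.
- NDVI: a double-logistic annual curve sampled as 23 maximum-value
  16-day composites per 365-day year, with radiometric noise, cloud/snow
  flags and outright gaps injectable at configurable rates.

What the generator does **not** emulate: spatially correlated observer
error, species-specific process models (chilling/forcing), uneven
volunteer density (sites are uniform over the grid), land-cover effects
on NDVI, or leap-day bookkeeping. Passing tests therefore demonstrate
that the pipeline recovers what its own model family generates — they do
not certify performance on real networks, where the linearity and
independence assumptions are approximations.

## Numerical choices

- OLS via statsmodels; rank deficiency detected by a condition-number
  threshold of 1e10 on the design matrix.
- LOESS is locally quadratic with tricube weights; the bandwidth at each
  evaluation day is the distance to the q-th nearest composite
  (q = ceil(span·23)). The local coordinate is scaled by the bandwidth
  before the 3×3 normal equations are formed — unscaled day offsets to
  the fourth power make the system ill-conditioned — and a 1e-12 ridge
  keeps windows with few distinct points solvable.
- Half-amplitude crossings are located by linear interpolation between
  days and rounded to whole days; SOS is the first upward crossing
  before the day of the annual maximum, EOS the last downward crossing
  after it. Years with amplitude < 0.1 NDVI yield no season. Multi-modal
  years pivot on the global annual maximum.
- Rasters are ESRI ASCII grids; rectangular cells use the GDAL `dx`/`dy`
  header extension. All grids are cell-center referenced, row 0 north.

## Experiment scales

The benchmark experiments (`phenomap.experiments`, driven by the test
suite and `scripts/acceptance.py`) use: 20×20–25×25 cell worlds; 80
observers for exactness checks, 200 for noise recovery (100
repetitions), 600 for the thinning curve (200 repetitions per retention
level); 69-year series with 300 stations and 500 grid cells for trend
recovery; 10⁴ simulations of length 30 for the Mann–Kendall size check;
144-cell worlds for correlation structure; and 200 repetitions of
3-year NDVI series for season extraction. These sizes give Monte-Carlo
error comfortably below the effects being measured while keeping the
whole evidence base reproducible in about a minute.

## Known limitations

- Kriging/spline alternatives, additional covariates (slope, aspect,
  continentality) and cross-year smoothing are out of scope.
- The LOOCV surface inherits the IDW convexity property: it cannot
  exceed the largest circle value, so very local error hot-spots are
  smoothed away.
- The per-year preseason window dilutes correlations at month
  boundaries (see above); the climatological window avoids this at the
  cost of ignoring genuinely early/late years' window shifts.
- CRS transformations are not performed; all inputs must already share
  one geographic coordinate system.
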