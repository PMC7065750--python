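# Methods

This note documents the models, conventions and numerical choices behind
`kelpsat`, and what the synthetic-data layer does and does not emulate.

## Spectral mixture model

Each pixel's reflectance vector is modelled as a sum-to-one linear mixture of
exactly two endmembers, kelp canopy **k** and seawater **w**:
*r* = *f*·**k** + (1 − *f*)·**w** + ε. The least-squares fraction has the
closed form *f* = ⟨*r* − **w**, **k** − **w**⟩ / ‖**k** − **w**‖²; it is
clipped to [0, 1] before the RMSE is evaluated, because canopy fraction is a
physical proportion. There is no shade endmember and no multi-endmember
combination beyond the kelp/water pair. Per image, every one of the *K*
seawater endmembers (default 30) is tried and the lowest-RMSE model is kept;
RMSE is computed over all bands, unweighted; ties are broken by the lowest
endmember index so results are deterministic. For real imagery the seawater
endmembers would be drawn per image (e.g. offshore pixels far from any kelp
mask); the synthetic generator sidesteps derivation by constructing the
library directly.

Dynamic (per-image) seawater endmembers absorb changing water conditions —
phytoplankton, suspended sediment, sunglint — which is why the generator
randomizes the visible bands of its water spectra while keeping near-infrared
low; kelp is the only NIR-bright material in scene, which is the physical
contrast the unmixer exploits.

## Canopy series conventions

* **Cloud rule.** A date is dropped for a site when *strictly more than* 25 %
  of the site's pixels are obscured; exactly 25 % is retained.
* **Site extraction.** Pixels whose *centers* fall within the extraction
  radius (default 100 m; per-site overrides such as 400 m or 1000 m are
  passed per call) are summed. Raster convention: north-up, row-major,
  origin at the top-left corner. "Canopy density" is carried in
  fraction-sum units throughout; every downstream statistic is
  scale-invariant or relative, so an unknown linear fraction→biomass
  coefficient cancels.
* **Trimesters.** Three 4-month bins per calendar year, fixed at Jan–Apr /
  May–Aug / Sep–Dec. Observations are averaged within bins; interior empty
  bins are linearly interpolated (flagged `n_obs = 0`); leading/trailing
  gaps are left missing rather than extrapolated.
* **Standardization.** Each series is divided by its maximum over the full
  record, mapping to [0, 1]; an all-zero series is returned unchanged so no
  NaNs propagate.
* **Running mean.** Centered, nominal 6-trimester (2-year) window spanning
  offsets −⌊(w−1)/2⌋ … ⌊w/2⌋, shrinking at the edges; NaN steps are excluded
  from each window. Applied identically to canopy, SST-like and ENSO-like
  series.
* **Lag convention.** `lagged_pearson(x, y, lag)` correlates y(t) with
  x(t − lag): the climate index leads the canopy. One year = 3 trimesters.
  p-values for correlations of running-mean series are reported but should
  be read as descriptive: smoothing inflates autocorrelation and the nominal
  t-based p does not account for it.

## AR(1) trend test

`gls_ar1_trend` fits value = a + b·t with AR(1) errors. The autoregressive
coefficient is profiled on a grid (−0.95 … 0.95, step 0.01) using the
Prais–Winsten whitening transform and the *restricted* (REML) likelihood;
REML avoids the downward bias of the maximum-likelihood rho estimate. The
selected rho then receives the standard first-order small-sample bias
correction (+(1 + 3ρ)/n, Marriott–Pope/Kendall) before the slope covariance
is formed; without it the test is slightly anticonservative on short
autocorrelated series. The slope's two-sided p uses a t reference with
n − 2 degrees of freedom. On trendless AR1(ρ = 0.6) series of length 80 the
empirical size at α = 0.05 is ≈ 0.06 (ordinary regression: ≈ 0.3); the test
suite checks this on 500 replicates. The implementation agrees with R's
`nlme::gls(…, correlation = corAR1())` to grid precision on the same data.

## Validation regression and nitrate smoother

The satellite-vs-in-situ check averages the four pixels incident to the
pixel corner nearest each survey coordinate, across dates, and fits a
reduced major axis regression (slope = sign(r)·sd(y)/sd(x)) — appropriate
because both variables carry error. Sites can be excluded a priori (low
geographic precision) and sites with no kelp pixels within 500 m are dropped
automatically.

The temperature–nitrate relationship is fit with a penalized cubic smoothing
spline whose smoothing parameter is solved by bisection so the trace of the
smoother matrix equals a fixed effective df (default 4); tied abscissae are
collapsed to their mean response first. The fit object exposes the fitted
curve, r², and a depletion diagnostic (fitted values above a temperature
threshold as a fraction of the fitted maximum).

## Community statistics

* Natural logarithms everywhere: Margalef d = (S − 1)/ln N, Shannon
  H′ = −Σ pᵢ ln pᵢ, Pielou J′ = H′/ln S (missing when S = 1).
* The dominance table (IRD = %num × %freq, both on the 0–100 scale) and the
  diversity indices use raw densities; Bray–Curtis for PERMANOVA/PCO is
  computed on ln(x+1)-transformed densities.
* PERMANOVA partitions the Gower-centered matrix G = −½CD²C with Type-III
  (partial) sums of squares from sum-to-zero-coded designs:
  SS(term) = tr(H_full G) − tr(H_reduced G). Each term's null is built by
  Freedman–Lane permutation of reduced-model residuals,
  G* = (H_red + P(I − H_red)) G (·)ᵀ, and p = (b + 1)/(m + 1) with the
  observed statistic included (m = 999 by default; the seed is mandatory).
  Permuted statistics are compared to the observed one with a 1e-8 relative
  tolerance so that group-preserving relabelings, which tie the statistic
  exactly, are counted despite floating-point round-off. Inestimable
  (confounded) terms raise rather than being silently dropped.
* Pairwise tests report t = √(pseudo-F) of the two-group one-way PERMANOVA
  on the subset, optionally within strata; levels with fewer than 2 samples
  are skipped with a warning.
* PCO retains negative eigenvalues in the report (Bray–Curtis is semimetric)
  but excludes them from coordinates; percent variation is relative to the
  sum of positive eigenvalues, with no Lingoes/Cailliez correction. Vector
  overlays keep taxa whose |Pearson r| with axis 1 or 2 is ≥ 0.5.
* Pillai's trace V = Σ λᵢ/(1 + λᵢ) over eigenvalues of E⁻¹H with the
  standard F approximation; it reduces exactly to one-way ANOVA F for a
  single response (checked in the tests, alongside agreement with
  statsmodels).

## Synthetic-data layer

The generators emulate the *structure* of the real inputs, not their
physics:

* Scenes are 30 m pixels with 6 reflective bands; the kelp endmember is a
  fixed vegetation-like spectrum (high NIR) and water endmembers are low-NIR
  with randomized visible variation. No radiative transfer, sensor band
  responses, tides/currents, or geolocation error. Acquisition dates are
  drawn from August–April only, reflecting austral-winter data gaps.
* The climate index is a standardized AR(1) process (φ = 0.8 per trimester),
  giving ENSO-like interannual persistence; canopy is seasonal (period one
  year) minus β times the lagged index plus noise, min-max rescaled to
  [0, 1]. Because the index is persistent, lagged correlations are high at
  neighbouring lags too — as in real ENSO series — and the tests check that
  the *peak* sits at the planted lag.
* Community counts are negative binomial (gamma–Poisson) with multiplicative
  location/exposure effects on the log scale; baseline means mimic a
  barnacle-dominated Magellanic kelp-forest benthos at 50 m² transects; the
  default design is 18 stations in an unbalanced 2×2 (5/5/4/4).
* Generators are pure functions of (spec, seed). Passing tests on this layer
  demonstrate algorithmic correctness and statistical calibration, not
  robustness to real-sensor artifacts (atmospheric residuals, sunglint
  structure, georegistration error).

## Problem sizes and defaults

Calibration studies in the test suite use 200 replicate survey datasets
(PERMANOVA null, 199 permutations each) and 500 replicate AR1 series of
length 80 (trend-test size); the end-to-end recovery test uses 14 years of
16×16-pixel scenes at 2 acquisitions per trimester with a 30-spectrum water
library. These sizes give Monte-Carlo standard errors comfortably inside the
asserted bands while keeping the suite quick.

## Known limitations

* The fraction→biomass conversion is deliberately out of scope; results are
  in fraction-sum units.
* The trimester binning assumes calendar-aligned bins; alternative phase
  choices would shift seasonal structure slightly.
* PERMANOVA p-values are Monte-Carlo; with 999 permutations the smallest
  attainable p is 0.001.
* `read_climate_csv` shifts series internally to satisfy the non-negative
  site-series container and shifts back; exact round trips hold to floating
  precision.
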