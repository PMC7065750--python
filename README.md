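# kelpsat

Analysis pipeline for studying giant kelp (*Macrocystis pyrifera*) forests by
combining satellite estimates of emergent canopy with dive-survey community
data — the toolchain used to ask whether a remote, high-latitude kelp region
has changed over decades, what climate signal drives its canopy, and how its
benthic and fish communities are structured.

The package has two halves:

1. **Remote sensing.** Landsat-style multiband scenes are unmixed pixel by
   pixel with a two-endmember spectral mixture model — one static kelp-canopy
   spectrum and one of *K* per-image seawater spectra (default *K* = 30); for
   each pixel the seawater endmember giving the lowest model RMSE wins, and
   the kelp fraction *f* of that best model is the canopy estimate:
   *r* = *f*·**k** + (1 − *f*)·**w** + ε, with
   *f* = ⟨*r* − **w**, **k** − **w**⟩ / ‖**k** − **w**‖², clipped to [0, 1].
   Fraction maps become site series (summed fraction within 100 m of a site,
   dates with > 25 % cloud over the site removed), are binned onto 4-month
   trimesters, standardized by the site maximum ("proportional kelp canopy
   density"), smoothed with a 2-year running mean, and analysed with
   AR(1)-aware generalized least squares trend tests, lagged Pearson
   correlations against ENSO/SST-style climate indices, reduced major axis
   validation against in-situ density, and a penalized-spline
   temperature–nitrate fit.
2. **Community ecology.** Diversity indices (Margalef *d*, Shannon *H′*,
   Pielou *J′*), the Index of Relative Dominance
   (IRD = %num × %freq), Bray–Curtis dissimilarity of ln(x+1) densities,
   two-way PERMANOVA (Type-III partial sums of squares, permutation of
   residuals under the reduced model), pairwise permutation tests, principal
   coordinates ordination with taxon vector overlays (|r| ≥ 0.5), Pillai's
   trace MANOVA, paired/two-sample t-tests and chi-square composition tests —
   all implemented from first principles and cross-checked in the test suite
   against scikit-bio, statsmodels and scipy.

A synthetic-data layer (`kelpsat.synthdata`) generates every input with known
ground truth — scenes with a planted canopy-fraction field, climate/canopy
series coupled at a known lag, and factorial 2×2 community tables with
specifiable effect sizes — so the whole pipeline is verifiable end to end
without any satellite download.

## Worked example

```python
import numpy as np
from kelpsat import synthdata as sd, unmix, canopyseries as cs

# a world where canopy responds to the climate index one year (3 trimesters) late
climate, canopy = sd.gen_climate_canopy(
    sd.ClimateCouplingSpec(n_years=14, coupling_beta=1.0, lag_trimesters=3,
                           noise_sd=0.05, seed=0))
dates = sd.sample_acquisition_dates(2000, 14, per_trimester=2, seed=1)
peaks = canopy.values[cs.trimester_of(dates) - canopy.trimester_index[0]]
spec = sd.SceneSpec(n_rows=16, n_cols=16, dates=dates,
                    kelp_patch=sd.GaussianPatch(8, 8, 3.0, peaks=peaks),
                    noise_sd=0.01, water_variability=0.1, cloud_prob=0.05, seed=2)
library = sd.gen_endmember_library(n_water=30, n_bands=6, seed=3)
scenes, truth, clouds = sd.gen_scene_series(spec, library)

grid = unmix.Grid(16, 16, pixel_size=30.0)
maps = [unmix.unmix_scene(scenes[i], library, cloud_mask=clouds[i],
                          date=dates[i], grid=grid) for i in range(len(dates))]
site = cs.extract_site_series(maps, (8.5 * 30, -8.5 * 30), radius_m=100.0)
ts = cs.running_mean(cs.proportional_standardize(cs.to_trimesters(site)), 6)
clim = cs.running_mean(climate, 6)
for lag in (0, 3, 6):
    print(lag, round(cs.lagged_pearson(clim, ts, lag).r, 3))
```

prints

```
0 -0.633
3 -0.992
6 -0.587
```

— the canopy series reconstructed from unmixed imagery correlates most
strongly (and negatively) with the climate index at the planted one-year lag:
warm ENSO-like conditions are followed by canopy loss a year later, and the
pipeline recovers that coupling from pixels alone.

The same stages are scriptable from a shell:

```sh
kelpsat simulate --outdir run --seed 7
kelpsat unmix    --outdir run
kelpsat series   --outdir run --lag-trimesters 3
kelpsat stats    --outdir run --n-perm 999 --seed 7
kelpsat report   --outdir run
```

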