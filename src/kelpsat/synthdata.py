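"""Synthetic inputs with known ground truth for every pipeline stage.

Emulates the three data streams the analysis consumes:

* Landsat-like multiband scenes (30 m pixels, 6 reflective bands) containing a
  kelp patch with a known per-date true canopy-fraction field, variable
  seawater background, additive noise and cloud occlusion;
* trimester climate/canopy series where the canopy responds to the climate
  index at a known lag (ENSO-style forcing);
* factorial 2x2 (location x exposure) community survey tables drawn from an
  overdispersed count model with specifiable multiplicative effect sizes.

Generators are pure functions of (spec, seed); seeds are explicit fields and
never global state, so every recovery-style test is reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .unmix import EndmemberLibrary, Grid, Spectrum

__all__ = [
    "SceneSpec",
    "GaussianPatch",
    "ClimateCouplingSpec",
    "SurveySpec",
    "gen_endmember_library",
    "gen_scene_series",
    "gen_climate_canopy",
    "gen_survey_tables",
    "sample_acquisition_dates",
    "LOCATIONS",
    "EXPOSURES",
]

LOCATIONS = ("IE", "MP")
EXPOSURES = ("exposed", "sheltered")

# Imagery is usable only outside the austral winter (persistent cloud and low
# sun angles): acquisitions are drawn from August through April.
_ACQUISITION_MONTHS = (8, 9, 10, 11, 12, 1, 2, 3, 4)

# Band-order convention: blue, green, red, NIR, SWIR1, SWIR2 (Landsat-like).
_KELP_SHAPE = np.array([0.04, 0.06, 0.05, 0.38, 0.18, 0.09])
_WATER_SHAPE = np.array([0.06, 0.05, 0.03, 0.010, 0.004, 0.002])


@dataclass(frozen=True)
class GaussianPatch:
    """A radially decaying kelp patch: truth fraction =
    ``peak * exp(-((r/sigma)^2)/2)`` around (center_row, center_col), with a
    per-date peak amplitude in [0, 1]."""

    center_row: float
    center_col: float
    sigma_px: float
    peaks: np.ndarray  # one peak fraction per acquisition date

    def truth_fields(self, n_rows: int, n_cols: int) -> np.ndarray:
        peaks = np.asarray(self.peaks, dtype=float)
        if np.any((peaks < 0) | (peaks > 1)):
            raise ValueError("patch peak fractions must lie in [0, 1]")
        rr, cc = np.mgrid[0:n_rows, 0:n_cols]
        r2 = (rr - self.center_row) ** 2 + (cc - self.center_col) ** 2
        shape = np.exp(-0.5 * r2 / self.sigma_px**2)
        return peaks[:, None, None] * shape[None, :, :]


@dataclass
class SceneSpec:
    """Configuration of a synthetic multiband scene series."""

    n_rows: int = 16
    n_cols: int = 16
    dates: Sequence[np.datetime64] = ()
    kelp_patch: GaussianPatch | np.ndarray | None = None
    pixel_size: float = 30.0
    n_bands: int = 6
    water_variability: float = 0.0  # per-date perturbation scale of seawater spectra
    noise_sd: float = 0.0           # additive reflectance noise
    cloud_prob: float = 0.0         # per-pixel occlusion probability
    seed: int = 0

    def __post_init__(self):
        if self.n_bands < 2:
            raise ValueError("need at least 2 bands")
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("scene dimensions must be positive")
        if not 0.0 <= self.cloud_prob <= 1.0:
            raise ValueError("cloud_prob must be a probability")
        dates = np.array([np.datetime64(d) for d in self.dates])
        if len(dates) == 0:
            raise ValueError("at least one acquisition date is required")
        if np.any(np.diff(dates.astype("datetime64[D]").astype(int)) <= 0):
            raise ValueError("dates must be strictly increasing")
        self.dates = dates

    def truth_stack(self) -> np.ndarray:
        n_dates = len(self.dates)
        if self.kelp_patch is None:
            truth = np.zeros((n_dates, self.n_rows, self.n_cols))
        elif isinstance(self.kelp_patch, GaussianPatch):
            truth = self.kelp_patch.truth_fields(self.n_rows, self.n_cols)
        else:
            truth = np.asarray(self.kelp_patch, dtype=float)
        if truth.shape != (n_dates, self.n_rows, self.n_cols):
            raise ValueError("truth field shape must be (n_dates, n_rows, n_cols)")
        if np.any((truth < 0) | (truth > 1)):
            raise ValueError("true fractions must lie in [0, 1]")
        return truth


@dataclass
class ClimateCouplingSpec:
    """Climate-forced canopy dynamics on a trimester (4-month) grid."""

    n_years: int = 20
    coupling_beta: float = 1.0      # effect of the lagged index on canopy
    lag_trimesters: int = 3         # 3 trimesters = one year
    seasonal_amplitude: float = 0.5
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.lag_trimesters < 0:
            raise ValueError("lag_trimesters must be >= 0")
        if self.seasonal_amplitude < 0:
            raise ValueError("seasonal_amplitude must be >= 0")
        if self.n_years < 1:
            raise ValueError("n_years must be positive")
        if self.lag_trimesters >= 3 * self.n_years:
            raise ValueError("lag longer than the series")


@dataclass
class SurveySpec:
    """Factorial 2x2 (location x exposure) community survey design.

    ``effect_sizes`` maps factor level -> {taxon: multiplier} giving
    multiplicative (log-scale) shifts of the baseline mean count; a value of 1
    everywhere is the null. ``dispersion`` is the negative-binomial size
    parameter (smaller = more overdispersed; Poisson in the limit -> inf).
    """

    n_sites_per_cell: int | Mapping[tuple[str, str], int] = 5
    taxa_pool: Mapping[str, float] = field(default_factory=lambda: {
        # baseline mean counts per 50 m^2 transect, barnacle-dominated like a
        # Magellanic kelp-forest benthos
        "Balanus_laevis": 300.0,
        "Loxechinus_albus": 65.0,
        "Encrusting_bryozoan": 80.0,
        "Bunodactis_octoradiata": 48.0,
        "Didemnum_studeri": 37.0,
        "Gaimardia_trapesina": 70.0,
        "Anasterias_antarctica": 16.0,
        "Pseudechinus_magellanicus": 18.0,
        "Margarella_violacea": 25.0,
        "Pagurus_comptus": 12.0,
    })
    effect_sizes: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    dispersion: float = 2.0
    transect_area: float = 50.0
    seed: int = 0

    def __post_init__(self):
        if len(self.taxa_pool) == 0:
            raise ValueError("taxa pool must be non-empty")
        if any(m < 0 for m in self.taxa_pool.values()):
            raise ValueError("baseline means must be >= 0")
        if self.transect_area <= 0:
            raise ValueError("transect_area must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")

    def cell_sizes(self) -> dict[tuple[str, str], int]:
        if isinstance(self.n_sites_per_cell, int):
            sizes = {(l, e): self.n_sites_per_cell for l in LOCATIONS for e in EXPOSURES}
        else:
            sizes = {(l, e): int(self.n_sites_per_cell.get((l, e), 0))
                     for l in LOCATIONS for e in EXPOSURES}
        if any(n < 1 for n in sizes.values()):
            raise ValueError("every location x exposure cell needs >= 1 site")
        return sizes


def gen_endmember_library(n_water: int, n_bands: int = 6, seed: int = 0) -> EndmemberLibrary:
    """One static vegetation-like kelp endmember (elevated NIR) plus
    ``n_water`` low-NIR seawater endmembers with randomized visible-band
    variation (phytoplankton/sediment/sunglint-style differences)."""
    if n_water < 1 or n_bands < 2:
        raise ValueError("n_water must be >= 1 and n_bands >= 2")
    rng = np.random.default_rng(seed)
    kelp = _resample_shape(_KELP_SHAPE, n_bands)
    base_water = _resample_shape(_WATER_SHAPE, n_bands)
    water = []
    for _ in range(n_water):
        # visible-dominated multiplicative jitter; NIR stays low
        jitter = rng.lognormal(mean=0.0, sigma=0.25, size=n_bands)
        offset = rng.uniform(0.0, 0.01, size=n_bands)
        water.append(Spectrum(base_water * jitter + offset))
    return EndmemberLibrary(kelp=Spectrum(kelp), water=tuple(water))


def _resample_shape(shape: np.ndarray, n_bands: int) -> np.ndarray:
    if n_bands == shape.size:
        return shape.copy()
    x_old = np.linspace(0.0, 1.0, shape.size)
    x_new = np.linspace(0.0, 1.0, n_bands)
    return np.interp(x_new, x_old, shape)


def gen_scene_series(spec: SceneSpec, library: EndmemberLibrary):
    """Generate the scene stack, the truth fraction stack, and cloud masks.

    Each unmasked pixel is ``f*kelp + (1-f)*w + noise`` for that pixel's true
    fraction f and a randomly drawn (optionally perturbed) seawater spectrum w.

    Returns
    -------
    scenes : (n_dates, n_bands, n_rows, n_cols) float array
    truth : (n_dates, n_rows, n_cols) float array
    cloud_masks : (n_dates, n_rows, n_cols) boolean array (True = obscured)
    """
    if library.n_bands != spec.n_bands:
        raise ValueError("library band count does not match the scene spec")
    rng = np.random.default_rng(spec.seed)
    truth = spec.truth_stack()
    n_dates = len(spec.dates)
    W = library.water_array()
    k = library.kelp.values
    scenes = np.empty((n_dates, spec.n_bands, spec.n_rows, spec.n_cols))
    clouds = np.empty((n_dates, spec.n_rows, spec.n_cols), dtype=bool)
    npix = spec.n_rows * spec.n_cols
    for t in range(n_dates):
        idx = rng.integers(0, len(W), size=npix)
        w = W[idx]
        if spec.water_variability > 0:
            w = w * rng.lognormal(0.0, spec.water_variability, size=w.shape)
        f = truth[t].reshape(-1, 1)
        refl = f * k + (1.0 - f) * w
        if spec.noise_sd > 0:
            refl = refl + rng.normal(0.0, spec.noise_sd, size=refl.shape)
        scenes[t] = refl.T.reshape(spec.n_bands, spec.n_rows, spec.n_cols)
        clouds[t] = rng.random((spec.n_rows, spec.n_cols)) < spec.cloud_prob
    return scenes, truth, clouds


def sample_acquisition_dates(start_year: int, n_years: int, per_trimester: int = 2,
                             seed: int = 0) -> np.ndarray:
    """Acquisition dates restricted to August-April, ``per_trimester`` per
    4-month trimester, strictly increasing."""
    rng = np.random.default_rng(seed)
    dates = []
    for year in range(start_year, start_year + n_years):
        for tri, months in enumerate(((1, 2, 3, 4), (5, 6, 7, 8), (9, 10, 11, 12))):
            usable = [m for m in months if m in _ACQUISITION_MONTHS]
            days = sorted(rng.choice(28, size=per_trimester, replace=False))
            for j, day in enumerate(days):
                month = usable[j % len(usable)]
                dates.append(np.datetime64(f"{year}-{month:02d}-{day + 1:02d}"))
    return np.array(sorted(set(dates)))


def _trimester_index(dates) -> np.ndarray:
    d = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[D]"))
    return (d.year * 3 + (d.month - 1) // 4).to_numpy()


def gen_climate_canopy(spec: ClimateCouplingSpec):
    """A climate index and a canopy series coupled at a known lag.

    The climate index is a standardized smooth AR(1) process (ENSO-like
    interannual persistence). The canopy is
    ``seasonal(t) - coupling_beta * climate(t - lag) + noise``, min-max
    rescaled to [0, 1]; the seasonal term has a one-year (3-trimester) period.

    Returns ``(climate, canopy)`` as :class:`~kelpsat.canopyseries.TrimesterSeries`
    on a common trimester grid.
    """
    from .canopyseries import TrimesterSeries

    rng = np.random.default_rng(spec.seed)
    n = 3 * spec.n_years
    lag = spec.lag_trimesters
    # generate `lag` extra leading steps so the lagged forcing is defined
    # over the whole returned window
    m = n + lag
    phi = 0.8
    innov = rng.normal(0.0, 1.0, size=m)
    clim = np.empty(m)
    clim[0] = innov[0] / np.sqrt(1 - phi**2)
    for t in range(1, m):
        clim[t] = phi * clim[t - 1] + innov[t]
    clim = (clim - clim.mean()) / clim.std()

    t_idx = np.arange(n)
    seasonal = spec.seasonal_amplitude * np.cos(2 * np.pi * t_idx / 3.0)
    # internal index lag+t is output step t: clim[t] = climate(t - lag),
    # clim[lag+t] = climate(t)
    canopy = seasonal - spec.coupling_beta * clim[t_idx] + \
        rng.normal(0.0, spec.noise_sd, size=n)
    span = canopy.max() - canopy.min()
    canopy01 = (canopy - canopy.min()) / span if span > 0 else np.full(n, 0.5)

    tri0 = 2000 * 3  # arbitrary anchor year
    index = tri0 + t_idx
    climate_series = TrimesterSeries(trimester_index=index, values=clim[lag + t_idx],
                                     n_obs=np.ones(n, dtype=int))
    canopy_series = TrimesterSeries(trimester_index=index, values=canopy01,
                                    n_obs=np.ones(n, dtype=int))
    return climate_series, canopy_series


def gen_survey_tables(spec: SurveySpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Overdispersed community count tables for a 2x2 factorial design.

    Counts for taxon j on a transect in cell (location, exposure) are negative
    binomial with mean ``baseline_j * effect(location)_j * effect(exposure)_j``
    and size ``dispersion``; densities are counts / transect_area.

    Returns
    -------
    abundance : DataFrame (samples x taxa) of densities (individuals m^-2)
    factors : DataFrame with columns ``location`` and ``exposure``
    """
    rng = np.random.default_rng(spec.seed)
    sizes = spec.cell_sizes()
    taxa = list(spec.taxa_pool)
    base = np.array([spec.taxa_pool[t] for t in taxa])
    rows, loc_col, exp_col, ids = [], [], [], []
    i = 0
    for (loc, exp), n_cell in sizes.items():
        mult = np.ones(len(taxa))
        for level in (loc, exp):
            shifts = spec.effect_sizes.get(level, {})
            mult *= np.array([shifts.get(t, 1.0) for t in taxa])
        mean = base * mult
        for _ in range(n_cell):
            # NB via gamma-Poisson mixture; mean 0 stays exactly 0
            lam = np.where(mean > 0,
                           rng.gamma(spec.dispersion, 1.0, size=len(taxa))
                           * mean / spec.dispersion, 0.0)
            counts = rng.poisson(lam)
            rows.append(counts / spec.transect_area)
            loc_col.append(loc)
            exp_col.append(exp)
            ids.append(f"st{i:02d}")
            i += 1
    abundance = pd.DataFrame(rows, index=ids, columns=taxa)
    factors = pd.DataFrame({"location": loc_col, "exposure": exp_col}, index=ids)
    return abundance, factors
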