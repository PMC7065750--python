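"""Site and regional kelp-canopy time series and their statistical analyses.

From per-date fraction maps this module builds summed-canopy site series
(pixels within a radius of the site coordinate), bins them onto 4-month
trimesters, standardizes by the site maximum ("proportional kelp canopy
density"), applies 2-year running means, and runs the inferential pieces:
lagged Pearson correlation against climate indices, AR(1) generalized least
squares trend tests, reduced major axis validation regression, and a penalized
spline temperature-nitrate fit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import interpolate, stats

from .unmix import FractionMap, Grid, site_cloud_filter

__all__ = [
    "SiteSeries",
    "TrimesterSeries",
    "TrendResult",
    "LagCorrelation",
    "extract_site_series",
    "to_trimesters",
    "proportional_standardize",
    "regional_series",
    "running_mean",
    "lagged_pearson",
    "gls_ar1_trend",
    "rma_fit",
    "validate_fraction_vs_insitu",
    "smooth_fit",
]

_TRIMESTERS_PER_YEAR = 3  # Jan-Apr, May-Aug, Sep-Dec


def trimester_of(dates) -> np.ndarray:
    """Map dates to an absolute trimester index (year*3 + trimester-in-year)."""
    d = pd.DatetimeIndex(np.asarray(dates, dtype="datetime64[D]"))
    return (d.year * _TRIMESTERS_PER_YEAR + (d.month - 1) // 4).to_numpy()


def trimester_start(index: np.ndarray) -> np.ndarray:
    """Inverse of :func:`trimester_of`: the first day of each trimester."""
    index = np.asarray(index)
    year = index // _TRIMESTERS_PER_YEAR
    month = (index % _TRIMESTERS_PER_YEAR) * 4 + 1
    return np.array([np.datetime64(f"{y}-{m:02d}-01") for y, m in zip(year, month)])


@dataclass
class SiteSeries:
    """Per-date summed canopy density (fraction-sum units) at one site."""

    site_id: str
    dates: np.ndarray
    summed_density: np.ndarray
    n_valid: np.ndarray
    radius_m: float

    def __post_init__(self):
        self.dates = np.asarray(self.dates, dtype="datetime64[D]")
        self.summed_density = np.asarray(self.summed_density, dtype=float)
        self.n_valid = np.asarray(self.n_valid, dtype=int)
        if np.any(self.summed_density < 0):
            raise ValueError("summed density must be >= 0")
        if np.any(np.diff(self.dates.astype(int)) < 0):
            raise ValueError("dates must be increasing")


@dataclass
class TrimesterSeries:
    """A regularly spaced series on 4-month steps.

    ``n_obs`` counts the valid observations averaged into each step; steps
    filled by interpolation carry ``n_obs = 0``; steps outside the observed
    span are NaN.
    """

    trimester_index: np.ndarray
    values: np.ndarray
    n_obs: np.ndarray

    def __post_init__(self):
        self.trimester_index = np.asarray(self.trimester_index, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        self.n_obs = np.asarray(self.n_obs, dtype=int)
        if np.any(np.diff(self.trimester_index) != 1):
            raise ValueError("trimester index must be regular with step 1")
        if not (len(self.values) == len(self.trimester_index) == len(self.n_obs)):
            raise ValueError("inconsistent lengths")

    def __len__(self) -> int:
        return len(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trimester_start_date": trimester_start(self.trimester_index),
            "value": self.values,
            "n_obs": self.n_obs,
        })


@dataclass
class TrendResult:
    slope: float
    stderr: float
    rho: float
    p_value: float
    slope_per_year: float


@dataclass
class LagCorrelation:
    lag_trimesters: int
    r: float
    p_value: float
    n: int


def extract_site_series(maps: Sequence[FractionMap], site_coord,
                        radius_m: float = 100.0, grid: Grid | None = None,
                        site_id: str = "site",
                        cloud_threshold: float = 0.25) -> SiteSeries:
    """Sum canopy fractions over all pixels whose centers lie within
    ``radius_m`` of the site coordinate (default 100 m; 400 m and 1000 m
    overrides are passed the same way). Dates failing the site cloud filter
    (> 25% of site pixels obscured) are excluded."""
    if not maps:
        raise ValueError("no fraction maps supplied")
    g = grid or maps[0].grid
    if g is None:
        raise ValueError("a Grid is required (on the maps or passed explicitly)")
    if radius_m < g.pixel_size / np.sqrt(2.0):
        raise ValueError("radius too small to guarantee a pixel center")
    x, y = g.pixel_centers()
    dist2 = (x - site_coord[0]) ** 2 + (y - site_coord[1]) ** 2
    inside = dist2 <= radius_m**2
    if not inside.any():
        raise ValueError(f"no pixels within {radius_m} m of site {site_id!r}")
    pix = list(zip(*np.nonzero(inside)))
    kept = set(np.datetime64(d) for d in site_cloud_filter(maps, pix, cloud_threshold))

    dates, sums, nval = [], [], []
    for fmap in maps:
        if np.datetime64(fmap.date) not in kept:
            continue
        vals = fmap.fractions[inside]
        ok = np.isfinite(vals)
        dates.append(fmap.date)
        sums.append(float(np.nansum(vals)))
        nval.append(int(ok.sum()))
    order = np.argsort(np.array(dates, dtype="datetime64[D]"))
    return SiteSeries(site_id=site_id,
                      dates=np.array(dates, dtype="datetime64[D]")[order],
                      summed_density=np.array(sums)[order],
                      n_valid=np.array(nval)[order],
                      radius_m=radius_m)


def to_trimesters(series: SiteSeries) -> TrimesterSeries:
    """Average observations within calendar trimesters (Jan-Apr, May-Aug,
    Sep-Dec); interior empty trimesters are linearly interpolated between the
    neighbouring non-empty trimesters (``n_obs = 0``); leading/trailing gaps
    are left missing."""
    if len(series.dates) < 2:
        raise ValueError("need at least 2 dated observations")
    tri = trimester_of(series.dates)
    first, last = tri.min(), tri.max()
    index = np.arange(first, last + 1)
    values = np.full(index.size, np.nan)
    n_obs = np.zeros(index.size, dtype=int)
    for t in np.unique(tri):
        sel = tri == t
        values[t - first] = series.summed_density[sel].mean()
        n_obs[t - first] = sel.sum()
    missing = n_obs == 0
    if missing.any():
        filled = np.interp(index[missing], index[~missing], values[~missing])
        values[missing] = filled
    return TrimesterSeries(trimester_index=index, values=values, n_obs=n_obs)


def proportional_standardize(ts: TrimesterSeries) -> TrimesterSeries:
    """Divide by the series maximum over the whole record ("proportional kelp
    canopy density", in [0,1]). An all-zero series is returned unchanged."""
    vals = ts.values
    finite = vals[np.isfinite(vals)]
    mx = finite.max() if finite.size else 0.0
    out = vals if mx == 0 else vals / mx
    return TrimesterSeries(ts.trimester_index.copy(), out.copy(), ts.n_obs.copy())


def regional_series(maps: Sequence[FractionMap],
                    standardize: bool = True) -> TrimesterSeries:
    """Regional canopy series: per image, sum fractions over all valid pixels;
    per trimester, average the image-level sums (buffers tide/current-driven
    variation between same-trimester images); then proportional
    standardization."""
    if not maps:
        raise ValueError("no fraction maps supplied")
    dates = np.array([m.date for m in maps], dtype="datetime64[D]")
    sums = np.array([float(np.nansum(m.fractions)) for m in maps])
    tri = trimester_of(dates)
    first, last = tri.min(), tri.max()
    index = np.arange(first, last + 1)
    values = np.full(index.size, np.nan)
    n_obs = np.zeros(index.size, dtype=int)
    for t in np.unique(tri):
        sel = tri == t
        values[t - first] = sums[sel].mean()
        n_obs[t - first] = sel.sum()
    missing = n_obs == 0
    if missing.any():
        values[missing] = np.interp(index[missing], index[~missing], values[~missing])
    ts = TrimesterSeries(index, values, n_obs)
    return proportional_standardize(ts) if standardize else ts


def running_mean(ts: TrimesterSeries, window_trimesters: int = 6) -> TrimesterSeries:
    """Centered moving average (default 6 trimesters = 2 years).

    The nominal window spans offsets ``-(w-1)//2 .. w//2`` around each step and
    shrinks at the series edges; missing (NaN) steps are excluded from each
    window's mean.
    """
    w = int(window_trimesters)
    if w < 1:
        raise ValueError("window must be >= 1")
    vals = ts.values
    n = vals.size
    lo_off, hi_off = -((w - 1) // 2), w // 2
    out = np.full(n, np.nan)
    for i in range(n):
        lo, hi = max(0, i + lo_off), min(n, i + hi_off + 1)
        window = vals[lo:hi]
        window = window[np.isfinite(window)]
        if window.size:
            out[i] = window.mean()
    return TrimesterSeries(ts.trimester_index.copy(), out, ts.n_obs.copy())


def lagged_pearson(x: TrimesterSeries, y: TrimesterSeries,
                   lag_trimesters: int = 3) -> LagCorrelation:
    """Pearson correlation of ``y(t)`` with ``x(t - lag)`` — x leads y
    (climate index leads canopy); two-sided p from the t distribution on the
    overlapping sample."""
    lag = int(lag_trimesters)
    xs = pd.Series(x.values, index=x.trimester_index + lag)
    ys = pd.Series(y.values, index=y.trimester_index)
    joined = pd.concat([xs, ys], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValueError("fewer than 3 overlapping steps after lagging")
    r, p = stats.pearsonr(joined.iloc[:, 0], joined.iloc[:, 1])
    return LagCorrelation(lag_trimesters=lag, r=float(r), p_value=float(p),
                          n=len(joined))


def gls_ar1_trend(ts: TrimesterSeries, rho_grid: np.ndarray | None = None) -> TrendResult:
    """Linear trend test under AR(1) errors (generalized least squares).

    Fits ``value = a + b*t`` with first-order autoregressive errors. The AR
    coefficient rho is estimated by profile likelihood on a grid (default
    -0.95..0.95, step 0.01) using the Prais-Winsten whitening transform; the
    slope standard error and two-sided p-value are computed under the AR(1)
    covariance at the profiled rho.
    """
    mask = np.isfinite(ts.values)
    if mask.sum() < 10:
        raise ValueError("need >= 10 non-missing steps")
    # operate on the contiguous observed span (interior gaps are interpolated
    # upstream by to_trimesters)
    idx = np.nonzero(mask)[0]
    lo, hi = idx.min(), idx.max() + 1
    y = ts.values[lo:hi]
    if not np.all(np.isfinite(y)):
        raise ValueError("interior missing steps: interpolate before trend testing")
    t = np.arange(y.size, dtype=float)
    n = y.size
    X = np.column_stack([np.ones(n), t])

    if rho_grid is None:
        rho_grid = np.arange(-0.95, 0.9501, 0.01)

    def whiten(rho):
        ys = np.empty(n)
        Xs = np.empty_like(X)
        c = np.sqrt(1.0 - rho * rho)
        ys[0] = c * y[0]
        Xs[0] = c * X[0]
        ys[1:] = y[1:] - rho * y[:-1]
        Xs[1:] = X[1:] - rho * X[:-1]
        return ys, Xs

    best = (-np.inf, 0.0, None)
    for rho in rho_grid:
        ys, Xs = whiten(rho)
        beta, res, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
        ssr = float(res[0]) if res.size else float(((ys - Xs @ beta) ** 2).sum())
        ssr = max(ssr, 1e-300)
        # restricted (REML) profile log-likelihood up to constants; REML
        # avoids the downward bias of the ML rho estimate, which would make
        # the trend test anticonservative
        _, logdet_xtx = np.linalg.slogdet(Xs.T @ Xs)
        ll = (0.5 * np.log(1.0 - rho * rho)
              - 0.5 * (n - 2) * np.log(ssr / (n - 2))
              - 0.5 * logdet_xtx)
        if ll > best[0]:
            best = (ll, rho, (beta, ssr))
    _, rho_hat, (beta, ssr) = best
    # first-order small-sample bias correction of the AR coefficient
    # (Marriott-Pope/Kendall, -(1+3*rho)/n bias of the plug-in estimate);
    # without it the trend test is slightly anticonservative
    rho_hat = float(min(rho_grid.max(), rho_hat + (1.0 + 3.0 * rho_hat) / n))
    ys, Xs = whiten(rho_hat)
    beta, res, *_ = np.linalg.lstsq(Xs, ys, rcond=None)
    ssr = float(res[0]) if res.size else float(((ys - Xs @ beta) ** 2).sum())
    dof = n - 2
    sigma2 = ssr / dof
    cov = sigma2 * np.linalg.inv(Xs.T @ Xs)
    slope = float(beta[1])
    se = float(np.sqrt(cov[1, 1]))
    if se == 0.0:
        p = 0.0 if slope != 0 else 1.0
    else:
        p = 2.0 * stats.t.sf(abs(slope) / se, dof)
    return TrendResult(slope=slope, stderr=se, rho=float(rho_hat),
                       p_value=float(p),
                       slope_per_year=slope * _TRIMESTERS_PER_YEAR)


def rma_fit(x, y) -> tuple[float, float, float]:
    """Reduced major axis regression: slope = sign(r) * sd(y)/sd(x),
    intercept through the means; returns (slope, intercept, r_squared)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need >= 3 paired observations")
    sx, sy = x.std(ddof=1), y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance in x or y")
    r = float(np.corrcoef(x, y)[0, 1])
    slope = float(np.sign(r) if r != 0 else 1.0) * sy / sx
    intercept = float(y.mean() - slope * x.mean())
    return float(slope), intercept, r * r


def validate_fraction_vs_insitu(maps: Sequence[FractionMap], site_coords,
                                insitu_densities, grid: Grid | None = None,
                                exclude: Sequence[int] = (),
                                kelp_search_radius_m: float = 500.0):
    """Validation regression of satellite canopy fraction against in-situ
    adult kelp density.

    For each site the mean fraction of the 4 pixels surrounding the survey
    coordinate (the pixels incident to the nearest pixel corner) is averaged
    over dates and regressed (reduced major axis) on the in-situ density.
    Sites may be excluded a priori (index list, e.g. low geographic
    precision); sites with no kelp pixels (fraction > 0 on any date) within
    ``kelp_search_radius_m`` are dropped automatically.

    Returns ``(slope, intercept, r_squared, used_site_indices)``.
    """
    if not maps:
        raise ValueError("no fraction maps supplied")
    g = grid or maps[0].grid
    if g is None:
        raise ValueError("a Grid is required")
    frac = np.stack([m.fractions for m in maps])
    x, y = g.pixel_centers()
    exclude = set(exclude)
    sat, insitu, used = [], [], []
    for i, ((sx, sy), dens) in enumerate(zip(site_coords, insitu_densities)):
        if i in exclude:
            continue
        dist2 = (x - sx) ** 2 + (y - sy) ** 2
        near = dist2 <= kelp_search_radius_m**2
        if not np.any(np.nan_to_num(frac[:, near]) > 0):
            continue  # no kelp pixels within the search radius
        # 4 pixels incident to the nearest pixel corner
        col_f = (sx - g.x0) / g.pixel_size
        row_f = (g.y0 - sy) / g.pixel_size
        cols = np.clip([int(np.floor(col_f - 0.5)), int(np.floor(col_f + 0.5))], 0, g.n_cols - 1)
        rows = np.clip([int(np.floor(row_f - 0.5)), int(np.floor(row_f + 0.5))], 0, g.n_rows - 1)
        block = frac[:, rows[0]:rows[1] + 1, cols[0]:cols[1] + 1]
        sat.append(float(np.nanmean(block)))
        insitu.append(float(dens))
        used.append(i)
    if len(used) < 3:
        raise ValueError("fewer than 3 usable sites for the validation regression")
    slope, intercept, r2 = rma_fit(np.array(insitu), np.array(sat))
    return slope, intercept, r2, used


@dataclass
class SmoothFit:
    """A fitted penalized cubic spline smoother."""

    predict: Callable[[np.ndarray], np.ndarray]
    fitted: np.ndarray
    r_squared: float
    edf: float
    lam: float

    def fraction_of_max_above(self, x_threshold: float, x_eval: np.ndarray) -> np.ndarray:
        """Fitted values at ``x_eval > x_threshold`` as a fraction of the
        fitted maximum (depletion-threshold diagnostic)."""
        x_eval = np.asarray(x_eval, dtype=float)
        fmax = float(self.fitted.max())
        sel = x_eval > x_threshold
        return self.predict(x_eval[sel]) / fmax


def smooth_fit(x, y, edf: float = 4.0) -> SmoothFit:
    """Penalized cubic smoothing spline with a fixed effective df (default 4).

    The smoothing parameter is solved by bisection so that the trace of the
    smoother matrix equals ``edf``; used for the temperature (degrees C) vs
    seawater nitrate (uM) relationship, where nitrate is depleted at warm
    temperatures.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 8:
        raise ValueError("need n >= 8 for the smoother")
    if np.ptp(x) == 0:
        raise ValueError("degenerate x: all values equal")
    order = np.argsort(x)
    xs, ys = x[order], y[order]
    # collapse ties in x (make_smoothing_spline requires strictly increasing x)
    xu, inv = np.unique(xs, return_inverse=True)
    yu = np.bincount(inv, weights=ys) / np.bincount(inv)
    n = xu.size
    edf = min(float(edf), n - 1e-6)

    def trace_S(lam):
        tr = 0.0
        e = np.zeros(n)
        for i in range(n):
            e[i] = 1.0
            spl = interpolate.make_smoothing_spline(xu, e, lam=lam)
            tr += float(spl(xu[i]))
            e[i] = 0.0
        return tr

    # bisection on log10(lambda): trace decreases from n (lam->0) to 2 (lam->inf)
    lo, hi = -12.0, 12.0
    while trace_S(10.0**lo) < edf and lo > -30:
        lo -= 4
    while trace_S(10.0**hi) > edf and hi < 30:
        hi += 4
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if trace_S(10.0**mid) > edf:
            lo = mid
        else:
            hi = mid
    lam = 10.0 ** (0.5 * (lo + hi))
    spl = interpolate.make_smoothing_spline(xu, yu, lam=lam)
    fitted = spl(xs)
    ss_res = float(((ys - fitted) ** 2).sum())
    ss_tot = float(((ys - ys.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return SmoothFit(predict=lambda q: spl(np.asarray(q, dtype=float)),
                     fitted=fitted, r_squared=r2, edf=edf, lam=lam)
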