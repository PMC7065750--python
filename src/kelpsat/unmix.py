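"""Two-endmember spectral mixture analysis for kelp canopy fraction.

Each pixel's reflectance is modelled as a linear, sum-to-one combination of a
single static kelp-canopy endmember and one of K per-image seawater endmembers
(multiple endmember spectral mixture analysis restricted to kelp/water pairs).
For every pixel the water endmember yielding the lowest model RMSE is kept and
the kelp fraction of that best model is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Spectrum",
    "EndmemberLibrary",
    "FractionMap",
    "Grid",
    "unmix_pixel",
    "unmix_scene",
    "site_cloud_filter",
]


@dataclass(frozen=True)
class Spectrum:
    """A reflectance spectrum, one value per band (dimensionless)."""

    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 1 or v.size < 2:
            raise ValueError("a spectrum needs at least 2 bands")
        if not np.all(np.isfinite(v)):
            raise ValueError("spectrum contains non-finite values")
        object.__setattr__(self, "values", v)

    @property
    def n_bands(self) -> int:
        return self.values.size


@dataclass(frozen=True)
class EndmemberLibrary:
    """One kelp endmember plus K seawater endmembers (default K = 30)."""

    kelp: Spectrum
    water: tuple[Spectrum, ...]

    def __post_init__(self):
        water = tuple(self.water)
        if len(water) < 1:
            raise ValueError("library needs at least one seawater endmember")
        nb = self.kelp.n_bands
        for w in water:
            if w.n_bands != nb:
                raise ValueError("all endmembers must share the band count")
            if np.array_equal(w.values, self.kelp.values):
                raise ValueError("kelp endmember duplicates a water endmember")
        object.__setattr__(self, "water", water)

    @property
    def n_water(self) -> int:
        return len(self.water)

    @property
    def n_bands(self) -> int:
        return self.kelp.n_bands

    def water_array(self) -> np.ndarray:
        """(K, n_bands) array of the seawater endmembers."""
        return np.stack([w.values for w in self.water])


@dataclass(frozen=True)
class Grid:
    """North-up raster grid: origin at the top-left corner, row-major pixels.

    Pixel (row, col) has its center at
    ``x = x0 + (col + 0.5) * pixel_size``, ``y = y0 - (row + 0.5) * pixel_size``.
    """

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    x0: float = 0.0
    y0: float = 0.0

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        cols = self.x0 + (np.arange(self.n_cols) + 0.5) * self.pixel_size
        rows = self.y0 - (np.arange(self.n_rows) + 0.5) * self.pixel_size
        return np.meshgrid(cols, rows)  # (x, y), each (n_rows, n_cols)


@dataclass
class FractionMap:
    """Per-pixel kelp canopy fraction for one acquisition date.

    ``fractions``/``rmse`` are NaN wherever ``valid_mask`` is False (clouded or
    otherwise unusable pixels carry no fraction).
    """

    fractions: np.ndarray
    rmse: np.ndarray
    valid_mask: np.ndarray
    date: np.datetime64
    grid: Grid | None = None
    endmember_index: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self):
        f = np.asarray(self.fractions, dtype=float)
        r = np.asarray(self.rmse, dtype=float)
        m = np.asarray(self.valid_mask, dtype=bool)
        if not (f.shape == r.shape == m.shape):
            raise ValueError("fractions, rmse and valid_mask must be conformal")
        f = np.where(m, f, np.nan)
        r = np.where(m, r, np.nan)
        if np.any((f[m] < 0) | (f[m] > 1)):
            raise ValueError("valid fractions must lie in [0, 1]")
        if np.any(r[m] < 0):
            raise ValueError("rmse must be non-negative")
        self.fractions, self.rmse, self.valid_mask = f, r, m
        self.date = np.datetime64(self.date)

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())


def unmix_pixel(reflectance, kelp, water) -> tuple[float, float]:
    """Closed-form two-endmember unmixing of a single pixel.

    Solves ``min_f || r - (f*k + (1-f)*w) ||`` analytically:
    ``f = <r-w, k-w> / <k-w, k-w>``, clipped to [0, 1]; the RMSE is evaluated
    at the clipped fraction over all bands.
    """
    r = reflectance.values if isinstance(reflectance, Spectrum) else np.asarray(reflectance, float)
    k = kelp.values if isinstance(kelp, Spectrum) else np.asarray(kelp, float)
    w = water.values if isinstance(water, Spectrum) else np.asarray(water, float)
    if not (r.shape == k.shape == w.shape):
        raise ValueError("spectra must share the same band count")
    d = k - w
    denom = float(d @ d)
    if denom == 0.0:
        raise ValueError("degenerate endmembers: kelp equals water")
    f = float((r - w) @ d) / denom
    f = min(1.0, max(0.0, f))
    resid = r - (w + f * d)
    rmse = float(np.sqrt(np.mean(resid * resid)))
    return f, rmse


def unmix_scene(scene: np.ndarray, library: EndmemberLibrary,
                cloud_mask: np.ndarray | None = None,
                date=np.datetime64("NaT"), grid: Grid | None = None) -> FractionMap:
    """Unmix one multiband scene against every seawater endmember.

    Parameters
    ----------
    scene : (n_bands, n_rows, n_cols) reflectance array.
    cloud_mask : boolean (n_rows, n_cols); True marks obscured pixels.

    For each unmasked pixel every kelp/water pair is evaluated and the pair
    with the lowest RMSE is kept; ties go to the lowest water-endmember index.
    """
    scene = np.asarray(scene, dtype=float)
    if scene.ndim != 3:
        raise ValueError("scene must be (n_bands, n_rows, n_cols)")
    n_bands, n_rows, n_cols = scene.shape
    if n_bands != library.n_bands:
        raise ValueError("scene band count does not match the library")
    if cloud_mask is None:
        cloud_mask = np.zeros((n_rows, n_cols), dtype=bool)
    cloud_mask = np.asarray(cloud_mask, dtype=bool)
    if cloud_mask.shape != (n_rows, n_cols):
        raise ValueError("cloud mask not conformal with the scene")

    R = scene.reshape(n_bands, -1).T  # (npix, n_bands)
    k = library.kelp.values
    best_rmse = np.full(R.shape[0], np.inf)
    best_f = np.zeros(R.shape[0])
    best_idx = np.zeros(R.shape[0], dtype=int)
    for j, w in enumerate(library.water_array()):
        d = k - w
        denom = d @ d
        f = np.clip((R - w) @ d / denom, 0.0, 1.0)
        resid = R - (w + f[:, None] * d)
        rmse = np.sqrt(np.mean(resid * resid, axis=1))
        better = rmse < best_rmse  # strict: ties keep the lowest index
        best_rmse[better] = rmse[better]
        best_f[better] = f[better]
        best_idx[better] = j

    valid = ~cloud_mask
    return FractionMap(
        fractions=best_f.reshape(n_rows, n_cols),
        rmse=best_rmse.reshape(n_rows, n_cols),
        valid_mask=valid,
        date=date,
        grid=grid,
        endmember_index=np.where(valid, best_idx.reshape(n_rows, n_cols), -1),
    )


def site_cloud_filter(maps: Sequence[FractionMap], site_pixels,
                      threshold: float = 0.25) -> list[np.datetime64]:
    """Dates where more than `threshold` of a site's pixels are obscured are
    removed; a date at exactly the threshold is retained (strictly-greater
    removal rule, default 25%)."""
    site_pixels = list(site_pixels)
    if len(site_pixels) == 0:
        raise ValueError("site_pixels must be non-empty")
    rows = np.array([p[0] for p in site_pixels])
    cols = np.array([p[1] for p in site_pixels])
    kept = []
    for fmap in maps:
        obscured = ~fmap.valid_mask[rows, cols]
        if obscured.mean() <= threshold:
            kept.append(fmap.date)
    return kept
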