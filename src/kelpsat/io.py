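"""File formats: multiband scene rasters, fraction maps, survey and climate
tables, pipeline configuration.

Rasters are written as plain multiband TIFF (float32) with a JSON sidecar
(`<name>.json`) carrying the grid origin, pixel size, acquisition date and
nodata value; masked/invalid pixels hold the nodata value in the raster.
Tables are CSV with documented headers; configuration is YAML.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .canopyseries import TrimesterSeries, trimester_start
from .unmix import FractionMap, Grid

NODATA = -9999.0

__all__ = [
    "write_scene", "read_scene", "read_scene_stack",
    "write_fraction_map", "read_fraction_map",
    "write_trimester_series", "read_trimester_series",
    "write_survey_tables", "read_survey_tables",
    "read_climate_csv", "write_climate_csv",
    "load_config", "dump_config", "NODATA",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_scene(path, scene: np.ndarray, grid: Grid, date,
                cloud_mask: np.ndarray | None = None) -> None:
    """Write one (n_bands, n_rows, n_cols) reflectance scene; clouded pixels
    are stored as nodata in every band."""
    path = Path(path)
    scene = np.asarray(scene, dtype=np.float32).copy()
    if cloud_mask is not None:
        scene[:, np.asarray(cloud_mask, bool)] = NODATA
    tifffile.imwrite(path, scene, photometric="minisblack")
    meta = {"x0": grid.x0, "y0": grid.y0, "pixel_size": grid.pixel_size,
            "n_rows": grid.n_rows, "n_cols": grid.n_cols,
            "date": str(np.datetime64(date, "D")), "nodata": NODATA,
            "kind": "reflectance"}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_scene(path):
    """Returns (scene float64 array, cloud_mask, Grid, date)."""
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    mask = np.all(arr == meta["nodata"], axis=0)
    grid = Grid(n_rows=meta["n_rows"], n_cols=meta["n_cols"],
                pixel_size=meta["pixel_size"], x0=meta["x0"], y0=meta["y0"])
    if arr.shape[1:] != (grid.n_rows, grid.n_cols):
        raise ValueError(f"{path.name}: raster shape disagrees with its sidecar")
    return arr, mask, grid, np.datetime64(meta["date"])


def read_scene_stack(directory):
    """Read every scene TIFF in a directory, ordered by acquisition date.

    All scenes must share the grid and band count; a mismatch raises.
    Returns (scenes, cloud_masks, grid, dates).
    """
    directory = Path(directory)
    paths = sorted(p for p in directory.glob("*.tif") if _sidecar(p).exists())
    if not paths:
        raise FileNotFoundError(f"no scene TIFFs under {directory}")
    scenes, masks, grids, dates = [], [], [], []
    for p in paths:
        arr, mask, grid, date = read_scene(p)
        scenes.append(arr)
        masks.append(mask)
        grids.append(grid)
        dates.append(date)
    if any(g != grids[0] for g in grids):
        raise ValueError("scenes do not share a common pixel grid")
    if any(s.shape != scenes[0].shape for s in scenes):
        raise ValueError("scenes do not share a common band count")
    order = np.argsort(np.array(dates, dtype="datetime64[D]"))
    return (np.stack([scenes[i] for i in order]),
            np.stack([masks[i] for i in order]),
            grids[0],
            np.array(dates, dtype="datetime64[D]")[order])


def write_fraction_map(path, fmap: FractionMap) -> None:
    """Two-band float raster: band 1 kelp fraction, band 2 model RMSE;
    invalid pixels are nodata."""
    path = Path(path)
    frac = np.where(fmap.valid_mask, fmap.fractions, NODATA).astype(np.float32)
    rmse = np.where(fmap.valid_mask, fmap.rmse, NODATA).astype(np.float32)
    tifffile.imwrite(path, np.stack([frac, rmse]), photometric="minisblack")
    g = fmap.grid or Grid(n_rows=frac.shape[0], n_cols=frac.shape[1])
    meta = {"x0": g.x0, "y0": g.y0, "pixel_size": g.pixel_size,
            "n_rows": g.n_rows, "n_cols": g.n_cols,
            "date": str(np.datetime64(fmap.date, "D")), "nodata": NODATA,
            "kind": "fraction"}
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_fraction_map(path) -> FractionMap:
    path = Path(path)
    arr = tifffile.imread(path).astype(float)
    meta = json.loads(_sidecar(path).read_text())
    valid = arr[0] != meta["nodata"]
    grid = Grid(n_rows=meta["n_rows"], n_cols=meta["n_cols"],
                pixel_size=meta["pixel_size"], x0=meta["x0"], y0=meta["y0"])
    return FractionMap(fractions=np.where(valid, arr[0], np.nan),
                       rmse=np.where(valid, arr[1], np.nan),
                       valid_mask=valid, date=np.datetime64(meta["date"]),
                       grid=grid)


def write_trimester_series(path, ts: TrimesterSeries) -> None:
    """CSV with columns trimester_start_date, value, n_obs."""
    ts.to_frame().to_csv(path, index=False)


def read_trimester_series(path) -> TrimesterSeries:
    df = pd.read_csv(path, parse_dates=["trimester_start_date"])
    from .canopyseries import trimester_of
    return TrimesterSeries(trimester_index=trimester_of(df["trimester_start_date"]),
                           values=df["value"].to_numpy(),
                           n_obs=df["n_obs"].to_numpy())


def read_climate_csv(path) -> TrimesterSeries:
    """Climate index CSV (columns: date, value), averaged onto trimesters with
    interior gaps interpolated (same convention as the canopy series)."""
    from .canopyseries import SiteSeries, to_trimesters
    df = pd.read_csv(path, parse_dates=["date"]).sort_values("date")
    values = df["value"].to_numpy(dtype=float)
    series = SiteSeries(site_id="climate", dates=df["date"].to_numpy(),
                        summed_density=values - values.min(),  # shift: SiteSeries is non-negative
                        n_valid=np.ones(len(df), dtype=int), radius_m=0.0)
    ts = to_trimesters(series)
    ts.values = ts.values + values.min()
    return ts


def write_climate_csv(path, dates, values) -> None:
    pd.DataFrame({"date": np.asarray(dates, dtype="datetime64[D]"),
                  "value": values}).to_csv(path, index=False)


def write_survey_tables(dir_path, abundance: pd.DataFrame, factors: pd.DataFrame,
                        transect_area: float = 50.0) -> tuple[Path, Path]:
    """Write long-format counts (site, transect, taxon, count, area_m2) and the
    factor table (site, location, exposure)."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    rows = []
    for site, row in abundance.iterrows():
        for taxon, dens in row.items():
            rows.append((site, 1, taxon, dens * transect_area, transect_area))
    counts = pd.DataFrame(rows, columns=["site", "transect", "taxon", "count", "area_m2"])
    p_counts = dir_path / "survey_counts.csv"
    p_factors = dir_path / "survey_factors.csv"
    counts.to_csv(p_counts, index=False)
    factors.rename_axis("site").reset_index().to_csv(p_factors, index=False)
    return p_counts, p_factors


def read_survey_tables(path_counts, path_factors,
                       locations=("IE", "MP"),
                       exposures=("exposed", "sheltered")):
    """Pivot a long-format survey CSV to a wide (samples x taxa) density
    matrix and align the factor table.

    Densities are count / area_m2; absent (site, taxon) combinations become
    structural zeros. Duplicate (site, transect, taxon) rows and unknown
    factor levels raise.
    """
    counts = pd.read_csv(path_counts)
    required = {"site", "transect", "taxon", "count", "area_m2"}
    if not required.issubset(counts.columns):
        raise ValueError(f"survey CSV must have columns {sorted(required)}")
    key = counts[["site", "transect", "taxon"]]
    if key.duplicated().any():
        dup = key[key.duplicated()].iloc[0]
        raise ValueError(f"duplicate survey row for {tuple(dup)}")
    counts = counts.assign(sample=counts["site"].astype(str) + "/t"
                           + counts["transect"].astype(str),
                           density=counts["count"] / counts["area_m2"])
    wide = counts.pivot_table(index="sample", columns="taxon", values="density",
                              fill_value=0.0, aggfunc="sum")
    factors = pd.read_csv(path_factors).set_index("site")
    bad_loc = set(factors["location"]) - set(locations)
    bad_exp = set(factors["exposure"]) - set(exposures)
    if bad_loc or bad_exp:
        raise ValueError(f"unknown factor levels: {bad_loc | bad_exp}")
    site_of = counts.drop_duplicates("sample").set_index("sample")["site"]
    aligned = factors.loc[site_of.loc[wide.index]].set_index(wide.index)
    return wide, aligned[["location", "exposure"]]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config must be a YAML mapping")
    return cfg


def dump_config(path, cfg: dict) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=False)
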