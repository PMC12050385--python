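"""Gridded projection of the potential hibernation area.

Runs the seasonal energy budget over every cell of a latitude-longitude
grid of daily temperatures and classifies each cell per winter:

* ``no_season`` — temperature never stays below the foraging threshold long
  enough for a hibernation season to exist (too warm; the budget is missing);
* ``suitable`` — a season exists and its total fat consumption does not
  exceed the fat budget;
* ``unsuitable`` — a season exists but survival would require more fat than
  the budget.

The suitable cells form the potential hibernation area, summarised per
winter by its surface area (cosine-weighted cell areas) and the
area-weighted median / min / max latitude, optionally as km displacements
against a baseline winter. Multi-decade series are smoothed with a centred
moving average and climate-model ensembles are combined pointwise
(mean + min/max envelope).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .budget import (
    EnergyParams,
    SeasonParams,
    TemperatureSeries,
    detect_hibernation_season,
    season_budget,
)

__all__ = [
    "KM_PER_DEGREE",
    "GridSpec",
    "SuitabilityMap",
    "AreaSummary",
    "build_grid",
    "read_daily_tas",
    "map_suitability",
    "area_summary",
    "smooth_series",
    "ensemble_average",
]

KM_PER_DEGREE = 111.2  # km per degree of latitude


@dataclass
class GridSpec:
    """Regular lat-lon grid; cell centres sit at half-resolution offsets."""

    lat_min: float
    lat_max: float
    lon_min: float
    lon_max: float
    resolution: float = 0.5

    def __post_init__(self):
        for lo, hi, name in (
            (self.lat_min, self.lat_max, "lat"),
            (self.lon_min, self.lon_max, "lon"),
        ):
            span = hi - lo
            n = span / self.resolution
            if span <= 0 or abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"{name} extent {span} is not a positive multiple of "
                    f"resolution {self.resolution}"
                )

    @property
    def n_lat(self) -> int:
        return round((self.lat_max - self.lat_min) / self.resolution)

    @property
    def n_lon(self) -> int:
        return round((self.lon_max - self.lon_min) / self.resolution)

    @property
    def n_cells(self) -> int:
        return self.n_lat * self.n_lon

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        half = self.resolution / 2
        lats = self.lat_min + half + self.resolution * np.arange(self.n_lat)
        lons = self.lon_min + half + self.resolution * np.arange(self.n_lon)
        return lats, lons

    def cell_area_km2(self, lat) -> np.ndarray:
        """Surface area of a cell centred at ``lat`` (cosine weighting)."""
        side = self.resolution * KM_PER_DEGREE
        return side * side * np.cos(np.deg2rad(np.asarray(lat, dtype=float)))


def build_grid(spec: GridSpec) -> pd.DataFrame:
    """Tabulate all cell centres (lat, lon, cell area in km²)."""
    lats, lons = spec.cell_centers()
    lat_grid, lon_grid = np.meshgrid(lats, lons, indexing="ij")
    return pd.DataFrame(
        {
            "lat": lat_grid.ravel(),
            "lon": lon_grid.ravel(),
            "area_km2": spec.cell_area_km2(lat_grid.ravel()),
        }
    )


def read_daily_tas(path, spec: GridSpec, winter_year: int) -> xr.DataArray:
    """Read one winter window (July 1 – June 30) of gridded daily temperature.

    The variable's ``units`` attribute is mandatory; Kelvin input is
    converted to Celsius. Cells are cropped to ``spec`` and the file must
    cover the full winter window.
    """
    ds = xr.open_dataset(path, engine="scipy")
    name = "tas" if "tas" in ds else list(ds.data_vars)[0]
    da = ds[name]
    units = da.attrs.get("units")
    if units is None:
        raise ValueError(f"variable {name!r} has no units attribute")
    if units in ("K", "Kelvin", "kelvin"):
        da = da - 273.15
        da.attrs["units"] = "degC"
    elif units in ("degC", "C", "celsius", "Celsius", "degrees_Celsius"):
        da.attrs["units"] = "degC"
    else:
        raise ValueError(f"unrecognised temperature units {units!r}")

    start = pd.Timestamp(f"{winter_year}-07-01")
    end = pd.Timestamp(f"{winter_year + 1}-06-30")
    time = pd.DatetimeIndex(da["time"].values)
    if time.min() > start or time.max() < end:
        raise ValueError(
            f"file covers {time.min().date()}..{time.max().date()}, "
            f"which does not span winter {winter_year} "
            f"({start.date()}..{end.date()})"
        )
    da = da.sel(time=slice(start, end))
    da = da.sel(
        lat=slice(spec.lat_min, spec.lat_max), lon=slice(spec.lon_min, spec.lon_max)
    )
    da.attrs["winter_year"] = winter_year
    return da


@dataclass
class SuitabilityMap:
    """Per-cell classification for one winter.

    ``fat_consumed`` is NaN exactly where ``classes`` is ``no_season``.
    """

    winter_year: int
    lats: np.ndarray
    lons: np.ndarray
    fat_consumed: np.ndarray  # (n_lat, n_lon), g; NaN where no season
    classes: np.ndarray       # (n_lat, n_lon) of {no_season, suitable, unsuitable}

    def to_dataset(self) -> xr.Dataset:
        codes = {"no_season": 0, "suitable": 1, "unsuitable": 2}
        return xr.Dataset(
            {
                "fat_consumed": (("lat", "lon"), self.fat_consumed),
                "class_code": (
                    ("lat", "lon"),
                    np.vectorize(codes.get)(self.classes),
                ),
            },
            coords={"lat": self.lats, "lon": self.lons},
            attrs={"winter_year": self.winter_year, "class_codes": str(codes)},
        )


@dataclass
class AreaSummary:
    winter_year: int
    area_km2: float
    median_lat: float  # NaN when no suitable cell
    min_lat: float
    max_lat: float
    median_shift_km: float = np.nan
    min_shift_km: float = np.nan
    max_shift_km: float = np.nan

    def to_row(self) -> dict:
        return self.__dict__.copy()


def map_suitability(
    tas: xr.DataArray,
    sm,
    tc,
    ep: EnergyParams | None = None,
    sp: SeasonParams | None = None,
    winter_year: int | None = None,
) -> SuitabilityMap:
    """Classify every grid cell of one winter's temperature cube."""
    ep = ep or EnergyParams()
    sp = sp or SeasonParams()
    if winter_year is None:
        winter_year = int(tas.attrs.get("winter_year"))
    lats = np.asarray(tas["lat"].values, dtype=float)
    lons = np.asarray(tas["lon"].values, dtype=float)
    dates = pd.DatetimeIndex(tas["time"].values)
    values = np.asarray(tas.values, dtype=float)

    fat = np.full((len(lats), len(lons)), np.nan)
    classes = np.full((len(lats), len(lons)), "no_season", dtype=object)
    for i in range(len(lats)):
        for j in range(len(lons)):
            series = TemperatureSeries(
                location_id=f"{lats[i]:.2f}N_{lons[j]:.2f}E",
                winter_year=winter_year,
                dates=dates,
                ta=values[:, i, j],
            )
            season = detect_hibernation_season(series, sp)
            if season is None:
                continue
            traj = season_budget(series, season, sm, tc, ep)
            fat[i, j] = traj.total_fat_g
            classes[i, j] = (
                "suitable" if traj.total_fat_g <= ep.fat_budget else "unsuitable"
            )
    return SuitabilityMap(
        winter_year=winter_year, lats=lats, lons=lons,
        fat_consumed=fat, classes=classes,
    )


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values)
    values, weights = values[order], weights[order]
    cum = np.cumsum(weights)
    return float(values[np.searchsorted(cum, 0.5 * cum[-1])])


def area_summary(
    smap: SuitabilityMap,
    baseline: AreaSummary | None = None,
    resolution: float | None = None,
    area_weighted: bool = True,
) -> AreaSummary:
    """Summarise the suitable cells of one winter's map.

    Latitude statistics are area-weighted by default (cosine cell weights);
    km displacements against ``baseline`` use 111.2 km per degree.
    """
    if resolution is None:
        resolution = float(np.diff(smap.lats).mean()) if len(smap.lats) > 1 else 0.5
    mask = smap.classes == "suitable"
    if not mask.any():
        return AreaSummary(
            winter_year=smap.winter_year, area_km2=0.0,
            median_lat=np.nan, min_lat=np.nan, max_lat=np.nan,
        )
    lat_grid = np.broadcast_to(smap.lats[:, None], smap.classes.shape)
    cell_lats = lat_grid[mask].astype(float)
    side = resolution * KM_PER_DEGREE
    areas = side * side * np.cos(np.deg2rad(cell_lats))
    weights = areas if area_weighted else np.ones_like(areas)
    summary = AreaSummary(
        winter_year=smap.winter_year,
        area_km2=float(areas.sum()),
        median_lat=_weighted_median(cell_lats, weights),
        min_lat=float(cell_lats.min()),
        max_lat=float(cell_lats.max()),
    )
    if baseline is not None:
        summary.median_shift_km = (summary.median_lat - baseline.median_lat) * KM_PER_DEGREE
        summary.min_shift_km = (summary.min_lat - baseline.min_lat) * KM_PER_DEGREE
        summary.max_shift_km = (summary.max_lat - baseline.max_lat) * KM_PER_DEGREE
    return summary


def smooth_series(values: pd.Series, window: int = 10) -> pd.Series:
    """Centred moving average; edges use the available years only."""
    if len(values) < 1:
        raise ValueError("need at least one value to smooth")
    return values.sort_index().rolling(window, center=True, min_periods=1).mean()


def ensemble_average(members: list[pd.Series]) -> pd.DataFrame:
    """Pointwise mean and min/max envelope over ensemble members.

    All members must share the same year index.
    """
    if len(members) < 1:
        raise ValueError("need at least one ensemble member")
    index = members[0].index
    for m in members[1:]:
        if not m.index.equals(index):
            raise ValueError("ensemble members cover different year spans")
    stacked = pd.concat(members, axis=1)
    return pd.DataFrame(
        {
            "mean": stacked.mean(axis=1),
            "min": stacked.min(axis=1),
            "max": stacked.max(axis=1),
        },
        index=index,
    )
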