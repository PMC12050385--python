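"""Synthetic-data generators for every input the pipeline consumes.

Three kinds of input are emulated with known ground truth so that each
downstream stage can be validated without any external data:

1. **State series** — binary normothermy/torpor observations of captive
   individuals held at fixed chamber temperatures, drawn Bernoulli from a
   known link-scale model with Gaussian individual random intercepts. The
   default layout mirrors a month-long captive experiment: groups of
   individuals at 2, 7 and 12 °C observed every 30 minutes.
2. **Respirometry** — steady-state metabolic measurements across a -3…35 °C
   temperature grid, two-state with multiplicative lognormal noise around
   known thermoregulatory curves; the latent state is kept as a ground-truth
   column for validation and is never used by the fitters.
3. **Daily temperature** — seasonal sinusoid plus AR(1) noise with a linear
   warming trend, on a 365-day calendar, per winter window (July 1 – June
   30); optionally on a small latitude-longitude grid written as NetCDF.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import xarray as xr

from .budget import TemperatureSeries
from .respirometry import ThermoCurves, predict_mr
from .state import StateModel, predict_p_normothermy

__all__ = [
    "StateSimConfig",
    "RespSimConfig",
    "ClimateSimConfig",
    "simulate_state_series",
    "simulate_respirometry",
    "simulate_daily_temperature",
    "simulate_grid_climate",
    "default_torpor_probability",
]

DAYS_PER_YEAR = 365


@dataclass
class StateSimConfig:
    """Configuration of the captive state-series experiment."""

    beta0: float
    beta1: float
    mirror_temp: float = 2.0
    link: str = "cauchit"
    re_sd: float = 0.5                # individual random-intercept SD (link scale)
    n_individuals: int = 22
    chamber_temps: Sequence[float] = (2.0, 7.0, 12.0)
    n_days: int = 21                  # ~22k retained 30-min records at defaults
    interval_minutes: int = 30
    seed: int = 0

    def __post_init__(self):
        if 1440 % self.interval_minutes != 0:
            raise ValueError("interval_minutes must divide 1440")
        if self.n_individuals < 1:
            raise ValueError("n_individuals must be >= 1")
        if self.re_sd < 0:
            raise ValueError("re_sd must be >= 0")


def simulate_state_series(config: StateSimConfig) -> pd.DataFrame:
    """Simulate binary state records (one row per individual x time step).

    Individuals are split evenly across the chamber temperatures (as in a
    grouped captive design). Each individual carries a Gaussian random
    intercept; the state is Bernoulli with probability given by the mirrored
    link model at the chamber temperature.
    """
    rng = np.random.default_rng(config.seed)
    model = StateModel(
        link=config.link, beta0=config.beta0, beta1=config.beta1,
        mirror_temp=config.mirror_temp,
    )
    steps_per_day = 1440 // config.interval_minutes
    n_steps = steps_per_day * config.n_days
    t0 = pd.Timestamp("2018-11-15")
    times = t0 + pd.to_timedelta(np.arange(n_steps) * config.interval_minutes, unit="m")

    frames = []
    temps = np.asarray(config.chamber_temps, dtype=float)
    for i in range(config.n_individuals):
        ta = temps[i % len(temps)]
        b = rng.normal(0.0, config.re_sd) if config.re_sd > 0 else 0.0
        # random intercept shifts the linear predictor, not the probability
        shifted = StateModel(
            link=config.link, beta0=config.beta0 + b, beta1=config.beta1,
            mirror_temp=config.mirror_temp,
        )
        p = float(predict_p_normothermy(shifted, ta))
        states = (rng.random(n_steps) < p).astype(int)
        frames.append(
            pd.DataFrame(
                {"individual_id": f"bat{i:02d}", "timestamp": times,
                 "chamber_temp": ta, "state": states}
            )
        )
    return pd.concat(frames, ignore_index=True)


def default_torpor_probability(ta: float, t_min: float = 4.5,
                               warm_end: float = 28.0) -> float:
    """Probability that a steady-state measurement is torpid at ``ta``.

    High (0.9) at and below the thermoconforming minimum, declining linearly
    to zero at ``warm_end`` — above which animals are invariably normothermic.
    """
    if ta <= t_min:
        return 0.9
    return max(0.0, 0.9 * (warm_end - ta) / (warm_end - t_min))


@dataclass
class RespSimConfig:
    """Configuration of the respirometry experiment simulator."""

    true_curves: ThermoCurves
    n_individuals: int = 12
    ta_grid: Sequence[float] = tuple(np.arange(-3.0, 35.01, 2.0))
    noise_cv: float = 0.10
    p_torpor_at_ta: Callable[[float], float] = default_torpor_probability
    samples_per_window: int = 4
    sample_spacing_minutes: float = 1.0
    within_window_rate_cv: float = 0.02   # instrument jitter, relative
    within_window_skin_sd: float = 0.2
    seed: int = 0

    def __post_init__(self):
        if len(self.ta_grid) == 0:
            raise ValueError("ta_grid must not be empty")
        if not (min(self.ta_grid) >= -3.0 - 1e-9 and max(self.ta_grid) <= 35.0 + 1e-9):
            raise ValueError("ta_grid must lie within [-3, 35] °C")
        if self.noise_cv <= 0:
            raise ValueError("noise_cv must be positive")


def simulate_respirometry(config: RespSimConfig) -> pd.DataFrame:
    """Simulate steady-state respirometry windows.

    Each individual x grid temperature yields one stable measurement window
    of ``samples_per_window`` samples. The window's biological rate is the
    true curve value for the (latent) state times lognormal noise with the
    configured CV; samples within a window add only small instrument jitter,
    so the steady-state screen passes them. Skin temperature tracks the
    chamber in conforming torpor, sits above it in regulated torpor, and is
    near body temperature (32 °C) in normothermy.

    The returned table carries the latent ``state`` column (ground truth for
    validation; fitters must not read it). The rate column is ``rate_kj_h``.
    """
    rng = np.random.default_rng(config.seed)
    tc = config.true_curves
    sigma = np.sqrt(np.log(1.0 + config.noise_cv**2))
    rows = []
    t0 = pd.Timestamp("2019-01-10")
    window_gap = pd.Timedelta(hours=1)
    for i in range(config.n_individuals):
        t_cursor = t0 + pd.Timedelta(days=i)
        for ta in config.ta_grid:
            torpid = rng.random() < config.p_torpor_at_ta(float(ta))
            state = "torpor" if torpid else "normothermy"
            mean_rate = predict_mr(tc, float(ta), state)
            window_rate = mean_rate * rng.lognormal(-sigma**2 / 2, sigma)
            if state == "torpor":
                skin = max(float(ta), tc.t_min) + 0.5
            else:
                skin = max(32.0, float(ta) + 2.0)  # defended body temperature
            for j in range(config.samples_per_window):
                ts = t_cursor + pd.Timedelta(minutes=j * config.sample_spacing_minutes)
                rows.append(
                    {
                        "individual_id": f"bat{i:02d}",
                        "timestamp": ts,
                        "chamber_temp": float(ta),
                        "skin_temp": skin + rng.normal(0.0, config.within_window_skin_sd),
                        "rate_kj_h": window_rate * max(
                            1e-6,
                            1.0 + rng.normal(0.0, config.within_window_rate_cv),
                        ),
                        "state": state,
                    }
                )
            t_cursor += window_gap
    return pd.DataFrame(rows)


@dataclass
class ClimateSimConfig:
    """Seasonal sinusoid + AR(1) daily-temperature generator.

    ``annual_mean`` is the long-run mean at the first year; ``amplitude`` is
    half the peak-to-trough seasonal swing, with the minimum falling on
    ``coldest_day`` (day of year). ``trend`` adds ``trend * (year - first
    year)`` °C. Noise is AR(1) with marginal SD ``noise_sd``. The calendar
    has 365 days (no Feb 29) and winters run July 1 – June 30.
    """

    annual_mean: float
    amplitude: float
    coldest_day: int = 15          # mid January
    trend: float = 0.0             # °C per calendar year
    ar_coef: float = 0.7
    noise_sd: float = 2.0
    years: range = field(default_factory=lambda: range(2015, 2016))
    seed: int = 0

    def __post_init__(self):
        if abs(self.ar_coef) >= 1:
            raise ValueError("ar_coef must satisfy |ar_coef| < 1")
        if self.amplitude < 0:
            raise ValueError("amplitude must be >= 0")


def _winter_dates(winter_year: int) -> pd.DatetimeIndex:
    dates = pd.date_range(
        start=f"{winter_year}-07-01", end=f"{winter_year + 1}-06-30", freq="D"
    )
    return dates[~((dates.month == 2) & (dates.day == 29))]


_MONTH_OFFSETS = np.array([0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334])


def _seasonal_mean(config: ClimateSimConfig, dates: pd.DatetimeIndex) -> np.ndarray:
    first_year = config.years[0]
    # leap-free day-of-year so the sinusoid phase is identical every year
    doy = (_MONTH_OFFSETS[dates.month.to_numpy() - 1]
           + dates.day.to_numpy()).astype(float)
    year_offset = dates.year.to_numpy() - first_year
    seasonal = -config.amplitude * np.cos(
        2 * np.pi * (doy - config.coldest_day) / DAYS_PER_YEAR
    )
    return config.annual_mean + config.trend * year_offset + seasonal


def simulate_daily_temperature(
    config: ClimateSimConfig, location_id: str = "loc"
) -> list[TemperatureSeries]:
    """One TemperatureSeries per requested winter year.

    AR(1) noise is continuous across the whole simulated span (not reset at
    winter boundaries), with innovations scaled so the marginal SD equals
    ``noise_sd``.
    """
    rng = np.random.default_rng(config.seed)
    out = []
    innov_sd = config.noise_sd * np.sqrt(1.0 - config.ar_coef**2)
    prev = rng.normal(0.0, config.noise_sd) if config.noise_sd > 0 else 0.0
    for wy in config.years:
        dates = _winter_dates(wy)
        mean = _seasonal_mean(config, dates)
        noise = np.empty(len(dates))
        if config.noise_sd > 0:
            eps = rng.normal(0.0, innov_sd, size=len(dates))
            for i in range(len(dates)):
                prev = config.ar_coef * prev + eps[i]
                noise[i] = prev
        else:
            noise[:] = 0.0
        out.append(
            TemperatureSeries(
                location_id=location_id, winter_year=wy, dates=dates,
                ta=mean + noise,
            )
        )
    return out


def simulate_grid_climate(
    grid,
    lat_gradient: float,
    base_config: ClimateSimConfig,
    path,
    kelvin: bool = False,
) -> None:
    """Write a small gridded daily-temperature NetCDF fixture.

    Every cell follows ``base_config`` except that its annual mean is offset
    by ``lat_gradient`` °C per degree of latitude above the southernmost cell
    centre. Cells get independent AR(1) noise with per-cell sub-seeds spawned
    deterministically from ``base_config.seed``. Dimensions are (time, lat,
    lon) with a CF-style units attribute ("K" or "degC") on variable ``tas``.
    """
    from dataclasses import replace

    if base_config.years.step != 1:
        raise ValueError("gridded fixtures need consecutive winter years")
    lats, lons = grid.cell_centers()
    dates = _winter_dates(base_config.years[0])
    for wy in list(base_config.years)[1:]:
        dates = dates.append(_winter_dates(wy))

    ss = np.random.SeedSequence(base_config.seed)
    children = ss.spawn(len(lats) * len(lons))
    cube = np.empty((len(dates), len(lats), len(lons)))
    for ilat, lat in enumerate(lats):
        offset = lat_gradient * (lat - lats[0])
        for ilon in range(len(lons)):
            sub = children[ilat * len(lons) + ilon]
            cfg = replace(
                base_config,
                annual_mean=base_config.annual_mean + offset,
                seed=int(sub.generate_state(1)[0] % (2**31)),
            )
            series = simulate_daily_temperature(cfg, location_id=f"{lat}_{lons[ilon]}")
            vals = np.concatenate([s.ta for s in series])
            cube[:, ilat, ilon] = vals[: len(dates)]
    if kelvin:
        cube = cube + 273.15
    ds = xr.Dataset(
        {"tas": (("time", "lat", "lon"), cube)},
        coords={"time": dates, "lat": lats, "lon": lons},
    )
    ds["tas"].attrs["units"] = "K" if kelvin else "degC"
    ds["tas"].attrs["long_name"] = "daily near-surface air temperature"
    ds.to_netcdf(path, engine="scipy")
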