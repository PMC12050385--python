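"""Daily and seasonal hibernation energy budgets.

A winter is survivable where the fat consumed over the whole hibernation
season stays within the animal's fat store. The daily budget combines the
state model (hours per day in normothermy vs. torpor at the roost
temperature) with the thermoregulatory curves (kJ/h in each state), then
converts kJ to grams of fat. Two roost corrections apply:

* **insulation** — the roost is warmer than outside air by a fixed offset
  (default +5 °C); the effective temperature drives both the state model and
  the curves;
* **huddling** — clustering halves thermoregulatory expenditure (default
  factor 0.5), applied to normothermy always and to torpor only below the
  thermoconforming minimum (conforming torpor produces no regulatory heat).

The hibernation season is detected from the daily temperature series: it
exists only if temperature stays below the foraging threshold (default 7 °C)
for at least ``min_season_days`` consecutive days, and its boundaries are the
first and last day whose centred rolling mean is below the threshold. Days
outside the season consume no budget (the animal is assumed to forage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from datetime import date

import numpy as np
import pandas as pd

from .respirometry import ThermoCurves, predict_mr
from .state import StateModel, state_minutes

__all__ = [
    "EnergyParams",
    "SeasonParams",
    "TemperatureSeries",
    "HibernationSeason",
    "BudgetTrajectory",
    "detect_hibernation_season",
    "daily_expenditure",
    "season_budget",
    "budget_without_normothermy",
]


@dataclass
class EnergyParams:
    """Fixed constants of the energy budget.

    The fat budget defaults to 27 g: pre-hibernation body mass (46 g) minus
    the minimum viable mass (19 g). ``solitary`` disables huddling and
    ``uninsulated`` disables the roost temperature offset.
    """

    huddling_factor: float = 0.5
    insulation_offset: float = 5.0
    fat_energy_density: float = 37.7  # kJ per g fat
    fat_budget: float = 27.0          # g
    solitary: bool = False
    uninsulated: bool = False

    def __post_init__(self):
        if not 0 < self.huddling_factor <= 1:
            raise ValueError("huddling_factor must be in (0, 1]")
        if self.fat_budget <= 0:
            raise ValueError("fat_budget must be positive")

    @classmethod
    def from_masses(cls, prehibernation_mass_g: float = 46.0,
                    minimum_mass_g: float = 19.0, **kwargs) -> "EnergyParams":
        """Derive the fat budget from pre-hibernation and minimum body mass."""
        return cls(fat_budget=prehibernation_mass_g - minimum_mass_g, **kwargs)


@dataclass
class SeasonParams:
    forage_threshold: float = 7.0  # °C below which foraging is negligible
    min_season_days: int = 14
    smoothing_days: int = 14       # centred rolling window for boundaries

    def __post_init__(self):
        if self.min_season_days < 1:
            raise ValueError("min_season_days must be >= 1")


@dataclass
class TemperatureSeries:
    """Daily ambient temperature over one winter window (July 1 – June 30)."""

    location_id: str
    winter_year: int
    dates: pd.DatetimeIndex
    ta: np.ndarray

    def __post_init__(self):
        self.dates = pd.DatetimeIndex(self.dates)
        self.ta = np.asarray(self.ta, dtype=float)
        if len(self.dates) != len(self.ta):
            raise ValueError("dates and ta must have equal length")
        gaps = np.diff(self.dates.to_numpy()) / np.timedelta64(1, "D")
        for i, g in enumerate(gaps):
            if g == 1:
                continue
            skipped = self.dates[i] + pd.Timedelta(days=1)
            if g == 2 and skipped.month == 2 and skipped.day == 29:
                continue  # 365-day calendar: Feb 29 may be absent
            raise ValueError(f"daily series has a gap after {self.dates[i].date()}")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"location_id": self.location_id, "winter_year": self.winter_year,
             "date": self.dates, "ta": self.ta}
        )


@dataclass
class HibernationSeason:
    start_date: pd.Timestamp
    end_date: pd.Timestamp
    duration: int        # days, inclusive of both endpoints
    mean_ta: float       # °C averaged over the season days

    def __post_init__(self):
        if self.start_date > self.end_date:
            raise ValueError("season start after end")


@dataclass
class BudgetTrajectory:
    dates: pd.DatetimeIndex
    kj_per_day: np.ndarray
    fat_g_per_day: np.ndarray
    cumulative_fat_g: np.ndarray
    death_date: pd.Timestamp | None
    survived: bool

    @property
    def total_fat_g(self) -> float:
        return float(self.cumulative_fat_g[-1]) if len(self.cumulative_fat_g) else 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"date": self.dates, "kj": self.kj_per_day,
             "fat_g": self.fat_g_per_day, "cumulative_fat_g": self.cumulative_fat_g}
        )


def _longest_cold_run(ta: np.ndarray, threshold: float) -> int:
    best = run = 0
    for v in ta:
        run = run + 1 if v < threshold else 0
        best = max(best, run)
    return best


def detect_hibernation_season(
    series: TemperatureSeries, sp: SeasonParams | None = None
) -> HibernationSeason | None:
    """Detect the hibernation season, or return None when no hibernation occurs.

    Existence requires at least ``min_season_days`` consecutive raw days
    strictly below the foraging threshold. Boundaries are then the first and
    last day whose centred ``smoothing_days`` rolling mean is below the
    threshold (short warm spells inside the season do not split it).
    """
    sp = sp or SeasonParams()
    if _longest_cold_run(series.ta, sp.forage_threshold) < sp.min_season_days:
        return None
    rolled = (
        pd.Series(series.ta, index=series.dates)
        .rolling(sp.smoothing_days, center=True, min_periods=1)
        .mean()
    )
    below = rolled < sp.forage_threshold
    if not below.any():
        return None
    idx = np.flatnonzero(below.to_numpy())
    start, end = series.dates[idx[0]], series.dates[idx[-1]]
    duration = int(idx[-1] - idx[0]) + 1  # days present in the series
    if duration < sp.min_season_days:
        return None
    mask = (series.dates >= start) & (series.dates <= end)
    return HibernationSeason(
        start_date=start, end_date=end, duration=duration,
        mean_ta=float(series.ta[mask].mean()),
    )


def daily_expenditure(
    sm: StateModel, tc: ThermoCurves, ta: float, ep: EnergyParams | None = None
) -> tuple[float, float]:
    """Energy spent on one day at ambient temperature ``ta``: (kJ, g fat).

    The roost (effective) temperature t* = ta + insulation offset drives both
    the state split and the metabolic rates. Huddling multiplies
    thermoregulatory expenditure: normothermy always, torpor only when
    t* is below the thermoconforming minimum.
    """
    ep = ep or EnergyParams()
    t_eff = float(ta) + (0.0 if ep.uninsulated else ep.insulation_offset)
    mins_n, mins_t = state_minutes(sm, t_eff)
    hours_n, hours_t = float(mins_n) / 60.0, float(mins_t) / 60.0
    rate_n = predict_mr(tc, t_eff, "normothermy")
    rate_t = predict_mr(tc, t_eff, "torpor")
    f_n = 1.0 if ep.solitary else ep.huddling_factor
    f_t = 1.0 if (ep.solitary or t_eff >= tc.t_min) else ep.huddling_factor
    kj = hours_n * rate_n * f_n + hours_t * rate_t * f_t
    return kj, kj / ep.fat_energy_density


def _accumulate(
    series: TemperatureSeries,
    season: HibernationSeason,
    day_fn,
    ep: EnergyParams,
) -> BudgetTrajectory:
    mask = (series.dates >= season.start_date) & (series.dates <= season.end_date)
    if not mask.any():
        raise ValueError("season does not overlap the temperature series")
    dates = series.dates[mask]
    kj = np.array([day_fn(t)[0] for t in series.ta[mask]])
    fat = kj / ep.fat_energy_density
    cum = np.cumsum(fat)
    over = np.flatnonzero(cum > ep.fat_budget)
    death = dates[over[0]] if len(over) else None
    return BudgetTrajectory(
        dates=dates, kj_per_day=kj, fat_g_per_day=fat, cumulative_fat_g=cum,
        death_date=death, survived=death is None,
    )


def season_budget(
    series: TemperatureSeries,
    season: HibernationSeason,
    sm: StateModel,
    tc: ThermoCurves,
    ep: EnergyParams | None = None,
) -> BudgetTrajectory:
    """Accumulate daily fat consumption over the season; flag death on the
    first day the cumulative total strictly exceeds the fat budget."""
    ep = ep or EnergyParams()
    return _accumulate(series, season, lambda ta: daily_expenditure(sm, tc, ta, ep), ep)


def budget_without_normothermy(
    series: TemperatureSeries,
    season: HibernationSeason,
    tc: ThermoCurves,
    ep: EnergyParams | None = None,
) -> BudgetTrajectory:
    """Comparison budget assuming 24 h of torpor per day (no normothermy)."""
    ep = ep or EnergyParams()

    def day_fn(ta: float):
        t_eff = float(ta) + (0.0 if ep.uninsulated else ep.insulation_offset)
        rate_t = predict_mr(tc, t_eff, "torpor")
        f_t = 1.0 if (ep.solitary or t_eff >= tc.t_min) else ep.huddling_factor
        kj = 24.0 * rate_t * f_t
        return kj, kj / ep.fat_energy_density

    return _accumulate(series, season, day_fn, ep)
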