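"""Two-variable approximation of the hibernation niche.

The full mechanistic budget depends on the entire daily temperature
trajectory, but survival is well summarised by just two winter statistics:
the mean ambient temperature of the hibernation season and its duration.
Binning many simulated (or projected) winters on these two axes and
recording the proportion that were survivable yields a descriptive niche
table whose bins are classified *unsuitable* (proportion 0), *fully
suitable* (proportion 1) or *ambiguous* (anything between).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .budget import HibernationSeason, TemperatureSeries

__all__ = ["season_descriptors", "build_niche_table", "classify_bins"]


def season_descriptors(
    series: TemperatureSeries, season: HibernationSeason
) -> tuple[float, float]:
    """(mean season temperature °C, duration in days, endpoints inclusive)."""
    mask = (series.dates >= season.start_date) & (series.dates <= season.end_date)
    return float(series.ta[mask].mean()), int(mask.sum())


def build_niche_table(
    outcomes: pd.DataFrame,
    bin_width_ta: float = 1.0,
    bin_width_days: float = 10.0,
) -> pd.DataFrame:
    """Bin winters by (mean_ta, duration) and tabulate survival proportions.

    ``outcomes`` needs columns ``mean_ta`` (°C), ``duration`` (days) and
    ``survived`` (bool). Bin edges are aligned to multiples of the widths;
    empty bins are omitted. Columns of the result: bin edges, ``n_seasons``
    and ``proportion_suitable``.
    """
    if len(outcomes) < 1:
        raise ValueError("need at least one winter outcome")
    df = outcomes.copy()
    df["ta_bin"] = np.floor(df["mean_ta"] / bin_width_ta) * bin_width_ta
    df["dur_bin"] = np.floor(df["duration"] / bin_width_days) * bin_width_days
    grouped = df.groupby(["ta_bin", "dur_bin"], sort=True)["survived"].agg(
        n_seasons="count", proportion_suitable="mean"
    )
    table = grouped.reset_index()
    table["ta_bin_hi"] = table["ta_bin"] + bin_width_ta
    table["dur_bin_hi"] = table["dur_bin"] + bin_width_days
    return table[
        ["ta_bin", "ta_bin_hi", "dur_bin", "dur_bin_hi",
         "n_seasons", "proportion_suitable"]
    ]


def classify_bins(table: pd.DataFrame) -> pd.DataFrame:
    """Attach a class per bin: unsuitable (0), suitable (1), else ambiguous."""
    table = table.copy()
    p = table["proportion_suitable"]
    table["class"] = np.select(
        [p == 0.0, p == 1.0], ["unsuitable", "suitable"], default="ambiguous"
    )
    return table
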