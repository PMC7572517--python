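"""Seasonal statistics per station: z-score profiles, peak timing, ranges.

For each station and metric (log10 cell abundance, alpha richness, alpha
ENS) the seasonal layer computes

* within-year z-scores, standardising each year to mean 0 / sd 1 so that
  seasonal shape can be compared across stations with different levels;
* the annual peak month (0 = January ... 11 = December) for each adequately
  sampled year, summarised across years by the **circular mean** — months
  live on a 12-point wheel, so averaging December (11) and February (1)
  must give January (0), not June;
* the within-year range (max - min), averaged over years, measuring seasonal
  amplitude in the metric's own units.

Years with fewer than ``min_months`` sampled months are skipped for peak and
range statistics, mirroring the station-inclusion criterion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import DomainError

logger = logging.getLogger("saltgrad")


class UndefinedMeanError(DomainError):
    """Circular mean undefined: the resultant vector has ~zero length."""


@dataclass
class SeasonalStats:
    """Seasonal summary for one station and metric."""

    station_id: str
    metric: str
    zscores: pd.DataFrame = field(default_factory=pd.DataFrame)
    # columns year, month, z
    peak_months: dict[int, int] = field(default_factory=dict)  # year -> month
    circular_mean_peak: float | None = None  # fractional month on [0, 12)
    resultant_length: float | None = None
    mean_within_year_range: float | None = None


def within_year_zscores(series: pd.DataFrame) -> pd.DataFrame:
    """Standardise a (year, month, value) series within each year.

    Years with < 2 values or zero spread give missing z-scores (warned).
    Returns columns year, month, z.
    """
    out = []
    for year, grp in series.groupby("year"):
        x = grp["value"].astype(float)
        if len(x) < 2 or x.std(ddof=1) == 0:
            logger.warning(
                "z-scores undefined for year %s (n=%d, sd=%s)",
                year,
                len(x),
                0 if len(x) >= 2 else "n/a",
            )
            z = pd.Series(np.nan, index=x.index)
        else:
            z = (x - x.mean()) / x.std(ddof=1)
        out.append(pd.DataFrame({"year": year, "month": grp["month"], "z": z}))
    return pd.concat(out, ignore_index=True)


def peak_month(series: pd.DataFrame, min_months: int = 8) -> dict[int, int]:
    """Month of the annual maximum, per year with >= min_months samples.

    Ties break to the earliest month, so the result is deterministic and
    independent of row order.
    """
    peaks: dict[int, int] = {}
    for year, grp in series.groupby("year"):
        if grp["month"].nunique() < min_months:
            continue
        g = grp.sort_values("month")
        vmax = g["value"].max()
        peaks[int(year)] = int(g.loc[g["value"] == vmax, "month"].iloc[0])
    return peaks


def circular_mean_month(
    months, eps: float = 1e-8
) -> tuple[float, float]:
    """Circular mean of month indices on the 12-month wheel.

    Maps month m to angle 2*pi*m/12, averages the unit vectors, and maps the
    mean direction back to a fractional month on [0, 12).  Also returns the
    mean resultant length in [0, 1] (1 = perfectly concentrated).  Raises
    :class:`UndefinedMeanError` when the resultant is ~zero (e.g. {0, 6}).
    """
    m = np.asarray(list(months), dtype=float)
    if m.size == 0:
        raise DomainError("circular mean of an empty list")
    ang = 2 * np.pi * m / 12.0
    c, s = np.cos(ang).mean(), np.sin(ang).mean()
    r = float(np.hypot(c, s))
    if r < eps:
        raise UndefinedMeanError(
            "mean month undefined: peak months are balanced around the year"
        )
    mean = float(np.mod(np.arctan2(s, c) / (2 * np.pi) * 12.0, 12.0))
    if mean >= 12.0:  # rounding at the wrap: keep the contract [0, 12)
        mean = 0.0
    return mean, r


def within_year_range(series: pd.DataFrame, min_months: int = 8) -> float | None:
    """Mean over qualifying years of the within-year max - min."""
    ranges = []
    for _, grp in series.groupby("year"):
        if grp["month"].nunique() < min_months:
            continue
        ranges.append(float(grp["value"].max() - grp["value"].min()))
    return float(np.mean(ranges)) if ranges else None


def seasonal_stats(
    series: pd.DataFrame,
    station_id: str,
    metric: str,
    min_months: int = 8,
) -> SeasonalStats:
    """All seasonal statistics for one station's monthly series.

    ``series`` needs columns year, month, value.  Peaks and ranges are
    computed on raw values (not z-scores).
    """
    stats = SeasonalStats(station_id=station_id, metric=metric)
    stats.zscores = within_year_zscores(series)
    stats.peak_months = peak_month(series, min_months=min_months)
    if stats.peak_months:
        try:
            stats.circular_mean_peak, stats.resultant_length = circular_mean_month(
                stats.peak_months.values()
            )
        except UndefinedMeanError:
            logger.warning(
                "station %s metric %s: circular mean peak undefined", station_id, metric
            )
    stats.mean_within_year_range = within_year_range(series, min_months=min_months)
    return stats


def seasonal_tables(
    monthly: pd.DataFrame,
    metrics: list[str],
    min_months: int = 8,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Z-score, peak and range tables across stations and metrics.

    ``monthly`` is wide: one row per (station_id, year, month) with one
    column per metric.  Returns (zscores, peaks, ranges) tidy frames.
    """
    z_rows, p_rows, r_rows = [], [], []
    for sid, grp in monthly.groupby("station_id"):
        for metric in metrics:
            series = grp[["year", "month", metric]].rename(columns={metric: "value"})
            series = series.dropna(subset=["value"])
            if series.empty:
                continue
            st = seasonal_stats(series, sid, metric, min_months=min_months)
            z = st.zscores.assign(station_id=sid, metric=metric)
            z_rows.append(z)
            if st.circular_mean_peak is not None:
                p_rows.append(
                    {
                        "station_id": sid,
                        "metric": metric,
                        "circular_mean_peak": st.circular_mean_peak,
                        "resultant_length": st.resultant_length,
                        "n_years": len(st.peak_months),
                    }
                )
            if st.mean_within_year_range is not None:
                r_rows.append(
                    {
                        "station_id": sid,
                        "metric": metric,
                        "mean_within_year_range": st.mean_within_year_range,
                    }
                )
    zscores = (
        pd.concat(z_rows, ignore_index=True)[
            ["station_id", "metric", "year", "month", "z"]
        ]
        if z_rows
        else pd.DataFrame(columns=["station_id", "metric", "year", "month", "z"])
    )
    return zscores, pd.DataFrame(p_rows), pd.DataFrame(r_rows)
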