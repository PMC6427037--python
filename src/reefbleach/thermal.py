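"""Thermal-stress covariates from weekly sea-surface temperature.

Implements the CoRTAD-style metric family used as bleaching predictors:
the week-of-year climatology and its warmest-month baseline (MMM), weekly
SST anomalies (SSTA, relative to the week-of-year climatology) and thermal
stress anomalies (TSA, relative to the MMM), their frequencies and
dispersions, Degree Heating Weeks (DHW), and the long-run SST trend.

Conventions (NOAA Coral Reef Watch style, exposed as keyword arguments):

* DHW accumulates ``temp - MMM`` over the trailing 12-week window ending at
  the survey week, counting only weeks at least 1 degC above the MMM; units
  are degC-weeks.
* Anomaly "frequency" metrics count weeks with SSTA (or TSA) >= 1 degC.
* Week-of-year 53 is folded into week 52, giving a fixed 52-week climatology.
* All running statistics (min, max, stdev, frequencies) are taken over the
  series from its start up to and including the survey week.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, fields
from typing import Iterable

import numpy as np
import pandas as pd
import xarray as xr


class InsufficientBaselineError(ValueError):
    """Climatology requested over fewer than two full years."""


class WindowError(ValueError):
    """DHW requested with fewer than 12 weeks of history."""


DHW_WINDOW_WEEKS = 12
HOTSPOT_THRESHOLD = 1.0  # degC above MMM


@dataclass
class SSTSeries:
    """Weekly SST series for one grid cell."""

    week_dates: np.ndarray  # datetime64[ns], strictly increasing, ~7-day steps
    temps: np.ndarray       # degC, NaN marks missing weeks
    cell: tuple[float, float] = (np.nan, np.nan)  # (lat, lon)

    def __post_init__(self) -> None:
        self.week_dates = np.asarray(self.week_dates, dtype="datetime64[ns]")
        self.temps = np.asarray(self.temps, dtype=float)
        if self.week_dates.shape != self.temps.shape:
            raise ValueError("week_dates and temps must have identical shape")
        diffs = np.diff(self.week_dates).astype("timedelta64[D]").astype(int)
        if diffs.size and (diffs <= 0).any():
            raise ValueError("week_dates must be strictly increasing")

    def __len__(self) -> int:
        return len(self.temps)

    @property
    def years(self) -> np.ndarray:
        return pd.DatetimeIndex(self.week_dates).year.to_numpy()

    @property
    def week_of_year(self) -> np.ndarray:
        """Fixed-52 week-of-year index (0-based); week 53 folded into 52."""
        doy = pd.DatetimeIndex(self.week_dates).dayofyear.to_numpy()
        return np.minimum((doy - 1) // 7, 51)

    @property
    def fractional_years(self) -> np.ndarray:
        t = self.week_dates.astype("datetime64[D]").astype(float)
        return t / 365.25


@dataclass
class Climatology:
    """Long-term weekly baseline for one cell."""

    weekly_means: np.ndarray        # 52 values, degC
    mmm: float                      # maximum of long-term monthly means, degC
    baseline_years: tuple[int, int]

    def __post_init__(self) -> None:
        self.weekly_means = np.asarray(self.weekly_means, dtype=float)
        if self.weekly_means.shape != (52,):
            raise ValueError("weekly_means must have exactly 52 entries")


@dataclass
class ThermalMetricSet:
    """The per-survey thermal covariate vector."""

    sst_at_survey: float
    sst_min: float
    sst_max: float
    sst_stdev: float
    ssta: float
    ssta_stdev: float
    ssta_freq: float           # weeks with SSTA >= threshold
    ssta_freq_stdev: float     # sd of yearly SSTA-exceedance counts
    tsa: float
    tsa_stdev: float
    tsa_freq: float            # weeks with TSA >= threshold
    tsa_freq_stdev: float      # sd of yearly TSA-exceedance counts
    dhw: float                 # degC-weeks
    rate_of_sst_change: float  # degC per year
    clim_sst: float            # climatological SST for the survey week
    missing: bool = False

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


METRIC_NAMES: tuple[str, ...] = tuple(
    f.name for f in fields(ThermalMetricSet) if f.name != "missing"
)


def compute_climatology(
    series: SSTSeries, baseline_years: tuple[int, int]
) -> Climatology:
    """Week-of-year climatology and warmest-month baseline (MMM).

    ``weekly_means`` is the mean temperature per week-of-year over the
    baseline; ``mmm`` is the maximum over the 12 calendar months of the
    long-term monthly mean.
    """
    y0, y1 = baseline_years
    years = series.years
    mask = (years >= y0) & (years <= y1) & np.isfinite(series.temps)
    n_years = len(np.unique(years[mask]))
    if n_years < 2:
        raise InsufficientBaselineError(
            f"climatology baseline {y0}-{y1} covers {n_years} year(s) of data; "
            "need at least 2 full years"
        )
    woy = series.week_of_year[mask]
    temps = series.temps[mask]
    weekly = np.full(52, np.nan)
    sums = np.bincount(woy, weights=temps, minlength=52)
    counts = np.bincount(woy, minlength=52)
    nz = counts > 0
    weekly[nz] = sums[nz] / counts[nz]
    # fill any never-observed week from its neighbours (short baselines only)
    if not nz.all():
        idx = np.arange(52)
        weekly = np.interp(idx, idx[nz], weekly[nz], period=52)

    months = pd.DatetimeIndex(series.week_dates[mask]).month.to_numpy()
    msums = np.bincount(months - 1, weights=temps, minlength=12)
    mcounts = np.bincount(months - 1, minlength=12)
    monthly = msums[mcounts > 0] / mcounts[mcounts > 0]
    return Climatology(weekly, float(monthly.max()), (y0, y1))


def compute_anomalies(
    series: SSTSeries, clim: Climatology
) -> tuple[np.ndarray, np.ndarray]:
    """Weekly SSTA and TSA vectors.

    SSTA(t) = temp(t) - weekly climatological mean for t's week-of-year;
    TSA(t) = temp(t) - MMM.
    """
    ssta = series.temps - clim.weekly_means[series.week_of_year]
    tsa = series.temps - clim.mmm
    return ssta, tsa


def compute_dhw(
    series: SSTSeries,
    clim: Climatology,
    at_date,
    window: int = DHW_WINDOW_WEEKS,
    threshold: float = HOTSPOT_THRESHOLD,
) -> float:
    """Degree Heating Weeks at ``at_date``.

    Sums hotspot values (temp - MMM) over the trailing ``window`` weeks
    ending at the week containing ``at_date``, counting only weeks whose
    hotspot is at least ``threshold`` degC.
    """
    idx = _week_index(series, at_date)
    if idx + 1 < window:
        raise WindowError(
            f"DHW needs {window} weeks of history; only {idx + 1} available"
        )
    hotspots = series.temps[idx + 1 - window : idx + 1] - clim.mmm
    hot = hotspots[hotspots >= threshold]
    return float(hot.sum()) if hot.size else 0.0


def compute_rate_of_change(
    series: SSTSeries, year_range: tuple[int, int] | None = None
) -> float:
    """OLS slope of weekly SST against time, in degC per year."""
    mask = np.isfinite(series.temps)
    if year_range is not None:
        years = series.years
        mask &= (years >= year_range[0]) & (years <= year_range[1])
    if mask.sum() < 2:
        raise ValueError(f"rate of change needs >= 2 weeks in range {year_range}")
    t = series.fractional_years[mask]
    if len(np.unique(series.years[mask])) < 2:
        raise ValueError("rate of change needs >= 2 distinct years")
    slope = np.polyfit(t, series.temps[mask], 1)[0]
    return float(slope)


def metrics_for_survey(
    series: SSTSeries,
    clim: Climatology,
    survey_date,
    threshold: float = HOTSPOT_THRESHOLD,
    max_gap_fraction: float = 0.05,
) -> ThermalMetricSet:
    """Assemble the full thermal covariate vector for one survey.

    All running statistics use the series from its start up to and including
    the survey week. If more than ``max_gap_fraction`` of those weeks are
    missing, the metrics are returned as NaN with ``missing=True`` so the
    preprocessing stage can drop the row.
    """
    idx = _week_index(series, survey_date)
    temps = series.temps[: idx + 1]
    gap = float(np.mean(~np.isfinite(temps)))
    if gap > max_gap_fraction:
        nan = float("nan")
        return ThermalMetricSet(*([nan] * len(METRIC_NAMES)), missing=True)

    sub = SSTSeries(series.week_dates[: idx + 1], temps, series.cell)
    ssta, tsa = compute_anomalies(sub, clim)
    years = sub.years
    ok = np.isfinite(temps)

    def yearly_count_sd(exceed: np.ndarray) -> float:
        per_year = pd.Series(exceed[ok]).groupby(years[ok]).sum()
        return float(per_year.std(ddof=1)) if len(per_year) > 1 else 0.0

    dhw = compute_dhw(series, clim, survey_date, threshold=threshold)
    rate = compute_rate_of_change(sub)
    return ThermalMetricSet(
        sst_at_survey=float(temps[idx]),
        sst_min=float(np.nanmin(temps)),
        sst_max=float(np.nanmax(temps)),
        sst_stdev=float(np.nanstd(temps, ddof=1)),
        ssta=float(ssta[idx]),
        ssta_stdev=float(np.nanstd(ssta, ddof=1)),
        ssta_freq=float(np.nansum(ssta >= threshold)),
        ssta_freq_stdev=yearly_count_sd(ssta >= threshold),
        tsa=float(tsa[idx]),
        tsa_stdev=float(np.nanstd(tsa, ddof=1)),
        tsa_freq=float(np.nansum(tsa >= threshold)),
        tsa_freq_stdev=yearly_count_sd(tsa >= threshold),
        dhw=dhw,
        rate_of_sst_change=rate,
        clim_sst=float(clim.weekly_means[sub.week_of_year[idx]]),
    )


def series_for_cell(sst: xr.Dataset | xr.DataArray, lat: float, lon: float) -> SSTSeries:
    """Extract the weekly series of the grid cell nearest to (lat, lon)."""
    da = sst["sst"] if isinstance(sst, xr.Dataset) else sst
    cell = da.sel(lat=lat, lon=lon, method="nearest")
    return SSTSeries(
        cell["time"].values,
        cell.values.astype(float),
        (float(cell["lat"]), float(cell["lon"])),
    )


def covariates_for_surveys(
    sst: xr.Dataset,
    surveys: pd.DataFrame,
    baseline_years: tuple[int, int],
    threshold: float = HOTSPOT_THRESHOLD,
    max_gap_fraction: float = 0.05,
) -> pd.DataFrame:
    """Thermal covariate table for a survey table, one row per site x date.

    ``surveys`` needs columns site_id, latitude, longitude, date (and
    optionally depth). The result is keyed by (site_id, date) and appends
    abs_latitude (degrees north or south of the equator), depth and survey
    year as covariates.
    """
    rows: list[dict] = []
    n_missing = 0
    for (site, lat, lon), grp in surveys.groupby(
        ["site_id", "latitude", "longitude"], sort=False
    ):
        series = series_for_cell(sst, lat, lon)
        clim = compute_climatology(series, baseline_years)
        for _, rec in grp.iterrows():
            m = metrics_for_survey(
                series, clim, rec["date"], threshold=threshold,
                max_gap_fraction=max_gap_fraction,
            )
            n_missing += int(m.missing)
            row = {"site_id": site, "date": rec["date"], **m.as_dict()}
            row["abs_latitude"] = abs(float(lat))
            if "depth_m" in rec:
                row["depth"] = float(rec["depth_m"])
            row["year"] = pd.Timestamp(rec["date"]).year
            rows.append(row)
    if n_missing:
        warnings.warn(
            f"{n_missing} survey(s) flagged missing thermal data "
            f"(gap fraction > {max_gap_fraction})"
        )
    return pd.DataFrame(rows)


def _week_index(series: SSTSeries, at_date) -> int:
    """Index of the series week containing ``at_date`` (last week starting <= date)."""
    ts = np.datetime64(pd.Timestamp(at_date), "ns")
    if ts < series.week_dates[0] or ts > series.week_dates[-1] + np.timedelta64(7, "D"):
        raise ValueError(f"date {at_date} outside the SST time axis")
    return int(np.searchsorted(series.week_dates, ts, side="right") - 1)
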