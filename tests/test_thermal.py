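"""Thermal-stress metric computations against closed forms and brute force."""
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import reefbleach as rb
from reefbleach.thermal import (
    InsufficientBaselineError,
    WindowError,
    metrics_for_survey,
    _week_index,
)

from conftest import sinusoid_series, weekly_series


class TestClimatology:
    def test_constant_series(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        assert np.allclose(clim.weekly_means, 28.0)
        assert clim.mmm == pytest.approx(28.0)

    def test_sinusoid_mmm_matches_bruteforce_monthly_means(self):
        series = sinusoid_series(520, mean=27.0, amplitude=2.0)
        clim = rb.compute_climatology(series, (1990, 1999))
        # independent oracle: monthly means by explicit dict accumulation
        by_month = {}
        for d, t in zip(pd.DatetimeIndex(series.week_dates), series.temps):
            by_month.setdefault(d.month, []).append(t)
        oracle_mmm = max(np.mean(v) for v in by_month.values())
        assert clim.mmm == pytest.approx(oracle_mmm, abs=1e-9)
        # peak of a +-2 degC sinusoid around 27, flattened by monthly averaging
        assert clim.mmm == pytest.approx(29.0, abs=0.15)

    def test_two_year_average(self):
        year1 = np.linspace(25, 29, 52)
        series = weekly_series(np.concatenate([year1, year1 + 1.0]))
        clim = rb.compute_climatology(series, (1990, 1992))
        # week 52 of year 1 spills into early year 2; restrict to weeks fully
        # aligned across the two years
        assert np.allclose(clim.weekly_means[:51], year1[:51] + 0.5, atol=0.05)

    def test_insufficient_baseline_rejected(self, flat_series):
        with pytest.raises(InsufficientBaselineError):
            rb.compute_climatology(flat_series, (1990, 1990))


class TestAnomalies:
    def test_series_equal_to_climatology_gives_zero_ssta(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        ssta, _ = rb.compute_anomalies(flat_series, clim)
        assert np.allclose(ssta, 0.0)

    def test_constant_offset_above_mmm(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        hot = weekly_series(np.full(260, clim.mmm + 2.0))
        _, tsa = rb.compute_anomalies(hot, clim)
        assert np.allclose(tsa, 2.0)

    def test_single_spike_counted_once(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        temps = np.full(260, 28.0)
        temps[100] += 3.0
        spiked = weekly_series(temps)
        ssta, _ = rb.compute_anomalies(spiked, clim)
        assert int(np.sum(ssta >= 1.0)) == 1

    def test_ssta_mean_zero_over_baseline(self):
        rng = np.random.default_rng(0)
        series = weekly_series(28 + rng.normal(0, 1, 520))
        clim = rb.compute_climatology(series, (1990, 1999))
        ssta, _ = rb.compute_anomalies(series, clim)
        # climatology built from the whole series: anomalies average out
        assert abs(ssta.mean()) < 1e-9


class TestDHW:
    def test_flat_series_zero(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        assert rb.compute_dhw(flat_series, clim, flat_series.week_dates[100]) == 0.0

    def test_twelve_weeks_one_degree_above(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        temps = np.full(260, 28.0)
        temps[100:112] = clim.mmm + 1.0
        series = weekly_series(temps)
        assert rb.compute_dhw(series, clim, series.week_dates[111]) == pytest.approx(12.0)

    def test_subthreshold_weeks_do_not_accumulate(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        temps = np.full(260, 28.0)
        temps[100:106] = clim.mmm + 0.9   # below the 1 degC hotspot threshold
        temps[106:112] = clim.mmm + 2.0
        series = weekly_series(temps)
        assert rb.compute_dhw(series, clim, series.week_dates[111]) == pytest.approx(12.0)

    def test_short_history_rejected(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        with pytest.raises(WindowError):
            rb.compute_dhw(flat_series, clim, flat_series.week_dates[5])

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(shift=st.floats(-5, 5, allow_nan=False))
    def test_invariant_to_constant_shift(self, shift):
        rng = np.random.default_rng(99)
        temps = 28 + rng.normal(0, 1.5, 208)
        series = weekly_series(temps)
        clim = rb.compute_climatology(series, (1990, 1993))
        shifted = weekly_series(temps + shift)
        clim_shifted = rb.compute_climatology(shifted, (1990, 1993))
        at = series.week_dates[150]
        assert rb.compute_dhw(series, clim, at) == pytest.approx(
            rb.compute_dhw(shifted, clim_shifted, at), abs=1e-9
        )


class TestRateOfChange:
    def test_exact_line(self):
        series = weekly_series(27.0 + 0.02 * np.arange(260) * 7 / 365.25)
        assert rb.compute_rate_of_change(series) == pytest.approx(0.02, abs=1e-12)

    def test_flat_series(self, flat_series):
        assert rb.compute_rate_of_change(flat_series) == pytest.approx(0.0, abs=1e-12)

    def test_seasonal_cycle_does_not_bias_trend(self):
        # cosine aligned with the window start over whole 52-week periods is
        # (near-)orthogonal to the linear term, so the slope survives intact
        n = 520  # 10 full periods
        t_years = np.arange(n) * 7 / 365.25
        seasonal = 2.0 * np.cos(2 * np.pi * np.arange(n) / 52)
        series = weekly_series(27.0 + seasonal + 0.03 * t_years)
        ours = rb.compute_rate_of_change(series)
        # oracle: detrend by subtracting the known seasonal component
        oracle = np.polyfit(t_years, series.temps - seasonal, 1)[0]
        assert oracle == pytest.approx(0.03, abs=1e-9)
        assert ours == pytest.approx(oracle, abs=5e-3)


class TestMetricsForSurvey:
    def test_flat_series_degenerate_metrics(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        m = metrics_for_survey(flat_series, clim, flat_series.week_dates[200])
        assert m.ssta_freq == 0 and m.tsa_freq == 0
        assert m.dhw == 0.0 and m.sst_stdev == pytest.approx(0.0)
        assert not m.missing

    def test_injected_anomalies_counted(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        temps = np.full(260, 28.0)
        hot_weeks = [50, 51, 120, 200]
        for w in hot_weeks:
            temps[w] = 29.5
        series = weekly_series(temps)
        m = metrics_for_survey(series, clim, series.week_dates[210])
        assert m.ssta_freq == pytest.approx(len(hot_weeks), abs=1)
        assert m.tsa_freq == len(hot_weeks)

    def test_dhw_monotone_while_anomaly_in_window(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        temps = np.full(260, 28.0)
        temps[150:156] = clim.mmm + 2.0
        series = weekly_series(temps)
        early = metrics_for_survey(series, clim, series.week_dates[151])
        late = metrics_for_survey(series, clim, series.week_dates[156])
        assert late.dhw >= early.dhw > 0

    def test_gappy_series_flagged_missing(self, flat_series):
        clim = rb.compute_climatology(flat_series, (1990, 1994))
        temps = np.full(260, 28.0)
        temps[0:40] = np.nan
        series = weekly_series(temps)
        m = metrics_for_survey(series, clim, series.week_dates[200])
        assert m.missing and np.isnan(m.dhw)


def _brute_force_metrics(series, clim, survey_date, threshold=1.0):
    """Independent loop-based oracle for the full metric set."""
    idx = _week_index(series, survey_date)
    temps = list(series.temps[: idx + 1])
    dates = list(pd.DatetimeIndex(series.week_dates[: idx + 1]))
    woy = [min((d.dayofyear - 1) // 7, 51) for d in dates]
    ssta = [t - clim.weekly_means[w] for t, w in zip(temps, woy)]
    tsa = [t - clim.mmm for t in temps]
    hot = [t - clim.mmm for t in temps[max(0, idx - 11): idx + 1]]
    dhw = sum(h for h in hot if h >= threshold)
    years = [d.year for d in dates]
    t_frac = [d.to_datetime64().astype("datetime64[D]").astype(float) / 365.25 for d in dates]
    slope = np.polyfit(t_frac, temps, 1)[0]

    def yearly_sd(flags):
        per_year = {}
        for y, f in zip(years, flags):
            per_year[y] = per_year.get(y, 0) + int(f)
        vals = list(per_year.values())
        return np.std(vals, ddof=1) if len(vals) > 1 else 0.0

    return {
        "sst_at_survey": temps[idx],
        "sst_min": min(temps),
        "sst_max": max(temps),
        "sst_stdev": np.std(temps, ddof=1),
        "ssta": ssta[idx],
        "ssta_stdev": np.std(ssta, ddof=1),
        "ssta_freq": sum(1 for v in ssta if v >= threshold),
        "ssta_freq_stdev": yearly_sd([v >= threshold for v in ssta]),
        "tsa": tsa[idx],
        "tsa_stdev": np.std(tsa, ddof=1),
        "tsa_freq": sum(1 for v in tsa if v >= threshold),
        "tsa_freq_stdev": yearly_sd([v >= threshold for v in tsa]),
        "dhw": dhw,
        "rate_of_sst_change": slope,
        "clim_sst": clim.weekly_means[woy[idx]],
    }


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_all_metrics_agree_with_bruteforce_oracle(seed):
    rng = np.random.default_rng(seed)
    temps = 27 + 2 * np.sin(np.arange(200) * 2 * np.pi / 52) + rng.normal(0, 0.8, 200)
    series = weekly_series(temps)
    clim = rb.compute_climatology(series, (1990, 1993))
    at = series.week_dates[180]
    ours = metrics_for_survey(series, clim, at).as_dict()
    oracle = _brute_force_metrics(series, clim, at)
    for key, val in oracle.items():
        assert ours[key] == pytest.approx(val, abs=1e-9), key


def test_survey_outside_time_axis_rejected(flat_series):
    clim = rb.compute_climatology(flat_series, (1990, 1994))
    with pytest.raises(ValueError):
        metrics_for_survey(flat_series, clim, "2030-01-01")
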