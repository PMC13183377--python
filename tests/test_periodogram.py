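"""Lomb-Scargle estimator, shuffle significance lines, peak handling."""

import numpy as np
import pytest

from ovirhythm.periodogram import (DegenerateSeriesError, Periodogram,
                                   estimate_period, find_peaks, lomb_scargle,
                                   period_grid, quantile_thresholds,
                                   significance_lines)
from ovirhythm.records import RecordError

from .oracles import lomb_scargle_bruteforce


def _pg(periods, power, lines=None):
    return Periodogram(periods_h=np.asarray(periods, float),
                       power=np.asarray(power, float),
                       sig_lines=lines or {})


def test_power_matches_bruteforce_least_squares_oracle(rng):
    """Phase-shifted evaluation equals a naive per-frequency lstsq fit."""
    worst = 0.0
    for _ in range(200):
        n = int(rng.integers(10, 49))
        t = np.sort(rng.uniform(0, 168, n))
        y = rng.normal(size=n)
        periods = period_grid(t)
        p_impl = lomb_scargle(t, y, periods)
        p_ref = lomb_scargle_bruteforce(t, y, periods)
        worst = max(worst, np.max(np.abs(p_impl - p_ref) / np.maximum(p_ref, 1e-12)))
    assert worst < 1e-9


def test_noiseless_sinusoid_is_recovered_within_one_grid_step(times_7d):
    y = 1 + 0.5 * np.cos(2 * np.pi * (times_7d - 10) / 24.0)
    periods = period_grid(times_7d)
    power = lomb_scargle(times_7d, y, periods)
    best = periods[np.argmax(power)]
    step = np.max(np.abs(np.diff(periods)[np.argsort(np.abs(periods - 24.0))[:2]]))
    assert abs(best - 24.0) <= step


def test_expected_noise_power_is_about_one(times_7d, rng):
    """Scargle variance normalization: E[P] ~ 1 at a fixed frequency."""
    periods = period_grid(times_7d)
    powers = np.array([lomb_scargle(times_7d, rng.normal(size=42), periods)
                       for _ in range(300)])
    # average over replicates at a handful of fixed frequencies
    assert np.allclose(powers[:, ::40].mean(axis=0), 1.0, atol=0.2)


def test_power_invariances(times_7d, rng):
    """Adding a constant, positive scaling, and time translation leave
    the periodogram unchanged."""
    y = rng.lognormal(0, 0.4, 42)
    periods = period_grid(times_7d)
    base = lomb_scargle(times_7d, y, periods)
    assert np.allclose(lomb_scargle(times_7d, y + 7.3, periods), base, rtol=1e-9)
    assert np.allclose(lomb_scargle(times_7d, 3.7 * y, periods), base, rtol=1e-9)
    assert np.allclose(lomb_scargle(times_7d + 1000.0, y, periods), base,
                       rtol=1e-6, atol=1e-9)


def test_missing_values_are_omitted(times_7d, rng):
    y = rng.lognormal(0, 0.4, 42)
    y_nan = y.copy()
    y_nan[[5, 17]] = np.nan
    keep = ~np.isnan(y_nan)
    periods = period_grid(times_7d)
    assert np.allclose(lomb_scargle(times_7d, y_nan, periods),
                       lomb_scargle(times_7d[keep], y[keep], periods))


def test_degenerate_series_raise(times_7d):
    periods = period_grid(times_7d)
    with pytest.raises(DegenerateSeriesError, match="constant"):
        lomb_scargle(times_7d, np.ones(42), periods)
    with pytest.raises(DegenerateSeriesError, match="4"):
        lomb_scargle(times_7d[:3], np.array([1.0, 2.0, 3.0]), periods)


def test_significance_lines_are_ordered_and_deterministic(times_7d, rng):
    y = rng.lognormal(0, 0.4, 42)
    periods = period_grid(times_7d)
    a = significance_lines(times_7d, y, periods, n_rand=300, seed=5)
    b = significance_lines(times_7d, y, periods, n_rand=300, seed=5)
    c = significance_lines(times_7d, y, periods, n_rand=300, seed=6)
    assert a == b
    assert a != c
    assert a[0.01] >= a[0.05] > 0


def test_small_n_rand_warns(times_7d, rng):
    with pytest.warns(UserWarning, match="n_rand"):
        significance_lines(times_7d, rng.normal(size=42),
                           period_grid(times_7d), n_rand=50, seed=0)


def test_bad_levels_are_rejected(times_7d, rng):
    with pytest.raises(RecordError, match="level"):
        significance_lines(times_7d, rng.normal(size=42), period_grid(times_7d),
                           levels=(1.5,), n_rand=100, seed=0)


def test_quantile_threshold_order_statistic_convention():
    """With R=999 maxima, the 0.05 line is the 950th order statistic, so
    exactly 49/999 sample values lie above it."""
    maxima = np.arange(1.0, 1000.0)
    lines = quantile_thresholds(maxima, (0.05, 0.01))
    assert lines[0.05] == 950.0
    assert np.sum(maxima > lines[0.05]) == 49
    assert lines[0.01] == 990.0


def test_single_sinusoid_gives_exactly_one_peak(times_7d):
    y = 1 + 0.5 * np.cos(2 * np.pi * times_7d / 24.0)
    periods = period_grid(times_7d)
    pg = _pg(periods, lomb_scargle(times_7d, y, periods))
    peaks = find_peaks(pg, (16, 32))
    assert len(peaks) == 1
    assert abs(peaks[0].period_h - 24.0) < 0.5


def test_monotone_power_curve_has_no_peaks():
    periods = np.linspace(48, 8, 100)
    pg = _pg(periods, np.linspace(0.1, 5.0, 100))
    assert find_peaks(pg, (16, 32)) == []


def test_window_outside_grid_is_an_error():
    pg = _pg(np.linspace(48, 8, 50), np.ones(50))
    with pytest.raises(RecordError):
        find_peaks(pg, (50, 60))
    with pytest.raises(RecordError, match="window"):
        find_peaks(pg, (32, 16))


def test_estimate_period_on_noiseless_sinusoid(times_7d):
    y = 1 + 0.5 * np.cos(2 * np.pi * times_7d / 24.0)
    periods = period_grid(times_7d)
    est = estimate_period(_pg(periods, lomb_scargle(times_7d, y, periods)), (16, 32))
    assert abs(est.period_h - 24.0) < 0.4
    assert 0 < est.uncertainty_h < 5.0
    assert not est.tied


def test_no_peak_returns_none_not_exception():
    periods = np.linspace(48, 8, 100)
    assert estimate_period(_pg(periods, np.linspace(0.1, 5.0, 100)), (16, 32)) is None


def test_equal_power_peaks_tie_break_to_smaller_period():
    periods = np.linspace(48, 8, 81)
    power = np.full(81, 0.1)
    # two exactly equal triangular peaks near 30 h and 18 h
    for centre in (30.0, 18.0):
        i = int(np.argmin(np.abs(periods - centre)))
        power[i - 1], power[i], power[i + 1] = 2.0, 4.0, 2.0
    est = estimate_period(_pg(periods, power), (16, 32))
    assert est.tied
    assert est.period_h < 20.0
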