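"""Activity probability, operative-temperature pooling, potential activity."""

import numpy as np
import pandas as pd
import pytest

from dieloverlap import (
    CircularSample,
    EstimationError,
    InputError,
    activity_probability,
    aggregate_to,
    fit_pearson,
    kde_circular,
    overlap_delta,
    potential_activity,
)
from dieloverlap.synthetic import diel_sinusoid
from dieloverlap.thermal import N_BINS, OperativeTempSeries


def series_from_values(values):
    vals = np.asarray(values, dtype=float)
    n = np.where(np.isnan(vals), 0, 1)
    return OperativeTempSeries(mean_to=vals, n_records=n)


def to_frame(hours, temps, microenv="soil_exposed", logger="L1", day=0):
    base = pd.Timestamp("2017-07-15") + pd.Timedelta(days=day)
    return pd.DataFrame({
        "logger_id": logger,
        "microenv": microenv,
        "timestamp": base + pd.to_timedelta(np.round(np.asarray(hours) * 3600), "s"),
        "temp_c": temps,
    })


@pytest.fixture(scope="module")
def gamma_fit():
    rng = np.random.default_rng(42)
    return fit_pearson(20.0 + rng.gamma(9.0, 1.0, 20_000))


class TestActivityProbability:
    def test_peak_is_exactly_one(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(18, 45, 400))
        assert curve.prob.max() == pytest.approx(1.0, abs=1e-12)
        assert np.all(curve.prob >= 0)

    def test_zero_outside_support(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(0, 45, 901))
        lo = gamma_fit.support[0]
        assert np.all(curve.prob[curve.temps < lo - 0.1] == 0.0)

    def test_symmetric_fit_gives_symmetric_curve(self):
        rng = np.random.default_rng(3)
        fit = fit_pearson(rng.normal(30.0, 2.0, 30_000))
        assert fit.family == "normal"
        mu = fit.parameters["mean"]
        grid = mu + np.linspace(-8, 8, 321)
        curve = activity_probability(fit, grid)
        assert np.allclose(curve.prob, curve.prob[::-1], atol=1e-9)

    def test_grid_missing_support_is_estimation_error(self, gamma_fit):
        with pytest.raises(EstimationError):
            activity_probability(gamma_fit, np.linspace(-50, -40, 50))


class TestAggregateTo:
    def test_noise_free_sinusoid_recovered_at_bin_midpoints(self):
        mids = (np.arange(N_BINS) + 0.5) * 5.0 / 60.0
        temps = diel_sinusoid(mids, 10.0, 40.0, 14.0)
        series = aggregate_to(to_frame(mids, temps))
        assert np.allclose(series.mean_to, temps, atol=1e-9)
        assert np.all(series.n_records == 1)

    def test_two_constant_loggers_average(self):
        mids = (np.arange(N_BINS) + 0.5) * 5.0 / 60.0
        df = pd.concat([
            to_frame(mids, np.full(N_BINS, 20.0), logger="A"),
            to_frame(mids, np.full(N_BINS, 30.0), logger="B", microenv="shade"),
        ])
        series = aggregate_to(df)
        assert np.allclose(series.mean_to, 25.0)
        assert np.all(series.n_records == 2)
        assert series.microenvs_included == ("shade", "soil_exposed")

    def test_two_days_pool_into_same_bins(self):
        # hand-computed toy: bin 06:00-06:05 gets 18 on day 1 and 22 on day 2
        df = pd.concat([
            to_frame([6.0, 12.0], [18.0, 30.0], day=0),
            to_frame([6.0, 12.0], [22.0, 34.0], day=1),
        ])
        series = aggregate_to(df)
        assert series.mean_to[72] == pytest.approx(20.0)   # bin 72 = 06:00
        assert series.mean_to[144] == pytest.approx(32.0)  # bin 144 = 12:00
        assert np.isnan(series.mean_to[0])
        assert series.n_records[72] == 2

    def test_microenv_subset_filtering(self):
        mids = (np.arange(N_BINS) + 0.5) * 5.0 / 60.0
        df = pd.concat([
            to_frame(mids, np.full(N_BINS, 40.0), microenv="soil_exposed"),
            to_frame(mids, np.full(N_BINS, 20.0), microenv="burrow", logger="B"),
        ])
        series = aggregate_to(df, microenvs=["burrow"])
        assert np.allclose(series.mean_to, 20.0)
        with pytest.raises(InputError):
            aggregate_to(df, microenvs=["lava_field"])

    def test_empty_input_rejected(self):
        with pytest.raises(InputError):
            aggregate_to(pd.DataFrame(columns=["timestamp", "temp_c"]))


class TestPotentialActivity:
    def test_constant_to_at_mode_is_uniform_weighting(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(18, 45, 400))
        series = series_from_values(np.full(N_BINS, 28.0))
        s = potential_activity(series, curve, n_out=5000, seed=1)
        counts = np.bincount((s.hours // 1.0).astype(int), minlength=24)
        from scipy.stats import chisquare

        _, p = chisquare(counts)
        assert p > 0.01
        assert s.role == "potential"

    def test_support_restriction_to_warm_window(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(18, 45, 400))
        vals = np.full(N_BINS, np.nan)
        vals[72:97] = 28.0  # 06:00-08:05 warm, everything else missing
        s = potential_activity(series_from_values(vals), curve, n_out=500, seed=2)
        assert np.all((s.hours >= 6.0) & (s.hours < 8.0 + 5.0 / 60.0))

    def test_fixed_seed_deterministic(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(18, 45, 400))
        series = series_from_values(
            diel_sinusoid((np.arange(N_BINS) + 0.5) / 12.0, 15.0, 40.0, 14.0)
        )
        s1 = potential_activity(series, curve, n_out=200, seed=9)
        s2 = potential_activity(series, curve, n_out=200, seed=9)
        assert np.array_equal(s1.angles, s2.angles)

    def test_empirical_frequencies_converge_to_weights(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(18, 45, 400))
        mids = (np.arange(N_BINS) + 0.5) / 12.0
        series = series_from_values(diel_sinusoid(mids, 12.0, 38.0, 14.0))
        w = curve.at(series.mean_to)
        w = w / w.sum()
        s = potential_activity(series, curve, n_out=100_000, seed=3)
        idx = np.round(s.hours * 12.0 - 0.5).astype(int) % N_BINS
        freq = np.bincount(idx, minlength=N_BINS) / s.n
        assert 0.5 * np.abs(freq - w).sum() < 0.02

    def test_cold_day_thermal_mismatch(self):
        rng = np.random.default_rng(12)
        fit = fit_pearson(30.0 + rng.gamma(9.0, 0.5, 5_000))
        curve = activity_probability(fit, np.linspace(30, 45, 200))
        series = series_from_values(np.full(N_BINS, 5.0))
        with pytest.raises(EstimationError):
            potential_activity(series, curve, n_out=100, seed=0)

    def test_invalid_n_out(self, gamma_fit):
        curve = activity_probability(gamma_fit, np.linspace(18, 45, 400))
        with pytest.raises(InputError):
            potential_activity(series_from_values(np.full(N_BINS, 28.0)),
                               curve, n_out=0, seed=0)


class TestThermalShiftRecovery:
    def test_hot_midday_gives_bimodal_potential_closest_to_unshifted(self):
        """With mid-day operative temperature far above preference, potential
        activity is bimodal, and it overlaps an unshifted copy of itself more
        than copies shifted by +/-1 h."""
        rng = np.random.default_rng(21)
        fit = fit_pearson(20.0 + rng.gamma(9.0, 1.0, 20_000))
        curve = activity_probability(fit, np.linspace(5, 55, 600))
        mids = (np.arange(N_BINS) + 0.5) / 12.0
        series = series_from_values(diel_sinusoid(mids, 8.0, 48.0, 14.0))
        pot = potential_activity(series, curve, n_out=4000, seed=5)
        dens = kde_circular(pot)
        n_modes = np.sum(
            (dens.values > np.roll(dens.values, 1))
            & (dens.values > np.roll(dens.values, -1))
        )
        assert n_modes == 2
        obs = potential_activity(series, curve, n_out=2000, seed=6)
        d_unshifted = overlap_delta(dens, kde_circular(obs))
        one_hour = 2.0 * np.pi / 24.0
        for shift in (+one_hour, -one_hour):
            d_shifted = overlap_delta(dens, kde_circular(obs.rotated(shift)))
            assert d_shifted < d_unshifted
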