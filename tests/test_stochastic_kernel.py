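"""Spread model, station LDD workflow, release scan and the kernel IBM."""

import numpy as np
import pandas as pd
import pytest

from anemochory.core_models import FlightConditions, gradient_distance
from anemochory.exceptions import DomainError
from anemochory.stochastic_kernel import (
    KernelConfig,
    WindRecord,
    dispersal_sd,
    max_dispersal_estimate,
    release_times,
    simulate_kernel,
)


def constant_wind_frame(gust, n=5, mean=None, height=10.0):
    return pd.DataFrame(
        {
            "timestamp": pd.date_range("2020-09-01", periods=n, freq="30min"),
            "mean_speed_ms": [mean if mean is not None else gust * 0.7] * n,
            "gust_ms": [gust] * n,
            "anemometer_height_m": [height] * n,
        }
    )


class TestDispersalSd:
    @pytest.mark.parametrize(
        "v, expected", [(12.0, 4.71), (17.0, 6.46), (0.0, 0.51)]
    )
    def test_linear_spread_model(self, v, expected):
        assert dispersal_sd(v) == pytest.approx(expected, abs=1e-9)

    def test_negative_wind_rejected(self):
        with pytest.raises(DomainError, match="wind_speed_ms"):
            dispersal_sd(-1.0)


class TestMaxDispersalEstimate:
    @pytest.mark.parametrize(
        "station_wind, v_t, corrected, distance, sd",
        [
            (16.0, 0.91, 12, 39, 5),  # Syktyvkar, slowest-falling mericarps
            (23.0, 0.91, 17, 56, 6),  # Kazan (closed form: 55.75 m)
            (16.0, 1.65, 12, 22, 5),  # Syktyvkar, median terminal velocity
            (23.0, 1.65, 17, 31, 6),  # Kazan, median terminal velocity
        ],
    )
    def test_station_workflow(self, station_wind, v_t, corrected, distance, sd):
        est = max_dispersal_estimate(station_wind, 3.85, v_t, alpha=0.29)
        assert est.corrected_wind_ms == corrected
        assert est.distance_m == distance
        assert est.sd_m == sd

    def test_rounding_applied_before_distance(self):
        # distance must use the integer-rounded corrected wind (12), not 12.13
        est = max_dispersal_estimate(16.0, 3.85, 0.91, alpha=0.29)
        expected = gradient_distance(FlightConditions(3.85, 12.0, 0.91, 0.29))
        assert est.distance_unrounded_m == pytest.approx(expected, rel=1e-12)

    def test_accepts_wind_record(self):
        rec = WindRecord(pd.Timestamp("2020-09-01"), 10.0, 16.0, 10.0)
        est = max_dispersal_estimate(rec, 3.85, 0.91)
        assert est.corrected_wind_ms == 12


class TestReleaseTimes:
    def test_zero_critical_releases_immediately(self):
        idx = release_times(constant_wind_frame(5.0), 0.0)
        assert idx[0] == 0

    def test_unreachable_critical_never_releases(self):
        idx = release_times(constant_wind_frame(5.0), 99.0)
        assert idx[0] == -1

    def test_first_crossing_scan(self):
        df = constant_wind_frame(1.0, n=3)
        df["gust_ms"] = [3.0, 5.0, 8.0]
        df["mean_speed_ms"] = [1.0, 1.0, 1.0]
        assert release_times(df, 6.0)[0] == 2
        assert release_times(df, np.array([2.0, 4.0, 6.0])).tolist() == [0, 1, 2]

    def test_unordered_series_rejected(self):
        df = constant_wind_frame(5.0, n=3)
        df["timestamp"] = df["timestamp"].iloc[::-1].to_numpy()
        with pytest.raises(DomainError, match="time-ordered"):
            release_times(df, 1.0)

    def test_gust_below_mean_rejected(self):
        with pytest.raises(DomainError, match="gust_ms"):
            WindRecord(pd.Timestamp("2020-09-01"), 5.0, 3.0)


class TestSimulateKernel:
    def degenerate_config(self, **overrides):
        kwargs = dict(
            n_propagules=50,
            seed=11,
            alpha=0.29,
            terminal_velocity_ms=0.91,
            release_height_m=3.85,
            critical_wind_ms=0.0,
            noise=False,
        )
        kwargs.update(overrides)
        return KernelConfig(**kwargs)

    def test_noise_off_equals_deterministic_distance(self):
        wind = constant_wind_frame(16.0)
        kernel = simulate_kernel(wind, self.degenerate_config())
        corrected = 16.0 * (3.85 / 10.0) ** 0.29
        expected = gradient_distance(FlightConditions(3.85, corrected, 0.91, 0.29))
        assert np.allclose(kernel.distances, expected, rtol=1e-12)

    def test_noise_on_kernel_matches_spread_model(self):
        wind = constant_wind_frame(16.0)
        config = self.degenerate_config(n_propagules=10_000, noise=True, seed=5)
        kernel = simulate_kernel(wind, config)
        corrected = 16.0 * (3.85 / 10.0) ** 0.29
        expected = gradient_distance(FlightConditions(3.85, corrected, 0.91, 0.29))
        sd = dispersal_sd(corrected)
        se = sd / np.sqrt(config.n_propagules)
        assert abs(kernel.distances.mean() - expected) < 3 * se
        assert abs(kernel.distances.std(ddof=1) - sd) / sd < 0.10

    def test_release_conservation(self):
        wind = constant_wind_frame(5.0)
        config = self.degenerate_config(critical_wind_ms=99.0)
        kernel = simulate_kernel(wind, config)
        assert kernel.n_released == 0
        assert kernel.n_not_released == config.n_propagules
        mixed = simulate_kernel(wind, self.degenerate_config(critical_wind_ms=(0.0, 15.0)))
        assert mixed.n_released + mixed.n_not_released == 50

    def test_distances_non_negative_even_with_noise(self):
        wind = constant_wind_frame(2.0)  # small distances, noise can dip below 0
        for mode in ("resample", "floor"):
            config = self.degenerate_config(
                n_propagules=2000, noise=True, noise_mode=mode, seed=3,
                terminal_velocity_ms=1.72, release_height_m=3.0,
            )
            kernel = simulate_kernel(wind, config)
            assert (kernel.distances >= 0).all()

    def test_same_seed_reproduces_kernel_exactly(self):
        wind = constant_wind_frame(9.0)
        cfg = self.degenerate_config(noise=True, critical_wind_ms=(0.0, 15.0))
        k1 = simulate_kernel(wind, cfg)
        k2 = simulate_kernel(wind, cfg)
        pd.testing.assert_frame_equal(k1.table, k2.table)
        k3 = simulate_kernel(wind, self.degenerate_config(noise=True, seed=12))
        assert not np.array_equal(k1.table["critical_wind_ms"], k3.table["critical_wind_ms"])

    def test_alpha_zero_noise_off_recovers_ballistic(self):
        wind = constant_wind_frame(8.0, height=3.85)  # anemometer at release height
        config = self.degenerate_config(alpha=0.0)
        kernel = simulate_kernel(wind, config)
        assert np.allclose(kernel.distances, 3.85 * 8.0 / 0.91, rtol=1e-12)

    def test_tail_quantile_grows_with_max_gust(self):
        cfg = self.degenerate_config(n_propagules=500, critical_wind_ms=(0.0, 15.0), noise=True)
        q99 = []
        for gust in (8.0, 12.0, 16.0):
            df = constant_wind_frame(gust, n=10)
            q99.append(simulate_kernel(df, cfg).quantiles()["q99"])
        assert q99[0] <= q99[1] <= q99[2]

    def test_trait_resampling_draws_from_supplied_table(self, north_traits):
        wind = constant_wind_frame(16.0)
        config = KernelConfig(
            n_propagules=300,
            seed=2,
            terminal_velocity_ms=north_traits["terminal_velocity_ms"].to_numpy(),
            release_height_m=3.0,
            critical_wind_ms=0.0,
            noise=False,
        )
        kernel = simulate_kernel(wind, config)
        sampled = set(np.round(kernel.table["v_t_ms"], 12))
        source = set(np.round(north_traits["terminal_velocity_ms"], 12))
        assert sampled <= source

    def test_exceedance_counts_against_threshold(self):
        wind = constant_wind_frame(16.0)
        kernel = simulate_kernel(wind, self.degenerate_config())
        # deterministic distance ~39.8 m: every propagule is beyond 10 m
        assert kernel.exceedance_counts()["beyond_10_m"] == 50
        summary = kernel.summary_dict()
        assert summary["n_released"] == 50
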