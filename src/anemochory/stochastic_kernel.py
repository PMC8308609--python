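"""Stochastic dispersal: spread model, LDD workflow and the kernel IBM.

Three layers on top of the deterministic flight models:

* :func:`dispersal_sd` — the empirical linear spread model
  ``D_sd = 0.35 * v + 0.51`` (metres) relating the standard deviation of
  landing distances within a batch to the wind speed ``v`` during release;
* :func:`max_dispersal_estimate` — the weather-station long-distance
  dispersal (LDD) workflow: correct the seasonal maximum station wind from
  anemometer height down to the release height via the Hellmann profile,
  then report the gradient-model distance ± the spread model's sd;
* :func:`simulate_kernel` — an individual-based model (IBM) that computes
  each propagule's release and flight separately: traits are resampled from
  empirical tables, each propagule detaches at the first wind record whose
  gust reaches its critical wind speed, and its flight distance is the
  gradient-model distance at the height-corrected gust plus optional
  spread-model noise.

The *gust* (not the period-mean speed) drives both release and flight,
because the maximum wind during a launch is the best predictor of the mean
landing distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .core_models import (
    DEFAULT_ALPHA,
    FlightConditions,
    WindProfilePoint,
    gradient_distance,
    wind_at_height,
)
from .exceptions import DomainError

#: Coefficients of the empirical spread model, metres per (m/s) and metres.
SPREAD_SLOPE = 0.35
SPREAD_INTERCEPT = 0.51

#: Landing distances beyond this are conventionally long-distance dispersal
#: for tall hogweeds.
LDD_THRESHOLD_M = 10.0


@dataclass(frozen=True)
class WindRecord:
    """One weather-station observation (typically every 30 min)."""

    timestamp: pd.Timestamp
    mean_speed_ms: float
    gust_ms: float
    anemometer_height_m: float = 10.0

    def __post_init__(self) -> None:
        if not self.anemometer_height_m > 0:
            raise DomainError(
                f"anemometer_height_m must be > 0, got {self.anemometer_height_m!r}"
            )
        if not 0 <= self.mean_speed_ms <= self.gust_ms:
            raise DomainError(
                f"need 0 <= mean_speed_ms <= gust_ms, got "
                f"{self.mean_speed_ms!r} vs {self.gust_ms!r}"
            )


def dispersal_sd(
    wind_speed_ms: float,
    slope: float = SPREAD_SLOPE,
    intercept: float = SPREAD_INTERCEPT,
) -> float:
    """Standard deviation of landing distances at wind speed ``v`` (metres).

    Identically shaped propagules dropped together land at different
    distances; the scatter grows linearly with wind speed.  Default
    coefficients are the empirical fit from launch experiments with
    standardised paper propagules.
    """
    if wind_speed_ms < 0:
        raise DomainError(f"wind_speed_ms must be >= 0, got {wind_speed_ms!r}")
    return slope * wind_speed_ms + intercept


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass(frozen=True)
class MaxDispersalEstimate:
    """Result of the weather-station LDD workflow (reported, rounded values
    plus the unrounded intermediates)."""

    corrected_wind_ms: int
    distance_m: int
    sd_m: int
    corrected_wind_unrounded_ms: float
    distance_unrounded_m: float
    sd_unrounded_m: float


def max_dispersal_estimate(
    station_wind: WindRecord | float,
    release_height_m: float,
    terminal_velocity_ms: float,
    alpha: float = DEFAULT_ALPHA,
    anemometer_height_m: float = 10.0,
) -> MaxDispersalEstimate:
    """Expected maximum dispersal distance from a station's maximum wind.

    The station wind (measured at anemometer height) is corrected down to
    the release height with the Hellmann profile and rounded to the nearest
    integer m/s — the reporting convention — *before* the gradient-model
    distance is computed and rounded to the nearest metre.  The attached sd
    is the spread model evaluated at the rounded corrected wind, rounded to
    the nearest metre.  Unrounded intermediates are retained alongside.
    """
    if isinstance(station_wind, WindRecord):
        speed = station_wind.gust_ms
        height = station_wind.anemometer_height_m
    else:
        speed = float(station_wind)
        height = anemometer_height_m
    corrected = wind_at_height(
        WindProfilePoint(speed_ms=speed, height_m=height), release_height_m, alpha
    )
    corrected_rounded = _round_half_up(corrected)
    cond = FlightConditions(
        release_height_m=release_height_m,
        wind_at_release_ms=float(corrected_rounded),
        terminal_velocity_ms=terminal_velocity_ms,
        hellmann_alpha=alpha,
    )
    distance = gradient_distance(cond)
    sd = dispersal_sd(float(corrected_rounded))
    return MaxDispersalEstimate(
        corrected_wind_ms=corrected_rounded,
        distance_m=_round_half_up(distance),
        sd_m=_round_half_up(sd),
        corrected_wind_unrounded_ms=corrected,
        distance_unrounded_m=distance,
        sd_unrounded_m=sd,
    )


def _as_wind_frame(wind_series: pd.DataFrame | Sequence[WindRecord]) -> pd.DataFrame:
    if isinstance(wind_series, pd.DataFrame):
        df = wind_series.copy()
        df["timestamp"] = pd.to_datetime(df["timestamp"])
    else:
        df = pd.DataFrame(
            {
                "timestamp": [r.timestamp for r in wind_series],
                "mean_speed_ms": [r.mean_speed_ms for r in wind_series],
                "gust_ms": [r.gust_ms for r in wind_series],
                "anemometer_height_m": [r.anemometer_height_m for r in wind_series],
            }
        )
    if len(df) == 0:
        raise DomainError("wind series is empty")
    if not df["timestamp"].is_monotonic_increasing:
        raise DomainError("wind series must be time-ordered (ascending timestamps)")
    return df


def release_times(
    wind_series: pd.DataFrame | Sequence[WindRecord],
    critical_wind_ms: float | np.ndarray,
) -> np.ndarray:
    """Index of the first record whose gust reaches each critical wind.

    A propagule detaches at the first wind record whose gust is at least
    its critical wind speed; if no record qualifies it stays on the umbel
    for the season (index -1).  Accepts a scalar or an array of critical
    winds; returns an int array of record indices.
    """
    df = _as_wind_frame(wind_series)
    gusts = df["gust_ms"].to_numpy(dtype=float)
    crit = np.atleast_1d(np.asarray(critical_wind_ms, dtype=float))
    # running max of gusts is non-decreasing: first crossing via searchsorted
    runmax = np.maximum.accumulate(gusts)
    idx = np.searchsorted(runmax, crit, side="left")
    return np.where(idx < len(gusts), idx, -1)


@dataclass(frozen=True)
class KernelConfig:
    """Configuration of one kernel simulation.

    ``terminal_velocity_ms`` and ``release_height_m`` may each be a fixed
    scalar or a 1-D array of empirical values to resample from (with
    replacement).  ``critical_wind_ms`` is either a fixed scalar or a
    ``(low, high)`` tuple for a uniform draw — the default Uniform(0, 15)
    m/s spans release at almost-zero wind up to propagules that survive
    >15 m/s gusts.  ``seed`` is mandatory: no hidden global random state.
    """

    n_propagules: int
    seed: int
    alpha: float = DEFAULT_ALPHA
    terminal_velocity_ms: float | np.ndarray = 1.62
    release_height_m: float | np.ndarray = 3.0
    critical_wind_ms: float | tuple[float, float] = (0.0, 15.0)
    noise: bool = True
    noise_mode: str = "resample"  # or "floor"
    spread_slope: float = SPREAD_SLOPE
    spread_intercept: float = SPREAD_INTERCEPT
    ldd_thresholds_m: tuple[float, ...] = (LDD_THRESHOLD_M,)

    def __post_init__(self) -> None:
        if self.n_propagules < 1:
            raise DomainError(f"n_propagules must be >= 1, got {self.n_propagules!r}")
        if self.noise_mode not in ("resample", "floor"):
            raise DomainError(f"noise_mode must be 'resample' or 'floor', got {self.noise_mode!r}")
        if self.seed is None:
            raise DomainError("seed is mandatory for kernel simulations")


@dataclass
class DispersalKernel:
    """Simulated distribution of landing distances.

    ``table`` has one row per propagule (released or not); ``distances``
    are the landing distances of released propagules only.
    """

    table: pd.DataFrame
    config: KernelConfig

    @property
    def distances(self) -> np.ndarray:
        return self.table.loc[self.table["released"], "distance_m"].to_numpy(dtype=float)

    @property
    def n_released(self) -> int:
        return int(self.table["released"].sum())

    @property
    def n_not_released(self) -> int:
        return len(self.table) - self.n_released

    def quantiles(self) -> dict[str, float]:
        d = self.distances
        if d.size == 0:
            return {"median": np.nan, "q95": np.nan, "q99": np.nan, "max": np.nan}
        return {
            "median": float(np.median(d)),
            "q95": float(np.percentile(d, 95)),
            "q99": float(np.percentile(d, 99)),
            "max": float(d.max()),
        }

    def exceedance_counts(self) -> dict[str, int]:
        d = self.distances
        return {
            f"beyond_{thr:g}_m": int((d > thr).sum())
            for thr in self.config.ldd_thresholds_m
        }

    def summary_dict(self) -> dict:
        return {
            "n_propagules": int(len(self.table)),
            "n_released": self.n_released,
            "n_not_released": self.n_not_released,
            "quantiles_m": self.quantiles(),
            "exceedance": self.exceedance_counts(),
        }

    def plot(self, ax=None, bins: int = 50):
        """Histogram of the simulated landing distances."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.hist(self.distances, bins=bins, color="tab:green", alpha=0.8)
        ax.set_xlabel("landing distance (m)")
        ax.set_ylabel("propagules")
        return ax


def _sample(source: float | np.ndarray, n: int, rng: np.random.Generator) -> np.ndarray:
    arr = np.asarray(source, dtype=float)
    if arr.ndim == 0:
        return np.full(n, float(arr))
    if arr.size == 0:
        raise DomainError("empirical trait sample is empty; cannot resample")
    return rng.choice(arr, size=n, replace=True)


def simulate_kernel(
    wind_series: pd.DataFrame | Sequence[WindRecord],
    config: KernelConfig,
) -> DispersalKernel:
    """Individual-based kernel simulation over a wind series.

    For each propagule: draw its terminal velocity, release height and
    critical wind; find its release record (first gust >= critical wind);
    correct that gust from anemometer height to the release height via the
    Hellmann profile; compute the gradient-model distance; optionally add
    zero-mean Gaussian noise with the spread model's sd (negative draws
    resampled, or floored at 0, per ``noise_mode``).  Deterministic given
    ``config.seed``.
    """
    df = _as_wind_frame(wind_series)
    rng = np.random.default_rng(config.seed)
    n = config.n_propagules

    v_t = _sample(config.terminal_velocity_ms, n, rng)
    h_r = _sample(config.release_height_m, n, rng)
    if np.any(v_t <= 0):
        raise DomainError("sampled terminal velocities must be > 0")
    if np.any(h_r <= 0):
        raise DomainError("sampled release heights must be > 0")
    if isinstance(config.critical_wind_ms, tuple):
        lo, hi = config.critical_wind_ms
        critical = rng.uniform(lo, hi, size=n)
    else:
        critical = np.full(n, float(config.critical_wind_ms))

    idx = release_times(df, critical)
    released = idx >= 0
    safe_idx = np.where(released, idx, 0)

    gusts = df["gust_ms"].to_numpy(dtype=float)[safe_idx]
    anemo = df["anemometer_height_m"].to_numpy(dtype=float)[safe_idx]
    timestamps = df["timestamp"].to_numpy()[safe_idx]

    corrected = gusts * (h_r / anemo) ** config.alpha
    distance = h_r * corrected / (v_t * (1.0 + config.alpha))

    if config.noise:
        sd = config.spread_slope * corrected + config.spread_intercept
        noisy = distance + rng.normal(0.0, 1.0, size=n) * sd
        if config.noise_mode == "floor":
            distance = np.maximum(noisy, 0.0)
        else:  # resample negative draws until non-negative
            bad = noisy < 0
            while np.any(bad):
                noisy[bad] = distance[bad] + rng.normal(0.0, 1.0, size=int(bad.sum())) * sd[bad]
                bad = noisy < 0
            distance = noisy

    table = pd.DataFrame(
        {
            "propagule_id": [f"p{i:06d}" for i in range(n)],
            "released": released,
            "release_timestamp": np.where(released, timestamps, np.datetime64("NaT")),
            "critical_wind_ms": critical,
            "v_t_ms": v_t,
            "h_r_m": h_r,
            "corrected_wind_ms": np.where(released, corrected, np.nan),
            "distance_m": np.where(released, distance, np.nan),
        }
    )
    return DispersalKernel(table=table, config=config)
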