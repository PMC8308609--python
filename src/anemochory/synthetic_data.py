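"""Synthetic input tables with the statistical structure of the field study.

Every other module consumes one of four table kinds: propagule traits,
drop-timing trials, launch experiments (distances + per-launch winds) and
weather-station wind series.  This module generates all four so the whole
pipeline is exercisable without any external dataset.

What the generator emulates — and what it does not — is documented in
docs/methods.md.  In brief: trait marginals are log-normal (positive,
right-skewed, median ≈ mean as observed), matched to the target median and
IQR in closed form; terminal velocity is driven linearly by wing loading
with Gaussian noise calibrated so wing loading explains ~80 % of its
variance; launch distances follow the wind-gradient model at the true
Hellmann exponent plus the linear spread model's Gaussian noise, floored at
zero; wind series are Weibull-mean records with proportional gusts at a
30-min cadence.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_models import DEFAULT_ALPHA
from .exceptions import DomainError
from .stochastic_kernel import SPREAD_INTERCEPT, SPREAD_SLOPE

# distinct sub-streams so the four table kinds are independently seeded
_STREAM_TRAITS, _STREAM_LAUNCH, _STREAM_WIND, _STREAM_DROPS = 1, 2, 3, 4


@dataclass(frozen=True)
class TraitTargets:
    """Median/IQR targets for the log-normal trait marginals (one group)."""

    mass_median_mg: float
    mass_iqr_mg: float
    area_median_cm2: float
    area_iqr_cm2: float
    vt_median_ms: float
    vt_sd_ms: float
    vt_r2: float = 0.8  # variance share of V_t explained by wing loading


#: Field-study trait targets per group: natural mericarps from the northern
#: population (N = 70 in the study; median mass 11.0 mg, area 0.56 cm²,
#: fall speed 1.62 m/s) and the standardised artificial paper propagules
#: (median mass 21.5 mg, area 0.966 cm², terminal velocity 1.72 m/s).
#: The southern population's flight-relevant traits were statistically
#: indistinguishable from the northern ones, so it shares the targets.
GROUP_PRESETS: dict[str, TraitTargets] = {
    "north": TraitTargets(11.0, 3.2, 0.56, 0.17, 1.62, 0.25),
    "south": TraitTargets(11.0, 3.2, 0.56, 0.17, 1.62, 0.25),
    "artificial": TraitTargets(21.5, 0.5, 0.966, 0.018, 1.72, 0.0815),
}


@dataclass(frozen=True)
class GeneratorSpec:
    """All knobs of the synthetic-data generator, with study defaults."""

    seed: int
    # launch experiment: 37 launches of 8–20 propagules at 0–9 m/s winds
    n_launches: int = 37
    batch_size_range: tuple[int, int] = (8, 20)
    wind_range_ms: tuple[float, float] = (0.0, 9.0)
    alpha_true: float = DEFAULT_ALPHA
    launch_release_height_m: float = 3.0
    launch_terminal_velocity_ms: float = 1.72
    spread_slope: float = SPREAD_SLOPE
    spread_intercept: float = SPREAD_INTERCEPT
    launch_noise: bool = True
    v_mean_fraction: float = 0.8  # v_mean / v_max within a launch
    v_median_fraction: float = 0.75  # v_median / v_max within a launch
    # wind series: 30-min station records over a dispersal season
    record_interval_min: int = 30
    season_days: int = 92
    anemometer_height_m: float = 10.0
    wind_weibull_shape: float = 2.0
    wind_weibull_scale_ms: float = 4.0
    gust_factor: float = 1.5
    max_gust_ms: float | None = None
    # drop trials
    drop_release_height_m: float = 2.68
    drop_replicates: int = 5
    drop_timing_cv: float = 0.03

    def __post_init__(self) -> None:
        if self.seed is None:
            raise DomainError("GeneratorSpec.seed is mandatory")
        if self.n_launches < 1:
            raise DomainError("n_launches must be >= 1")
        lo, hi = self.batch_size_range
        if not 1 <= lo <= hi:
            raise DomainError(f"invalid batch_size_range {self.batch_size_range!r}")
        if not 0 <= self.wind_range_ms[0] < self.wind_range_ms[1]:
            raise DomainError(f"invalid wind_range_ms {self.wind_range_ms!r}")
        if self.v_median_fraction > 1 or self.v_mean_fraction > 1:
            raise DomainError("wind aggregate fractions must be <= 1")


def _rng(spec: GeneratorSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng([spec.seed, stream])


def _lognormal_params(median: float, iqr: float) -> tuple[float, float]:
    """(mu, sigma) of a log-normal with the given median and IQR.

    For X ~ LogNormal(mu, sigma): median = exp(mu) and
    IQR = exp(mu) * 2 sinh(z75 * sigma) with z75 = 0.674490 the upper
    quartile of the standard normal, hence sigma in closed form.
    """
    if median <= 0 or iqr < 0:
        raise DomainError(f"invalid median/IQR targets ({median!r}, {iqr!r})")
    z75 = 0.6744897501960817
    sigma = np.arcsinh(iqr / (2.0 * median)) / z75
    return np.log(median), sigma


def generate_traits(
    spec: GeneratorSpec, n: int = 70, group: str = "north"
) -> pd.DataFrame:
    """Synthetic propagule trait table (one row per propagule).

    Columns: ``propagule_id, group, mass_mg, area_cm2, terminal_velocity_ms``.
    Mass and area are independent log-normals matched to the group's
    median/IQR targets; terminal velocity is a linear function of the
    resulting wing loading plus Gaussian noise, scaled so wing loading
    explains ``vt_r2`` of its variance and the median sits at the target.
    """
    if n < 1:
        raise DomainError(f"n must be >= 1, got {n!r}")
    if group not in GROUP_PRESETS:
        raise DomainError(f"unknown group {group!r}; options: {sorted(GROUP_PRESETS)}")
    t = GROUP_PRESETS[group]
    rng = _rng(spec, _STREAM_TRAITS)

    mu_m, sg_m = _lognormal_params(t.mass_median_mg, t.mass_iqr_mg)
    mu_a, sg_a = _lognormal_params(t.area_median_cm2, t.area_iqr_cm2)
    mass = rng.lognormal(mu_m, sg_m, size=n)
    area = rng.lognormal(mu_a, sg_a, size=n)
    wl = (mass / 1000.0) / area

    # heavier-loaded propagules fall faster; slope fixes the target R^2
    wl_sd = float(np.std(wl)) if n > 1 else 0.0
    if wl_sd > 0 and t.vt_r2 > 0:
        slope = np.sqrt(t.vt_r2) * t.vt_sd_ms / wl_sd
    else:
        slope = 0.0
    noise_sd = np.sqrt(max(1.0 - t.vt_r2, 0.0)) * t.vt_sd_ms
    vt = (
        t.vt_median_ms
        + slope * (wl - float(np.median(wl)))
        + rng.normal(0.0, noise_sd, size=n)
    )
    vt = np.clip(vt, 0.2, None)  # keep draws physical

    return pd.DataFrame(
        {
            "propagule_id": [f"{group[:1]}{i:04d}" for i in range(n)],
            "group": group,
            "mass_mg": mass,
            "area_cm2": area,
            "terminal_velocity_ms": vt,
        }
    )


def generate_launch_experiment(
    spec: GeneratorSpec,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic launch experiment: (launch table, launch-wind table).

    Launch table columns: ``launch_id, release_height_m, distance_m`` (one
    row per propagule); wind table: ``launch_id, v_median_ms, v_mean_ms,
    v_max_ms``.  Per launch, ``v_max`` is uniform over the configured wind
    range and the batch size uniform over its range; per propagule the
    landing distance is the gradient-model distance at ``alpha_true`` plus
    zero-mean Gaussian noise with the spread model's sd, floored at zero.
    """
    rng = _rng(spec, _STREAM_LAUNCH)
    lo, hi = spec.batch_size_range
    launch_rows, wind_rows = [], []
    for i in range(spec.n_launches):
        launch_id = f"L{i + 1:03d}"
        v_max = rng.uniform(*spec.wind_range_ms)
        n_prop = int(rng.integers(lo, hi + 1))
        base = (
            spec.launch_release_height_m
            * v_max
            / (spec.launch_terminal_velocity_ms * (1.0 + spec.alpha_true))
        )
        if spec.launch_noise:
            sd = spec.spread_slope * v_max + spec.spread_intercept
            dist = np.maximum(base + rng.normal(0.0, sd, size=n_prop), 0.0)
        else:
            dist = np.full(n_prop, base)
        for d in dist:
            launch_rows.append(
                {
                    "launch_id": launch_id,
                    "release_height_m": spec.launch_release_height_m,
                    "distance_m": float(d),
                }
            )
        wind_rows.append(
            {
                "launch_id": launch_id,
                "v_median_ms": spec.v_median_fraction * v_max,
                "v_mean_ms": spec.v_mean_fraction * v_max,
                "v_max_ms": v_max,
            }
        )
    return pd.DataFrame(launch_rows), pd.DataFrame(wind_rows)


def generate_wind_series(spec: GeneratorSpec) -> pd.DataFrame:
    """Synthetic weather-station series at the configured cadence.

    Columns: ``timestamp, mean_speed_ms, gust_ms, anemometer_height_m``.
    Mean speeds are Weibull draws (shape ~2 is typical of surface winds);
    gusts are proportionally inflated means with non-negative extra jitter,
    so ``gust >= mean`` holds per record.  When ``max_gust_ms`` is set the
    whole series is rescaled so the seasonal maximum gust equals it exactly
    (emulating a station's seasonal maximum).
    """
    rng = _rng(spec, _STREAM_WIND)
    n = int(spec.season_days * 24 * 60 / spec.record_interval_min)
    timestamps = pd.date_range(
        "2020-08-01", periods=n, freq=f"{spec.record_interval_min}min", tz="UTC"
    )
    mean = spec.wind_weibull_scale_ms * rng.weibull(spec.wind_weibull_shape, size=n)
    gust = mean * (spec.gust_factor + np.abs(rng.normal(0.0, 0.2, size=n)))
    if spec.max_gust_ms is not None:
        peak = float(gust.max())
        if peak <= 0:
            raise DomainError("cannot rescale an all-zero wind series")
        factor = spec.max_gust_ms / peak
        mean *= factor
        gust *= factor
    return pd.DataFrame(
        {
            "timestamp": timestamps,
            "mean_speed_ms": mean,
            "gust_ms": gust,
            "anemometer_height_m": spec.anemometer_height_m,
        }
    )


def generate_drop_trials(
    spec: GeneratorSpec, traits: pd.DataFrame
) -> pd.DataFrame:
    """Synthetic drop-timing trials for a trait table with terminal velocities.

    Each propagule is timed ``drop_replicates`` times falling from
    ``drop_release_height_m``; replicate times are the true fall time
    ``h / V_t`` with multiplicative Gaussian timing error of coefficient of
    variation ``drop_timing_cv`` (stopwatch error).
    """
    if "terminal_velocity_ms" not in traits.columns:
        raise DomainError("trait table lacks terminal_velocity_ms; cannot time drops")
    rng = _rng(spec, _STREAM_DROPS)
    rows = []
    h = spec.drop_release_height_m
    for _, row in traits.iterrows():
        t_true = h / float(row["terminal_velocity_ms"])
        times = t_true * (1.0 + rng.normal(0.0, spec.drop_timing_cv, size=spec.drop_replicates))
        times = np.maximum(times, 1e-3)
        record = {"propagule_id": row["propagule_id"], "release_height_m": h}
        for j, tv in enumerate(times, start=1):
            record[f"t{j}_s"] = float(tv)
        rows.append(record)
    return pd.DataFrame(rows)
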