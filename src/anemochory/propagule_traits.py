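"""Propagule trait computation.

Wing loading, terminal velocity from timed drop trials, Table-style trait
summaries and ordinary least-squares trait→velocity regressions.

Conventions fixed here (and relied on elsewhere):

* masses travel through files in **milligrams** and are converted to grams
  only inside :func:`wing_loading`, whose output is g/cm²;
* the quartiles behind the IQR use linear interpolation of the empirical
  distribution (numpy's default), and the median of an even number of
  replicates is the midpoint of the central pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .exceptions import DomainError

#: Trait columns summarised by :func:`summarize_traits`, in report order.
TRAIT_COLUMNS = ("mass_mg", "area_cm2", "wing_loading_g_cm2", "terminal_velocity_ms")


@dataclass(frozen=True)
class Propagule:
    """One mericarp (real or artificial paper model)."""

    id: str
    group: str
    mass_mg: float
    area_cm2: float
    terminal_velocity_ms: float | None = None
    critical_wind_ms: float | None = None

    def __post_init__(self) -> None:
        if not self.mass_mg > 0:
            raise DomainError(f"mass_mg must be > 0, got {self.mass_mg!r}")
        if not self.area_cm2 > 0:
            raise DomainError(f"area_cm2 must be > 0, got {self.area_cm2!r}")

    @property
    def wing_loading_g_cm2(self) -> float:
        return wing_loading(self.mass_mg, self.area_cm2)


@dataclass(frozen=True)
class DropTrial:
    """One timed-fall experiment: a release height and replicate fall times."""

    propagule_id: str
    release_height_m: float
    fall_times_s: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.release_height_m > 0:
            raise DomainError(
                f"release_height_m must be > 0, got {self.release_height_m!r}"
            )
        if len(self.fall_times_s) == 0:
            raise DomainError("fall_times_s must contain at least one replicate")
        if any(t <= 0 for t in self.fall_times_s):
            raise DomainError(f"all fall times must be > 0, got {self.fall_times_s!r}")


@dataclass(frozen=True)
class TraitSummary:
    """The five summary statistics reported per trait, plus the sample size."""

    mean: float
    median: float
    sd: float
    iqr: float
    sem: float
    n: int


def wing_loading(mass_mg: float, area_cm2: float) -> float:
    """Wing loading WL = mass (g) / one-side area (cm²), in g/cm².

    Masses arrive in milligrams (the unit used in trait tables) and are
    converted to grams here.
    """
    if not mass_mg > 0:
        raise DomainError(f"mass_mg must be > 0, got {mass_mg!r}")
    if not area_cm2 > 0:
        raise DomainError(f"area_cm2 must be > 0, got {area_cm2!r}")
    return (mass_mg / 1000.0) / area_cm2


def terminal_velocity_from_drops(trial: DropTrial) -> float:
    """Terminal velocity estimate V_t = h / median(fall times), m/s.

    The median over replicates (nominally five) damps stopwatch error; an
    even replicate count uses the midpoint of the two central values.
    """
    return trial.release_height_m / float(np.median(trial.fall_times_s))


def _summary(values: np.ndarray) -> TraitSummary:
    n = values.size
    sd = float(np.std(values, ddof=1))
    q1, q3 = np.percentile(values, [25, 75])
    return TraitSummary(
        mean=float(np.mean(values)),
        median=float(np.median(values)),
        sd=sd,
        iqr=float(q3 - q1),
        sem=sd / float(np.sqrt(n)),
        n=n,
    )


def summarize_traits(
    propagules: pd.DataFrame | Iterable[Propagule],
) -> dict[str, TraitSummary]:
    """Per-trait mean, median, sd, IQR and SEM for a trait table.

    Accepts either a trait DataFrame (``mass_mg``, ``area_cm2``, optional
    ``terminal_velocity_ms``; ``wing_loading_g_cm2`` is derived if absent)
    or an iterable of :class:`Propagule`.  Requires at least two rows (the
    sample standard deviation is undefined otherwise).
    """
    if not isinstance(propagules, pd.DataFrame):
        rows = list(propagules)
        df = pd.DataFrame(
            {
                "mass_mg": [p.mass_mg for p in rows],
                "area_cm2": [p.area_cm2 for p in rows],
                "terminal_velocity_ms": [p.terminal_velocity_ms for p in rows],
            }
        )
    else:
        df = propagules.copy()
    if len(df) < 2:
        raise DomainError("summarize_traits needs N >= 2 (sd undefined for N < 2)")
    if "wing_loading_g_cm2" not in df.columns:
        df["wing_loading_g_cm2"] = (df["mass_mg"] / 1000.0) / df["area_cm2"]
    out: dict[str, TraitSummary] = {}
    for trait in TRAIT_COLUMNS:
        if trait not in df.columns:
            continue
        values = df[trait].dropna().to_numpy(dtype=float)
        if values.size < 2:
            continue
        out[trait] = _summary(values)
    return out


def summary_frame(summaries: Mapping[str, TraitSummary]) -> pd.DataFrame:
    """Arrange trait summaries as a statistics × traits table."""
    rows = ["mean", "median", "sd", "iqr", "sem", "n"]
    data = {
        trait: [s.mean, s.median, s.sd, s.iqr, s.sem, s.n]
        for trait, s in summaries.items()
    }
    return pd.DataFrame(data, index=rows)


@dataclass(frozen=True)
class TraitRegression:
    """OLS fit of terminal velocity on a single propagule trait."""

    predictor: str
    slope: float
    intercept: float
    r_squared: float
    slope_se: float
    p_value: float
    n: int


def velocity_trait_regression(
    propagules: pd.DataFrame, predictor: str
) -> TraitRegression:
    """Regress measured terminal velocity on one trait by OLS with intercept.

    ``predictor`` is one of ``mass_mg``, ``area_cm2`` or
    ``wing_loading_g_cm2`` (derived on the fly when absent).  Untransformed
    linear regression: wing loading typically explains the bulk (>80 %) of
    terminal-velocity variance, mass roughly half.
    """
    df = propagules.copy()
    if predictor == "wing_loading_g_cm2" and predictor not in df.columns:
        df[predictor] = (df["mass_mg"] / 1000.0) / df["area_cm2"]
    if predictor not in df.columns:
        raise DomainError(f"unknown predictor column {predictor!r}")
    sub = df[[predictor, "terminal_velocity_ms"]].dropna()
    if len(sub) < 3:
        raise DomainError("velocity_trait_regression needs N >= 3 complete rows")
    x = sub[predictor].to_numpy(dtype=float)
    y = sub["terminal_velocity_ms"].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise DomainError(f"predictor {predictor!r} is constant; OLS undefined")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    # a constant response has zero explainable variance: R^2 is 0, not NaN
    r_squared = float(fit.rsquared) if np.ptp(y) > 0 else 0.0
    return TraitRegression(
        predictor=predictor,
        slope=float(fit.params[1]),
        intercept=float(fit.params[0]),
        r_squared=r_squared,
        slope_se=float(fit.bse[1]),
        p_value=float(fit.pvalues[1]),
        n=len(sub),
    )


def drop_trials_from_frame(df: pd.DataFrame) -> list[DropTrial]:
    """Build :class:`DropTrial` objects from a drop-trial table.

    Expects ``propagule_id``, ``release_height_m`` and replicate columns
    ``t1_s`` … ``t5_s``; trailing replicate cells may be empty.
    """
    time_cols = [c for c in df.columns if c.startswith("t") and c.endswith("_s")]
    trials = []
    for _, row in df.iterrows():
        times = tuple(
            float(row[c]) for c in time_cols if pd.notna(row[c])
        )
        trials.append(
            DropTrial(
                propagule_id=str(row["propagule_id"]),
                release_height_m=float(row["release_height_m"]),
                fall_times_s=times,
            )
        )
    return trials
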