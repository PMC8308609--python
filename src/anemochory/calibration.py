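"""Calibration of the Hellmann exponent against field launch experiments.

A launch experiment releases a batch of propagules of known terminal
velocity from a fixed height while logging the wind; each launch yields a
set of landing distances plus aggregated wind speeds (median, mean, max).
The maximum wind during a launch is the covariate that best predicts the
mean landing distance, so the calibration regresses the empirical per-launch
mean distance on the gradient-model prediction driven by ``v_max``, sweeping
the Hellmann exponent over a grid and picking the value whose regression
slope is closest to 1 (model on the 1:1 line with the data).

:class:`AlphaCalibration` is the model object (built from launch records or
from the launch/launch-wind tables); its :meth:`~AlphaCalibration.fit`
returns an :class:`AlphaCalibrationResults` carrying the per-alpha sweep,
the optimum, its diagnostics and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .core_models import DEFAULT_ALPHA, FlightConditions, ballistic_distance, gradient_distance
from .exceptions import DomainError

#: Grid swept by default: 0.05 to 0.50 in steps of 0.01.
DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.05, 0.5001, 0.01), 2))

#: Distance aggregates and wind covariates examined by correlate_aggregates.
DISTANCE_AGGREGATES = ("D_min", "D_median", "D_mean", "D_max")
WIND_COVARIATES = ("v_median_ms", "v_mean_ms", "v_max_ms")


@dataclass(frozen=True)
class LaunchRecord:
    """One batch release: landing distances plus wind aggregates."""

    launch_id: str
    release_height_m: float
    distances_m: tuple[float, ...]
    wind_median_ms: float
    wind_mean_ms: float
    wind_max_ms: float

    def __post_init__(self) -> None:
        if not self.release_height_m > 0:
            raise DomainError(
                f"release_height_m must be > 0, got {self.release_height_m!r}"
            )
        if len(self.distances_m) == 0:
            raise DomainError(f"launch {self.launch_id}: no distances")
        if any(d < 0 for d in self.distances_m):
            raise DomainError(f"launch {self.launch_id}: distances must be >= 0")
        for name in ("wind_median_ms", "wind_mean_ms"):
            v = getattr(self, name)
            if not 0 <= v <= self.wind_max_ms:
                raise DomainError(
                    f"launch {self.launch_id}: need 0 <= {name} <= wind_max_ms, "
                    f"got {v!r} vs {self.wind_max_ms!r}"
                )


@dataclass(frozen=True)
class LaunchAggregate:
    """Order statistics of one launch's landing distances."""

    launch_id: str
    release_height_m: float
    D_min: float
    D_median: float
    D_mean: float
    D_max: float
    D_iqr: float
    n_propagules: int
    v_median_ms: float
    v_mean_ms: float
    v_max_ms: float


def aggregate_launch(record: LaunchRecord) -> LaunchAggregate:
    """Min / median / mean / max (and IQR) of one launch's distances."""
    d = np.asarray(record.distances_m, dtype=float)
    q1, q3 = np.percentile(d, [25, 75])
    return LaunchAggregate(
        launch_id=record.launch_id,
        release_height_m=record.release_height_m,
        D_min=float(d.min()),
        D_median=float(np.median(d)),
        D_mean=float(d.mean()),
        D_max=float(d.max()),
        D_iqr=float(q3 - q1),
        n_propagules=d.size,
        v_median_ms=record.wind_median_ms,
        v_mean_ms=record.wind_mean_ms,
        v_max_ms=record.wind_max_ms,
    )


def aggregates_frame(aggregates: Iterable[LaunchAggregate]) -> pd.DataFrame:
    return pd.DataFrame([vars(a) for a in aggregates])


def correlate_aggregates(
    aggregates: Sequence[LaunchAggregate],
) -> tuple[pd.DataFrame, tuple[str, str]]:
    """Pearson r (and p) for every wind-covariate × distance-aggregate pair.

    Returns the long-format correlation table and the ``(wind, distance)``
    pair with the largest |r|.  Raises on constant covariates, for which the
    correlation is undefined.
    """
    if len(aggregates) < 3:
        raise DomainError("correlate_aggregates needs at least 3 launches")
    df = aggregates_frame(aggregates)
    rows = []
    for wind in WIND_COVARIATES:
        w = df[wind].to_numpy(dtype=float)
        if np.ptp(w) == 0:
            raise DomainError(f"wind covariate {wind} is constant; correlation undefined")
        for dist in DISTANCE_AGGREGATES:
            r, p = stats.pearsonr(w, df[dist].to_numpy(dtype=float))
            rows.append({"wind": wind, "distance": dist, "r": r, "p_value": p})
    table = pd.DataFrame(rows)
    best = table.loc[table["r"].abs().idxmax()]
    return table, (str(best["wind"]), str(best["distance"]))


def predict_launch_mean(
    aggregate: LaunchAggregate,
    model: str = "gradient",
    alpha: float = DEFAULT_ALPHA,
    terminal_velocity_ms: float = 1.72,
    wind_covariate: str = "v_max_ms",
) -> float:
    """Modelled mean landing distance for one launch.

    Drives the chosen flight model with the launch's wind covariate
    (default ``v_max_ms``) at the launch release height.
    """
    wind = getattr(aggregate, wind_covariate)
    if wind == 0:
        return 0.0
    cond = FlightConditions(
        release_height_m=aggregate.release_height_m,
        wind_at_release_ms=wind,
        terminal_velocity_ms=terminal_velocity_ms,
        hellmann_alpha=alpha,
    )
    if model == "ballistic":
        return ballistic_distance(cond)
    if model == "gradient":
        return gradient_distance(cond)
    raise DomainError(f"unknown model {model!r}; expected 'ballistic' or 'gradient'")


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Slope, intercept and R² of y on x (with intercept), from sums."""
    xm, ym = x.mean(), y.mean()
    sxx = float(((x - xm) ** 2).sum())
    if sxx == 0:
        raise DomainError("modelled distances are constant; regression undefined")
    sxy = float(((x - xm) * (y - ym)).sum())
    slope = sxy / sxx
    intercept = ym - slope * xm
    syy = float(((y - ym) ** 2).sum())
    r2 = 0.0 if syy == 0 else (sxy * sxy) / (sxx * syy)
    return slope, intercept, r2


@dataclass
class AlphaCalibrationResults:
    """Results of a Hellmann-exponent sweep.

    Attributes
    ----------
    alpha_opt
        Grid value whose empirical-on-modelled regression slope is closest
        to 1 (ties broken toward smaller alpha).
    sweep
        DataFrame with one row per grid alpha: slope, intercept, R².
    pearson_r, pearson_p
        Correlation between empirical and modelled mean distances at
        ``alpha_opt``.
    ks_statistic, ks_p
        Two-sample Kolmogorov–Smirnov comparison of the pooled empirical
        landing distances against the modelled distances (launch values
        repeated once per propagule) at ``alpha_opt``.
    """

    alpha_opt: float
    sweep: pd.DataFrame
    slope: float
    intercept: float
    r_squared: float
    pearson_r: float
    pearson_p: float
    ks_statistic: float
    ks_p: float
    terminal_velocity_ms: float
    n_launches: int
    model: "AlphaCalibration" = field(repr=False)

    def predict(self, alpha: float | None = None) -> np.ndarray:
        """Modelled per-launch mean distances at ``alpha`` (default optimum)."""
        return self.model.modelled_means(self.alpha_opt if alpha is None else alpha)

    def summary(self) -> str:
        """Plain-text summary table in the style of regression results."""
        at = self.sweep[self.sweep["alpha"] == self.alpha_opt].iloc[0]
        lines = [
            "Hellmann exponent calibration",
            "=" * 46,
            f"Launches:              {self.n_launches}",
            f"Terminal velocity:     {self.terminal_velocity_ms:.3f} m/s",
            f"Alpha grid:            [{self.sweep['alpha'].min():.2f}, "
            f"{self.sweep['alpha'].max():.2f}] step "
            f"{self.sweep['alpha'].diff().dropna().median():.2f}",
            "-" * 46,
            f"alpha_opt:             {self.alpha_opt:.2f}",
            f"slope at alpha_opt:    {at['slope']:.4f}",
            f"intercept:             {at['intercept']:.4f} m",
            f"R^2:                   {at['r_squared']:.4f}",
            f"Pearson r (emp, mod):  {self.pearson_r:.4f}  (p = {self.pearson_p:.3g})",
            f"KS two-sample:         D = {self.ks_statistic:.4f}, p = {self.ks_p:.3g}",
            "=" * 46,
        ]
        return "\n".join(lines)

    def plot(self, ax=None):
        """Diagnostic plot: empirical vs modelled means at the optimum."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        x = self.predict()
        y = self.model.empirical_means
        ax.scatter(x, y, s=18, color="tab:blue")
        lim = max(float(x.max()), float(y.max())) * 1.05
        ax.plot([0, lim], [0, lim], "k:", lw=1, label="1:1")
        ax.plot(
            [0, lim],
            [self.intercept, self.intercept + self.slope * lim],
            "r-",
            lw=1,
            label=f"fit (slope {self.slope:.2f})",
        )
        ax.set_xlabel("modelled mean distance (m)")
        ax.set_ylabel("empirical mean distance (m)")
        ax.set_title(f"gradient model, alpha = {self.alpha_opt:.2f}")
        ax.legend()
        return ax


class AlphaCalibration:
    """Model object: calibrate the Hellmann exponent from launch records.

    Parameters
    ----------
    launches
        Launch records (distances + wind aggregates).  At least 3 with
        non-degenerate winds are required to fit.
    terminal_velocity_ms
        Terminal velocity of the (standardised) propagules used in the
        launches, m/s.
    alpha_grid
        Grid of candidate exponents; default 0.05–0.50 step 0.01.
    wind_covariate
        Which per-launch wind aggregate drives the model (default
        ``v_max_ms``, empirically the best predictor of the mean distance).
    """

    def __init__(
        self,
        launches: Sequence[LaunchRecord],
        terminal_velocity_ms: float = 1.72,
        alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
        wind_covariate: str = "v_max_ms",
    ):
        if len(launches) < 3:
            raise DomainError("calibration needs at least 3 launches")
        if not terminal_velocity_ms > 0:
            raise DomainError(
                f"terminal_velocity_ms must be > 0, got {terminal_velocity_ms!r}"
            )
        self.launches = list(launches)
        self.aggregates = [aggregate_launch(rec) for rec in self.launches]
        self.terminal_velocity_ms = float(terminal_velocity_ms)
        self.alpha_grid = tuple(float(a) for a in alpha_grid)
        self.wind_covariate = wind_covariate
        winds = np.array([getattr(a, wind_covariate) for a in self.aggregates])
        if np.ptp(winds) == 0:
            raise DomainError(f"{wind_covariate} is constant across launches")
        # ballistic per-launch distances; gradient = ballistic / (1 + alpha)
        self._ballistic = np.array(
            [
                a.release_height_m * getattr(a, wind_covariate) / terminal_velocity_ms
                for a in self.aggregates
            ]
        )
        self.empirical_means = np.array([a.D_mean for a in self.aggregates])

    @classmethod
    def from_tables(
        cls,
        launch_df: pd.DataFrame,
        wind_df: pd.DataFrame,
        terminal_velocity_ms: float = 1.72,
        **kwargs,
    ) -> "AlphaCalibration":
        """Build from the launch table (one row per propagule) + wind table."""
        records = launch_records_from_tables(launch_df, wind_df)
        return cls(records, terminal_velocity_ms=terminal_velocity_ms, **kwargs)

    def modelled_means(self, alpha: float) -> np.ndarray:
        return self._ballistic / (1.0 + alpha)

    def fit(self) -> AlphaCalibrationResults:
        """Sweep the grid and return the calibration results."""
        rows = []
        best_alpha, best_gap = None, np.inf
        for alpha in self.alpha_grid:
            modelled = self.modelled_means(alpha)
            try:
                slope, intercept, r2 = _ols_line(modelled, self.empirical_means)
            except DomainError as exc:
                raise DomainError(f"regression failed at alpha={alpha}: {exc}") from exc
            rows.append(
                {"alpha": alpha, "slope": slope, "intercept": intercept, "r_squared": r2}
            )
            gap = abs(slope - 1.0)
            if gap < best_gap:  # strict: ties resolve to the smaller alpha
                best_alpha, best_gap = alpha, gap
        sweep = pd.DataFrame(rows)
        at = sweep[sweep["alpha"] == best_alpha].iloc[0]
        modelled = self.modelled_means(best_alpha)
        pr, pp = stats.pearsonr(modelled, self.empirical_means)
        pooled_emp = np.concatenate([rec.distances_m for rec in self.launches])
        pooled_mod = np.concatenate(
            [
                np.full(len(rec.distances_m), m)
                for rec, m in zip(self.launches, modelled)
            ]
        )
        ks = stats.ks_2samp(pooled_emp, pooled_mod)
        return AlphaCalibrationResults(
            alpha_opt=float(best_alpha),
            sweep=sweep,
            slope=float(at["slope"]),
            intercept=float(at["intercept"]),
            r_squared=float(at["r_squared"]),
            pearson_r=float(pr),
            pearson_p=float(pp),
            ks_statistic=float(ks.statistic),
            ks_p=float(ks.pvalue),
            terminal_velocity_ms=self.terminal_velocity_ms,
            n_launches=len(self.launches),
            model=self,
        )


def calibrate_alpha(
    launches: Sequence[LaunchRecord],
    terminal_velocity_ms: float = 1.72,
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    wind_covariate: str = "v_max_ms",
) -> AlphaCalibrationResults:
    """Functional wrapper: build an :class:`AlphaCalibration` and fit it."""
    return AlphaCalibration(
        launches,
        terminal_velocity_ms=terminal_velocity_ms,
        alpha_grid=alpha_grid,
        wind_covariate=wind_covariate,
    ).fit()


@dataclass(frozen=True)
class SpreadRegression:
    """Linear fit of per-wind-class distance spread on wind speed."""

    slope: float
    intercept: float
    r_squared: float
    n_classes: int
    classes: pd.DataFrame


def distance_spread_regression(
    launches: Sequence[LaunchRecord],
    bin_width_ms: float = 1.0,
    wind_covariate: str = "wind_max_ms",
) -> SpreadRegression:
    """Regress the distance standard deviation on wind speed, by wind class.

    Distances are pooled into left-closed wind classes of ``bin_width_ms``
    on the launch's wind covariate; classes with fewer than 2 distances are
    dropped (sd undefined).  The per-class sd is regressed on the class mean
    wind, yielding the linear spread model ``D_sd = slope * v + intercept``.
    """
    winds, dists = [], []
    for rec in launches:
        w = getattr(rec, wind_covariate)
        winds.extend([w] * len(rec.distances_m))
        dists.extend(rec.distances_m)
    winds = np.asarray(winds, dtype=float)
    dists = np.asarray(dists, dtype=float)
    bins = np.floor(winds / bin_width_ms).astype(int)
    rows = []
    for b in np.unique(bins):
        mask = bins == b
        if mask.sum() < 2:
            continue
        rows.append(
            {
                "wind_class_left_ms": b * bin_width_ms,
                "wind_mean_ms": float(winds[mask].mean()),
                "distance_sd_m": float(np.std(dists[mask], ddof=1)),
                "n": int(mask.sum()),
            }
        )
    if len(rows) < 3:
        raise DomainError(
            f"distance_spread_regression needs >= 3 wind classes, got {len(rows)}"
        )
    classes = pd.DataFrame(rows)
    slope, intercept, r2 = _ols_line(
        classes["wind_mean_ms"].to_numpy(), classes["distance_sd_m"].to_numpy()
    )
    return SpreadRegression(
        slope=slope,
        intercept=intercept,
        r_squared=r2,
        n_classes=len(rows),
        classes=classes,
    )


def launch_records_from_tables(
    launch_df: pd.DataFrame, wind_df: pd.DataFrame
) -> list[LaunchRecord]:
    """Join the per-propagule launch table with the per-launch wind table."""
    wind = wind_df.set_index(wind_df["launch_id"].astype(str))
    records = []
    for launch_id, grp in launch_df.groupby(launch_df["launch_id"].astype(str), sort=True):
        if launch_id not in wind.index:
            raise DomainError(f"launch {launch_id} missing from the wind table")
        wrow = wind.loc[launch_id]
        records.append(
            LaunchRecord(
                launch_id=str(launch_id),
                release_height_m=float(grp["release_height_m"].iloc[0]),
                distances_m=tuple(grp["distance_m"].astype(float)),
                wind_median_ms=float(wrow["v_median_ms"]),
                wind_mean_ms=float(wrow["v_mean_ms"]),
                wind_max_ms=float(wrow["v_max_ms"]),
            )
        )
    return records
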