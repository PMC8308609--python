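"""Deterministic flight-distance models for wind-dispersed propagules.

Two mechanistic models of the horizontal flight of a propagule released at
height ``h_r`` into a horizontal air flow:

* the **simple ballistic model**, ``D = h_r * u / V_t``, which assumes the
  propagule instantly reaches its terminal velocity ``V_t`` and travels at
  the (height-independent) wind speed ``u`` for the whole fall; and
* the **wind-gradient model**, which lets the wind decay toward the ground
  following the Hellmann power law ``v(z) = v_ref * (z / z_ref)**alpha``
  and integrates the resulting wind history over the fall, giving the
  closed form ``D = h_r * v_hr / (V_t * (1 + alpha))``.

Both assume flat open terrain, no turbulence and no obstacle wakes —
reasonable for large-seeded tall herbs whose propagules fall faster than
about 1 m/s.  All quantities are SI (metres, seconds, m/s).
"""

from __future__ import annotations

from dataclasses import dataclass

from .exceptions import DomainError

#: Default Hellmann exponent: the value calibrated against launch
#: experiments with artificial propagules (see :mod:`anemochory.calibration`).
#: It sits between the textbook values for unstable (0.27) and neutral
#: (0.34) air above inhabited areas.
DEFAULT_ALPHA = 0.29


def _require_positive(value: float, name: str) -> None:
    if not value > 0:
        raise DomainError(f"{name} must be > 0, got {value!r}")


def _require_non_negative(value: float, name: str) -> None:
    if not value >= 0:
        raise DomainError(f"{name} must be >= 0, got {value!r}")


@dataclass(frozen=True)
class FlightConditions:
    """Conditions of a single propagule release.

    Parameters
    ----------
    release_height_m
        Height of the umbel above ground at release (``h_r``), metres; > 0.
    wind_at_release_ms
        Horizontal wind speed at the release height (``u`` in the ballistic
        model, ``v_hr`` in the gradient model), m/s; >= 0.
    terminal_velocity_ms
        Terminal (constant) falling velocity of the propagule in still air
        (``V_t``), m/s; > 0.
    hellmann_alpha
        Hellmann exponent ``alpha`` (surface roughness / air stability),
        dimensionless; >= 0.  Ignored by the ballistic model.
    """

    release_height_m: float
    wind_at_release_ms: float
    terminal_velocity_ms: float
    hellmann_alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        _require_positive(self.release_height_m, "release_height_m")
        _require_positive(self.terminal_velocity_ms, "terminal_velocity_ms")
        _require_non_negative(self.wind_at_release_ms, "wind_at_release_ms")
        _require_non_negative(self.hellmann_alpha, "hellmann_alpha")

    @property
    def fall_time_s(self) -> float:
        """Total fall time ``t_f = h_r / V_t`` in seconds."""
        return self.release_height_m / self.terminal_velocity_ms


@dataclass(frozen=True)
class WindProfilePoint:
    """A wind-speed observation at a known height (e.g. an anemometer)."""

    speed_ms: float
    height_m: float

    def __post_init__(self) -> None:
        _require_positive(self.height_m, "height_m")
        _require_non_negative(self.speed_ms, "speed_ms")


def ballistic_distance(conditions: FlightConditions) -> float:
    """Horizontal flight distance under the simple ballistic model.

    ``D = h_r * u / V_t``: the propagule falls at ``V_t`` for
    ``t_f = h_r / V_t`` seconds while drifting at the constant wind speed
    ``u``.  ``hellmann_alpha`` is ignored.  Returns metres; zero iff the
    wind is zero.
    """
    return (
        conditions.release_height_m
        * conditions.wind_at_release_ms
        / conditions.terminal_velocity_ms
    )


def wind_at_height(
    reference: WindProfilePoint, target_height_m: float, alpha: float = DEFAULT_ALPHA
) -> float:
    """Transfer a wind speed between heights via the Hellmann power law.

    ``v(z) = v_ref * (z / z_ref)**alpha``.  With ``alpha > 0`` the result
    is monotone increasing in the target height; at the reference height it
    returns the reference speed exactly.
    """
    _require_positive(target_height_m, "target_height_m")
    _require_non_negative(alpha, "alpha")
    return reference.speed_ms * (target_height_m / reference.height_m) ** alpha


def fall_time(release_height_m: float, terminal_velocity_ms: float) -> float:
    """Total fall time ``t_f = h_r / V_t`` (seconds) for a still-air drop."""
    _require_positive(release_height_m, "release_height_m")
    _require_positive(terminal_velocity_ms, "terminal_velocity_ms")
    return release_height_m / terminal_velocity_ms


def wind_during_fall(conditions: FlightConditions, elapsed_time_s: float) -> float:
    """Instantaneous wind speed experienced ``elapsed_time_s`` into the fall.

    The propagule height at time ``t`` is ``h(t) = V_t * (t_f - t)``, so the
    Hellmann profile gives ``v(t) = v_hr * ((t_f - t) / t_f)**alpha``.
    Equals ``v_hr`` at ``t = 0`` and, for ``alpha > 0``, zero at ``t = t_f``.
    """
    t_f = conditions.fall_time_s
    if not 0 <= elapsed_time_s <= t_f:
        raise DomainError(
            f"elapsed_time_s must lie in [0, t_f={t_f:.6g}], got {elapsed_time_s!r}"
        )
    if conditions.hellmann_alpha == 0:
        return conditions.wind_at_release_ms
    remaining = 1.0 - elapsed_time_s / t_f
    return conditions.wind_at_release_ms * remaining**conditions.hellmann_alpha


def gradient_distance(conditions: FlightConditions) -> float:
    """Horizontal flight distance under the wind-gradient model.

    Integrating the height-dependent wind ``v(t)`` over the fall gives the
    closed form::

        D = h_r * v_hr / (V_t * (1 + alpha))

    i.e. the ballistic distance shrunk by ``1 / (1 + alpha)``.  With
    ``alpha = 0`` this reduces to :func:`ballistic_distance` exactly.  The
    closed form is verified against adaptive quadrature of the wind history
    in the test suite.
    """
    return ballistic_distance(conditions) / (1.0 + conditions.hellmann_alpha)
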