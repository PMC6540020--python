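"""Screening and settling-value extrapolation for short skin-contact impedance transients.

Small dry electrodes have a narrow skin contact area, so the measured impedance
approaches its stabilized value through a slow first-order transient governed by
the parasitic RC of the electrode–skin interface,

    y(t) = b + c * exp(-a * t),

where ``b`` is the settled impedance, ``c`` the (signed) transient amplitude and
``a = 1/RC`` the decay rate.  Rather than waiting for convergence, the settled
value is extrapolated from the first few seconds of data: consecutive-sample
differences (deltas) cancel the unknown asymptote, their ratios isolate the
decay rate (each ratio equals ``exp(a * delta_s)`` on a pure exponential), and a
log-linear regression of ``ln|delta|`` on time recovers ``a`` and ``c``, from
which ``b`` follows.

Before extrapolation each series is screened: a series that keeps rising has
not begun to converge, and a final value outside the plausible impedance range
indicates poor contact; either case earns a re-measurement flag.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import (
    ConfigError,
    DegenerateDeltaError,
    InsufficientSamplesError,
    MalformedSeriesError,
)

__all__ = [
    "ImpedanceSeries",
    "FeasibilityResult",
    "SettlingEstimate",
    "CalibrationConfig",
    "Violation",
    "SettlingMethod",
    "check_feasibility",
    "compute_deltas",
    "compute_delta_ratios",
    "estimate_settled_value",
]

_SPACING_TOL = 1e-9


class Violation(enum.Enum):
    """Reasons a series earns a re-measurement flag."""

    CONDITION_1_INCREASING = "CONDITION_1_INCREASING"
    CONDITION_2_RANGE = "CONDITION_2_RANGE"


class SettlingMethod(enum.Enum):
    """How the settled impedance was obtained."""

    EXTRAPOLATED = "EXTRAPOLATED"
    ALREADY_SETTLED = "ALREADY_SETTLED"
    RATIO_IN_BAND = "RATIO_IN_BAND"
    FALLBACK_LAST = "FALLBACK_LAST"


@dataclass(frozen=True)
class ImpedanceSeries:
    """Timed raw impedance samples from one contact event.

    Parameters
    ----------
    times
        Sample times in seconds; strictly increasing with uniform spacing
        ``delta_s``.
    values
        Impedance samples in ohms; finite and positive.
    delta_s
        Sampling interval in seconds (default 1.0).
    subject_id
        Opaque label carried through the pipeline.
    """

    times: np.ndarray
    values: np.ndarray
    delta_s: float = 1.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "values", values)
        if times.ndim != 1 or values.ndim != 1 or len(times) != len(values):
            raise MalformedSeriesError("times and values must be 1-d of equal length")
        if len(values) < 3:
            raise MalformedSeriesError("need at least 3 samples")
        if not np.all(np.isfinite(values)) or np.any(values <= 0):
            raise MalformedSeriesError("values must be finite and > 0")
        gaps = np.diff(times)
        if np.any(np.abs(gaps - self.delta_s) > _SPACING_TOL):
            raise MalformedSeriesError(
                f"non-uniform sampling: gaps deviate from delta_s={self.delta_s}"
            )

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class FeasibilityResult:
    """Outcome of the signal feasibility screen."""

    valid: bool
    violations: tuple[Violation, ...]
    final_value: float


@dataclass(frozen=True)
class CalibrationConfig:
    """Thresholds for screening and settling estimation.

    ``valid_range`` is the acceptable window for the final sample (ohms);
    ``settle_threshold`` is the largest last-gap magnitude (ohms) at which the
    series is considered already settled; ``ratio_band`` is the delta-ratio
    interval treated as indistinguishable from drift.
    """

    valid_range: tuple[float, float] = (500.0, 2000.0)
    settle_threshold: float = 5.0
    ratio_band: tuple[float, float] = (0.95, 1.05)

    def __post_init__(self) -> None:
        if not self.valid_range[0] < self.valid_range[1]:
            raise ConfigError("valid_range low must be < high")
        if not self.ratio_band[0] < self.ratio_band[1]:
            raise ConfigError("ratio_band low must be < high")
        if not self.settle_threshold > 0:
            raise ConfigError("settle_threshold must be > 0")


@dataclass(frozen=True)
class SettlingEstimate:
    """Extrapolated settled impedance with decay parameters and diagnostics.

    ``decay_rate`` and ``amplitude`` are NaN unless ``method`` is
    ``EXTRAPOLATED``.  ``delta_ratios`` holds NaN entries where a zero delta
    made a ratio undefined (such series take the fallback path).
    """

    settled_ohms: float
    decay_rate: float
    amplitude: float
    deltas: tuple[float, ...]
    delta_ratios: tuple[float, ...]
    method: SettlingMethod


def check_feasibility(
    series: ImpedanceSeries, config: CalibrationConfig = CalibrationConfig()
) -> FeasibilityResult:
    """Screen a series for the two re-measurement conditions.

    Condition 1: the samples increase across every consecutive pair, i.e. the
    reading has not started to converge.  Condition 2: the final sample lies
    outside ``config.valid_range``.  A series is valid iff neither holds.
    """
    values = series.values
    violations: list[Violation] = []
    if np.all(np.diff(values) > 0):
        violations.append(Violation.CONDITION_1_INCREASING)
    low, high = config.valid_range
    final = float(values[-1])
    if final < low or final > high:
        violations.append(Violation.CONDITION_2_RANGE)
    return FeasibilityResult(
        valid=not violations, violations=tuple(violations), final_value=final
    )


def compute_deltas(series: ImpedanceSeries) -> np.ndarray:
    """Consecutive-sample differences, earlier minus later.

    A series decaying from above yields positive deltas.  The differences
    cancel the unknown asymptote: on ``b + c*exp(-a*t)`` each delta is
    ``c * exp(-a*t_i) * (1 - exp(-a*delta_s))``, free of ``b``.
    """
    return series.values[:-1] - series.values[1:]


def compute_delta_ratios(deltas: np.ndarray) -> np.ndarray:
    """Ratios of consecutive deltas; equals ``exp(a*delta_s)`` on a pure exponential.

    Raises
    ------
    DegenerateDeltaError
        If any denominator delta is zero; the caller must take the
        settled/fallback path rather than divide.
    """
    deltas = np.asarray(deltas, dtype=float)
    if len(deltas) < 2:
        raise InsufficientSamplesError("need at least 2 deltas for a ratio")
    denom = deltas[1:]
    if np.any(denom == 0):
        raise DegenerateDeltaError("zero delta in ratio denominator")
    return deltas[:-1] / denom


def estimate_settled_value(
    series: ImpedanceSeries, config: CalibrationConfig = CalibrationConfig()
) -> SettlingEstimate:
    """Estimate the settled impedance from a short transient.

    Decision cascade:

    1. If the last inter-sample gap is within ``settle_threshold`` the series
       has effectively converged: return the last sample (ALREADY_SETTLED).
    2. If any delta is zero or the deltas change sign, no single exponential
       fits: return the last sample (FALLBACK_LAST).
    3. If every delta ratio lies inside ``ratio_band``, the transient is
       indistinguishable from linear drift: return the last sample
       (RATIO_IN_BAND).
    4. Otherwise fit ``ln|delta_i| = ln|c*(1 - exp(-a*delta_s))| - a*t_i`` by
       ordinary least squares, recover the decay rate ``a`` (slope) and signed
       amplitude ``c`` (intercept; sign taken from the deltas), and set the
       settled value to the mean of ``values - c*exp(-a*t)`` (EXTRAPOLATED).
       A non-positive fitted decay rate means the deltas grow with time, which
       no settling transient produces; such series fall back to the last
       sample.

    On a noise-free series exactly of the form ``b + c*exp(-a*t)`` with
    ``a > 0`` and path 4 taken, the returned value equals ``b`` to well below
    1e-6 ohms.
    """
    values = series.values
    times = series.times
    last = float(values[-1])
    deltas = compute_deltas(series)
    nan = float("nan")

    if abs(values[-1] - values[-2]) <= config.settle_threshold:
        ratios = _safe_ratios(deltas)
        return SettlingEstimate(
            last, nan, nan, tuple(deltas), ratios, SettlingMethod.ALREADY_SETTLED
        )

    if np.any(deltas == 0) or (np.any(deltas > 0) and np.any(deltas < 0)):
        ratios = _safe_ratios(deltas)
        return SettlingEstimate(
            last, nan, nan, tuple(deltas), ratios, SettlingMethod.FALLBACK_LAST
        )

    ratios_arr = compute_delta_ratios(deltas)
    ratios = tuple(float(r) for r in ratios_arr)
    low, high = config.ratio_band
    if np.all((ratios_arr >= low) & (ratios_arr <= high)):
        return SettlingEstimate(
            last, nan, nan, tuple(deltas), ratios, SettlingMethod.RATIO_IN_BAND
        )

    if len(deltas) < 3:
        raise InsufficientSamplesError(
            f"need at least 3 deltas to extrapolate, got {len(deltas)}"
        )

    # log-linear fit: ln|delta_i| against the earlier sample time of each pair
    t_d = times[:-1]
    slope, intercept = np.polyfit(t_d, np.log(np.abs(deltas)), 1)
    a_hat = -float(slope)
    if a_hat <= 0:
        return SettlingEstimate(
            last, nan, nan, tuple(deltas), ratios, SettlingMethod.FALLBACK_LAST
        )
    c_mag = math.exp(float(intercept)) / (1.0 - math.exp(-a_hat * series.delta_s))
    c_hat = math.copysign(c_mag, float(deltas[0]))
    b_hat = float(np.mean(values - c_hat * np.exp(-a_hat * times)))
    return SettlingEstimate(
        b_hat, a_hat, c_hat, tuple(deltas), ratios, SettlingMethod.EXTRAPOLATED
    )


def _safe_ratios(deltas: np.ndarray) -> tuple[float, ...]:
    """Delta ratios with NaN where the denominator vanishes (diagnostic only)."""
    out = np.full(len(deltas) - 1, float("nan"))
    denom = deltas[1:]
    ok = denom != 0
    out[ok] = deltas[:-1][ok] / denom[ok]
    return tuple(float(r) for r in out)
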