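"""Exposure events, piecewise-constant profiles and toxic-unit scaling.

Exposure in above-ground terrestrial test systems is event-based (topical
application, feeding windows, replenishing of a contaminated food source).
This module turns such events into model-ready concentration time series:

* :func:`discretize_events` -- generic discretization with a smallest time
  unit (default 1 h): constant level while the event lasts, zero otherwise.
* :func:`beeguts_preprocess` -- the legacy bee-specific effective-exposure
  proxy (fixed first-order decline rates per route), emitted on a dense grid.
* :func:`fit_dose_response` / :func:`to_toxic_units` -- two-parameter
  log-logistic concentration-response fitting and the linear toxic-unit
  (TU) normalization ``c -> c / LC50`` it enables.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln

__all__ = [
    "Route",
    "ExposureEvent",
    "ExposureProfile",
    "DoseResponseFit",
    "discretize_events",
    "beeguts_preprocess",
    "fit_dose_response",
    "to_toxic_units",
    "from_toxic_units",
    "BEEGUTS_CONTACT_DECAY",
    "BEEGUTS_ORAL_DECAY",
    "DEFAULT_DT_UNIT",
]

#: Fixed first-order decline rate for topically applied doses (1/day).
BEEGUTS_CONTACT_DECAY = 0.4
#: Fixed first-order decline rate after an acute feeding window (1/day).
BEEGUTS_ORAL_DECAY = 0.625
#: Smallest time unit for event discretization: one hour, in days.
DEFAULT_DT_UNIT = 1.0 / 24.0


class Route(str, enum.Enum):
    """Exposure route of a laboratory test."""

    ACUTE_CONTACT = "acute_contact"
    ACUTE_ORAL = "acute_oral"
    CHRONIC_ORAL = "chronic_oral"


@dataclass(frozen=True)
class ExposureEvent:
    """A single exposure happening.

    Parameters
    ----------
    route
        How the organisms are exposed.
    magnitude
        Dose or food concentration in study units (e.g. µg/bee, mg/kg food),
        or in TU after normalization. Must be >= 0.
    t_start, t_end
        Event window in days. ``t_end == t_start`` marks an instantaneous
        event (e.g. topical application).
    unit
        Free-text unit label.
    """

    route: Route
    magnitude: float
    t_start: float = 0.0
    t_end: float | None = None
    unit: str = ""

    def __post_init__(self) -> None:
        if self.t_end is None:
            object.__setattr__(self, "t_end", self.t_start)
        if not (math.isfinite(self.t_start) and math.isfinite(self.t_end)):
            raise ValueError("event times must be finite")
        if not math.isfinite(self.magnitude) or self.magnitude < 0:
            raise ValueError(f"event magnitude must be finite and >= 0, got {self.magnitude}")
        if self.t_end < self.t_start:
            raise ValueError(f"t_end ({self.t_end}) < t_start ({self.t_start})")
        object.__setattr__(self, "route", Route(self.route))

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start


@dataclass
class ExposureProfile:
    """Concentration time series C(t).

    Two representations are supported:

    * piecewise-constant (the default): ``levels[i]`` holds on the
      right-open interval ``[breakpoints[i], breakpoints[i+1])`` and
      ``levels[-1]`` from the last breakpoint onward;
    * dense (used by the legacy preprocessing mode, whose exponential decay
      is not piecewise-constant): values on ``dense_t`` interpolated
      linearly in between.
    """

    breakpoints: np.ndarray
    levels: np.ndarray
    unit_label: str = ""
    is_toxic_units: bool = False
    dense_t: np.ndarray | None = None
    dense_values: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.breakpoints = np.asarray(self.breakpoints, dtype=float)
        self.levels = np.asarray(self.levels, dtype=float)
        if self.breakpoints.shape != self.levels.shape:
            raise ValueError("breakpoints and levels must have equal length")
        if self.breakpoints.size == 0:
            raise ValueError("profile needs at least one breakpoint")
        if np.any(np.diff(self.breakpoints) <= 0):
            raise ValueError("breakpoints must be strictly increasing")
        if np.any(~np.isfinite(self.levels)) or np.any(self.levels < 0):
            raise ValueError("levels must be finite and >= 0")
        if self.dense_t is not None:
            self.dense_t = np.asarray(self.dense_t, dtype=float)
            self.dense_values = np.asarray(self.dense_values, dtype=float)
            if self.dense_t.shape != self.dense_values.shape:
                raise ValueError("dense_t and dense_values must have equal length")

    @property
    def is_dense(self) -> bool:
        return self.dense_t is not None

    @property
    def t_last(self) -> float:
        if self.is_dense:
            return float(self.dense_t[-1])
        return float(self.breakpoints[-1])

    @property
    def max_level(self) -> float:
        if self.is_dense:
            return float(np.max(self.dense_values))
        return float(np.max(self.levels))

    def value_at(self, t: np.ndarray | float) -> np.ndarray:
        """Evaluate C(t); scalar or vectorized."""
        t = np.asarray(t, dtype=float)
        if self.is_dense:
            return np.interp(t, self.dense_t, self.dense_values)
        idx = np.searchsorted(self.breakpoints, t, side="right") - 1
        out = np.where(idx >= 0, self.levels[np.clip(idx, 0, None)], 0.0)
        return out

    def integral(self, t0: float, t1: float) -> float:
        """Exact integral of the step function on [t0, t1] (dense: trapezoid)."""
        if self.is_dense:
            grid = np.linspace(t0, t1, 20001)
            return float(np.trapezoid(self.value_at(grid), grid))
        edges = np.concatenate([[t0], self.breakpoints[(self.breakpoints > t0) & (self.breakpoints < t1)], [t1]])
        mids = 0.5 * (edges[:-1] + edges[1:])
        return float(np.sum(self.value_at(mids) * np.diff(edges)))

    def min_pulse_duration(self) -> float | None:
        """Shortest nonzero-level segment, or None if constant/zero."""
        if self.is_dense:
            return None
        edges = np.append(self.breakpoints, np.inf)
        durations = [
            edges[i + 1] - edges[i]
            for i in range(len(self.levels))
            if self.levels[i] > 0 and np.isfinite(edges[i + 1])
        ]
        return min(durations) if durations else None

    def scaled(self, factor: float) -> "ExposureProfile":
        out = replace(self, levels=self.levels * factor)
        if self.is_dense:
            out.dense_values = self.dense_values * factor
        return out


@dataclass(frozen=True)
class DoseResponseFit:
    """Two-parameter log-logistic concentration-response fit.

    The fitted survival curve is ``h(c) = 1 / (1 + (c / lc50)**slope)``,
    so ``h(0) = 1`` and ``h(lc50) = 0.5``.
    """

    lc50: float
    slope: float
    timepoint: float
    endpoint_label: str = "LC50"
    fitted_timepoint: float | None = None

    def __post_init__(self) -> None:
        if not (self.lc50 > 0):
            raise ValueError("lc50 must be > 0")
        if not (self.slope > 0):
            raise ValueError("slope must be > 0")

    def predict(self, c: np.ndarray | float) -> np.ndarray:
        c = np.asarray(c, dtype=float)
        with np.errstate(divide="ignore"):
            return 1.0 / (1.0 + (c / self.lc50) ** self.slope)


# ---------------------------------------------------------------------------
# event discretization
# ---------------------------------------------------------------------------

def _event_interval(ev: ExposureEvent, dt_unit: float, horizon: float | None) -> tuple[float, float]:
    if ev.route is Route.CHRONIC_ORAL:
        end = horizon if horizon is not None else math.inf
        return ev.t_start, max(end, ev.t_start + dt_unit)
    if ev.route is Route.ACUTE_CONTACT or ev.duration < dt_unit:
        # (quasi-)instant and sub-unit events occupy one smallest time unit
        return ev.t_start, ev.t_start + dt_unit
    return ev.t_start, ev.t_end


def discretize_events(
    events: list[ExposureEvent],
    dt_unit: float = DEFAULT_DT_UNIT,
    horizon: float | None = None,
) -> ExposureProfile:
    """Convert exposure events into a piecewise-constant profile.

    The level is held constant at the event magnitude while the event lasts
    and is zero otherwise. Instantaneous events (topical application) occupy
    exactly one smallest time unit ``dt_unit``; chronic events hold their
    level until ``horizon`` (or indefinitely if no horizon is given). The
    discretization preserves the area under the curve:
    ``integral == magnitude * max(duration, dt_unit)``.

    Raises
    ------
    ValueError
        If ``dt_unit <= 0`` or two events overlap with conflicting levels.
    """
    if dt_unit <= 0:
        raise ValueError("dt_unit must be > 0")
    unit = next((ev.unit for ev in events if ev.unit), "")
    if not events:
        return ExposureProfile(np.array([0.0]), np.array([0.0]), unit_label=unit)

    intervals = []
    for i, ev in enumerate(events):
        a, b = _event_interval(ev, dt_unit, horizon)
        intervals.append((a, b, ev.magnitude, i))

    for a, b, lvl, i in intervals:
        for a2, b2, lvl2, j in intervals:
            if j <= i:
                continue
            if a < b2 and a2 < b and not np.isclose(lvl, lvl2):
                raise ValueError(
                    f"events {i} and {j} overlap with conflicting levels ({lvl} vs {lvl2})"
                )

    edges = {0.0}
    for a, b, _, _ in intervals:
        edges.add(a)
        if math.isfinite(b):
            edges.add(b)
    breakpoints = np.array(sorted(edges))
    levels = np.zeros_like(breakpoints)
    for k, t0 in enumerate(breakpoints):
        for a, b, lvl, _ in intervals:
            if a <= t0 < b:
                levels[k] = max(levels[k], lvl)
    # drop redundant breakpoints (equal consecutive levels)
    keep = np.concatenate([[True], np.diff(levels) != 0])
    return ExposureProfile(breakpoints[keep], levels[keep], unit_label=unit)


def beeguts_preprocess(
    events: list[ExposureEvent],
    horizon: float,
    grid_step: float | None = None,
) -> ExposureProfile:
    """Legacy bee-specific effective-exposure proxy on a dense grid.

    Route-specific interpolation of exposure events: acute contact doses
    decline first-order at 0.4/d from the application time; acute oral
    exposure ramps linearly from zero to the magnitude over the feeding
    window and then declines first-order at 0.625/d; chronic exposure is
    constant over the whole period. The result is returned as a dense
    profile because the exponentials are not piecewise-constant.
    """
    if grid_step is None:
        grid_step = horizon / 1000.0
    if grid_step <= 0 or horizon <= 0:
        raise ValueError("horizon and grid_step must be > 0")
    for ev in events:
        if ev.t_end > horizon:
            raise ValueError(f"horizon {horizon} does not cover event ending at {ev.t_end}")
    t = np.arange(0.0, horizon + 0.5 * grid_step, grid_step)
    vals = np.zeros_like(t)
    unit = next((ev.unit for ev in events if ev.unit), "")
    for ev in events:
        if ev.route is Route.ACUTE_CONTACT:
            mask = t >= ev.t_start
            vals[mask] += ev.magnitude * np.exp(-BEEGUTS_CONTACT_DECAY * (t[mask] - ev.t_start))
        elif ev.route is Route.ACUTE_ORAL:
            if ev.duration > 0:
                ramp = (t >= ev.t_start) & (t < ev.t_end)
                vals[ramp] += ev.magnitude * (t[ramp] - ev.t_start) / ev.duration
            decay = t >= ev.t_end
            vals[decay] += ev.magnitude * np.exp(-BEEGUTS_ORAL_DECAY * (t[decay] - ev.t_end))
        elif ev.route is Route.CHRONIC_ORAL:
            vals[t >= ev.t_start] += ev.magnitude
        else:  # pragma: no cover - Route() coercion makes this unreachable
            raise ValueError(f"unknown route {ev.route!r}")
    return ExposureProfile(
        breakpoints=np.array([0.0]),
        levels=np.array([0.0]),
        unit_label=unit,
        dense_t=t,
        dense_values=vals,
    )


# ---------------------------------------------------------------------------
# dose-response fitting and toxic-unit conversion
# ---------------------------------------------------------------------------

def _loglogistic(c: np.ndarray, lc50: float, slope: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return 1.0 / (1.0 + (np.asarray(c, float) / lc50) ** slope)


def fit_dose_response(
    concentrations,
    survival_fraction=None,
    timepoint: float = 2.0,
    *,
    n_alive=None,
    n_total=None,
    endpoint_label: str = "LC50",
    allow_extrapolation: bool = False,
    fitted_timepoint: float | None = None,
) -> DoseResponseFit:
    """Fit the two-parameter log-logistic survival curve h(c).

    If survivor counts (``n_alive``, ``n_total``) are supplied the fit
    maximizes the binomial likelihood -- counts are the native data; with
    fractions only, it minimizes squared error. Optimization runs on
    ``(log lc50, log slope)`` so the positivity constraints are implicit.

    Raises
    ------
    ValueError
        Fewer than 3 distinct concentrations, identical survival everywhere
        (no identifiable LC50), or no response below 50% survival without
        ``allow_extrapolation``.
    """
    c = np.asarray(concentrations, dtype=float)
    if n_alive is not None:
        n_alive = np.asarray(n_alive, dtype=float)
        n_total = np.asarray(n_total, dtype=float)
        frac = n_alive / n_total
    else:
        if survival_fraction is None:
            raise ValueError("need survival_fraction or n_alive/n_total")
        frac = np.asarray(survival_fraction, dtype=float)
    if np.any((frac < 0) | (frac > 1)):
        raise ValueError("survival fractions must lie in [0, 1]")
    if len(np.unique(c)) < 3:
        raise ValueError("need at least 3 distinct concentrations")
    if np.all(frac == frac[0]):
        raise ValueError("survival identical at all concentrations: LC50 not identifiable")
    if not np.any(frac < 0.5) and not allow_extrapolation:
        raise ValueError(
            "no observation below 50% survival; pass allow_extrapolation=True to extrapolate"
        )

    pos = c[c > 0]
    lc50_0 = float(np.exp(np.interp(0.5, frac[::-1], np.log(np.maximum(c[::-1], pos.min() * 1e-3))))) \
        if pos.size else 1.0
    x0 = np.array([np.log(max(lc50_0, 1e-12)), 0.0])

    if n_alive is not None:
        def objective(x):
            h = np.clip(_loglogistic(c, np.exp(x[0]), np.exp(x[1])), 1e-9, 1 - 1e-9)
            return -np.sum(
                n_alive * np.log(h)
                + (n_total - n_alive) * np.log1p(-h)
                + gammaln(n_total + 1)
                - gammaln(n_alive + 1)
                - gammaln(n_total - n_alive + 1)
            )
    else:
        def objective(x):
            h = _loglogistic(c, np.exp(x[0]), np.exp(x[1]))
            return np.sum((h - frac) ** 2)

    best = None
    for slope0 in (0.0, np.log(3.0), np.log(0.5)):
        res = minimize(objective, np.array([x0[0], slope0]), method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 4000})
        if best is None or res.fun < best.fun:
            best = res
    lc50, slope = float(np.exp(best.x[0])), float(np.exp(best.x[1]))
    return DoseResponseFit(
        lc50=lc50,
        slope=slope,
        timepoint=timepoint,
        endpoint_label=endpoint_label,
        fitted_timepoint=fitted_timepoint,
    )


def to_toxic_units(profile: ExposureProfile, fit: DoseResponseFit) -> ExposureProfile:
    """Normalize a profile to toxic units by dividing all levels by the LC50."""
    if profile.is_toxic_units:
        raise ValueError("profile is already in toxic units")
    out = profile.scaled(1.0 / fit.lc50)
    out.is_toxic_units = True
    out.unit_label = "TU"
    return out


def from_toxic_units(profile: ExposureProfile, fit: DoseResponseFit, unit_label: str = "") -> ExposureProfile:
    """Invert :func:`to_toxic_units` (multiply levels by the LC50)."""
    if not profile.is_toxic_units:
        raise ValueError("profile is not in toxic units")
    out = profile.scaled(fit.lc50)
    out.is_toxic_units = False
    out.unit_label = unit_label
    return out
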