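"""Segmentation of aging kinetics into unidirectional stages.

Colloidal aging under heat stress typically shows two-stage behaviour in a
channel — e.g. supernatant iron first drops (adsorption/co-precipitation with
growing clusters) and later rises (cluster degradation releases iron).  Each
stage is well described by a straight line, so the pipeline:

1. finds the breakpoint by exhaustive search over sample times, minimising
   the total squared error of two independent linear fits;
2. accepts the split only when it reduces the SSE by more than 20 % relative
   to a single line, otherwise the series is one stage;
3. labels each stage decrease/increase/flat from its fitted slope;
4. converts a stage fit into a threshold-crossing time (e.g. "time for a
   25 % drop in supernatant iron"), the quantity the Van't Hoff
   extrapolation needs.

Fits use ordinary least squares in absolute time: the intercept is the value
of the fitted line at t = 0, so crossing times come out directly as
t = (target - intercept) / slope.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from nanoshelf.data_model_io import Channel, KineticSeries

__all__ = [
    "LinearFit",
    "Stage",
    "BreakpointResult",
    "ThresholdCrossing",
    "CoronaEstimate",
    "fit_linear",
    "find_breakpoint",
    "segment_unidirectional",
    "threshold_time",
    "percent_change_target",
    "corona_thickness",
]

MIN_POINTS_PER_SEGMENT = 3
SSE_REDUCTION_TO_SPLIT = 0.20
DEFAULT_FLAT_TOL = 0.02


class InsufficientDataError(ValueError):
    pass


class NoCrossingError(ValueError):
    pass


class NegativeTimeError(ValueError):
    pass


@dataclass(frozen=True)
class LinearFit:
    """OLS line over one stage; intercept is the fitted value at t = 0."""

    slope: float
    intercept: float
    slope_se: float
    r_squared: float
    n_points: int
    t_start_min: float
    t_end_min: float

    def predict(self, t: float) -> float:
        return self.intercept + self.slope * t

    @property
    def value_at_start(self) -> float:
        return self.predict(self.t_start_min)


@dataclass(frozen=True)
class Stage:
    direction: str  # "decrease" | "increase" | "flat"
    fit: LinearFit
    channel: Channel


@dataclass(frozen=True)
class BreakpointResult:
    breakpoint_min: float
    sse_two_stage: float
    sse_profile: list[tuple[float, float]] = field(repr=False)
    degenerate: bool = False


@dataclass(frozen=True)
class ThresholdCrossing:
    time_min: float
    target: float
    extrapolated: bool


@dataclass(frozen=True)
class CoronaEstimate:
    thickness_nm: float
    no_corona: bool


def _channel_arrays(
    series: KineticSeries, channel: Channel
) -> tuple[np.ndarray, np.ndarray]:
    t = np.asarray(series.times(channel), dtype=float)
    y = np.asarray(series.values(channel), dtype=float)
    return t, y


def fit_linear(t: np.ndarray, y: np.ndarray) -> LinearFit:
    """Ordinary least-squares line through the points of one stage."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 points for a linear fit")
    res = stats.linregress(t, y)
    slope_se = 0.0 if math.isnan(res.stderr) else float(res.stderr)
    r2 = float(res.rvalue**2)
    if math.isnan(r2):  # zero-variance y: perfect flat fit
        r2 = 1.0
    return LinearFit(
        slope=float(res.slope),
        intercept=float(res.intercept),
        slope_se=slope_se,
        r_squared=r2,
        n_points=len(t),
        t_start_min=float(t[0]),
        t_end_min=float(t[-1]),
    )


def _sse(t: np.ndarray, y: np.ndarray) -> float:
    fit = fit_linear(t, y)
    resid = y - (fit.intercept + fit.slope * t)
    return float(np.sum(resid**2))


def find_breakpoint(series: KineticSeries, channel: Channel) -> BreakpointResult:
    """Exhaustive breakpoint search over sample times.

    Candidate breakpoints are sample times with at least
    ``MIN_POINTS_PER_SEGMENT`` points on each side; the breakpoint sample is
    shared by both segments.  Returns the time minimising the total SSE of
    the two independent OLS fits, with the full SSE profile for diagnostics.
    A flat profile (all candidate SSEs equal within numerical tolerance) is
    flagged degenerate and the earliest admissible breakpoint is returned.
    """
    t, y = _channel_arrays(series, channel)
    n = len(t)
    if n < 2 * MIN_POINTS_PER_SEGMENT:
        raise InsufficientDataError(
            f"breakpoint search needs >= {2 * MIN_POINTS_PER_SEGMENT} points "
            f"with channel {channel.value}, got {n}"
        )
    profile: list[tuple[float, float]] = []
    for j in range(MIN_POINTS_PER_SEGMENT - 1, n - MIN_POINTS_PER_SEGMENT + 1):
        sse = _sse(t[: j + 1], y[: j + 1]) + _sse(t[j:], y[j:])
        profile.append((float(t[j]), sse))
    sses = np.array([s for _, s in profile])
    best = int(np.argmin(sses))
    scale = max(float(np.max(sses)), float(np.sum(y**2)), 1.0)
    degenerate = bool(np.ptp(sses) <= 1e-10 * scale)
    if degenerate:
        best = 0
    return BreakpointResult(
        breakpoint_min=profile[best][0],
        sse_two_stage=profile[best][1],
        sse_profile=profile,
        degenerate=degenerate,
    )


def _direction(fit: LinearFit, y_mean: float, flat_tol: float) -> str:
    """Label a stage by slope sign; tiny relative change over the stage is flat."""
    span = fit.t_end_min - fit.t_start_min
    total_change = abs(fit.slope) * span
    if y_mean != 0 and total_change / abs(y_mean) < flat_tol:
        return "flat"
    if fit.slope == 0:
        return "flat"
    return "decrease" if fit.slope < 0 else "increase"


def segment_unidirectional(
    series: KineticSeries,
    channel: Channel,
    flat_tol: float = DEFAULT_FLAT_TOL,
) -> list[Stage]:
    """Split a series into one or two unidirectional stages.

    The two-stage model is accepted when it reduces the SSE by more than
    20 % relative to a single line; series too short for a breakpoint search
    are fitted as a single stage.
    """
    t, y = _channel_arrays(series, channel)
    if len(t) < 2:
        raise InsufficientDataError("need at least 2 points to segment")
    one = fit_linear(t, y)
    sse_one = _sse(t, y)

    stages_single = [Stage(_direction(one, float(np.mean(y)), flat_tol), one, channel)]
    if len(t) < 2 * MIN_POINTS_PER_SEGMENT:
        return stages_single

    bp = find_breakpoint(series, channel)
    if bp.degenerate:
        return stages_single
    if sse_one > 0 and (sse_one - bp.sse_two_stage) / sse_one <= SSE_REDUCTION_TO_SPLIT:
        return stages_single
    if sse_one == 0:  # already a perfect single line
        return stages_single

    j = int(np.searchsorted(t, bp.breakpoint_min))
    left = fit_linear(t[: j + 1], y[: j + 1])
    right = fit_linear(t[j:], y[j:])
    return [
        Stage(_direction(left, float(np.mean(y[: j + 1])), flat_tol), left, channel),
        Stage(_direction(right, float(np.mean(y[j:])), flat_tol), right, channel),
    ]


def threshold_time(fit: LinearFit, target: float) -> ThresholdCrossing:
    """Time at which the fitted line reaches ``target``.

    t = (target - intercept) / slope.  The crossing is flagged extrapolated
    when it falls outside the fitted window [t_start, t_end] — e.g. a 25 %
    iron drop predicted between sparse sampling points.
    """
    if fit.slope == 0:
        raise NoCrossingError("slope is zero: the line never reaches the target")
    t = (target - fit.intercept) / fit.slope
    if t < 0:
        raise NegativeTimeError(f"crossing at negative time {t:.3g} min")
    extrapolated = not (fit.t_start_min <= t <= fit.t_end_min)
    return ThresholdCrossing(time_min=t, target=target, extrapolated=extrapolated)


def percent_change_target(initial: float, percent: float, direction: str) -> float:
    """Channel value after a given percent decrease or increase from initial."""
    if not 0 < percent < 100:
        raise ValueError("percent must be in (0, 100)")
    if initial <= 0:
        raise ValueError("initial value must be positive")
    if direction == "decrease":
        return initial * (1.0 - percent / 100.0)
    if direction == "increase":
        return initial * (1.0 + percent / 100.0)
    raise ValueError(f"direction must be 'decrease' or 'increase', got {direction!r}")


def corona_thickness(d_with_albumin_nm: float, d_without_nm: float) -> CoronaEstimate:
    """Protein-corona layer as the Z-average size difference with vs without
    albumin (the full size difference, not half).  A negative difference is
    returned with the ``no_corona`` flag rather than raising."""
    if d_with_albumin_nm <= 0 or d_without_nm <= 0:
        raise ValueError("diameters must be positive")
    diff = d_with_albumin_nm - d_without_nm
    return CoronaEstimate(thickness_nm=diff, no_corona=diff < 0)
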