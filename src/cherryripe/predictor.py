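"""Harvest prediction from the early-season reference state.

The reference state t0 is the moment the NAI crosses zero on its way up,
at which point the NDVI should lie between -0.5 and -0.4.  From t0 the
optimum harvest date follows a fixed horizon:

    OHD = t0 + 12 to 14 days

with the 13-day midpoint used as the point estimate and an additional
±2-day uncertainty attributable to growth conditions reported as metadata.

A measurement taken before t0 (negative NAI) is projected forward with a
linear pre-t0 progression rate (NAI units per day).  The default rate,
0.55/6 ≈ 0.0917/day, is the unique linear calibration under which a state
of NAI = -0.55 is 6 days short of t0 and hence 19 days short of harvest —
together with the 13-day midpoint.  The rate can be re-estimated from a
user's own early-season series with :func:`calibrate_pre_t0_rate`.
"""

from __future__ import annotations

import datetime
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .errors import CalibrationError, ConfigurationError, ValidationError
from .trajectory import FittedCurve, IndexSeries, MaturityCriteria

#: Default pre-t0 NAI progression rate (index units per day).
DEFAULT_PRE_T0_RATE = 0.55 / 6.0

#: Tolerance within which a measured NAI counts as "at zero" (the t0 state).
T0_NAI_TOLERANCE = 0.005


def _shift(origin, days: float):
    """Add (possibly fractional) days to a calendar date or a relative day.

    Calendar dates move by the round-half-to-even integer number of days;
    relative (float) origins move exactly.
    """
    if isinstance(origin, datetime.date):
        return origin + datetime.timedelta(days=round(days))
    return float(origin) + days


def _delta_days(a, b) -> float:
    """Days from b to a, for matching calendar or relative origins."""
    if isinstance(a, datetime.date) and isinstance(b, datetime.date):
        return float((a - b).days)
    return float(a) - float(b)


@dataclass(frozen=True)
class MaturityState:
    """A single pre-harvest observation: date plus the two indices."""

    date: object
    nai: float
    ndvi: float

    def __post_init__(self):
        for name in ("nai", "ndvi"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < -1.0 or v > 1.0:
                raise ValidationError(f"{name} must lie in [-1, 1], got {v!r}")


@dataclass(frozen=True)
class T0Result:
    """Location of the NAI zero upcrossing and the NDVI state there."""

    status: str
    t0_day: float | None = None
    ndvi_at_t0: float | None = None
    ndvi_in_range: bool | None = None

    @property
    def found(self) -> bool:
        return self.status == "found"


@dataclass(frozen=True)
class OhdPrediction:
    """Predicted optimum harvest date.

    ``model_interval`` carries the 12–14-day horizon spread; the ±2-day
    growth-condition uncertainty is a separate metadata field, not folded
    into the interval.  ``regime`` records which branch of the model was
    used: at_t0, pre_t0, post_t0 (between t0 and the plateau) or
    at_or_past_ohd.
    """

    point_date: object
    model_interval: tuple
    condition_uncertainty_days: int
    regime: str
    t0_date: object = None
    warnings: tuple = ()

    def __post_init__(self):
        lo, hi = self.model_interval
        if _delta_days(lo, self.point_date) > 1e-9 or _delta_days(self.point_date, hi) > 1e-9:
            raise ValidationError("model interval must bracket the point prediction")

    def days_after(self, origin) -> float:
        """Days from ``origin`` to the point prediction."""
        return _delta_days(self.point_date, origin)


def find_t0(
    nai_curve: FittedCurve,
    ndvi_curve: FittedCurve,
    criteria: MaturityCriteria | None = None,
    extend_days: float = 0.0,
) -> T0Result:
    """Locate t0: the upcrossing of the fitted NAI curve through zero.

    The root is bracketed on a 0.25-day scan of the NAI curve's domain
    (optionally extended by ``extend_days`` on both sides, for series that
    started after the colour break) and polished by Brent's method to
    1e-6 day.  The NDVI value at t0 is reported together with a flag for
    whether it falls inside the expected (-0.5, -0.4) window — the flag is
    advisory, not blocking.
    """
    crit = criteria or MaturityCriteria()
    lo = nai_curve.domain[0] - extend_days
    hi = nai_curve.domain[1] + extend_days

    def f(t):
        return float(np.asarray(nai_curve.value(t, extend=True))) - crit.t0_nai_value

    ts = np.arange(lo, hi + 1e-9, 0.25)
    vals = np.array([f(t) for t in ts])
    crossing = None
    for i in range(len(ts) - 1):
        if vals[i] < 0 <= vals[i + 1]:
            crossing = (ts[i], ts[i + 1], vals[i + 1])
            break
    if crossing is None:
        # no upcrossing: the curve never reaches zero, or was above it all along
        return T0Result(status="not_reached")
    a, b, fb = crossing
    t0 = float(b) if fb == 0.0 else float(brentq(f, a, b, xtol=1e-6))
    ndvi_at = float(np.asarray(ndvi_curve.value(t0, extend=True)))
    in_range = crit.t0_ndvi_range[0] <= ndvi_at <= crit.t0_ndvi_range[1]
    return T0Result(status="found", t0_day=t0, ndvi_at_t0=ndvi_at, ndvi_in_range=bool(in_range))


def predict_from_t0(t0_date, criteria: MaturityCriteria | None = None) -> OhdPrediction:
    """Project the harvest window from a known t0 date.

    ``t0_date`` may be a calendar date or a relative day number; the
    prediction uses the criteria's horizon (default 12–14 days) with the
    midpoint as the point estimate.
    """
    crit = criteria or MaturityCriteria()
    lo, hi = crit.horizon_days
    return OhdPrediction(
        point_date=_shift(t0_date, crit.horizon_midpoint_days),
        model_interval=(_shift(t0_date, lo), _shift(t0_date, hi)),
        condition_uncertainty_days=crit.condition_uncertainty_days,
        regime="at_t0",
        t0_date=t0_date,
    )


def predict_from_state(
    state: MaturityState,
    criteria: MaturityCriteria | None = None,
    pre_t0_rate: float | None = DEFAULT_PRE_T0_RATE,
    nai_curve: FittedCurve | None = None,
) -> OhdPrediction:
    """Predict the optimum harvest date from a single maturity state.

    Branches on the measured NAI:

    * |NAI| <= 0.005 — the state *is* t0; delegate to :func:`predict_from_t0`
      (with a warning if NDVI is outside the expected t0 window).
    * NAI < 0 — pre-t0: the time to t0 is (-NAI)/rate with the linear
      progression rate, then the horizon midpoint is added; the model
      interval is the point ±1 day.
    * NAI >= the lower OHD bound (0.7) — the fruit is already at or past
      harvest maturity; the prediction is the state date itself.
    * 0 < NAI < 0.7 — past t0 but below the plateau.  With a fitted NAI
      curve the elapsed time since t0 is read off the curve; without one a
      linear interpolation between t0 (NAI 0) and the harvest threshold
      (NAI 0.7) stands in, flagged with an "unsupported-regime" warning.
    """
    crit = criteria or MaturityCriteria()
    warnings: list[str] = []
    mid = crit.horizon_midpoint_days

    if abs(state.nai - crit.t0_nai_value) <= T0_NAI_TOLERANCE:
        if not (crit.t0_ndvi_range[0] <= state.ndvi <= crit.t0_ndvi_range[1]):
            warnings.append(
                f"NDVI {state.ndvi:+.3f} at t0 lies outside the expected window "
                f"[{crit.t0_ndvi_range[0]:+.2f}, {crit.t0_ndvi_range[1]:+.2f}]"
            )
        base = predict_from_t0(state.date, crit)
        return OhdPrediction(
            point_date=base.point_date,
            model_interval=base.model_interval,
            condition_uncertainty_days=base.condition_uncertainty_days,
            regime="at_t0",
            t0_date=state.date,
            warnings=tuple(warnings),
        )

    if state.nai < crit.t0_nai_value:
        if pre_t0_rate is None:
            raise ConfigurationError(
                "pre-t0 state requires a progression rate; pass pre_t0_rate or "
                "calibrate one with calibrate_pre_t0_rate"
            )
        if pre_t0_rate <= 0:
            raise ConfigurationError("pre_t0_rate must be positive")
        days_to_t0 = (crit.t0_nai_value - state.nai) / pre_t0_rate
        total = days_to_t0 + mid
        point = _shift(state.date, round(total))
        return OhdPrediction(
            point_date=point,
            model_interval=(_shift(point, -1), _shift(point, 1)),
            condition_uncertainty_days=crit.condition_uncertainty_days,
            regime="pre_t0",
            t0_date=_shift(state.date, round(days_to_t0)),
            warnings=tuple(warnings),
        )

    if state.nai >= crit.nai_ohd_range[0]:
        return OhdPrediction(
            point_date=state.date,
            model_interval=(state.date, state.date),
            condition_uncertainty_days=crit.condition_uncertainty_days,
            regime="at_or_past_ohd",
            warnings=tuple(warnings),
        )

    # between t0 and the plateau
    if nai_curve is not None:
        def g(t):
            return float(np.asarray(nai_curve.value(t, extend=True))) - state.nai

        lo, hi = nai_curve.domain
        ts = np.arange(lo - 30.0, hi + 30.0, 0.25)
        t_state = None
        prev = g(ts[0])
        for t in ts[1:]:
            cur = g(t)
            if prev < 0 <= cur:
                t_state = brentq(g, t - 0.25, t, xtol=1e-6)
                break
            prev = cur
        t0_res = find_t0(nai_curve, nai_curve, crit, extend_days=30.0)
        if t_state is not None and t0_res.found:
            elapsed = t_state - t0_res.t0_day
            remaining = max(mid - elapsed, 0.0)
        else:
            warnings.append("unsupported-regime: could not place the state on the fitted curve")
            remaining = mid * (1.0 - state.nai / crit.nai_ohd_range[0])
    else:
        warnings.append(
            "unsupported-regime: NAI between t0 and the plateau without a fitted "
            "curve; using linear interpolation between NAI 0 and the harvest threshold"
        )
        remaining = mid * (1.0 - state.nai / crit.nai_ohd_range[0])
    point = _shift(state.date, round(remaining))
    return OhdPrediction(
        point_date=point,
        model_interval=(_shift(point, -1), _shift(point, 1)),
        condition_uncertainty_days=crit.condition_uncertainty_days,
        regime="post_t0",
        warnings=tuple(warnings),
    )


def calibrate_pre_t0_rate(series: IndexSeries) -> float:
    """Estimate the pre-t0 NAI progression rate from an early-season series.

    Least-squares slope of the per-date NAI median against time, restricted
    to the pre-t0 colour-break range (NAI in [-0.6, 0]).  Requires at least
    three dates with negative NAI medians.

    Raises
    ------
    CalibrationError
        If the slope is not positive (the fruit is not ripening).
    """
    negative = series.nai_median < 0
    if int(np.sum(negative)) < 3:
        raise ValidationError("calibration requires at least 3 dates with negative NAI medians")
    mask = (series.nai_median >= -0.6) & (series.nai_median <= 0.0)
    t = series.days[mask]
    y = series.nai_median[mask]
    if t.size < 2:
        raise ValidationError("too few dates inside the calibration range [-0.6, 0]")
    slope = float(np.polyfit(t, y, 1)[0])
    if slope <= 0:
        raise CalibrationError(f"estimated NAI slope {slope:.4f}/day is not positive; fruit not ripening")
    return slope
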