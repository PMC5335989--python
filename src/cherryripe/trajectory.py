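"""Ripening trajectories: per-date medians, curve fitting, OHD detection.

Per-fruit index records are pooled per sampling date (both sides of all
fruit) and summarized by the median.  The median series is fitted with a
four-parameter logistic

    y(t) = L + (U - L) / (1 + exp(-k (t - m)))

whose derivative decays to zero on the plateau — the behaviour the optimum
harvest date (OHD) criteria rely on.  A cubic polynomial is retained as a
fallback family for series the logistic cannot fit.

The OHD is the earliest time at which, jointly,

* NDVI(t) lies in [0, 0.2]  (chlorophyll essentially degraded),
* NAI(t) lies in [0.7, 0.8] (anthocyanins saturated), and
* |NAI'(t)| <= epsilon      (the anthocyanin curve has plateaued),

searched on a regular time grid.  The interval bounds are treated as closed
so the exact NDVI zero crossing qualifies.  "NAI'(t) = 0" is unattainable
exactly for a logistic, hence the epsilon tolerance; the default 0.01 index
units/day is below day-scale measurement resolution.
"""

from __future__ import annotations

import dataclasses
import datetime
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit
from scipy.special import expit

from .errors import (
    ConfigurationError,
    DegenerateSeriesError,
    FitError,
    ValidationError,
)
from .spectra import IndexRecord

Channel = Literal["nai", "ndvi"]

_CRITERIA_ORDER = ("ndvi_range", "nai_range", "nai_derivative")


# ---------------------------------------------------------------------------
# logistic family
# ---------------------------------------------------------------------------

def logistic4(t, lower, upper, rate, midpoint):
    """Four-parameter logistic L + (U-L)/(1+exp(-k(t-m))), overflow-safe."""
    t = np.asarray(t, dtype=float)
    return lower + (upper - lower) * expit(rate * (t - midpoint))


def logistic4_derivative(t, lower, upper, rate, midpoint):
    """Analytic first derivative k(U-L)s(1-s) with s the inner sigmoid."""
    t = np.asarray(t, dtype=float)
    s = expit(rate * (t - midpoint))
    return rate * (upper - lower) * s * (1.0 - s)


# ---------------------------------------------------------------------------
# series aggregation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IndexSeries:
    """Per-date median NAI/NDVI series on a days-since-first-observation axis.

    ``start_date`` keeps the calendar anchor (day 0.0 on the ``days`` axis)
    when the input records carried calendar dates; it is ``None`` for purely
    relative (simulated) time axes.
    """

    days: np.ndarray
    nai_median: np.ndarray
    ndvi_median: np.ndarray
    n_per_date: np.ndarray
    start_date: datetime.date | None = None

    def __post_init__(self):
        days = np.asarray(self.days, dtype=float)
        nai = np.asarray(self.nai_median, dtype=float)
        ndvi = np.asarray(self.ndvi_median, dtype=float)
        n = np.asarray(self.n_per_date, dtype=int)
        for name, arr in (("days", days), ("nai_median", nai), ("ndvi_median", ndvi), ("n_per_date", n)):
            object.__setattr__(self, name, arr)
        if not (days.size == nai.size == ndvi.size == n.size):
            raise ValidationError("series arrays must have equal length")
        if days.size == 0:
            raise ValidationError("series must contain at least one date")
        if np.any(np.diff(days) <= 0):
            raise ValidationError("series days must be strictly increasing")
        if np.any(n <= 0):
            raise ValidationError("n_per_date entries must be positive")

    def __len__(self):
        return self.days.size

    def channel(self, channel: Channel) -> np.ndarray:
        if channel == "nai":
            return self.nai_median
        if channel == "ndvi":
            return self.ndvi_median
        raise ValidationError(f"unknown channel {channel!r}")

    def day_to_date(self, day: float) -> datetime.date | None:
        if self.start_date is None:
            return None
        return self.start_date + datetime.timedelta(days=round(float(day)))


def aggregate_median(records: Iterable[IndexRecord]) -> IndexSeries:
    """Pool all records per date (both sides of all fruit) and take medians.

    Even per-date counts use the conventional mean of the two central order
    statistics.  The time axis is days since the first observation.
    """
    records = list(records)
    if not records:
        raise ValidationError("aggregate_median requires at least one record")
    df = pd.DataFrame(
        {
            "date": [r.date for r in records],
            "nai": [r.nai for r in records],
            "ndvi": [r.ndvi for r in records],
        }
    )
    grouped = df.groupby("date", sort=True)
    agg = grouped.agg(nai_median=("nai", "median"), ndvi_median=("ndvi", "median"), n=("nai", "size"))
    dates = list(agg.index)
    first = dates[0]
    if isinstance(first, datetime.date):
        days = np.array([(d - first).days for d in dates], dtype=float)
        start_date = first
    else:
        days = np.asarray(dates, dtype=float) - float(first)
        start_date = None
    return IndexSeries(
        days=days,
        nai_median=agg["nai_median"].to_numpy(),
        ndvi_median=agg["ndvi_median"].to_numpy(),
        n_per_date=agg["n"].to_numpy(),
        start_date=start_date,
    )


def write_series_csv(series: IndexSeries, path) -> None:
    df = pd.DataFrame(
        {
            "date": [series.day_to_date(d) if series.start_date else d for d in series.days],
            "nai_median": series.nai_median,
            "ndvi_median": series.ndvi_median,
            "n": series.n_per_date,
        }
    )
    df.to_csv(path, index=False)


def read_series_csv(path) -> IndexSeries:
    df = pd.read_csv(path)
    required = {"date", "nai_median", "ndvi_median", "n"}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"series CSV missing columns: {sorted(missing)}")
    try:
        dates = [datetime.date.fromisoformat(str(d)) for d in df["date"]]
        first = dates[0]
        days = np.array([(d - first).days for d in dates], dtype=float)
        start = first
    except ValueError:
        days = df["date"].to_numpy(float)
        days = days - days[0]
        start = None
    return IndexSeries(
        days=days,
        nai_median=df["nai_median"].to_numpy(float),
        ndvi_median=df["ndvi_median"].to_numpy(float),
        n_per_date=df["n"].to_numpy(int),
        start_date=start,
    )


# ---------------------------------------------------------------------------
# fitted curves
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FittedCurve:
    """A fitted ripening curve with an analytic first derivative.

    Parameters
    ----------
    family : {"logistic4", "polynomial"}
    params : tuple of float
        ``(lower, upper, rate, midpoint)`` for logistic4; ascending
        polynomial coefficients otherwise.
    domain : (float, float)
        Time span (days) covered by the data the curve was fitted to.
        Evaluation outside the domain requires ``extend=True``.
    fit_residual_rms : float
        Root-mean-square residual of the fit (0 for curves built from known
        parameters).
    """

    family: str
    params: tuple
    domain: tuple
    fit_residual_rms: float = 0.0

    def __post_init__(self):
        if self.family not in ("logistic4", "polynomial"):
            raise ValidationError(f"unknown curve family {self.family!r}")
        object.__setattr__(self, "params", tuple(float(p) for p in self.params))
        lo, hi = self.domain
        if not lo < hi:
            raise ValidationError("curve domain must be a non-empty interval")
        object.__setattr__(self, "domain", (float(lo), float(hi)))
        if self.family == "logistic4":
            lower, upper, rate, _ = self.params
            if not (upper > lower and rate > 0):
                raise ValidationError("logistic4 requires upper > lower and rate > 0")
        if self.fit_residual_rms < 0:
            raise ValidationError("fit_residual_rms must be >= 0")

    def _check_domain(self, t, extend):
        if extend:
            return
        t = np.asarray(t, dtype=float)
        lo, hi = self.domain
        if np.any(t < lo - 1e-9) or np.any(t > hi + 1e-9):
            raise ValidationError(
                f"t outside curve domain [{lo:g}, {hi:g}]; pass extend=True to extrapolate"
            )

    def value(self, t, extend: bool = False):
        self._check_domain(t, extend)
        if self.family == "logistic4":
            out = logistic4(t, *self.params)
        else:
            out = np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), np.asarray(self.params))
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out

    def derivative(self, t, extend: bool = False):
        self._check_domain(t, extend)
        if self.family == "logistic4":
            out = logistic4_derivative(t, *self.params)
        else:
            dcoef = np.polynomial.polynomial.polyder(np.asarray(self.params))
            out = np.polynomial.polynomial.polyval(np.asarray(t, dtype=float), dcoef)
        return float(out) if np.isscalar(t) or np.ndim(t) == 0 else out


def _logistic_initial_guess(t, y):
    lo, hi = float(np.min(y)), float(np.max(y))
    span = hi - lo
    mid_target = lo + span / 2.0
    m0 = float(t[np.argmin(np.abs(y - mid_target))])
    # secant slope at the steepest segment -> k0 = 4*slope/span
    slopes = np.diff(y) / np.diff(t)
    k0 = 4.0 * float(np.max(np.abs(slopes))) / span if span > 0 else 0.3
    k0 = min(max(k0, 0.01), 3.0)
    return [lo - 0.05 * span, hi + 0.05 * span, k0, m0]


def _fit_logistic(t, y):
    p0 = _logistic_initial_guess(t, y)
    bounds = (
        [-1.5, -1.5, 1e-4, t[0] - 60.0],
        [1.5, 1.5, 5.0, t[-1] + 60.0],
    )
    p0 = [min(max(p, lo), hi) for p, lo, hi in zip(p0, bounds[0], bounds[1])]
    try:
        popt, _ = curve_fit(
            logistic4, t, y, p0=p0, bounds=bounds, method="trf",
            maxfev=50000, xtol=1e-13, ftol=1e-13, gtol=1e-13,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(f"logistic fit did not converge: {exc}") from exc
    lower, upper, rate, midpoint = popt
    if not (np.all(np.isfinite(popt)) and upper > lower and rate > 0):
        raise FitError("logistic fit converged to an invalid parameter set")
    return tuple(float(p) for p in popt)


def _fit_cubic(t, y):
    # fit in numpy's scaled Chebyshev-free basis, convert back to plain coeffs
    poly = np.polynomial.Polynomial.fit(t, y, deg=3).convert()
    return tuple(float(c) for c in poly.coef)


def fit_curve(series: IndexSeries, channel: Channel, family: str = "logistic4") -> FittedCurve:
    """Least-squares fit of one index channel of a median series.

    ``logistic4`` is the default family; when it fails to converge the cubic
    polynomial fallback is used automatically.  Pass ``family="polynomial"``
    to force the cubic.  The fit is deterministic: fixed initial guess, no
    randomness.

    Raises
    ------
    DegenerateSeriesError
        If the channel values are all identical.
    FitError
        If no admissible family converges.
    """
    y = series.channel(channel)
    t = series.days
    if len(series) < 4:
        raise ValidationError("curve fitting requires at least 4 dates")
    if np.ptp(y) == 0:
        raise DegenerateSeriesError(f"channel {channel!r} is constant; nothing to fit")
    domain = (float(t[0]), float(t[-1]))
    if family == "logistic4":
        try:
            params = _fit_logistic(t, y)
            fam = "logistic4"
        except FitError:
            params = _fit_cubic(t, y)
            fam = "polynomial"
    elif family == "polynomial":
        params = _fit_cubic(t, y)
        fam = "polynomial"
    else:
        raise ValidationError(f"unknown fit family {family!r}")
    curve = FittedCurve(family=fam, params=params, domain=domain)
    resid = y - curve.value(t)
    return dataclasses.replace(curve, fit_residual_rms=float(np.sqrt(np.mean(resid**2))))


# ---------------------------------------------------------------------------
# maturity criteria and OHD detection
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MaturityCriteria:
    """All thresholds of the maturity model.

    * ``ndvi_ohd_range`` / ``nai_ohd_range``: closed index intervals both
      indices must occupy at the optimum harvest date.
    * ``derivative_epsilon``: plateau tolerance on |NAI'(t)| (index/day).
    * ``t0_nai_value`` / ``t0_ndvi_range``: the reference state — NAI crosses
      zero while NDVI sits between -0.5 and -0.4.
    * ``horizon_days``: harvest is expected 12–14 days after t0.
    * ``condition_uncertainty_days``: ±2-day spread from growth conditions
      (sunny weather accelerates, cool/rainy weather delays ripening),
      reported as metadata alongside the model interval.
    """

    ndvi_ohd_range: tuple = (0.0, 0.2)
    nai_ohd_range: tuple = (0.7, 0.8)
    derivative_epsilon: float = 0.01
    t0_nai_value: float = 0.0
    t0_ndvi_range: tuple = (-0.5, -0.4)
    horizon_days: tuple = (12.0, 14.0)
    condition_uncertainty_days: int = 2

    def __post_init__(self):
        for name in ("ndvi_ohd_range", "nai_ohd_range", "t0_ndvi_range", "horizon_days"):
            pair = tuple(float(v) for v in getattr(self, name))
            if len(pair) != 2 or pair[0] > pair[1]:
                raise ValidationError(f"{name} must be an ordered pair")
            object.__setattr__(self, name, pair)
        if self.derivative_epsilon < 0:
            raise ValidationError("derivative_epsilon must be >= 0")

    @property
    def horizon_midpoint_days(self) -> float:
        return 0.5 * (self.horizon_days[0] + self.horizon_days[1])

    def to_dict(self) -> dict:
        return {
            "ndvi_ohd_range": list(self.ndvi_ohd_range),
            "nai_ohd_range": list(self.nai_ohd_range),
            "derivative_epsilon": self.derivative_epsilon,
            "t0_nai_value": self.t0_nai_value,
            "t0_ndvi_range": list(self.t0_ndvi_range),
            "horizon_days": list(self.horizon_days),
            "condition_uncertainty_days": self.condition_uncertainty_days,
        }

    @classmethod
    def from_dict(cls, data: dict) -> "MaturityCriteria":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(f"unknown criteria keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "MaturityCriteria":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError("criteria YAML must contain a mapping")
        return cls.from_dict(data)


@dataclass(frozen=True)
class OhdDetection:
    """Result of the joint OHD grid search.

    ``status`` is "detected" or "not_reached".  ``binding`` lists the
    criteria that were still unmet one grid step before detection (the
    constraints that set the date); ``first_unmet`` names, for a not-reached
    result, the first criterion in evaluation order (NDVI range, NAI range,
    NAI derivative) that never holds jointly with its predecessors.
    """

    status: str
    t_ohd: float | None
    nai_at_ohd: float | None = None
    ndvi_at_ohd: float | None = None
    nai_slope_at_ohd: float | None = None
    binding: tuple = ()
    first_unmet: str | None = None
    grid_step_days: float = 0.25

    @property
    def detected(self) -> bool:
        return self.status == "detected"


def detect_ohd(
    nai_curve: FittedCurve,
    ndvi_curve: FittedCurve,
    criteria: MaturityCriteria | None = None,
    grid_step_days: float = 0.25,
) -> OhdDetection:
    """Earliest grid time satisfying all three OHD criteria.

    Scans the intersection of the two curve domains on a regular grid
    (default 0.25 day) and returns the first time at which NDVI and NAI are
    inside their harvest windows and the NAI slope has dropped below
    ``derivative_epsilon``.  A trajectory that never qualifies yields a
    not-reached status (not an error) naming the first unmet criterion.
    """
    crit = criteria or MaturityCriteria()
    if grid_step_days <= 0:
        raise ValidationError("grid_step_days must be > 0")
    lo = max(nai_curve.domain[0], ndvi_curve.domain[0])
    hi = min(nai_curve.domain[1], ndvi_curve.domain[1])
    if lo >= hi:
        raise ValidationError("curves share no common time domain")
    ts = np.arange(lo, hi + grid_step_days * 1e-6, grid_step_days)
    nai = np.asarray(nai_curve.value(ts))
    ndvi = np.asarray(ndvi_curve.value(ts))
    slope = np.abs(np.asarray(nai_curve.derivative(ts)))
    ok = {
        "ndvi_range": (ndvi >= crit.ndvi_ohd_range[0]) & (ndvi <= crit.ndvi_ohd_range[1]),
        "nai_range": (nai >= crit.nai_ohd_range[0]) & (nai <= crit.nai_ohd_range[1]),
        "nai_derivative": slope <= crit.derivative_epsilon,
    }
    joint = ok["ndvi_range"] & ok["nai_range"] & ok["nai_derivative"]
    if np.any(joint):
        i = int(np.argmax(joint))
        binding = tuple(name for name in _CRITERIA_ORDER if i > 0 and not ok[name][i - 1])
        return OhdDetection(
            status="detected",
            t_ohd=float(ts[i]),
            nai_at_ohd=float(nai[i]),
            ndvi_at_ohd=float(ndvi[i]),
            nai_slope_at_ohd=float(np.asarray(nai_curve.derivative(ts[i]))),
            binding=binding,
            grid_step_days=grid_step_days,
        )
    # not reached: find the first criterion that never holds jointly with
    # the ones before it in evaluation order
    mask = np.ones_like(joint, dtype=bool)
    first_unmet = _CRITERIA_ORDER[-1]
    for name in _CRITERIA_ORDER:
        if not np.any(mask & ok[name]):
            first_unmet = name
            break
        mask &= ok[name]
    return OhdDetection(
        status="not_reached",
        t_ohd=None,
        first_unmet=first_unmet,
        grid_step_days=grid_step_days,
    )
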