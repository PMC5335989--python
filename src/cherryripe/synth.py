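"""Synthetic ripening datasets with the reported trajectory structure.

The simulator emulates a season of 2-day-cadence orchard measurements: both
indices follow four-parameter logistic curves rising through maturation,
with the time axis anchored so that day 0 is t0 (the NAI zero upcrossing).

Default curve constants (solved from the reported anchor points, with day 0
at t0):

* NAI:  lower -0.6 (breaker stage), upper 0.8 (overripe plateau), rate
  0.35/day, midpoint ln(4/3)/0.35 ≈ 0.822 d so that NAI(0) = 0 exactly.
  These give NAI(13) ≈ 0.780 and |NAI'(13)| ≈ 0.0067/day — inside the
  harvest window and below the plateau tolerance at the expected OHD.
* NDVI: lower -0.5, upper 0.5, midpoint 13 d (so NDVI(13) = 0 exactly,
  the harvest-date zero crossing), rate ln(19)/13 ≈ 0.2265/day so that
  NDVI(0) = -0.45, the centre of the expected t0 window.

Per-measurement noise is additive Gaussian on the index scale (default
sd 0.05), independent across fruit, sides and dates, clipped to
(-0.999, 0.999).  Each fruit draws from its own seeded stream so datasets
are bit-reproducible regardless of iteration order.

Band intensities are obtained by exact algebraic inversion of the index
formulas with the near-infrared band fixed as reference, so the index
computed from simulated bands reproduces the simulated index exactly.
"""

from __future__ import annotations

import datetime
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import ValidationError
from .spectra import IndexRecord
from .trajectory import FittedCurve, MaturityCriteria, detect_ohd, logistic4


@dataclass(frozen=True)
class LogisticParams:
    """Four-parameter logistic: lower/upper asymptote, rate (1/day), midpoint (day)."""

    lower: float
    upper: float
    rate: float
    midpoint: float

    def __post_init__(self):
        if not self.upper > self.lower:
            raise ValidationError("upper asymptote must exceed lower asymptote")
        if not self.rate > 0:
            raise ValidationError("rate must be positive")

    def value(self, t):
        return logistic4(t, self.lower, self.upper, self.rate, self.midpoint)

    def inverse(self, y: float) -> float:
        """Time at which the curve attains ``y`` (strictly between the asymptotes)."""
        if not self.lower < y < self.upper:
            raise ValidationError("value must lie strictly between the asymptotes")
        return self.midpoint - math.log((self.upper - y) / (y - self.lower)) / self.rate

    def curve(self, domain: tuple) -> FittedCurve:
        return FittedCurve(
            family="logistic4",
            params=(self.lower, self.upper, self.rate, self.midpoint),
            domain=domain,
        )


#: NAI defaults: breaker-stage -0.6 to overripe plateau +0.8; midpoint pinned
#: by NAI(0) = 0.
DEFAULT_NAI_LOGISTIC = LogisticParams(
    lower=-0.6, upper=0.8, rate=0.35, midpoint=math.log(4.0 / 3.0) / 0.35
)

#: NDVI defaults: -0.5 to +0.5 with the zero crossing at day 13 and
#: NDVI(0) = -0.45.
DEFAULT_NDVI_LOGISTIC = LogisticParams(
    lower=-0.5, upper=0.5, rate=math.log(19.0) / 13.0, midpoint=13.0
)


@dataclass(frozen=True)
class RipeningParams:
    """Study conditions for one simulated season.

    Defaults mirror the 2012 campaign: 30 fruit, two sides each, sampled at
    2-day intervals (the 2013 campaign used 20 fruit).  ``noise_sd`` is the
    per-measurement index noise standard deviation.
    """

    nai_logistic: LogisticParams = DEFAULT_NAI_LOGISTIC
    ndvi_logistic: LogisticParams = DEFAULT_NDVI_LOGISTIC
    t0_day: float = 0.0
    cadence_days: float = 2.0
    n_fruit: int = 30
    sides_per_fruit: int = 2
    noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.cadence_days <= 0:
            raise ValidationError("cadence_days must be positive")
        if self.n_fruit < 1 or self.sides_per_fruit < 1:
            raise ValidationError("n_fruit and sides_per_fruit must be >= 1")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.seed < 0:
            raise ValidationError("seed must be non-negative")


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind a simulated dataset."""

    params: RipeningParams
    t0_day: float
    ohd_day: float | None


@dataclass(frozen=True)
class SyntheticDataset:
    truth: SyntheticTruth
    records: tuple
    bands: pd.DataFrame | None = None


def reference_trajectory(params: RipeningParams | None = None, t=0.0):
    """Noise-free (NAI, NDVI) values at time ``t`` (days relative to t0)."""
    p = params or RipeningParams()
    shift = np.asarray(t, dtype=float) - p.t0_day
    nai = p.nai_logistic.value(shift)
    ndvi = p.ndvi_logistic.value(shift)
    if np.ndim(t) == 0:
        return float(nai), float(ndvi)
    return nai, ndvi


def index_to_band(v: float, reference_intensity: float = 1.0):
    """Band intensity whose index against the reference equals ``v`` exactly.

    Inverts ``v = (ref - x)/(ref + x)`` to ``x = ref (1 - v)/(1 + v)``.
    """
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(v) >= 1.0):
        raise ValidationError("index value must satisfy |v| < 1")
    if reference_intensity <= 0:
        raise ValidationError("reference_intensity must be positive")
    out = reference_intensity * (1.0 - v) / (1.0 + v)
    return float(out) if out.ndim == 0 else out


def true_curves(params: RipeningParams, domain: tuple) -> tuple:
    """The noise-free (NAI, NDVI) curves as FittedCurve objects on ``domain``."""
    p_nai = replace(
        params.nai_logistic, midpoint=params.nai_logistic.midpoint + params.t0_day
    )
    p_ndvi = replace(
        params.ndvi_logistic, midpoint=params.ndvi_logistic.midpoint + params.t0_day
    )
    return p_nai.curve(domain), p_ndvi.curve(domain)


def _true_ohd(params: RipeningParams, start_day: float, end_day: float) -> float | None:
    # detect on the noise-free curves; the grid starts on an integer day so
    # the canonical day-13 crossing sits exactly on a grid node
    lo = math.floor(start_day)
    hi = max(end_day, params.t0_day + params.ndvi_logistic.midpoint + 7.0)
    nai_curve, ndvi_curve = true_curves(params, (lo, hi))
    det = detect_ohd(nai_curve, ndvi_curve, MaturityCriteria())
    return det.t_ohd if det.detected else None


def simulate_orchard(
    params: RipeningParams | None = None,
    start_day: float = -8.0,
    end_day: float = 18.0,
    base_date=None,
    with_bands: bool = False,
) -> SyntheticDataset:
    """Simulate a season of per-fruit, per-side index measurements.

    Sampling dates run from ``start_day`` to ``end_day`` on the cadence
    grid (days relative to t0).  Each measurement is the reference
    trajectory value plus independent Gaussian noise, clipped to
    (-0.999, 0.999).  With ``base_date`` set, day ``d`` is mapped to the
    calendar date ``base_date + d`` (integer day offsets required).

    The truth block records the generating parameters, the true t0 and the
    true OHD obtained by running the detector on the noise-free curves.
    """
    p = params or RipeningParams()
    if start_day >= end_day:
        raise ValidationError("start_day must be < end_day")
    days = np.arange(start_day, end_day + p.cadence_days * 1e-6, p.cadence_days)
    if base_date is not None and not np.allclose(days, np.round(days)):
        raise ValidationError("calendar output requires integer day offsets")
    nai_true, ndvi_true = reference_trajectory(p, days)

    records = []
    bands_rows = [] if with_bands else None
    side_labels = [chr(ord("A") + s) for s in range(p.sides_per_fruit)]
    for i in range(p.n_fruit):
        fruit_id = f"F{i + 1:02d}"
        if p.noise_sd > 0:
            rng = np.random.default_rng([p.seed, i])
            noise = rng.normal(0.0, p.noise_sd, size=(2, len(days), p.sides_per_fruit))
        else:
            noise = np.zeros((2, len(days), p.sides_per_fruit))
        nai_obs = np.clip(nai_true[:, None] + noise[0], -0.999, 0.999)
        ndvi_obs = np.clip(ndvi_true[:, None] + noise[1], -0.999, 0.999)
        for j, d in enumerate(days):
            date = base_date + datetime.timedelta(days=int(round(d))) if base_date else float(d)
            for s, side in enumerate(side_labels):
                records.append(
                    IndexRecord(
                        date=date,
                        fruit_id=fruit_id,
                        side=side,
                        nai=float(nai_obs[j, s]),
                        ndvi=float(ndvi_obs[j, s]),
                    )
                )
                if bands_rows is not None:
                    bands_rows.append(
                        {
                            "date": date,
                            "fruit_id": fruit_id,
                            "side": side,
                            "i570": index_to_band(float(nai_obs[j, s])),
                            "i660": index_to_band(float(ndvi_obs[j, s])),
                            "i780": 1.0,
                        }
                    )
    truth = SyntheticTruth(params=p, t0_day=p.t0_day, ohd_day=_true_ohd(p, start_day, end_day))
    bands = pd.DataFrame(bands_rows) if bands_rows is not None else None
    return SyntheticDataset(truth=truth, records=tuple(records), bands=bands)


def make_truncated_cover_scenario(
    params: RipeningParams | None = None,
    end_day: float = 18.0,
    onset_nai: float = 0.35,
    base_date=None,
) -> SyntheticDataset:
    """A season whose observation window starts after t0.

    Emulates the under-cover 2012 series: ripening was already advanced when
    measurements began, with first-date NAI around +0.3 to +0.4, so the NAI
    zero crossing is never observed and must be extrapolated.  The window
    start is solved from the logistic inverse at ``onset_nai`` (default
    0.35, the centre of the reported onset range).
    """
    p = params or RipeningParams()
    start = p.t0_day + p.nai_logistic.inverse(onset_nai)
    if base_date is not None:
        start = math.ceil(start)
    return simulate_orchard(p, start_day=start, end_day=end_day, base_date=base_date)
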