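# Methods

## The maturity model

Sweet cherry lacks a starch-based maturity index, so ripeness is tracked
optically through two pigment proxies computed from remission spectra of the
fruit peel (400–1100 nm, contact spectrometer head):

* **NDVI** = (I780 − I660)/(I780 + I660), a proxy for chlorophyll,
* **NAI** = (I780 − I570)/(I780 + I570), a proxy for anthocyanins,

with I_x the remission intensity in a narrow band around x nm. Both indices
are confined to (−1, +1) for positive intensities. During ripening the
chlorophyll is degraded and anthocyanins accumulate, so both indices rise.
Two anchor states define the model:

* **t0** — the NAI zero upcrossing, with NDVI expected in (−0.5, −0.4);
* **OHD** (optimum harvest date) — NDVI in [0, 0.2], NAI in [0.7, 0.8], and
  the NAI curve has plateaued (first derivative ≈ 0).

Harvest is predicted as **OHD = t0 + 12 to 14 days** (midpoint 13 used as
the point estimate), with an additional ±2-day spread attributable to growth
conditions reported as metadata, not folded into the model interval — the
two sources of uncertainty are conceptually distinct (horizon spread of the
model vs. weather-driven acceleration/delay).

## Curve fitting

Per-date series are the **pooled medians** over both sides of all fruit
(sides are not averaged per fruit first; the median is robust either way and
pooling keeps the per-date n transparent). Time is measured in days since
the first observation; calendar dates are converted on ingestion.

The primary fit family is the four-parameter logistic

    y(t) = L + (U − L) / (1 + exp(−k (t − m))),

fitted by trust-region least squares with a deterministic data-driven
initial guess (asymptotes from the data range, rate from the steepest secant)
and box bounds keeping the asymptotes within the physically meaningful
[−1.5, 1.5] band and k in (10⁻⁴, 5]. The logistic is preferred over a raw
polynomial because the OHD criterion needs a derivative that genuinely
decays to zero on the plateau; high-order polynomials oscillate. A cubic
polynomial is retained as an automatic fallback for series the logistic
cannot fit, honouring the sigmoidal-polynomial description of the original
protocol. The derivative is always analytic: k(y−L)(U−y)/(U−L) for the
logistic, exact coefficient differentiation for the polynomial.

**Plateau tolerance.** "NAI′(t) = 0" is unattainable exactly for a logistic,
so the detector uses |NAI′(t)| ≤ ε with ε = 0.01 index units/day by default
— below day-scale measurement resolution. Interval bounds in the criteria
are treated as closed so the exact NDVI zero crossing qualifies.

**Detection numerics.** The OHD search walks a regular grid (default
0.25 day) over the intersection of the two curve domains and returns the
earliest time where all three criteria hold, recording which criteria were
still unmet one step earlier ("binding"). A trajectory that never qualifies
returns a *not-reached status*, naming the first criterion (in the order
NDVI range, NAI range, NAI derivative) that never holds jointly with its
predecessors — deliberately a status, not an error, since a truncated or
unripe season is a legitimate observation. t0 is located by a 0.25-day sign
scan plus Brent root polishing to 10⁻⁶ day; for windows that missed the
colour break, the search domain can be extended (`extend_days`) to
extrapolate the fitted curve backwards.

## Prediction regimes

`predict_from_state` branches on the measured NAI:

* |NAI| ≤ 0.005 → the state *is* t0; the 12–14-day horizon is applied
  directly. The NDVI gate at t0 is advisory: an out-of-window NDVI produces
  a warning, not a refusal, so users who missed the window can still
  extrapolate.
* NAI < 0 → pre-t0: days to t0 = (−NAI)/rate with a linear progression
  rate, then the 13-day midpoint is added; total days are rounded
  half-to-even; the model interval is the point ±1 day. The default rate
  0.55/6 ≈ 0.0917 index/day is the unique linear calibration that makes a
  state of NAI −0.55 sit 6 days before t0 — consistent with the published
  19-day worked example under the 13-day midpoint (which we read as the
  point estimate, the source not specifying endpoint vs midpoint).
  `calibrate_pre_t0_rate` replaces it with the least-squares slope of the
  user's own early-season medians restricted to NAI ∈ [−0.6, 0].
* NAI ≥ 0.7 → at or past harvest maturity; the prediction is the state date.
* 0.005 < NAI < 0.7 → between t0 and the plateau, a regime the model was
  not specified for. With a fitted NAI curve the elapsed time since t0 is
  read off the curve and subtracted from the midpoint; without one, a linear
  interpolation between NAI 0 (t0) and NAI 0.7 (harvest threshold) stands
  in and the prediction carries an "unsupported-regime" warning. This adds a
  fourth regime label, `post_t0`, beyond the three anchored ones.

## The synthetic season generator

The simulator emulates an orchard campaign: 30 fruit × 2 sides (the 2012
sample size; 2013 used 20 fruit) measured every 2 days from 8 days before t0
to 18 days after (breaker stage through two weeks past commercial harvest).
Both indices follow logistic curves whose defaults are solved from the
reported anchor values rather than chosen freely:

* NAI: L = −0.6 (breaker stage), U = 0.8 (overripe plateau), k = 0.35/day,
  m = ln(4/3)/k ≈ 0.822 d pinned by NAI(0) = 0. These give NAI(13) ≈ 0.780
  and |NAI′(13)| ≈ 0.0067/day, inside the harvest window at the expected OHD.
* NDVI: L = −0.5, U = 0.5, m = 13 d (zero crossing exactly at the OHD),
  k = ln(19)/13 ≈ 0.2265/day pinned by NDVI(0) = −0.45. The lower asymptote
  −0.5 reconciles the reported "rising from −0.4" with the t0 window
  (−0.5, −0.4); the source states both and we keep the window satisfiable.
  (Published work elsewhere describes NDVI *decreasing* with chlorophyll
  loss; this instrument's convention has it increasing, and we follow the
  trajectories as reported.)

Noise is additive Gaussian on the index scale (default sd 0.05 per
measurement), independent across fruit, sides and dates, clipped to
(−0.999, 0.999). No per-fruit random effect is included — fruit-level
colour heterogeneity is plausible in real orchards but unquantified, so the
generator omits it; real data will also carry illumination geometry,
instrument drift and weather-modulated ripening rates that the generator
does not emulate. Passing recovery tests therefore demonstrates the
estimator's statistical behaviour under the stated noise model, not field
performance. Each fruit draws from its own `default_rng([seed, fruit])`
stream, so datasets are bit-reproducible regardless of iteration order.
Band intensities, when requested, come from exact algebraic inversion of the
index formula with the 780 nm band fixed at 1 (simulating indices forward
and inverting guarantees round-trip consistency; simulating pigment optics
forward would require optical constants the model does not define).

The truncated-cover scenario starts the observation window where NAI = 0.35
(solved from the logistic inverse), reproducing the under-cover seasons
whose colour break was missed; it exercises the not-reached and
extrapolation paths.

**Convergence check.** The per-date median's sampling error is checked
against 3 standard errors of the median, se ≈ √(π/2)·sd/√n with n = 60
measurements per date, requiring 99% of date-medians within the bound; the
√(π/2) factor is the median's asymptotic efficiency penalty relative to the
mean, without which the 3σ bound would correspond to only ≈2.4 median
standard errors and fail at the ~1.7% rate by construction.

## Problem sizes and determinism

The replicate study (t0 and OHD recovery under noise) uses 200 seeded
seasons of 840 records each, which completes in a few seconds; both
recovery rates are observed at 200/200 against the ≥95% requirement.
All fits are deterministic (fixed initial guess, no stochastic optimizer),
so identical inputs give byte-identical reports; simulation randomness is
fully determined by the root seed.

## Known limitations

* The fitted logistic's lower asymptote is weakly identified when the
  observation window misses the colour break (truncated-cover scenario);
  extrapolated t0 estimates then carry errors of a day or two and
  occasionally more, which is why the NDVI-at-t0 flag is advisory.
* The pre-t0 progression rate is a linear stand-in for a locally logistic
  process; it is calibrated to the published worked example and is about
  19% below the instantaneous logistic slope at NAI = −0.3 (a secant vs.
  tangent difference).
* The transcribed reference tables carry the source's printed precision and
  one known non-monotonicity (fruit size 23.5 → 22.9 in the covered Bellise
  series), which is whitelisted in the transcription checks rather than
  corrected.
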