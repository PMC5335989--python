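# cherryripe

Non-destructive maturity assessment and optimum-harvest-date (OHD)
prediction for sweet cherry (*Prunus avium* L.) from portable spectrometer
measurements of the fruit peel.

Stone fruit have no starch-based maturity index, so `cherryripe` tracks
ripening through two normalized remission indices measured in situ:

* **NDVI** = (I₇₈₀ − I₆₆₀)/(I₇₈₀ + I₆₆₀) — relative chlorophyll (degrades
  during ripening, so the index rises from ≈ −0.5 toward +0.5),
* **NAI** = (I₇₈₀ − I₅₇₀)/(I₇₈₀ + I₅₇₀) — relative anthocyanin (red pigment,
  rises from ≈ −0.6 at the colour break to a +0.8 plateau in overripe fruit),

where I_x is the remission intensity near x nm. Per-date medians over all
fruit and sides are fitted with four-parameter logistic curves NAI(t) and
NDVI(t), and the model declares the optimum harvest date at the earliest t
with

    0 ≤ NDVI(t) ≤ 0.2,   0.7 ≤ NAI(t) ≤ 0.8,   |NAI′(t)| ≤ ε  (ε = 0.01/day),

i.e. chlorophyll gone, anthocyanins saturated, and the NAI curve plateaued.
Harvest can also be *predicted* weeks ahead from the reference state t0 —
the NAI zero upcrossing, where NDVI sits in (−0.5, −0.4):

    OHD = t0 + 12 to 14 days   (±2 days depending on growth conditions),

and from any earlier measurement via a linear pre-t0 NAI progression rate
(default 0.55/6 per day, re-calibratable from your own early-season data).

The package is aimed at growers, extension services and phenotyping
researchers working with pigment-analyzer-class instruments. It includes a
seeded synthetic season generator with known ground truth and the
transcribed fruit-quality and pigment-chemistry reference tables of the
2012 campaign the model was developed on.

## Worked example

Predict harvest from a single early measurement (NAI −0.55, NDVI −0.40):

```sh
$ cherryripe predict --nai -0.55 --ndvi -0.40
{
  "days_to_ohd": 19.0,
  "regime": "pre_t0",
  "model_interval": [18.0, 20.0],
  "condition_uncertainty_days": 2,
  ...
}
```

The fruit is 0.55/(0.55/6) = 6 days short of the NAI zero crossing, plus the
13-day midpoint of the harvest horizon: **harvest in 19 days**, give or take
a day of model spread and ±2 days of weather.

Run the full pipeline on a simulated season (30 fruit × 2 sides, 2-day
cadence, noise sd 0.05):

```sh
$ cherryripe reproduce-reference --seed 42
```

prints (abridged; day 0 is the first observation, 8 days before true t0):

```
nai params [-0.5969, 0.7946, 0.3574, 8.8361]   rms 0.0076
t0 day 8.036   ndvi_at_t0 -0.4433
ohd day 21.0   nai 0.7769   ndvi 0.004
interval [20.04, 22.04]
```

The fitted logistic recovers the generating parameters (−0.6, 0.8, 0.35,
8.82), t0 is found 0.04 days from truth with NDVI inside its (−0.5, −0.4)
window, and the detected OHD at day 21 sits 12.96 days after t0 — inside the
predicted 12–14-day interval.

Library use mirrors the CLI:

```python
from cherryripe import (RipeningParams, simulate_orchard, aggregate_median,
                        fit_curve, detect_ohd, find_t0, predict_from_t0)

ds = simulate_orchard(RipeningParams(seed=42))
series = aggregate_median(ds.records)
nai, ndvi = fit_curve(series, "nai"), fit_curve(series, "ndvi")
print(detect_ohd(nai, ndvi).t_ohd, find_t0(nai, ndvi).t0_day)
```

Other subcommands: `simulate` (index CSV + truth sidecar), `indices`
(spectra/band CSV → index CSV), `fit`, `detect` (report JSON; exit code 4
signals a not-reached harvest window), `fixtures --table quality|pigments`,
and YAML criteria overrides via `--criteria`.

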