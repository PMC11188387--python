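# swimpower

Cross-sport bioenergetic modelling of record performances: estimate the
physiology of a prototypical record-holding athlete from yearly top-1
**running** times, transfer it to **front-crawl swimming** through a lumped
drag power law, extrapolate the parameter trends over the years, and solve
for predicted record times.

The package is aimed at sport scientists and performance analysts who want a
physiologically grounded alternative to extrapolating race times directly —
useful, for example, when rule changes (full-body swimsuits) have distorted
the raw time series of one sport but not the physiology that underlies both.

## Model

Supply: the metabolic power (W/kg) a prototypical athlete can sustain for an
all-out effort of duration *t* is

    P(t) = BMR + B(t) · [1 + (k₁/t)(e^(−t/k₁) − 1)] + (S(t)/t)(1 − e^(−t/k₂))

with aerobic reserve B = MAP − BMR and anaerobic store S = A for t ≤ t_MAP
(≈ 420 s), both declining logarithmically beyond t_MAP (B via the decrement
E·ln(t/t_MAP), S via the fixed rate f = −0.233).  k₁ = 30 s and k₂ = 20 s are
the onset time constants of aerobic and anaerobic metabolism.

Demand, running over distance *d* at speed *v*:

    P(v) = BMR + 3.86·v + 0.4·(BSA/m)·v³ + v³/(2d)

Demand, front-crawl swimming, with active drag, propelling efficiency and
gross efficiency lumped into a single coefficient K and exponent n:

    P(v) = K·v^(n+1)

Pipeline (per sex): for each year, fit (MAP, A, E) to the five top-1 running
times (200–5000 m) by minimising the mean absolute relative duration error
with the race-time solver nested in the objective; fit (K, n) to the six
top-1 swim times (50–1500 m) the same way with the physiology held fixed;
regress every parameter on the calendar year and take the 2024 value from the
regression line when the trend is significant (Pearson p ≤ 0.05), else the
series mean; finally root-solve K·(d/t)^(n+1) = P(t) for each distance.

## Worked example

Predict the six 2024 men's front-crawl times from the all-years 2024
parameter forecasts (MAP 29.68 W/kg, E −1.96 W/kg, A 1653.03 J/kg,
K 8.87, n 1.21):

```python
from swimpower import (MALE, PhysioParams, SwimParams,
                       SWIM_DISTANCES, predict_times)

physio = PhysioParams(map=29.68, a_cap=1653.03, e_decay=-1.96)
swim = SwimParams(k_coef=8.87, n_exp=1.21)
for d, t in zip(SWIM_DISTANCES, predict_times(physio, swim, MALE)):
    print(f"{d:6.0f} m  {t:8.2f} s")
```

```
    50 m     20.99 s
   100 m     46.97 s
   200 m    104.14 s
   400 m    219.79 s
   800 m    452.53 s
  1500 m    879.45 s
```

The 400 m and 800 m values sit below the standing world records at the end
of 2023 (220.07 s and 452.12 s), i.e. both records are predicted to fall.

The same pipeline runs from the shell on a record CSV
(`year,sex,discipline,distance_m,time_s`; times as seconds or `m:ss.hh`):

```sh
swimpower simulate --seed 7 --out records.csv      # synthetic top-lists
swimpower run-all --records records.csv --out-dir results/ \
    --subset olympic --wr tests/data/world_records_2023.csv
```

which writes `fits.csv` (per-year MAP, A, E, K, n), `trends.csv` (slopes,
Pearson r/p, Durbin–Watson, Shapiro–Wilk and Breusch–Pagan diagnostics, the
gated 2024 forecast), `predictions.csv` and `comparisons.csv`.

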