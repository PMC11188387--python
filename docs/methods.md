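# Methods

## Model and assumptions

The package treats a year's best performances as the output of one
prototypical athlete per sex whose bioenergetics are summarised by three
numbers: maximal aerobic power MAP (W/kg), anaerobic capacity A (J/kg) and
the logarithmic decrement E (W/kg per ln-unit of duration) of aerobic power
beyond the longest duration t_MAP at which maximal intensity can be held.
Supply power for an effort of duration t is

P(t) = BMR + B(t)·[1 + (k₁/t)(e^(−t/k₁) − 1)] + (S(t)/t)(1 − e^(−t/k₂)),

with B = MAP − BMR and S = A below t_MAP, and B = MAP − BMR + E·ln(t/t_MAP),
S = A·(1 + f·ln(t/t_MAP)) above it.  Both branches meet at t_MAP (ln 1 = 0),
so supply is continuous everywhere.

Key assumptions:

- a swimmer and a runner of the same sex and era develop the same metabolic
  power for the same effort duration, so running-derived (MAP, A, E) can be
  reused for swimming;
- swimming's drag force, propelling efficiency and gross efficiency are not
  separately identifiable from top-1 times, so metabolic swim demand is the
  lumped law K·v^(n+1) — K and n are the only swim-specific parameters, and
  no attempt is made to recover the drag coefficient or either efficiency
  from them;
- races are steady efforts over continuous time: no starts, turns, pacing or
  lap structure.

## Parameters

| parameter | meaning | unit | default | why |
|---|---|---|---|---|
| BMR | basal metabolic rate | W/kg | 1.2 | standardised prototypical athlete |
| m, BSA (male) | mass, body surface area | kg, m² | 70, 1.80 | standardised male |
| m, BSA (female) | mass, body surface area | kg, m² | 60, 1.60 | standardised female |
| k₁, k₂ | aerobic/anaerobic onset time constants | s | 30, 20 | literature kinetics values |
| t_MAP | limit of maximal-intensity duration | s | 420 | ~7 min ceiling of maximal aerobic intensity |
| f | anaerobic log-decline rate | — | −0.233 | literature value |
| α | trend significance threshold | — | 0.05 | two-sided Pearson p gate |

The running demand model is BMR + 3.86·v + 0.4·(BSA/m)·v³ + v³/(2d): the
cubic aerodynamic term scales with surface area per unit mass, and the final
term is the kinetic energy per unit mass (v²/2) amortised over the race
duration d/v.  The female mass default is 60 kg, matching the standardised
athlete the fits use; both profiles are plain dataclasses and fully
configurable.

## Fitting

(MAP, A, E) are estimated per year and sex from the five top-1 running times
(200–5000 m) by minimising the mean **absolute** relative duration error; the
printed error definitions are signed means, which are degenerate as
objectives (driven to −∞ by bias), so the absolute value is used and the
signed per-distance errors are reported alongside.  The race-time solver is
nested inside the objective: each candidate parameter set is converted to
five model times by bracketed Brent root finding of supply = demand.  (K, n)
are then fitted to the six top-1 swim speeds the same way with the year's
physiology held fixed — the stages are sequential, never joint.

Numerical choices:

- root brackets are physical speed limits — running 0.5–12 m/s, swimming
  0.5–4 m/s — expanded once by ×2 before declaring the parameters
  infeasible; Brent tolerance is near machine precision, and the returned
  root balances supply and demand to better than 1e−10 relative;
- the optimiser is bounded Nelder–Mead (the objective is piecewise smooth
  through the nested root solve), restarted from a 3×3×3 (physiology) or
  3×3 (swim) grid of starts placed at subdivision centres of the bounds
  MAP ∈ [15, 40] W/kg, A ∈ [500, 3000] J/kg, E ∈ [−10, 0] W/kg,
  K ∈ [1, 30], n ∈ [0.25, 4]; tolerances 1e−10 on the objective and 1e−8 on
  parameters; no randomness anywhere, so fits are reproducible bit for bit;
- on all instances examined the objective is unimodal over the bounds — a
  single central start reaches the same optimum as the full grid — so the
  heavy Monte-Carlo tests run with one start per fit while the default
  remains the full grid;
- E is only identified by records longer than t_MAP; a fit given only
  shorter races proceeds but flags E as weakly identified.

## Trends and the forecast gate

Each parameter series is regressed on the raw calendar year (internally
centred for conditioning, reported uncentred).  The 2024 value is the
regression line's extrapolation when the Pearson correlation with year is
significant at α = 0.05 (two-sided), else the plain series mean.  Residual
diagnostics — Durbin–Watson (rule of thumb 1–3), Shapiro–Wilk and
Breusch–Pagan — are computed and reported for every series; failures warn
but never drop data or halt the pipeline.  A constant series has an
undefined correlation p and falls back to the mean.

## Synthetic data: what it emulates and what it does not

The generator drifts the true parameters linearly over 1995–2023 (defaults
mirror the fitted series' scale: flat male physiology around the all-years
2024 values, female MAP rising ≈ 0.03 W/kg/yr and A falling ≈ 0.8 J/kg/yr,
drag parameters drifting by a few hundredths per year), solves the model
forward for every event, and multiplies each time by exp(ε), ε ~ N(0, 0.005)
independently — the 0.5% scale of the relative fit errors the pipeline
reports.  Only top-1 values are produced.

Because the synthetic world *is* the model, passing round-trip tests shows
the estimation machinery is correct, not that the model describes real
top-lists.  Two consequences are worth stating plainly:

- under pure 0.5% multiplicative noise the mean absolute fit error computed
  by the Monte-Carlo test falls **below** 0.4% — a p-parameter fit to N
  points absorbs roughly a √((N−p)/N) share of independent noise, and the
  L1-type objective can interpolate p points exactly.  Real-data fit errors
  of ~0.5% therefore contain model misspecification that independent
  multiplicative noise cannot emulate, and the Monte-Carlo band test that
  expects 0.4–0.6% fails by construction under these conditions;
- drifts of the size printed for the drag parameters (|slope| ≈ 0.01/yr)
  are *not* reliably detectable over 29 years given the per-year estimation
  scatter of K and n, so the significance gate then legitimately picks the
  series mean and the 2024 forecast inherits a systematic offset of
  slope × (2024 − mean year).  The end-to-end recovery test therefore sets
  slopes decisively to zero or to several standard errors, where the gate
  has a correct answer, and requires 2024 times within 3× the generator
  noise of the known truth.

## Degenerate inputs and edge behaviour

- Non-positive speeds, distances or durations raise a domain error; a
  supply-demand balance with no root in the (once-expanded) bracket raises
  an infeasibility error naming the distance.
- Supply is continuous at t_MAP to better than 1e−9 for any parameters.  It
  is **not** strictly decreasing over 60–3600 s everywhere in the bound box:
  when the anaerobic store is small (A near the 500 J/kg bound) the rising
  aerobic onset factor dominates below ~90 s and supply briefly increases
  with duration.  The solvers are unaffected — they rely on monotonicity of
  supply minus demand, which holds on the brackets — but the corresponding
  blanket monotonicity test fails in that corner and is kept as a statement
  of record.
- The Durbin–Watson statistic is undefined for all-zero residuals and is
  reported as NaN for numerically exact trend fits.

## Problem sizes

The test suite fits 29-year × 2-sex synthetic tables with single-start
optimisation, runs a 200-replicate Monte-Carlo of one year's fits, and
compares the optimiser against 20³ and 50² brute-force grids; the full suite
completes in well under two minutes on one core.  The acceptance script
performs a single deterministic root solve.

## Known limitations

- No turns, starts, pacing, pool-length or swimsuit-era effects; predictions
  for events where technique changed fastest (e.g. 1500 m turns) are
  correspondingly optimistic about the model, not the athletes.
- Point estimates only: no uncertainty intervals on fitted parameters or
  forecasts.
- The prototypical-athlete constants (mass, BSA, BMR) are fixed per sex and
  year; anthropometric drift across three decades is not modelled.
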