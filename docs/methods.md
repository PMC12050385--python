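# Methods

## Scope and model structure

`hiberniche` implements a mechanistic (process-based) species-distribution
model for hibernators. The response variable is survival of one "average"
individual over one hibernation season at one location; everything upstream
exists to compute the season's cumulative fat consumption. The model has
deliberately few moving parts: two fitted physiological relationships (state
probability and state-specific metabolic rate, both functions of temperature
alone), four fixed energetic constants, and a season-detection rule. It does
not model foraging, water balance, humidity, micro-site choice beyond a
scalar insulation offset, or individual variation at prediction time.

## State-probability model

Binary observations (normothermy = 1, torpor = 0) are modelled as a binomial
GLMM with a linear predictor in ambient temperature and a Gaussian random
intercept per individual. The default link is the cauchit (Cauchy CDF):
its heavy tails keep the normothermy probability strictly positive far below
the observed temperature range and approach 1 only slowly above it, which is
the observed behaviour at warm temperatures (essentially all time
normothermic above 20 °C) without imposing a hard ceiling.

Fitting maximises the marginal likelihood, integrating the random intercept
by 25-node Gauss–Hermite quadrature; the optimiser (Nelder–Mead) is
warm-started from a population-average GLM with the same link. Standard
errors come from the inverse numerical Hessian, and link selection uses
marginal AIC (3 parameters). Population-level predictions evaluate the
linear predictor at the mean (zero) random effect; with a non-linear link
this is the conditional-mode curve, not the population-averaged probability,
which is the quantity the rest of the pipeline needs (an "average bat").

**Extrapolation by mirroring.** Captive animals cannot safely be held far
below the torpor optimum, so the model is fitted on the observed 2–12 °C
range and extrapolated downward by reflecting the effective temperature
around a mirror point (default 2 °C, configurable — the fitted
thermoconforming minimum of 4.5 °C is a defensible alternative):
`t_eff = mirror + |ta − mirror|`. Mirroring is applied at prediction time
only; fitting uses the raw temperatures.

## Thermoregulatory curves

Metabolic rate observations are steady-state means: windows of at least
3 minutes whose within-window SD of rate (< 0.2) and of skin temperature
(< 0.5) both pass; windows are delimited by time gaps (> 30 min) or chamber
set-point changes (> 1 °C). CO₂ production converts to power at
27.8 kJ/L CO₂ (respiratory quotient 0.7, fat catabolism).

The two states follow:

* normothermy: `Mn(ta) = mtnz` for `ta ≥ t_lc`, else
  `mtnz + c_n·(t_lc − ta)`;
* torpor: `Mt(ta) = m_tmin + c_r·(t_min − ta)` below the thermoconforming
  minimum, `m_tmin·exp(k·(ta − t_min))` above it (continuous at `t_min`).

The exponential coefficient corresponds to Q10 = 2.5 at the default
`k = ln(2.5)/10 ≈ 0.092 /°C`. Observations carry no state labels; the fit
is a two-component mixture with a global mixing weight, lognormal residuals
(shared log-scale SD, mean parametrised so the curve value is the expected
rate), maximised by L-BFGS-B under box constraints from nine deterministic
starting points (a 3 × 3 grid over the plateau rate and `t_min`). Multi-start
matters: a single start occasionally lands in a local optimum that absorbs
the normothermic plateau into the torpid exponential. Wald intervals come
from the numerical Hessian; each observation is assigned the component with
the higher posterior probability. MCMC would give equivalent intervals here;
constrained MLE was chosen for determinism and speed.

## Reference parameter set

The package carries a reference parameterisation for the common noctule used
by examples, tests and the acceptance script, anchored at published
estimates: normothermy 0.86 h/day at −5 °C and p = 0.99 at 20 °C (fixing the
cauchit intercept and slope exactly); `t_min = 4.5 °C`, `c_r = 0.14 kJ/h/°C`
and a torpid rate of 1.35 kJ/h at −5 °C (together forcing
`m_tmin = 0.02 kJ/h`); a normothermic rate of 5.71 kJ/h at −5 °C with chosen
`t_lc = 30 °C` and `mtnz = 0.71 kJ/h` (plausible for a ~30 g vespertilionid;
only the anchored −5 °C value is load-bearing in the worked example).

## Energy budget and season rule

Daily energy is `E = h_n·Mn(t*)·f_n + h_t·Mt(t*)·f_t` with `t*` the roost
temperature (ambient + 5 °C insulation offset unless `uninsulated`), hours
from the state model at `t*`, and huddling factor `f = 0.5` (unless
`solitary`) applied whenever the state is actively thermoregulating:
normothermy always, torpor only below `t_min` (conforming torpor produces no
regulatory heat, so clustering cannot reduce it). Fat = E / 37.7 kJ/g. The
same `t*` drives both the state split and the rates, because the captive
experiments measured both against the temperature the animal actually
experienced.

A season exists only if temperature stays strictly below the 7 °C foraging
threshold for at least 14 consecutive days. Season boundaries are the first
and last day whose centred 14-day rolling mean is below the threshold, so
short mid-winter warm spells neither split the season nor end it. Both
conditions are needed: a boundary-only rule based on the smoothed series
would accept a 13-day cold snap (the rolling window inflates its apparent
span), violating the existence rule. Days outside the season cost nothing
(the animal forages). Death occurs on the first day cumulative fat strictly
exceeds the 27 g budget. A torpor-only comparison mode (`h_t = 24`)
quantifies how much the classical all-torpor simplification underestimates
the budget.

## Geospatial projection and niche table

Grid cells sit at half-resolution offsets; the continental default
(27–72 °N × −13–56 °E at 0.5°) has 90 × 138 = 12,420 cells. Cell areas use
111.2 km/degree with cosine latitude weighting, and latitude summaries of
the suitable set (median/min/max) are area-weighted by default. Time series
of area and latitude are smoothed with a centred 10-year moving average
(edges use available years); ensembles of climate models are combined as a
pointwise mean with a min–max envelope. Per-cell classification loops over
cells in Python — adequate for the fixture scales used here (≤ ~30 × 2 cells
× a few winters); a vectorised path would be the first optimisation for
continental runs.

The niche table bins seasons by mean temperature (1 °C) and duration
(10 days), recording the proportion survivable per bin; bins are unsuitable
at proportion 0, fully suitable at 1, ambiguous between. Winters with no
detected season carry no descriptors and are excluded.

## Synthetic data: what it does and does not emulate

* **State series** — Bernoulli draws from a known link model with Gaussian
  random intercepts (SD 0.5 on the link scale); defaults (22 individuals,
  2/7/12 °C groups, 30-min intervals, 21 days) reproduce the retained data
  volume of a month-long captive experiment (~22k records). Not emulated:
  serial autocorrelation of states within a bout — every draw is
  independent, so fitted SEs on synthetic data are optimistic relative to
  real bout-structured data.
* **Respirometry** — one stable window per individual × temperature
  (−3…35 °C every 2 °C, ~240 windows ≈ the 281 means of the reference
  experiment); the window's rate is the true curve times lognormal noise
  (CV 10%), plus 2% relative within-window instrument jitter; latent state
  is drawn from a temperature-dependent torpor probability (0.9 below
  `t_min`, linearly to 0 at 28 °C) and kept as a ground-truth column that
  fitters never read. Not emulated: transition (arousal/entry) records —
  the screening step would have to reject them; here all windows are stable
  by construction, so the SD screen is exercised but not stressed.
* **Daily temperature** — seasonal sinusoid (minimum on a configurable
  day-of-year) plus linear warming trend plus AR(1) noise (defaults:
  lag-1 0.7, marginal SD 2 °C — typical mid-latitude daily anomaly
  behaviour), on a 365-day calendar with winters running July 1 – June 30.
  Not emulated: weather regimes, cold spells with realistic duration
  statistics, elevation, coast effects. Gridded fixtures offset each cell's
  annual mean linearly with latitude and use independent per-cell noise
  (deterministically spawned sub-seeds), written as CF-style NetCDF
  (time/lat/lon, mandatory units attribute, Kelvin auto-converted).

Consequently, passing tests demonstrate internal correctness (estimators
recover generating parameters; the budget machinery is exact against
brute-force oracles; qualitative responses to warming and to the torpor-only
simplification have the right sign and shape) — not that the reference
parameters are accurate for any particular wild population, which only the
original measurements can establish.

## Numerical choices and degenerate inputs

Probabilities are clipped to the open unit interval at machine precision;
single-state or single-temperature state data raise immediately (degenerate
fit / rank deficiency); a mixture fit in which every observation lands in
one component raises rather than returning meaningless curves; empty
respirometry input yields an empty means table (not an error). Duration
counting uses days present in the series (the 365-day calendar omits
Feb 29). Ties in link selection go to the earlier candidate. All simulators
are bit-reproducible under a fixed seed.

## Known limitations

* Arousal costs are folded into the forced daily normothermy period rather
  than scheduled explicitly; the budget is therefore smooth in temperature
  and cannot reproduce bout-level dynamics.
* The population-level prediction uses the zero-random-effect curve; with
  substantial individual heterogeneity the population-averaged probability
  differs (slightly, for these parameter values).
* Wald intervals for the mixture parameters can be optimistic near the
  `t_min` kink; interval coverage is validated empirically in the tests at
  the study's data sizes only.
* The acceptance fits use reduced problem sizes (240 steady-state means,
  single winters, ≤ 30 × 2 grids) chosen to keep each run in seconds while
  leaving every estimator identifiable.
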