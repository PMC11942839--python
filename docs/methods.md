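# Methods

`thermaldev` estimates the thermal performance of insect development from
constant-temperature life tables and turns the estimates into phenology
predictions. It was built around the rearing design used for two pupal
parasitoids of the fall webworm (*Chouioia cunea* and *Psychophagus
omnivorus* reared at 10–30 °C), but every step is generic.

## Rate models

The development rate is the reciprocal of the egg-to-adult development time,
D(T) = 1/dev_time, in 1/day. Two models are fitted per species–sex group:

**Linear (degree-day) model.** D(T) = a + bT, fitted by (weighted) ordinary
least squares via statsmodels. Its derived quantities are the lower
developmental threshold T_b = −a/b (the x-intercept) and the thermal
constant DD = 1/b in degree-days. Both are *derived at access time* from a
and b, never stored independently, and are reported only when b is
meaningfully positive: slopes below 10⁻¹² 1/(day·°C) are treated as zero
(real insect slopes sit around 10⁻³; the cutoff only guards against
floating-point noise in degenerate flat-rate data, where −a/b would explode
to absurd values).

**Brière model.** D(T) = n·T·(T−T_b)·(T_L−T)^(1/m) on [T_b, T_L], zero
outside (development is theoretically impossible there; the clamp keeps the
function continuous at both thresholds). The curve's maximizer has a closed
form, obtained by differentiating T(T−T_b)(T_L−T)^(1/m):

    T_opt = [2m·T_L + (m+1)·T_b + √(4m²T_L² + (m+1)²T_b² − 4m²T_b·T_L)] / (4m+2)

which the test suite checks against brute-force grid maximization at 10⁻³ °C
resolution.

### Brière fitting

The least-squares objective is multimodal in (T_b, T_L, m), so `fit_briere`
uses a deterministic multistart: a 5×5×5 grid of starts evenly spaced
*inside* the box bounds (cell midpoints, so no start sits on a bound), the
scale coefficient n initialised at its conditional closed-form optimum, and
each start refined with SciPy's bounded trust-region solver
(`least_squares`, tolerances 10⁻¹²). The best objective wins; ties go to the
first start in grid order. There is no randomness anywhere in fitting —
identical data give bit-identical fits.

Default bounds, all overridable: T_b ∈ [0 °C, coolest developing
temperature), T_L ∈ (warmest observed temperature, 45 °C], m ∈ [0.3, 6],
n > 0. The thresholds must bracket the observed developing window by
definition, and 45 °C is a safe biological ceiling for these wasps.

Preconditions: at least 3 distinct temperatures and an effective sample size
(sum of observation weights) of at least 4. A 4-parameter fit to only 3
distinct temperatures is accepted — groups like *P. omnivorus*, which
developed at only 20/25/30 °C, could not be analysed otherwise — but flagged
`underdetermined`, and a solution on a box bound is flagged `at_bounds`.

Standard errors (linear: classical OLS/WLS; Brière: local quadratic
approximation J'J at the optimum) are reported as *approximate* diagnostics
only; published ± values for such fits rarely state their method, and ours
are not comparable to any particular one.

### Fitting unit

Fits operate on whatever rate observations they are given. Two units are
supported: per-individual observations, and cell means weighted by cell n
(`weighted-means`, the CLI default), which is the only option when a study
publishes only means. Temperatures where nothing emerged are reported as
"non-developing temperatures" metadata and contribute **no** zero-rate
observations: a zero rate is censoring (no survivor), not a measured
development rate, and injecting zeros would drag both fits down.

## What the published means can and cannot support

The packaged fixture holds the published mean development times (14
developing cells: 4 + 4 for *C. cunea* female/male, 3 + 3 for
*P. omnivorus*; n = 50 per cell). Refitting these means reproduces the
*qualitative* published picture for *C. cunea* (lower threshold near
11.5–12 °C, optimum near 28.7 °C, Brière R² ≈ 0.99 above linear ≈ 0.93) but
not the exact published parameters, which were estimated from unpublished
individual-level data.

For *P. omnivorus* the published means *decrease* monotonically over the
three developing temperatures (1/19.76 > 1/19.98 > 1/22.1). Consequences,
verified by brute force over the full bounds box:

* the linear slope is negative, so T_b and DD are undefined for this
  species from the means (the published positive slopes and R² ≈ 0.62–0.69
  come from individual data whose scatter the means hide);
* no Brière curve with T_b ≥ 0, T_L ≤ 45 °C, m ∈ [0.3, 6] fits the three
  means better than the straight line (best attainable R² ≈ 0.69 vs ≈ 0.83;
  an exact interpolation exists only at a meaningless T_b ≈ −137 °C). The
  "nonlinear beats linear" pattern therefore cannot be reproduced from the
  published means for this species, and the test asserting it across all
  four groups fails for the two *P. omnivorus* groups by design — the
  honest outcome, not a fitting defect.

Further internal inconsistencies of the published table, flagged here and
deliberately *not* tuned to: −a/b reproduces the printed lower threshold
only for the *C. cunea* female row (11.97 °C); the printed 268.8 degree-days
is not 1/b for any printed slope; and the printed *P. omnivorus* optimum of
30 ± 1 °C is not the closed-form maximizer of the printed Brière parameters
(≈ 25.8 °C).

## Degree-day phenology

Thermal time is accumulated by the rectangle method on daily means:
increment max(T_i − T_b, 0)·Δt with Δt = 1 day by default. Days at or below
T_b contribute exactly zero — never negative. No upper-threshold cutoff is
applied by default (the accumulation formula subtracts only T_b); an
optional horizontal cutoff capping T_i at an upper threshold is available
but off. Emergence is predicted on the first day the running sum reaches the
DD requirement, which under constant T > T_b equals ⌈DD/((T−T_b)Δt)⌉ — a
closed form the tests sweep against the summation. Only daily means are
supported; no single-sine or within-day interpolation.

## Synthetic life tables

The generator emulates the rearing design: 2 species × 2 sexes × 5 constant
temperatures (10, 15, 20, 25, 30 °C), ~50 individuals per cell. Per
individual: sex ~ Bernoulli (default 0.5, so cells hold ~50; the real,
heavily female-biased sex ratios of these wasps can be set per species);
emergence ~ Bernoulli with a logistic-window survival P(emerge|T), forced to
zero outside the group's (T_b, T_L); development time = (1/Brière rate) ×
exp(ε), ε ~ N(0, σ²), σ = 0.05 by default.

Choices worth stating:

* Noise is multiplicative lognormal on *time*, not additive on rate:
  simulated times are then always positive and right-skewed like real
  development data. The implied mean simulated rate is the true rate times
  exp(σ²/2) (lognormal identity), which the tests verify at n = 10⁴.
* σ = 0.05 is a convention: the published table's standard errors of means
  (SE/mean roughly 0.1–4 % at n = 50) are consistent with an
  individual-level CV of a few percent, but the true between-individual
  variance is not recoverable from means alone.
* True parameters default to the published Brière rows; survival windows
  approximate the published emergence fractions, with a sharp rising edge
  for *P. omnivorus* (P(emerge) ≈ 0.3 % at 15 °C) because that species never
  emerged below 20 °C in the emulated design.
* Cold storage is emulated only as a flag forcing non-emergence (matching
  the all-or-nothing published outcome); no thermal-injury dose model is
  invented.
* One seeded generator per simulate call; replicate r of a recovery
  experiment uses seed + r, so replicates are independent and reproducible.

What passing recovery tests show — and what they do not: with the design's
five temperatures, n = 50/cell and σ = 0.05, the Brière T_b is recovered
with median absolute error ≈ 0.07 °C and RMSE ≈ 0.10 °C (100 replicates),
and the linear model's extrapolated T_b is biased ≈ 2.2 °C *low* relative
to the true Brière threshold — the classic artifact of fitting a line to a
curved response inside the observed window. These figures describe the
generator's idealised world (correct model, independent lognormal errors,
no rearing covariates); they bound estimator error under real data only to
the extent that world resembles the laboratory.

## Problem sizes

Defaults were chosen so a full fit of the packaged fixture takes seconds and
the 100-replicate recovery experiment about a minute on one CPU: 125
multistarts per Brière fit, 20-replicate analysis driver, 100-replicate
validation in the test suite.
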