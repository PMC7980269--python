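# Methods

This note documents the statistical procedures, the generative model behind
the synthetic data, the numerical conventions, and the design decisions
taken where the methodology was genuinely open. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Climate: Thornthwaite PET and aridity indices

Potential evapotranspiration uses the classical temperature-based
Thornthwaite formulation: annual heat index
I = Σ<sub>m:T&gt;0</sub> (T<sub>m</sub>/5)<sup>1.514</sup>, exponent
a(I) = 6.75·10⁻⁷I³ − 7.71·10⁻⁵I² + 1.792·10⁻²I + 0.49239, and
PET<sub>m</sub> = 16 · c<sub>m</sub> · (10 T<sub>m</sub>/I)<sup>a</sup> mm
for months above freezing (0 otherwise). The correction
c<sub>m</sub> = (N<sub>m</sub>/12)(d<sub>m</sub>/30) uses mid-month
daylength N from solar declination
δ = 0.409 sin(2πJ/365 − 1.39) (J = day-of-year of the 15th) and the sunset
hour angle ω = arccos(−tan φ tan δ), clamped for polar day/night.

Conventions the method leaves open, fixed here:

- **Fixed 365-day calendar.** Month lengths are the non-leap values
  everywhere. Leap days would otherwise inject a spurious ~0.1%
  year-to-year PET wobble that leaks into the deviation index; with fixed
  lengths, a site whose years are identical has deviation AI exactly 0.
- **Heat index per calendar year**, from that year's own 12 monthly means.
- **No high-temperature variant by default.** Months above 26.5 °C follow
  the standard power law unless `high_temp_correction=True`, which switches
  them to the quadratic −415.85 + 32.24T − 0.43T² (per-day, scaled by
  c<sub>m</sub>).

The historical aridity index is the **ratio of window means** — (mean
annual P) / (mean annual PET) over the reference years (default
1985–2014) — not the mean of annual ratios; the collection index covers a
configurable 12-month water-year (default May 2014 – April 2015). Deviation
AI = collection − historical, negative when the collection year was drier.

## Seed records and filters

Each seed has one terminal observation: emergence on a recorded day,
retrieval with a viability verdict (viable → persistent, non-viable →
dead), or emergence during the daily-watered retrieval period (scored
persistent and flagged, since the extra watering is an artifact of
retrieval). Emergence days are optionally re-anchored per species: the
shipped preset subtracts 10 days (a later watering pulse) and assigns 4
days to anything emerging before day 14, the earliest time observed in an
initial low-emergence cohort. Emergence time is analyzed as √days and
averaged over seeds within a line (transform-then-average).

The **persistence fraction** uses living seeds as the denominator:
persistent / (emerged + persistent). The inference that this is the
intended quantity comes from the boundary case — a line in which "100% of
living seeds persisted" has no emergence time and must be dropped from the
trade-off fits, which only makes sense with the living-seed denominator. A
planted-seed denominator is available as a switch.

Filters run before every analysis: lines with viable fraction strictly
below 0.5 (across both treatments) are dropped, then populations with
strictly fewer than 10 retained lines are dropped whole. Both thresholds
are configurable; every exclusion is logged with its reason. The filters
are idempotent and order-invariant.

## Trade-off fits

The core model regresses line mean √days on line persistence fraction with
population random intercepts, fitted by REML (statsmodels `MixedLM`). The
slope is tested with a Type II Wald χ² on 1 df. If the mixed fit fails or
degenerates (zero residual variance on noise-free fixtures, non-finite
standard errors), the model falls back to population *fixed* intercepts
with a logged warning — the slope estimate is identical on balanced
noise-free data and the fallback keeps exact fixtures exactly solvable.

- **Deviation variant:** both traits centered on their population means
  (populations contributing one usable line are excluded — their deviations
  are identically zero), then the same grouped fit. This isolates the
  within-population association from covariation of population means; a
  two-population crossover fixture in the tests has a negative pooled slope
  and a within-population slope of exactly +1.
- **Mass residualization:** a first-stage OLS of mean √days on mean seed
  mass across all usable lines; the trade-off model is then refitted with
  the residuals as response. This is deliberately two-stage (not a joint
  covariate) so the second stage asks exactly "does persistence predict the
  part of emergence time that mass does not explain?"
- **Cook's distance** is computed on the fixed-effects representation
  (population intercept dummies + persistence slope) because no standard
  Cook's distance exists for the mixed model; the default flag threshold is
  7 (configurable), and the pipeline reports fits with and without flagged
  lines. The implementation agrees with a literal leave-one-out refit
  oracle to 10⁻⁸; exact replication of any specific dataset's flags is not
  claimed, since the mixed-model generalization used elsewhere is
  unspecified.

**Seed-level screens.** Four responses are modeled with maternal-line
random intercepts: √days for emerged seeds (Gaussian LMM) and
persistence / emergence / mortality indicators for all planted seeds
(binomial-logit GLMMs). Terms — population, watering treatment, their
interaction, seed mass — are tested Type II style: each term is evaluated
in the model containing all terms that do not contain it (so main effects
are tested without the interaction). The Gaussian model uses Wald χ²
blocks; the binomial models use likelihood-ratio χ² = 2·Δlog-likelihood of
nested fits. The binomial marginal likelihood integrates the line intercept
with 25-point Gauss–Hermite quadrature and is maximized by L-BFGS with an
analytic gradient; it is verified against adaptive numerical integration in
the tests. Apparent separation (|coefficient| > 15 on the logit scale) or
non-convergence marks the term unstable in the output. No multiplicity
correction is applied across screens.

## Pareto front

Directions are fixed: minimize mean √days, maximize persistence fraction;
both traits weighted equally (weights cannot affect pure front membership
and are recorded as metadata only). Default dominance is **weak** (at least
as good in both, strictly better in one) — the standard non-dominated-set
semantics; a **strict** rule (strictly better in both) is a first-class
alternative, since the two differ only at exact ties. `identify_front` is a
sort-and-sweep (groups of equal emergence handled together so equal points
never dominate each other under the weak rule); `front_oracle` is the
exhaustive all-pairs check, kept as the independent cross-check. Output
order is deterministic (emergence, then id); each off-front population
records one witness dominator.

## Permutation tests and regressions

The two-sample statistic is the difference in group means (a Welch-t
alternative is available); the method statement leaves the statistic open
and the mean difference is the conventional choice. When the number of
equal-size arrangements C(n, k) ≤ 20,000 the test enumerates all of them
and reports the exact p (proportion of arrangements at least as extreme,
observed included, with a 10⁻¹² relative tie tolerance); otherwise it draws
B arrangements (default 10,000) and reports the add-one estimate
(b+1)/(B+1), which is strictly positive and type-I valid. Historical AI
uses the lower tail ("more arid" = smaller AI); deviation AI is two-sided
(no directional hypothesis). With 8 populations the exact test is discrete:
the smallest attainable p is 1/C(8, k), so the realized size at α = 0.05 is
slightly below nominal (≈ 0.03–0.04) — inherent to exact permutation
inference at this n, not an implementation artifact.

Trait–climate regressions are ordinary least squares of population trait
means on an aridity index, tested with F = MS<sub>reg</sub>/MS<sub>res</sub>
on (1, n−2) df.

## Synthetic data generator

A single latent **dormancy liability** d (per line, Gaussian around its
population mean) drives both traits — the pleiotropy mechanism made
explicit rather than a bivariate correlation knob, so the induced
trade-off slope is computable:

- emergence probability: logistic(η₀ − b_persist·d + m_e·mass_c + treatment),
- emergence day: (base + b_time·d + m_t·mass_c + lag + ε)², floored at 1
  day, ε ~ N(0, σ_seed) — squaring a Gaussian keeps the √-scale analysis
  model exactly correct,
- non-emerged seeds die with logistic mortality (treatment- and
  lag-shifted); survivors persist.

Masses are log-normal (median 5 mg, σ_log = 0.3), centered at their known
mean in all linear predictors; larger seeds emerge earlier (m_t = −0.05
√days/mg) and more often (m_e = +0.2 logit/mg). Treatment presets mirror
the two response syndromes seen in such trials: a "stipa_like" preset (low
water → less emergence, more persistence) and a "bromus_like" preset (low
water → more mortality, less persistence; the default).

Default study dimensions: 8 populations × 20 lines × 22 seeds (11 per
watering treatment), sites evenly spaced over AI ∈ [0.35, 1.6] (the
variance components σ_pop = 0.25, σ_line = 0.8, σ_seed = 0.35 put most
trait variance within populations, matching the design's emphasis).

**Scenarios.** `null` silences the liability (b_time = b_persist = 0);
`tradeoff_only` activates it (b_time = 0.5, b_persist = 1.2) with no
aridity structure; `constrained_adaptation` adds two aridity couplings:

1. a **liability cline** — population mean liability increases with site
   aridity (`dormancy_aridity_slope` per unit −AI), and
2. an **adaptation lag** — wetter populations are displaced into the
   dominated region (later emergence, + 0.6 √days per lag unit; higher
   mortality among non-emerged seeds, +1.5 logit per lag unit), with lag =
   `adaptation_lag_slope` × relative wetness.

The lag term is what makes front membership track aridity. A liability
cline alone moves populations *along* the trade-off curve — under
near-linear links the configuration is symmetric under swapping the two
trait axes and flipping the gradient, so on- and off-front groups have the
same expected aridity and the front test has no power. Constrained
adaptation in the intended sense — arid populations held *on* the front by
selection, mesic populations lagging behind it — requires the off-curve
displacement, so the presets couple both couplings to one strength knob
(none/medium/large = 0 / 0.3 / 1.0). The medium value was chosen by a
design-stage power analysis so the three presets have clearly separated
front-test power (roughly 0.03 / 0.25 / 0.4 at the default design) rather
than two saturated, statistically indistinguishable levels.

**Climate construction.** Each site gets a fixed seasonal temperature
cycle and winter-weighted (Mediterranean) monthly precipitation scaled so
annual P = AI × annual PET in every year — making the historical index
exact by construction; the final four months of the collection water-year
(outside the historical window) are then adjusted so the collection index
equals AI + deviation (deviation defaults to 0). `aridity_summaries`
recovers the assigned AI to machine precision, well inside the 10⁻³
round-trip tolerance the tests assert.

**Recovery target.** `implied_line_slope` is the within-population
regression slope of realized line mean √days on realized persistence
fraction, computed by Monte-Carlo at 10⁶ lines *at the design's seed
counts*. This — rather than the slope between noise-free conditional
expectations — is the estimand the trade-off fit targets: with ~22 seeds
per line, binomial noise in the persistence fraction attenuates any
line-level regression (errors-in-variables), and the definition absorbs
that attenuation plus the exclusion of lines with no emerged or no viable
seeds. It is 0 when b_time = 0 and the mass channel is off, and scales
linearly in b_time. (With the mass channel on, a small residual slope
≈ −0.02 survives even at b_time = 0: conditioning on emergence selects
heavier, earlier-emerging seeds more strongly in high-liability lines.)

**What the generator does not emulate:** dormancy cycling and
after-ripening, assay error in viability scoring, spatial structure within
the greenhouse, seed-bank demography across multiple real years, or
between-species differences beyond the treatment-response presets. Passing
calibration and recovery tests therefore demonstrates correctness of the
statistical machinery under the stated generative assumptions, not
robustness to these unmodeled features of real data.

## Operating characteristics

The harness reruns the standard pipeline (generate → summarize → filter →
fit/front/permute) per replicate with deterministically derived child
seeds, and reports rejection rates with binomial standard errors.
Replicates where a test is undefined — e.g. every population on the front,
which leaves no off-front group — are excluded from that test's
denominator and counted. Default replication: 1,000 for type-I error, 500
per preset for power; sizes chosen so Monte-Carlo standard errors
(≈ 0.007 and 0.02 respectively) are small against the effects being
measured.

## Numerical conventions and degenerate inputs

- Permutation ties: comparisons use a 10⁻¹² relative tolerance so exact
  ties count as "at least as extreme"; a constant covariate yields p = 1
  with a warning.
- Regression on a perfectly collinear fixture reports F = ∞, p = 0.
- The GLMM optimizer warm-starts from the ridge-stabilized unmixed
  logistic fit with σ₀ = 0.5; LRT statistics are clipped at 0 (optimizer
  noise can make nested log-likelihoods cross by < 10⁻⁶).
- The Gaussian screen model retries REML under lbfgs → bfgs → cg before
  failing; the line-level trade-off fit falls back to fixed intercepts.
- All randomness flows from one seed per run; every permutation result
  records the child seed that regenerates it; reports carry a SHA-256 hash
  of their deterministic sections.

## Known limitations

- Cook's distance is defined on the fixed-effects representation, so flags
  need not match a mixed-model-specific influence measure.
- Wald Type II tests for the LMMs carry no small-sample (Kenward–Roger
  style) correction; with 8 populations and ~150 lines the χ² reference is
  adequate but slightly liberal.
- The exact permutation test is conservative at n = 8 because of
  discreteness (realized size ≈ 0.03 at nominal 0.05).
- The GLMM supports a single random intercept (maternal line), which is
  all the screens require; crossed or nested structures are out of scope.
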