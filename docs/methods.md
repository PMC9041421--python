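# Methods

This note documents the models, defaults and numerical choices behind
`pshpassage`, and what its synthetic-data tests do and do not establish
about real passage data.

## Shear flume model

The flume accelerates flow through a conical nozzle (15 → 5 cm) and the
gauge head differential H (m of water) gives the jet velocity by Bernoulli,
`v = √(2gH)` with g = 9.81 m s⁻². The exposure metric is the
characteristic strain rate `e = v/y` (s⁻¹): the velocity difference is
resolved over the organism's body width y, taken as the distance
perpendicular to the force. This is a characteristic-scale approximation —
no jet-plume or CFD modelling is attempted, and none is intended.

Widths y: 1.5 mm (egg diameter), 1 mm (larvae 12–18 DPH), 2 mm (larvae
28–30 DPH), 10 mm (juveniles). The four default jet velocities
{5.05, 12.61, 16.87, 18.53} m s⁻¹ are reconstructed, not measured: the
published per-stage strain ladders are mutually consistent under `e = v/y`
only for this shared velocity grid, and the reconstruction reproduces every
printed strain value exactly at integer precision (a regression test
asserts this). Strain values are kept at full precision internally and
rounded to integer s⁻¹ for display only.

The psi → head conversion uses 0.703070 m/psi (fresh water at 4 °C). The
gauge's 10 psi resolution is treated as metadata; computed heads are not
quantized, since reported strains are continuous.

## Blade-strike models

Deterministic model (transit-time argument): a fish crossing the runner
plane with apparent length `L·cosθ` at normal velocity V is exposed to
blades passing at `n·N/60` per second, so

    P = min(1, (n·N/60) · L·cosθ / V),     S = 1 − MR·P.

The cap at 1 is needed because the linear formula is otherwise unbounded.
The mutilation ratio MR (fraction of strikes that are lethal) defaults to
1 — every strike fatal, the conservative assumption — but is an explicit
parameter, since measured mutilation ratios for percids would raise
survival.

Normal-velocity closure: V = Q/(πDB), the radial inflow velocity through
the runner entrance cylinder (D runner inlet diameter, B distributor
height). This is the package's own closure for a radial-inflow machine;
it is deliberately pluggable (`closure=` argument) so a full Francis
velocity-triangle derivation can be substituted without touching the rest
of the model. Under this closure large fish saturate the cap on small
high-speed runners; absolute strike values for any real machine therefore
depend on the supplied geometry, which is typically confidential.

Deterministic runs fix orientation at 45° (midpoint of the admissible
0–90° range, since one run yields one estimate) and evaluate a 3 × 3 grid:
{min, mid, max} discharge from the operating table × {min, mean, max}
length.

Stochastic model: per realization, wicket-gate angle ~ Uniform(min, max)
over the operating-table span (the span is configurable; min→max is the
default reading of "minimum to maximum flow angle"), discharge linearly
interpolated from the table (no extrapolation), orientation ~
Uniform(0°, 90°), length ~ Normal(mean, sd) truncated to
[length_min, length_max]. 10 000 realizations by default. The truncated
normal is sampled by inverse-CDF truncation (scipy's `truncnorm`), which is
exact and loop-free; a rejection sampler would draw from the identical
distribution. Seeds are mandatory — there is no implicit global RNG — and
identical seeds give bit-identical results.

Sensitivity analysis: all inputs and the output are z-scored and the
coefficients come from one joint ordinary-least-squares regression. OLS on
standardized variables is the classical "standardized regression
coefficient" sensitivity measure for Monte Carlo models; with a single
dominant linear driver its coefficient approaches 1 exactly (a test
constructs this case). A constant output leaves sensitivity undefined
(NaN + flag, not an exception); rank-deficient inputs produce the
minimum-norm solution with an explicit collinearity warning.

Engine checks: degenerate (zero-width) distributions collapse to the
deterministic value to ≤1e-12; with uniform orientation and the cap not
binding, the Monte Carlo mean matches the analytic `P(0°)·E[cosθ] =
P(0°)·2/π` within 3 Monte Carlo standard errors; the standard error of the
mean scales as 1/√n across n ∈ {100, 1000, 10 000}.

## Pressure profile

The full-capacity pumping exposure is three continuous linear segments:
220→1100 kPa over 1997 s, 1100→7600 kPa over 19 ms, 7600→10 kPa over
5134 s. Two in-source inconsistencies are surfaced rather than resolved:
the transient is quoted both as 17 ms and 19 ms (19 ms is the default;
17 ms is available via `transient_duration`), and the segment durations sum
to 7131.019 s against a reported 7133 s total travel time — the segments
are primary truth and the 1.981 s gap lives in profile metadata. Linear
interpolation within segments is an assumption; the slow ramps' true
functional form is not published. No physiological barotrauma model is
included: compression (unlike decompression) shrinks the swim bladder, and
the laboratory evidence this package mirrors found little mortality, so
the profile is an exposure description, not a dose–response.

## Survival statistics

Trial tables are replicate-level binomial records: (life stage, experiment,
group, replicate, exposed n, alive at 0 h, alive at 24 h), with
0 ≤ alive₂₄ ≤ alive₀ ≤ n enforced. The primary endpoint is 24-h survival;
immediate survival is computed but secondary. Replicates are pooled within
groups for estimation (group is the sole model factor); a replicate-level
Pearson X²/df overdispersion diagnostic is reported with every fit so
pooling can be challenged on real data.

Fitting: binomial GLM with logit link and cell-means coding (one indicator
per group), so each coefficient is a group's survival on the logit scale
and the least-squares means are the inverse-logit coefficients. The link
is a documented choice; with a saturated group factor the estimates equal
pooled sample proportions regardless, and an unpenalized single-group fit
is tested to reproduce the sample proportion exactly.

Firth penalty: when any group is invariant (all alive or all dead) the MLE
diverges, so the fit maximizes ℓ(β) + ½log|X'WX| (Jeffreys prior) via
Newton iterations with the hat-matrix half-correction to the score,
`U*ⱼ = Σᵢ (yᵢ − nᵢπᵢ + hᵢ(½ − πᵢ)) xᵢⱼ`, convergence 1e-8 on the step, max
100 iterations, with step-halving guarding divergence. `penalized="auto"`
(the default) triggers on any invariant group. For an intercept-only fit
the penalized estimate is exactly (y+½)/(n+1); with cell-means coding the
information matrix is block-diagonal, so each group independently attains
this closed form — both are tested to 1e-8, including 0/n and n/n groups.

Intervals are Wald on the logit scale, back-transformed (hence always
inside [0, 1] and finite under separation); profile-likelihood intervals
are a possible extension but are not implemented.

LLR test: 2(ℓ_full − ℓ_null) against intercept-only, df = #groups − 1,
chi-square reference. Under penalization the penalized log-likelihoods are
differenced (the penalty applies to the overall model test) and the
statistic is floored at 0, since penalties of different design matrices
need not preserve the nesting inequality exactly; the penalized flag is
carried in the result. The statistic is invariant to replicate aggregation
within groups (binomial sufficiency — tested), and unpenalized fits and
LLRs are cross-checked against statsmodels GLM.

Post hoc: classical Scheffé protection is a linear-model construct; the
adaptation here tests every pairwise contrast on the logit scale,
(βₐ − β_b)²/(seₐ² + se_b²), against the chi-square (1−α) quantile on
(k−1) df — the large-sample limit of the (k−1)·F Scheffé bound — after
removing invariant groups (which carry no contrast information and were
excluded from post hoc analysis in the source protocol). Letters are
assigned per maximal clique of the "not significantly different" graph
(brute-force clique enumeration; group counts are ≤ 6), ordered by best
survival. Blocks where every group is all-alive get the "100% survival all
round" rendering and no test.

## Synthetic-data generator

The generator emulates the study conditions, not the withheld raw data:

- **Shear trials**: per (treatment × replicate), alive₂₄ ~ Binomial(m, p(e))
  with logistic dose–response `p(e) = invlogit(logit(p₀) + β·e/1000)`.
  Egg defaults solve the two-parameter logistic through the published
  anchor probabilities (0 s⁻¹ → 0.58; 8407 s⁻¹ → 0.24); zero survival at
  11 247 s⁻¹ then emerges only approximately (a logistic never reaches 0,
  the fitted expectation there is ≈0.16). Juvenile defaults anchor a
  near-perfect control (0.995, since logit(1) is infinite) to survival 0.7
  at 1853 s⁻¹. The larval slopes are stand-ins reaching ≈0.02 survival at
  each stage's top strain; the 28–30 DPH control is set to 0.40 to
  represent that cohort's temperature-compromised controls — controls are
  ordinary groups, never assumed perfect. Designs: 5 replicates × 25 eggs,
  5 × 15 and 5 × 10 larvae, 10 × 1 juveniles.
- **Immediate vs 24-h split**: deaths visible at the immediate check are a
  binomial thinning (default fraction 0.5) of all deaths, which enforces
  alive₀ ≥ alive₂₄ by construction; the true split is unreported.
- **Pressure trials**: two groups (pressure, control) × 5 replicates, group
  sizes 25/30/10/6/2 per stage from egg to adult. Juvenile and adult
  survival defaults are 1.0 in both groups — the invariant "100% survival
  all round" outcome that exercises the Firth auto-trigger. The egg effect
  (0.60 control vs 0.25 pressure) is large and detectable at these sizes;
  the larval effects (0.95/0.92, 0.97/0.95) are negligible by design.
- **Turbine configs**: 13–17 blades, 250–500 rpm, D 3–6 m, B 0.6–1.5 m,
  strictly monotone 3-node gate-angle/discharge tables — the regime of
  large pump-turbines, for end-to-end tests only.
- **Fish lengths**: truncated normal within [length_min, length_max]; the
  per-stage length defaults are synthetic stand-ins on the scale of
  *Perca fluviatilis* biometrics (the measured tables are not public).

All generators are pure functions of (config, seed). The logistic
generating model is richer than the categorical-group model fitted
downstream; that asymmetry is deliberate — it enables parameter-recovery
tests (refit the generating slope from generated tables) that a
group-means generator could not support.

What passing tests show: the machinery is internally correct (closed forms,
analytic expectations, calibration of coverage and type-I error under the
generating model). What they do not show: agreement with any real trial
data (withheld), correctness of the radial-inflow closure for a specific
machine (geometry confidential), or real biological dose–response shapes —
the anchored probabilities constrain expectation at a few points only.
Overdispersion between real replicate containers, handling effects and
non-binomial mortality are not emulated.

## Problem sizes and runtimes

Calibration suites use the study-design group sizes (5 × 25 eggs per
group): 500 simulated studies for CI coverage, 200 for type-I error,
10 000 Monte Carlo realizations for the strike engine, and a
5 × 10 000-per-group table for slope recovery. The full test suite runs in
well under a minute; `scripts/acceptance.py` in a few seconds.

## Known limitations

- Stressors are modelled independently; cumulative or interacting effects
  (e.g. shear-disoriented fish facing higher strike risk) are out of scope.
- The strike model ignores near-blade hydrodynamics (small organisms may be
  swept around the leading edge, so egg/larval strike risk is likely
  overestimated even before the MR = 1 assumption).
- 24 h is the last assessment; delayed mortality beyond that horizon is
  not represented.
- The Scheffé adaptation and the logit-scale least-squares means are
  documented defaults where the original commercial-software computations
  are unspecified; alternatives (response-scale means, profile CIs) would
  change borderline letters, not the machinery.
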