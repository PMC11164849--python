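# Methods

## The estimand and the pipeline

Each graded exercise test yields per-stage pairs of blood lactate (bLa,
mmol/l, earlobe capillary sample in the last 30 s of each 3-min stage)
and Borg RPE (ordinal 6–20). The analysis asks two questions: what
ordinal RPE corresponds, per person, to the fixed lactate anchors 2, 3
and 4 mmol/l and to the individual anaerobic threshold; and how do sex,
age, ergometry type, VO₂max and test duration shift that RPE.

The pipeline is: screen → detect thresholds → interpolate → summarise →
model. Every record that drops out at any stage is counted with its
reason, and per-anchor accounting (kept = modelled + skipped + missing
anchor) is asserted at run time.

## Thresholds

Baseline bLa is min(resting sample, stage-1 bLa); the minimum protects
against a warm-up-elevated resting draw (configurable to resting-only).
LT1 is the first stage whose bLa exceeds baseline + δ and whose
successor does not fall back below it (the sustained-rise guard keeps a
single noisy sample from triggering detection); δ defaults to
0.2 mmol/l, the conventional minimal rise for capillary sampling, and is
a parameter. LT2 is the *concentration* bLa(LT1) + 1.5 mmol/l — an
offset anchor, not a workload — so LT2 − LT1 = 1.5 holds identically
wherever LT1 is detected. The LT1 concentration is the measured value at
the detected stage, not baseline + δ, because the offset construction is
anchored to a measurement.

Two caveats are deliberate. First, "first rise over baseline" and the
minimal-lactate-equivalent construction it is often cited alongside are
not identical procedures; this implementation follows the verbal
first-rise rule and exposes δ rather than guessing a proprietary
detector's internals. Second, detection happens on a discrete stage
grid, so the detected LT1 overshoots the true crossing by up to one
stage's lactate increment; finer protocols (more stages) overshoot less.
This is a real property of grid-based threshold detection and it leaves
a small negative association between detected LT2 and stage count
(visible as a mild shrinkage of the stage-count odds ratio in the LT2
model, about −4% on the odds-ratio scale at the default conditions).

## Monotone interpolation

The spline knots are the stage (bLa, RPE) pairs after a running-maximum
filter on bLa (a pair is kept iff its bLa strictly exceeds every kept
predecessor — strictly increasing abscissae are required; with the usual
convention that reported RPE never decreases in an incremental test, the
kept RPE sequence is non-decreasing too). Records with fewer than three kept pairs are
skipped and counted, separately from the screening criteria.

Slopes follow Fritsch–Carlson: secant averages at interior knots,
one-sided at the ends; both slopes bracketing a flat secant are zeroed;
normalised slopes (α, β) = (mᵢ, mᵢ₊₁)/dᵢ outside the monotonicity region
(2α+β > 3, α+2β > 3 and 3α(α+β−2) < (2α+β−3)²) are projected onto the
circle of radius 3. One refinement: the classic interval-by-interval
sweep checks interval i against slope values that a *later* flat-secant
zeroing may still shrink, which can strand an interval outside the
region — the reference implementation of this construction in the
standard statistical stack exhibits exactly that (a dense-grid dip of
order 1e−5 on knots like x = (0.5, 1, 4, 5), y = (6, 6.25, 6.5, 6.5)).
Ordinal RPE data has flat runs constantly, so a fixpoint pass re-projects
any stranded interval; it only fires in those degenerate configurations
and leaves all other slopes bit-identical to the classic construction.

Anchors are the rounded spline predictions, rounding half-up (a
documented choice, isolated so half-to-even can be toggled), clipped to
6–20. Anchors outside the observed bLa range are missing, never
extrapolated — a clamped cubic beyond the data would fabricate
measurements. Resting bLa is not a knot: no RPE exists at rest.

## The cumulative ordinal model

P(Y ≤ cⱼ | x) = logistic(ζⱼ − x′β) with strictly increasing cutpoints ζ
and one β shared across cutpoints; exp(β) is the odds ratio for higher
RPE. The five covariates (male, treadmill, age in years, VO₂max in
ml/kg/min, number of stages) are fixed by design, complete cases only.

Fitting maximises the likelihood with an analytic gradient; cutpoints
are reparameterised (first free, increments through exponentials) so the
optimisation is unconstrained, covariates are standardised internally
for conditioning and the estimates mapped back. Initial values: β = 0,
cutpoints from marginal cumulative frequencies. The covariance is the
inverse observed information at the optimum, computed in the original
(β, ζ) coordinates by central differences of the analytic gradient;
CIs are Wald. Wald rather than profile likelihood is a documented
choice: it is fully specified and deterministic, and at the sample sizes
here (thousands of observations, |β| ≤ 0.5) the two differ well under
the reporting precision. Ordinal levels absent from the data drop out of
the cutpoint set with the observed labels recorded. Degenerate inputs
(one outcome category, a constant covariate, singular information)
return a non-converged fit carrying diagnostics instead of raising.

Crossover profiles: along a grid of one covariate (the other continuous
covariates at their cohort means, per the prediction convention; sex and
ergometry enumerated), the most-probable category is computed per grid
point with ties broken toward the lower RPE (the conservative intensity
prescription), and a crossover is reported at the grid midpoint where it
changes.

## The synthetic cohort generator

The generator defines the study conditions; it is emitted with ground
truth that the pipeline never reads.

**Covariates.** Sex (62.6% male) and ergometry (58.2% bicycle) are
independent Bernoulli draws; age ~ N(36.65, 16.68²) truncated to
[10, 95] years; VO₂max is sampled per ergometry stratum
(bicycle N(31.40, 10.76²), treadmill N(48.72, 6.99²), truncated to
[12, 75] ml/kg/min) — the two populations differ strongly, which makes
ergometry and VO₂max collinear in the models exactly as in the emulated
clinic; height and weight are sampled per sex.

**Protocols.** Maximal capacity is an affine function of VO₂max and body
mass with the standard steady-state cost constants (cycling ≈ 11 W per
ml/kg/min above the 7 ml/kg/min unloaded cost, scaled by mass; running
0.2 ml/kg/min per m/min above rest), jittered ±5% and snapped onto the
protocol grid (bicycle: start 10–100 W rounded to 10 W near 20% of
capacity, increments 10–50 W; treadmill: start 3–10 km/h near 30% of
maximal speed, increments 1–2 km/h) so exhaustion falls on the last
stage. Stage counts land in 3–14 with a 6–11 target, 3-min stages fixed.

**Lactate.** bLa(p) = b₀ + A(e^{kp} − 1) at relative intensity
p = load/maximal load, with b₀ ~ N(1.0, 0.10²) mmol/l (baseline ≈ 1),
A = 0.02 and k = 6 (log-normal person effects, CV 10% and 3%): maximal
bLa ≈ 9 mmol/l and the first rise near 40% of maximal load. Measurement
noise is N(0, 0.08²) floored at 0.3 mmol/l — the emulated analyser class
has ~1.5–3% CV, so 0.08 covers device plus stage-to-stage biological
variation. The heterogeneity is deliberately moderate: the anchor's
relative-intensity position p(c) = ln(1 + (c − b₀)/A)/k varies with the
curve shape, and that variation acts as omitted-variable noise that
attenuates every latent covariate effect by
1/√(1 + γ₁²·var(p(c))/(π²/3)); the chosen CVs keep that factor ≈ 0.96 so
the effects stay identifiable through the anchor read-out. Real cohorts
vary more (threshold location spans tens of percent of maximal load),
so parameter recovery there would be correspondingly attenuated.

**RPE.** Stage RPE is drawn from P(RPE ≤ j) = logistic(ζⱼ − η) with
η = γ₀ + γ₁·p + x′β_true, cutpoints at Borg half-integers (so η reads as
a latent Borg value), and the logistic disturbance drawn **once per
record** — a persistent perceptual trait. Every stage's margin is then
exactly cumulative-logit, and because η rises strictly with p the
reported sequence is non-decreasing by construction. The alternative —
independent per-stage draws forced monotone by a running maximum — was
rejected after measurement: the max-accumulation bias depends on stage
spacing in latent units, which differs by protocol and duration, and it
leaked into the treadmill and stage-count odds ratios (treadmill OR
drifting from 0.754 toward 1). β_true defaults to the natural logs of
the published 2 mmol/l odds ratios; preset OR maps for the other three
anchor models are provided, with unpublished cells set to 1.0, and
swapping β sets recenters γ₀ so the mean latent exertion is unchanged.

γ₀ = −1.504 and γ₁ = 17.0 were frozen by a one-time grid search
(`scripts/calibrate_generator.py`) maximising the margin with which the
full pipeline's anchor medians hit 13/15/16/15; the same run checks the
cohort-mean LT2 concentration (2.82 mmol/l, within the 0.3 mmol/l band
around the reference 3.03 — the residual gap reflects the first-rise
detector triggering near baseline + δ under the stated baseline, and is
left rather than distorting the curve family). At the frozen values the
latent exertion at rest sits below the RPE-8 cutpoint and at exhaustion
implies a most-probable RPE ≥ 18.

**Defects.** Configured fractions of records carry injected defects so
the screening has work: re-tests (5%, duplicating the previous
participant with a later date), one missing bLa (1%) or RPE (1%),
truncation to two stages (0.5%), an implausible lactate of 30 mmol/l
(0.2%), foreign ergometry (0% by default). Rates are free parameters;
the flow-chart proportions of the emulated study are not reproduced.

**What the generator does not emulate.** No heart-rate/VO₂ kinetics, no
menstrual-cycle covariate, no age–fitness correlation within ergometry
strata, anthropometrics independent within sex (the BMI tails are wider
than a real clinic's), no device drift or user error beyond the defect
channels, and lactate-curve heterogeneity below real-world levels (see
above). Passing tests therefore certify the pipeline's correctness and
calibration under these controlled conditions, not clinical
transferability.

## Numerical choices and problem sizes

Quartiles use linear interpolation between order statistics (toggleable
to discrete). Reports round to 6 decimals; cohort CSVs use shortest
round-tripping decimals so seeded runs are byte-identical. The test
suite runs the oracle comparison at 200 knot sets × 100 queries
(tolerance 1e−8 against the reference monotone-Hermite implementation),
CI coverage at 40 replicates of n = 1500, and odds-ratio recovery
through the full pipeline at n = 6000 (tolerance 5% relative or truth
inside the fitted 95% CI — at this n the male-sex OR has sampling SE
≈ 0.037 and the LT2-model treadmill OR ≈ 0.04, so single-run estimates
scatter accordingly); the calibration check runs n = 2000. These sizes
keep the whole suite under a minute while leaving Monte-Carlo error well
inside the asserted bands.

## Known limitations

- The LT2 grid-overshoot effect above couples detected LT2 mildly to
  protocol density; alternative threshold constructions (fixed 4 mmol/l,
  Dmax, log-log) are out of scope by design.
- The implausibility rules of criterion F (bLa > 25 mmol/l, RPE outside
  6–20, non-increasing load, non-positive anthropometrics) are a
  documented default for an undefined criterion and configurable.
- Exclusion order A→F is first-match and fixed; a record matching
  several criteria is counted once.
- Anchors beyond the measured lactate range are missing; cohorts tested
  at low intensities will lose the 4 mmol/l anchor most often.
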