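# Methods

This note documents the models and procedures implemented in `markresight`,
the choices made where the design was genuinely open, and what the
synthetic-data generator does and does not emulate.

## Study structure and data model

A *survey period* is a field trip anchored on one night of mass carapace
painting (M turtles marked, recorded in `MarkingRecord`). Over the
following days (1–3 in the standard design) the inter-nesting waters are
surveyed in AM and PM slots by one or more platforms — surface observer
(SO), underwater video (UWV), UAV — each survey yielding marked and
unmarked counts (`SurveyRecord`). `total_seen` is always recomputed as
`marked_seen + unmarked_seen`; a total column in an input file is ignored.
Validation reports findings rather than raising: marked counts exceeding M,
duplicate or missing marking records, days outside the 1–3 design (unless
explicitly relaxed for longer simulated designs), and sparse periods (which
are flagged, never dropped).

## Lincoln-Petersen estimation

* Point estimate N̂ = M·C/R; R = 0 raises an estimation error, and callers
  may opt into the Chapman variant (M+1)(C+1)/(R+1) − 1, which is defined
  at R = 0 and less biased at small counts. The classical form is the
  default because the programme's counts are large (R of order 10²).
* Per-survey SE uses the classical large-sample form √(M²C(C−R)/R³)
  (identical to the delta-method expression N̂²·C·p(1−p)/R² with p = R/C).
* A period estimate is the mean of per-survey estimates; its SE is the
  standard error of that mean (sample SD/√n), falling back to the analytic
  SE for a single survey. Surveys with R = 0 are excluded with a warning.
* Cumulative pooling averages counts *before* the quotient:
  N̂ₖ = M·mean(C₁..Cₖ)/mean(R₁..Rₖ), surveys ordered by (day, AM before
  PM). The alternative (averaging per-survey quotients) is deliberately not
  used for pooling; the count-first form is the natural ratio estimator of
  the pooled design.
* The 95% interval for k ≥ 2 is normal-theory, ±1.96·√v where v is the
  leave-one-out jackknife variance (k−1)/k·Σ(θ₍ᵢ₎−θ̄)²; for k = 1 it uses
  the analytic SE. The interval is symmetric about N̂ₖ by construction.
  Note a consequence of normal-theory intervals at tiny k: the k = 2 width
  rests on a 1-df spread estimate and is extremely variable, so the width
  does not shrink monotonically in every realisation — it shrinks in
  expectation, which is what the tests assert (mean widths over thousands
  of replicate periods fall from k = 2 to k = 6, and change by <25% from
  k = 3 to k = 6, i.e. precision has essentially stabilised by the third
  survey).

## The detection GLMM

Marked fraction per survey row (period i, day j, diel k):

    marked_seen ~ Binomial(total_seen, P)
    logit(P) = α + β·Method + b_i + b_ij + b_ijk + ε

* Reference level SO, so β are contrasts against the historical platform.
* The nested random intercepts are Gaussian; ε is an observation-level
  Gaussian intercept carrying binomial overdispersion (a binomial GLMM has
  no free residual variance, so a "residual error" term can only enter this
  way).
* "Vague priors" are made concrete as N(0, 10²) on α and β and
  half-Cauchy(scale 5) on all four random-effect SDs. A random-slope
  variant (day trend varying by period) is out of scope; only the selected
  nested-intercepts model is implemented.

### Sampler

A Metropolis-within-Gibbs scheme written for this model:

1. Random-walk Metropolis on α and each β (Gaussian proposals).
2. Vectorised random-walk Metropolis on each level's intercepts: groups
   within a level touch disjoint rows, so all groups are proposed and
   accepted/rejected simultaneously and independently.
3. Conjugate Gibbs draws for each variance through the inverse-gamma
   expansion of the half-Cauchy prior: σ²|b,a ~ InvGamma((n+1)/2,
   Σb²/2 + 1/a), a|σ² ~ InvGamma(1, 1/A² + 1/σ²), whose marginal over a is
   exactly half-Cauchy(A) on σ.
4. Exact-Gibbs *translation sweeps* along the hierarchy (α↔period,
   period↔day, day↔diel, diel↔residual): a shift δ is moved from a parent
   to its children, leaving every linear predictor — hence the likelihood —
   unchanged, with δ drawn from its Gaussian full conditional under the
   priors. Large counts pin the *sums* α + bᵢ + … tightly, so without these
   sweeps the intercept mixes pathologically slowly; with them, intercept
   credible intervals attain nominal coverage (18–20/20 across the
   seeded recovery suite).

Step sizes adapt every 50 burn-in iterations toward 30–45% acceptance and
are frozen afterwards; chains are deterministic given the seed. Correctness
checks: a prior-only run (likelihood switched off) reproduces the prior
moments of α; the model with all σ fixed at 0 matches a maximum-likelihood
logistic regression to <0.01 on the logit scale; split-chain R̂ < 1.1 at
study scale.

### Summaries

* `variance_partition`: per draw, shareᶜ = σ²ᶜ/(σ²_period+σ²_day+σ²_diel)
  (residual excluded by default, available via flag); posterior mean and
  95% HPD per component; all-zero draws get uniform shares with a warning.
* `marked_proportions`: by default the conditional (fixed-predictor) scale
  expit(α + β); a `marginal=True` flag integrates the random effects out by
  Gauss–Hermite quadrature. The conditional scale is the default because
  the quantity of interest is the typical-survey marked fraction.
* HPD intervals are the shortest window containing 95% of sorted draws.

## Conversion factors and comparisons

* CF(A→B) = mean over jointly surveyed periods of N̂_B/N̂_A, with the
  sample SD over periods; quotients are formed from period-mean estimates
  (a per-survey pairing is available separately). The direction is defined
  so that the factor scaling the bias-deflated SO series up to UAV/UWV
  level exceeds 1.
* The CF-vs-abundance trend uses Spearman rank correlation (average
  ranks); the two-sided p-value is an exact full enumeration of all n!
  orderings for n ≤ 8 — at the programme's n = 6 an asymptotic p would be
  meaningless — plus a least-squares line of CF on abundance.
* The totals comparison fits Gaussian models to log_e period-mean totals
  with and without a method effect and reports the LR deviance
  D = n·log(RSS₀/RSS₁) against χ² with (n_methods − 1) df; the same test is
  run on log densities when per-method areas are supplied. Closed-form MLE
  log-likelihoods are used (verified against OLS log-likelihoods in the
  tests).

## Geometry and the detectability experiment

* hfov = 2·atan(tan(dfov/2)·w/√(w²+h²)) for a rectilinear lens;
  alternatively hfov = 2·atan(w_frame/2f) from an equivalent focal length.
  The focal-length route is preferred when a manufacturer quotes one: it
  pins the horizontal FOV without an aspect assumption, and for the UAV
  camera here (20 mm equivalent, 94° diagonal on the 3:2 frame) it yields
  the 90.0 m swathe at 50 m altitude that the programme reports, whereas
  naively applying the 94° diagonal to a 16:9 video aspect would give
  93.5 m.
* area (km²) = swathe (m) × path (km)/1000; density = count/area. The SO
  (0.3 km²) and UWV (0.4 km²) areas are configured constants — their
  zig-zag tracks are not reconstructible from swathe alone — while the UAV
  area 0.585 km² derives exactly from 90 m × 6.5 km.
* The paired model-turtle experiment (plain vs marked disappearance depth
  at 3 sites) is analysed by a t-test on log_e depths. The Welch
  unequal-variance form with fractional Welch–Satterthwaite df is the
  default (a pooled-variance option exists); the mean gain is reported in
  metres on the original scale. Degenerate zero-variance inputs return
  t = 0, p = 1 (equal means) rather than NaN.

## The synthetic-data generator

`simulate_dataset` draws, per period, nested Gaussian intercepts on the
logit detection scale; per day, permanent departures (binomial thinning,
marked and unmarked alike — closure is violated only if
`departure_prob > 0`); per survey, binomial detection counts with
logit p(unmarked) = logit(base_detect) + b_i + b_ij + b_ijk and an extra
log-odds term log(κ) for marked animals. Bias enters as additive log-odds
(an odds ratio), not a probability multiplier, so probabilities stay
bounded; values that still fall outside (0,1) are clamped to
[1e-9, 1−1e-9] with a warning finding. Random streams are derived per
(period), (period, presence) and (period, day, diel, method), so a fixed
seed is byte-reproducible and adding a platform does not perturb the
others' draws.

Defaults encode the field programme's conditions: 6 periods, n_true
20 000, M 2 000, 3 days × AM/PM, base detection 0.05/0.06/0.12 for
SO/UWV/UAV (chosen to reproduce the observed per-survey totals of order
10²–10³ given 20 000 females), SO mark-bias odds ratio 1.6 (the magnitude
implied by conversion factors of ~1.5–1.7), σ_period 0.5, σ_day 0.1,
σ_diel 0.05 (detection varies far more between trips than within),
departure 0 (closure held in the field data).

Two limits matter for interpreting tests. First, detection-scale random
intercepts act on marked and unmarked animals alike and cancel out of the
marked *fraction* at low detection probability, so this generator cannot
realise a prescribed period variance on the GLMM scale; sampler-recovery
tests therefore use `simulate_marked_counts`, which generates directly
from the binomial mixed model. Second, the generator treats the surface
observer's bias purely as extra detections of marked animals; if part of
the real bias were double-counting of marked individuals, the marked
fraction would be inflated the same way but the total count would differ —
the simulator does not separate the two mechanisms. There is also no
spatial structure, no depth/availability process in time, and no
individual identity in the output, so passing tests demonstrate the
statistical machinery, not the field protocol.

`simulate_detectability_trials` pairs plain and marked disappearance depths
per site with independent multiplicative log-normal noise around plain_mu
and plain_mu + mark_gain.

## Problem sizes used in the test suite

Recovery tests run at the scale of the field design (6 periods × 6 surveys
× 3 methods; counts of order 10²–10³): 200 replicate periods for LP
unbiasedness and conversion-factor recovery, 20 seeded fits of 5 000
iterations (1 000 burn-in) for GLMM interval coverage, and 4 000 replicate
periods for the jackknife width curve. These sizes put Monte-Carlo error
well inside the asserted tolerances while keeping the full suite under a
couple of minutes on one core.

## Known limitations

* The sampler is single-threaded random-walk MCMC; for much larger designs
  (hundreds of periods) a gradient-based sampler would be preferable.
* Exact Spearman enumeration is factorial and capped at n ≤ 8 by default.
* Open-population models (Jolly–Seber/POPAN), tag loss, model averaging
  and any image/video handling are out of scope.
* Historical December series values are accepted as user input for
  conversion (`apply_conversion`); the package ships no historical series.
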