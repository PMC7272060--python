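# markresight

Mark-resight abundance estimation for nesting sea turtles, built around the
survey design used at the Raine Island green turtle (*Chelonia mydas*)
rookery: nesting females are painted with a white carapace stripe on one
night, and the surrounding inter-nesting waters are then surveyed repeatedly
— by a surface observer on a boat, by hull-mounted underwater video (UWV),
or by UAV — counting marked and unmarked turtles.

The package is for quantitative ecologists who need to

* estimate abundance from such counts with the **Lincoln-Petersen (LP)
  estimator** and quantify its precision under repeated sampling,
* test the LP **equal-detectability assumption** by modelling the marked
  fraction per survey with a **Bayesian binomial mixed model**,
* derive **conversion factors** that place estimates from different survey
  platforms on a common scale, and
* handle the supporting arithmetic: strip-survey geometry (field of view,
  swathe, area, density) and the paired depth-detectability experiment.

Everything is testable without field data: an individual-based simulator
generates surveys with the exact statistical structure the analysis assumes
(closed population, method-specific detection, marked-detection bias,
nested random variation, optional departure).

## The statistics

**Lincoln-Petersen.** With M marked animals, C sighted in a survey and R of
those marked, N̂ = M·C/R, with large-sample SE √(M²C(C−R)/R³). Period-level
estimates average per-survey N̂ (SE = sd/√n). Pooling the first k surveys
uses N̂ₖ = M·mean(C₁..Cₖ)/mean(R₁..Rₖ) with a leave-one-out jackknife 95%
interval — the precision-versus-effort analysis of the repeated design.

**Detection model.** Per survey row (period i, day j, diel slot k),

    marked_seen ~ Binomial(total_seen, P)
    logit(P) = α + β·Method + b_i + b_ij + b_ijk + ε

with reference level SO, nested Gaussian random intercepts, and an
observation-level overdispersion term ε. Priors are vague — N(0, 10²) on
fixed effects, half-Cauchy(5) on random-effect SDs — and inference is a
seeded Metropolis-within-Gibbs sampler (see `docs/methods.md`). If marked
and unmarked turtles are equally detectable, P is the same for every
method; a higher surface-observer P is the signature of marked-detection
bias, which deflates the historical LP series and motivates conversion
factors CF = N̂(method B)/N̂(method A) averaged over jointly surveyed
periods.

## Worked example

```python
import markresight as mr

# a synthetic six-period study at field scale: 20 000 females, 2 000 painted,
# surface observer with a 1.6 marked-detection odds bias, UAV/UWV unbiased
res = mr.simulate_dataset(mr.SimulationConfig(seed=42))
data = res.dataset

so = mr.period_estimate(data, "Dec 2016", "SO")
uav = mr.period_estimate(data, "Dec 2016", "UAV")
print(so.n_hat, so.se)    # 14169.9 668.4   <- deflated by the bias
print(uav.n_hat, uav.se)  # 20474.3 522.9   <- near the true 20 000

cf = mr.conversion_factor(mr.estimate_all(data), "SO", "UAV")
print(cf.mean_cf, cf.sd_cf)  # 1.47 0.07

fit = mr.DetectionGLMM(data).fit(n_iter=4000, n_burn=1000, seed=6)
print(fit.marked_proportions())
#  method   mean  ci_low  ci_high
#      SO 0.1462  0.1413   0.1507   <- marked fraction inflated for SO
#     UWV 0.0997  0.0961   0.1032   <- ~ M/N = 0.10 for unbiased methods
#     UAV 0.1003  0.0974   0.1030

for c in mr.cumulative_estimates(data, "Dec 2016", "UAV"):
    print(c.k, round(c.n_hat), round(c.ci_low), round(c.ci_high))
# k=1 22123 [18250, 25996]
# k=3 20540 [19198, 21883]   <- interval stabilises after ~3 surveys
# k=6 20362 [19448, 21276]
```

The surface observer sees a marked fraction of 0.146 against 0.100 for the
unbiased platforms, its abundance estimate is ~30% low, and the recovered
SO→UAV conversion factor (1.47) reflects the simulated odds bias of 1.6
(the odds ratio exceeds the probability ratio at non-trivial detection
probabilities). Survey geometry is one call each:

```python
hfov = mr.horizontal_fov_from_focal(20.0)   # 83.97 deg for a 20 mm equivalent lens
mr.swathe_width(50.0, hfov)                 # 90.0 m strip at 50 m altitude
mr.survey_area(90.0, 6.5)                   # 0.585 km^2 over the 6.5 km reef track
```

A CLI mirrors the library: `markresight simulate | estimate | glmm |
compare | geometry | report` (see `markresight --help`). `report` runs the
whole pipeline and writes each stage's CSVs plus a plain-text summary.

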