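# wolfpack

Simulation and Bayesian analysis of interactive avoidance ("wolfpack")
tasks, built for researchers in visual psychophysics and behavioral
modeling who study perceived displacement of agent-like stimuli.

In these tasks a participant steers a green circle (the *chasee*) with the
mouse among autonomously moving sprites (*agents*) whose orientation is
manipulated: agents pointing head-on at the chasee degrade avoidance
performance relative to perpendicular agents — the wolfpack effect.  The
package implements the perceived-displacement account of that effect as a
tested, reusable pipeline: the perceived center of an agent's body sits a
distance *k* ahead of the sprite's nominal pivot along its nose, so a
nominal rotation is perceived partly as a translation; shifting the pivot
by *d* along the body axis changes every displacement measure linearly
in *d*, and the avoidance effect vanishes when the pivot is moved to the
perceived center (at the zero-crossing of the occupancy regression).

The package contains:

* a 75 Hz stimulus simulator (quadrant-confined constant-speed agents with
  Poisson direction changes, mirrored wall bounces, pivot-shift rendering,
  exact dart-polygon collision tests, trial assembly for the avoidance /
  bisection / recall / static tasks);
* synthetic participants with known ground truth: a net-force-descending
  cursor controller for the avoidance task, a midpoint-tracking controller
  for bisection, the additive four-factor vector model for recall
  (h = Σ_k α_k·u(φ_k) + ε), and beta-distributed per-trial occupancy;
* the analysis stages: hierarchical four-factor recall regression (with
  the pivot-shift extension α₄ = μ₄ + β₄·d), the hierarchical bivariate
  bisection model and its pivot regression, the hierarchical beta
  occupancy model w ~ Beta(μκ, (1−μ)κ) with identity-link pivot
  regression, zero-crossing estimate (0.5 − μ)/β and logit-normal
  robustness variant, the inverse-square net-force analysis of cursor
  dwell events with per-participant grid searches and Student-t pooling,
  and a cross-task model giving per-participant parameters a common
  trivariate normal prior with correlation estimates and a fake-data
  power analysis.

Hierarchical posteriors are sampled with analytically marginalized
linear-Gaussian likelihoods plus ensemble MCMC (emcee), or a vectorized
Metropolis-within-Gibbs sampler for the beta model; convergence is checked
with split R-hat over four chains (R̂ < 1.05) and results are reported as
"mean, 95% PI [a, b]" percentile intervals.  See `docs/methods.md` for the
models, priors, numerical choices and limitations.

## Worked example

Recover the occupancy regression from synthetic avoidance data: 20
synthetic participants, 42 trials each across the dart pivot-shift
schedule, generated at a zero-pivot occupancy of 0.482 and a slope of
−0.093 per degree:

```python
import numpy as np
from wolfpack import PopulationSpec, fit_occupancy, zero_crossing
from wolfpack.synthetic_participant import make_occupancy_dataset

population = PopulationSpec(lma_mu_mean=0.482)
profiles = population.draw(20, seed=0)
schedule = np.repeat([-0.4, -0.2, 0.2, 0.4], 11)[:42]
records = make_occupancy_dataset(profiles, 42, d_schedule=schedule,
                                 slope=-0.093, seed=1)

fit = fit_occupancy(records, with_pivot_regression=True, seed=2)
print(fit.summaries["mu_pop"])
print(fit.summaries["slope"])
print(zero_crossing(fit))
```

prints

```
mu_pop: 0.482, 95% PI [0.468, 0.495]
slope: -0.0852, 95% PI [-0.103, -0.0649]
zero_crossing: 0.217, 95% PI [0.056, 0.407]
```

`mu_pop` is the population occupancy at zero pivot shift (below 0.5: the
avoidance effect is present), `slope` its change per degree of tailward
pivot shift, and `zero_crossing` the pivot-shift magnitude at which
predicted occupancy returns to chance — both generating values lie inside
their recovered intervals, and the zero-crossing says the wolfpack effect
disappears once the pivot is moved ≈0.2° toward the perceived body center.

A command-line interface wraps every stage
(`wolfpack simulate | synth | analyze-recall | analyze-bisection |
analyze-lma | analyze-forcefield | analyze-joint | power | study`); the
`study` command runs the end-to-end synthetic study and emits a recovery
report.

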