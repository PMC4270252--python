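# Methods

This note documents the models implemented in `wolfpack`, the assumptions
behind the synthetic-data generators, the numerical choices made where the
design was genuinely open, and the known limitations.

## The scientific setting

In interactive avoidance displays, participants steer a green circle (the
*chasee*) with the mouse among autonomously moving sprites (*agents*:
bugs — circles with eye dots, darts — concave arrowheads, or eyeless
circles).  When agents are oriented head-on toward the chasee, avoidance
performance degrades relative to perpendicular orientation — the *wolfpack
effect*.  The package implements the computational content of the
perceived-displacement account of this effect: the subjectively perceived
center of an agent's body is displaced from the sprite's nominal pivot
toward its nose, so a nominal rotation about the pivot is perceived partly
as a translation.  Three tasks measure the displacement: Location Recall
(click the last position of a vanished agent), Distance Bisection (keep the
chasee midway between two agents), and the avoidance (LMA) task itself,
analyzed through quadrant occupancy and through a net-force model of cursor
placement.

### Coordinate and sign conventions

Screen-centered coordinates, x rightward, y upward, degrees of visual
angle.  The four quadrants are delimited by the axes with a half-open
convention (x >= 0 counts as right, y >= 0 as top).  Each agent has a
pivot (the simulated, rotation-center point) and a body reference point
(dart's concave vertex / circle center); the signed pivot shift `d` places
the reference point at `ref = pivot + d * orientation`, so negative `d`
moves the pivot toward the nose.  Perceived displacements are positive
toward the nose.  Angles are stored in degrees in files; unit vectors in
memory.

## Stimulus simulator (`kinematics`)

Agents move at 7.8 deg/s inside 5.9-degree quadrant squares flush with the
display center, at 75 Hz, for 17 s per trial.  Direction changes form a
Poisson process with rate 3/s (implemented by exponential/Poisson thinning
per frame — the simplest process consistent with a stated mean rate); each
change turns the heading by a uniform draw within +/-45 degrees.  Wall
contact mirrors the trajectory (coordinate reflection, which preserves path
length) and leaves the orientation untouched.  Head-on agents point at the
chasee's current position every frame; perpendicular agents are rotated 90
degrees from that direction, with the side chosen randomly per agent at
trial start and held fixed.  Orientation is referenced to the pivot
position (the rotation center); this is a configuration choice, exposed in
code.

The dart polygon is built from the stated geometry: three convex vertices
on an equilateral triangle of circumradius 0.95 degrees around the concave
vertex.  Its uniform-lamina centroid (~0.158 degrees ahead of the concave
vertex) is computed, not hard-coded, because the figure-quoted 0.13-degree
center of mass is not reproducible from the printed geometry alone.
Dart-chasee collision uses an exact polygon-circle test (shapely); bugs and
circles use circle overlap.

## Synthetic participants (`synthetic_participant`)

Generators produce data with exactly the statistical structure each
analysis assumes, so parameter recovery is well defined.

* **Recall**: judged = true + sum_k alpha_k u(phi_k) + bivariate isotropic
  Gaussian noise (sd 1.0 deg per axis, matching the scatter scale of
  recall judgments).  Default population coefficients are the bug-row
  values (0.01, -0.02, 0.26, 0.14); between-participant sds (0.49, 0.29,
  0.65, 0.32) are sized so that a 20-participant mean has the reported
  interval widths.
* **Bisection**: the chasee tracks the midpoint of the two *perceived*
  centers (reference point + per-agent body-frame shift along the nose)
  with a first-order lag (rate 8/s) and small tracking noise.  Population
  head-on/perpendicular displacements 0.25 / 0.10 deg with between sds
  0.3 / 0.25, again derived from the reported interval widths at 20
  participants; the measurement-level generator adds trial noise of 0.4
  deg (the per-trial scatter scale).
* **Occupancy**: w ~ Beta(mu kappa, (1-mu) kappa) with mu = mu_i +
  slope * d; participant means mu_i spread with sd 0.025 around the
  population mean, within-participant concentration kappa = 30.
* **LMA controller**: the cursor descends the net-force field of the
  perceived agent centers (each at `ref + d_perceived * orientation`, a
  fixed body-frame point) using agent positions one perception-action lag
  (200 ms) earlier, with mobility 150 deg/s per unit force integrated in 3
  substeps per frame (explicit integration is otherwise unstable in stiff
  regions of the field), a 30 deg/s speed cap, per-frame motor noise of
  0.02 deg, and Poisson-triggered relocation bursts (0.8/s, 250 ms) during
  which the cursor moves at near-cap speed down the field.  The bursts give
  the cursor the dwell-and-jump character of real mouse use; without them
  low-boundary-weight participants barely move and produce no analyzable
  dwell events.  Boundary weights c are drawn uniformly on (0.3, 2.5)
  across participants.

The controller is deliberately minimal plumbing: it exists so that the
claim "participants minimize the net force" is true by construction in the
synthetic data.  It does not model learning, trial-order effects, strategy
switches, or the sigmoidal condition pattern seen in real data; passing
recovery tests therefore show that the analyses recover the parameters of
these idealized processes, not that real behavior is this simple.

## Analysis stages

All hierarchical models are Bayesian with uniform priors on bounded ranges
(coefficients within +/-5 deg, sds below 5 deg, mean proportions on (0, 1),
beta concentrations on (1, 500)) and are summarized as the posterior mean
with 50% and 95% percentile intervals.  Convergence requires split R-hat <
1.05 on four chains; fits raise a diagnostic error carrying the R-hat table
otherwise (suppressable for exploratory runs).

**Sampling machinery.**  No general-purpose MCMC framework with built-in
hierarchical model support is used; instead:

* Linear-Gaussian hierarchies (recall regression, bisection model,
  logit-normal occupancy, the cross-task joint model) integrate the
  participant-level coefficients out analytically.  With participant data
  `y_i = X_i beta_i + F_i gamma + eps` and `beta_i ~ N(mu, D)`, the
  marginal is Gaussian with covariance `X_i D X_i' + R_i`, evaluated via
  low-rank (Woodbury) identities from per-participant Gram statistics, so
  one likelihood evaluation costs O(P K^3) with K <= 6.  The resulting
  low-dimensional population posterior is sampled with the
  affine-invariant ensemble sampler (emcee), walkers grouped into four
  chains; participant-level coefficients are then drawn from their exact
  conjugate conditionals.  The marginal likelihood implementation is
  verified against a dense multivariate-normal evaluation in the tests.
* The beta occupancy model (not marginalizable) uses a blocked
  random-walk Metropolis-within-Gibbs sampler, vectorized across four
  chains and across participants (participant blocks are conditionally
  independent), with proposal scales adapted during burn-in only.
* The Student-t pooling of per-participant force minima samples
  (location, log scale, log df) with emcee.

**Recall** (`recall_model`): h = judged - reference position; judgments
farther than 4 degrees are excluded.  Predictors: gravity (0, -1), momentum
(last motion direction), hand inertia (unit vector from the agent to the
final cursor position), orientation (last nose direction).  Static trials
define only the orientation axis; the static stage reports the hierarchical
mean of the body-frame (nose = +x) displacement.  The predictor set is a
user choice (e.g. dropping gravity for darts); automatic predictor
selection is deliberately not implemented.  With `pivot_regression`, the
orientation displacement is re-referenced to the pivot (h + d * u4) and
modeled as alpha_4 = mu_4 + beta_4 * d.  The re-referencing is the reading
under which a percept anchored to the agent's *body* produces a slope of
one — shifting the sprite moves the percept with it — and it reproduces the
reported near-unit slopes; measuring from the sprite reference point
instead would make the slope identically zero for a body-anchored percept.
Residual noise is bivariate with independent per-axis sds (axis correlation
fixed at zero; the data-generating assumption is silent on it).  A
`--exclude-zero-pivot` option reproduces the reported practice of fitting
the pivot line without the zero-shift block.

**Bisection** (`bisection_model`): discard the first 2 s; displacement =
cursor - nominal midpoint (midpoint of the segment joining the two pivots);
rotate *per frame* so the head-on agent lies on -x (the agents move, so the
instantaneous configuration defines the axes; a per-trial rotation would
mix them); flip the y sign so +y lies along the perpendicular agent's nose;
average retained frames and multiply both axes by 2.  The +y convention is
forced by the doubling identity: a controller with per-agent nose-ward
shifts (a, b) must yield measures with means (d + a, d + b), which holds
only if +y is along the perpendicular agent's orientation.  The doubling
exactly undoes the halving of one agent's shift by the midpoint.  The
hierarchical model treats the two axes independently (normal hierarchies);
the regression variant adds offset + slope * d at the population level.
`implied_midpoint_shift` converts a slope to the cursor shift per degree of
agent displacement (slope / 2).

**Occupancy** (`lma_model`): w = fraction of frames in the two wolfpack
quadrants (half-open boundary convention).  The beta model uses the
mean/concentration parameterization at both levels; the pivot regression is
linear on the mean scale (identity link — the reported slope is in
proportion units per degree), with means clipped to (0.01, 0.99) and exact
0/1 proportions clipped at 1e-4 (counted and logged).  A logit-normal
variant provides the robustness check; both give practically identical
population means on well-behaved data.  The zero-crossing (0.5 - mu) /
slope is computed draw-wise and reported as a magnitude, because the
prose descriptions of the slope sign under the two shift directions are
contradictory while the magnitude is not; a warning flags heavy-tailed
summaries when the slope posterior has mass near zero.  The two-stage
participant-mean t-test that the hierarchical model replaces is provided
for comparison.

**Net force** (`forcefield`): F_a = (1/r^2) u(g -> h) per agent;
F_boundary has magnitude (1/r^2 - 1/2) directed from the display center
toward h.  The boundary magnitude is implemented literally from its
(ambiguously typeset) definition — beyond r = sqrt(2) it pushes inward,
which is what boundary avoidance requires — and is isolated behind a
configuration hook so alternatives can be swapped in.  Dwell events:
per-frame speed, Gaussian-smoothed with sigma = 1 frame (truncated at 4
sigma), runs below 15 deg/s lasting >= 300 ms (>= 23 frames at 75 Hz); the
first event per trial is excluded.  The displacement analysis evaluates
|F_net| at the raw cursor position 100 ms after event onset against agent
positions 200 ms earlier (the perception-action lag), over a displacement
grid (-0.2..0.5, step 0.05) and a boundary-weight grid (0 plus 24
log-spaced values on 0.05..10 — the grid must be fine because the basin in
d is only well-formed near the participant's true boundary weight).  Per
participant, (c, d) is the joint grid argmin of the median force magnitude,
with ties resolved toward the smallest displacement; participant minima are
pooled with a location-scale Student-t posterior.

**Cross-task model** (`crosstask`): participant triples (recall orientation
coefficient from the dart model without gravity, bisection head-on mean,
logit-occupancy mean) receive a common trivariate normal prior; Sigma is
decomposed into sds (bounded uniform) and correlations uniform over valid
correlation matrices (independent uniforms with positive-definiteness
rejection), which reproduces the familiar wide (about [-0.9, 0.9]) marginal
intervals under weak data.  The remaining recall coefficients keep
independent normal hierarchies; all likelihoods are linear-Gaussian, so the
whole participant level is marginalized and the 17-dimensional population
posterior is sampled directly.  The power analysis refits simulated
datasets over a participant-count grid and reports the mean posterior sd of
the correlations.

## Problem sizes and reproducibility

Every generator and sampler is a pure function of its parameters and seed;
trials serialize to JSON-lines and round-trip bit-exactly.  Tests and the
acceptance script run at desk scale: recovery suites use about 20 synthetic
participants with 18–42 trials per task (the study's per-condition scale),
the net-force recovery uses 12 participants x 20 trials, and long-run
simulator statistics use 1000 simulated seconds.  MCMC defaults (2,000–
4,000 ensemble steps or Gibbs sweeps, half discarded) are sized for those
problem sizes and reach R-hat < 1.05 with margin; paper-scale runs simply
increase the step counts.

## Known limitations

* The net-force displacement estimate is biased slightly downward (a few
  hundredths of a degree at the default conditions): dwell positions lag
  the moving equilibrium of the field, and the residual force this leaves
  is cheapest to cancel by shifting force origins slightly backward.  The
  recovery tests bound, but do not remove, this bias; it shrinks when
  agents move slowly or the cursor tracks more tightly.
* The identity-link beta regression can require mean clipping for extreme
  pivot shifts; the logit link is available but changes the slope's units.
* The controller and generators deliberately omit learning and trial-order
  effects, threat averaging across trials, gaze-related biases, and any
  nonlinearity in the displacement-vs-shift relation; linear-model results
  on synthetic data must be interpreted accordingly.
* Correlation recovery in the cross-task model is attenuated at small
  samples by measurement noise in the per-task parameters; the power
  analysis quantifies this rather than correcting it.
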