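# Methods

## The probabilistic ensemble

The level-0 data are N instances (x_n, y_n) with x ∈ ℝ^D and a scalar
response per variable of interest. For cross-validation the instances are
split into K almost-equal random folds (default K = 5; leave-one-out when
N < 10, since tiny data sets dominate this domain). Each of the M base
learners is fitted K times on the fold complements; its out-of-fold
predictions z_mn = f_m^(−k)(x_n) form the level-1 data, which is the only
evidence the metalearner ever sees. The final predictive model couples the
metalearner's posterior with base learners refitted on the full data — the
usual stacking arrangement, which prevents the weights from rewarding
memorization.

The metalearner is the convex combination y = wᵀ f(x) + ε with
ε ~ N(0, σ²), w on the (M−1)-simplex. Both the weights and the noise are
random variables; their joint posterior given the level-1 data carries the
model's epistemic uncertainty, while σ carries the aleatoric part.

### Base learners

Eight families are registered: random forest, multilayer perceptron,
support-vector regressor, kernel ridge, k-nearest-neighbours, Gaussian
process, gradient boosting, and an automated pipeline-search slot. Each
uses fixed, reasonable hyperparameters (documented in
`learners._build_estimator` and overridable per spec) rather than per-task
tuning: the heterogeneous ensemble, not any single tuned member, is the
model. Scale-sensitive families are wrapped with a standardizer fitted on
the same partition as the learner, so folds never leak. The
pipeline-search slot ships disabled with a pluggable builder hook
(`learners.AUTO_PIPELINE_BUILDER`); its search backend is heavyweight and
the ensemble mathematics only needs M ≥ 2. A learner whose fit fails on
any fold is dropped with a warning. k-NN clamps its neighbour count to the
training-partition size, which matters in leave-one-out regimes.

### Posterior sampling

The posterior p(w, σ | level-1 data) is sampled by adaptive random-walk
Metropolis in an unconstrained parameterization:

* weights via softmax of u ∈ ℝ^M with u_M anchored at 0 (removing the
  translation non-identifiability), prior u_m ~ N(0, 1) — a smooth,
  near-uniform prior on the simplex under which every proposal is feasible;
* noise via log σ with a half-normal prior on σ scaled to the response SD
  (and the log-transform Jacobian included).

Defaults: 5 000 kept draws after 1 000 burn-in steps; during burn-in the
isotropic proposal scale adapts every 50 steps toward ≈0.3 acceptance and
is then frozen, so the kept draws form a valid Markov chain. Acceptance
outside [0.05, 0.95] triggers a diagnostic warning, not a failure. With
M ≤ 8 parameters this sampler mixes well and needs no gradient. A guard at
|log σ| > 50 keeps the chain proper in the degenerate zero-residual case
(where the σ-posterior would otherwise drift without bound); predictive
quantiles use an expanding bracket so even those near-point-mass mixtures
invert cleanly.

`log_posterior` exposes the equivalent density in the natural (w, σ)
coordinates — uniform simplex prior plus the half-normal — for direct
inspection and for grid-integration cross-checks.

### Prediction

The posterior predictive at x* is the equal-weight Gaussian mixture with
components N(w_sᵀ f(x*), σ_s²) over posterior samples s. Mean and variance
follow the law of total variance: E = mean of w_sᵀ f(x*), Var = mean σ_s²
plus the variance of the component locations; quantiles invert the mixture
CDF by bisection. The mean always lies in the convex hull of the base
predictions because each component location is a convex combination.

Cross-validated metrics (R², MAE, 95% credible intervals) use per-fold
posteriors — the posterior entering instance n's prediction is fitted with
n's fold removed — while operational predictions use the single full-data
posterior.

Multiple responses are handled as fully independent per-response ensembles
(shared features, per-response base fits and posteriors, seeds keyed by
response name so column order is irrelevant).

### Success probabilities

P(at least one of a batch succeeds) treats recommendations as independent
(the joint predictive across inputs is not modelled — a declared
simplification): each single-shot probability is estimated by Monte Carlo
from its predictive mixture (default 10⁵ draws) and combined as
1 − Π(1 − p_i). The specification objective counts |y − y*| ≤ tolerance as
success; the default tolerance is 5% of the observed response range. The
companion `n_required(p_single, p_target)` inverts the same geometric
relation to report how many builds a desired overall success chance needs.

## Recommendation

The surrogate G(x) blends predictive mean and SD via α (maximization:
(1−α)E + α·SD; minimization negates the mean term; specification:
−(1−α)‖E − y*‖² + α·SD, distance summed over responses). The target
density π(x) ∝ exp(G(x)) on the bounded box B (uniform prior; bounds from
the user or per-feature data min/max with an optional margin) is sampled
by parallel tempering:

* 5 chains at geometric temperatures 1…25;
* per-sweep Gaussian random-walk proposals with per-dimension SD equal to
  0.1× the feature range, reflected at the bounds (symmetric, so no
  correction term);
* adjacent-pair swap attempts every 10 sweeps with the standard
  (β_i − β_j)(G_j − G_i) acceptance;
* draws taken from the temperature-1 chain only, one per post-burn-in
  sweep, each carrying its already-computed G value. Default 10 000 draws
  after 1 000 burn-in sweeps; all chains below 1% acceptance raises a
  sampler-failure error.

Selection scans draws in non-increasing G order (ties by draw index) and
accepts a draw iff **some feature** differs by at least a relative factor
γ from that feature's value in **every reference point** (training inputs
plus already-accepted recommendations). The relative difference is
|x_f − r_f| / max(|r_f|, 0.01·range_f); the floor keeps zero-valued
references meaningful. If the draws are exhausted early, γ is halved (at
most 5 times, floor 0.01) and the scan restarts; a still-short batch is
returned flagged incomplete rather than padded. The ∃-feature/∀-reference
quantifier order is the literal reading of the rule; the alternative
(∀ point ∃ feature) is weaker and was not adopted. Late in a dense
campaign the incomplete path is expected behavior: once training points
blanket the optimum at the γ floor there is nothing usefully new to build.

## The benchmark generator

Three landscapes emulate a production response of increasing learning
difficulty: a smooth quadratic bowl with a narrow bump (easy; box [0,10]^d,
maximum 25), the classical quartic multi-minimum landscape (medium;
[−5,5]^d), and Σ√x_i·sin(x_i) (difficult, highly multimodal; [0,10]^d,
which also satisfies its x ≥ 0 domain). Boxes are chosen so each
landscape's interesting structure is inside the search volume. Observation
noise defaults to 0 (configurable Gaussian SD).

A campaign starts from a 16-point Latin-hypercube design (one sample per
equal-width interval per dimension, via scipy's QMC engine), runs
maximization cycles of 16 recommendations each, and tempers α linearly
from 0.9 to 0 across cycles — exploratory early, exploitative late.
Held-out error is measured on a fresh 100-point Latin-hypercube probe
evaluated noise-free and never added to training. Aggregation over
repeated runs reports per-cycle means with t-based 95% confidence
intervals.

What the generator does **not** emulate: measurement batch effects,
heteroscedastic or non-Gaussian assay noise, discrete/categorical design
choices (promoter identities), biological replicate structure, and the
strong coupling of a pathway to host metabolism that makes real proteomics
responses hard to learn. Passing trend tests therefore demonstrates that
the learn-recommend loop closes on well-posed continuous problems, not
that any particular wet-lab campaign would improve at the same rate.

## Problem sizes and seeds

Library defaults keep the full-scale constants (5 000 posterior draws,
10 000 tempered draws). The test suite and the acceptance script run the
same code at desk scale as the package's own default benchmark setting:
fast learner subset (small random forest, k-NN, kernel ridge, GP),
1 000–2 000 posterior draws, 500–3 000 tempered draws, 10 campaigns × 10
cycles in 2-D. Every stochastic component receives a seed derived
deterministically from one global seed and a label path (CRC32-based), so
a single integer reproduces folds, learner fits, both MCMC samplers and
whole campaigns; d = 50 problems are supported but not exercised by
default suites.

## Known limitations

* Base-learner covariance is ignored by the metalearner (weights are the
  only coupling), and recommendations are scored independently for the
  batch success probability.
* Continuous inputs only; no mixed objectives across responses (e.g.
  maximize one while minimizing another).
* The level-1 likelihood assumes homoscedastic Gaussian noise; heavy-tailed
  responses will widen σ rather than re-shape the predictive.
* Tempering constants (ladder 1…25, step 0.1·range) are robust for the
  bundled landscapes but may need adjustment for very high-dimensional or
  extremely peaked surrogates.
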