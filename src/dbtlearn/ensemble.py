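"""Bayesian weighted ensemble: the level-1 metalearner and its posterior.

The response at input x is modelled as a convex combination of base-learner
predictions with Gaussian noise,

    y = w^T f(x) + eps,   eps ~ N(0, sigma^2),   sum_m w_m = 1,  w_m >= 0,

where theta = (w, sigma) carries the ensemble's epistemic uncertainty. The
posterior p(theta | D) is inferred from level-1 data (out-of-fold base
predictions paired with observations) by adaptive random-walk Metropolis in
an unconstrained parameterization: the weights live on the simplex via a
softmax of u in R^M with the last coordinate anchored at 0, and the noise is
sampled as log sigma. Priors: u_m ~ N(0, 1) (a smooth near-uniform prior on
the simplex) and a half-normal on sigma scaled to the response SD.

The predictive posterior at a new input x* integrates over theta,

    p(y | x*, D) = Int N(y; w^T f(x*), sigma^2) p(theta | D) dtheta,

represented here as an equal-weight Gaussian mixture over posterior samples.
Its mean and variance follow from the law of total variance.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import optimize, stats

from ._utils import derive_seed
from .datasets import FoldPartition, TrainingSet, default_fold_count, make_folds
from .exceptions import ArgumentError, ConfigurationError, InfeasibleError
from .learners import (
    LearnerCollection,
    LearnerSpec,
    Level1Data,
    build_level1,
    default_learners,
    fit_full,
)

logger = logging.getLogger(__name__)

_LOG_2PI = math.log(2.0 * math.pi)


@dataclass
class EnsembleParams:
    """One point theta = (w, sigma): simplex weights and noise SD."""

    w: np.ndarray
    sigma: float

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.ndim != 1:
            raise ArgumentError("w must be a vector")
        if abs(self.w.sum() - 1.0) > 1e-12 or (self.w < 0).any():
            raise ArgumentError("weights must be non-negative and sum to 1")
        if not self.sigma > 0:
            raise ArgumentError("sigma must be positive")


@dataclass
class PosteriorSamples:
    """MCMC draws of theta: weight matrix (S x M) and noise vector (S,)."""

    weights: np.ndarray
    sigmas: np.ndarray
    acceptance_rate: float
    burn_in: int
    seed: int
    learner_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.sigmas = np.asarray(self.sigmas, dtype=float)
        if self.weights.ndim != 2 or len(self.sigmas) != len(self.weights):
            raise ArgumentError("weights must be S x M with matching sigmas")

    def __len__(self) -> int:
        return len(self.weights)

    @property
    def m(self) -> int:
        return self.weights.shape[1]

    def thetas(self) -> list[EnsembleParams]:
        return [EnsembleParams(w, s) for w, s in zip(self.weights, self.sigmas)]


class PredictiveDistribution:
    """Posterior predictive of y at one input: a Gaussian mixture.

    One equally weighted component N(w_s^T f(x*), sigma_s^2) per posterior
    sample s. Mean and variance are exact mixture moments; quantiles invert
    the mixture CDF numerically.
    """

    def __init__(self, locations: np.ndarray, scales: np.ndarray):
        self.locations = np.asarray(locations, dtype=float)
        self.scales = np.asarray(scales, dtype=float)
        if self.locations.shape != self.scales.shape or self.locations.ndim != 1:
            raise ArgumentError("locations and scales must be matching vectors")
        if (self.scales <= 0).any():
            raise ArgumentError("component scales must be positive")

    @property
    def mean(self) -> float:
        return float(self.locations.mean())

    @property
    def variance(self) -> float:
        # law of total variance: E[sigma^2] + Var[w^T f]
        return float((self.scales**2).mean() + self.locations.var())

    @property
    def sd(self) -> float:
        return math.sqrt(self.variance)

    def cdf(self, y: float) -> float:
        return float(stats.norm.cdf(y, loc=self.locations, scale=self.scales).mean())

    def sf(self, y: float) -> float:
        return float(stats.norm.sf(y, loc=self.locations, scale=self.scales).mean())

    def quantile(self, p: float) -> float:
        if not 0.0 < p < 1.0:
            raise ArgumentError("quantile level must be in (0, 1)")
        # bracket width floored at the representable spacing so nearly
        # degenerate mixtures (scales below ulp of the location) still bracket
        center = float(np.median(self.locations))
        span = float(
            max(
                self.locations.max() - self.locations.min() + 10 * self.scales.max(),
                1e-9 * (1.0 + abs(center)),
            )
        )
        lo, hi = center - span, center + span
        for _ in range(200):
            if self.cdf(lo) < p:
                break
            lo -= span
            span *= 2
        span = hi - center
        for _ in range(200):
            if self.cdf(hi) > p:
                break
            hi += span
            span *= 2
        return float(optimize.brentq(lambda y: self.cdf(y) - p, lo, hi, xtol=1e-10))

    def credible_interval(self, level: float = 0.95) -> tuple[float, float]:
        tail = (1.0 - level) / 2.0
        return self.quantile(tail), self.quantile(1.0 - tail)

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        idx = rng.integers(0, len(self.locations), size=n)
        return rng.normal(self.locations[idx], self.scales[idx])


def _softmax_anchored(u_free: np.ndarray) -> np.ndarray:
    """Map u in R^(M-1) to the M-simplex (last logit anchored at 0)."""
    u = np.append(u_free, 0.0)
    u -= u.max()
    e = np.exp(u)
    return e / e.sum()


def _gauss_loglik(y: np.ndarray, mu: np.ndarray, sigma: float) -> float:
    resid = y - mu
    n = len(y)
    return float(-0.5 * n * _LOG_2PI - n * math.log(sigma) - 0.5 * resid @ resid / sigma**2)


def log_posterior(
    theta: EnsembleParams, level1: Level1Data, sigma_scale: float | None = None
) -> float:
    """Log posterior density of theta given level-1 data (up to a constant).

    Prior: uniform over the weight simplex, half-normal on sigma with scale
    ``sigma_scale`` (default: SD of the observed responses). Returns -inf
    outside the support instead of raising.
    """
    w = np.asarray(theta.w, dtype=float)
    sigma = float(theta.sigma)
    if sigma <= 0 or (w < 0).any() or abs(w.sum() - 1.0) > 1e-9:
        return -np.inf
    if sigma_scale is None:
        sigma_scale = float(np.std(level1.y)) or 1.0
    log_prior = float(stats.halfnorm.logpdf(sigma, scale=sigma_scale))
    return log_prior + _gauss_loglik(level1.y, level1.z @ w, sigma)


def _sampler_logpost(
    phi: np.ndarray, z: np.ndarray, y: np.ndarray, sigma_scale: float
) -> float:
    """Unconstrained-space target: likelihood + N(0,1) prior on free logits
    + half-normal prior on sigma with log-sigma Jacobian."""
    m = z.shape[1]
    u_free, log_sigma = phi[: m - 1], phi[-1]
    if not np.isfinite(log_sigma) or abs(log_sigma) > 50:
        return -np.inf
    sigma = math.exp(log_sigma)
    w = _softmax_anchored(u_free)
    lp = -0.5 * float(u_free @ u_free)
    # half-normal logpdf inlined (hot loop), plus the log-sigma Jacobian
    lp += -0.5 * (sigma / sigma_scale) ** 2 + log_sigma
    return lp + _gauss_loglik(y, z @ w, sigma)


def sample_posterior(
    level1: Level1Data,
    n_samples: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
) -> PosteriorSamples:
    """Draw posterior samples of (w, sigma) by adaptive random-walk Metropolis.

    The proposal scale adapts during burn-in toward ~0.3 acceptance; after
    burn-in the chain is fixed (so the draws are a valid Markov chain) and
    every state is kept. Samples lie on the simplex exactly by construction.
    """
    if level1.n < level1.m:
        warnings.warn(
            f"level-1 data has fewer instances ({level1.n}) than learners "
            f"({level1.m}); posterior will be prior-dominated",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    m = level1.m
    z, y = level1.z, level1.y
    sigma_scale = float(np.std(y)) or 1.0
    dim = m  # (m - 1) free logits + log sigma
    phi = np.zeros(dim)
    phi[-1] = math.log(sigma_scale)
    lp = _sampler_logpost(phi, z, y, sigma_scale)
    scale = 0.5
    accepted_burn = 0
    window = 0
    # burn-in with adaptation
    for i in range(burn_in):
        prop = phi + scale * rng.standard_normal(dim)
        lp_prop = _sampler_logpost(prop, z, y, sigma_scale)
        if math.log(rng.random()) < lp_prop - lp:
            phi, lp = prop, lp_prop
            accepted_burn += 1
            window += 1
        if (i + 1) % 50 == 0:
            rate = window / 50.0
            scale *= math.exp(rate - 0.3)
            window = 0
    # sampling phase, fixed scale
    W = np.empty((n_samples, m))
    sig = np.empty(n_samples)
    accepted = 0
    for s in range(n_samples):
        prop = phi + scale * rng.standard_normal(dim)
        lp_prop = _sampler_logpost(prop, z, y, sigma_scale)
        if math.log(rng.random()) < lp_prop - lp:
            phi, lp = prop, lp_prop
            accepted += 1
        W[s] = _softmax_anchored(phi[: m - 1])
        sig[s] = math.exp(phi[-1])
    rate = accepted / n_samples
    if not 0.05 <= rate <= 0.95:
        warnings.warn(
            f"MCMC acceptance rate {rate:.3f} outside [0.05, 0.95]; "
            "inspect chain diagnostics",
            stacklevel=2,
        )
    return PosteriorSamples(
        weights=W,
        sigmas=sig,
        acceptance_rate=rate,
        burn_in=burn_in,
        seed=seed,
        learner_names=list(level1.learner_names),
    )


@dataclass
class EnsembleModel:
    """A trained probabilistic predictive model of the response(s).

    Couples base learners fitted on the full data with one posterior over
    ensemble parameters per response variable.
    """

    learners: LearnerCollection
    posteriors: list[PosteriorSamples]
    level1: list[Level1Data]
    feature_names: list[str]
    response_names: list[str]
    seed: int = 0
    training_inputs: np.ndarray | None = None
    training_responses: np.ndarray | None = None

    def __post_init__(self) -> None:
        for post in self.posteriors:
            if post.m != self.learners.m:
                raise ArgumentError("posterior dimension must match learner count")
        if len(self.posteriors) != len(self.response_names):
            raise ArgumentError("need one posterior per response")

    @property
    def n_responses(self) -> int:
        return len(self.response_names)

    def predict(self, x_star: np.ndarray, response_index: int = 0) -> PredictiveDistribution:
        """Posterior predictive distribution of one response at one input."""
        x_star = np.asarray(x_star, dtype=float)
        if x_star.ndim != 1 or len(x_star) != len(self.feature_names):
            raise ArgumentError(
                f"x_star must be a vector of dimension {len(self.feature_names)}"
            )
        f = self.learners.predict(x_star[None, :])[0]  # (M,)
        post = self.posteriors[response_index]
        return PredictiveDistribution(post.weights @ f, post.sigmas)

    def predict_moments(
        self, X: np.ndarray, response_index: int = 0
    ) -> tuple[np.ndarray, np.ndarray]:
        """Vectorized predictive mean and variance over a batch of inputs."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        F = self.learners.predict(X)  # (n, M)
        post = self.posteriors[response_index]
        L = F @ post.weights.T  # (n, S)
        mean = L.mean(axis=1)
        var = float((post.sigmas**2).mean()) + L.var(axis=1)
        return mean, var


def fit_ensemble(
    data: TrainingSet,
    learners: Sequence[LearnerSpec] | None = None,
    k: int | None = None,
    n_samples: int = 5000,
    burn_in: int = 1000,
    seed: int = 0,
) -> EnsembleModel:
    """Train the full stacked model: folds, level-1 data, posteriors, full fits.

    Each response variable gets its own independent posterior over ensemble
    parameters; the base learners are fitted per response on the full data.
    """
    if learners is None:
        learners = default_learners()
    if k is None:
        k = default_fold_count(data.n_instances)
    folds = make_folds(data.n_instances, k, derive_seed(seed, "folds"))
    if data.n_responses > 1:
        # responses are modelled as independent per-response ensembles
        return MultiResponseEnsemble.fit(data, learners, folds, n_samples, burn_in, seed)

    lvl1 = build_level1(data, folds, learners, response_index=0, seed=seed)
    surviving = [s for s in learners if s.enabled and s.name in lvl1.learner_names]
    coll = fit_full(data, surviving, response_index=0, seed=seed)
    if coll.names != lvl1.learner_names:
        # align level-1 columns with whatever survived the full fit
        keep = [lvl1.learner_names.index(n) for n in coll.names]
        lvl1 = Level1Data(lvl1.z[:, keep], lvl1.y, coll.names, folds)
    post = sample_posterior(
        lvl1, n_samples=n_samples, burn_in=burn_in, seed=derive_seed(seed, "mcmc", 0)
    )
    return EnsembleModel(
        learners=coll,
        posteriors=[post],
        level1=[lvl1],
        feature_names=list(data.feature_names),
        response_names=list(data.response_names),
        seed=seed,
        training_inputs=data.inputs.copy(),
        training_responses=data.responses.copy(),
    )


class MultiResponseEnsemble(EnsembleModel):
    """Independent per-response ensembles sharing features and folds."""

    def __init__(self, per_response: list[EnsembleModel], feature_names, response_names,
                 seed, training_inputs, training_responses):
        self._per_response = per_response
        self.learners = per_response[0].learners
        self.posteriors = [m.posteriors[0] for m in per_response]
        self.level1 = [m.level1[0] for m in per_response]
        self.feature_names = feature_names
        self.response_names = response_names
        self.seed = seed
        self.training_inputs = training_inputs
        self.training_responses = training_responses

    @classmethod
    def fit(cls, data, learners, folds, n_samples, burn_in, seed):
        models = []
        for r in range(data.n_responses):
            sub = TrainingSet(
                inputs=data.inputs,
                responses=data.responses[:, [r]],
                feature_names=list(data.feature_names),
                response_names=[data.response_names[r]],
                instance_ids=list(data.instance_ids),
            )
            # seed keyed by response name so permuting columns permutes results
            models.append(
                fit_ensemble(sub, learners, folds.k, n_samples, burn_in,
                             derive_seed(seed, "response", data.response_names[r]))
            )
        return cls(models, list(data.feature_names), list(data.response_names), seed,
                   data.inputs.copy(), data.responses.copy())

    def predict(self, x_star, response_index: int = 0):
        return self._per_response[response_index].predict(x_star, 0)

    def predict_moments(self, X, response_index: int = 0):
        return self._per_response[response_index].predict_moments(X, 0)


def cv_posteriors(
    level1: Level1Data,
    n_samples: int = 2000,
    burn_in: int = 500,
    seed: int = 0,
) -> dict[int, PosteriorSamples]:
    """One posterior per fold, each fitted with that fold's rows held out."""
    out = {}
    for fold in range(1, level1.fold_partition.k + 1):
        idx = level1.fold_partition.complement_indices(fold)
        out[fold] = sample_posterior(
            level1.subset(idx), n_samples, burn_in, derive_seed(seed, "cvpost", fold)
        )
    return out


def cv_metrics(
    level1: Level1Data,
    posterior_by_fold: dict[int, PosteriorSamples] | None = None,
    seed: int = 0,
    ci_level: float = 0.95,
    intervals: bool = True,
) -> dict:
    """Cross-validated fit metrics of the metalearner.

    For each instance, the predictive distribution combines its out-of-fold
    base predictions with a posterior fitted without its fold. R^2 and MAE
    use the cross-validated predictive means only; per-instance credible
    intervals come from the predictive quantiles (skip with
    ``intervals=False`` when only the scalar metrics are needed).
    """
    if posterior_by_fold is None:
        posterior_by_fold = cv_posteriors(level1, seed=seed)
    n = level1.n
    means = np.empty(n)
    lower = np.full(n, np.nan)
    upper = np.full(n, np.nan)
    for fold, post in posterior_by_fold.items():
        idx = level1.fold_partition.fold_indices(fold)
        for i in idx:
            pred = PredictiveDistribution(post.weights @ level1.z[i], post.sigmas)
            means[i] = pred.mean
            if intervals:
                lower[i], upper[i] = pred.credible_interval(ci_level)
    resid = level1.y - means
    mae = float(np.abs(resid).mean())
    ss_tot = float(((level1.y - level1.y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        warnings.warn("response has zero variance; R^2 undefined", stacklevel=2)
        r2 = float("nan")
    else:
        r2 = 1.0 - float((resid**2).sum()) / ss_tot
    return {"r2": r2, "mae": mae, "mean": means, "lower": lower, "upper": upper}


def success_probability(
    predictions: Sequence[PredictiveDistribution],
    objective,
    best_observed: float,
    n_draws: int = 100_000,
    seed: int = 0,
    tolerance: float | None = None,
) -> float:
    """P(at least one recommendation achieves the objective), by Monte Carlo.

    Recommendations are treated as independent: each prediction's single-shot
    success probability is estimated from draws of its predictive posterior,
    then combined as 1 - prod(1 - p_i). For the specification objective a
    recommendation succeeds when |y - y*| <= tolerance.
    """
    predictions = list(predictions)
    if not predictions:
        raise ArgumentError("at least one prediction is required")
    mode = objective.mode
    rng = np.random.default_rng(seed)
    log_fail = 0.0
    for pred in predictions:
        ys = pred.sample(n_draws, rng)
        if mode == "maximize":
            p = float((ys > best_observed).mean())
        elif mode == "minimize":
            p = float((ys < best_observed).mean())
        elif mode == "specification":
            tol = tolerance if tolerance is not None else objective.success_tolerance
            if tol is None:
                raise ConfigurationError("specification mode needs a success tolerance")
            p = float((np.abs(ys - objective.target) <= tol).mean())
        else:
            raise ConfigurationError(f"unknown objective mode {mode!r}")
        if p >= 1.0:
            return 1.0
        log_fail += math.log1p(-p)
    return float(1.0 - math.exp(log_fail))


def n_required(p_single: float, p_target: float) -> int:
    """Smallest n with 1 - (1 - p_single)^n >= p_target, assuming independence."""
    if not 0.0 <= p_single <= 1.0 or not 0.0 < p_target < 1.0:
        raise ArgumentError("probabilities out of range")
    if p_single == 0.0:
        raise InfeasibleError("single-attempt success probability is zero")
    if p_single == 1.0:
        return 1
    n = math.log1p(-p_target) / math.log1p(-p_single)
    return max(1, math.ceil(n - 1e-12))


__all__ = [
    "EnsembleParams",
    "PosteriorSamples",
    "PredictiveDistribution",
    "EnsembleModel",
    "log_posterior",
    "sample_posterior",
    "fit_ensemble",
    "cv_posteriors",
    "cv_metrics",
    "success_probability",
    "n_required",
]
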