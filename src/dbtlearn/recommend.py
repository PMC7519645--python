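"""Batch recommendation: surrogate objective, tempered sampling, diversity.

Given a trained ensemble, the next experiments are chosen by optimizing the
upper-confidence-bound style surrogate

    G(x) =  (1 - alpha) E(y) + alpha Var(y)^(1/2)        (maximize)
           -(1 - alpha) E(y) + alpha Var(y)^(1/2)        (minimize)
           -(1 - alpha) ||E(y) - y*||_2^2 + alpha Var(y)^(1/2)   (specification)

with alpha in [0, 1] trading exploitation (predicted response) against
exploration (predictive uncertainty). Rather than a point optimizer, the
engine samples the target density pi(x) ∝ exp(G(x)) p(x), p(x) uniform on
the bounded box B, with parallel tempering so multimodal surrogates are
explored globally; recommendations are then greedily selected from the
temperature-1 draws in decreasing G order under a gamma-diversity rule: a
draw is accepted only if at least one feature differs by a relative factor
of at least gamma from that feature's value in every training instance and
every previously accepted recommendation.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

from ._utils import derive_seed
from .datasets import TrainingSet
from .ensemble import EnsembleModel, PredictiveDistribution, success_probability
from .exceptions import (
    ArgumentError,
    BoundsDegeneracyError,
    ConfigurationError,
    SamplerFailureError,
)

logger = logging.getLogger(__name__)

GAMMA_FLOOR = 0.01
MAX_GAMMA_DECAYS = 5


@dataclass
class InputBounds:
    """Per-feature lower/upper bounds defining the search box B."""

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        self.lower = np.atleast_1d(np.asarray(self.lower, dtype=float))
        self.upper = np.atleast_1d(np.asarray(self.upper, dtype=float))
        if self.lower.shape != self.upper.shape:
            raise ArgumentError("lower and upper must have equal length")
        if not (self.lower < self.upper).all():
            raise ArgumentError("need lower < upper for every feature")

    @property
    def dim(self) -> int:
        return len(self.lower)

    @property
    def range(self) -> np.ndarray:
        return self.upper - self.lower

    def contains(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        return ((X >= self.lower) & (X <= self.upper)).all(axis=1)


def default_bounds(data: TrainingSet, margin: float = 0.0) -> InputBounds:
    """Bounds from the data: [min - margin*range, max + margin*range] per feature."""
    lo = data.inputs.min(axis=0)
    hi = data.inputs.max(axis=0)
    rng = hi - lo
    degenerate = np.flatnonzero(rng == 0)
    if degenerate.size and margin == 0.0:
        names = [data.feature_names[i] for i in degenerate]
        raise BoundsDegeneracyError(
            f"feature(s) {names} are constant; provide bounds or a positive margin"
        )
    if degenerate.size:
        # widen zero-range features by the margin relative to |value| (or 1)
        base = np.where(np.abs(lo) > 0, np.abs(lo), 1.0)
        rng = np.where(rng == 0, base, rng)
    return InputBounds(lo - margin * rng, hi + margin * rng)


@dataclass
class ObjectiveConfig:
    """What to optimize and how: mode, exploration weight, diversity, batch."""

    mode: str = "maximize"
    alpha: float = 0.0
    target: float | np.ndarray | None = None
    gamma: float = 0.2
    batch_size: int = 16
    bounds: InputBounds | None = None
    success_tolerance: float | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("maximize", "minimize", "specification"):
            raise ConfigurationError(f"unknown objective mode {self.mode!r}")
        if not 0.0 <= self.alpha <= 1.0:
            raise ConfigurationError("alpha must be in [0, 1]")
        if not 0.0 < self.gamma < 1.0:
            raise ConfigurationError("gamma must be in (0, 1)")
        if self.batch_size < 1:
            raise ConfigurationError("batch_size must be >= 1")
        if (self.mode == "specification") != (self.target is not None):
            raise ConfigurationError("target y* must be given iff mode is 'specification'")


def surrogate_values(
    X: np.ndarray, model: EnsembleModel, objective: ObjectiveConfig
) -> np.ndarray:
    """Vectorized surrogate G over a batch of inputs (n x D)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    alpha = objective.alpha
    if objective.mode == "specification":
        targets = np.atleast_1d(np.asarray(objective.target, dtype=float))
        if len(targets) != model.n_responses:
            raise ConfigurationError(
                "specification target must give one value per response"
            )
        sq_dist = np.zeros(len(X))
        var_sum = np.zeros(len(X))
        for r in range(model.n_responses):
            mean, var = model.predict_moments(X, r)
            sq_dist += (mean - targets[r]) ** 2
            var_sum += var
        return -(1.0 - alpha) * sq_dist + alpha * np.sqrt(var_sum)
    mean, var = model.predict_moments(X, 0)
    sd = np.sqrt(var)
    if objective.mode == "maximize":
        return (1.0 - alpha) * mean + alpha * sd
    return -(1.0 - alpha) * mean + alpha * sd


def surrogate_G(x: np.ndarray, model: EnsembleModel, objective: ObjectiveConfig) -> float:
    """Surrogate objective at a single input."""
    return float(surrogate_values(np.asarray(x, dtype=float)[None, :], model, objective)[0])


@dataclass
class TemperingLadder:
    """Temperatures for parallel tempering: strictly increasing, lowest = 1."""

    temperatures: np.ndarray = field(
        default_factory=lambda: np.geomspace(1.0, 25.0, 5)
    )

    def __post_init__(self) -> None:
        t = np.asarray(self.temperatures, dtype=float)
        if t[0] != 1.0 or (np.diff(t) <= 0).any():
            raise ArgumentError("temperatures must start at 1 and strictly increase")
        self.temperatures = t

    @property
    def n_chains(self) -> int:
        return len(self.temperatures)


def _reflect(X: np.ndarray, lower: np.ndarray, upper: np.ndarray) -> np.ndarray:
    """Reflect coordinates into [lower, upper] (periodic fold of width 2*range)."""
    rng = upper - lower
    t = np.mod(X - lower, 2.0 * rng)
    return lower + np.where(t <= rng, t, 2.0 * rng - t)


def sample_pi(
    model: EnsembleModel,
    objective: ObjectiveConfig,
    n_draws: int = 10_000,
    burn_in: int = 1_000,
    ladder: TemperingLadder | None = None,
    seed: int = 0,
    step_fraction: float = 0.1,
    swap_every: int = 10,
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Sample pi(x) ∝ exp(G(x)) on the bounds box by parallel tempering.

    Returns the temperature-1 draws (one per post-burn-in sweep), their G
    values, and sampler diagnostics. Each sweep updates every chain with a
    reflected Gaussian random walk; adjacent chains attempt a state swap
    every ``swap_every`` sweeps.
    """
    if objective.bounds is None:
        raise ConfigurationError("objective.bounds must be set for sampling")
    bounds = objective.bounds
    ladder = ladder or TemperingLadder()
    rng = np.random.default_rng(seed)
    temps = ladder.temperatures
    betas = 1.0 / temps
    c = ladder.n_chains
    d = bounds.dim
    step = step_fraction * bounds.range  # per-dimension proposal SD

    states = bounds.lower + rng.random((c, d)) * bounds.range
    g = surrogate_values(states, model, objective)
    n_sweeps = burn_in + n_draws
    draws = np.empty((n_draws, d))
    g_draws = np.empty(n_draws)
    accepted = np.zeros(c)
    swaps_tried = 0
    swaps_accepted = 0
    for sweep in range(n_sweeps):
        props = _reflect(states + rng.standard_normal((c, d)) * step,
                         bounds.lower, bounds.upper)
        g_props = surrogate_values(props, model, objective)
        log_u = np.log(rng.random(c))
        accept = log_u < betas * (g_props - g)
        states[accept] = props[accept]
        g[accept] = g_props[accept]
        accepted += accept
        if (sweep + 1) % swap_every == 0:
            for i in range(c - 1):
                swaps_tried += 1
                log_r = (betas[i] - betas[i + 1]) * (g[i + 1] - g[i])
                if math.log(rng.random()) < log_r:
                    states[[i, i + 1]] = states[[i + 1, i]]
                    g[[i, i + 1]] = g[[i + 1, i]]
                    swaps_accepted += 1
        if sweep >= burn_in:
            j = sweep - burn_in
            draws[j] = states[0]
            g_draws[j] = g[0]
    rates = accepted / n_sweeps
    if (rates < 0.01).all():
        raise SamplerFailureError(
            f"all tempering chains stuck (acceptance rates {rates.round(4)})"
        )
    diagnostics = {
        "acceptance_rates": rates,
        "swap_rate": swaps_accepted / max(swaps_tried, 1),
        "temperatures": temps,
        "seed": seed,
        "top_draw": draws[int(np.argmax(g_draws))],
    }
    return draws, g_draws, diagnostics


def relative_differences(
    x: np.ndarray, refs: np.ndarray, bounds: InputBounds
) -> np.ndarray:
    """|x_f - ref_f| / max(|ref_f|, 0.01 * range_f) for every (ref, feature).

    The floor keeps the denominator positive when a reference coordinate
    is zero. Returns an (n_refs x D) matrix.
    """
    refs = np.atleast_2d(refs)
    denom = np.maximum(np.abs(refs), 0.01 * bounds.range)
    return np.abs(x - refs) / denom


def _is_diverse(x: np.ndarray, refs: np.ndarray, gamma: float, bounds: InputBounds) -> bool:
    """True iff some feature differs by >= gamma from every reference point."""
    if len(refs) == 0:
        return True
    rel = relative_differences(x, refs, bounds)
    return bool((rel.min(axis=0) >= gamma).any())


@dataclass
class RecommendationBatch:
    """Selected inputs with surrogate values and (optionally) predictions."""

    inputs: np.ndarray
    surrogate_values: np.ndarray
    gamma_used: float
    predictions: list[PredictiveDistribution] = field(default_factory=list)
    success_prob: float | None = None
    incomplete: bool = False
    diagnostics: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.inputs)


def select_recommendations(
    draws: np.ndarray,
    g_values: np.ndarray,
    data: TrainingSet | None,
    objective: ObjectiveConfig,
) -> RecommendationBatch:
    """Greedy diverse selection from sampled inputs in decreasing G order.

    Scans draws from best to worst surrogate value; accepts a draw when the
    gamma rule holds against all training inputs and all previously accepted
    recommendations. If the scan ends short of the batch size, gamma is
    halved (down to a floor) and the scan restarts; a batch that is still
    short is returned with ``incomplete=True``.
    """
    draws = np.atleast_2d(np.asarray(draws, dtype=float))
    g_values = np.asarray(g_values, dtype=float)
    if len(draws) == 0:
        raise ArgumentError("draws must be non-empty")
    bounds = objective.bounds
    if bounds is None:
        if data is None:
            raise ConfigurationError("need bounds or training data for the gamma rule")
        bounds = default_bounds(data, margin=0.0)
    train = data.inputs if data is not None else np.empty((0, draws.shape[1]))
    order = np.argsort(-g_values, kind="stable")  # ties broken by draw index

    gamma = objective.gamma
    chosen: list[int] = []
    for decay in range(MAX_GAMMA_DECAYS + 1):
        chosen = []
        refs = train
        for idx in order:
            if _is_diverse(draws[idx], refs, gamma, bounds):
                chosen.append(idx)
                refs = np.vstack([refs, draws[idx][None, :]])
                if len(chosen) == objective.batch_size:
                    break
        if len(chosen) == objective.batch_size:
            break
        new_gamma = max(gamma / 2.0, GAMMA_FLOOR)
        if new_gamma == gamma:
            break
        logger.info("gamma decay: %.4g -> %.4g (batch %d/%d)",
                    gamma, new_gamma, len(chosen), objective.batch_size)
        gamma = new_gamma
    incomplete = len(chosen) < objective.batch_size
    if incomplete:
        warnings.warn(
            f"could only select {len(chosen)}/{objective.batch_size} diverse "
            f"recommendations (gamma floor {gamma})",
            stacklevel=2,
        )
    chosen_arr = np.asarray(chosen, dtype=int)
    return RecommendationBatch(
        inputs=draws[chosen_arr],
        surrogate_values=g_values[chosen_arr],
        gamma_used=gamma,
        incomplete=incomplete,
    )


def recommend(
    model: EnsembleModel,
    data: TrainingSet,
    objective: ObjectiveConfig,
    seed: int = 0,
    n_draws: int = 10_000,
    burn_in: int = 1_000,
    ladder: TemperingLadder | None = None,
    response_index: int = 0,
    success_draws: int = 20_000,
) -> RecommendationBatch:
    """End-to-end recommendation: sample pi, select a diverse batch, attach
    predictive distributions and the batch success probability."""
    if objective.bounds is None:
        objective = ObjectiveConfig(
            mode=objective.mode,
            alpha=objective.alpha,
            target=objective.target,
            gamma=objective.gamma,
            batch_size=objective.batch_size,
            bounds=default_bounds(data, margin=0.0),
            success_tolerance=objective.success_tolerance,
        )
    draws, g_vals, diagnostics = sample_pi(
        model, objective, n_draws=n_draws, burn_in=burn_in, ladder=ladder,
        seed=derive_seed(seed, "pi"),
    )
    batch = select_recommendations(draws, g_vals, data, objective)
    batch.diagnostics = diagnostics
    batch.predictions = [model.predict(x, response_index) for x in batch.inputs]
    if len(batch.predictions):
        y = data.response(response_index)
        best = float(y.max() if objective.mode != "minimize" else y.min())
        tol = objective.success_tolerance
        if objective.mode == "specification" and tol is None:
            # default tolerance: 5% of the observed response range
            span = float(y.max() - y.min()) or 1.0
            tol = 0.05 * span
        batch.success_prob = success_probability(
            batch.predictions, objective, best,
            n_draws=success_draws, seed=derive_seed(seed, "success"), tolerance=tol,
        )
    return batch


__all__ = [
    "InputBounds",
    "ObjectiveConfig",
    "TemperingLadder",
    "RecommendationBatch",
    "default_bounds",
    "surrogate_G",
    "surrogate_values",
    "sample_pi",
    "select_recommendations",
    "relative_differences",
    "recommend",
]
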