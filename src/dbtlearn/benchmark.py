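"""Synthetic landscapes and the simulated Design-Build-Test-Learn loop.

Three test functions of increasing learning difficulty stand in for a real
production response (e.g. titer as a function of pathway protein levels):

* ``FE`` ("easy"):   F(x) = -(1/d) sum_i (x_i - 5)^2 + exp(-sum_i x_i^2) + 25,
  a smooth quadratic bowl (maximum 25 near x_i = 5) with a small narrow bump
  at the origin; default box [0, 10]^d.
* ``FM`` ("medium"): F(x) = (1/d) sum_i (x_i^4 - 16 x_i^2 + 5 x_i), the
  classical multi-minimum quartic landscape; default box [-5, 5]^d.
* ``FD`` ("difficult"): F(x) = sum_i sqrt(x_i) sin(x_i), highly multimodal,
  defined for x_i >= 0; default box [0, 10]^d.

The simulator emulates a DBTL campaign: a Latin-hypercube initial design is
"built and tested" by evaluating the landscape, then each cycle trains the
ensemble, asks for a batch of recommendations at a scheduled exploration
weight alpha (tempered from 0.9 down to 0), evaluates the landscape at the
recommended inputs, appends them to the training set and records metrics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.stats import qmc

from ._utils import derive_seed
from .datasets import TrainingSet
from .ensemble import cv_metrics, fit_ensemble
from .exceptions import ArgumentError
from .learners import LearnerSpec, fast_learners
from .recommend import InputBounds, ObjectiveConfig, recommend

logger = logging.getLogger(__name__)


def _f_easy(X: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    return -np.sum((X - 5.0) ** 2, axis=1) / d + np.exp(-np.sum(X**2, axis=1)) + 25.0


def _f_medium(X: np.ndarray) -> np.ndarray:
    d = X.shape[1]
    return np.sum(X**4 - 16.0 * X**2 + 5.0 * X, axis=1) / d


def _f_difficult(X: np.ndarray) -> np.ndarray:
    if (X < 0).any():
        raise ArgumentError("the difficult landscape requires x_i >= 0 (sqrt)")
    return np.sum(np.sqrt(X) * np.sin(X), axis=1)


LANDSCAPES: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "FE": _f_easy,
    "FM": _f_medium,
    "FD": _f_difficult,
}

_DEFAULT_BOX = {"FE": (0.0, 10.0), "FM": (-5.0, 5.0), "FD": (0.0, 10.0)}


@dataclass
class BenchmarkProblem:
    """A synthetic optimization landscape with bounds and optional noise."""

    landscape: str
    dim: int = 2
    bounds: InputBounds | None = None
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.landscape not in LANDSCAPES:
            raise ArgumentError(f"unknown landscape {self.landscape!r}; use FE, FM or FD")
        if self.dim < 1:
            raise ArgumentError("dimension must be >= 1")
        if self.noise_sd < 0:
            raise ArgumentError("noise SD must be non-negative")
        if self.bounds is None:
            lo, hi = _DEFAULT_BOX[self.landscape]
            self.bounds = InputBounds(np.full(self.dim, lo), np.full(self.dim, hi))
        if self.landscape == "FD" and (self.bounds.lower < 0).any():
            raise ArgumentError("the difficult landscape needs non-negative lower bounds")

    def evaluate(self, X: np.ndarray, seed: int | None = None) -> np.ndarray:
        """Landscape value at each row of X, plus Gaussian noise if configured."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.dim:
            raise ArgumentError(f"inputs must have dimension {self.dim}")
        y = LANDSCAPES[self.landscape](X)
        if self.noise_sd > 0:
            rng = np.random.default_rng(seed)
            y = y + rng.normal(0.0, self.noise_sd, size=len(y))
        return y

    def grid_optimum(self, points_per_dim: int = 1000) -> float:
        """Brute-force maximum over a regular grid (practical for dim <= 2)."""
        axes = [
            np.linspace(self.bounds.lower[i], self.bounds.upper[i], points_per_dim)
            for i in range(self.dim)
        ]
        mesh = np.meshgrid(*axes, indexing="ij")
        X = np.column_stack([m.ravel() for m in mesh])
        return float(LANDSCAPES[self.landscape](X).max())


def evaluate_landscape(problem: BenchmarkProblem, x: np.ndarray, seed: int | None = None):
    """Convenience scalar/batch evaluation of a benchmark landscape."""
    x = np.asarray(x, dtype=float)
    if x.ndim == 1:
        return float(problem.evaluate(x[None, :], seed)[0])
    return problem.evaluate(x, seed)


def latin_hypercube(n: int, bounds: InputBounds, seed: int = 0) -> np.ndarray:
    """Space-filling design: one sample per equal-width interval per dimension."""
    if n < 1:
        raise ArgumentError("need n >= 1")
    sampler = qmc.LatinHypercube(d=bounds.dim, seed=seed)
    unit = sampler.random(n)
    return qmc.scale(unit, bounds.lower, bounds.upper)


def alpha_schedule(
    n_cycles: int, alpha_start: float = 0.9, alpha_end: float = 0.0
) -> np.ndarray:
    """Linear exploration-weight tempering from alpha_start down to alpha_end."""
    if n_cycles < 1:
        raise ArgumentError("need at least one cycle")
    for a in (alpha_start, alpha_end):
        if not 0.0 <= a <= 1.0:
            raise ArgumentError("alpha endpoints must lie in [0, 1]")
    if n_cycles == 1:
        return np.array([alpha_end])
    return np.linspace(alpha_start, alpha_end, n_cycles)


@dataclass
class CycleRecord:
    cycle: int
    training_size: int
    best_so_far: float
    top_sd: float
    mae_train_cv: float
    mae_test: float
    alpha: float


@dataclass
class DbtlHistory:
    """Per-cycle metrics of one simulated DBTL run."""

    records: list[CycleRecord]
    seed: int
    completed: bool = True

    def __post_init__(self) -> None:
        best = [r.best_so_far for r in self.records]
        if any(b2 < b1 for b1, b2 in zip(best, best[1:])):
            raise ArgumentError("best-so-far must be non-decreasing")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.records])
        df["seed"] = self.seed
        return df


def _training_set_from(problem: BenchmarkProblem, X: np.ndarray, y: np.ndarray) -> TrainingSet:
    return TrainingSet(
        inputs=X,
        responses=y[:, None],
        feature_names=[f"x{i + 1}" for i in range(problem.dim)],
        response_names=["response"],
    )


def simulate_dbtl(
    problem: BenchmarkProblem,
    n_cycles: int = 10,
    n_init: int = 16,
    batch: int = 16,
    seed: int = 0,
    learners: Sequence[LearnerSpec] | None = None,
    n_samples: int = 2000,
    burn_in: int = 500,
    pi_draws: int = 2000,
    pi_burn: int = 400,
    probe_size: int = 100,
    alpha_start: float = 0.9,
    alpha_end: float = 0.0,
    gamma: float = 0.2,
    compute_cv_mae: bool = True,
) -> DbtlHistory:
    """Simulate a DBTL campaign on a synthetic landscape (maximization).

    Cycle 0 "builds" an n_init-point Latin-hypercube design; each cycle then
    trains the ensemble on all data so far, recommends ``batch`` inputs at
    the scheduled alpha, evaluates the true landscape there and appends the
    results. Test MAE is measured on a fresh held-out probe design that is
    never added to training. A cycle failure aborts the run and returns the
    partial history.
    """
    if learners is None:
        learners = fast_learners()
    alphas = alpha_schedule(n_cycles, alpha_start, alpha_end)
    X = latin_hypercube(n_init, problem.bounds, derive_seed(seed, "init"))
    y = problem.evaluate(X, derive_seed(seed, "noise", 0))
    probe_X = latin_hypercube(probe_size, problem.bounds, derive_seed(seed, "probe"))
    probe_y = problem.evaluate(probe_X)  # noise-free ground truth

    records: list[CycleRecord] = []
    completed = True
    for cycle in range(1, n_cycles + 1):
        data = _training_set_from(problem, X, y)
        try:
            model = fit_ensemble(
                data, learners=learners, n_samples=n_samples, burn_in=burn_in,
                seed=derive_seed(seed, "cycle", cycle),
            )
            if compute_cv_mae:
                mae_train = cv_metrics(
                    model.level1[0],
                    seed=derive_seed(seed, "cvm", cycle),
                    intervals=False,
                )["mae"]
            else:
                mae_train = float("nan")
            probe_mean, _ = model.predict_moments(probe_X)
            mae_test = float(np.abs(probe_mean - probe_y).mean())
            objective = ObjectiveConfig(
                mode="maximize", alpha=float(alphas[cycle - 1]), gamma=gamma,
                batch_size=batch, bounds=problem.bounds,
            )
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")  # partial batches are recorded below
                rec = recommend(
                    model, data, objective, seed=derive_seed(seed, "rec", cycle),
                    n_draws=pi_draws, burn_in=pi_burn, success_draws=4000,
                )
            if rec.predictions:
                top_sd = rec.predictions[0].sd
            else:
                # diversity exhausted: report uncertainty at the best sampled input
                top_draw = rec.diagnostics.get("top_draw")
                top_sd = model.predict(top_draw).sd if top_draw is not None else float("nan")
        except Exception as exc:  # noqa: BLE001 - return partial history
            logger.warning("cycle %d failed: %s", cycle, exc)
            completed = False
            break
        if len(rec.inputs):
            new_y = problem.evaluate(rec.inputs, derive_seed(seed, "noise", cycle))
            X = np.vstack([X, rec.inputs])
            y = np.concatenate([y, new_y])
        records.append(
            CycleRecord(
                cycle=cycle,
                training_size=len(y),
                best_so_far=float(y.max()),
                top_sd=top_sd,
                mae_train_cv=mae_train,
                mae_test=mae_test,
                alpha=float(alphas[cycle - 1]),
            )
        )
    return DbtlHistory(records=records, seed=seed, completed=completed)


def repeated_runs(
    problem: BenchmarkProblem,
    n_cycles: int = 10,
    n_runs: int = 10,
    seed: int = 0,
    **kwargs,
) -> pd.DataFrame:
    """Aggregate simulate_dbtl over repeated runs: per-cycle mean and 95% CI.

    The confidence interval uses the t distribution over runs. Returns a tidy
    frame with columns (cycle, metric, mean, ci_low, ci_high, n_runs).
    """
    if n_runs < 2:
        raise ArgumentError("need at least two runs to form a confidence interval")
    frames = []
    for run in range(n_runs):
        hist = simulate_dbtl(problem, n_cycles=n_cycles,
                             seed=derive_seed(seed, "run", run), **kwargs)
        df = hist.to_frame()
        df["run"] = run
        frames.append(df)
    tidy = pd.concat(frames, ignore_index=True)
    metrics = ["best_so_far", "top_sd", "mae_train_cv", "mae_test", "training_size"]
    rows = []
    for cycle, grp in tidy.groupby("cycle"):
        for metric in metrics:
            vals = grp[metric].to_numpy(dtype=float)
            mean = float(np.mean(vals))
            if len(vals) > 1 and np.std(vals, ddof=1) > 0:
                half = float(
                    stats.t.ppf(0.975, len(vals) - 1) * np.std(vals, ddof=1) / np.sqrt(len(vals))
                )
            else:
                half = 0.0
            rows.append(
                {"cycle": int(cycle), "metric": metric, "mean": mean,
                 "ci_low": mean - half, "ci_high": mean + half, "n_runs": len(vals)}
            )
    return pd.DataFrame(rows)


__all__ = [
    "BenchmarkProblem",
    "DbtlHistory",
    "CycleRecord",
    "LANDSCAPES",
    "evaluate_landscape",
    "latin_hypercube",
    "alpha_schedule",
    "simulate_dbtl",
    "repeated_runs",
]
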