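"""Level-0 base learners: registry, per-fold fitting, level-1 data assembly.

The ensemble is heterogeneous: a fixed set of regression families with
reasonable (not tuned) hyperparameters. The default registry lists eight
families; the automated pipeline-search slot ships disabled because its
search backend is a heavyweight optional plug-in — the ensemble mathematics
never depends on the exact number of surviving learners (M >= 2 suffices).

Scale-sensitive families are wrapped in a standardization pipeline whose
scaler is fitted on the same partition as the learner, so no information
leaks across cross-validation folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from sklearn.ensemble import GradientBoostingRegressor, RandomForestRegressor
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import RBF, ConstantKernel, WhiteKernel
from sklearn.kernel_ridge import KernelRidge
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR

from ._utils import derive_seed
from .datasets import FoldPartition, TrainingSet
from .exceptions import ArgumentError, NumericalError

logger = logging.getLogger(__name__)

FAMILIES = (
    "random_forest",
    "neural_net",
    "support_vector",
    "kernel_ridge",
    "k_neighbors",
    "gaussian_process",
    "gradient_boosting",
    "auto_pipeline_search",
)

# families whose estimators assume roughly unit-scale inputs
_SCALED_FAMILIES = {
    "neural_net",
    "support_vector",
    "kernel_ridge",
    "k_neighbors",
    "gaussian_process",
}

# hook for plugging in an automated pipeline-search backend:
# a callable (hyperparameters, n_train, seed) -> sklearn estimator
AUTO_PIPELINE_BUILDER: Callable | None = None


@dataclass
class LearnerSpec:
    """One base learner: a family from the registry plus hyperparameter overrides."""

    name: str
    family: str
    hyperparameters: dict = field(default_factory=dict)
    enabled: bool = True

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ArgumentError(f"unknown learner family {self.family!r}")


def default_learners() -> list[LearnerSpec]:
    """The default registry of eight base-learner families.

    The automated pipeline-search learner is listed but disabled by default;
    enable it by setting ``enabled=True`` after registering a builder via
    :data:`AUTO_PIPELINE_BUILDER`.
    """
    return [
        LearnerSpec("random_forest", "random_forest"),
        LearnerSpec("neural_net", "neural_net"),
        LearnerSpec("support_vector", "support_vector"),
        LearnerSpec("kernel_ridge", "kernel_ridge"),
        LearnerSpec("k_neighbors", "k_neighbors"),
        LearnerSpec("gaussian_process", "gaussian_process"),
        LearnerSpec("gradient_boosting", "gradient_boosting"),
        LearnerSpec("auto_pipeline_search", "auto_pipeline_search", enabled=False),
    ]


def fast_learners() -> list[LearnerSpec]:
    """A lean subset for desk-scale simulations: cheap to refit many times."""
    return [
        LearnerSpec("random_forest", "random_forest", {"n_estimators": 30}),
        LearnerSpec("k_neighbors", "k_neighbors"),
        LearnerSpec("kernel_ridge", "kernel_ridge"),
        LearnerSpec("gaussian_process", "gaussian_process", {"n_restarts_optimizer": 0}),
    ]


def _build_estimator(spec: LearnerSpec, n_train: int, seed: int):
    hp = dict(spec.hyperparameters)
    fam = spec.family
    if fam == "random_forest":
        est = RandomForestRegressor(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    elif fam == "neural_net":
        est = MLPRegressor(
            hidden_layer_sizes=hp.pop("hidden_layer_sizes", (50,)),
            max_iter=hp.pop("max_iter", 2000),
            solver=hp.pop("solver", "lbfgs"),
            alpha=hp.pop("alpha", 1e-2),
            random_state=seed,
            **hp,
        )
    elif fam == "support_vector":
        est = SVR(C=hp.pop("C", 10.0), gamma=hp.pop("gamma", "scale"), **hp)
    elif fam == "kernel_ridge":
        est = KernelRidge(kernel=hp.pop("kernel", "rbf"), alpha=hp.pop("alpha", 0.1), **hp)
    elif fam == "k_neighbors":
        k = min(hp.pop("n_neighbors", 5), max(1, n_train - 1))
        est = KNeighborsRegressor(n_neighbors=k, **hp)
    elif fam == "gaussian_process":
        kernel = hp.pop(
            "kernel", ConstantKernel(1.0) * RBF(1.0) + WhiteKernel(1e-3, (1e-8, 1e2))
        )
        est = GaussianProcessRegressor(
            kernel=kernel,
            normalize_y=True,
            n_restarts_optimizer=hp.pop("n_restarts_optimizer", 1),
            random_state=seed,
            **hp,
        )
    elif fam == "gradient_boosting":
        est = GradientBoostingRegressor(
            n_estimators=hp.pop("n_estimators", 100), random_state=seed, **hp
        )
    elif fam == "auto_pipeline_search":
        if AUTO_PIPELINE_BUILDER is None:
            raise NumericalError(
                "no automated pipeline-search backend registered "
                "(set dbtlearn.learners.AUTO_PIPELINE_BUILDER)"
            )
        est = AUTO_PIPELINE_BUILDER(hp, n_train, seed)
    else:  # pragma: no cover - guarded by LearnerSpec
        raise ArgumentError(f"unknown family {fam!r}")
    if fam in _SCALED_FAMILIES:
        est = make_pipeline(StandardScaler(), est)
    return est


def _fit_one(spec: LearnerSpec, X: np.ndarray, y: np.ndarray, seed: int):
    est = _build_estimator(spec, n_train=len(y), seed=seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # convergence chatter from small folds
        est.fit(X, y)
    return est


@dataclass
class LearnerCollection:
    """Fitted base learners with vectorized prediction f(x) = [f_1(x) ... f_M(x)]."""

    estimators: list
    names: list[str]

    @property
    def m(self) -> int:
        return len(self.estimators)

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Predict all learners on X (n x D); returns an (n x M) matrix."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        return np.column_stack([est.predict(X) for est in self.estimators])


@dataclass
class Level1Data:
    """Out-of-fold base-learner predictions z (N x M) paired with observed y."""

    z: np.ndarray
    y: np.ndarray
    learner_names: list[str]
    fold_partition: FoldPartition

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.z.shape != (len(self.y), len(self.learner_names)):
            raise ArgumentError("z must be N x M with matching labels")
        if not (np.isfinite(self.z).all() and np.isfinite(self.y).all()):
            raise NumericalError("level-1 data contain non-finite values")

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def m(self) -> int:
        return self.z.shape[1]

    def subset(self, idx: np.ndarray) -> "Level1Data":
        return Level1Data(
            self.z[idx], self.y[idx], list(self.learner_names), self.fold_partition
        )


def _enabled(learners: Sequence[LearnerSpec]) -> list[LearnerSpec]:
    specs = [s for s in learners if s.enabled]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ArgumentError("learner names must be unique")
    return specs


def build_level1(
    data: TrainingSet,
    folds: FoldPartition,
    learners: Sequence[LearnerSpec],
    response_index: int = 0,
    seed: int = 0,
) -> Level1Data:
    """Assemble level-1 data: out-of-fold predictions of every base learner.

    For each fold k, each learner is trained on the fold's complement and
    predicts the held-out fold, so z[n, m] never uses instance n's fold.
    A learner whose fit fails on any fold is dropped with a warning; at least
    two learners must survive.
    """
    if folds.n != data.n_instances:
        raise ArgumentError("fold partition does not match data size")
    y = data.response(response_index)
    specs = _enabled(learners)
    columns: dict[str, np.ndarray] = {s.name: np.full(data.n_instances, np.nan) for s in specs}
    failed: set[str] = set()
    for fold in range(1, folds.k + 1):
        train_idx = folds.complement_indices(fold)
        test_idx = folds.fold_indices(fold)
        X_tr, y_tr = data.inputs[train_idx], y[train_idx]
        for spec in specs:
            if spec.name in failed:
                continue
            try:
                est = _fit_one(
                    spec, X_tr, y_tr, derive_seed(seed, "learner", spec.name, "fold", fold)
                )
                columns[spec.name][test_idx] = est.predict(data.inputs[test_idx])
            except Exception as exc:  # noqa: BLE001 - any fit failure drops the learner
                failed.add(spec.name)
                logger.warning("dropping learner %s (fold %d failed: %s)", spec.name, fold, exc)
    surviving = [s.name for s in specs if s.name not in failed]
    if len(surviving) < 2:
        raise NumericalError(f"fewer than 2 base learners survived (got {surviving})")
    z = np.column_stack([columns[name] for name in surviving])
    return Level1Data(z=z, y=y, learner_names=surviving, fold_partition=folds)


def fit_full(
    data: TrainingSet,
    learners: Sequence[LearnerSpec],
    response_index: int = 0,
    seed: int = 0,
) -> LearnerCollection:
    """Fit every enabled learner on the full data set."""
    y = data.response(response_index)
    estimators, names = [], []
    for spec in _enabled(learners):
        try:
            est = _fit_one(spec, data.inputs, y, derive_seed(seed, "learner", spec.name, "full"))
        except Exception as exc:  # noqa: BLE001
            logger.warning("dropping learner %s (full fit failed: %s)", spec.name, exc)
            continue
        estimators.append(est)
        names.append(spec.name)
    if len(estimators) < 2:
        raise NumericalError("fewer than 2 base learners survived the full fit")
    return LearnerCollection(estimators=estimators, names=names)


__all__ = [
    "FAMILIES",
    "LearnerSpec",
    "LearnerCollection",
    "Level1Data",
    "default_learners",
    "fast_learners",
    "build_level1",
    "fit_full",
]
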