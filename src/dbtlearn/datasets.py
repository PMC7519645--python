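"""Training data containers, CSV import in two dialects, and K-fold partitions.

The training set is the "level-0" data of a stacked ensemble: N instances
(engineered strains, fermentation conditions, ...) each described by a
D-dimensional input vector (e.g. protein intensities) and R response values
(e.g. product titer in mg/L).

Two CSV dialects are supported:

* ``wide`` — one row per instance; first column is the instance id, remaining
  columns are features and responses.
* ``edd_long`` — long format in the style of Experiment Data Depot exports:
  one row per (line, measurement) with columns ``Line Name``,
  ``Measurement Type`` and ``Value``; extra columns are ignored with a warning.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .exceptions import (
    ArgumentError,
    ConfigurationError,
    DataCompletenessError,
    ParseError,
)

logger = logging.getLogger(__name__)

EDD_LINE_COL = "Line Name"
EDD_TYPE_COL = "Measurement Type"
EDD_VALUE_COL = "Value"


@dataclass
class TrainingSet:
    """Level-0 data: inputs X (N x D), responses Y (N x R), and labels.

    No missing values are permitted; features and responses are real-valued
    with caller-defined units.
    """

    inputs: np.ndarray
    responses: np.ndarray
    feature_names: list[str]
    response_names: list[str]
    instance_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.inputs = np.asarray(self.inputs, dtype=float)
        self.responses = np.asarray(self.responses, dtype=float)
        if self.inputs.ndim != 2 or self.responses.ndim != 2:
            raise ArgumentError("inputs and responses must be 2-D arrays")
        n, d = self.inputs.shape
        if n < 1 or d < 1 or self.responses.shape[1] < 1:
            raise ArgumentError("need N >= 1 instances, D >= 1 features, R >= 1 responses")
        if self.responses.shape[0] != n:
            raise ArgumentError("inputs and responses disagree on instance count")
        if len(self.feature_names) != d:
            raise ArgumentError("feature_names length must equal D")
        if len(self.response_names) != self.responses.shape[1]:
            raise ArgumentError("response_names length must equal R")
        if len(set(self.feature_names)) != d:
            raise ArgumentError("feature names must be unique")
        if len(set(self.response_names)) != len(self.response_names):
            raise ArgumentError("response names must be unique")
        if not self.instance_ids:
            self.instance_ids = [f"instance-{i}" for i in range(n)]
        if len(self.instance_ids) != n:
            raise ArgumentError("instance_ids length must equal N")
        if not (np.isfinite(self.inputs).all() and np.isfinite(self.responses).all()):
            raise DataCompletenessError("training data contain missing or non-finite values")

    @property
    def n_instances(self) -> int:
        return self.inputs.shape[0]

    @property
    def n_features(self) -> int:
        return self.inputs.shape[1]

    @property
    def n_responses(self) -> int:
        return self.responses.shape[1]

    def response(self, index: int = 0) -> np.ndarray:
        return self.responses[:, index]

    def to_frame(self) -> pd.DataFrame:
        """Wide-format frame: instance id, features, responses."""
        df = pd.DataFrame(self.inputs, columns=self.feature_names)
        for j, name in enumerate(self.response_names):
            df[name] = self.responses[:, j]
        df.insert(0, "line", self.instance_ids)
        return df

    def write_wide_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def append(self, inputs: np.ndarray, responses: np.ndarray,
               ids: Sequence[str] | None = None) -> "TrainingSet":
        """Return a new TrainingSet with extra instances appended."""
        inputs = np.atleast_2d(np.asarray(inputs, dtype=float))
        responses = np.atleast_2d(np.asarray(responses, dtype=float))
        if responses.shape[0] != inputs.shape[0]:
            responses = responses.reshape(inputs.shape[0], -1)
        if ids is None:
            start = self.n_instances
            ids = [f"instance-{start + i}" for i in range(inputs.shape[0])]
        return TrainingSet(
            inputs=np.vstack([self.inputs, inputs]),
            responses=np.vstack([self.responses, responses]),
            feature_names=list(self.feature_names),
            response_names=list(self.response_names),
            instance_ids=list(self.instance_ids) + list(ids),
        )


@dataclass(frozen=True)
class FoldPartition:
    """Assignment of N instances to K almost-equal folds (labels 1..K)."""

    k: int
    assignments: np.ndarray
    seed: int

    def __post_init__(self) -> None:
        a = np.asarray(self.assignments, dtype=int)
        object.__setattr__(self, "assignments", a)
        sizes = np.bincount(a, minlength=self.k + 1)[1:]
        if len(sizes) != self.k or (sizes == 0).any():
            raise ArgumentError("every fold must be non-empty")
        if sizes.max() - sizes.min() > 1:
            raise ArgumentError("fold sizes must differ by at most 1")

    @property
    def n(self) -> int:
        return len(self.assignments)

    def fold_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments == fold)

    def complement_indices(self, fold: int) -> np.ndarray:
        return np.flatnonzero(self.assignments != fold)


def default_fold_count(n: int) -> int:
    """K = 5, except leave-one-out when fewer than 10 instances."""
    return n if n < 10 else 5


def make_folds(n: int, k: int, seed: int) -> FoldPartition:
    """Randomly split N instances into K almost-equal disjoint folds."""
    if not (2 <= k <= n):
        raise ArgumentError(f"need 2 <= k <= n, got k={k}, n={n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    assignments = np.empty(n, dtype=int)
    # cycling 1..K over a random permutation keeps sizes within 1
    assignments[order] = (np.arange(n) % k) + 1
    return FoldPartition(k=k, assignments=assignments, seed=seed)


def _coerce_numeric(series: pd.Series, context: str) -> np.ndarray:
    values = pd.to_numeric(series, errors="coerce")
    bad = values.isna() & series.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"non-numeric value {series.iloc[row]!r} in {context} at data row {row + 1}"
        )
    return values.to_numpy(dtype=float)


def _from_wide_frame(df: pd.DataFrame, response_names: Sequence[str]) -> TrainingSet:
    id_col = df.columns[0]
    missing = [r for r in response_names if r not in df.columns[1:]]
    if missing:
        raise ConfigurationError(f"response column(s) not found: {missing}")
    feature_cols = sorted(c for c in df.columns[1:] if c not in set(response_names))
    if not feature_cols:
        raise ConfigurationError("no feature columns remain after removing responses")
    na_mask = df[feature_cols + list(response_names)].isna()
    if na_mask.to_numpy().any():
        rows, cols = np.nonzero(na_mask.to_numpy())
        inst = df[id_col].iloc[rows[0]]
        col = (feature_cols + list(response_names))[cols[0]]
        raise DataCompletenessError(f"instance {inst!r} is missing measurement {col!r}")
    inputs = np.column_stack([_coerce_numeric(df[c], f"column {c!r}") for c in feature_cols])
    responses = np.column_stack(
        [_coerce_numeric(df[c], f"column {c!r}") for c in response_names]
    )
    return TrainingSet(
        inputs=inputs,
        responses=responses,
        feature_names=feature_cols,
        response_names=list(response_names),
        instance_ids=[str(v) for v in df[id_col]],
    )


def _from_long_frame(
    df: pd.DataFrame, response_names: Sequence[str], merge_replicates: bool
) -> TrainingSet:
    required = [EDD_LINE_COL, EDD_TYPE_COL, EDD_VALUE_COL]
    missing_cols = [c for c in required if c not in df.columns]
    if missing_cols:
        raise ConfigurationError(f"long-format CSV lacks required column(s): {missing_cols}")
    extra = [c for c in df.columns if c not in required]
    if extra:
        logger.warning("ignoring extra columns in long-format CSV: %s", extra)
    df = df[required].copy()
    df[EDD_VALUE_COL] = _coerce_numeric(df[EDD_VALUE_COL], f"column {EDD_VALUE_COL!r}")

    measurements = sorted(df[EDD_TYPE_COL].unique())
    missing_resp = [r for r in response_names if r not in measurements]
    if missing_resp:
        raise ConfigurationError(f"response measurement(s) not found: {missing_resp}")

    if merge_replicates:
        df = (
            df.groupby([EDD_LINE_COL, EDD_TYPE_COL], as_index=False, sort=False)[EDD_VALUE_COL]
            .mean()
        )
    else:
        # replicate rows of the same (line, measurement) become separate
        # instances: line, line-rep2, line-rep3, ...
        rep = df.groupby([EDD_LINE_COL, EDD_TYPE_COL]).cumcount()
        if rep.max() > 0:
            suffix = rep.map(lambda r: "" if r == 0 else f"-rep{r + 1}")
            df = df.assign(**{EDD_LINE_COL: df[EDD_LINE_COL] + suffix})

    pivot = df.pivot_table(
        index=EDD_LINE_COL, columns=EDD_TYPE_COL, values=EDD_VALUE_COL, aggfunc="first"
    ).sort_index()
    if pivot.isna().to_numpy().any():
        rows, cols = np.nonzero(pivot.isna().to_numpy())
        raise DataCompletenessError(
            f"instance {pivot.index[rows[0]]!r} is missing measurement "
            f"{pivot.columns[cols[0]]!r}"
        )
    feature_cols = sorted(c for c in pivot.columns if c not in set(response_names))
    if not feature_cols:
        raise ConfigurationError("no feature measurements remain after removing responses")
    return TrainingSet(
        inputs=pivot[feature_cols].to_numpy(dtype=float),
        responses=pivot[list(response_names)].to_numpy(dtype=float),
        feature_names=feature_cols,
        response_names=list(response_names),
        instance_ids=[str(v) for v in pivot.index],
    )


def read_training_csv(
    path: str | Path,
    dialect: str = "wide",
    response_names: Sequence[str] = (),
    merge_replicates: bool = False,
) -> TrainingSet:
    """Read a training CSV in ``wide`` or ``edd_long`` dialect.

    Parameters
    ----------
    path
        CSV file (UTF-8, header row required).
    dialect
        ``"wide"`` or ``"edd_long"``.
    response_names
        Labels of the response column(s)/measurement(s); everything else
        becomes an input feature. Feature columns are sorted by label so the
        result is independent of the file's column/row order.
    merge_replicates
        Long dialect only: average replicate rows of the same
        (line, measurement) instead of splitting them into extra instances.
    """
    path = Path(path)
    if not path.exists():
        raise ParseError(f"input file not found: {path}")
    if not response_names:
        raise ConfigurationError("at least one response name is required")
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # malformed CSV structure
        raise ParseError(f"could not parse {path}: {exc}") from exc
    if dialect == "wide":
        return _from_wide_frame(df, response_names)
    if dialect == "edd_long":
        return _from_long_frame(df, response_names, merge_replicates)
    raise ConfigurationError(f"unknown dialect {dialect!r}; use 'wide' or 'edd_long'")


def read_wide_csv(path: str | Path, response_names: Sequence[str]) -> TrainingSet:
    return read_training_csv(path, "wide", response_names)


__all__ = [
    "TrainingSet",
    "FoldPartition",
    "make_folds",
    "default_fold_count",
    "read_training_csv",
    "read_wide_csv",
]
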