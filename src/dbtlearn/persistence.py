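"""Model persistence: a JSON envelope plus a joblib sidecar.

The envelope carries everything human-readable — feature/response labels,
learner names, posterior sample arrays, seeds — and references an opaque
binary blob (joblib) holding the fitted scikit-learn estimators.
"""

from __future__ import annotations

import json
from pathlib import Path

import joblib
import numpy as np

from .datasets import FoldPartition
from .ensemble import EnsembleModel, PosteriorSamples
from .exceptions import DataError
from .learners import LearnerCollection, Level1Data

ENVELOPE_FORMAT = "dbtlearn-model/1"


def save_model(model: EnsembleModel, path: str | Path) -> Path:
    """Write ``path`` (JSON envelope) and ``path`` + ``.blob`` (fitted learners)."""
    path = Path(path)
    blob_path = path.with_suffix(path.suffix + ".blob")
    envelope = {
        "format": ENVELOPE_FORMAT,
        "feature_names": model.feature_names,
        "response_names": model.response_names,
        "learner_names": model.learners.names,
        "seed": model.seed,
        "blob": blob_path.name,
        "posteriors": [
            {
                "weights": post.weights.tolist(),
                "sigmas": post.sigmas.tolist(),
                "acceptance_rate": post.acceptance_rate,
                "burn_in": post.burn_in,
                "seed": post.seed,
                "learner_names": post.learner_names,
            }
            for post in model.posteriors
        ],
        "level1": [
            {
                "z": lvl.z.tolist(),
                "y": lvl.y.tolist(),
                "learner_names": lvl.learner_names,
                "folds": {
                    "k": lvl.fold_partition.k,
                    "assignments": lvl.fold_partition.assignments.tolist(),
                    "seed": lvl.fold_partition.seed,
                },
            }
            for lvl in model.level1
        ],
        "training_inputs": None
        if model.training_inputs is None
        else model.training_inputs.tolist(),
        "training_responses": None
        if model.training_responses is None
        else model.training_responses.tolist(),
    }
    path.write_text(json.dumps(envelope, indent=1))
    joblib.dump(model.learners.estimators, blob_path)
    return path


def load_model(path: str | Path) -> EnsembleModel:
    path = Path(path)
    if not path.exists():
        raise DataError(f"model file not found: {path}")
    try:
        envelope = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise DataError(f"model envelope is not valid JSON: {path}") from exc
    if envelope.get("format") != ENVELOPE_FORMAT:
        raise DataError(f"unrecognized model format in {path}")
    blob_path = path.parent / envelope["blob"]
    if not blob_path.exists():
        raise DataError(f"model blob not found: {blob_path}")
    estimators = joblib.load(blob_path)
    learners = LearnerCollection(estimators=estimators, names=envelope["learner_names"])
    posteriors = [
        PosteriorSamples(
            weights=np.asarray(p["weights"]),
            sigmas=np.asarray(p["sigmas"]),
            acceptance_rate=p["acceptance_rate"],
            burn_in=p["burn_in"],
            seed=p["seed"],
            learner_names=p["learner_names"],
        )
        for p in envelope["posteriors"]
    ]
    level1 = [
        Level1Data(
            z=np.asarray(lvl["z"]),
            y=np.asarray(lvl["y"]),
            learner_names=lvl["learner_names"],
            fold_partition=FoldPartition(
                k=lvl["folds"]["k"],
                assignments=np.asarray(lvl["folds"]["assignments"]),
                seed=lvl["folds"]["seed"],
            ),
        )
        for lvl in envelope["level1"]
    ]
    return EnsembleModel(
        learners=learners,
        posteriors=posteriors,
        level1=level1,
        feature_names=envelope["feature_names"],
        response_names=envelope["response_names"],
        seed=envelope["seed"],
        training_inputs=None
        if envelope["training_inputs"] is None
        else np.asarray(envelope["training_inputs"]),
        training_responses=None
        if envelope["training_responses"] is None
        else np.asarray(envelope["training_responses"]),
    )


__all__ = ["save_model", "load_model", "ENVELOPE_FORMAT"]
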