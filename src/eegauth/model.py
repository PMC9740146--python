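"""Random-forest genuine/imposter classifier: tuning, training, scoring.

The verifier is a bagged ensemble of Gini-impurity decision trees fit on
the SMOTE-balanced training split. Hyperparameters are chosen by an
exhaustive grid evaluated on the (imbalanced) validation split, ties
going to the first grid point encountered; the chosen combination is
then frozen for the benchmark and for every channel-ablation refit so
accuracy changes are attributable to channel removal alone. Accuracy is
the fraction of 0.5 s test windows classified correctly at the ensemble
majority vote. Wall-clock training and classification times are recorded
for descriptive reporting only.
"""

from __future__ import annotations

import itertools
import time
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .exceptions import ContractError, ParameterError, ValidationError
from .prep import BinarizedSet


@dataclass(frozen=True)
class ModelParams:
    """Random-forest hyperparameters.

    ``feature_subsample`` is the fraction of feature columns examined at
    each split; the 0.1 default suits the pipeline's wide channel-major
    tables, where most columns carry no identity information.
    """

    n_trees: int = 100
    max_depth: int | None = None
    min_samples_split: int = 2
    feature_subsample: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1 or self.min_samples_split < 2:
            raise ParameterError("n_trees >= 1 and min_samples_split >= 2 required")
        if self.max_depth is not None and self.max_depth < 1:
            raise ParameterError("max_depth must be None or >= 1")
        if not 0 < self.feature_subsample <= 1:
            raise ParameterError("feature_subsample must lie in (0, 1]")

    def to_dict(self) -> dict:
        return {
            "n_trees": self.n_trees,
            "max_depth": self.max_depth,
            "min_samples_split": self.min_samples_split,
            "feature_subsample": self.feature_subsample,
            "seed": self.seed,
        }


#: Default tuning grids, centred on the library defaults.
DEFAULT_GRIDS: dict[str, list] = {
    "n_trees": [50, 100, 200],
    "max_depth": [8, 16, None],
    "min_samples_split": [2, 8],
}


@dataclass
class TrainedModel:
    """A fitted ensemble bound to the exact feature columns it saw."""

    estimator: RandomForestClassifier = field(repr=False)
    params: ModelParams
    feature_columns: tuple[tuple[str, str], ...]
    train_time: float = 0.0
    classify_time: float = 0.0


def _make_forest(params: ModelParams) -> RandomForestClassifier:
    return RandomForestClassifier(
        n_estimators=params.n_trees,
        max_depth=params.max_depth,
        min_samples_split=params.min_samples_split,
        max_features=params.feature_subsample,
        criterion="gini",
        random_state=params.seed,
        n_jobs=1,
    )


def train_classifier(train: BinarizedSet, params: ModelParams) -> TrainedModel:
    """Fit the forest on a balanced binarized training set."""
    if np.unique(train.y).size < 2:
        raise ValidationError("training labels contain a single class")
    if not np.all(np.isfinite(train.X)):
        raise ValidationError("training matrix contains non-finite values")
    forest = _make_forest(params)
    t0 = time.perf_counter()
    forest.fit(train.X, train.y)
    elapsed = time.perf_counter() - t0
    return TrainedModel(
        estimator=forest,
        params=params,
        feature_columns=tuple(train.column_index),
        train_time=elapsed,
    )


def evaluate_accuracy(model: TrainedModel, test: BinarizedSet) -> float:
    """Fraction of test windows classified correctly.

    Also records the wall-clock prediction time on ``model.classify_time``.
    """
    if tuple(test.column_index) != model.feature_columns:
        raise ContractError("test feature columns differ from the fit-time columns")
    t0 = time.perf_counter()
    pred = model.estimator.predict(test.X)
    model.classify_time = time.perf_counter() - t0
    return float(np.mean(pred == test.y))


def tune_hyperparameters(
    train: BinarizedSet,
    val: BinarizedSet,
    grids: dict[str, list] = DEFAULT_GRIDS,
    base: ModelParams = ModelParams(),
    return_trace: bool = False,
):
    """Exhaustive grid search maximising validation accuracy.

    Every point of the Cartesian product of ``grids`` (in the given key
    order) is fit on ``train`` and scored on ``val``; the arg-max is
    returned, ties broken by first encounter. With ``return_trace=True``
    the full list of ``(params, accuracy)`` pairs is returned as well.
    """
    if not grids or any(len(v) == 0 for v in grids.values()):
        raise ParameterError("grids must be non-empty")
    unknown = set(grids) - set(ModelParams.__dataclass_fields__)
    if unknown:
        raise ParameterError(f"unknown hyperparameters in grid: {sorted(unknown)}")
    keys = list(grids)
    best: ModelParams | None = None
    best_acc = -np.inf
    trace: list[tuple[ModelParams, float]] = []
    for combo in itertools.product(*(grids[k] for k in keys)):
        params = replace(base, **dict(zip(keys, combo)))
        model = train_classifier(train, params)
        acc = evaluate_accuracy(model, val)
        trace.append((params, acc))
        if acc > best_acc:
            best, best_acc = params, acc
    assert best is not None
    if return_trace:
        return best, trace
    return best


def benchmark_full_channels(
    train: BinarizedSet, test: BinarizedSet, params: ModelParams
) -> tuple[float, TrainedModel]:
    """Train and score with every channel present: the ablation reference."""
    model = train_classifier(train, params)
    return evaluate_accuracy(model, test), model
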