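"""Impurity-based channel ranking and sequential ablation.

Exhaustively testing every electrode subset of a C-channel montage would
take sum_k C(C, k) = 2^C model fits (4 294 967 296 for C = 32), so the
montage is instead ranked once with a gradient-boosted tree classifier:
per-column impurity-gain importances are summed within each channel's
feature-column block and renormalized so the channel scores form
fractions summing to 1. The ablation then removes the lowest-ranked
remaining channel one step at a time, retrains the random forest with the
frozen hyperparameters, and records accuracy at every channel count from
C down to 1. The smallest usable montage is the smallest count whose
accuracy — and that of every larger count — stays within a 1-percentage-
point tolerance of the full-montage benchmark.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from xgboost import XGBClassifier

from .exceptions import ContractError, ParameterError, ValidationError
from .model import ModelParams, evaluate_accuracy, train_classifier
from .prep import BinarizedSet


def search_space_size(n_channels: int) -> int:
    """Number of unordered channel subsets of an ``n_channels`` montage: 2**n."""
    if n_channels < 0:
        raise ParameterError(f"channel count must be >= 0, got {n_channels}")
    return 2 ** int(n_channels)


@dataclass
class ChannelRanking:
    """Per-channel importance fractions with their descending order."""

    labels: tuple[str, ...]
    importances: np.ndarray = field(repr=False)
    order: tuple[str, ...]
    genuine_subject: object = None
    band: str | None = None

    def __post_init__(self) -> None:
        self.importances = np.asarray(self.importances, dtype=np.float64)
        self.labels = tuple(self.labels)
        self.order = tuple(self.order)
        if self.importances.shape != (len(self.labels),):
            raise ValidationError("one importance per label required")
        if np.any(self.importances < 0) or abs(self.importances.sum() - 1.0) > 1e-6:
            raise ValidationError("importances must be non-negative and sum to 1")
        if sorted(self.order) != sorted(self.labels):
            raise ValidationError("order must be a permutation of the labels")

    def importance_of(self, label: str) -> float:
        return float(self.importances[self.labels.index(label)])

    def top(self, k: int) -> tuple[str, ...]:
        return self.order[:k]


def _channel_blocks(column_index) -> dict[str, np.ndarray]:
    blocks: dict[str, list[int]] = {}
    for i, (chan, _) in enumerate(column_index):
        blocks.setdefault(chan, []).append(i)
    return {c: np.asarray(ix) for c, ix in blocks.items()}


def rank_channels(
    train,
    seed: int = 0,
    n_estimators: int = 30,
    max_depth: int = 3,
) -> ChannelRanking:
    """Rank channels by summed gradient-boosting gain importance.

    ``train`` is normally the subject-labelled training
    :class:`~eegauth.features.FeatureTable`: a multiclass XGBoost model
    is fit on all feature columns, so each channel's score measures the
    inter-subject variance it accounts for across the whole cohort. A
    genuine-vs-imposter :class:`~eegauth.prep.BinarizedSet` may be passed
    instead for a single-hypothesis ranking. Per-column gain importances
    are summed within each channel's column block and renormalized to
    fractions summing to 1; the boosting stays shallow (30 stumps-ish
    trees of depth 3 by default) so gain concentrates on genuinely
    informative columns rather than overfitting noise.

    Order is descending; ties break by channel position for determinism.
    """
    if isinstance(train, BinarizedSet):
        X, y = train.X, train.y
        column_index = train.column_index
        genuine = train.genuine_subject
        objective_metric = "logloss"
    else:  # subject-labelled feature table
        X = train.matrix
        codes, y = np.unique(np.asarray(train.subject_labels), return_inverse=True)
        column_index = train.column_index
        genuine = None
        objective_metric = "mlogloss"
    if not column_index:
        raise ContractError("training data lacks a (channel, feature) column index")
    blocks = _channel_blocks(column_index)
    clf = XGBClassifier(
        n_estimators=n_estimators,
        max_depth=max_depth,
        random_state=seed,
        n_jobs=1,
        tree_method="hist",
        importance_type="gain",
        eval_metric=objective_metric,
    )
    clf.fit(X, y)
    col_imp = np.asarray(clf.feature_importances_, dtype=np.float64)
    labels = tuple(blocks)
    raw = np.array([col_imp[blocks[c]].sum() for c in labels])
    total = raw.sum()
    fractions = raw / total if total > 0 else np.full(len(labels), 1.0 / len(labels))
    # Stable descending sort: by -importance, then original channel position.
    order_idx = np.lexsort((np.arange(len(labels)), -fractions))
    order = tuple(labels[i] for i in order_idx)
    return ChannelRanking(
        labels=labels,
        importances=fractions,
        order=order,
        genuine_subject=genuine,
    )


@dataclass
class AblationRecord:
    """Accuracy and timing of one retrained model at a given montage size."""

    n_channels: int
    channels_used: tuple[str, ...]
    accuracy: float
    train_time: float
    classify_time: float

    def __post_init__(self) -> None:
        self.channels_used = tuple(self.channels_used)
        if len(self.channels_used) != self.n_channels:
            raise ValidationError(
                f"{len(self.channels_used)} channels listed for n_channels={self.n_channels}"
            )


def ablate(
    train: BinarizedSet,
    test: BinarizedSet,
    ranking: ChannelRanking,
    params: ModelParams,
    rerank: bool = False,
    rerank_seed: int = 0,
) -> list[AblationRecord]:
    """Sequentially drop the lowest-ranked channel with retraining.

    Produces one record per montage size n = C, C-1, ..., 1. At each step
    the lowest-ranked remaining channel's feature columns are removed from
    both splits and the forest is retrained with the frozen ``params``.
    By default removal follows the single initial ranking; ``rerank=True``
    re-ranks the remaining channels before every removal instead.
    """
    if params is None:
        raise ContractError("ablation requires tuned ModelParams; run tuning first")
    all_channels = tuple(dict.fromkeys(c for c, _ in train.column_index))
    if sorted(ranking.labels) != sorted(all_channels):
        raise ContractError("ranking does not cover the training set's channels")
    records: list[AblationRecord] = []
    remaining = list(all_channels)
    current_order = ranking.order
    while remaining:
        sub_train = train.select_channels(remaining)
        sub_test = test.select_channels(remaining)
        model = train_classifier(sub_train, params)
        acc = evaluate_accuracy(model, sub_test)
        records.append(
            AblationRecord(
                n_channels=len(remaining),
                channels_used=tuple(remaining),
                accuracy=acc,
                train_time=model.train_time,
                classify_time=model.classify_time,
            )
        )
        if len(remaining) == 1:
            break
        if rerank:
            current_order = rank_channels(sub_train, seed=rerank_seed).order
        lowest = next(c for c in reversed(current_order) if c in remaining)
        remaining.remove(lowest)
    return records


def _min_channels_from_curve(
    n_channels: np.ndarray, accuracies: np.ndarray, benchmark: float, tolerance_pp: float
) -> int:
    """Scan a descending-n accuracy curve for the first tolerance violation."""
    n_channels = np.asarray(n_channels)
    accuracies = np.asarray(accuracies)
    if len(n_channels) == 0:
        raise ValidationError("empty ablation curve")
    if np.any(np.diff(n_channels) >= 0):
        raise ValidationError("curve must be ordered by strictly decreasing channel count")
    threshold = benchmark - tolerance_pp / 100.0
    prev_n = int(n_channels[0]) + 1
    for n, acc in zip(n_channels, accuracies):
        if acc < threshold:
            return prev_n
        prev_n = int(n)
    return int(n_channels[-1])


def min_channels_before_drop(
    records: list[AblationRecord], benchmark: float, tolerance: float = 1.0
) -> int:
    """Smallest montage size keeping accuracy within ``tolerance`` points.

    Scanning from the full montage downward, returns the smallest n such
    that every record with count >= n has accuracy >= benchmark -
    tolerance/100. If no record violates the tolerance the scan runs out
    and the smallest recorded count (1 for a complete ablation) is
    returned.
    """
    if not records:
        raise ValidationError("no ablation records")
    ns = np.array([r.n_channels for r in records])
    accs = np.array([r.accuracy for r in records])
    return _min_channels_from_curve(ns, accs, benchmark, tolerance)
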