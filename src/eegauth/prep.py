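"""Train/validation/test splitting, label binarization, and SMOTE.

Authentication is framed one subject at a time: the claimed "genuine"
subject's windows get label 1 and every other subject's windows label 0,
giving a 1:(S-1) class imbalance for an S-subject cohort. The training
split is rebalanced to exactly 50/50 with SMOTE — each synthetic genuine
row is ``x + u * (x_nn - x)`` for a genuine row ``x``, one of its k
nearest genuine neighbours ``x_nn`` (Euclidean) and ``u ~ U(0, 1)`` —
while validation and test keep their natural imbalance.

Splitting is per-subject stratified uniform sampling without replacement
(window-level, so adjacent half-overlapping windows may straddle splits;
a contiguous block splitter is available for leakage-controlled
experiments).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .exceptions import ParameterError, ValidationError
from .features import FeatureTable

DEFAULT_FRACTIONS = (0.8, 0.1, 0.1)


@dataclass
class SplitSet:
    """Row-disjoint train/validation/test feature tables."""

    train: FeatureTable
    validation: FeatureTable
    test: FeatureTable
    fractions: tuple[float, float, float]
    seed: int
    indices: dict[str, np.ndarray] = field(default_factory=dict, repr=False)


def split_dataset(
    table: FeatureTable,
    fractions: tuple[float, float, float] = DEFAULT_FRACTIONS,
    seed: int = 0,
    method: str = "random",
) -> SplitSet:
    """Split a feature table 80/10/10 (by default), stratified by subject.

    Validation and test counts are floored per subject; the remainder goes
    to train. ``method="random"`` permutes each subject's windows before
    assignment (the pipeline default); ``method="blocks"`` keeps windows in
    time order so each split is a contiguous segment per subject.
    """
    if len(fractions) != 3 or abs(sum(fractions) - 1.0) > 1e-9 or min(fractions) < 0:
        raise ParameterError(f"fractions must be 3 non-negative values summing to 1, got {fractions}")
    if method not in ("random", "blocks"):
        raise ParameterError(f"unknown split method {method!r}")
    rng = np.random.default_rng(seed)
    subjects = np.asarray(table.subject_labels)
    train_idx: list[np.ndarray] = []
    val_idx: list[np.ndarray] = []
    test_idx: list[np.ndarray] = []
    # Iterate subjects in first-appearance order for determinism.
    for subj in dict.fromkeys(subjects.tolist()):
        rows = np.flatnonzero(subjects == subj)
        if rows.size < 10:
            raise ValidationError(
                f"subject {subj!r} has only {rows.size} windows; >= 10 required to split"
            )
        if method == "random":
            rows = rng.permutation(rows)
        n_val = int(np.floor(rows.size * fractions[1]))
        n_test = int(np.floor(rows.size * fractions[2]))
        n_train = rows.size - n_val - n_test
        train_idx.append(rows[:n_train])
        val_idx.append(rows[n_train : n_train + n_val])
        test_idx.append(rows[n_train + n_val :])
    indices = {
        "train": np.sort(np.concatenate(train_idx)),
        "validation": np.sort(np.concatenate(val_idx)),
        "test": np.sort(np.concatenate(test_idx)),
    }
    return SplitSet(
        train=table.select_rows(indices["train"]),
        validation=table.select_rows(indices["validation"]),
        test=table.select_rows(indices["test"]),
        fractions=tuple(fractions),
        seed=seed,
        indices=indices,
    )


def binarize_labels(labels: np.ndarray, genuine_subject) -> np.ndarray:
    """Map subject labels to {0, 1}: 1 for the genuine subject, 0 otherwise."""
    labels = np.asarray(labels)
    mask = labels == genuine_subject
    if not mask.any():
        raise KeyError(f"genuine subject {genuine_subject!r} not present in labels")
    return mask.astype(np.int64)


@dataclass
class BinarizedSet:
    """Feature matrix with {0,1} labels for one genuine-user hypothesis."""

    X: np.ndarray = field(repr=False)
    y: np.ndarray = field(repr=False)
    genuine_subject: object
    balanced: bool
    column_index: tuple[tuple[str, str], ...]

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.int64)
        if self.X.shape[0] != self.y.shape[0]:
            raise ValidationError("X and y row counts differ")
        if not set(np.unique(self.y)) <= {0, 1}:
            raise ValidationError("labels must be in {0, 1}")

    def select_channels(self, labels) -> "BinarizedSet":
        """Restrict to the feature columns of the given channels."""
        keep = set(labels)
        cols = [i for i, (c, _) in enumerate(self.column_index) if c in keep]
        return BinarizedSet(
            X=self.X[:, cols],
            y=self.y.copy(),
            genuine_subject=self.genuine_subject,
            balanced=self.balanced,
            column_index=tuple(self.column_index[i] for i in cols),
        )


def make_binarized(table: FeatureTable, genuine_subject) -> BinarizedSet:
    """Binarize a feature table's subject labels for one genuine user."""
    y = binarize_labels(table.subject_labels, genuine_subject)
    return BinarizedSet(
        X=table.matrix,
        y=y,
        genuine_subject=genuine_subject,
        balanced=bool(y.sum() * 2 == y.size),
        column_index=table.column_index,
    )


def smote_upsample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    seed: int = 0,
    standardize: bool = False,
) -> tuple[np.ndarray, np.ndarray]:
    """Upsample the minority class to parity with SMOTE.

    Original rows are preserved verbatim and synthetic minority rows are
    appended until both classes have the majority count. ``standardize``
    z-scores features for the neighbour search only (synthesis still
    happens in raw feature space).
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    if k < 1:
        raise ParameterError(f"k must be >= 1, got {k}")
    classes, counts = np.unique(y, return_counts=True)
    if classes.size != 2:
        raise ValidationError(f"SMOTE needs exactly two classes, got {classes.tolist()}")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min <= k:
        raise ParameterError(
            f"minority class has {n_min} rows but k={k}; lower k below the minority count"
        )
    rng = np.random.default_rng(seed)
    Xmin = X[y == minority]
    search_space = Xmin
    if standardize:
        mu = Xmin.mean(axis=0)
        sd = Xmin.std(axis=0)
        sd[sd == 0] = 1.0
        search_space = (Xmin - mu) / sd
    nn = NearestNeighbors(n_neighbors=k + 1).fit(search_space)
    neighbours = nn.kneighbors(search_space, return_distance=False)[:, 1:]  # drop self

    n_new = n_maj - n_min
    base = np.tile(np.arange(n_min), n_new // n_min)
    if n_new % n_min:
        base = np.concatenate([base, rng.choice(n_min, n_new % n_min, replace=False)])
    picked = neighbours[base, rng.integers(0, k, size=n_new)]
    u = rng.random(n_new)[:, None]
    synthetic = Xmin[base] + u * (Xmin[picked] - Xmin[base])

    X_out = np.vstack([X, synthetic])
    y_out = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    return X_out, y_out


def balance_training_set(bset: BinarizedSet, k: int = 5, seed: int = 0,
                         standardize: bool = False) -> BinarizedSet:
    """SMOTE-balance a binarized training set to a 50/50 class split."""
    X, y = smote_upsample(bset.X, bset.y, k=k, seed=seed, standardize=standardize)
    return BinarizedSet(
        X=X,
        y=y,
        genuine_subject=bset.genuine_subject,
        balanced=True,
        column_index=bset.column_index,
    )
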