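"""End-to-end authentication + channel-reduction runs.

Chains the whole method for one (genuine subject, band) hypothesis:

1. band-limit every subject's raw recording to 0.2-50 Hz, extract the
   requested band;
2. window (0.5 s / 0.25 s step) and extract the per-channel feature set;
3. split 80/10/10 per subject, binarize genuine vs imposter, SMOTE the
   training split to 50/50;
4. optionally grid-tune the random forest on the validation split, then
   freeze the hyperparameters;
5. benchmark on all channels, rank channels by boosted-tree gain, and
   ablate down to one channel with retraining at each step.

All randomness flows from the explicit ``seed``; two runs with the same
inputs and seed produce identical bundles (timings aside).
"""

from __future__ import annotations

import numpy as np

from .exceptions import ParameterError
from .features import FeatureTable, WindowSpec, build_feature_table, concat_tables
from .filters import BAND_NAMES, preprocess_recording
from .io import EEGRecording
from .model import ModelParams, train_classifier, evaluate_accuracy, tune_hyperparameters
from .prep import balance_training_set, make_binarized, split_dataset
from .reduction import ablate, rank_channels
from .results import ResultsBundle


def cohort_feature_table(
    recordings: list[EEGRecording],
    band: str = "gamma",
    wspec: WindowSpec = WindowSpec(),
) -> FeatureTable:
    """Filter, window and featurize a whole cohort for one band."""
    if band not in BAND_NAMES:
        raise ParameterError(f"unknown band {band!r}")
    tables = [
        build_feature_table(preprocess_recording(rec, band), wspec, band=band)
        for rec in recordings
    ]
    return concat_tables(tables)


def run_authentication(
    recordings: list[EEGRecording] | FeatureTable,
    genuine_subject,
    band: str = "gamma",
    wspec: WindowSpec = WindowSpec(),
    params: ModelParams | None = None,
    grids: dict[str, list] | None = None,
    seed: int = 0,
    smote_k: int = 5,
) -> ResultsBundle:
    """Full pipeline for one genuine-user hypothesis; returns the bundle.

    Pass ``grids`` to tune on the validation split, or ``params`` to use
    fixed hyperparameters (exactly one of the two). ``recordings`` may be
    raw recordings (filtered and featurized here) or an already-built
    cohort :class:`FeatureTable` for the requested band.
    """
    if (params is None) == (grids is None):
        raise ParameterError("provide exactly one of params or grids")
    if isinstance(recordings, FeatureTable):
        table = recordings
    else:
        table = cohort_feature_table(recordings, band=band, wspec=wspec)

    split = split_dataset(table, seed=seed)
    train = balance_training_set(make_binarized(split.train, genuine_subject), k=smote_k, seed=seed)
    val = make_binarized(split.validation, genuine_subject)
    test = make_binarized(split.test, genuine_subject)

    if grids is not None:
        params = tune_hyperparameters(train, val, grids, base=ModelParams(seed=seed))
    assert params is not None

    ranking = rank_channels(split.train, seed=seed)
    ranking.band = band
    ranking.genuine_subject = genuine_subject
    steps = ablate(train, test, ranking, params)
    return ResultsBundle(
        genuine_subject=genuine_subject,
        band=band,
        benchmark_accuracy=steps[0].accuracy,
        ranking=ranking,
        steps=steps,
        tuned_params=params.to_dict(),
    )


def shuffled_label_accuracy(
    table: FeatureTable,
    genuine_subject,
    params: ModelParams,
    seed: int = 0,
    smote_k: int = 5,
) -> float:
    """Permutation-null accuracy: subject labels shuffled before training.

    The training split's subject labels are independently permuted, then
    binarized, SMOTE-balanced and fit as usual; test labels keep their
    true values. Accuracy is scored on a class-balanced test subsample
    (every genuine window plus an equal-sized seeded draw of imposter
    windows), so chance sits at 0.5 regardless of how a signal-free model
    biases its predictions. Serves as the chance reference for the
    signal condition.
    """
    split = split_dataset(table, seed=seed)
    rng = np.random.default_rng(seed + 1)
    shuffled = split.train
    shuffled = FeatureTable(
        matrix=shuffled.matrix,
        column_index=shuffled.column_index,
        subject_labels=rng.permutation(np.asarray(shuffled.subject_labels)),
        band=shuffled.band,
    )
    train = balance_training_set(make_binarized(shuffled, genuine_subject), k=smote_k, seed=seed)
    test = make_binarized(split.test, genuine_subject)
    model = train_classifier(train, params)
    genuine_rows = np.flatnonzero(test.y == 1)
    imposter_rows = rng.choice(np.flatnonzero(test.y == 0), size=genuine_rows.size, replace=False)
    rows = np.concatenate([genuine_rows, imposter_rows])
    pred = model.estimator.predict(test.X[rows])
    return float(np.mean(pred == test.y[rows]))
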