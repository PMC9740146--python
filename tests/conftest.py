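"""Shared fixtures: tiny seeded cohorts and hand-built feature tables."""

import numpy as np
import pytest

from eegauth import CohortSpec, EEGRecording, FeatureTable, generate_cohort
from eegauth.features import FEATURE_NAMES


def make_table(rows_per_subject, subjects, n_channels=4, seed=0, band="gamma"):
    """Random feature table with a proper channel-major column index."""
    rng = np.random.default_rng(seed)
    labels = [f"C{i}" for i in range(n_channels)]
    column_index = tuple((c, f) for c in labels for f in FEATURE_NAMES)
    n_rows = rows_per_subject * len(subjects)
    return FeatureTable(
        matrix=rng.normal(size=(n_rows, len(column_index))),
        column_index=column_index,
        subject_labels=np.repeat(subjects, rows_per_subject),
        band=band,
    )


@pytest.fixture
def sine_recording():
    """Two-channel 500 Hz recording: 10 Hz and 30 Hz unit sines, 4 s."""
    fs = 500.0
    t = np.arange(int(4 * fs)) / fs
    data = np.vstack([np.sin(2 * np.pi * 10 * t), np.sin(2 * np.pi * 30 * t)])
    return EEGRecording(subject_id=0, fs=fs, channel_labels=("Fp1", "Fp2"), data=data)


@pytest.fixture(scope="session")
def small_cohort():
    """Fast 6-subject, 8-channel cohort with 3 planted channels."""
    spec = CohortSpec(
        n_subjects=6, n_channels=8, duration=15.0, seed=0, informative_channels=(0, 1, 2)
    )
    return spec, generate_cohort(spec)
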