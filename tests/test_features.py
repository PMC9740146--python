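"""Windowing and the per-window feature set, against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eegauth import EEGRecording, WindowSpec, build_feature_table, compute_features, window_signal
from eegauth.exceptions import ParameterError, ValidationError
from eegauth.features import FEATURE_NAMES, N_FEATURES, concat_tables

IDX = {name: i for i, name in enumerate(FEATURE_NAMES)}


def rec_of(data, fs=500.0):
    labels = tuple(f"C{i}" for i in range(data.shape[0]))
    return EEGRecording(subject_id=0, fs=fs, channel_labels=labels, data=data)


def hjorth_oracle(x):
    """Hjorth parameters straight from their variance-ratio definitions."""
    x = np.asarray(x, dtype=float)
    var = np.var(x)
    if var == 0:
        return var, 0.0, 0.0
    d1 = np.diff(x)
    mobility = np.sqrt(np.var(d1) / var)
    if np.var(d1) == 0:
        return var, mobility, 0.0
    mobility_d1 = np.sqrt(np.var(np.diff(d1)) / np.var(d1))
    return var, mobility, mobility_d1 / mobility


class TestWindowing:
    def test_two_seconds_gives_seven_half_overlapped_windows(self):
        rec = rec_of(np.zeros((32, 1000)))
        windows = window_signal(rec, WindowSpec())
        assert len(windows) == (1000 - 250) // 125 + 1 == 7
        assert all(w.shape == (32, 250) for w in windows)

    def test_exactly_one_window(self):
        assert len(window_signal(rec_of(np.zeros((2, 250))))) == 1

    def test_too_short_recording_warns_and_returns_empty(self):
        with pytest.warns(UserWarning):
            assert window_signal(rec_of(np.zeros((2, 200)))) == []

    def test_windows_advance_by_step(self):
        data = np.arange(1000, dtype=float)[None, :]
        windows = window_signal(rec_of(data))
        for i, w in enumerate(windows):
            assert w[0, 0] == i * 125

    def test_invalid_window_spec(self):
        with pytest.raises(ParameterError):
            WindowSpec(length=0.5, step=0.6)


class TestFeatureValues:
    def test_constant_window_degenerates_gracefully(self):
        f = compute_features(np.full(250, 5.0))
        assert f[IDX["mean"]] == 5.0
        assert f[IDX["std"]] == 0.0
        assert f[IDX["mav"]] == 5.0
        assert f[IDX["rms"]] == 5.0
        for name in ("skewness", "kurtosis", "hjorth_activity", "hjorth_mobility",
                     "hjorth_complexity", "shannon_entropy"):
            assert f[IDX[name]] == 0.0

    def test_alternating_unit_window(self):
        x = np.tile([1.0, -1.0], 125)
        f = compute_features(x)
        assert f[IDX["mean"]] == pytest.approx(0.0)
        assert f[IDX["mav"]] == pytest.approx(1.0)
        assert f[IDX["rms"]] == pytest.approx(1.0)

    def test_gaussian_moments_and_spectral_flatness_at_large_n(self):
        rng = np.random.default_rng(42)
        x = rng.standard_normal(4096)
        f = compute_features(x)
        assert abs(f[IDX["kurtosis"]] - 3.0) < 0.3
        assert abs(f[IDX["skewness"]]) < 0.2
        assert f[IDX["spectral_entropy"]] >= 0.9

    def test_pure_sine_has_concentrated_spectrum(self):
        t = np.arange(250) / 500.0
        f = compute_features(np.sin(2 * np.pi * 20.0 * t))  # 10 cycles, bin-centred
        assert f[IDX["spectral_entropy"]] <= 0.3

    def test_hjorth_matches_bruteforce_oracle_on_random_windows(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            x = rng.normal(size=rng.integers(10, 500))
            f = compute_features(x)
            act, mob, comp = hjorth_oracle(x)
            assert f[IDX["hjorth_activity"]] == pytest.approx(act, rel=1e-9)
            assert f[IDX["hjorth_mobility"]] == pytest.approx(mob, rel=1e-9)
            assert f[IDX["hjorth_complexity"]] == pytest.approx(comp, rel=1e-9)

    def test_non_finite_window_rejected(self):
        with pytest.raises(ValidationError):
            compute_features(np.array([1.0, np.nan, 2.0]))

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(seed=st.integers(0, 10_000), scale=st.floats(0.01, 100.0))
    def test_scale_equivariance(self, seed, scale):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=128)
        f1, f2 = compute_features(x), compute_features(scale * x)
        for name in ("mean", "std", "mav", "rms"):
            assert f2[IDX[name]] == pytest.approx(scale * f1[IDX[name]], rel=1e-9)
        assert f2[IDX["hjorth_activity"]] == pytest.approx(scale**2 * f1[IDX["hjorth_activity"]], rel=1e-9)
        for name in ("skewness", "kurtosis", "hjorth_mobility", "hjorth_complexity",
                     "spectral_entropy"):
            assert f2[IDX[name]] == pytest.approx(f1[IDX[name]], rel=1e-7)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.floats(-1e6, 1e6), min_size=3, max_size=64))
    def test_features_are_finite_for_finite_input(self, values):
        f = compute_features(np.array(values))
        assert np.all(np.isfinite(f))


class TestFeatureTables:
    def test_table_shape_and_channel_major_columns(self):
        rng = np.random.default_rng(0)
        rec = rec_of(rng.normal(size=(32, 1000)))
        table = build_feature_table(rec)
        assert table.matrix.shape == (7, 32 * N_FEATURES)
        # channel-major: first 11 columns all belong to channel 0
        assert {c for c, _ in table.column_index[:N_FEATURES]} == {"C0"}
        assert [f for _, f in table.column_index[:N_FEATURES]] == list(FEATURE_NAMES)
        assert np.all(np.asarray(table.subject_labels) == 0)

    def test_table_rows_match_per_window_features(self):
        rng = np.random.default_rng(3)
        rec = rec_of(rng.normal(size=(2, 500)))
        table = build_feature_table(rec)
        windows = window_signal(rec)
        for i, w in enumerate(windows):
            for c in range(2):
                np.testing.assert_allclose(
                    table.matrix[i, c * N_FEATURES : (c + 1) * N_FEATURES],
                    compute_features(w[c]),
                    rtol=1e-12,
                )

    def test_select_channels_keeps_original_order(self):
        rng = np.random.default_rng(1)
        table = build_feature_table(rec_of(rng.normal(size=(4, 500))))
        sub = table.select_channels(["C2", "C0"])
        assert sub.channel_labels == ("C0", "C2")
        assert sub.matrix.shape[1] == 2 * N_FEATURES

    def test_concat_requires_matching_layout(self):
        rng = np.random.default_rng(2)
        t1 = build_feature_table(rec_of(rng.normal(size=(2, 500))))
        t2 = build_feature_table(rec_of(rng.normal(size=(3, 500))))
        with pytest.raises(ValidationError):
            concat_tables([t1, t2])

    def test_round_trip_through_disk(self, tmp_path):
        from eegauth.features import read_feature_table, write_feature_table

        rng = np.random.default_rng(4)
        table = build_feature_table(rec_of(rng.normal(size=(3, 500))))
        write_feature_table(table, tmp_path / "t.h5")
        back = read_feature_table(tmp_path / "t.h5")
        np.testing.assert_array_equal(back.matrix, table.matrix)
        assert back.column_index == table.column_index
        assert back.band == table.band
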