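"""Cross-participant aggregation identities and data-rate arithmetic."""

import numpy as np
import pytest

from eegauth import (
    AblationRecord,
    ChannelRanking,
    CohortResults,
    ResultsBundle,
    average_band_accuracy,
    average_importance_by_band,
    change_in_accuracy,
    data_rate,
    min_channels_table,
    timing_summary,
    top_k_membership_counts,
)
from eegauth.exceptions import ParameterError, ValidationError

LABELS = ("Fp1", "Cz", "O2", "T8")


def bundle(subject, band, accs, importances=None, classify_times=None):
    C = len(LABELS)
    imp = np.asarray(importances if importances is not None else [0.4, 0.3, 0.2, 0.1])
    order = tuple(LABELS[i] for i in np.argsort(-imp, kind="stable"))
    times = classify_times or [0.1] * len(accs)
    steps = [
        AblationRecord(C - i, LABELS[: C - i], acc, 0.05, t)
        for i, (acc, t) in enumerate(zip(accs, times))
    ]
    return ResultsBundle(
        genuine_subject=subject, band=band, benchmark_accuracy=accs[0],
        ranking=ChannelRanking(labels=LABELS, importances=imp, order=order,
                               genuine_subject=subject, band=band),
        steps=steps,
    )


class TestCohortResults:
    def test_duplicate_key_rejected(self):
        b = bundle(0, "gamma", [0.9, 0.9, 0.8, 0.7])
        with pytest.raises(ValidationError):
            CohortResults([b, b])

    def test_bands_and_subjects_enumerated(self):
        cr = CohortResults([
            bundle(0, "gamma", [0.9, 0.9, 0.8, 0.7]),
            bundle(1, "beta", [0.8, 0.8, 0.7, 0.6]),
        ])
        assert cr.bands == ("gamma", "beta")
        assert cr.subjects == (0, 1)


class TestAverageAccuracy:
    def test_single_subject_passthrough(self):
        curve = [0.9, 0.88, 0.8, 0.7]
        cr = CohortResults([bundle(0, "gamma", curve)])
        out = average_band_accuracy(cr, "gamma")
        np.testing.assert_allclose(out.to_numpy(), curve)
        assert list(out.index) == [4, 3, 2, 1]

    def test_mean_of_shifted_curves(self):
        c = np.array([0.8, 0.78, 0.7, 0.6])
        cr = CohortResults([bundle(0, "gamma", list(c)), bundle(1, "gamma", list(c + 0.1))])
        np.testing.assert_allclose(average_band_accuracy(cr, "gamma").to_numpy(), c + 0.05)

    def test_subject_order_is_irrelevant(self):
        b0 = bundle(0, "gamma", [0.9, 0.85, 0.8, 0.7])
        b1 = bundle(1, "gamma", [0.7, 0.72, 0.6, 0.5])
        a = average_band_accuracy(CohortResults([b0, b1]), "gamma")
        b = average_band_accuracy(CohortResults([b1, b0]), "gamma")
        np.testing.assert_array_equal(a.to_numpy(), b.to_numpy())

    def test_missing_band_raises(self):
        cr = CohortResults([bundle(0, "gamma", [0.9, 0.9, 0.8, 0.7])])
        with pytest.raises(KeyError):
            average_band_accuracy(cr, "delta")


class TestChangeInAccuracy:
    def test_constant_curve_gives_zero_deltas(self):
        deltas = change_in_accuracy(bundle(0, "gamma", [0.8] * 4))
        np.testing.assert_array_equal(deltas, np.zeros(3))

    def test_telescoping_sum_identity(self):
        rng = np.random.default_rng(0)
        accs = list(rng.uniform(0.5, 1.0, 6))
        b = bundle(0, "gamma", accs[:4])
        deltas = change_in_accuracy(b)
        assert deltas.sum() == pytest.approx(accs[3] - accs[0])

    def test_strictly_decreasing_curve_gives_negative_deltas(self):
        deltas = change_in_accuracy(bundle(0, "gamma", [0.9, 0.8, 0.7, 0.6]))
        assert np.all(deltas < 0)


class TestImportanceAggregation:
    def test_identical_rankings_average_to_themselves(self):
        imp = [0.4, 0.3, 0.2, 0.1]
        cr = CohortResults([
            bundle(0, "gamma", [0.9, 0.9, 0.8, 0.7], imp),
            bundle(1, "gamma", [0.8, 0.8, 0.7, 0.6], imp),
        ])
        np.testing.assert_allclose(average_importance_by_band(cr, "gamma").to_numpy(), imp)

    def test_disjoint_one_hot_rankings_average_to_half(self):
        cr = CohortResults([
            bundle(0, "gamma", [0.9] * 4, [1.0, 0.0, 0.0, 0.0]),
            bundle(1, "gamma", [0.9] * 4, [0.0, 1.0, 0.0, 0.0]),
        ])
        out = average_importance_by_band(cr, "gamma")
        assert out["Fp1"] == out["Cz"] == 0.5
        assert out.sum() == pytest.approx(1.0)


class TestTopKMembership:
    def make_cr(self):
        return CohortResults([
            bundle(0, "gamma", [0.9] * 4, [0.4, 0.3, 0.2, 0.1]),
            bundle(1, "gamma", [0.9] * 4, [0.4, 0.3, 0.2, 0.1]),
            bundle(0, "beta", [0.8] * 4, [0.1, 0.2, 0.3, 0.4]),
        ])

    def test_shared_ranking_gives_maximal_counts(self):
        cr = CohortResults([
            bundle(s, "gamma", [0.9] * 4, [0.4, 0.3, 0.2, 0.1]) for s in range(3)
        ])
        counts = top_k_membership_counts(cr, k=2, bands=("gamma",))
        assert counts["Fp1"] == counts["Cz"] == 3
        assert counts["O2"] == counts["T8"] == 0

    def test_k_equal_to_montage_counts_everything(self):
        counts = top_k_membership_counts(self.make_cr(), k=4, bands=("gamma", "beta"))
        assert np.all(counts.to_numpy() == 3)

    def test_pigeonhole_identity(self):
        for k in (1, 2, 3, 4):
            counts = top_k_membership_counts(self.make_cr(), k=k, bands=("gamma", "beta"))
            assert counts.sum() == k * 3  # three (subject, band) lists

    def test_oversized_k_rejected(self):
        with pytest.raises(ParameterError):
            top_k_membership_counts(self.make_cr(), k=5, bands=("gamma",))


class TestMinChannelsTable:
    def test_constructed_curves(self):
        cr = CohortResults([
            bundle(0, "gamma", [0.90, 0.90, 0.90, 0.70]),   # violates at n=1
            bundle(0, "delta", [0.90, 0.90, 0.80, 0.70]),   # violates at n=2
        ])
        table = min_channels_table(cr)
        assert table == {"gamma": 2, "delta": 3}

    def test_zero_tolerance_on_strictly_decreasing_curve(self):
        cr = CohortResults([bundle(0, "gamma", [0.9, 0.89, 0.88, 0.87])])
        assert min_channels_table(cr, tolerance=0.0)["gamma"] == 4


class TestDataRate:
    def test_brainid_like_montage(self):
        assert data_rate(14, 128).samples_per_second == 1792

    def test_high_density_montage_with_bit_depth(self):
        rate = data_rate(64, 512, bit_depth=16)
        assert rate.samples_per_second == 32768
        assert rate.bits_per_second == 524288

    def test_unit_montage(self):
        assert data_rate(1, 1).samples_per_second == 1


class TestTimingSummary:
    def test_single_bundle_passthrough_and_length(self):
        times = [0.4, 0.3, 0.2, 0.1]
        cr = CohortResults([bundle(0, "gamma", [0.9] * 4, classify_times=times)])
        out = timing_summary(cr, "gamma")
        np.testing.assert_allclose(out.to_numpy(), times)
        assert len(out) == 4

    def test_mean_of_equal_times_is_that_time(self):
        cr = CohortResults([
            bundle(0, "gamma", [0.9] * 4, classify_times=[0.2] * 4),
            bundle(1, "gamma", [0.8] * 4, classify_times=[0.2] * 4),
        ])
        assert np.all(timing_summary(cr, "gamma").to_numpy() == pytest.approx(0.2))
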