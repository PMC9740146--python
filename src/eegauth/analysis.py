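"""Cross-participant aggregation of authentication results.

Collects :class:`~eegauth.results.ResultsBundle` objects across subjects
and bands and computes the study-level summaries: per-band average
accuracy curves, per-step accuracy changes, averaged channel
importances, top-k ranking membership counts, the minimum-channel table
under the 1-percentage-point criterion, classification-time trends, and
the acquisition data-rate arithmetic. All aggregations are pure,
permutation-invariant functions of the bundles; plotting is an optional
rendering of the returned tables.
"""

from __future__ import annotations

from collections import namedtuple

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError
from .reduction import _min_channels_from_curve
from .results import ResultsBundle


class CohortResults:
    """Bundles keyed by (genuine subject, band), sharing channel labels."""

    def __init__(self, bundles: list[ResultsBundle]):
        self.bundles: dict[tuple, ResultsBundle] = {}
        labels: set | None = None
        for b in bundles:
            key = (b.genuine_subject, b.band)
            if key in self.bundles:
                raise ValidationError(f"duplicate bundle for {key}")
            have = set(b.ranking.labels)
            if labels is None:
                labels = have
            elif have != labels:
                raise ValidationError("bundles do not share channel labels")
            self.bundles[key] = b
        if not self.bundles:
            raise ValidationError("no bundles")

    @property
    def bands(self) -> tuple[str, ...]:
        return tuple(dict.fromkeys(band for _, band in self.bundles))

    @property
    def subjects(self) -> tuple:
        return tuple(dict.fromkeys(subj for subj, _ in self.bundles))

    @property
    def channel_labels(self) -> tuple[str, ...]:
        return next(iter(self.bundles.values())).ranking.labels

    def for_band(self, band: str) -> list[ResultsBundle]:
        out = [b for (_, bd), b in self.bundles.items() if bd == band]
        if not out:
            raise KeyError(f"no bundles for band {band!r}")
        return out


def average_band_accuracy(cr: CohortResults, band: str) -> pd.Series:
    """Mean accuracy across subjects at each channel count (descending n)."""
    bundles = cr.for_band(band)
    ns, _ = bundles[0].accuracy_curve()
    curves = []
    for b in bundles:
        bn, acc = b.accuracy_curve()
        if not np.array_equal(bn, ns):
            raise ValidationError("bundles record different channel counts")
        curves.append(acc)
    return pd.Series(np.mean(curves, axis=0), index=pd.Index(ns, name="n_channels"), name=band)


def change_in_accuracy(bundle: ResultsBundle) -> np.ndarray:
    """Per-step accuracy deltas; delta[i] = acc(step i+1) - acc(step i).

    The deltas telescope: their sum equals last minus first accuracy.
    """
    _, acc = bundle.accuracy_curve()
    return np.diff(acc)


def average_importance_by_band(cr: CohortResults, band: str) -> pd.Series:
    """Per-channel mean importance across subjects, renormalized to sum 1."""
    bundles = cr.for_band(band)
    labels = cr.channel_labels
    stacked = np.array(
        [[b.ranking.importance_of(lab) for lab in labels] for b in bundles]
    )
    mean = stacked.mean(axis=0)
    mean = mean / mean.sum()
    return pd.Series(mean, index=pd.Index(labels, name="channel"), name=band)


def top_k_membership_counts(
    cr: CohortResults, k: int = 14, bands: tuple[str, ...] = ("gamma", "beta", "overall")
) -> pd.Series:
    """How often each channel makes a (subject, band) top-k importance list.

    Counts lie in [0, n_subjects * n_bands] and sum to k times the number
    of lists considered.
    """
    labels = cr.channel_labels
    if k > len(labels):
        raise ParameterError(f"k={k} exceeds the {len(labels)}-channel montage")
    counts = pd.Series(0, index=pd.Index(labels, name="channel"), name="times_in_top_k")
    for band in bands:
        for bundle in cr.for_band(band):
            for lab in bundle.ranking.top(k):
                counts[lab] += 1
    return counts


def top_channels_overall(
    cr: CohortResults, k: int = 14, bands: tuple[str, ...] = ("gamma", "beta", "overall")
) -> tuple[str, ...]:
    """The overall top-k montage: channels appearing most often in
    individual top-k lists across the given bands; ties broken by mean
    importance over those bands, then label order."""
    counts = top_k_membership_counts(cr, k=k, bands=bands)
    mean_imp = np.mean(
        [average_importance_by_band(cr, band).to_numpy() for band in bands], axis=0
    )
    labels = list(counts.index)
    order = sorted(
        range(len(labels)), key=lambda i: (-counts.iloc[i], -mean_imp[i], i)
    )
    return tuple(labels[i] for i in order[:k])


def min_channels_table(cr: CohortResults, tolerance: float = 1.0) -> dict[str, int]:
    """Per-band minimum channel count before a 1-point accuracy loss.

    Applies the tolerance scan to each band's subject-averaged accuracy
    curve, the benchmark being that curve's full-montage value.
    """
    out: dict[str, int] = {}
    for band in cr.bands:
        curve = average_band_accuracy(cr, band)
        ns = curve.index.to_numpy()
        accs = curve.to_numpy()
        out[band] = _min_channels_from_curve(ns, accs, benchmark=accs[0], tolerance_pp=tolerance)
    return out


DataRate = namedtuple("DataRate", ["samples_per_second", "bits_per_second"])


def data_rate(n_electrodes: int, fs: float, bit_depth: int | None = None) -> DataRate:
    """Acquisition data rate of a montage: samples/s and, with a bit
    depth, bits/s."""
    if n_electrodes < 0 or fs < 0:
        raise ParameterError("n_electrodes and fs must be >= 0")
    samples = n_electrodes * fs
    bits = samples * bit_depth if bit_depth is not None else None
    return DataRate(samples, bits)


def timing_summary(cr: CohortResults, band: str) -> pd.Series:
    """Mean classification time across subjects per channel count.

    Descriptive only — wall-clock values are hardware-dependent.
    """
    bundles = cr.for_band(band)
    ns = [s.n_channels for s in bundles[0].steps]
    times = np.array([[s.classify_time for s in b.steps] for b in bundles])
    return pd.Series(times.mean(axis=0), index=pd.Index(ns, name="n_channels"), name=band)


def plot_accuracy_curves(cr: CohortResults, ax=None):
    """Average accuracy vs channel count, one line per band (optional)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for band in cr.bands:
        curve = average_band_accuracy(cr, band)
        ax.plot(curve.index, curve.to_numpy(), label=band)
    ax.set_xlabel("channels used")
    ax.set_ylabel("mean accuracy")
    ax.invert_xaxis()
    ax.legend()
    return ax
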