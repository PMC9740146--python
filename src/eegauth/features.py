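"""Windowing and per-window statistical features.

Each band-limited recording is cut into overlapping rectangular windows
(default 0.5 s length, 0.25 s step at 500 Hz -> 250-sample windows,
half-overlapped) and every window of every channel is summarised by the
feature set used throughout the authentication pipeline:

mean, standard deviation (population), mean absolute value, RMS,
skewness (biased moment ratio m3/m2^1.5), kurtosis (non-excess m4/m2^2,
3 for a Gaussian), Hjorth activity (variance), Hjorth mobility
(sqrt(var(dx)/var(x))), Hjorth complexity (mobility(dx)/mobility(x)),
Shannon entropy of a 16-bin amplitude histogram (bits), and spectral
entropy of the normalized periodogram (scaled to [0, 1] by the log of the
number of spectral bins).

Zero-variance and empty-spectrum degeneracies are guarded to 0 so every
feature is finite for finite input. Feature tables are laid out
channel-major: all features of the first channel, then the second, ...
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ParameterError, ValidationError
from .io import EEGRecording

#: Canonical feature order for table columns.
FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "std",
    "mav",
    "rms",
    "skewness",
    "kurtosis",
    "hjorth_activity",
    "hjorth_mobility",
    "hjorth_complexity",
    "shannon_entropy",
    "spectral_entropy",
)

N_FEATURES = len(FEATURE_NAMES)

#: Amplitude-histogram bin count for Shannon entropy.
SHANNON_BINS = 16


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class WindowSpec:
    """Rectangular sliding-window geometry in seconds."""

    length: float = 0.5
    step: float = 0.25

    def __post_init__(self) -> None:
        if not 0 < self.step <= self.length:
            raise ParameterError(
                f"need 0 < step <= length, got step={self.step}, length={self.length}"
            )

    def samples(self, fs: float) -> tuple[int, int]:
        """(window length, step) in samples, rounding half away from zero."""
        return _round_half_away(self.length * fs), _round_half_away(self.step * fs)


def window_signal(rec: EEGRecording, wspec: WindowSpec = WindowSpec()) -> list[np.ndarray]:
    """Cut a recording into overlapping channels x L window matrices.

    Windows start at sample 0 and advance by the step; a trailing partial
    window is dropped, so the count is floor((N - L)/S) + 1. A recording
    shorter than one window yields an empty list and a warning.
    """
    length, step = wspec.samples(rec.fs)
    n = rec.n_samples
    if n < length:
        warnings.warn(
            f"recording of {n} samples is shorter than one {length}-sample window",
            stacklevel=2,
        )
        return []
    n_windows = (n - length) // step + 1
    view = np.lib.stride_tricks.sliding_window_view(rec.data, length, axis=1)
    return [np.array(view[:, i * step, :]) for i in range(n_windows)]


def _feature_matrix(windows: np.ndarray) -> np.ndarray:
    """Features for a stack of windows; shape (n_windows, L) -> (n_windows, 11)."""
    w = np.asarray(windows, dtype=np.float64)
    n, length = w.shape

    mean = w.mean(axis=1)
    centered = w - mean[:, None]
    m2 = np.mean(centered**2, axis=1)
    m3 = np.mean(centered**3, axis=1)
    m4 = np.mean(centered**4, axis=1)
    std = np.sqrt(m2)
    mav = np.abs(w).mean(axis=1)
    rms = np.sqrt(np.mean(w**2, axis=1))

    nz = m2 > 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        skew = np.where(nz, m3 / np.where(nz, m2, 1.0) ** 1.5, 0.0)
        kurt = np.where(nz, m4 / np.where(nz, m2, 1.0) ** 2, 0.0)

        d1 = np.diff(w, axis=1)
        v1 = d1.var(axis=1)
        d2 = np.diff(d1, axis=1)
        v2 = d2.var(axis=1)
        mobility = np.where(nz & (v1 >= 0), np.sqrt(v1 / np.where(nz, m2, 1.0)), 0.0)
        nz1 = v1 > 0.0
        mobility_d = np.where(nz1, np.sqrt(v2 / np.where(nz1, v1, 1.0)), 0.0)
        complexity = np.where(mobility > 0, mobility_d / np.where(mobility > 0, mobility, 1.0), 0.0)

    # Shannon entropy over a fixed-width amplitude histogram per window.
    lo = w.min(axis=1)
    hi = w.max(axis=1)
    span = hi - lo
    flat = span <= 0
    safe_span = np.where(flat, 1.0, span)
    idx = ((w - lo[:, None]) / safe_span[:, None] * SHANNON_BINS).astype(np.int64)
    np.clip(idx, 0, SHANNON_BINS - 1, out=idx)
    idx += SHANNON_BINS * np.arange(n)[:, None]
    counts = np.bincount(idx.ravel(), minlength=SHANNON_BINS * n).reshape(n, SHANNON_BINS)
    p = counts / length
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(p > 0, p * np.log2(np.where(p > 0, p, 1.0)), 0.0)
    shannon = np.where(flat, 0.0, -plogp.sum(axis=1))

    # Spectral entropy of the normalized periodogram, in [0, 1].
    psd = np.abs(np.fft.rfft(w, axis=1)) ** 2
    total = psd.sum(axis=1)
    pos = total > 0
    q = psd / np.where(pos, total, 1.0)[:, None]
    with np.errstate(divide="ignore", invalid="ignore"):
        qlogq = np.where(q > 0, q * np.log2(np.where(q > 0, q, 1.0)), 0.0)
    n_bins = psd.shape[1]
    spectral = np.where(pos, -qlogq.sum(axis=1) / np.log2(n_bins), 0.0)

    return np.column_stack(
        [mean, std, mav, rms, skew, kurt, m2, mobility, complexity, shannon, spectral]
    )


def compute_features(window: np.ndarray, fs: float | None = None) -> np.ndarray:
    """Feature vector of one window, ordered as :data:`FEATURE_NAMES`.

    ``fs`` is accepted for interface symmetry; the features are either
    time-domain or expressed as rate-free ratios, so it does not enter
    the computation.
    """
    window = np.asarray(window, dtype=np.float64).ravel()
    if window.size < 3:
        raise ValidationError(f"window must have >= 3 samples, got {window.size}")
    if not np.all(np.isfinite(window)):
        raise ValidationError("window contains non-finite samples")
    return _feature_matrix(window[None, :])[0]


@dataclass
class FeatureTable:
    """Windows x (channel, feature) matrix with provenance.

    ``column_index`` is channel-major: for channel labels c1, c2, ... the
    columns are (c1, f1)...(c1, f11), (c2, f1)...; ``subject_labels``
    assigns each row (window) to the subject it came from.
    """

    matrix: np.ndarray = field(repr=False)
    column_index: tuple[tuple[str, str], ...]
    subject_labels: np.ndarray = field(repr=False)
    band: str

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.subject_labels = np.asarray(self.subject_labels)
        self.column_index = tuple((str(c), str(f)) for c, f in self.column_index)
        if self.matrix.ndim != 2 or self.matrix.shape[1] != len(self.column_index):
            raise ValidationError(
                f"matrix shape {self.matrix.shape} does not match {len(self.column_index)} columns"
            )
        if len(self.subject_labels) != self.matrix.shape[0]:
            raise ValidationError("one subject label per row required")
        if not np.all(np.isfinite(self.matrix)):
            raise ValidationError("feature matrix contains non-finite values")

    @property
    def n_windows(self) -> int:
        return self.matrix.shape[0]

    @property
    def channel_labels(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for chan, _ in self.column_index:
            seen.setdefault(chan, None)
        return tuple(seen)

    def columns_for_channel(self, label: str) -> np.ndarray:
        """Positional indices of all feature columns belonging to a channel."""
        idx = np.array([i for i, (c, _) in enumerate(self.column_index) if c == label])
        if idx.size == 0:
            raise KeyError(f"no columns for channel {label!r}")
        return idx

    def select_channels(self, labels: tuple[str, ...] | list[str]) -> "FeatureTable":
        """Sub-table restricted to the given channels, original order kept."""
        keep = [lab for lab in self.channel_labels if lab in set(labels)]
        cols = np.concatenate([self.columns_for_channel(lab) for lab in keep])
        return FeatureTable(
            matrix=self.matrix[:, cols],
            column_index=tuple(self.column_index[i] for i in cols),
            subject_labels=self.subject_labels.copy(),
            band=self.band,
        )

    def select_rows(self, rows: np.ndarray) -> "FeatureTable":
        return FeatureTable(
            matrix=self.matrix[rows],
            column_index=self.column_index,
            subject_labels=self.subject_labels[rows],
            band=self.band,
        )

    def to_dataframe(self) -> pd.DataFrame:
        cols = pd.MultiIndex.from_tuples(self.column_index, names=["channel", "feature"])
        return pd.DataFrame(self.matrix, columns=cols)


def build_feature_table(
    band_rec: EEGRecording, wspec: WindowSpec = WindowSpec(), band: str = "overall"
) -> FeatureTable:
    """Window one band-limited recording and extract all features.

    Row i holds every channel's features for window i (channel-major
    columns); the recording's subject id is replicated across rows.
    """
    windows = window_signal(band_rec, wspec)
    n_win = len(windows)
    labels = band_rec.channel_labels
    column_index = tuple((chan, feat) for chan in labels for feat in FEATURE_NAMES)
    if n_win == 0:
        matrix = np.empty((0, len(column_index)))
    else:
        stack = np.stack(windows)  # (n_win, C, L)
        blocks = [_feature_matrix(stack[:, c, :]) for c in range(len(labels))]
        matrix = np.hstack(blocks)
    return FeatureTable(
        matrix=matrix,
        column_index=column_index,
        subject_labels=np.repeat(band_rec.subject_id, n_win),
        band=band,
    )


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a table as an HDF5 matrix plus JSON column-index sidecar."""
    import json
    from pathlib import Path

    import h5py

    path = Path(path)
    with h5py.File(path, "w") as fh:
        fh.create_dataset("features", data=table.matrix)
    meta = {
        "band": table.band,
        "columns": [list(c) for c in table.column_index],
        "subjects": [s.item() if hasattr(s, "item") else s for s in table.subject_labels],
    }
    path.with_name(path.name + ".json").write_text(json.dumps(meta))


def read_feature_table(path) -> FeatureTable:
    """Read a table written by :func:`write_feature_table`."""
    import json
    from pathlib import Path

    import h5py

    from .exceptions import FormatError

    path = Path(path)
    sidecar = path.with_name(path.name + ".json")
    if not sidecar.exists():
        raise FormatError(f"missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    with h5py.File(path, "r") as fh:
        matrix = np.asarray(fh["features"])
    return FeatureTable(
        matrix=matrix,
        column_index=tuple(tuple(c) for c in meta["columns"]),
        subject_labels=np.asarray(meta["subjects"]),
        band=meta["band"],
    )


def concat_tables(tables: list[FeatureTable]) -> FeatureTable:
    """Stack per-subject tables that share a band and column layout."""
    if not tables:
        raise ValidationError("need at least one table to concatenate")
    first = tables[0]
    for t in tables[1:]:
        if t.column_index != first.column_index or t.band != first.band:
            raise ValidationError("tables differ in columns or band")
    return FeatureTable(
        matrix=np.vstack([t.matrix for t in tables]),
        column_index=first.column_index,
        subject_labels=np.concatenate([t.subject_labels for t in tables]),
        band=first.band,
    )
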