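"""Recording container and disk I/O.

An :class:`EEGRecording` is one subject's multichannel scalp recording:
a channels x samples matrix of potentials (µV) together with the sampling
rate and the ordered 10-10 electrode labels. Two on-disk layouts are
supported, both with a JSON metadata sidecar (``<file>.json``) carrying
``subject_id``, ``fs`` and ``labels``:

* an HDF5 container holding the matrix channels x samples (canonical), and
* delimited text (CSV) laid out samples x channels with a header row of
  10-10 labels, transposed on read.

Readers validate the label/row correspondence and reject non-finite
samples; writers never mutate their inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError

#: 32-channel actiCap montage in recording order (10-10 positions).
STANDARD_32_LABELS: tuple[str, ...] = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5",
    "FC1", "FC2", "FC6", "T7", "C3", "Cz", "C4", "T8",
    "TP9", "CP5", "CP1", "CP2", "CP6", "TP10", "P7", "P3",
    "Pz", "P4", "P8", "PO9", "O1", "Oz", "O2", "PO10",
)


def default_labels(n_channels: int) -> tuple[str, ...]:
    """Channel labels for an ``n_channels``-electrode montage.

    The standard 32-position set when it fits, padded/truncated with
    positional names otherwise.
    """
    if n_channels <= len(STANDARD_32_LABELS):
        return STANDARD_32_LABELS[:n_channels]
    extra = tuple(f"CH{i + 1:02d}" for i in range(len(STANDARD_32_LABELS), n_channels))
    return STANDARD_32_LABELS + extra


@dataclass
class EEGRecording:
    """One subject's multichannel EEG time series.

    Attributes
    ----------
    subject_id : int or str
        Cohort-unique subject identifier.
    fs : float
        Sampling rate in Hz, > 0.
    channel_labels : tuple of str
        Ordered, unique 10-10 position names, one per data row.
    data : ndarray, shape (n_channels, n_samples)
        Potentials in µV.
    """

    subject_id: int | str
    fs: float
    channel_labels: tuple[str, ...]
    data: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.channel_labels = tuple(self.channel_labels)
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.fs <= 0:
            raise ValidationError(f"fs must be > 0, got {self.fs}")
        if self.data.ndim != 2 or self.data.shape[1] < 1:
            raise ValidationError(
                f"data must be a channels x samples matrix with >= 1 sample, got shape {self.data.shape}"
            )
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValidationError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ValidationError("channel labels must be unique")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Recording length in seconds."""
        return self.n_samples / self.fs

    def with_data(self, data: np.ndarray) -> "EEGRecording":
        """Copy of this recording with ``data`` replaced (labels/fs kept)."""
        return replace(self, data=data)


def _sidecar_path(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def _check_finite(data: np.ndarray, where: str) -> None:
    if not np.all(np.isfinite(data)):
        raise ValidationError(f"non-finite samples in {where}")


def write_recording(rec: EEGRecording, path: str | Path) -> Path:
    """Write a recording plus its JSON sidecar; returns the matrix path.

    ``.csv`` paths get the delimited-text layout (samples x channels with a
    header of labels); anything else gets the HDF5 container with the
    matrix stored channels x samples under dataset ``"eeg"``.
    """
    path = Path(path)
    _check_finite(rec.data, "recording data")
    if path.suffix.lower() == ".csv":
        frame = pd.DataFrame(rec.data.T, columns=list(rec.channel_labels))
        frame.to_csv(path, index=False)
    else:
        with h5py.File(path, "w") as fh:
            fh.create_dataset("eeg", data=rec.data)
    sidecar = {
        "subject_id": rec.subject_id,
        "fs": rec.fs,
        "labels": list(rec.channel_labels),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> EEGRecording:
    """Read a recording written by :func:`write_recording`.

    Row order always follows the sidecar label order; for the CSV layout
    columns are matched to the sidecar by header label and transposed.
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such recording file: {path}")
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FormatError(f"missing JSON sidecar {sidecar_path}")
    meta = json.loads(sidecar_path.read_text())
    try:
        labels = [str(lab) for lab in meta["labels"]]
        fs = float(meta["fs"])
        subject_id = meta["subject_id"]
    except KeyError as exc:
        raise FormatError(f"sidecar {sidecar_path} lacks key {exc}") from exc

    if path.suffix.lower() == ".csv":
        frame = pd.read_csv(path)
        missing = [lab for lab in labels if lab not in frame.columns]
        if missing or len(frame.columns) != len(labels):
            raise ValidationError(
                f"CSV header {list(frame.columns)} does not match sidecar labels"
            )
        data = frame[labels].to_numpy(dtype=np.float64).T
    else:
        with h5py.File(path, "r") as fh:
            if "eeg" not in fh:
                raise FormatError(f"{path} has no 'eeg' dataset")
            data = np.asarray(fh["eeg"], dtype=np.float64)
        if data.shape[0] != len(labels):
            raise ValidationError(
                f"{len(labels)} sidecar labels for {data.shape[0]} matrix rows"
            )
    _check_finite(data, str(path))
    return EEGRecording(subject_id=subject_id, fs=fs, channel_labels=tuple(labels), data=data)
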