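"""The results bundle: one authentication + ablation run, serializable.

A :class:`ResultsBundle` is the pipeline's unit of output for one
(genuine subject, band) hypothesis: the full-montage benchmark accuracy,
the channel ranking, the tuned hyperparameters, and one record per
ablation step with accuracy and wall-clock times. Bundles round-trip
through a single versioned JSON document.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .exceptions import FormatError, ValidationError
from .model import ModelParams
from .reduction import AblationRecord, ChannelRanking

SCHEMA_VERSION = 1


@dataclass
class ResultsBundle:
    """Benchmark, ranking and per-ablation-step results for one run."""

    genuine_subject: object
    band: str
    benchmark_accuracy: float
    ranking: ChannelRanking
    steps: list[AblationRecord]
    tuned_params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.steps:
            raise ValidationError("a results bundle needs at least one ablation step")
        ns = [s.n_channels for s in self.steps]
        if any(b >= a for a, b in zip(ns, ns[1:])):
            raise ValidationError("steps must be ordered by strictly decreasing channel count")
        if abs(self.steps[0].accuracy - self.benchmark_accuracy) > 1e-12:
            raise ValidationError(
                "benchmark_accuracy must equal the accuracy of the full-montage step"
            )
        if not 0 <= self.benchmark_accuracy <= 1:
            raise ValidationError("benchmark_accuracy must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return self.steps[0].n_channels

    def accuracy_curve(self) -> tuple[np.ndarray, np.ndarray]:
        """(channel counts, accuracies) in recorded (descending-n) order."""
        return (
            np.array([s.n_channels for s in self.steps]),
            np.array([s.accuracy for s in self.steps]),
        )


def bundle_to_dict(bundle: ResultsBundle, include_timing: bool = True) -> dict:
    doc: dict = {
        "schema_version": SCHEMA_VERSION,
        "genuine_subject": bundle.genuine_subject,
        "band": bundle.band,
        "benchmark": bundle.benchmark_accuracy,
        "tuned_params": dict(bundle.tuned_params),
        "ranking": {
            "labels": list(bundle.ranking.labels),
            "importances": [float(v) for v in bundle.ranking.importances],
            "order": list(bundle.ranking.order),
        },
        "steps": [
            {
                "n_channels": s.n_channels,
                "channels_used": list(s.channels_used),
                "accuracy": s.accuracy,
            }
            for s in bundle.steps
        ],
        "times": {
            "train": [s.train_time for s in bundle.steps],
            "classify": [s.classify_time for s in bundle.steps],
        },
    }
    if include_timing:
        for step, s in zip(doc["steps"], bundle.steps):
            step["train_time"] = s.train_time
            step["classify_time"] = s.classify_time
    else:
        doc["times"] = {"train": [], "classify": []}
    return doc


def results_to_json(bundle: ResultsBundle, include_timing: bool = True) -> str:
    """Canonical JSON text for a bundle (sorted keys, stable floats)."""
    return json.dumps(bundle_to_dict(bundle, include_timing), sort_keys=True, indent=1)


def write_results(bundle: ResultsBundle, path: str | Path) -> Path:
    """Serialize a bundle to one JSON document."""
    path = Path(path)
    path.write_text(results_to_json(bundle))
    return path


def read_results(path: str | Path) -> ResultsBundle:
    """Read a bundle written by :func:`write_results`."""
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path} is not valid JSON: {exc}") from exc
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise FormatError(f"unknown results schema version {version!r}")
    ranking = ChannelRanking(
        labels=tuple(doc["ranking"]["labels"]),
        importances=np.array(doc["ranking"]["importances"]),
        order=tuple(doc["ranking"]["order"]),
        genuine_subject=doc["genuine_subject"],
        band=doc["band"],
    )
    times = doc.get("times", {"train": [], "classify": []})
    steps = []
    for i, s in enumerate(doc["steps"]):
        steps.append(
            AblationRecord(
                n_channels=int(s["n_channels"]),
                channels_used=tuple(s["channels_used"]),
                accuracy=float(s["accuracy"]),
                train_time=float(s.get("train_time", times["train"][i] if times["train"] else 0.0)),
                classify_time=float(
                    s.get("classify_time", times["classify"][i] if times["classify"] else 0.0)
                ),
            )
        )
    return ResultsBundle(
        genuine_subject=doc["genuine_subject"],
        band=doc["band"],
        benchmark_accuracy=float(doc["benchmark"]),
        ranking=ranking,
        steps=steps,
        tuned_params=dict(doc.get("tuned_params", {})),
    )
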