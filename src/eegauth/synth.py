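"""Seeded synthetic EEG cohorts with planted subject signatures.

Real multi-subject EEG is replaced by a controllable generative stand-in:
each subject's recording is a sum of five narrowband oscillations — one
per EEG rhythm (delta, theta, alpha, beta, gamma) — on every channel,
plus seeded pink (1/f) background noise. A small planted set of
"informative" channels carries subject-specific band amplitudes: on each
such channel the cohort's subjects occupy equally spaced amplitude
levels under a channel-specific permutation, so any single channel
identifies a subject only coarsely (adjacent levels are blurred by
noise) while the joint pattern across the planted set separates the
cohort cleanly. Every other channel uses one shared baseline amplitude
and frequency per band, identical across subjects, so it contributes no
identity information. This makes authentication accuracy and
channel-ranking recovery downstream properties of known ground truth.

Sinusoids (rather than filtered noise) are used for the narrowband
components so their spectral location is analytic and cheap to verify
with a periodogram. Everything is a pure function of the cohort spec and
its seeds; no trial/event structure is simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ParameterError, ValidationError
from .filters import SUB_BAND_NAMES, BAND_TABLE
from .io import EEGRecording, default_labels

#: Fraction of each band's width kept clear at both edges when drawing
#: oscillation frequencies, so components sit inside the filter pass-band.
_EDGE_MARGIN = 0.15


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition knobs for one synthetic cohort.

    Defaults emulate the acquisition setup the pipeline targets: 12
    subjects, 32 channels at 500 Hz. ``amp_spread`` controls how far a
    subject's informative-channel band amplitudes may deviate from the
    shared baseline (multiplier drawn from U(1-spread, 1+spread)), and
    ``noise_scale`` sets the total standard deviation of the pink
    background noise; together they set the difficulty dial for
    authentication and ranking recovery.
    """

    n_subjects: int = 12
    n_channels: int = 32
    fs: float = 500.0
    duration: float = 90.0
    seed: int = 0
    n_informative: int = 5
    informative_channels: tuple[int, ...] | None = None
    amp_baseline: float = 1.0
    amp_spread: float = 0.5
    noise_scale: float = 2.5

    def __post_init__(self) -> None:
        if self.n_subjects < 2 or self.n_channels < 2:
            raise ParameterError("need n_subjects >= 2 and n_channels >= 2")
        if self.fs <= 0 or self.duration * self.fs < 3:
            raise ParameterError("need fs > 0 and at least one window of samples")
        if self.amp_baseline < 0 or self.amp_spread < 0 or self.noise_scale < 0:
            raise ParameterError("amplitudes and noise_scale must be >= 0")
        info = self.resolve_informative()
        if not set(info) <= set(range(self.n_channels)):
            raise ParameterError(f"informative channels {info} outside 0..{self.n_channels - 1}")

    def resolve_informative(self) -> tuple[int, ...]:
        """The planted informative channel set (explicit or seeded draw)."""
        if self.informative_channels is not None:
            return tuple(sorted(self.informative_channels))
        if self.n_informative < 0:
            raise ParameterError("n_informative must be >= 0")
        size = min(self.n_informative, self.n_channels)
        rng = np.random.default_rng(np.random.SeedSequence([self.seed, 0xC0117]))
        picked = rng.choice(self.n_channels, size=size, replace=False)
        return tuple(sorted(int(i) for i in picked))

    @property
    def n_samples(self) -> int:
        return int(round(self.duration * self.fs))


def _band_freq_bounds(band: str) -> tuple[float, float]:
    bdef = BAND_TABLE[band]
    width = bdef.f_high - bdef.f_low
    return bdef.f_low + _EDGE_MARGIN * width, bdef.f_high - _EDGE_MARGIN * width


@dataclass
class SubjectProfile:
    """One subject's generative parameters.

    ``band_amplitudes`` and ``band_frequencies`` map each band name to a
    per-channel array; informative channels hold subject-specific draws,
    all other channels the cohort-shared baseline values.
    """

    subject_id: int
    band_amplitudes: dict[str, np.ndarray] = field(repr=False)
    band_frequencies: dict[str, np.ndarray] = field(repr=False)
    informative_channels: tuple[int, ...]
    noise_scale: float
    seed: int

    def __post_init__(self) -> None:
        for band, amps in self.band_amplitudes.items():
            if np.any(np.asarray(amps) < 0):
                raise ValidationError(f"negative amplitude in band {band}")
        if self.noise_scale < 0:
            raise ValidationError("noise_scale must be >= 0")


def make_subject_profile(subject_id: int, spec: CohortSpec, seed: int | None = None) -> SubjectProfile:
    """Deterministic per-subject generative profile.

    Baseline amplitudes/frequencies are drawn once from the cohort seed
    (identical for every subject); informative channels are overwritten
    with draws keyed by (seed, subject_id).
    """
    if not 0 <= subject_id < spec.n_subjects:
        raise ParameterError(
            f"subject_id {subject_id} out of range for a {spec.n_subjects}-subject cohort"
        )
    seed = spec.seed if seed is None else seed
    informative = spec.resolve_informative()
    shared_rng = np.random.default_rng(np.random.SeedSequence([seed, 0x5A5ED]))

    band_amplitudes: dict[str, np.ndarray] = {}
    band_frequencies: dict[str, np.ndarray] = {}
    info = np.asarray(informative, dtype=int)
    n_subj = spec.n_subjects
    for band in SUB_BAND_NAMES:
        lo, hi = _band_freq_bounds(band)
        # Shared baseline: one frequency per channel, common amplitude.
        amps = np.full(spec.n_channels, spec.amp_baseline)
        freqs = shared_rng.uniform(lo, hi, size=spec.n_channels)
        # Planted signature: on each informative channel the subjects take
        # equally spaced amplitude levels in baseline*(1 +/- amp_spread)
        # under a channel-specific permutation drawn from the cohort seed.
        # Adjacent levels are close relative to window-level noise, so one
        # channel identifies a subject only coarsely while the joint
        # pattern across the planted set separates the cohort cleanly.
        for chan in info:
            perm = shared_rng.permutation(n_subj)
            level = 2.0 * perm[subject_id] / (n_subj - 1) - 1.0 if n_subj > 1 else 0.0
            amps[chan] = spec.amp_baseline * (1.0 + spec.amp_spread * level)
        band_amplitudes[band] = amps
        band_frequencies[band] = freqs
    return SubjectProfile(
        subject_id=subject_id,
        band_amplitudes=band_amplitudes,
        band_frequencies=band_frequencies,
        informative_channels=informative,
        noise_scale=spec.noise_scale,
        seed=seed,
    )


def _pink_noise(rng: np.random.Generator, n_channels: int, n_samples: int, scale: float) -> np.ndarray:
    """1/f-spectrum noise, unit std per channel before scaling."""
    if scale == 0:
        return np.zeros((n_channels, n_samples))
    white = rng.standard_normal((n_channels, n_samples))
    spectrum = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    pink = np.fft.irfft(spectrum * shaping, n=n_samples, axis=1)
    # Normalize by the analytic expected per-sample variance rather than
    # the realized std: the realized total power is dominated by a handful
    # of low-frequency bins and fluctuates strongly between realizations,
    # which would imprint a spurious per-realization power signature on
    # every band.
    weights = np.full_like(shaping, 2.0)
    weights[0] = 1.0
    if n_samples % 2 == 0:
        weights[-1] = 1.0
    expected_std = np.sqrt(np.sum(weights * shaping**2) / n_samples)
    return scale * pink / expected_std


def generate_recording(profile: SubjectProfile, spec: CohortSpec) -> EEGRecording:
    """Render one subject's channels x samples recording.

    Each band contributes ``amp * sin(2*pi*f*t + phase)`` per channel
    (phases seeded per subject), summed with pink background noise.
    Bit-identical for identical (profile, spec).
    """
    n = spec.n_samples
    t = np.arange(n) / spec.fs
    rng = np.random.default_rng(np.random.SeedSequence([profile.seed, 1000 + profile.subject_id]))
    data = np.zeros((spec.n_channels, n))
    for band in SUB_BAND_NAMES:
        amps = profile.band_amplitudes[band][:, None]
        freqs = profile.band_frequencies[band][:, None]
        phases = rng.uniform(0, 2 * np.pi, size=(spec.n_channels, 1))
        data += amps * np.sin(2 * np.pi * freqs * t[None, :] + phases)
    data += _pink_noise(rng, spec.n_channels, n, profile.noise_scale)
    return EEGRecording(
        subject_id=profile.subject_id,
        fs=spec.fs,
        channel_labels=default_labels(spec.n_channels),
        data=data,
    )


def generate_cohort(spec: CohortSpec) -> list[EEGRecording]:
    """One recording per subject, fully determined by the spec."""
    return [
        generate_recording(make_subject_profile(sid, spec), spec)
        for sid in range(spec.n_subjects)
    ]
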