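"""Temporal filtering, montage selection and epoching for motor-imagery EEG.

The pipeline expects continuous multichannel recordings in microvolts with
10-20 system channel labels and per-trial cue events.  All temporal filters
are zero-phase FIR (windowed-sinc, Hamming window) applied forward-backward,
so no group delay is introduced and the effective magnitude response is the
square of the single-pass design.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy import signal

__all__ = [
    "MultichannelRecording",
    "ChannelScheme",
    "TrialSet",
    "EIGHT_CHANNEL_SCHEME",
    "NINE_CHANNEL_SCHEME",
    "bandpass_filter",
    "notch_filter",
    "select_channels",
    "epoch_trials",
]

VALID_CLASSES = (1, 2, 3)


class InvalidParameterError(ValueError):
    """A filter band edge or window parameter is outside its legal range."""


class ChannelNotFoundError(KeyError):
    """A channel-scheme label is absent from the recording."""


@dataclass(frozen=True)
class ChannelScheme:
    """An ordered electrode montage (subset of the 10-20 system)."""

    name: str
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(set(self.labels)) != len(self.labels):
            raise InvalidParameterError(f"scheme {self.name!r} has duplicate labels")


EIGHT_CHANNEL_SCHEME = ChannelScheme(
    "eight", ("FP1", "FP2", "C3", "Cz", "C4", "O1", "Oz", "O2")
)
NINE_CHANNEL_SCHEME = ChannelScheme(
    "nine", ("FC3", "FCz", "FC4", "C3", "Cz", "C4", "CP3", "CPz", "CP4")
)


@dataclass
class MultichannelRecording:
    """Continuous labeled EEG: samples (n_channels x n_samples, microvolts),
    sampling rate, channel labels, and (onset_sample, class_label) events."""

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        self.channel_labels = list(self.channel_labels)
        if self.fs <= 0:
            raise InvalidParameterError(f"sampling rate must be positive, got {self.fs}")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise InvalidParameterError(
                f"{len(self.channel_labels)} labels for {self.samples.shape[0]} channels"
            )
        self.events = [(int(o), int(l)) for o, l in self.events]
        onsets = [o for o, _ in self.events]
        if any(b <= a for a, b in zip(onsets, onsets[1:])):
            raise InvalidParameterError("event onsets must be strictly increasing")
        if onsets and (onsets[0] < 0 or onsets[-1] >= self.n_samples):
            raise InvalidParameterError("event onsets outside sample range")
        for _, lab in self.events:
            if lab not in VALID_CLASSES:
                raise InvalidParameterError(f"event label {lab} not in {VALID_CLASSES}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class TrialSet:
    """Epoched trials (each n_channels x n_trial_samples) with class labels.

    ``trial_index`` keeps the original 1-based position of each trial in its
    run so that selection reports can refer to e.g. "the 43rd trial".
    ``window`` is the epoch extent in seconds relative to the cue.
    """

    trials: list[np.ndarray]
    labels: np.ndarray
    trial_index: np.ndarray
    window: tuple[float, float]
    fs: float
    channel_labels: list[str]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.trial_index = np.asarray(self.trial_index, dtype=int)
        if len(self.trials) != len(self.labels):
            raise InvalidParameterError("one label per trial required")
        if len(self.trials) != len(self.trial_index):
            raise InvalidParameterError("one trial_index per trial required")
        shapes = {t.shape for t in self.trials}
        if len(shapes) > 1:
            raise InvalidParameterError(f"trials differ in shape: {shapes}")
        if self.labels.size and not np.isin(self.labels, VALID_CLASSES).all():
            raise InvalidParameterError("labels must be in {1, 2, 3}")

    def __len__(self) -> int:
        return len(self.trials)

    @property
    def n_channels(self) -> int:
        return self.trials[0].shape[0] if self.trials else len(self.channel_labels)

    def subset(self, indices: Sequence[int]) -> "TrialSet":
        """New TrialSet restricted to the given positional indices."""
        idx = list(indices)
        return TrialSet(
            trials=[self.trials[i] for i in idx],
            labels=self.labels[idx],
            trial_index=self.trial_index[idx],
            window=self.window,
            fs=self.fs,
            channel_labels=self.channel_labels,
        )


# --------------------------------------------------------------------------
# FIR design.  Transition width 2 Hz for the band-pass (0.5 Hz for the
# notch); the -6 dB cutoffs are placed half a transition band outside the
# requested passband so the passband edges themselves stay near unity gain.

def _odd(n: int) -> int:
    return n if n % 2 else n + 1


@lru_cache(maxsize=32)
def bandpass_taps(low: float, high: float, fs: float, width: float = 2.0) -> np.ndarray:
    """Hamming windowed-sinc band-pass coefficients for [low, high] Hz."""
    numtaps = _odd(int(np.ceil(3.3 * fs / width)))
    return signal.firwin(
        numtaps,
        [low - width / 2.0, high + width / 2.0],
        pass_zero=False,
        window="hamming",
        fs=fs,
    )


@lru_cache(maxsize=32)
def notch_taps(freq: float, fs: float, half_width: float = 1.0,
               trans: float = 0.5) -> np.ndarray:
    numtaps = _odd(int(np.ceil(3.3 * fs / trans)))
    return signal.firwin(
        numtaps,
        [freq - half_width, freq + half_width],
        pass_zero=True,
        window="hamming",
        fs=fs,
    )


def zero_phase(taps: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Forward-backward FIR filtering with reflect padding of one filter length."""
    padlen = min(len(taps), x.shape[-1] - 1)
    return signal.filtfilt(taps, 1.0, x, axis=-1, padlen=padlen)


def bandpass_filter(rec: MultichannelRecording, low: float, high: float) -> MultichannelRecording:
    """Zero-phase FIR band-pass (e.g. the 8-30 Hz mu/beta band)."""
    nyq = rec.fs / 2.0
    if not (0 < low < high) or high + 1.0 >= nyq:
        raise InvalidParameterError(
            f"band ({low}, {high}) Hz invalid for Nyquist {nyq} Hz"
        )
    taps = bandpass_taps(low, high, rec.fs)
    return replace(rec, samples=zero_phase(taps, rec.samples))


def notch_filter(rec: MultichannelRecording, freq: float = 50.0) -> MultichannelRecording:
    """Zero-phase narrow FIR band-stop at the power-line frequency."""
    nyq = rec.fs / 2.0
    if not (0 < freq) or freq + 1.5 >= nyq:
        raise InvalidParameterError(f"notch {freq} Hz invalid for Nyquist {nyq} Hz")
    taps = notch_taps(freq, rec.fs)
    return replace(rec, samples=zero_phase(taps, rec.samples))


def select_channels(rec: MultichannelRecording, scheme: ChannelScheme) -> MultichannelRecording:
    """Reorder/subset recording rows to a montage (pure row permutation)."""
    try:
        rows = [rec.channel_labels.index(lab) for lab in scheme.labels]
    except ValueError as exc:
        missing = [l for l in scheme.labels if l not in rec.channel_labels]
        raise ChannelNotFoundError(
            f"channels {missing} of scheme {scheme.name!r} not in recording"
        ) from exc
    return MultichannelRecording(
        samples=rec.samples[rows],
        fs=rec.fs,
        channel_labels=list(scheme.labels),
        events=list(rec.events),
    )


def epoch_trials(rec: MultichannelRecording, window: tuple[float, float]) -> TrialSet:
    """Cut one trial per event.  Windows are half-open [start, end) in samples,
    relative to the cue onset; trial length is round((end-start)*fs)."""
    t0, t1 = window
    if t1 <= t0:
        raise InvalidParameterError(f"empty epoch window {window}")
    n_len = int(round((t1 - t0) * rec.fs))
    onsets = [o for o, _ in rec.events]
    if len(onsets) > 1:
        min_gap = min(b - a for a, b in zip(onsets, onsets[1:]))
        if n_len > min_gap:
            raise InvalidParameterError(
                f"epoch length {n_len} samples exceeds inter-event spacing {min_gap}"
            )
    trials, labels = [], []
    for onset, lab in rec.events:
        start = onset + int(round(t0 * rec.fs))
        stop = start + n_len
        if start < 0 or stop > rec.n_samples:
            raise InvalidParameterError(
                f"epoch [{start}, {stop}) outside recording of {rec.n_samples} samples"
            )
        trials.append(rec.samples[:, start:stop].copy())
        labels.append(lab)
    return TrialSet(
        trials=trials,
        labels=np.asarray(labels, dtype=int),
        trial_index=np.arange(1, len(trials) + 1),
        window=(t0, t1),
        fs=rec.fs,
        channel_labels=list(rec.channel_labels),
    )
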