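"""Forward-model simulator of three-class motor-imagery EEG.

Sensors are an instantaneous mixture x = A_true s of N sources:

* three motor-related sources with unimodal Gaussian scalp profiles
  centered on C3, Cz and C4 (width one inter-electrode spacing over a 2-D
  montage layout), carried by amplitude-modulated band-limited Gaussian
  noise in the subject band (the modulation makes them super-Gaussian, as
  real mu bursts are);
* N-3 background sources with random smooth topographies and 1/f-shaped
  broadband spectra.

Event-related desynchronization is simulated by attenuating the band power
of exactly one motor source during each trial's imagery window, following
the contralateral rule the zero-training classifier assumes: left-hand
trials (class 1) attenuate the C4 source, right-hand (class 2) the C3
source, foot (class 3) the Cz source.  White sensor noise at a configurable
SNR, plus optional eye-blink, occipital-alpha and broadband burst
artifacts, complete the model.  All randomness derives from one seed.
"""
from __future__ import annotations

import copy
import json
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import signal

from .mric import DetectionFilterSet
from .preprocessing import (EIGHT_CHANNEL_SCHEME, NINE_CHANNEL_SCHEME,
                            MultichannelRecording, bandpass_taps, zero_phase)

__all__ = ["SimConfig", "ArtifactSpec", "SyntheticGroundTruth",
           "generate_dataset", "inject_burst", "oracle_filters"]

#: Approximate 2-D layout of the 10-20 electrodes used by the two montages
#: (x: left-negative, y: anterior-positive; inter-electrode spacing 0.5).
ELECTRODE_XY = {
    "FP1": (-0.4, 1.0), "FP2": (0.4, 1.0),
    "FC3": (-0.5, 0.5), "FCz": (0.0, 0.5), "FC4": (0.5, 0.5),
    "C3": (-0.5, 0.0), "Cz": (0.0, 0.0), "C4": (0.5, 0.0),
    "CP3": (-0.5, -0.5), "CPz": (0.0, -0.5), "CP4": (0.5, -0.5),
    "O1": (-0.4, -1.0), "Oz": (0.0, -1.0), "O2": (0.4, -1.0),
}

SPACING = 0.5  # inter-electrode spacing in layout units

#: Gaussian profile width: FWHM of one inter-electrode spacing, so each
#: motor source projects essentially onto its own electrode neighborhood
#: and the mixing matrix stays well conditioned.
PROFILE_SIGMA = SPACING / 2.355

#: Contralateral ERD: class -> motor channel whose source is attenuated.
ERD_TARGET = {1: "C4", 2: "C3", 3: "Cz"}

SENSOR_SCALE_UV = 10.0  # nominal microvolt scale of the mixed signal


@dataclass(frozen=True)
class ArtifactSpec:
    """One artifact family: kind 'blink' | 'alpha' | 'burst', events per
    trial (rate), amplitude in multiples of the clean channel std, and the
    1-based target trials (None = all trials eligible)."""

    kind: str
    rate: float = 1.0
    amplitude: float = 15.0
    trials: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("blink", "alpha", "burst"):
            raise ValueError(f"unknown artifact kind {self.kind!r}")
        if self.rate < 0:
            raise ValueError("artifact rate must be >= 0")


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated run: 8- or 9-channel montage,
    250 Hz, 10 s trials, 25 trials per class, ERD power ratio erd_depth
    during the imagery window, and sensor noise at snr_db."""

    n_channels: int = 9
    fs: float = 250.0
    trial_s: float = 10.0
    n_trials_per_class: int = 25
    erd_depth: float = 0.5
    snr_db: float = 10.0
    subject_band: tuple[float, float] = (10.0, 14.0)
    imagery_window: tuple[float, float] = (0.5, 5.0)
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_channels not in (8, 9):
            raise ValueError("n_channels must be 8 or 9 (the montage schemes)")
        if not (0 < self.erd_depth <= 1):
            raise ValueError("erd_depth must lie in (0, 1]")
        if self.n_trials_per_class < 1:
            raise ValueError("need at least one trial per class")

    @property
    def scheme(self):
        return NINE_CHANNEL_SCHEME if self.n_channels == 9 else EIGHT_CHANNEL_SCHEME

    @property
    def n_trials(self) -> int:
        return 3 * self.n_trials_per_class


@dataclass
class SyntheticGroundTruth:
    """Everything the simulator knows that an analyst would not."""

    A_true: np.ndarray
    source_roles: dict[str, int]       # 'C3'/'Cz'/'C4' -> source index
    labels: np.ndarray                 # class per trial
    artifact_trials: set[int] = field(default_factory=set)  # 1-based
    erd_windows: list[tuple[float, float]] = field(default_factory=list)
    channel_labels: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps({
            "A_true": self.A_true.tolist(),
            "source_roles": self.source_roles,
            "labels": self.labels.tolist(),
            "artifact_trials": sorted(self.artifact_trials),
            "erd_windows": self.erd_windows,
            "channel_labels": self.channel_labels,
        }, indent=1)


def _gaussian_profile(labels: list[str], center: str, width: float) -> np.ndarray:
    cx, cy = ELECTRODE_XY[center]
    out = np.array([
        math.exp(-((x - cx) ** 2 + (y - cy) ** 2) / (2 * width ** 2))
        for x, y in (ELECTRODE_XY[l] for l in labels)
    ])
    return out / np.linalg.norm(out)


def _background_profiles(labels: list[str], n: int,
                         rng: np.random.Generator,
                         forbidden_rows: set[int]) -> np.ndarray:
    """Topographies of the n background sources: each is a jittered Gaussian
    patch under a distinct non-motor electrode (diverse centers keep the
    mixing matrix well conditioned, as distinct cortical patches would)."""
    centers = [i for i in range(len(labels)) if i not in forbidden_rows]
    if n > len(centers):
        raise RuntimeError("more background sources than non-motor electrodes")
    order = rng.permutation(len(centers))[:n]
    cols = np.empty((len(labels), n))
    for k, ci in enumerate(order):
        width = PROFILE_SIGMA * float(rng.uniform(1.0, 1.6))
        col = _gaussian_profile(labels, labels[centers[ci]], width)
        col += 0.05 * rng.standard_normal(len(labels))
        cols[:, k] = col / np.linalg.norm(col)
    return cols


def _am_envelope(T: int, fs: float, rng: np.random.Generator,
                 depth: float = 0.5, cutoff: float = 0.5) -> np.ndarray:
    """Slow positive envelope 1 + depth*z, z ~ low-passed unit noise."""
    z = rng.standard_normal(T)
    b, a = signal.butter(2, cutoff / (fs / 2))
    z = signal.filtfilt(b, a, z)
    z /= max(z.std(), 1e-12)
    return np.clip(1.0 + depth * z, 0.1, None)


def _band_carrier(T: int, fs: float, band: tuple[float, float],
                  rng: np.random.Generator) -> np.ndarray:
    """Quasi-continuous narrow-band oscillation with random phase structure.

    Band-limited Gaussian noise is amplitude-stabilized (divided by its
    smoothed Hilbert envelope): raw band noise has ~1/sqrt(BT) window-power
    fluctuation, which at B = 4 Hz would rival the ERD contrast itself,
    whereas an ongoing mu rhythm keeps a far steadier amplitude (and is
    mildly sub-Gaussian, like real alpha/mu).  The AM envelope applied on
    top restores realistic waxing and waning at a controlled depth.
    """
    taps = bandpass_taps(band[0], band[1], fs)
    x = zero_phase(taps, rng.standard_normal(T))
    amp = np.abs(signal.hilbert(x))
    b, a = signal.butter(2, 2.0 / (fs / 2))
    amp = signal.filtfilt(b, a, amp)
    x = x / np.clip(amp, 0.1 * np.median(amp), None)
    return x / max(x.std(), 1e-12)


def _one_over_f(T: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    spec = np.fft.rfft(rng.standard_normal(T))
    f = np.fft.rfftfreq(T, 1 / fs)
    spec /= np.sqrt(f + 1.0)
    x = np.fft.irfft(spec, n=T)
    return x / max(x.std(), 1e-12)


def _erd_gate(T: int, fs: float, onsets: np.ndarray, mask: np.ndarray,
              window: tuple[float, float], depth: float,
              ramp_s: float = 0.2) -> np.ndarray:
    """Multiplicative gain: sqrt(depth) inside each masked trial's imagery
    window (power ratio = depth), with raised-cosine ramps."""
    gate = np.ones(T)
    n_ramp = int(round(ramp_s * fs))
    ramp = 0.5 * (1 - np.cos(np.linspace(0, np.pi, max(n_ramp, 2))))
    gain = math.sqrt(depth)
    for onset, on in zip(onsets, mask):
        if not on:
            continue
        i0 = onset + int(round(window[0] * fs))
        i1 = onset + int(round(window[1] * fs))
        gate[i0:i1] = gain
        up = min(n_ramp, i1 - i0)
        gate[i0:i0 + up] = 1 + (gain - 1) * ramp[:up]
        gate[i1 - up:i1] = gain + (1 - gain) * ramp[:up]
    return gate


def _blink_pulse(fs: float) -> np.ndarray:
    """Biphasic ~0.4 s pulse (derivative-of-Gaussian), unit peak."""
    t = np.arange(int(0.4 * fs)) / fs - 0.2
    p = -t * np.exp(-t ** 2 / (2 * 0.07 ** 2))
    return p / np.abs(p).max()


def generate_dataset(cfg: SimConfig) -> tuple[MultichannelRecording, SyntheticGroundTruth]:
    """Simulate one run and return it with its ground truth."""
    rng = np.random.default_rng(cfg.seed)
    labels_ch = list(cfg.scheme.labels)
    N = cfg.n_channels
    n_trial = int(round(cfg.trial_s * cfg.fs))
    L = cfg.n_trials
    T = L * n_trial
    onsets = np.arange(L) * n_trial

    # class labels: 25 per class, shuffled
    y = np.repeat([1, 2, 3], cfg.n_trials_per_class)
    rng.shuffle(y)

    # mixing matrix: 3 motor columns + N-3 background columns
    motor_rows = {c: labels_ch.index(c) for c in ("C3", "Cz", "C4")}
    A = np.zeros((N, N))
    roles = {}
    for j, chan in enumerate(("C3", "Cz", "C4")):
        A[:, j] = _gaussian_profile(labels_ch, chan, PROFILE_SIGMA)
        roles[chan] = j
    forbidden = set(motor_rows.values())
    A[:, 3:] = _background_profiles(labels_ch, N - 3, rng, forbidden)
    # guard conditioning so oracle filters do not amplify sensor noise
    while np.linalg.cond(A) > 30:
        A[:, 3:] = _background_profiles(labels_ch, N - 3, rng, forbidden)

    # sources
    S = np.zeros((N, T))
    for chan, j in roles.items():
        carrier = _band_carrier(T, cfg.fs, cfg.subject_band, rng)
        # envelope fast enough (5 Hz) that window-averaged band power is
        # stable across trials relative to the ERD contrast
        env = _am_envelope(T, cfg.fs, rng, depth=0.4, cutoff=5.0)
        src = carrier * env
        src /= src.std()
        gate = _erd_gate(T, cfg.fs, onsets, np.array([ERD_TARGET[c] == chan for c in y]),
                         cfg.imagery_window, cfg.erd_depth)
        S[j] = src * gate
    for j in range(3, N):
        src = _one_over_f(T, cfg.fs, rng) * _am_envelope(T, cfg.fs, rng, depth=0.3)
        S[j] = src / src.std()

    X = A @ S
    sig_power = float(np.mean(X ** 2))
    noise_sd = math.sqrt(sig_power / 10 ** (cfg.snr_db / 10))
    X = X + noise_sd * rng.standard_normal(X.shape)
    X *= SENSOR_SCALE_UV

    events = [(int(o), int(lab)) for o, lab in zip(onsets, y)]
    rec = MultichannelRecording(samples=X, fs=cfg.fs, channel_labels=labels_ch,
                                events=events)
    gt = SyntheticGroundTruth(
        A_true=A, source_roles=roles, labels=y,
        erd_windows=[cfg.imagery_window] * L, channel_labels=labels_ch,
    )

    for spec in cfg.artifacts:
        rec = _apply_artifact(rec, gt, spec, cfg, rng)
    return rec, gt


def _posterior_channels(labels: list[str]) -> list[int]:
    ys = [ELECTRODE_XY[l][1] for l in labels]
    ymin = min(ys)
    return [i for i, v in enumerate(ys) if v == ymin]


def _frontal_channels(labels: list[str]) -> list[int]:
    ys = [ELECTRODE_XY[l][1] for l in labels]
    ymax = max(ys)
    return [i for i, v in enumerate(ys) if v == ymax]


def _apply_artifact(rec: MultichannelRecording, gt: SyntheticGroundTruth,
                    spec: ArtifactSpec, cfg: SimConfig,
                    rng: np.random.Generator) -> MultichannelRecording:
    n_trial = int(round(cfg.trial_s * cfg.fs))
    trials = list(spec.trials) if spec.trials is not None else list(
        range(1, cfg.n_trials + 1))
    X = rec.samples  # modified in place; rec already owns this array
    ch_std = X.std(axis=1)
    if spec.kind == "burst":
        for t in trials:
            dur = float(rng.uniform(0.5, 1.0))
            t0 = float(rng.uniform(0.0, cfg.trial_s - dur))
            # movement/cable bursts hit several electrodes at once with
            # independent waveforms (no fixed topography, so no single IC
            # can absorb them); a strict subset of the montage leaves the
            # mixture rank-deficient for ICA and reliably corrupts the fit
            N = rec.n_channels
            lo = (N + 1) // 2
            n_ch = int(rng.integers(lo, max(lo, N - 2) + 1))
            chans = sorted(rng.choice(N, size=n_ch, replace=False))
            rec = inject_burst(rec, t, t0, dur, spec.amplitude, chans,
                               trial_s=cfg.trial_s, rng=rng, ground_truth=gt)
        return rec
    if spec.kind == "blink":
        rows, wave = _frontal_channels(rec.channel_labels), _blink_pulse(cfg.fs)
    else:  # alpha: 10 Hz posterior bursts of ~1.5 s
        rows = _posterior_channels(rec.channel_labels)
        t = np.arange(int(1.5 * cfg.fs)) / cfg.fs
        wave = np.sin(2 * np.pi * 10.0 * t) * np.hanning(t.size)
    for trial in trials:
        n_events = rng.poisson(spec.rate)
        for _ in range(n_events):
            start = (trial - 1) * n_trial + int(rng.integers(0, n_trial - wave.size))
            for r in rows:
                X[r, start:start + wave.size] += spec.amplitude * ch_std[r] * wave
    # physiological artifacts are deliberately NOT flagged in artifact_trials:
    # the burst (non-physiological) family is what degrades the ICA filters
    return rec


def inject_burst(rec: MultichannelRecording, trial_idx: int, t0: float,
                 dur: float, amp: float, channels, *, trial_s: float = 10.0,
                 rng: np.random.Generator | None = None, seed: int = 0,
                 ground_truth: SyntheticGroundTruth | None = None,
                 ) -> MultichannelRecording:
    """Add a broadband high-amplitude transient to one trial.

    The burst is white noise shaped by a Tukey taper whose RMS amplitude is
    ``amp`` multiples of each target channel's standard deviation (so its
    peaks reach roughly 3 amp channel-stds), starting ``t0`` seconds into
    1-based trial ``trial_idx``.  The ground truth's artifact_trials set is
    updated when provided.
    """
    rng = rng if rng is not None else np.random.default_rng(seed)
    n_trial = int(round(trial_s * rec.fs))
    n_trials_total = rec.n_samples // n_trial
    if not (1 <= trial_idx <= n_trials_total):
        raise ValueError(f"trial {trial_idx} outside 1..{n_trials_total}")
    if t0 < 0 or t0 + dur > trial_s:
        raise ValueError(f"burst window ({t0}, {t0 + dur}) outside the trial")
    n_burst = int(round(dur * rec.fs))
    start = (trial_idx - 1) * n_trial + int(round(t0 * rec.fs))
    out = copy.deepcopy(rec)
    if amp == 0 or n_burst == 0:
        return out
    taper = signal.windows.tukey(n_burst, alpha=0.5)
    for ch in channels:
        sd = rec.samples[ch].std()
        noise = rng.standard_normal(n_burst) * taper
        noise /= max(np.sqrt(np.mean(noise ** 2)), 1e-12)
        out.samples[ch, start:start + n_burst] += amp * sd * noise
    if ground_truth is not None:
        ground_truth.artifact_trials.add(int(trial_idx))
    return out


def oracle_filters(gt: SyntheticGroundTruth) -> DetectionFilterSet:
    """Ground-truth detection filters: the MRIC rows of inv(A_true)."""
    W = np.linalg.inv(gt.A_true)
    return DetectionFilterSet(
        w_l=W[gt.source_roles["C3"]],
        w_f=W[gt.source_roles["Cz"]],
        w_r=W[gt.source_roles["C4"]],
        channel_labels=list(gt.channel_labels),
        origin="oracle",
    )
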