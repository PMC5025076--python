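"""Motor-related IC detection, zero-training classification, and the
two-round trial selection that optimizes the ICA spatial filters.

Motor imagery desynchronizes the mu rhythm over the contralateral primary
motor cortex: left-hand imagery depresses band power under C4, right-hand
under C3, and foot imagery near Cz.  A motor-related independent component
(MRIC) is therefore an ICA source whose spatial pattern (column of the
mixing matrix A) projects maximally onto one of C3, Cz, C4.  The W-rows of
the three MRICs form detection filters (w_l for the C3-dominant,
left-hemisphere source; w_r for C4; w_f for Cz), and a parameter-free
classifier assigns the class whose contralateral MRIC has minimum band
variance in the analysis window:

    V = min( var(u_l), var(u_r), var(u_f) )
    class 1 (left hand)  if V = var(u_r)
    class 2 (right hand) if V = var(u_l)
    class 3 (foot)       if V = var(u_f)

Trial selection is two-round: round one keeps trials whose single-trial ICA
mixing matrix contains three distinct columns peaking (in magnitude) at C3,
Cz and C4; round two keeps trials whose single-trial-BCI training accuracy
R_j reaches the mean of the nonzero accuracies.  The surviving top-m trials
are concatenated for one final ICA fit (ICA-T); a 10-trial sliding window
(ICA-S) serves as the unoptimized baseline.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .infomax import IcaConfig, IcaError, MixingModel, apply_filters, fit_ica
from .preprocessing import TrialSet, bandpass_taps, zero_phase

__all__ = [
    "MRICAssignment",
    "DetectionFilterSet",
    "SelectionReport",
    "match_mrics",
    "first_round_select",
    "classify_trial",
    "evaluate_filters",
    "second_round_select",
    "build_ica_t",
    "build_ica_s",
    "affected_windows",
    "band_window_covariances",
    "two_round_select",
]

log = logging.getLogger(__name__)

MOTOR_CHANNELS = ("C3", "Cz", "C4")

#: ERD is contralateral: minimum band variance of the C4 source (u_r) means
#: left-hand imagery (class 1), of the C3 source (u_l) right-hand (class 2),
#: of the Cz source (u_f) foot (class 3).  Ties resolve in this order.
_MIN_VAR_CLASS = (("r", 1), ("l", 2), ("f", 3))


class MatchingError(RuntimeError):
    """MRIC topography matching failed where a match was required."""


@dataclass(frozen=True)
class MRICAssignment:
    """Which mixing-matrix columns (0-based) are the C3/Cz/C4 MRICs."""

    ic_C3: int | None
    ic_Cz: int | None
    ic_C4: int | None
    matched: bool

    def indices(self) -> tuple[int, int, int]:
        if not self.matched:
            raise MatchingError("assignment is unmatched")
        return (self.ic_C3, self.ic_Cz, self.ic_C4)  # type: ignore[return-value]


@dataclass
class DetectionFilterSet:
    """The three MRIC spatial filters.

    w_l filters the C3-dominant (left-hemisphere) source, w_r the
    C4-dominant, w_f the Cz-dominant.  ``origin`` records the 1-based trial
    index (or segment/window identifier) the filters were fitted on.
    """

    w_l: np.ndarray
    w_f: np.ndarray
    w_r: np.ndarray
    channel_labels: list[str]
    origin: object = None

    def __post_init__(self) -> None:
        for name in ("w_l", "w_f", "w_r"):
            v = np.asarray(getattr(self, name), dtype=float).ravel()
            if v.size != len(self.channel_labels) or not np.all(np.isfinite(v)):
                raise ValueError(f"{name} must be a finite length-N row")
            setattr(self, name, v)

    @property
    def matrix(self) -> np.ndarray:
        """Rows stacked in (w_l, w_f, w_r) order."""
        return np.vstack([self.w_l, self.w_f, self.w_r])

    def to_json(self) -> str:
        return json.dumps({
            "channel_labels": self.channel_labels,
            "w_l": self.w_l.tolist(),
            "w_f": self.w_f.tolist(),
            "w_r": self.w_r.tolist(),
            "origin": self.origin if not isinstance(self.origin, np.ndarray)
            else self.origin.tolist(),
        }, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "DetectionFilterSet":
        d = json.loads(text)
        return cls(w_l=np.asarray(d["w_l"]), w_f=np.asarray(d["w_f"]),
                   w_r=np.asarray(d["w_r"]),
                   channel_labels=list(d["channel_labels"]),
                   origin=d.get("origin"))


@dataclass
class SelectionReport:
    """Per-trial record of the two-round selection.

    ``accuracies`` holds R_j for round-one good trials and 0.0 for bad ones
    (bad trials are plotted/exported as zeros but excluded from the
    threshold mean).  All trial indices are 1-based run positions.
    """

    trial_index: np.ndarray
    round1_label: list[str]
    accuracies: np.ndarray
    threshold: float | None = None
    kept_trials: list[int] = field(default_factory=list)
    top_m: list[int] = field(default_factory=list)

    @property
    def good_trials(self) -> list[int]:
        return [int(t) for t, lab in zip(self.trial_index, self.round1_label)
                if lab == "good"]

    @property
    def n_good(self) -> int:
        return len(self.good_trials)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "trial_index": self.trial_index,
            "round1_label": self.round1_label,
            "R_j": self.accuracies,
            "kept": [int(t) in self.kept_trials for t in self.trial_index],
            "in_top_m": [int(t) in self.top_m for t in self.trial_index],
        })

    def to_json(self) -> str:
        return json.dumps({
            "P": self.n_good,
            "threshold": self.threshold,
            "kept_trials": list(map(int, self.kept_trials)),
            "top_m": list(map(int, self.top_m)),
        }, indent=1)


# --------------------------------------------------------------------------
# First round: topography matching on the mixing matrix.

def match_mrics(A: np.ndarray, labels: list[str] | tuple[str, ...]) -> MRICAssignment:
    """Find the three A-columns whose largest-|entry| row is C3, Cz, C4.

    For each target electrode, candidate columns are those whose dominant
    electrode is the target; among several candidates the one with the
    largest magnitude at the target wins.  The assignment is matched only if
    all three targets receive (necessarily distinct) columns.
    """
    labels = list(labels)
    missing = [c for c in MOTOR_CHANNELS if c not in labels]
    if missing:
        raise MatchingError(f"channel labels lack {missing}; cannot match MRICs")
    A = np.abs(np.asarray(A, dtype=float))
    dominant_row = A.argmax(axis=0)
    picks: dict[str, int | None] = {}
    for chan in MOTOR_CHANNELS:
        row = labels.index(chan)
        cands = np.flatnonzero(dominant_row == row)
        picks[chan] = int(cands[np.argmax(A[row, cands])]) if cands.size else None
    matched = all(v is not None for v in picks.values())
    return MRICAssignment(ic_C3=picks["C3"], ic_Cz=picks["Cz"], ic_C4=picks["C4"],
                          matched=matched)


def _filters_from_model(model: MixingModel, assignment: MRICAssignment,
                        origin: object) -> DetectionFilterSet:
    return DetectionFilterSet(
        w_l=model.W[assignment.ic_C3],
        w_f=model.W[assignment.ic_Cz],
        w_r=model.W[assignment.ic_C4],
        channel_labels=list(model.channel_labels),
        origin=origin,
    )


def first_round_select(trials: TrialSet, cfg: IcaConfig | None = None,
                       ) -> tuple[dict[int, DetectionFilterSet], SelectionReport]:
    """Single-trial ICA + topography matching over a (mu/beta-band) TrialSet.

    Returns detection filters keyed by 1-based trial index for every good
    trial, and a report labeling each trial good/bad.  ICA failures label
    the trial bad rather than aborting the run.
    """
    if len(trials) == 0:
        raise ValueError("first_round_select needs at least one trial")
    cfg = cfg or IcaConfig()
    filters: dict[int, DetectionFilterSet] = {}
    labels: list[str] = []
    for x, tidx in zip(trials.trials, trials.trial_index):
        tidx = int(tidx)
        try:
            model = fit_ica(x, cfg, channel_labels=trials.channel_labels)
        except IcaError as exc:
            log.warning("trial %d: ICA failed (%s); labeled bad", tidx, exc)
            labels.append("bad")
            continue
        assign = match_mrics(model.A, model.channel_labels)
        if assign.matched:
            filters[tidx] = _filters_from_model(model, assign, origin=tidx)
            labels.append("good")
        else:
            labels.append("bad")
    report = SelectionReport(
        trial_index=trials.trial_index.copy(),
        round1_label=labels,
        accuracies=np.zeros(len(trials)),
    )
    return filters, report


# --------------------------------------------------------------------------
# Zero-training classification.

def _window_slice(trials_window: tuple[float, float], window: tuple[float, float],
                  fs: float, n_samples: int) -> slice:
    off = trials_window[0]
    i0 = int(round((window[0] - off) * fs))
    i1 = int(round((window[1] - off) * fs))
    i0, i1 = max(i0, 0), min(i1, n_samples)
    if i1 <= i0:
        raise ValueError(f"window {window} empty within trial extent {trials_window}")
    return slice(i0, i1)


def _band_cov(x: np.ndarray, band: tuple[float, float], fs: float,
              sl: slice) -> np.ndarray:
    """Channel covariance of the band-filtered, windowed trial.  Because
    variance of w @ x equals w C w^T, classification reduces to quadratic
    forms in this matrix."""
    taps = bandpass_taps(band[0], band[1], fs)
    xf = zero_phase(taps, np.asarray(x, dtype=float))[:, sl]
    xf = xf - xf.mean(axis=1, keepdims=True)
    return (xf @ xf.T) / xf.shape[1]


def band_window_covariances(trials: TrialSet, band: tuple[float, float],
                            window: tuple[float, float]) -> np.ndarray:
    """Stack of per-trial band/window channel covariances, shape (L, N, N)."""
    n = trials.trials[0].shape[1]
    sl = _window_slice(trials.window, window, trials.fs, n)
    return np.stack([_band_cov(x, band, trials.fs, sl) for x in trials.trials])


def _classify_cov(f: DetectionFilterSet, cov: np.ndarray) -> int:
    var = {
        "l": float(f.w_l @ cov @ f.w_l),
        "f": float(f.w_f @ cov @ f.w_f),
        "r": float(f.w_r @ cov @ f.w_r),
    }
    vmin = min(var.values())
    for key, cls in _MIN_VAR_CLASS:
        if var[key] == vmin:
            return cls
    raise AssertionError("unreachable")


def classify_trial(f: DetectionFilterSet, x: np.ndarray, fs: float,
                   band: tuple[float, float], window: tuple[float, float],
                   trial_window: tuple[float, float] = (0.0, np.inf)) -> int:
    """Zero-training minimum-variance classification of one trial.

    The trial is band-filtered to the subject band, the MRIC time courses
    u_l, u_r, u_f are extracted, and their variances over the analysis
    window decide the class (contralateral ERD rule).  ``trial_window``
    locates the trial's own samples relative to the cue when the trial was
    epoched with a nonzero start.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    t0 = 0.0 if not np.isfinite(trial_window[0]) else trial_window[0]
    sl = _window_slice((t0, t0 + x.shape[1] / fs), window, fs, x.shape[1])
    cov = _band_cov(x, band, fs, sl)
    return _classify_cov(f, cov)


def evaluate_filters(f: DetectionFilterSet, trials: TrialSet,
                     band: tuple[float, float], window: tuple[float, float],
                     covs: np.ndarray | None = None) -> float:
    """Fraction of trials classified correctly by one detection-filter set.

    ``covs`` may carry precomputed band/window covariances (from
    band_window_covariances) to amortize the temporal filtering across many
    filter sets; results are identical with or without it.
    """
    if len(trials) == 0:
        raise ValueError("cannot evaluate on an empty TrialSet")
    if covs is None:
        covs = band_window_covariances(trials, band, window)
    pred = np.fromiter((_classify_cov(f, c) for c in covs), dtype=int,
                       count=len(covs))
    return float(np.mean(pred == trials.labels))


# --------------------------------------------------------------------------
# Second round: accuracy-based selection and final filter construction.

def second_round_select(report: SelectionReport,
                        rule: str | float = "mean") -> SelectionReport:
    """Keep good trials whose st-BCI accuracy reaches a threshold.

    ``rule`` is "mean" (default: mean of the P nonzero accuracies), a float
    in [0, 1] used as an absolute threshold, or "q<frac>" for a quantile of
    the nonzero accuracies (e.g. "q0.5").
    """
    good = report.good_trials
    if not good:
        raise MatchingError("no good trials survived the first round (P = 0)")
    acc = {int(t): float(a) for t, a in zip(report.trial_index, report.accuracies)}
    nonzero = np.array([acc[t] for t in good])
    if rule == "mean":
        thr = float(nonzero.mean())
    elif isinstance(rule, str) and rule.startswith("q"):
        thr = float(np.quantile(nonzero, float(rule[1:])))
    else:
        thr = float(rule)
    kept = [t for t in good if acc[t] >= thr]
    report.threshold = thr
    report.kept_trials = kept
    return report


def _rank_kept(report: SelectionReport) -> list[int]:
    """Kept trials by descending R_j, ties broken by ascending trial index."""
    acc = {int(t): float(a) for t, a in zip(report.trial_index, report.accuracies)}
    return sorted(report.kept_trials, key=lambda t: (-acc[t], t))


def build_ica_t(trials: TrialSet, report: SelectionReport, m: int = 10,
                cfg: IcaConfig | None = None) -> DetectionFilterSet:
    """ICA-T: refit ICA on the concatenation of the top-m selected trials.

    Trials surviving both rounds are sorted by descending st-BCI accuracy;
    the best m are concatenated along time for one ICA fit whose matched
    MRIC rows become the final optimized detection filters.
    """
    if m <= 0:
        raise ValueError("m must be positive")
    ranked = _rank_kept(report)
    if not ranked:
        raise MatchingError("no kept trials to build ICA-T from")
    if len(ranked) < m:
        log.warning("only %d kept trials for top-%d; using all kept", len(ranked), m)
    top = ranked[:m]
    report.top_m = top
    pos = {int(t): i for i, t in enumerate(trials.trial_index)}
    data = np.concatenate([trials.trials[pos[t]] for t in top], axis=1)
    model = fit_ica(data, cfg or IcaConfig(), channel_labels=trials.channel_labels)
    assign = match_mrics(model.A, model.channel_labels)
    if not assign.matched:
        raise MatchingError(
            "MRIC matching failed on the top-m concatenation; "
            "try a different m or ICA seed"
        )
    return _filters_from_model(model, assign, origin=list(map(int, top)))


def build_ica_s(trials: TrialSet, win: int = 10, step: int = 1,
                cfg: IcaConfig | None = None) -> list[DetectionFilterSet | None]:
    """ICA-S baseline: ICA on a sliding window of ``win`` trials.

    Returns one entry per window start (1-based starts 1 .. L-win+1 at step
    1); windows whose MRIC matching fails contribute None.
    """
    if win <= 0 or step <= 0:
        raise ValueError("win and step must be positive")
    L = len(trials)
    if L < win:
        raise ValueError(f"need at least win={win} trials, got {L}")
    cfg = cfg or IcaConfig()
    out: list[DetectionFilterSet | None] = []
    for start in range(0, L - win + 1, step):
        data = np.concatenate(trials.trials[start:start + win], axis=1)
        window_id = f"window {start + 1}-{start + win}"
        try:
            model = fit_ica(data, cfg, channel_labels=trials.channel_labels)
        except IcaError as exc:
            log.warning("%s: ICA failed (%s)", window_id, exc)
            out.append(None)
            continue
        assign = match_mrics(model.A, model.channel_labels)
        if assign.matched:
            out.append(_filters_from_model(model, assign, origin=window_id))
        else:
            log.warning("%s: MRIC matching failed", window_id)
            out.append(None)
    return out


def affected_windows(artifact_idx, n_trials: int, win: int = 10,
                     step: int = 1) -> set[int]:
    """1-based sliding-window indices whose trial range touches any artifact
    trial.  With 75 trials, window 10, step 1, artifacts {43, 46} affect
    windows 34-46."""
    bad = {int(i) for i in artifact_idx}
    if any(i < 1 or i > n_trials for i in bad):
        raise ValueError("artifact indices must lie in 1..n_trials")
    out = set()
    for k, start in enumerate(range(1, n_trials - win + 2, step), start=1):
        if bad.intersection(range(start, start + win)):
            out.add(k)
    return out


def two_round_select(trials: TrialSet, cfg: IcaConfig | None = None,
                     band: tuple[float, float] = (10.0, 14.0),
                     window: tuple[float, float] = (0.5, 5.0),
                     rule: str | float = "mean",
                     ) -> tuple[dict[int, DetectionFilterSet], SelectionReport]:
    """Run both selection rounds and fill in R_j, threshold and kept trials."""
    filters, report = first_round_select(trials, cfg)
    covs = band_window_covariances(trials, band, window)
    acc = np.zeros(len(trials))
    for i, tidx in enumerate(trials.trial_index):
        f = filters.get(int(tidx))
        if f is not None:
            acc[i] = evaluate_filters(f, trials, band, window, covs=covs)
    report.accuracies = acc
    report = second_round_select(report, rule)
    return filters, report
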