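"""Accuracy-matrix artifact localization over overlapping trial segments.

A trial of length T_t seconds is cut into M consecutively overlapping
segments of length T_s with overlap T_o,

    M = round( (T_t - T_o) / (T_s - T_o) ),

rounding half away from zero.  Each segment of each training trial yields
one ICA fit and (if MRIC matching succeeds) one segment-level BCI whose
accuracy over a test set fills entry (i, j) of an M x L accuracy matrix.
Low columns localize artifact trials; low cells localize artifact segments
within a trial.  Cells whose matching fails hold the sentinel -1 ("no BCI",
distinct from an always-wrong BCI) and are excluded from summaries.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .infomax import IcaConfig, IcaError, fit_ica
from .mric import (DetectionFilterSet, _filters_from_model,
                   band_window_covariances, evaluate_filters, match_mrics)
from .preprocessing import TrialSet

__all__ = ["SegmentationParams", "AccuracyMatrix", "segment_count",
           "segment_trial", "build_accuracy_matrix", "summarize_rows"]

log = logging.getLogger(__name__)

SENTINEL = -1.0


@dataclass(frozen=True)
class SegmentationParams:
    """Trial length T_t, segment length T_s, neighbor overlap T_o (seconds)."""

    T_t: float
    T_s: float
    T_o: float

    def __post_init__(self) -> None:
        if not (0 <= self.T_o < self.T_s <= self.T_t):
            raise ValueError(
                f"need 0 <= T_o < T_s <= T_t, got ({self.T_t}, {self.T_s}, {self.T_o})"
            )


def _round_half_away(x: float) -> int:
    return int(np.sign(x) * np.floor(np.abs(x) + 0.5))


def segment_count(p: SegmentationParams) -> int:
    """Number of overlapping segments per trial, M = round((T_t-T_o)/(T_s-T_o))."""
    return _round_half_away((p.T_t - p.T_o) / (p.T_s - p.T_o))


def segment_trial(x: np.ndarray, p: SegmentationParams, fs: float) -> list[np.ndarray]:
    """Cut one trial into its M overlapping segments.

    Segment i (1-based) starts at (i-1)(T_s - T_o) seconds; each holds
    T_s * fs samples.  A final segment running past the trial end is
    truncated and zero-padded back to full length (logged).
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n_trial = int(round(p.T_t * fs))
    if x.shape[1] < n_trial:
        raise ValueError(
            f"trial holds {x.shape[1]} samples but T_t={p.T_t}s at fs={fs} "
            f"needs {n_trial}"
        )
    n_seg = int(round(p.T_s * fs))
    stride = p.T_s - p.T_o
    out = []
    for i in range(segment_count(p)):
        start = int(round(i * stride * fs))
        stop = start + n_seg
        seg = x[:, start:min(stop, x.shape[1])]
        if seg.shape[1] < n_seg:
            log.info("segment %d truncated (%d/%d samples); zero-padding",
                     i + 1, seg.shape[1], n_seg)
            seg = np.pad(seg, ((0, 0), (0, n_seg - seg.shape[1])))
        out.append(seg)
    return out


@dataclass
class AccuracyMatrix:
    """M x L matrix of segment-level BCI accuracies (sentinel -1 = no BCI)."""

    values: np.ndarray
    params: SegmentationParams
    train_id: str = "train"
    test_id: str = "test"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        valid = self.values[self.values != SENTINEL]
        if valid.size and (valid.min() < 0 or valid.max() > 1):
            raise ValueError("accuracies must lie in [0, 1]")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def to_frame(self) -> pd.DataFrame:
        """1-based (i, j) labeling matching the segment/trial convention."""
        m, l = self.values.shape
        return pd.DataFrame(self.values,
                            index=[f"segment_{i}" for i in range(1, m + 1)],
                            columns=[f"trial_{j}" for j in range(1, l + 1)])


def build_accuracy_matrix(train: TrialSet, test: TrialSet, p: SegmentationParams,
                          band: tuple[float, float] = (10.0, 14.0),
                          window: tuple[float, float] = (0.5, 5.0),
                          cfg: IcaConfig | None = None,
                          train_id: str = "train", test_id: str = "test",
                          ) -> AccuracyMatrix:
    """Fit one ICA per (segment, trial) of ``train`` and score each matched
    segment-level BCI on ``test`` (self-testing when train is test)."""
    cfg = cfg or IcaConfig()
    M = segment_count(p)
    L = len(train)
    values = np.full((M, L), SENTINEL)
    covs = band_window_covariances(test, band, window)
    for j, x in enumerate(train.trials):
        for i, seg in enumerate(segment_trial(x, p, train.fs)):
            cell = f"segment {i + 1} of trial {int(train.trial_index[j])}"
            try:
                model = fit_ica(seg, cfg, channel_labels=train.channel_labels)
            except IcaError as exc:
                log.warning("%s: ICA failed (%s)", cell, exc)
                continue
            assign = match_mrics(model.A, model.channel_labels)
            if not assign.matched:
                log.info("%s: MRIC matching failed", cell)
                continue
            fset = _filters_from_model(model, assign, origin=cell)
            values[i, j] = evaluate_filters(fset, test, band, window, covs=covs)
    return AccuracyMatrix(values=values, params=p, train_id=train_id,
                          test_id=test_id)


def summarize_rows(am: AccuracyMatrix) -> pd.DataFrame:
    """Five-number summary (min, Q1, median, Q3, max) per segment row,
    sentinel-excluded; all-sentinel rows are omitted with a warning."""
    rows = {}
    for i, row in enumerate(am.values, start=1):
        valid = row[row != SENTINEL]
        if valid.size == 0:
            warnings.warn(f"segment row {i} has no valid accuracies; omitted",
                          RuntimeWarning, stacklevel=2)
            continue
        q1, med, q3 = np.percentile(valid, [25, 50, 75])
        rows[i] = {"min": valid.min(), "q1": q1, "median": med,
                   "q3": q3, "max": valid.max()}
    return pd.DataFrame.from_dict(rows, orient="index")
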