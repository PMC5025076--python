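"""Common spatial patterns (CSP) baseline with one-versus-rest voting.

For two classes with (trace-normalized, trial-averaged) channel covariances
S+ and S-, CSP finds W jointly diagonalizing them,

    W^T S+ W = diag(lambda_1..N),    W^T S- W = I - diag(lambda),

via the generalized eigenproblem S+ v = lambda (S+ + S-) v.  The
eigenvectors of the largest and smallest lambda maximize the variance ratio
between the classes and form one filter pair.  The three-class problem is
decomposed one-versus-rest: three binary splits, each contributing a max/min
filter pair (six spatial filters in total) and a linear discriminant on
log-variance features; votes are combined, with the largest discriminant
score breaking zero- or multi-vote ties.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .preprocessing import TrialSet, VALID_CLASSES

__all__ = ["CspPair", "CspOvrModel", "class_covariance", "compute_csp_pair",
           "fit_csp_ovr", "classify_csp", "csp_self_test"]

log = logging.getLogger(__name__)


class CspError(RuntimeError):
    pass


@dataclass
class CspPair:
    """Max/min-eigenvalue filter pair of one binary CSP problem."""

    filters: np.ndarray          # (2, N): rows = max- then min-eigenvalue filter
    eigvals: tuple[float, float]  # (lambda_max, lambda_min)
    class_pair: tuple[object, object]


@dataclass
class CspOvrModel:
    """Three one-vs-rest CSP pairs plus their linear discriminants."""

    pairs: list[CspPair]
    discriminants: list[LinearDiscriminantAnalysis]
    classes: tuple[int, ...] = VALID_CLASSES

    @property
    def n_filters(self) -> int:
        return sum(p.filters.shape[0] for p in self.pairs)


def class_covariance(trials: list[np.ndarray]) -> np.ndarray:
    """Trial-averaged, trace-normalized channel covariance of one class."""
    if len(trials) == 0:
        raise CspError("empty trial list")
    acc = None
    for x in trials:
        x = np.asarray(x, dtype=float)
        xc = x - x.mean(axis=1, keepdims=True)
        c = xc @ xc.T / xc.shape[1]
        tr = np.trace(c)
        if tr <= 0:
            raise CspError("trial has zero total variance")
        if np.any(np.diag(c) < 1e-12 * tr):
            warnings.warn("constant channel detected; covariance is rank deficient",
                          RuntimeWarning, stacklevel=2)
        c = c / tr
        acc = c if acc is None else acc + c
    return acc / len(trials)


def compute_csp_pair(X1: list[np.ndarray], X2: list[np.ndarray],
                     class_pair: tuple[object, object] = ("+", "-")) -> CspPair:
    """CSP filter pair for class X1 (positive) against X2 (rest)."""
    S1 = class_covariance(X1)
    S2 = class_covariance(X2)
    if S1.shape != S2.shape:
        raise CspError("class covariances differ in size")
    comp = S1 + S2
    # reject rank deficiency up front so eigh errors are interpretable
    diag = np.diag(comp)
    bad = np.flatnonzero(diag < 1e-10 * diag.max())
    if bad.size:
        raise CspError(f"composite covariance rank-deficient at channels {bad.tolist()}")
    evals, evecs = linalg.eigh(S1, comp)
    # eigh(S1, comp) returns ascending lambda with evecs^T comp evecs = I,
    # hence evecs^T S1 evecs = diag(lambda) and evecs^T S2 evecs = I - diag.
    w_max = evecs[:, -1]
    w_min = evecs[:, 0]
    return CspPair(filters=np.vstack([w_max, w_min]),
                   eigvals=(float(evals[-1]), float(evals[0])),
                   class_pair=class_pair)


def _features(filters: np.ndarray, x: np.ndarray) -> np.ndarray:
    xc = np.asarray(x, dtype=float)
    xc = xc - xc.mean(axis=1, keepdims=True)
    y = filters @ xc
    return np.log(y.var(axis=1) + 1e-20)


def fit_csp_ovr(trials: TrialSet) -> CspOvrModel:
    """Fit the three one-vs-rest CSP splits and their discriminants."""
    present = set(np.unique(trials.labels))
    missing = set(VALID_CLASSES) - present
    if missing:
        raise CspError(f"classes {sorted(missing)} absent from training set")
    pairs, ldas = [], []
    for c in VALID_CLASSES:
        own = [t for t, lab in zip(trials.trials, trials.labels) if lab == c]
        rest = [t for t, lab in zip(trials.trials, trials.labels) if lab != c]
        pair = compute_csp_pair(own, rest, class_pair=(c, "rest"))
        feats = np.vstack([_features(pair.filters, t) for t in trials.trials])
        y = (trials.labels == c).astype(int)
        lda = LinearDiscriminantAnalysis()
        lda.fit(feats, y)
        pairs.append(pair)
        ldas.append(lda)
    return CspOvrModel(pairs=pairs, discriminants=ldas)


def classify_csp(model: CspOvrModel, x: np.ndarray) -> int:
    """OVR voting: a split with positive score votes its class; zero or
    multiple positive votes fall back to the largest score."""
    scores = []
    for pair, lda in zip(model.pairs, model.discriminants):
        f = _features(pair.filters, x)[None, :]
        scores.append(float(lda.decision_function(f)[0]))
    scores = np.asarray(scores)
    positive = np.flatnonzero(scores > 0)
    if positive.size == 1:
        return int(model.classes[positive[0]])
    return int(model.classes[int(np.argmax(scores))])


def csp_self_test(trials: TrialSet, frac: float = 0.8, repeats: int = 30,
                  seed: int = 0) -> tuple[float, float]:
    """Self-testing protocol: per repeat, a random stratified ``frac`` of the
    trials trains the model, which is then scored on ALL trials; returns the
    mean and standard deviation of the accuracies over repeats."""
    if not (0 < frac <= 1):
        raise CspError("frac must be in (0, 1]")
    rng = np.random.default_rng(seed)
    accs = []
    for _ in range(repeats):
        train_idx: list[int] = []
        for c in VALID_CLASSES:
            pos = np.flatnonzero(trials.labels == c)
            n_take = max(1, int(round(frac * pos.size)))
            take = pos if frac >= 1.0 else rng.choice(pos, size=n_take, replace=False)
            train_idx.extend(int(i) for i in take)
        model = fit_csp_ovr(trials.subset(sorted(train_idx)))
        pred = np.array([classify_csp(model, t) for t in trials.trials])
        accs.append(float(np.mean(pred == trials.labels)))
    return float(np.mean(accs)), float(np.std(accs))
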