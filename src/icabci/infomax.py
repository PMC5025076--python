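"""Infomax ICA with natural-gradient updates and sub/super-Gaussian switching.

The measured EEG x(t) is modeled as a noiseless instantaneous mixture
x = A s of statistically independent sources.  A separating matrix W is
learned by stochastic natural-gradient ascent on the information-maximization
objective,

    dW  ~  [ I - E( K tanh(u) u^T + u u^T ) ] W ,      u = W x,

where K is a diagonal switch matrix whose entries are +1 for super-Gaussian
and -1 for sub-Gaussian sources, estimated each iteration from the sign of
the excess kurtosis of the current source estimates.  W is initialized as a
small positive multiple of the identity.  After convergence the sources are
rescaled to unit standard deviation and the mixing matrix A = W^-1 absorbs
the scale, removing ICA's amplitude indeterminacy; the residual sign
indeterminacy is fixed by flipping each pattern so its dominant electrode
weight is positive.

This is a from-scratch implementation (no pre-whitening; channels are only
centered): the natural gradient makes the update equivariant, so whitening
is not required.
"""
from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

__all__ = ["IcaConfig", "MixingModel", "fit_ica", "normalize_model",
           "apply_filters", "amari_index"]

log = logging.getLogger(__name__)


class IcaError(RuntimeError):
    pass


class SingularUpdateError(IcaError):
    """W diverged or became numerically singular during iteration."""


@dataclass(frozen=True)
class IcaConfig:
    """Optimizer constants for the natural-gradient Infomax iteration.

    learning_rate defaults to 0.05/ln(N) when None; it is annealed by 0.9
    whenever the angle between successive epoch updates exceeds 60 degrees.
    One iteration is a full pass over the data in shuffled blocks of
    ``block_size`` samples; the kurtosis switch is re-estimated on the full
    current sources each iteration.  ``tol`` bounds the largest absolute
    element of the per-iteration change of W at convergence.
    """

    learning_rate: float | None = None
    max_iter: int = 512
    tol: float = 1e-7
    block_size: int = 256
    seed: int = 0

    def __post_init__(self) -> None:
        if self.learning_rate is not None and self.learning_rate <= 0:
            raise ValueError("learning_rate must be positive")
        if self.max_iter <= 0 or self.block_size <= 0:
            raise ValueError("max_iter and block_size must be positive")
        if not (0 < self.tol < 1):
            raise ValueError("tol must be in (0, 1)")


@dataclass
class MixingModel:
    """Fitted ICA model: mixing matrix A (columns = spatial patterns),
    separating matrix W (rows = spatial filters), sources U = W x."""

    A: np.ndarray
    W: np.ndarray
    U: np.ndarray
    channel_labels: list[str]
    converged: bool = False
    n_iter: int = 0
    config: IcaConfig | None = None

    @property
    def n_components(self) -> int:
        return self.A.shape[0]

    def to_json(self) -> str:
        d = {
            "channel_labels": self.channel_labels,
            "A": self.A.tolist(),
            "W": self.W.tolist(),
            "converged": self.converged,
            "n_iter": self.n_iter,
            "config": asdict(self.config) if self.config else None,
        }
        return json.dumps(d, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MixingModel":
        d = json.loads(text)
        A = np.asarray(d["A"], dtype=float)
        W = np.asarray(d["W"], dtype=float)
        cfg = IcaConfig(**d["config"]) if d.get("config") else None
        return cls(A=A, W=W, U=np.zeros((A.shape[0], 0)),
                   channel_labels=list(d["channel_labels"]),
                   converged=bool(d["converged"]), n_iter=int(d["n_iter"]),
                   config=cfg)


def _kurtosis_signs(U: np.ndarray) -> np.ndarray:
    """Diagonal of the switch matrix K: +1 super-Gaussian, -1 sub-Gaussian."""
    k = stats.kurtosis(U, axis=1, fisher=True, bias=True)
    s = np.sign(k)
    s[s == 0] = 1.0
    return s


def _iterate(X: np.ndarray, cfg: IcaConfig, lr0: float,
             rng: np.random.Generator) -> tuple[np.ndarray, bool, int]:
    N, T = X.shape
    eye = np.eye(N)
    W = 0.1 * np.eye(N)
    lr = lr0
    prev_dW = None
    starts = np.arange(0, T - cfg.block_size + 1, cfg.block_size)
    if starts.size == 0:
        starts = np.array([0])
    converged = False
    it = 0
    for it in range(1, cfg.max_iter + 1):
        ksign = _kurtosis_signs(W @ X)
        W_old = W.copy()
        for s in rng.permutation(starts):
            xb = X[:, s:s + cfg.block_size]
            u = W @ xb
            nb = u.shape[1]
            grad = eye - ((ksign[:, None] * np.tanh(u)) @ u.T + u @ u.T) / nb
            W = W + lr * (grad @ W)
            if not np.all(np.isfinite(W)) or np.abs(W).max() > 1e8:
                raise SingularUpdateError("separating matrix diverged")
        dW = W - W_old
        if prev_dW is not None:
            denom = np.linalg.norm(dW) * np.linalg.norm(prev_dW)
            if denom > 0 and float(np.sum(dW * prev_dW)) / denom < 0.5:
                lr *= 0.9  # update direction swung by more than 60 degrees
        prev_dW = dW
        if np.abs(dW).max() < cfg.tol:
            converged = True
            break
    return W, converged, it


def fit_ica(data: np.ndarray, cfg: IcaConfig | None = None,
            channel_labels: list[str] | None = None) -> MixingModel:
    """Fit the Infomax model to an (N x T) data matrix.

    Channels are centered; T must be at least 20 N.  On numerical blow-up the
    iteration restarts with a halved learning rate (at most 3 restarts).
    """
    cfg = cfg or IcaConfig()
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise IcaError(f"expected a 2-D matrix, got shape {X.shape}")
    N, T = X.shape
    if not np.all(np.isfinite(X)):
        raise IcaError("input contains non-finite values")
    if T < 20 * N:
        raise IcaError(f"need T >= 20 N samples, got T={T} for N={N}")
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(N)]
    if len(channel_labels) != N:
        raise IcaError("channel_labels length must equal channel count")

    X = X - X.mean(axis=1, keepdims=True)
    lr = cfg.learning_rate if cfg.learning_rate is not None else 0.05 / math.log(max(N, 2))
    rng = np.random.default_rng(cfg.seed)
    last_exc: Exception | None = None
    for attempt in range(4):
        try:
            W, converged, n_iter = _iterate(X, cfg, lr, rng)
            break
        except SingularUpdateError as exc:
            last_exc = exc
            lr *= 0.5
            log.warning("ICA update diverged; restarting with learning rate %.2e", lr)
    else:
        raise SingularUpdateError(
            "ICA failed to converge after 3 learning-rate restarts"
        ) from last_exc

    A = np.linalg.inv(W)
    model = MixingModel(A=A, W=W, U=W @ X, channel_labels=list(channel_labels),
                        converged=converged, n_iter=n_iter, config=cfg)
    model = normalize_model(model)
    _canonicalize_signs(model)
    return model


def normalize_model(model: MixingModel) -> MixingModel:
    """Rescale sources to unit standard deviation, absorbing the scale into A.

    u <- u / diag(std(u));  A <- A diag(std(u));  W = A^-1.  Idempotent.
    """
    stds = model.U.std(axis=1)
    bad = np.flatnonzero(stds < 1e-12)
    if bad.size:
        raise IcaError(f"zero-variance source(s) at index {bad.tolist()}")
    U = model.U / stds[:, None]
    A = model.A * stds[None, :]
    W = np.linalg.inv(A)
    return MixingModel(A=A, W=W, U=U, channel_labels=model.channel_labels,
                       converged=model.converged, n_iter=model.n_iter,
                       config=model.config)


def _canonicalize_signs(model: MixingModel) -> None:
    """Flip each (pattern, filter) pair so the dominant electrode weight is
    positive — removes the sign indeterminacy before topography matching."""
    for j in range(model.n_components):
        i = int(np.argmax(np.abs(model.A[:, j])))
        if model.A[i, j] < 0:
            model.A[:, j] *= -1.0
            model.W[j, :] *= -1.0
            model.U[j, :] *= -1.0


def apply_filters(w: np.ndarray, x: np.ndarray) -> np.ndarray:
    """Apply spatial-filter rows to a trial: sources = w @ x."""
    w = np.atleast_2d(np.asarray(w, dtype=float))
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if w.shape[1] != x.shape[0]:
        raise IcaError(f"filter width {w.shape[1]} != channel count {x.shape[0]}")
    return w @ x


def amari_index(P: np.ndarray) -> float:
    """Normalized Amari separation index of P = W @ A_true (0 = perfect).

    Permutation- and scale-invariant; 1 is the chance level for a matrix with
    no dominant entry per row/column.
    """
    P = np.abs(np.asarray(P, dtype=float))
    N = P.shape[0]
    if N < 2 or P.shape[0] != P.shape[1]:
        raise ValueError("amari_index needs a square matrix of size >= 2")
    rows = (P / P.max(axis=1, keepdims=True)).sum(axis=1) - 1.0
    cols = (P / P.max(axis=0, keepdims=True)).sum(axis=0) - 1.0
    return float((rows.sum() + cols.sum()) / (2.0 * N * (N - 1)))
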