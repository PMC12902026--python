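"""Training objectives: triplet loss with semi-hard mining, BCE, focal loss.

Distances are squared Euclidean throughout.  A triplet (anchor a, positive p,
negative n) with margin m incurs

    L(a, p, n) = max(0, d(a, p) - d(a, n) + m),

and semi-hard mining keeps exactly the label-valid triplets satisfying the
strict double inequality d(A, P) < d(A, N) < d(A, P) + margin — negatives
that are farther than the positive but still inside the margin, the regime
that yields informative, stable gradients.

Focal loss uses the standard modulating factor (1 - p_t)^gamma with
p_t = y_p if y = 1 else 1 - y_p; with gamma = 0 and alpha = 1 it reduces
exactly to binary cross-entropy.  (A published variant writes the factor in
terms of the true label rather than p_t, which silences all positive samples
for gamma > 0; the p_t form is what the reduction identity and the class-
imbalance motivation require.)

Gradient helpers (``*_grad``) return analytic derivatives used by the
trainer; each is validated against numerical differentiation in the tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np

EPS = 1e-7


@dataclass
class TripletParams:
    """Margin m, which also serves as the mining inequality's alpha."""

    margin: float = 0.2

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin must be non-negative")


@dataclass
class FocalParams:
    alpha: float = 0.25
    gamma: float = 2.0

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.gamma < 0:
            raise ValueError("gamma must be non-negative")


@dataclass(frozen=True)
class TripletIndices:
    a: int
    p: int
    n: int


def pairwise_sq_distances(vectors: np.ndarray) -> np.ndarray:
    """N x N matrix of squared Euclidean distances."""
    v = np.asarray(vectors, dtype=float)
    if v.ndim != 2:
        raise ValueError("expected an N x D matrix")
    sq = (v**2).sum(axis=1)
    d = sq[:, None] + sq[None, :] - 2.0 * (v @ v.T)
    return np.maximum(d, 0.0)


def triplet_loss(a: np.ndarray, p: np.ndarray, n: np.ndarray,
                 params: TripletParams | None = None) -> float:
    params = params or TripletParams()
    a, p, n = (np.asarray(x, dtype=float) for x in (a, p, n))
    if not (a.shape == p.shape == n.shape):
        raise ValueError("anchor/positive/negative must share a dimension")
    d_ap = float(((a - p) ** 2).sum())
    d_an = float(((a - n) ** 2).sum())
    return max(0.0, d_ap - d_an + params.margin)


def semi_hard_triplets(vectors: np.ndarray, labels: np.ndarray,
                       params: TripletParams | None = None) -> List[TripletIndices]:
    """All label-valid semi-hard triplets, in (a, p, n) ascending order.

    Returns an empty list when only one class is present (no valid triplet
    exists — a signal, not an error).
    """
    params = params or TripletParams()
    labels = np.asarray(labels)
    d = pairwise_sq_distances(vectors)
    n_items = len(labels)
    out: List[TripletIndices] = []
    for a in range(n_items):
        same = labels == labels[a]
        for p in range(n_items):
            if p == a or not same[p]:
                continue
            d_ap = d[a, p]
            for n in range(n_items):
                if same[n]:
                    continue
                d_an = d[a, n]
                if d_ap < d_an < d_ap + params.margin:
                    out.append(TripletIndices(a, p, n))
    return out


def batch_triplet_objective(vectors: np.ndarray, labels: np.ndarray,
                            params: TripletParams | None = None) -> float:
    """Mean triplet loss over the mined semi-hard set; 0 if none mined."""
    params = params or TripletParams()
    triplets = semi_hard_triplets(vectors, labels, params)
    if not triplets:
        return 0.0
    v = np.asarray(vectors, dtype=float)
    losses = [triplet_loss(v[t.a], v[t.p], v[t.n], params) for t in triplets]
    return float(np.mean(losses))


def batch_triplet_grad(vectors: np.ndarray, labels: np.ndarray,
                       params: TripletParams | None = None
                       ) -> Tuple[float, np.ndarray, int]:
    """(mean loss, d loss / d vectors, number of mined triplets).

    For an active triplet (hinge not saturated) the per-triplet gradients are
    dL/da = 2(n - p) + 2(a - p) - 2(a - n) ... i.e. 2[(a-p) - (a-n)] for the
    anchor, -2(a-p) for the positive and +2(a-n) for the negative; the batch
    gradient averages over all mined triplets.
    """
    params = params or TripletParams()
    v = np.asarray(vectors, dtype=float)
    triplets = semi_hard_triplets(v, labels, params)
    grad = np.zeros_like(v)
    if not triplets:
        return 0.0, grad, 0
    total = 0.0
    for t in triplets:
        a, p, n = v[t.a], v[t.p], v[t.n]
        d_ap = ((a - p) ** 2).sum()
        d_an = ((a - n) ** 2).sum()
        val = d_ap - d_an + params.margin
        if val > 0:
            total += val
            grad[t.a] += 2 * ((a - p) - (a - n))
            grad[t.p] += -2 * (a - p)
            grad[t.n] += 2 * (a - n)
    m = len(triplets)
    return float(total / m), grad / m, m


def sigmoid(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


def _clamp(y_p):
    return np.clip(np.asarray(y_p, dtype=float), EPS, 1.0 - EPS)


def bce_loss(y, y_p) -> float | np.ndarray:
    """-[y log y_p + (1-y) log(1-y_p)], with an eps-clamp on y_p."""
    y = np.asarray(y, dtype=float)
    p = _clamp(y_p)
    out = -(y * np.log(p) + (1 - y) * np.log(1 - p))
    return float(out) if out.ndim == 0 else out


def focal_loss(y, y_p, params: FocalParams | None = None) -> float | np.ndarray:
    """-alpha (1 - p_t)^gamma log(p_t), p_t = y_p if y=1 else 1-y_p."""
    params = params or FocalParams()
    y = np.asarray(y, dtype=float)
    p = _clamp(y_p)
    p_t = np.where(y == 1, p, 1 - p)
    out = -params.alpha * (1 - p_t) ** params.gamma * np.log(p_t)
    return float(out) if out.ndim == 0 else out


def bce_grad_logit(y, logit) -> np.ndarray:
    """d BCE / d logit with y_p = sigmoid(logit): simply (y_p - y)."""
    return sigmoid(logit) - np.asarray(y, dtype=float)


def focal_grad_logit(y, logit, params: FocalParams | None = None) -> np.ndarray:
    """d focal / d logit, analytic.

    With p = sigmoid(x), p_t = p if y=1 else 1-p and dp_t/dx = s * p (1-p)
    where s = +1 for y=1 and -1 for y=0:

        dL/dp_t = alpha [ gamma (1-p_t)^(gamma-1) log p_t - (1-p_t)^gamma / p_t ]
    """
    params = params or FocalParams()
    y = np.asarray(y, dtype=float)
    p = _clamp(sigmoid(logit))
    p_t = np.where(y == 1, p, 1 - p)
    g = params.gamma
    one_m = 1 - p_t
    dL_dpt = params.alpha * (
        (g * one_m ** (g - 1) * np.log(p_t) if g > 0 else 0.0) - one_m**g / p_t
    )
    sign = np.where(y == 1, 1.0, -1.0)
    return dL_dpt * sign * p * (1 - p)
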