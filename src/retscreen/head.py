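"""Screening-oriented prediction head.

Maps the fused global representation h to per-disease probabilities:
r = W_s h projects into a compact screening space of dimension D, and each
disease c has an independent sigmoid classifier y_c = sigmoid(w_c . r).
Single-disease screening is the C = 1 special case; there is no softmax, so
co-occurring diseases are not assumed mutually exclusive.  No bias terms
are used by default.

Decision thresholds are not fixed at 0.5: they are selected per class on
validation data by maximising Youden's J (sensitivity + specificity - 1),
with ties broken toward the higher threshold.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special

EPS = 1e-7  # probability clipping bound for the cross-entropy losses


@dataclass
class HeadParams:
    screening_projection: np.ndarray  # W_s, (D, E)
    class_weights: np.ndarray         # one w_c per class, (C, D)

    def __post_init__(self) -> None:
        if self.screening_projection.ndim != 2 or self.class_weights.ndim != 2:
            raise ValueError("head parameters must be matrices")
        if self.class_weights.shape[1] != self.screening_projection.shape[0]:
            raise ValueError("class_weights and screening_projection disagree on D")

    @property
    def n_classes(self) -> int:
        return self.class_weights.shape[0]


@dataclass
class Prediction:
    probabilities: np.ndarray  # (C,) or (n, C), in (0, 1)
    decisions: np.ndarray      # binary, same shape
    thresholds: np.ndarray     # (C,)


def init_head_params(embed_dim: int, head_dim: int, n_classes: int,
                     seed: int = 0,
                     rng: np.random.Generator | None = None) -> HeadParams:
    from scipy.stats import truncnorm

    rng = np.random.default_rng(seed) if rng is None else rng
    ws = truncnorm.rvs(-2, 2, scale=0.02, size=(head_dim, embed_dim),
                       random_state=rng)
    wc = truncnorm.rvs(-2, 2, scale=0.02, size=(n_classes, head_dim),
                       random_state=rng)
    return HeadParams(screening_projection=ws, class_weights=wc)


def project(h: np.ndarray, params: HeadParams) -> np.ndarray:
    """Screening feature vector r = W_s h (linear, no bias)."""
    h = np.asarray(h)
    if h.shape[-1] != params.screening_projection.shape[1]:
        raise ValueError("fused vector length does not match W_s")
    return h @ params.screening_projection.T


def predict(r: np.ndarray, params: HeadParams,
            thresholds: np.ndarray | None = None) -> Prediction:
    """Independent per-class sigmoid probabilities and thresholded decisions."""
    logits = np.asarray(r) @ params.class_weights.T
    probs = special.expit(logits)
    C = params.n_classes
    if thresholds is None:
        thresholds = np.full(C, 0.5)
    thresholds = np.asarray(thresholds, dtype=float)
    decisions = (probs >= thresholds).astype(np.int8)
    return Prediction(probabilities=probs, decisions=decisions,
                      thresholds=thresholds)


def loss_single(y, y_hat) -> float:
    """Binary cross-entropy -[y log p + (1-y) log(1-p)] with p clipped to
    [EPS, 1-EPS]."""
    y = np.asarray(y, dtype=float)
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValueError("labels must be 0 or 1")
    p = np.clip(np.asarray(y_hat, dtype=float), EPS, 1.0 - EPS)
    return float(np.sum(-(y * np.log(p) + (1.0 - y) * np.log1p(-p))))


def loss_multi(y: np.ndarray, y_hat: np.ndarray) -> float:
    """Unweighted sum over classes of per-class binary cross-entropy."""
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape:
        raise ValueError("label and probability vectors differ in length")
    return loss_single(y, y_hat)


def select_thresholds(validation_probs: np.ndarray,
                      validation_labels: np.ndarray,
                      class_names=None) -> np.ndarray:
    """Per class, the observed probability maximising Youden's J
    (sensitivity + specificity - 1); ties broken toward the higher value.

    Raises when a validation column contains a single class (J undefined).
    """
    probs = np.atleast_2d(np.asarray(validation_probs, dtype=float))
    labels = np.atleast_2d(np.asarray(validation_labels))
    if probs.shape != labels.shape:
        raise ValueError("probability and label arrays differ in shape")
    C = probs.shape[1]
    names = class_names if class_names is not None else [str(c) for c in range(C)]
    out = np.empty(C)
    for c in range(C):
        y = labels[:, c]
        p = probs[:, c]
        n_pos, n_neg = int(y.sum()), int((1 - y).sum())
        if n_pos == 0 or n_neg == 0:
            raise ValueError(
                f"class {names[c]!r} has a single label value on validation; "
                "threshold selection undefined")
        best_j, best_t = -np.inf, None
        for t in np.unique(p):
            dec = p >= t
            sens = np.sum(dec & (y == 1)) / n_pos
            spec = np.sum(~dec & (y == 0)) / n_neg
            j = sens + spec - 1.0
            if j >= best_j:  # >= ties toward the higher threshold (sorted asc)
                best_j, best_t = j, t
        out[c] = best_t
    return out


# ---------------------------------------------------------------------------
# training-path forward/backward (used by the training loop)


def head_forward(h: np.ndarray, params: HeadParams):
    """h (B, E) -> probabilities (B, C) with cache for the backward pass."""
    r = h @ params.screening_projection.T
    logits = r @ params.class_weights.T
    probs = special.expit(logits)
    return probs, (h, r)


def head_backward(probs: np.ndarray, y: np.ndarray, cache, params: HeadParams):
    """Gradients of the mean-over-batch, sum-over-class cross-entropy.

    The gradient w.r.t. each logit is (y_hat - y) / B, the closed form for
    sigmoid + cross-entropy.
    Returns (dh, d_ws, d_wc).
    """
    h, r = cache
    B = probs.shape[0]
    dlogits = (probs - y) / B
    d_wc = dlogits.T @ r
    dr = dlogits @ params.class_weights
    d_ws = dr.T @ h
    dh = dr @ params.screening_projection
    return dh, d_ws, d_wc


def severity_grade_from_probs(grade_probs: np.ndarray) -> np.ndarray:
    """Ordinal severity reported as argmax over 5 one-vs-rest grade
    indicator probabilities (the head stays sigmoid-based; no softmax)."""
    return np.argmax(np.atleast_2d(grade_probs), axis=1)
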