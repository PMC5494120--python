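"""Extreme learning machine (ELM), its ridge-regularized variant (RELM),
and the reliability-gated sparse-representation fallback.

An ELM is a single-hidden-layer feed-forward network whose hidden-layer
input weights ``w_i`` and biases ``b_i`` are drawn randomly (here i.i.d.
Uniform(-1, 1)) and never trained. With hidden activations
``H[j, i] = g(w_i . x_j + b_i)`` the output weights are obtained in closed
form: plain ELM uses the Moore-Penrose pseudoinverse,

    beta = pinv(H) @ T,

the minimum-norm least-squares solution for one-hot targets T; RELM solves
the ridge system

    beta = (I / C + H'H)^{-1} H'T,

computed via a symmetric positive-definite factorization (contract-identical
to the explicit inverse, numerically more robust). Larger C means weaker
regularization; C -> infinity recovers plain ELM on full-column-rank H.

The hybrid predictor gates each test sample on a reliability score — the
margin between the top two output scores. Reliable samples keep the ELM
argmax label; unreliable ones are re-classified by sparse representation
over the retained training dictionary: the sample is sparse-coded on the
l2-normalized training atoms (greedy orthogonal matching pursuit) and
assigned to the class whose atoms' partial reconstruction leaves the
smallest residual.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.linalg import cho_factor, cho_solve
from scipy.special import expit
from sklearn.linear_model import orthogonal_mp

from ._errors import ConfigurationError, ValidationError

__all__ = [
    "ELMModel",
    "random_hidden_layer",
    "hidden_output",
    "fit_elm",
    "fit_relm",
    "predict_scores",
    "reliability",
    "sparse_fallback_classify",
    "predict_hybrid",
]

_ACTIVATIONS = {
    "sigmoid": expit,
    "tanh": np.tanh,
    "relu": lambda z: np.maximum(z, 0.0),
}


@dataclass(frozen=True)
class ELMModel:
    """Fitted (R)ELM.

    ``C`` is the ridge constant; ``numpy.inf`` encodes plain ELM.
    ``dictionary`` (training matrix, labels) is retained only when the
    sparse fallback may be used.
    """

    input_weights: np.ndarray  # (L, d)
    biases: np.ndarray  # (L,)
    activation: str
    beta: np.ndarray  # (L, K)
    C: float
    classes: tuple[str, ...]
    seed: int
    dictionary: tuple[np.ndarray, np.ndarray] | None = None


def random_hidden_layer(d: int, L: int, seed: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw the untrained hidden layer: weights and biases i.i.d. Uniform(-1, 1)."""
    if d < 1 or L < 1:
        raise ValidationError("d and L must be >= 1")
    rng = np.random.default_rng(seed)
    W = rng.uniform(-1.0, 1.0, size=(L, d))
    b = rng.uniform(-1.0, 1.0, size=L)
    return W, b


def hidden_output(
    input_weights: np.ndarray,
    biases: np.ndarray,
    activation: str,
    X: np.ndarray,
) -> np.ndarray:
    """Hidden-layer output matrix H with H[j, i] = g(w_i . x_j + b_i)."""
    if activation not in _ACTIVATIONS:
        raise ConfigurationError(
            f"unknown activation {activation!r}; choose from {sorted(_ACTIVATIONS)}"
        )
    X = np.atleast_2d(np.asarray(X, dtype=float))
    W = np.asarray(input_weights, dtype=float)
    if X.shape[1] != W.shape[1]:
        raise ValidationError(f"X has {X.shape[1]} columns, weights expect {W.shape[1]}")
    return _ACTIVATIONS[activation](X @ W.T + np.asarray(biases, dtype=float))


def fit_elm(H: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Minimum-norm least-squares output weights: beta = pinv(H) @ T."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(targets, dtype=float)
    if H.ndim != 2 or T.ndim != 2 or H.shape[0] != T.shape[0]:
        raise ValidationError(f"incompatible shapes H {H.shape}, targets {T.shape}")
    beta, *_ = np.linalg.lstsq(H, T, rcond=None)
    return beta


def fit_relm(H: np.ndarray, targets: np.ndarray, C: float) -> np.ndarray:
    """Ridge output weights beta = (I/C + H'H)^{-1} H'T via an SPD solve."""
    H = np.asarray(H, dtype=float)
    T = np.asarray(targets, dtype=float)
    if H.ndim != 2 or T.ndim != 2 or H.shape[0] != T.shape[0]:
        raise ValidationError(f"incompatible shapes H {H.shape}, targets {T.shape}")
    if not C > 0:
        raise ValidationError(f"C must be > 0, got {C}")
    L = H.shape[1]
    A = H.T @ H + np.eye(L) / C
    return cho_solve(cho_factor(A, lower=True), H.T @ T)


def predict_scores(model: ELMModel, X: np.ndarray) -> np.ndarray:
    """Output-layer scores h(x) @ beta, one row per sample."""
    H = hidden_output(model.input_weights, model.biases, model.activation, X)
    return H @ model.beta


def reliability(scores_row: np.ndarray) -> float:
    """Top-1 minus top-2 score margin; large means the ELM decision is clear."""
    s = np.asarray(scores_row, dtype=float).ravel()
    if s.size < 2:
        raise ValidationError("reliability needs at least 2 class scores")
    top2 = np.sort(s)[-2:]
    return float(top2[1] - top2[0])


def sparse_fallback_classify(
    dictionary: np.ndarray,
    dict_labels: Sequence[str],
    x: np.ndarray,
    n_nonzero: int = 10,
    classes: Sequence[str] | None = None,
) -> str:
    """Classify ``x`` by sparse representation over training atoms.

    The dictionary rows (training samples) are l2-normalized and ``x`` is
    greedily sparse-coded on them with at most ``n_nonzero`` atoms; the
    returned label is the class whose atoms' partial reconstruction
    ``D_c delta_c(alpha)`` has the smallest residual from ``x``. Ties break
    toward the earlier class in the declared order.
    """
    D_rows = np.atleast_2d(np.asarray(dictionary, dtype=float))
    labels = np.asarray(list(dict_labels))
    if D_rows.shape[0] == 0:
        raise ValidationError("empty dictionary")
    if labels.shape[0] != D_rows.shape[0]:
        raise ValidationError("dictionary rows and labels differ in length")
    x = np.asarray(x, dtype=float).ravel()
    if x.shape[0] != D_rows.shape[1]:
        raise ValidationError(f"x has {x.shape[0]} entries, atoms have {D_rows.shape[1]}")
    D = D_rows.T.copy()  # atoms as columns
    norms = np.linalg.norm(D, axis=0)
    norms[norms == 0] = 1.0
    D = D / norms
    k = max(1, min(int(n_nonzero), D.shape[0], D.shape[1]))
    alpha = orthogonal_mp(D, x, n_nonzero_coefs=k).ravel()
    if classes is None:
        classes = tuple(dict.fromkeys(labels.tolist()))
    best_cls, best_res = None, np.inf
    for c in classes:
        mask = labels == c
        if not mask.any():
            continue
        recon = D[:, mask] @ alpha[mask]
        res = float(np.linalg.norm(x - recon))
        if res < best_res - 1e-12:
            best_cls, best_res = c, res
    assert best_cls is not None
    return str(best_cls)


def predict_hybrid(model: ELMModel, X: np.ndarray, threshold: float,
                   n_nonzero: int = 10) -> np.ndarray:
    """Reliability-gated prediction.

    Rows whose score margin is at least ``threshold`` keep the ELM argmax
    label; the rest are routed to :func:`sparse_fallback_classify` over the
    model's retained training dictionary. ``threshold = 0`` reproduces pure
    ELM/RELM predictions exactly.
    """
    scores = predict_scores(model, X)
    if threshold > 0 and model.dictionary is None:
        raise ConfigurationError(
            "hybrid prediction with threshold > 0 requires a training dictionary"
        )
    out = []
    for i in range(scores.shape[0]):
        if threshold <= 0 or reliability(scores[i]) >= threshold:
            out.append(model.classes[int(np.argmax(scores[i]))])
        else:
            D, labels = model.dictionary
            out.append(
                sparse_fallback_classify(D, labels, np.atleast_2d(X)[i],
                                         n_nonzero=n_nonzero, classes=model.classes)
            )
    return np.array(out)
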