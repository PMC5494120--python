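"""Kernel logistic regression (KLR) and the import vector machine (IVM).

KLR places a softmax model over kernel evaluations against a set of
reference points: for a sample ``x`` with kernel column
``k(x) = [k(x, r_1), ..., k(x, r_m)]`` the class posterior is

    P(c | x) = exp(w_c' k(x) + b_c) / sum_c' exp(w_c'' k(x) + b_c')

and the weights minimize the regularized negative log-likelihood

    Q(w) = -log L(w) + (lambda/2) * sum_c w_c' K_rr w_c

with the Gram matrix ``K_rr`` of the reference points as penalty matrix
(the standard RKHS-norm penalty; an identity penalty is available for
comparison) and the bias unpenalized. Identifiability is fixed by pinning
the last class's weight column to zero, so the binary case reduces to the
familiar sigmoid of a single linear score. The objective is convex and is
minimized by damped Newton-Raphson iterations.

The IVM makes the model sparse: starting from an empty set it greedily adds
the training point ("import vector") whose inclusion most decreases Q, and
stops when the relative objective decrease over the last ``delta_t`` steps
falls below ``epsilon``. The fitted model evaluates kernels only against
the selected import vectors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial.distance import cdist

from ._errors import ConvergenceError, ValidationError

__all__ = [
    "KernelSpec",
    "KLRModel",
    "IVMFitReport",
    "kernel_matrix",
    "fit_klr",
    "fit_ivm",
    "predict_proba",
    "predict",
]


@dataclass(frozen=True)
class KernelSpec:
    """Kernel function: ``rbf`` with width gamma, k(x,x') = exp(-gamma*||x-x'||^2),
    or ``linear``, k(x,x') = x.x'."""

    name: str = "rbf"
    gamma: float | None = None

    def __post_init__(self):
        if self.name not in ("rbf", "linear"):
            raise ValidationError(f"unknown kernel {self.name!r}")
        if self.name == "rbf" and (self.gamma is None or self.gamma <= 0):
            raise ValidationError("rbf kernel requires gamma > 0")


def default_gamma(X: np.ndarray) -> float:
    """Scale-adaptive RBF width 1 / (d * Var(X)) (pooled feature variance)."""
    X = np.asarray(X, dtype=float)
    v = float(X.var())
    return 1.0 / (X.shape[1] * v) if v > 0 else 1.0


def kernel_matrix(A: np.ndarray, B: np.ndarray, kernel: KernelSpec) -> np.ndarray:
    """Pairwise kernel evaluations: entry (i, j) = k(A_i, B_j)."""
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValidationError(f"dimension mismatch: {A.shape[1]} vs {B.shape[1]}")
    if kernel.name == "linear":
        return A @ B.T
    return np.exp(-kernel.gamma * cdist(A, B, "sqeuclidean"))


@dataclass(frozen=True)
class KLRModel:
    """Fitted (kernel) softmax model.

    ``weights`` has one column per class (last column all-zero by the
    identifiability convention); ``reference_points`` are all training
    points for full KLR, or the import vectors for an IVM fit.
    """

    kernel: KernelSpec
    reference_points: np.ndarray  # (m, d)
    weights: np.ndarray  # (m, K)
    bias: np.ndarray  # (K,)
    lam: float
    classes: tuple[str, ...]
    objective: float = np.nan


@dataclass(frozen=True)
class IVMFitReport:
    """Trace of the greedy import-vector selection."""

    import_indices: tuple[int, ...]
    objective_trace: tuple[float, ...]  # Q after each addition
    epsilon_trace: tuple[float, ...]  # relative decrease ratios (aligned)
    stopped_reason: str  # converged | exhausted | max_size


def _softmax(F: np.ndarray) -> np.ndarray:
    F = F - F.max(axis=1, keepdims=True)
    P = np.exp(F)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _encode_labels(labels: Sequence[str], classes: Sequence[str] | None):
    labels = list(labels)
    if classes is None:
        classes = tuple(dict.fromkeys(labels))
    else:
        classes = tuple(classes)
        unknown = set(labels) - set(classes)
        if unknown:
            raise ValidationError(f"labels outside declared classes: {sorted(unknown)}")
    present = [c for c in classes if c in set(labels)]
    if len(present) < 2:
        raise ValidationError("need at least 2 classes present to fit a classifier")
    lut = {c: i for i, c in enumerate(classes)}
    y = np.array([lut[l] for l in labels], dtype=int)
    Y = np.zeros((len(labels), len(classes)))
    Y[np.arange(len(labels)), y] = 1.0
    return y, Y, classes


class _KLRProblem:
    """Regularized softmax objective over kernel features.

    Parameterized by the free weight block W (m x (K-1)) and bias b (K-1,);
    the last class is pinned at zero. ``Knm`` is the n x m matrix of kernel
    evaluations between training points and reference points, ``Krr`` the
    m x m penalty (Gram) matrix.
    """

    def __init__(self, Knm, Krr, Y, lam, penalty="gram"):
        self.Knm = Knm
        self.Y = Y
        self.lam = lam
        self.n, self.m = Knm.shape
        self.K = Y.shape[1]
        if penalty == "gram":
            self.Pen = Krr
        elif penalty == "identity":
            self.Pen = np.eye(self.m)
        else:
            raise ValidationError(f"unknown penalty {penalty!r}")

    def unpack(self, theta):
        Kf = self.K - 1
        W = theta[: self.m * Kf].reshape(self.m, Kf)
        b = theta[self.m * Kf :]
        return W, b

    def scores(self, W, b):
        F = np.zeros((self.n, self.K))
        F[:, : self.K - 1] = self.Knm @ W + b
        return F

    def value(self, theta):
        W, b = self.unpack(theta)
        F = self.scores(W, b)
        Fs = F - F.max(axis=1, keepdims=True)
        log_z = np.log(np.exp(Fs).sum(axis=1)) + F.max(axis=1)
        nll = float(log_z.sum() - (self.Y * F).sum())
        pen = 0.5 * self.lam * float(np.einsum("ik,ij,jk->", W, self.Pen, W))
        return nll + pen

    def grad(self, theta):
        W, b = self.unpack(theta)
        P = _softmax(self.scores(W, b))
        G = (P - self.Y)[:, : self.K - 1]
        gW = self.Knm.T @ G + self.lam * (self.Pen @ W)
        gb = G.sum(axis=0)
        return np.concatenate([gW.ravel(), gb])

    def hessian(self, theta):
        W, b = self.unpack(theta)
        P = _softmax(self.scores(W, b))
        Kf = self.K - 1
        m = self.m
        dim = (m + 1) * Kf
        H = np.zeros((dim, dim))
        Kn = self.Knm
        for c in range(Kf):
            for c2 in range(c, Kf):
                r = P[:, c] * ((1.0 if c == c2 else 0.0) - P[:, c2])
                KtRK = Kn.T @ (Kn * r[:, None])
                Ktr = Kn.T @ r
                rs = float(r.sum())
                block = np.zeros((m + 1, m + 1))
                block[:m, :m] = KtRK
                block[:m, m] = Ktr
                block[m, :m] = Ktr
                block[m, m] = rs
                if c == c2:
                    block[:m, :m] += self.lam * self.Pen
                sl_c = self._slice(c, m, Kf)
                sl_c2 = self._slice(c2, m, Kf)
                H[np.ix_(sl_c, sl_c2)] += block
                if c != c2:
                    H[np.ix_(sl_c2, sl_c)] += block.T
        return H

    @staticmethod
    def _slice(c, m, Kf):
        # indices of (W[:, c], b[c]) within theta
        return np.concatenate([np.arange(c, m * Kf, Kf), [m * Kf + c]])

    # theta layout: W stored row-major (m, Kf) then b; _slice must match
    # reshape order, so W.ravel() interleaves classes within each row.


def _newton(problem: _KLRProblem, theta0, tol, max_iter, strict=True):
    """Damped Newton with backtracking; monotone in the objective."""
    theta = theta0.copy()
    q = problem.value(theta)
    g = problem.grad(theta)
    for _ in range(max_iter):
        if np.linalg.norm(g, np.inf) <= tol:
            return theta, q, g
        H = problem.hessian(theta)
        jitter = 1e-10 * (1.0 + np.trace(H) / H.shape[0])
        try:
            step = np.linalg.solve(H + jitter * np.eye(H.shape[0]), g)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(H, g, rcond=None)[0]
        t = 1.0
        for _ls in range(40):
            cand = theta - t * step
            qc = problem.value(cand)
            if qc <= q - 1e-4 * t * float(g @ step):
                break
            t *= 0.5
        else:
            cand, qc = theta, q  # no progress possible
        if qc > q:
            break
        theta, q = cand, qc
        g = problem.grad(theta)
    if np.linalg.norm(g, np.inf) <= tol:
        return theta, q, g
    if strict:
        raise ConvergenceError(
            f"Newton did not reach gradient tolerance {tol} in {max_iter} "
            f"iterations (|grad|_inf = {np.linalg.norm(g, np.inf):.3e})",
            grad_norm=float(np.linalg.norm(g, np.inf)),
        )
    return theta, q, g


def _fit_on_kernel(Knm, Krr, Y, lam, tol, max_iter, theta0=None, strict=True,
                   penalty="gram"):
    problem = _KLRProblem(Knm, Krr, Y, lam, penalty=penalty)
    if theta0 is None:
        theta0 = np.zeros((problem.m + 1) * (problem.K - 1))
    theta, q, g = _newton(problem, theta0, tol, max_iter, strict=strict)
    W_free, b_free = problem.unpack(theta)
    W = np.zeros((problem.m, problem.K))
    W[:, : problem.K - 1] = W_free
    b = np.concatenate([b_free, [0.0]])
    return W, b, q, theta


def fit_klr(
    X: np.ndarray,
    labels: Sequence[str],
    kernel: KernelSpec,
    lam: float = 1e-2,
    tol: float = 1e-6,
    max_iter: int = 100,
    classes: Sequence[str] | None = None,
    penalty: str = "gram",
) -> KLRModel:
    """Fit full kernel logistic regression (all training points as references).

    Raises :class:`ConvergenceError` (carrying the last gradient norm) if the
    Newton iterations do not reach ``tol`` within ``max_iter``.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("X must be 2-D with at least 2 rows")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if kernel.name == "rbf" and lam == 0:
        raise ValidationError("rbf kernel requires lambda > 0 for a bounded optimum")
    _, Y, classes = _encode_labels(labels, classes)
    Knn = kernel_matrix(X, X, kernel)
    W, b, q, _ = _fit_on_kernel(Knn, Knn, Y, lam, tol, max_iter, penalty=penalty)
    return KLRModel(kernel=kernel, reference_points=X.copy(), weights=W, bias=b,
                    lam=lam, classes=classes, objective=q)


def fit_ivm(
    X: np.ndarray,
    labels: Sequence[str],
    kernel: KernelSpec,
    lam: float = 1e-2,
    epsilon: float = 1e-3,
    delta_t: int = 1,
    max_import: int | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    classes: Sequence[str] | None = None,
    exact_greedy: bool = False,
    candidate_iters: int = 2,
    candidate_subsample: int | None = None,
    subsample_seed: int = 0,
    penalty: str = "gram",
) -> tuple[KLRModel, IVMFitReport]:
    """Greedy import-vector selection for sparse KLR.

    At each step every remaining training point is tried as the next import
    vector: its weights are refit (warm-started bounded Newton updates by
    default, full refit when ``exact_greedy``) and the point minimizing the
    regularized objective Q is kept, with ties broken toward the smaller
    training index. Selection stops when the relative decrease
    ``|Q_t - Q_{t-delta_t}| / |Q_t|`` drops below ``epsilon``, when all
    points are import vectors, or at ``max_import``.

    ``candidate_subsample`` evaluates only a seeded random subset of that
    size of the remaining candidates per step — a standard large-n speedup
    that leaves every stopping rule unchanged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("X must be 2-D with at least 2 rows")
    if epsilon < 0:
        raise ValidationError("epsilon must be >= 0")
    if delta_t < 1:
        raise ValidationError("delta_t must be >= 1")
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    if kernel.name == "rbf" and lam == 0:
        raise ValidationError("rbf kernel requires lambda > 0 for a bounded optimum")
    _, Y, classes = _encode_labels(labels, classes)
    n = X.shape[0]
    Kf = Y.shape[1] - 1
    max_import = n if max_import is None else min(int(max_import), n)
    Knn = kernel_matrix(X, X, kernel)

    v: list[int] = []
    # bias-only starting model: Q with an empty import set
    W_cur = np.zeros((0, Y.shape[1]))
    _, b_cur, q_cur, theta_cur = _fit_on_kernel(
        np.zeros((n, 0)), np.zeros((0, 0)), Y, lam, tol, max_iter, penalty=penalty
    )
    trace: list[float] = []
    eps_trace: list[float] = []
    history: list[float] = [q_cur]  # Q_0 (empty set), then Q after each step
    reason = "exhausted"
    sub_rng = np.random.default_rng(subsample_seed)
    while len(v) < max_import:
        candidates = [j for j in range(n) if j not in set(v)]
        if candidate_subsample is not None and len(candidates) > candidate_subsample:
            pick = sub_rng.choice(len(candidates), size=candidate_subsample,
                                  replace=False)
            candidates = [candidates[i] for i in sorted(pick)]
        best_j, best_q = None, np.inf
        for j in candidates:
            v_try = v + [j]
            Knm = Knn[:, v_try]
            Krr = Knn[np.ix_(v_try, v_try)]
            theta0 = _pad_theta(theta_cur, len(v), Kf)
            problem = _KLRProblem(Knm, Krr, Y, lam, penalty=penalty)
            if exact_greedy:
                theta_j, q_j, _ = _newton(problem, theta0, tol, max_iter, strict=True)
            else:
                theta_j, q_j, _ = _newton(problem, theta0, tol, candidate_iters,
                                          strict=False)
            if q_j < best_q - 1e-12:
                best_j, best_q = j, q_j
        assert best_j is not None
        v.append(best_j)
        Knm = Knn[:, v]
        Krr = Knn[np.ix_(v, v)]
        theta0 = _pad_theta(theta_cur, len(v) - 1, Kf)
        W_cur, b_cur, q_cur, theta_cur = _fit_on_kernel(
            Knm, Krr, Y, lam, tol, max_iter, theta0=theta0, penalty=penalty
        )
        trace.append(q_cur)
        history.append(q_cur)
        t = len(trace)
        if t >= delta_t:
            q_prev = history[t - delta_t]
            ratio = abs(q_cur - q_prev) / abs(q_cur) if q_cur != 0 else 0.0
            eps_trace.append(ratio)
            if ratio < epsilon:
                reason = "converged"
                break
        else:
            eps_trace.append(np.nan)
    else:
        reason = "max_size" if len(v) < n else "exhausted"
    if len(v) == n and reason != "converged":
        reason = "exhausted"
    model = KLRModel(kernel=kernel, reference_points=X[v].copy(), weights=W_cur,
                     bias=b_cur, lam=lam, classes=classes, objective=q_cur)
    report = IVMFitReport(import_indices=tuple(v), objective_trace=tuple(trace),
                          epsilon_trace=tuple(eps_trace), stopped_reason=reason)
    return model, report


def _pad_theta(theta, m_old, Kf):
    """Embed a solution over m_old reference points into an (m_old+1)-point
    parameter vector, initializing the new point's weights at zero."""
    W = theta[: m_old * Kf].reshape(m_old, Kf) if m_old else np.zeros((0, Kf))
    b = theta[m_old * Kf :]
    W_new = np.vstack([W, np.zeros((1, Kf))])
    return np.concatenate([W_new.ravel(), b])


def predict_proba(model: KLRModel, X: np.ndarray) -> np.ndarray:
    """Class posterior probabilities; rows sum to 1."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != model.reference_points.shape[1]:
        raise ValidationError(
            f"X has {X.shape[1]} columns, model expects {model.reference_points.shape[1]}"
        )
    Kxm = kernel_matrix(X, model.reference_points, model.kernel)
    P = _softmax(Kxm @ model.weights + model.bias)
    return P / P.sum(axis=1, keepdims=True)


def predict(model: KLRModel, X: np.ndarray) -> np.ndarray:
    """Argmax class labels; ties break toward the earlier class in
    ``model.classes``."""
    P = predict_proba(model, X)
    idx = np.argmax(P, axis=1)  # first maximum wins
    return np.array([model.classes[i] for i in idx])
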