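"""Registry of fit/predict classifier adapters.

Each adapter wraps one of the package's classifiers (or the scikit-learn
SVM baseline) behind a uniform ``fit(X, labels) -> self`` /
``predict(X) -> labels`` surface so the evaluation harness can treat them
interchangeably. Registered spec strings:

``svm-linear``, ``svm-rbf``
    Maximum-margin baseline (scikit-learn SVC), multiclass one-versus-all.
``ivm``
    Import vector machine (sparse kernel logistic regression).
``elm``, ``relm``
    (Regularized) extreme learning machine; inputs standardized on the
    training fold so random Uniform(-1,1) hidden weights operate on O(1)
    inputs regardless of feature units.
``relm-hybrid``
    RELM with the reliability-gated sparse-representation fallback.

Custom classifiers can be added with :func:`register`.
"""

from __future__ import annotations

from typing import Callable, Sequence

import numpy as np
from sklearn.multiclass import OneVsRestClassifier
from sklearn.svm import SVC

from . import elm as _elm
from . import klr as _klr
from ._errors import ConfigurationError
from ._seeds import derive_seed

__all__ = ["register", "make_classifier", "registered_specs",
           "SVMClassifier", "IVMClassifier", "ELMClassifier"]

_REGISTRY: dict[str, Callable] = {}


def register(spec: str, factory: Callable) -> None:
    """Register ``factory(seed=..., classes=..., **params)`` under ``spec``."""
    _REGISTRY[spec] = factory


def registered_specs() -> tuple[str, ...]:
    return tuple(sorted(_REGISTRY))


def make_classifier(spec: str, seed: int = 0, classes: Sequence[str] | None = None,
                    **params):
    if spec not in _REGISTRY:
        raise ConfigurationError(
            f"unknown classifier spec {spec!r}; registered: {registered_specs()}"
        )
    return _REGISTRY[spec](seed=seed, classes=classes, **params)


class _FoldStandardizer:
    """Training-fold mean/SD standardization (constant columns left as-is)."""

    def fit(self, X):
        self.mean_ = X.mean(axis=0)
        sd = X.std(axis=0, ddof=0)
        sd[sd == 0] = 1.0
        self.sd_ = sd
        return self

    def transform(self, X):
        return (X - self.mean_) / self.sd_


class SVMClassifier:
    """One-versus-all SVM baseline (delegates to scikit-learn SVC).

    Inputs are standardized on the training fold by default: the solver's
    convergence degrades badly on raw mm^3-scale volume features, and the
    affine rescaling leaves the maximum-margin decision contract intact.
    """

    def __init__(self, kernel: str = "linear", C: float = 1.0,
                 gamma: float | str = "scale", standardize: bool = True,
                 seed: int = 0, classes: Sequence[str] | None = None):
        self.kernel = kernel
        self.C = C
        self.gamma = gamma
        self.standardize = standardize
        self.classes = tuple(classes) if classes else None

    def fit(self, X, labels):
        X = np.asarray(X, dtype=float)
        self._scaler = _FoldStandardizer().fit(X) if self.standardize else None
        Xs = self._scaler.transform(X) if self._scaler else X
        self._est = OneVsRestClassifier(
            SVC(kernel=self.kernel, C=self.C, gamma=self.gamma)
        )
        self._est.fit(Xs, np.asarray(labels))
        return self

    def _prep(self, X):
        X = np.asarray(X, dtype=float)
        return self._scaler.transform(X) if self._scaler else X

    def predict(self, X):
        return self._est.predict(self._prep(X))

    def decision_function(self, X):
        return self._est.decision_function(self._prep(X))


class IVMClassifier:
    """Import vector machine with scale-adaptive RBF width.

    ``lam`` defaults to 1e-2; passing ``lambda_grid`` selects lam by inner
    3-fold cross-validation on the training fold instead.
    """

    def __init__(self, gamma: float | None = None, lam: float = 1e-2,
                 epsilon: float = 1e-3, delta_t: int = 1, max_import: int = 30,
                 lambda_grid: Sequence[float] | None = None,
                 candidate_subsample: int | None = 50, candidate_iters: int = 1,
                 kernel: str = "rbf", seed: int = 0,
                 classes: Sequence[str] | None = None):
        self.gamma = gamma
        self.lam = lam
        self.epsilon = epsilon
        self.delta_t = delta_t
        self.max_import = max_import
        self.lambda_grid = lambda_grid
        self.candidate_subsample = candidate_subsample
        self.candidate_iters = candidate_iters
        self.kernel = kernel
        self.seed = seed
        self.classes = tuple(classes) if classes else None

    def _kernel_spec(self, X):
        gamma = self.gamma if self.gamma is not None else _klr.default_gamma(X)
        return _klr.KernelSpec(self.kernel, gamma if self.kernel == "rbf" else None)

    def fit(self, X, labels):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        spec = self._kernel_spec(X)
        lam = self.lam
        if self.lambda_grid is not None:
            lam = self._select_lambda(X, labels, spec)
        self.model_, self.report_ = _klr.fit_ivm(
            X, labels, spec, lam=lam, epsilon=self.epsilon, delta_t=self.delta_t,
            max_import=self.max_import, classes=self.classes,
            candidate_subsample=self.candidate_subsample,
            candidate_iters=self.candidate_iters,
            subsample_seed=derive_seed(self.seed, "ivm-subsample"),
        )
        self.lam_ = lam
        return self

    def _select_lambda(self, X, labels, spec):
        from sklearn.model_selection import StratifiedKFold

        cv = StratifiedKFold(3, shuffle=True, random_state=derive_seed(self.seed, "lam"))
        best_lam, best_acc = None, -np.inf
        for lam in self.lambda_grid:
            accs = []
            for tr, te in cv.split(X, labels):
                model, _ = _klr.fit_ivm(
                    X[tr], labels[tr], spec, lam=lam, epsilon=self.epsilon,
                    delta_t=self.delta_t, max_import=self.max_import,
                    classes=self.classes,
                    candidate_subsample=self.candidate_subsample,
                    candidate_iters=self.candidate_iters,
                    subsample_seed=derive_seed(self.seed, "ivm-subsample", 1),
                )
                accs.append(float(np.mean(_klr.predict(model, X[te]) == labels[te])))
            acc = float(np.mean(accs))
            if acc > best_acc:
                best_lam, best_acc = lam, acc
        return best_lam

    def predict(self, X):
        return _klr.predict(self.model_, np.asarray(X, dtype=float))

    def predict_proba(self, X):
        return _klr.predict_proba(self.model_, np.asarray(X, dtype=float))


class ELMClassifier:
    """(Regularized) extreme learning machine adapter.

    ``C=None`` fits plain ELM (pseudoinverse); a positive ``C`` fits the
    ridge solution. ``threshold > 0`` enables the reliability-gated
    sparse-representation fallback (the training fold is retained as the
    dictionary). Hidden width ``L`` is capped at ``10 * n_train``.
    """

    def __init__(self, L: int = 1000, activation: str = "relu",
                 C: float | None = None, threshold: float = 0.0,
                 n_nonzero: int = 10, standardize: bool = True, seed: int = 0,
                 classes: Sequence[str] | None = None):
        self.L = L
        self.activation = activation
        self.C = C
        self.threshold = threshold
        self.n_nonzero = n_nonzero
        self.standardize = standardize
        self.seed = seed
        self.classes = tuple(classes) if classes else None

    def fit(self, X, labels):
        X = np.asarray(X, dtype=float)
        labels = np.asarray(labels)
        classes = self.classes or tuple(dict.fromkeys(labels.tolist()))
        self._scaler = _FoldStandardizer().fit(X) if self.standardize else None
        Xs = self._scaler.transform(X) if self._scaler else X
        n, d = Xs.shape
        L = min(self.L, 10 * n)
        W, b = _elm.random_hidden_layer(d, L, self.seed)
        H = _elm.hidden_output(W, b, self.activation, Xs)
        lut = {c: i for i, c in enumerate(classes)}
        T = np.zeros((n, len(classes)))
        T[np.arange(n), [lut[l] for l in labels]] = 1.0
        if self.C is None:
            beta = _elm.fit_elm(H, T)
            C = np.inf
        else:
            beta = _elm.fit_relm(H, T, self.C)
            C = self.C
        dictionary = (Xs.copy(), labels.copy()) if self.threshold > 0 else None
        self.model_ = _elm.ELMModel(
            input_weights=W, biases=b, activation=self.activation, beta=beta,
            C=C, classes=tuple(classes), seed=self.seed, dictionary=dictionary,
        )
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        Xs = self._scaler.transform(X) if self._scaler else X
        return _elm.predict_hybrid(self.model_, Xs, self.threshold,
                                   n_nonzero=self.n_nonzero)

    def predict_scores(self, X):
        X = np.asarray(X, dtype=float)
        Xs = self._scaler.transform(X) if self._scaler else X
        return _elm.predict_scores(self.model_, Xs)


register("svm-linear", lambda seed=0, classes=None, **p: SVMClassifier(
    kernel="linear", seed=seed, classes=classes, **p))
register("svm-rbf", lambda seed=0, classes=None, **p: SVMClassifier(
    kernel="rbf", seed=seed, classes=classes, **p))
register("ivm", lambda seed=0, classes=None, **p: IVMClassifier(
    seed=seed, classes=classes, **p))
register("elm", lambda seed=0, classes=None, **p: ELMClassifier(
    C=None, seed=seed, classes=classes, **p))
register("relm", lambda seed=0, classes=None, **p: ELMClassifier(
    C=p.pop("C", 1.0), seed=seed, classes=classes, **p))
register("relm-hybrid", lambda seed=0, classes=None, **p: ELMClassifier(
    C=p.pop("C", 1.0), threshold=p.pop("threshold", 0.2), seed=seed,
    classes=classes, **p))
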