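"""PCA feature selection with training-fold-only fitting.

Each principal component is a linear combination of the original features;
components are ordered by decreasing explained variance, and projecting onto
the top ``k`` of them maps a subject from the ``d``-dimensional feature
space to a ``k``-dimensional subspace. ``select_k`` grid-searches ``k`` by
inner cross-validation, refitting the PCA inside every inner training fold
so no test information leaks into the loadings.

The component sign is fixed (largest-magnitude loading made positive) so
results are deterministic across linear-algebra backends.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._errors import ValidationError
from ._seeds import derive_seed

__all__ = ["DEFAULT_K", "DEFAULT_K_GRID", "PCAModel", "fit_pca", "transform", "select_k"]

#: Grid of component counts searched by default: 2 to 20 in steps of two.
DEFAULT_K_GRID: tuple[int, ...] = tuple(range(2, 21, 2))

#: Component count used when grid search is disabled.
DEFAULT_K: int = 10


@dataclass(frozen=True)
class PCAModel:
    """Fitted PCA: centering/scaling vectors and top-k loadings.

    ``components`` rows are orthonormal; ``explained_variance`` is the
    per-component sample variance (ddof=1), non-increasing.
    """

    mean: np.ndarray  # (d,)
    scale: np.ndarray  # (d,), ones if standardization off
    components: np.ndarray  # (k, d)
    explained_variance: np.ndarray  # (k,)
    k: int


def fit_pca(X: np.ndarray, k: int, standardize: bool = True) -> PCAModel:
    """Fit a top-``k`` PCA on the rows of ``X``.

    Standardization (on by default) divides each centered column by its
    sample SD, appropriate when features are volumes of structures with very
    different scales.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValidationError("X must be a 2-D matrix")
    n, d = X.shape
    if n < 2:
        raise ValidationError(f"need at least 2 rows to fit PCA, got {n}")
    kmax = min(n - 1, d)
    if not 1 <= k <= kmax:
        raise ValidationError(f"k={k} outside valid range [1, {kmax}] for shape {X.shape}")
    mean = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        zero = np.nonzero(scale == 0)[0]
        if zero.size:
            raise ValidationError(
                f"zero-variance column(s) {zero.tolist()} cannot be standardized"
            )
    else:
        scale = np.ones(d)
    Z = (X - mean) / scale
    _, s, Vt = np.linalg.svd(Z, full_matrices=False)
    components = Vt[:k].copy()
    explained = (s[:k] ** 2) / (n - 1)
    # deterministic sign: largest-|loading| entry of each component positive
    for i in range(k):
        j = int(np.argmax(np.abs(components[i])))
        if components[i, j] < 0:
            components[i] = -components[i]
    return PCAModel(mean=mean, scale=scale, components=components,
                    explained_variance=explained, k=k)


def transform(model: PCAModel, X: np.ndarray) -> np.ndarray:
    """Project rows of ``X`` onto the fitted components: scores of shape (m, k)."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.mean.shape[0]:
        raise ValidationError(
            f"X has {X.shape[1]} columns, model expects {model.mean.shape[0]}"
        )
    return ((X - model.mean) / model.scale) @ model.components.T


def select_k(
    X: np.ndarray,
    labels: Sequence[str],
    classifier_factory,
    grid: Sequence[int] | None = None,
    inner_splits: int = 5,
    standardize: bool = True,
    seed: int = 0,
) -> int:
    """Pick the component count from ``grid`` maximizing inner-CV accuracy.

    ``classifier_factory(fold_seed) -> estimator`` must return a fresh
    fit/predict object per inner fold. PCA is refit inside every inner
    training fold. Ties break toward smaller ``k``; infeasible ``k`` values
    (too large for an inner training fold) are skipped with a warning.
    """
    grid = tuple(DEFAULT_K_GRID if grid is None else grid)
    if not grid:
        raise ValidationError("empty k grid")
    if len(grid) == 1:
        k = int(grid[0])
        n, d = np.asarray(X).shape
        if not 1 <= k <= min(n - 1, d):
            raise ValidationError(f"k={k} infeasible for data of shape {(n, d)}")
        return k
    X = np.asarray(X, dtype=float)
    y = np.asarray(labels)
    cv = StratifiedKFold(n_splits=inner_splits, shuffle=True,
                         random_state=derive_seed(seed, "select_k"))
    folds = list(cv.split(X, y))
    best_k, best_acc = None, -np.inf
    for k in sorted(int(k) for k in grid):
        accs = []
        feasible = True
        for f, (tr, te) in enumerate(folds):
            if k > min(len(tr) - 1, X.shape[1]):
                feasible = False
                break
            model = fit_pca(X[tr], k, standardize=standardize)
            clf = classifier_factory(derive_seed(seed, "select_k", k, f))
            clf.fit(transform(model, X[tr]), y[tr])
            accs.append(float(np.mean(clf.predict(transform(model, X[te])) == y[te])))
        if not feasible:
            warnings.warn(f"k={k} infeasible for inner folds; skipped", stacklevel=2)
            continue
        acc = float(np.mean(accs))
        if acc > best_acc:  # strict > ties toward smaller k (grid ascending)
            best_k, best_acc = k, acc
    if best_k is None:
        raise ValidationError("every k in the grid was infeasible for the inner folds")
    return best_k
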