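"""Evaluation harness: confusion-matrix metrics, cross-validation
protocols, and permutation-test significance.

Metrics follow the standard binary definitions — ACC = (TP+TN)/total,
SEN = TP/(TP+FN), SPE = TN/(TN+FP) — with the first class of the declared
order playing the positive role. Multiclass matrices are reduced
one-versus-all: each class in turn is treated as positive, binary metrics
are computed on the collapsed 2x2 matrix, and the unweighted (macro)
average is reported; multiclass accuracy is trace/total.

Three stratified protocols are provided: repeated 70/30 splits
(``split7030``, default 100 repeats), repeated 10-fold CV (``kfold10``,
default 10 repeats), and leave-one-out (``loo``; repetition re-seeds
stochastic classifiers such as the ELM hidden layer). All fitting — PCA,
component-count selection, classifier training — is confined to the
training fold of each split.

The permutation test re-runs the chosen protocol on label-permuted copies
of the cohort to build the null distribution of the accuracy statistic; the
p-value uses the add-one estimator p = (1 + #{null >= observed}) / (1 + B),
which can never be exactly zero.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, StratifiedShuffleSplit

from . import pca as _pca
from ._errors import ValidationError
from ._seeds import derive_seed
from .classifiers import make_classifier
from .data_io import FeatureTable
from .klr import KernelSpec
from .synthetic import permute_labels

__all__ = [
    "ConfusionMatrix",
    "EvalResult",
    "PermutationResult",
    "confusion",
    "binary_metrics",
    "ova_metrics",
    "fit_svm",
    "cross_validate",
    "permutation_test",
    "DEFAULT_REPEATS",
]

logger = logging.getLogger(__name__)

#: Default repetition counts per protocol.
DEFAULT_REPEATS = {"split7030": 100, "kfold10": 10, "loo": 10}


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count matrix; rows are true classes, columns predicted."""

    counts: np.ndarray
    classes: tuple[str, ...]

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "classes", tuple(self.classes))
        K = len(self.classes)
        if counts.shape != (K, K):
            raise ValidationError(f"counts shape {counts.shape} != ({K}, {K})")
        if (counts < 0).any():
            raise ValidationError("negative confusion counts")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class EvalResult:
    """Per-fold and aggregate cross-validation metrics (percent scale)."""

    per_fold: tuple  # of (ConfusionMatrix, acc, sen, spe), percents
    mean_acc: float
    mean_sen: float
    mean_spe: float
    sd_acc: float
    scheme: str
    repeats: int
    seed: int
    classifier: str = ""
    selected_k: tuple = ()

    @property
    def pooled_confusion(self) -> ConfusionMatrix:
        cms = [cm.counts for cm, *_ in self.per_fold]
        return ConfusionMatrix(np.sum(cms, axis=0), self.per_fold[0][0].classes)


@dataclass(frozen=True)
class PermutationResult:
    """Observed accuracy, its permutation null, and the add-one p-value."""

    observed_stat: float  # percent
    null_stats: tuple[float, ...]  # percents
    p_value: float


def confusion(true_labels: Sequence[str], predicted_labels: Sequence[str],
              classes: Sequence[str]) -> ConfusionMatrix:
    """Tally counts[i, j] = #{true = classes[i] and predicted = classes[j]}."""
    t = list(true_labels)
    p = list(predicted_labels)
    if len(t) != len(p):
        raise ValidationError(f"{len(t)} true labels vs {len(p)} predictions")
    classes = tuple(classes)
    lut = {c: i for i, c in enumerate(classes)}
    unknown = (set(t) | set(p)) - set(classes)
    if unknown:
        raise ValidationError(f"labels outside declared classes: {sorted(unknown)}")
    counts = np.zeros((len(classes), len(classes)), dtype=int)
    for ti, pi in zip(t, p):
        counts[lut[ti], lut[pi]] += 1
    return ConfusionMatrix(counts, classes)


def binary_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(ACC, SEN, SPE) as fractions, first class positive.

    Zero-denominator ratios are returned as NaN with a warning.
    """
    if len(cm.classes) != 2:
        raise ValidationError(f"binary metrics need K=2, got K={len(cm.classes)}")
    tp, fn = int(cm.counts[0, 0]), int(cm.counts[0, 1])
    fp, tn = int(cm.counts[1, 0]), int(cm.counts[1, 1])
    total = tp + tn + fp + fn
    if total == 0:
        raise ValidationError("empty confusion matrix")
    acc = (tp + tn) / total
    if tp + fn == 0:
        warnings.warn("no positive subjects: sensitivity undefined", stacklevel=2)
        sen = float("nan")
    else:
        sen = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no negative subjects: specificity undefined", stacklevel=2)
        spe = float("nan")
    else:
        spe = tn / (tn + fp)
    return acc, sen, spe


def _collapse(cm: ConfusionMatrix, pos: int) -> ConfusionMatrix:
    """One-versus-all reduction with class index ``pos`` as positive."""
    c = cm.counts
    tp = c[pos, pos]
    fn = c[pos].sum() - tp
    fp = c[:, pos].sum() - tp
    tn = c.sum() - tp - fn - fp
    return ConfusionMatrix(np.array([[tp, fn], [fp, tn]]),
                           (cm.classes[pos], "rest"))


def ova_metrics(cm: ConfusionMatrix) -> tuple[float, float, float]:
    """(ACC, macro-SEN, macro-SPE) as fractions.

    Accuracy is trace/total; sensitivity and specificity are computed per
    class one-versus-all and unweighted-averaged (NaN-aware).
    """
    if cm.total == 0:
        raise ValidationError("empty confusion matrix")
    acc = float(np.trace(cm.counts)) / cm.total
    sens, spes = [], []
    for i in range(len(cm.classes)):
        _, sen, spe = binary_metrics(_collapse(cm, i))
        sens.append(sen)
        spes.append(spe)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return acc, float(np.nanmean(sens)), float(np.nanmean(spes))


def fit_svm(X: np.ndarray, labels: Sequence[str], kernel: KernelSpec,
            C_svm: float = 1.0):
    """Maximum-margin baseline with the requested kernel, multiclass OVA.

    Delegates to scikit-learn; returns a fitted handle with ``predict`` and
    ``decision_function``.
    """
    from .classifiers import SVMClassifier

    if C_svm <= 0:
        raise ValidationError("C_svm must be > 0")
    gamma = kernel.gamma if kernel.gamma is not None else "scale"
    clf = SVMClassifier(kernel=kernel.name, C=C_svm, gamma=gamma)
    return clf.fit(np.asarray(X, dtype=float), labels)


def _iter_folds(y: np.ndarray, scheme: str, repeats: int, seed: int):
    """Yield (repeat, fold_index, train_idx, test_idx) for the protocol."""
    n = len(y)
    if scheme == "split7030":
        for r in range(repeats):
            ss = StratifiedShuffleSplit(n_splits=1, test_size=0.3,
                                        random_state=derive_seed(seed, "split", r))
            for tr, te in ss.split(np.zeros(n), y):
                yield r, 0, tr, te
    elif scheme == "kfold10":
        for r in range(repeats):
            kf = StratifiedKFold(n_splits=10, shuffle=True,
                                 random_state=derive_seed(seed, "kfold", r))
            for f, (tr, te) in enumerate(kf.split(np.zeros(n), y)):
                yield r, f, tr, te
    elif scheme == "loo":
        loo = LeaveOneOut()
        folds = list(loo.split(np.zeros(n)))
        for r in range(repeats):
            for f, (tr, te) in enumerate(folds):
                yield r, f, tr, te
    else:
        raise ValidationError(f"unknown CV scheme {scheme!r}")


def cross_validate(
    table: FeatureTable,
    classifier_spec: str,
    scheme: str = "kfold10",
    repeats: int | None = None,
    seed: int = 0,
    pca_config: dict | None = None,
    classifier_params: dict | None = None,
) -> EvalResult:
    """Run a stratified CV protocol and aggregate ACC/SEN/SPE (percent).

    ``pca_config`` keys: ``k`` (fixed component count), ``grid`` (inner-CV
    search overrides ``k``), ``standardize``. ``None`` disables the PCA
    stage. All fitting is confined to training folds; per-fold metrics are
    binary for 2-class cohorts and one-versus-all macro otherwise.
    """
    if scheme not in DEFAULT_REPEATS:
        raise ValidationError(f"unknown CV scheme {scheme!r}")
    repeats = DEFAULT_REPEATS[scheme] if repeats is None else int(repeats)
    if repeats < 1:
        raise ValidationError("repeats must be >= 1")
    params = dict(classifier_params or {})
    classes = tuple(c for c in table.classes if c in set(table.labels))
    if len(classes) < 2:
        raise ValidationError("need at least 2 classes present to evaluate")
    y = np.asarray(table.labels)
    X = table.values
    per_fold = []
    selected_k = []
    for r, f, tr, te in _iter_folds(y, scheme, repeats, seed):
        if len(set(y[tr])) < 2:
            raise ValidationError(
                f"training fold {f} of repeat {r} contains a single class"
            )
        Xtr, Xte = X[tr], X[te]
        if pca_config is not None:
            std = bool(pca_config.get("standardize", True))
            grid = pca_config.get("grid")
            fold_seed = derive_seed(seed, "fold", r, f)
            if grid:
                k = _pca.select_k(
                    Xtr, y[tr],
                    lambda s: make_classifier(classifier_spec, seed=s,
                                              classes=classes, **params),
                    grid=grid, standardize=std, seed=fold_seed,
                )
            else:
                k = int(pca_config.get("k", _pca.DEFAULT_K))
                k = min(k, len(tr) - 1, X.shape[1])
            model = _pca.fit_pca(Xtr, k, standardize=std)
            Xtr, Xte = _pca.transform(model, Xtr), _pca.transform(model, Xte)
            selected_k.append(k)
            logger.debug("repeat %d fold %d: k=%d", r, f, k)
        clf = make_classifier(classifier_spec, seed=derive_seed(seed, "clf", r, f),
                              classes=classes, **params)
        clf.fit(Xtr, y[tr])
        pred = np.asarray(clf.predict(Xte))
        cm = confusion(y[te], pred, classes)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if len(classes) == 2:
                acc, sen, spe = binary_metrics(cm)
            else:
                acc, sen, spe = ova_metrics(cm)
        per_fold.append((cm, 100 * acc, 100 * sen, 100 * spe))
    accs = np.array([a for _, a, _, _ in per_fold])
    sens = np.array([s for _, _, s, _ in per_fold])
    spes = np.array([s for _, _, _, s in per_fold])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        return EvalResult(
            per_fold=tuple(per_fold),
            mean_acc=float(np.nanmean(accs)),
            mean_sen=float(np.nanmean(sens)),
            mean_spe=float(np.nanmean(spes)),
            sd_acc=float(np.nanstd(accs, ddof=1)) if len(accs) > 1 else 0.0,
            scheme=scheme,
            repeats=repeats,
            seed=seed,
            classifier=classifier_spec,
            selected_k=tuple(selected_k),
        )


def permutation_test(
    table: FeatureTable,
    classifier_spec: str,
    scheme: str = "kfold10",
    n_perm: int = 100,
    seed: int = 0,
    repeats: int | None = None,
    pca_config: dict | None = None,
    classifier_params: dict | None = None,
) -> PermutationResult:
    """Permutation-test significance of the cross-validated accuracy.

    The observed statistic is the mean CV accuracy on the true labels; the
    null distribution re-runs the identical protocol on ``n_perm``
    label-permuted cohorts.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    observed = cross_validate(
        table, classifier_spec, scheme, repeats=repeats,
        seed=derive_seed(seed, "observed"), pca_config=pca_config,
        classifier_params=classifier_params,
    ).mean_acc
    null = []
    for i in range(n_perm):
        permuted = permute_labels(table, derive_seed(seed, "permute", i))
        null.append(
            cross_validate(
                permuted, classifier_spec, scheme, repeats=repeats,
                seed=derive_seed(seed, "null", i), pca_config=pca_config,
                classifier_params=classifier_params,
            ).mean_acc
        )
    null_arr = np.array(null)
    p = (1.0 + int(np.sum(null_arr >= observed))) / (1.0 + n_perm)
    return PermutationResult(observed_stat=observed, null_stats=tuple(null),
                             p_value=float(p))
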