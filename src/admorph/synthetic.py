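"""Synthetic 3-class morphometric cohorts.

Emulates the statistical structure of a staged-dementia volumetry study:
three diagnostic groups (NC, MCI, AD) whose mean volumes in a subset of
"affected" regions decrease monotonically with disease stage, on top of
Gaussian between-subject variability that may be equicorrelated across
features. Defaults follow the study conditions this package targets:
70/74/70 subjects and 54 volume features.

The generator is a pure function of its :class:`CohortSpec` (including the
seed): same spec, bit-identical cohort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ._errors import ValidationError
from .data_io import DEFAULT_CLASSES, FeatureTable

__all__ = ["CohortSpec", "generate_cohort", "permute_labels"]


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of a synthetic staged cohort.

    Attributes
    ----------
    n_per_class : tuple of int
        Subjects per class in stage order (NC, MCI, AD). Default (70, 74, 70).
    n_features : int
        Number of volume features. Default 54.
    n_affected : int
        Number of class-sensitive features (the first ``n_affected`` columns).
        Default 12.
    effect : float
        Atrophy step per disease stage, in units of the within-class SD:
        an affected feature's mean for stage ``s`` is
        ``baseline_mean - s * effect * noise_sd``, with stages NC=0, MCI=1,
        AD=2. Default 1.0 (a moderate, detectable-but-noisy shift).
    noise_sd : float
        Within-class SD of every feature, in mm^3. Default 500.
    baseline_mean : float
        Stage-0 mean volume of every feature, in mm^3. Default 5000
        (a mid-sized subcortical/cortical ROI volume).
    correlation : float
        Equicorrelation rho between every feature pair. Default 0.
    classes : tuple of str
        Class names in stage order.
    seed : int
        RNG seed; the cohort is a pure function of the spec.
    """

    n_per_class: tuple[int, ...] = (70, 74, 70)
    n_features: int = 54
    n_affected: int = 12
    effect: float = 1.0
    noise_sd: float = 500.0
    baseline_mean: float = 5000.0
    correlation: float = 0.0
    classes: tuple[str, ...] = DEFAULT_CLASSES
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "n_per_class", tuple(int(n) for n in self.n_per_class))
        object.__setattr__(self, "classes", tuple(self.classes))
        if len(self.n_per_class) != len(self.classes):
            raise ValidationError(
                f"{len(self.n_per_class)} class sizes for {len(self.classes)} classes"
            )
        if any(n < 0 for n in self.n_per_class):
            raise ValidationError("class sizes must be >= 0")
        if self.n_features < 0 or self.n_affected < 0:
            raise ValidationError("feature counts must be >= 0")
        if self.n_affected > self.n_features:
            raise ValidationError(
                f"n_affected={self.n_affected} exceeds n_features={self.n_features}"
            )
        if not abs(self.correlation) < 1:
            raise ValidationError("|correlation| must be < 1")
        if self.effect < 0:
            raise ValidationError("effect must be >= 0")
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")


def generate_cohort(spec: CohortSpec) -> FeatureTable:
    """Draw a cohort from the spec's generative model.

    Affected features (columns ``0..n_affected-1``) have class means
    ``baseline_mean - stage * effect * noise_sd``; the remaining features are
    class-independent with mean ``baseline_mean``. Noise is Gaussian with SD
    ``noise_sd`` and equicorrelation ``correlation`` across features.
    """
    rng = np.random.default_rng(spec.seed)
    d = spec.n_features
    n_total = sum(spec.n_per_class)
    rho = spec.correlation
    if d > 1 and rho != 0.0 and rho < -1.0 / (d - 1):
        raise ValidationError(
            f"equicorrelation rho={rho} is not positive semi-definite for d={d}"
        )
    if rho == 0.0 or d <= 1:
        noise = rng.standard_normal((n_total, d))
    elif rho > 0:
        # X = sqrt(rho) * shared + sqrt(1-rho) * independent
        shared = rng.standard_normal((n_total, 1))
        noise = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * rng.standard_normal(
            (n_total, d)
        )
    else:
        cov = np.full((d, d), rho) + (1.0 - rho) * np.eye(d)
        chol = np.linalg.cholesky(cov)
        noise = rng.standard_normal((n_total, d)) @ chol.T
    values = spec.baseline_mean + spec.noise_sd * noise
    labels: list[str] = []
    row = 0
    for stage, (cls, n) in enumerate(zip(spec.classes, spec.n_per_class)):
        if spec.n_affected:
            values[row : row + n, : spec.n_affected] -= stage * spec.effect * spec.noise_sd
        labels.extend([cls] * n)
        row += n
    width = max(4, len(str(n_total)))
    ids = tuple(f"S{i + 1:0{width}d}" for i in range(n_total))
    names = tuple(
        f"roi_{j + 1:02d}{'_aff' if j < spec.n_affected else ''}" for j in range(d)
    )
    return FeatureTable(
        subject_ids=ids,
        labels=tuple(labels),
        feature_names=names,
        values=values,
        classes=spec.classes,
    )


def permute_labels(table: FeatureTable, seed: int) -> FeatureTable:
    """Return the table with labels uniformly permuted (values untouched).

    The label multiset is conserved; this is the null-hypothesis resampling
    step of the permutation test.
    """
    if table.n_subjects < 2:
        raise ValidationError("need at least 2 subjects to permute labels")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(table.n_subjects)
    return table.with_labels([table.labels[i] for i in perm])
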