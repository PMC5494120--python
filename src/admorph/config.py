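"""Run configuration and the end-to-end pipeline.

A run is: obtain a feature table (load from file or simulate a synthetic
cohort) -> PCA feature selection -> classifier -> cross-validated
evaluation -> optional permutation test -> JSON report. The whole pipeline
is a pure function of (config, master seed): identical inputs produce
byte-identical reports. The master seed fans out to per-stage seeds through
:func:`admorph._seeds.derive_seed`.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from importlib import resources
from pathlib import Path
from typing import Any, Optional

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict

from ._errors import ConfigurationError
from ._seeds import derive_seed
from .classifiers import registered_specs
from .data_io import FeatureTable, read_feature_table
from .evaluate import DEFAULT_REPEATS, cross_validate, permutation_test
from .pca import DEFAULT_K
from .synthetic import CohortSpec, generate_cohort

__all__ = ["RunConfig", "load_config", "run_pipeline", "report_json_schema",
           "RunReport"]

logger = logging.getLogger(__name__)

_KNOWN_KEYS = {
    "data", "synthetic", "classifier", "classifier_params", "pca", "scheme",
    "repeats", "n_perm", "seed", "out",
}
_PCA_KEYS = {"enabled", "k", "grid", "standardize"}
_SYNTH_KEYS = {f.name for f in dataclasses.fields(CohortSpec)}


@dataclasses.dataclass(frozen=True)
class RunConfig:
    """Validated pipeline configuration (exactly one data source)."""

    data: str | None = None  # path to a feature table
    synthetic: CohortSpec | None = None
    classifier: str = "relm"
    classifier_params: dict = dataclasses.field(default_factory=dict)
    pca_enabled: bool = True
    pca_k: int = DEFAULT_K
    pca_grid: tuple[int, ...] | None = None
    pca_standardize: bool = True
    scheme: str = "kfold10"
    repeats: int | None = None
    n_perm: int = 0
    seed: int = 0
    out: str | None = None

    def __post_init__(self):
        if (self.data is None) == (self.synthetic is None):
            raise ConfigurationError(
                "exactly one data source required: 'data' path or 'synthetic' spec"
            )
        if self.classifier not in registered_specs():
            raise ConfigurationError(
                f"classifier {self.classifier!r} not registered; "
                f"available: {registered_specs()}"
            )
        if self.scheme not in DEFAULT_REPEATS:
            raise ConfigurationError(f"unknown scheme {self.scheme!r}")
        if self.n_perm < 0:
            raise ConfigurationError("n_perm must be >= 0")


def load_config(path: str | None = None, **flags: Any) -> RunConfig:
    """Build a RunConfig from an optional YAML/JSON file plus flag overrides.

    Flags (non-None keyword arguments) take precedence over file values.
    Unknown file keys are an error, listed in the message.
    """
    raw: dict[str, Any] = {}
    if path is not None:
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigurationError(f"config file {path} must hold a mapping")
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    merged = dict(raw)
    for key, value in flags.items():
        if value is not None:
            merged[key] = value
    pca_raw = merged.pop("pca", {}) or {}
    if not isinstance(pca_raw, dict):
        raise ConfigurationError("'pca' must be a mapping")
    unknown = set(pca_raw) - _PCA_KEYS
    if unknown:
        raise ConfigurationError(f"unknown pca keys: {sorted(unknown)}")
    synth = merged.pop("synthetic", None)
    if isinstance(synth, dict):
        unknown = set(synth) - _SYNTH_KEYS
        if unknown:
            raise ConfigurationError(f"unknown synthetic keys: {sorted(unknown)}")
        for tup_key in ("n_per_class", "classes"):
            if tup_key in synth:
                synth[tup_key] = tuple(synth[tup_key])
        synth = CohortSpec(**synth)
    grid = pca_raw.get("grid")
    return RunConfig(
        data=merged.get("data"),
        synthetic=synth,
        classifier=merged.get("classifier", "relm"),
        classifier_params=dict(merged.get("classifier_params") or {}),
        pca_enabled=bool(pca_raw.get("enabled", True)),
        pca_k=int(pca_raw.get("k", DEFAULT_K)),
        pca_grid=tuple(int(k) for k in grid) if grid else None,
        pca_standardize=bool(pca_raw.get("standardize", True)),
        scheme=merged.get("scheme", "kfold10"),
        repeats=merged.get("repeats"),
        n_perm=int(merged.get("n_perm", 0)),
        seed=int(merged.get("seed", 0)),
        out=merged.get("out"),
    )


# --- report schema (pydantic; the JSON schema file ships with the package) --


class FoldRecord(BaseModel):
    model_config = ConfigDict(extra="forbid")
    repeat: int
    fold: int
    confusion: list[list[int]]
    acc: float
    sen: Optional[float]
    spe: Optional[float]


class Aggregates(BaseModel):
    model_config = ConfigDict(extra="forbid")
    mean_acc: float
    mean_sen: Optional[float]
    mean_spe: Optional[float]
    sd_acc: float


class PermutationSection(BaseModel):
    model_config = ConfigDict(extra="forbid")
    observed_acc: float
    n_perm: int
    null_acc: list[float]
    p_value: float


class RunReport(BaseModel):
    """Machine-readable pipeline report."""

    model_config = ConfigDict(extra="forbid")
    scheme: str
    classifier: str
    repeats: int
    seed: int
    n_subjects: int
    n_features: int
    classes: list[str]
    pca: dict
    selected_k: list[int]
    per_fold: list[FoldRecord]
    aggregates: Aggregates
    permutation: Optional[PermutationSection] = None


def report_json_schema() -> dict:
    """The published JSON schema the shipped ``report_schema.json`` mirrors."""
    return RunReport.model_json_schema()


def shipped_schema() -> dict:
    with resources.files("admorph").joinpath("report_schema.json").open() as fh:
        return json.load(fh)


def _clean(x: float) -> float | None:
    return None if not np.isfinite(x) else round(float(x), 10)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured pipeline; write the JSON report if ``out`` is
    set and return it as a dict."""
    if config.synthetic is not None:
        spec = dataclasses.replace(config.synthetic,
                                   seed=derive_seed(config.seed, "simulate",
                                                    config.synthetic.seed))
        table = generate_cohort(spec)
        logger.info("simulated cohort: %d subjects, %d features",
                    table.n_subjects, table.n_features)
    else:
        table = read_feature_table(config.data)
        logger.info("loaded %s: %d subjects, %d features", config.data,
                    table.n_subjects, table.n_features)
    pca_config = None
    if config.pca_enabled:
        pca_config = {"k": config.pca_k, "grid": config.pca_grid,
                      "standardize": config.pca_standardize}
    result = cross_validate(
        table, config.classifier, config.scheme, repeats=config.repeats,
        seed=derive_seed(config.seed, "cv"), pca_config=pca_config,
        classifier_params=config.classifier_params,
    )
    fold_records = []
    fold_iter = iter(result.per_fold)
    n_folds_per_repeat = len(result.per_fold) // result.repeats
    for i, (cm, acc, sen, spe) in enumerate(fold_iter):
        fold_records.append(FoldRecord(
            repeat=i // n_folds_per_repeat, fold=i % n_folds_per_repeat,
            confusion=cm.counts.tolist(), acc=_clean(acc) or 0.0,
            sen=_clean(sen), spe=_clean(spe),
        ))
    report = RunReport(
        scheme=config.scheme,
        classifier=config.classifier,
        repeats=result.repeats,
        seed=config.seed,
        n_subjects=table.n_subjects,
        n_features=table.n_features,
        classes=list(result.per_fold[0][0].classes),
        pca={"enabled": config.pca_enabled, "k": config.pca_k,
             "grid": list(config.pca_grid) if config.pca_grid else None,
             "standardize": config.pca_standardize},
        selected_k=list(result.selected_k),
        per_fold=fold_records,
        aggregates=Aggregates(
            mean_acc=_clean(result.mean_acc) or 0.0,
            mean_sen=_clean(result.mean_sen),
            mean_spe=_clean(result.mean_spe),
            sd_acc=_clean(result.sd_acc) or 0.0,
        ),
    )
    if config.n_perm > 0:
        perm = permutation_test(
            table, config.classifier, config.scheme, n_perm=config.n_perm,
            seed=derive_seed(config.seed, "permtest"), repeats=config.repeats,
            pca_config=pca_config, classifier_params=config.classifier_params,
        )
        report.permutation = PermutationSection(
            observed_acc=_clean(perm.observed_stat) or 0.0,
            n_perm=config.n_perm,
            null_acc=[_clean(v) or 0.0 for v in perm.null_stats],
            p_value=round(perm.p_value, 10),
        )
    payload = report.model_dump()
    if config.out:
        Path(config.out).parent.mkdir(parents=True, exist_ok=True)
        with open(config.out, "w", encoding="utf-8", newline="\n") as fh:
            json.dump(payload, fh, sort_keys=True, indent=2)
            fh.write("\n")
        logger.info("report written to %s", config.out)
    return payload


def summarize(payload: dict) -> str:
    """Human-readable one-run summary mirroring an ACC/SEN/SPE results row."""
    agg = payload["aggregates"]
    lines = [
        f"classifier: {payload['classifier']}   scheme: {payload['scheme']}"
        f"   repeats: {payload['repeats']}",
        f"subjects: {payload['n_subjects']}   features: {payload['n_features']}"
        f"   classes: {', '.join(payload['classes'])}",
        "metric      mean",
        f"ACC (%)   {agg['mean_acc']:7.2f}  (sd {agg['sd_acc']:.2f})",
        f"SEN (%)   {agg['mean_sen'] if agg['mean_sen'] is not None else float('nan'):7.2f}",
        f"SPE (%)   {agg['mean_spe'] if agg['mean_spe'] is not None else float('nan'):7.2f}",
    ]
    if payload.get("permutation"):
        lines.append(
            f"permutation: p = {payload['permutation']['p_value']:.4g} "
            f"({payload['permutation']['n_perm']} permutations)"
        )
    return "\n".join(lines)
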