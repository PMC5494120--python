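"""Feature-table I/O.

The universal exchange object is the :class:`FeatureTable`: one row per
subject, one column per numeric morphometric feature (typically regional
grey-matter volumes in mm^3), plus a diagnostic label per subject drawn
from an ordered class set such as ``("NC", "MCI", "AD")``.

Tables are read from / written to delimited text (CSV or TSV, header
row required) and can also be assembled from FreeSurfer-style
segmentation statistics files (``aseg.stats`` dialect), one file per
subject, taking the per-structure ``Volume_mm3`` column as features.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._errors import ConfigurationError, ParseError, ValidationError

__all__ = [
    "DEFAULT_CLASSES",
    "FeatureTable",
    "StatsRecord",
    "read_feature_table",
    "write_feature_table",
    "read_freesurfer_stats",
]

#: Canonical diagnostic staging order: normal control, mild cognitive
#: impairment, Alzheimer's disease.
DEFAULT_CLASSES: tuple[str, ...] = ("NC", "MCI", "AD")


def _ordered_classes(labels: Sequence[str]) -> tuple[str, ...]:
    """Class order: the canonical NC/MCI/AD order when labels are a subset
    of it, otherwise order of first appearance."""
    uniq = list(dict.fromkeys(labels))
    if set(uniq) <= set(DEFAULT_CLASSES):
        return tuple(c for c in DEFAULT_CLASSES if c in uniq)
    return tuple(uniq)


@dataclass(frozen=True)
class FeatureTable:
    """Subject-by-feature numeric matrix with class labels.

    Parameters
    ----------
    subject_ids : list of str
        Unique subject identifiers, one per row of ``values``.
    labels : list of str
        Diagnostic class per subject; members of ``classes``.
    feature_names : list of str
        Unique feature (column) names.
    values : ndarray of shape (n_subjects, n_features)
        Finite numeric feature matrix.
    classes : tuple of str
        Declared ordered class set. Defaults to the distinct labels in
        canonical NC/MCI/AD order when applicable.
    """

    subject_ids: tuple[str, ...]
    labels: tuple[str, ...]
    feature_names: tuple[str, ...]
    values: np.ndarray
    classes: tuple[str, ...] = field(default=())

    def __post_init__(self):
        object.__setattr__(self, "subject_ids", tuple(str(s) for s in self.subject_ids))
        object.__setattr__(self, "labels", tuple(str(l) for l in self.labels))
        object.__setattr__(self, "feature_names", tuple(str(f) for f in self.feature_names))
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2:
            values = values.reshape(len(self.subject_ids), -1)
        object.__setattr__(self, "values", values)
        if not self.classes:
            object.__setattr__(self, "classes", _ordered_classes(self.labels))
        else:
            object.__setattr__(self, "classes", tuple(self.classes))
        n, d = self.values.shape
        if len(self.subject_ids) != n:
            raise ValidationError(
                f"{len(self.subject_ids)} subject ids for {n} rows of values"
            )
        if len(self.labels) != n:
            raise ValidationError(f"{len(self.labels)} labels for {n} rows of values")
        if len(self.feature_names) != d:
            raise ValidationError(
                f"{len(self.feature_names)} feature names for {d} columns of values"
            )
        if len(set(self.subject_ids)) != n:
            dupes = sorted({s for s in self.subject_ids if self.subject_ids.count(s) > 1})
            raise ValidationError(f"duplicate subject ids: {dupes}")
        if len(set(self.feature_names)) != d:
            raise ValidationError("duplicate feature names")
        if self.values.size and not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise ValidationError(
                f"non-finite value at subject {self.subject_ids[bad[0]]!r}, "
                f"feature {self.feature_names[bad[1]]!r}"
            )
        unknown = set(self.labels) - set(self.classes)
        if unknown:
            raise ValidationError(f"labels outside declared class set: {sorted(unknown)}")

    @property
    def n_subjects(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def label_indices(self) -> np.ndarray:
        """Labels encoded as integer indices into ``classes``."""
        lut = {c: i for i, c in enumerate(self.classes)}
        return np.array([lut[l] for l in self.labels], dtype=int)

    def with_labels(self, labels: Sequence[str]) -> "FeatureTable":
        return replace(self, labels=tuple(labels))

    def subset_rows(self, idx: Sequence[int]) -> "FeatureTable":
        idx = np.asarray(idx, dtype=int)
        return replace(
            self,
            subject_ids=tuple(self.subject_ids[i] for i in idx),
            labels=tuple(self.labels[i] for i in idx),
            values=self.values[idx],
        )


@dataclass(frozen=True)
class StatsRecord:
    """One structure's volume measurement from a segmentation stats file."""

    structure_name: str
    volume: float  # mm^3
    source_file: str

    def __post_init__(self):
        if self.volume < 0:
            raise ValidationError(
                f"negative volume {self.volume} for {self.structure_name!r} "
                f"in {self.source_file}"
            )


def _detect_delimiter(first_line: str) -> str:
    # restricted to {comma, tab} so detection is unambiguous
    return "\t" if first_line.count("\t") > first_line.count(",") else ","


def read_feature_table(
    path: str | os.PathLike,
    label_column: str = "label",
    id_column: str = "subject_id",
    classes: Sequence[str] | None = None,
    missing: str = "reject",
) -> FeatureTable:
    """Read a delimited feature table (CSV or TSV, auto-detected).

    All columns other than ``id_column`` and ``label_column`` are parsed as
    numeric features; row order is preserved.

    ``missing`` policy: ``"reject"`` (default) raises on any missing or
    non-numeric feature cell; ``"impute-mean"`` fills missing cells with the
    column mean (of the whole file — see methods note for the caveat on
    evaluation protocols).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if missing not in ("reject", "impute-mean"):
        raise ConfigurationError(f"unknown missing policy {missing!r}")
    with open(path, "r", encoding="utf-8") as fh:
        first = fh.readline()
    sep = _detect_delimiter(first)
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    for col in (id_column, label_column):
        if col not in df.columns:
            raise ConfigurationError(
                f"column {col!r} not found in {path.name}; available: {list(df.columns)}"
            )
    feature_cols = [c for c in df.columns if c not in (id_column, label_column)]
    values = np.empty((len(df), len(feature_cols)), dtype=float)
    for j, col in enumerate(feature_cols):
        raw = df[col].to_numpy()
        # float() is correctly rounded, so write->read->write is byte-exact
        parsed = np.empty(len(raw))
        for i, v in enumerate(raw):
            if v == "":
                parsed[i] = np.nan
                continue
            try:
                parsed[i] = float(v)
            except ValueError:
                raise ParseError(
                    f"non-numeric value {v!r} at row {i + 2} (subject "
                    f"{df[id_column].iloc[i]!r}), column {col!r} of {path.name}"
                ) from None
        bad = np.nonzero(np.isnan(parsed) & (raw != ""))[0]
        if bad.size:
            i = int(bad[0])
            raise ParseError(
                f"non-numeric value {raw[i]!r} at row {i + 2} (subject "
                f"{df[id_column].iloc[i]!r}), column {col!r} of {path.name}"
            )
        if missing == "reject":
            missing_rows = np.nonzero(~np.isfinite(parsed))[0]
            if missing_rows.size:
                i = int(missing_rows[0])
                raise ParseError(
                    f"missing value at row {i + 2} (subject "
                    f"{df[id_column].iloc[i]!r}), column {col!r} of {path.name}"
                )
        else:
            mask = ~np.isfinite(parsed)
            if mask.all():
                raise ParseError(f"column {col!r} of {path.name} is entirely missing")
            parsed[mask] = np.nanmean(parsed)
        values[:, j] = parsed
    ids = df[id_column].tolist()
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate subject ids in {path.name}: {dupes}")
    return FeatureTable(
        subject_ids=tuple(ids),
        labels=tuple(df[label_column].tolist()),
        feature_names=tuple(feature_cols),
        values=values,
        classes=tuple(classes) if classes is not None else (),
    )


def write_feature_table(
    table: FeatureTable,
    path: str | os.PathLike,
    label_column: str = "label",
    id_column: str = "subject_id",
) -> None:
    """Write a feature table as comma-delimited text, floats at full
    (round-trip) precision."""
    buf = io.StringIO()
    header = [id_column, label_column, *table.feature_names]
    buf.write(",".join(header) + "\n")
    for i in range(table.n_subjects):
        row = [table.subject_ids[i], table.labels[i]]
        row.extend(repr(v) for v in table.values[i].tolist())
        buf.write(",".join(row) + "\n")
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(buf.getvalue())


# --- FreeSurfer segmentation statistics -------------------------------------

# positional layout of the standard aseg.stats data rows
_ASEG_POSITIONAL = ["Index", "SegId", "NVoxels", "Volume_mm3", "StructName"]


def _parse_stats_file(path: Path) -> list[StatsRecord]:
    colheaders: list[str] | None = None
    records: list[StatsRecord] = []
    with open(path, "r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            if line.startswith("#"):
                stripped = line.lstrip("#").strip()
                if stripped.startswith("ColHeaders"):
                    colheaders = stripped.split()[1:]
                continue
            fields = line.split()
            names = colheaders if colheaders is not None else _ASEG_POSITIONAL
            if len(fields) < len(names):
                raise ParseError(
                    f"malformed data row at {path.name}:{lineno}: expected at least "
                    f"{len(names)} fields, got {len(fields)}"
                )
            row = dict(zip(names, fields))
            if "StructName" not in row or "Volume_mm3" not in row:
                raise ParseError(
                    f"{path.name}: cannot locate StructName/Volume_mm3 columns "
                    f"(headers: {names})"
                )
            try:
                vol = float(row["Volume_mm3"])
            except ValueError as exc:
                raise ParseError(
                    f"non-numeric volume {row['Volume_mm3']!r} at {path.name}:{lineno}"
                ) from exc
            records.append(StatsRecord(row["StructName"], vol, str(path)))
    return records


def read_freesurfer_stats(
    paths: Sequence[str | os.PathLike],
    structures: Sequence[str] | None = None,
) -> FeatureTable:
    """Assemble a volume feature table from FreeSurfer-style stats files.

    One file per subject; the subject id is the filename stem. Features are
    the ``Volume_mm3`` entries of the requested ``structures`` (default: the
    intersection of structures present in every file, in first-file order).
    Labels are set to ``""`` — the caller attaches diagnoses separately.
    """
    if not paths:
        raise ValidationError("no stats files given")
    per_subject: list[tuple[str, dict[str, float]]] = []
    order_first: list[str] = []
    for p in paths:
        p = Path(p)
        recs = _parse_stats_file(p)
        if not recs:
            raise ValidationError(f"{p.name}: no structure rows found")
        vols = {r.structure_name: r.volume for r in recs}
        if not order_first:
            order_first = [r.structure_name for r in recs]
        per_subject.append((p.stem, vols))
    ids = [sid for sid, _ in per_subject]
    if len(set(ids)) != len(ids):
        dupes = sorted({s for s in ids if ids.count(s) > 1})
        raise ValidationError(f"duplicate subject ids from filename stems: {dupes}")
    if structures is None:
        common = set.intersection(*(set(v) for _, v in per_subject))
        structures = [s for s in order_first if s in common]
        if not structures:
            raise ValidationError("no structures common to all stats files")
    else:
        structures = list(structures)
        for sid, vols in per_subject:
            for s in structures:
                if s not in vols:
                    raise ValidationError(
                        f"structure {s!r} absent from stats file for subject {sid!r}"
                    )
    values = np.array([[vols[s] for s in structures] for _, vols in per_subject])
    return FeatureTable(
        subject_ids=tuple(ids),
        labels=tuple("" for _ in ids),
        feature_names=tuple(structures),
        values=values,
        classes=("",),
    )
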