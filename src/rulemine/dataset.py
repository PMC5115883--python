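"""Core data model for discretized multi-source tables.

A :class:`DiscretizedDataset` holds one row per subject, one column per
discretized explanatory variable, and a binary target (the two renal-function
modalities, by default ``below60`` / ``at_least_60`` for eGFR < 60 versus
>= 60 ml/min/1.73m^2).  Ordinal variables (NMR buckets, most clinical
measurements) carry small integer level codes ``1..k``; nominal variables
(sex, ethnicity, ...) carry category labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "VariableMeta",
    "DiscretizedDataset",
    "ValidationError",
    "read_table",
    "write_table",
    "impute_median",
    "DEFAULT_MODALITIES",
]

#: Canonical target modality order: (renal failure, no renal failure).
DEFAULT_MODALITIES: tuple[str, str] = ("below60", "at_least_60")


class ValidationError(ValueError):
    """Raised when a table violates the dataset contract."""


@dataclass(frozen=True)
class VariableMeta:
    """Description of one discretized explanatory variable.

    Parameters
    ----------
    name:
        Variable identifier, e.g. ``"bucket 3.16"`` or ``"Age"``.
    kind:
        ``"ordinal"`` (totally ordered level codes ``1..n_levels``) or
        ``"nominal"`` (unordered category labels).
    n_levels:
        Number of levels; equals ``len(level_labels)``.
    level_labels:
        Ordered labels.  For ordinal variables these are the bin indices
        ``1..n_levels``; for nominal variables the category names.
    origin:
        Data source: bucket, clinical, chemistry, pathology or demographic.
    """

    name: str
    kind: str
    n_levels: int
    level_labels: tuple = ()
    origin: str = "bucket"

    def __post_init__(self):
        if self.kind not in ("ordinal", "nominal"):
            raise ValidationError(f"{self.name}: kind must be ordinal or nominal")
        labels = tuple(self.level_labels)
        if not labels:
            if self.kind == "ordinal":
                labels = tuple(range(1, self.n_levels + 1))
            else:
                raise ValidationError(f"{self.name}: nominal variable needs level_labels")
        object.__setattr__(self, "level_labels", labels)
        if self.n_levels != len(labels) or self.n_levels < 1:
            raise ValidationError(
                f"{self.name}: n_levels={self.n_levels} does not match "
                f"{len(labels)} level labels"
            )

    @property
    def is_ordinal(self) -> bool:
        return self.kind == "ordinal"


@dataclass
class DiscretizedDataset:
    """Subjects x variables table of level codes with a binary target."""

    data: pd.DataFrame
    variables: list[VariableMeta]
    target: pd.Series
    modalities: tuple[str, str] = DEFAULT_MODALITIES

    def __post_init__(self):
        self.validate()

    # -- contract -----------------------------------------------------------
    def validate(self) -> None:
        names = [v.name for v in self.variables]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise ValidationError(f"duplicated variable names: {dup}")
        if list(self.data.columns) != names:
            raise ValidationError("data columns do not match variable metadata order")
        if not self.data.index.equals(self.target.index):
            raise ValidationError("target index does not match subjects")
        if len(self.modalities) != 2:
            raise ValidationError("target must have exactly 2 modalities")
        observed = set(self.target.unique())
        if not observed <= set(self.modalities):
            raise ValidationError(
                f"unknown target modalities: {sorted(observed - set(self.modalities))}"
            )
        counts = self.target.value_counts()
        for m in self.modalities:
            if counts.get(m, 0) == 0:
                raise ValidationError(f"target modality {m!r} is empty")
        for meta in self.variables:
            col = self.data[meta.name]
            if col.isna().any():
                subj = col.index[col.isna()][0]
                raise ValidationError(f"missing code for subject {subj!r}, variable {meta.name!r}")
            valid = set(meta.level_labels)
            bad = ~col.isin(valid)
            if bad.any():
                subj = col.index[bad][0]
                raise ValidationError(
                    f"invalid level code {col[subj]!r} for subject {subj!r}, "
                    f"variable {meta.name!r} (levels: {sorted(valid, key=str)})"
                )

    # -- convenience --------------------------------------------------------
    @property
    def subjects(self) -> list:
        return list(self.data.index)

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def variable_names(self) -> list[str]:
        return [v.name for v in self.variables]

    def variable(self, name: str) -> VariableMeta:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def codes(self, name: str) -> np.ndarray:
        """Integer codes 1..k for a variable (nominal labels mapped by
        position in ``level_labels``)."""
        meta = self.variable(name)
        col = self.data[name]
        if meta.is_ordinal:
            return col.to_numpy(dtype=np.int64)
        lut = {lab: i + 1 for i, lab in enumerate(meta.level_labels)}
        return col.map(lut).to_numpy(dtype=np.int64)

    def modality_indicator(self, modality: str) -> np.ndarray:
        if modality not in self.modalities:
            raise KeyError(modality)
        return (self.target == modality).to_numpy()

    def subset(self, index) -> "DiscretizedDataset":
        """Row subset by positional indices (splits keep all metadata)."""
        return DiscretizedDataset(
            data=self.data.iloc[index],
            variables=list(self.variables),
            target=self.target.iloc[index],
            modalities=self.modalities,
        )

    def select_variables(self, names: Sequence[str]) -> "DiscretizedDataset":
        metas = [self.variable(n) for n in names]
        return DiscretizedDataset(
            data=self.data[list(names)],
            variables=metas,
            target=self.target,
            modalities=self.modalities,
        )

    def with_target(self, target: pd.Series) -> "DiscretizedDataset":
        return dataclasses.replace(self, target=target)

    def __eq__(self, other) -> bool:
        if not isinstance(other, DiscretizedDataset):
            return NotImplemented
        return (
            self.variables == other.variables
            and self.modalities == other.modalities
            and self.data.equals(other.data)
            and self.target.equals(other.target)
        )


# ---------------------------------------------------------------------------
# I/O


def _metadata_frame(variables: Sequence[VariableMeta]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "name": [v.name for v in variables],
            "kind": [v.kind for v in variables],
            "n_levels": [v.n_levels for v in variables],
            "origin": [v.origin for v in variables],
            "levels": ["|".join(str(l) for l in v.level_labels) for v in variables],
        }
    )


def _parse_metadata(meta_df: pd.DataFrame) -> list[VariableMeta]:
    variables = []
    for _, row in meta_df.iterrows():
        kind = str(row["kind"]).strip().lower()
        n_levels = int(row["n_levels"])
        levels_field = row.get("levels", "")
        if isinstance(levels_field, str) and levels_field.strip():
            raw = levels_field.split("|")
            labels = tuple(int(x) for x in raw) if kind == "ordinal" else tuple(raw)
        else:
            labels = ()
        variables.append(
            VariableMeta(
                name=str(row["name"]),
                kind=kind,
                n_levels=n_levels,
                level_labels=labels,
                origin=str(row.get("origin", "bucket")),
            )
        )
    return variables


def read_table(
    path,
    layout: str = "wide_csv",
    metadata=None,
    target_column: str = "target",
    modalities: tuple[str, str] = DEFAULT_MODALITIES,
) -> DiscretizedDataset:
    """Read a discretized wide table into a validated dataset.

    ``wide_csv`` expects a CSV with the subject identifier in the first
    column, one column per variable and one target column, plus a metadata
    sidecar CSV (``metadata=``, default ``<path>.meta.csv``) with columns
    ``name, kind, n_levels, origin[, levels]``.  ``spreadsheet_s1`` expects
    an xlsx workbook whose first sheet is the data and second sheet the
    metadata (the layout of the cohort's deposited supplementary table).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if layout == "wide_csv":
        df = pd.read_csv(path, index_col=0)
        meta_path = Path(metadata) if metadata is not None else path.with_suffix(path.suffix + ".meta.csv")
        if not meta_path.exists():
            raise FileNotFoundError(f"metadata sidecar not found: {meta_path}")
        meta_df = pd.read_csv(meta_path)
    elif layout == "spreadsheet_s1":
        sheets = pd.read_excel(path, sheet_name=None, index_col=0)
        if len(sheets) < 2:
            raise ValidationError("spreadsheet layout needs a data sheet and a metadata sheet")
        names = list(sheets)
        df = sheets[names[0]]
        meta_df = sheets[names[1]].reset_index()
    else:
        raise ValueError(f"unknown layout {layout!r}")

    if target_column not in df.columns:
        raise ValidationError(f"missing target column {target_column!r}")
    target = df[target_column].astype(str)
    df = df.drop(columns=[target_column])

    variables = _parse_metadata(meta_df)
    meta_names = [v.name for v in variables]
    missing = [c for c in df.columns if c not in meta_names]
    if missing:
        raise ValidationError(f"variables without metadata: {missing}")
    variables = [v for v in variables if v.name in set(df.columns)]
    df = df[[v.name for v in variables]]

    # coerce ordinal columns to integer codes
    for v in variables:
        if v.is_ordinal:
            df[v.name] = pd.to_numeric(df[v.name]).astype(np.int64)
        else:
            df[v.name] = df[v.name].astype(str)
    return DiscretizedDataset(data=df, variables=variables, target=target, modalities=modalities)


def write_table(ds: DiscretizedDataset, path, metadata=None, target_column: str = "target") -> None:
    """Write a dataset in the ``wide_csv`` layout (inverse of read_table)."""
    path = Path(path)
    out = ds.data.copy()
    out[target_column] = ds.target
    out.to_csv(path, index_label="subject")
    meta_path = Path(metadata) if metadata is not None else path.with_suffix(path.suffix + ".meta.csv")
    _metadata_frame(ds.variables).to_csv(meta_path, index=False)


# ---------------------------------------------------------------------------
# Imputation


def impute_median(raw_table: pd.DataFrame) -> pd.DataFrame:
    """Replace missing entries by the per-variable median of observed values.

    Uses the standard sample median (midpoint of the two central order
    statistics for even counts).  Observed entries are untouched; a fully
    missing column is an error.
    """
    out = raw_table.copy()
    for col in out.columns:
        vals = out[col]
        if vals.isna().all():
            raise ValidationError(f"variable {col!r} has no observed values")
        if vals.isna().any():
            out[col] = vals.fillna(vals.median(skipna=True))
    return out
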