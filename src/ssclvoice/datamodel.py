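"""Domain types and CSV I/O for tabulated acoustic-parameter datasets.

The canonical table layout follows the public "Parkinson Dataset with
replicated acoustic features" distribution: one row per voice record, with a
subject identifier, a record index (each subject repeats the sustained-vowel
task three times), a binary health status (0 = healthy control, 1 = Parkinson's
disease), gender, and 44 acoustic parameters grouped into six families
(jitter, shimmer, harmonics-to-noise ratio, nonlinear measures, MFCC, Delta).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

UNLABELED = -1

FAMILIES = ("jitter", "shimmer", "hnr", "nonlinear", "mfcc", "delta")

#: Default parameter names per family, mirroring the public dataset's
#: abbreviations (4 jitter, 5 shimmer, 5 HNR, 4 nonlinear, 13 MFCC, 13 Delta).
DEFAULT_FAMILY_PARAMETERS: dict[str, tuple[str, ...]] = {
    "jitter": ("Jitter-Rel", "Jitter-Abs", "Jitter-RAP", "Jitter-PPQ"),
    "shimmer": ("Shim-Loc", "Shim-dB", "Shim-APQ3", "Shim-APQ5", "Shim-APQ11"),
    "hnr": ("HNR05", "HNR15", "HNR25", "HNR35", "HNR38"),
    "nonlinear": ("RPDE", "DFA", "PPE", "GNE"),
    "mfcc": tuple(f"MFCC{i}" for i in range(13)),
    "delta": tuple(f"Delta{i}" for i in range(13)),
}

_GENDERS = ("male", "female", "unknown")


class SchemaError(ValueError):
    """Input CSV does not match the declared column-role schema."""


class ParseError(ValueError):
    """A parameter cell could not be parsed as a number."""


class IntegrityError(ValueError):
    """The table violates a structural invariant (e.g. label inconsistency)."""


class ConfigError(ValueError):
    """A run-configuration value is outside its valid range."""


def infer_family(parameter_name: str) -> str | None:
    """Map a parameter name to its family via the standard abbreviations."""
    name = parameter_name.lower()
    if name.startswith("jitter"):
        return "jitter"
    if name.startswith(("shim", "shimmer")):
        return "shimmer"
    if name.startswith("hnr"):
        return "hnr"
    if name.startswith(("rpde", "dfa", "ppe", "gne")):
        return "nonlinear"
    if name.startswith("mfcc"):
        return "mfcc"
    if name.startswith("delta"):
        return "delta"
    return None


@dataclass
class TableSchema:
    """Column-role mapping for reading a feature CSV.

    ``family_of`` may be given explicitly; otherwise every non-role column is
    assigned a family by name prefix (`infer_family`), and columns that match
    no family are rejected.
    """

    subject_column: str = "ID"
    record_column: str = "Recording"
    label_column: str = "Status"
    gender_column: str = "Gender"
    family_of: dict[str, str] | None = None

    @classmethod
    def from_file(cls, path: str | Path) -> "TableSchema":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise SchemaError(f"unknown schema keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class FeatureTable:
    """Voice records x acoustic parameters with per-record metadata.

    Invariants (enforced by :meth:`validate`): every parameter belongs to
    exactly one family; records sharing a subject share label and gender; the
    value matrix is finite with no missing entries.
    """

    values: np.ndarray  # (n_records, n_parameters) float64
    parameter_names: list[str]
    family_of: dict[str, str]
    subject_id: np.ndarray  # (n_records,) str or int
    record_index: np.ndarray  # (n_records,) int, 1..records_per_subject
    label: np.ndarray  # (n_records,) int, 0/1 or UNLABELED
    gender: np.ndarray  # (n_records,) str in {male, female, unknown}

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.subject_id = np.asarray(self.subject_id)
        self.record_index = np.asarray(self.record_index, dtype=int)
        self.label = np.asarray(self.label, dtype=int)
        self.gender = np.asarray(self.gender, dtype=object)
        self.validate()

    # -- invariants ---------------------------------------------------------

    def validate(self) -> None:
        n, p = self.values.shape
        if len(self.parameter_names) != p:
            raise IntegrityError("parameter_names length does not match values")
        for arr, what in (
            (self.subject_id, "subject_id"),
            (self.record_index, "record_index"),
            (self.label, "label"),
            (self.gender, "gender"),
        ):
            if len(arr) != n:
                raise IntegrityError(f"{what} length does not match record count")
        if not np.all(np.isfinite(self.values)):
            bad = np.argwhere(~np.isfinite(self.values))[0]
            raise IntegrityError(
                f"missing/non-finite value at record {bad[0]}, "
                f"parameter {self.parameter_names[bad[1]]!r}"
            )
        for name in self.parameter_names:
            fam = self.family_of.get(name)
            if fam not in FAMILIES:
                raise IntegrityError(f"parameter {name!r} has no valid family ({fam!r})")
        bad_labels = set(np.unique(self.label)) - {0, 1, UNLABELED}
        if bad_labels:
            raise IntegrityError(f"labels must be 0/1/unlabeled, got {sorted(bad_labels)}")
        bad_gender = set(self.gender) - set(_GENDERS)
        if bad_gender:
            raise IntegrityError(f"unknown gender values {sorted(bad_gender)}")
        # records of one subject must agree on label and gender
        for subj in pd.unique(self.subject_id):
            mask = self.subject_id == subj
            if len(set(self.label[mask])) > 1:
                raise IntegrityError(f"subject {subj!r} has inconsistent labels")
            if len(set(self.gender[mask])) > 1:
                raise IntegrityError(f"subject {subj!r} has inconsistent gender")

    # -- convenience --------------------------------------------------------

    @property
    def n_records(self) -> int:
        return self.values.shape[0]

    @property
    def n_parameters(self) -> int:
        return self.values.shape[1]

    @property
    def families(self) -> list[str]:
        present = {self.family_of[p] for p in self.parameter_names}
        return [f for f in FAMILIES if f in present]

    def family_columns(self, family: str) -> list[int]:
        return [
            i for i, p in enumerate(self.parameter_names) if self.family_of[p] == family
        ]

    def family_values(self, family: str) -> np.ndarray:
        return self.values[:, self.family_columns(family)]

    def family_parameters(self, family: str) -> list[str]:
        return [p for p in self.parameter_names if self.family_of[p] == family]

    def subset(self, indices: Sequence[int] | np.ndarray) -> "FeatureTable":
        idx = np.asarray(indices)
        return FeatureTable(
            values=self.values[idx],
            parameter_names=list(self.parameter_names),
            family_of=dict(self.family_of),
            subject_id=self.subject_id[idx],
            record_index=self.record_index[idx],
            label=self.label[idx],
            gender=self.gender[idx],
        )

    def to_dataframe(self, schema: TableSchema | None = None) -> pd.DataFrame:
        schema = schema or TableSchema()
        data = {
            schema.subject_column: self.subject_id,
            schema.record_column: self.record_index,
            schema.label_column: [
                "" if v == UNLABELED else int(v) for v in self.label
            ],
            schema.gender_column: self.gender,
        }
        for j, name in enumerate(self.parameter_names):
            data[name] = self.values[:, j]
        return pd.DataFrame(data)


_LABEL_MAP = {"0": 0, "1": 1, "HC": 0, "PD": 1}
_GENDER_MAP = {
    "male": "male", "m": "male", "0": "male",
    "female": "female", "f": "female", "1": "female",
    "unknown": "unknown", "": "unknown",
}


def _parse_label(raw, row: int) -> int:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)):
        return UNLABELED
    text = str(raw).strip()
    if text == "" or text.lower() in ("nan", "unlabeled"):
        return UNLABELED
    if text.endswith(".0"):
        text = text[:-2]
    if text.upper() in _LABEL_MAP:
        return _LABEL_MAP[text.upper()]
    if text in _LABEL_MAP:
        return _LABEL_MAP[text]
    raise ParseError(f"row {row}: cannot interpret label {raw!r} (expect 0/1 or HC/PD)")


def _parse_gender(raw, row: int) -> str:
    text = "" if raw is None else str(raw).strip().lower()
    if text in ("nan",):
        text = ""
    if text in _GENDER_MAP:
        return _GENDER_MAP[text]
    raise ParseError(f"row {row}: cannot interpret gender {raw!r}")


def read_feature_table(path: str | Path, schema: TableSchema | None = None) -> FeatureTable:
    """Read a feature CSV into a validated :class:`FeatureTable`.

    Raises :class:`SchemaError` for missing role columns or an empty file,
    :class:`ParseError` for non-numeric parameter cells (with row/column),
    and :class:`IntegrityError` if a subject carries inconsistent labels.
    """
    schema = schema or TableSchema()
    try:
        df = pd.read_csv(path, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: empty file, no header row") from exc
    role_cols = [
        schema.subject_column, schema.record_column,
        schema.label_column, schema.gender_column,
    ]
    missing = [c for c in role_cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")

    param_cols = [c for c in df.columns if c not in role_cols]
    if schema.family_of is not None:
        family_of = dict(schema.family_of)
        unmapped = [c for c in param_cols if c not in family_of]
        if unmapped:
            raise SchemaError(f"{path}: columns with no family mapping: {unmapped}")
    else:
        family_of = {}
        for c in param_cols:
            fam = infer_family(c)
            if fam is None:
                raise SchemaError(
                    f"{path}: cannot infer family for column {c!r}; supply an "
                    "explicit schema family_of mapping"
                )
            family_of[c] = fam

    n = len(df)
    values = np.empty((n, len(param_cols)))
    for j, c in enumerate(param_cols):
        for i, cell in enumerate(df[c].to_numpy()):
            try:
                values[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"{path}: non-numeric value {cell!r} at row {i}, column {c!r}"
                ) from exc

    try:
        record_index = df[schema.record_column].astype(int).to_numpy()
    except ValueError as exc:
        raise ParseError(f"{path}: non-integer record index") from exc

    return FeatureTable(
        values=values,
        parameter_names=param_cols,
        family_of=family_of,
        subject_id=df[schema.subject_column].to_numpy(),
        record_index=record_index,
        label=np.array([_parse_label(v, i) for i, v in enumerate(df[schema.label_column])]),
        gender=np.array(
            [_parse_gender(v, i) for i, v in enumerate(df[schema.gender_column])],
            dtype=object,
        ),
    )


def write_feature_table(
    table: FeatureTable, path: str | Path, schema: TableSchema | None = None
) -> Path:
    """Write a FeatureTable as CSV; `read_feature_table` inverts it exactly.

    Floats are printed with `repr` (shortest round-trip representation), so a
    write -> read -> write cycle is byte-identical.
    """
    path = Path(path)
    df = table.to_dataframe(schema)
    df.to_csv(path, index=False, lineterminator="\n")
    return path


@dataclass
class RunConfig:
    """Hyperparameters for the full pipeline.

    ``eta`` / ``gamma`` may be given as absolutes; when None they are resolved
    from the data as the ``eta_quantile``-th percentile of pairwise distances
    and the ``gamma_quantile``-th percentile of the density distribution.
    """

    eta: float | None = None
    eta_quantile: float = 10.0
    gamma: float | None = None
    gamma_quantile: float = 75.0
    r_neighbors: int = 7
    knn_k: int = 7
    svm_sigma: float = 4.0
    n_folds: int = 10
    split_level: str = "record"  # or "subject"
    rng_seed: int = 0
    pca_threshold: float = 0.90
    alpha: float = 0.05
    fit_features_on_all: bool = False  # strict-compat: whole-dataset feature fit

    def __post_init__(self) -> None:
        if self.eta is not None and self.eta <= 0:
            raise ConfigError("eta must be positive")
        if not 0 < self.pca_threshold <= 1:
            raise ConfigError("pca_threshold must be in (0, 1]")
        if not 0 < self.alpha < 1:
            raise ConfigError("alpha must be in (0, 1)")
        if self.r_neighbors < 1:
            raise ConfigError("r_neighbors must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.split_level not in ("record", "subject"):
            raise ConfigError("split_level must be 'record' or 'subject'")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def replace(self, **kwargs) -> "RunConfig":
        return dataclasses.replace(self, **kwargs)
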