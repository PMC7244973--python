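"""Feature-table I/O, run configuration, and report serialization.

A feature table is a rectangular numeric matrix: one row per subject, one
column per biomarker variable, with a header row of unique variable names.
Missing or non-numeric cells are represented by an explicit NaN marker and
are never silently coerced to a number; downstream preprocessing decides
what to do with them.
"""

from __future__ import annotations

import csv
import dataclasses
import io
import json
import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Any, Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

from .exceptions import ConfigError, FormatError

__all__ = [
    "Group",
    "FeatureTable",
    "RunConfig",
    "DEFAULT_KEEP_LIST",
    "read_feature_table",
    "write_feature_table",
    "write_report",
    "read_report",
]


class Group(str, Enum):
    """Diagnostic group of a table of subjects."""

    NORMAL = "normal"
    ABNORMAL = "abnormal"
    UNKNOWN = "unknown"


#: Complete-blood-count variables retained after redundancy pruning in the
#: study this toolkit reproduces; shipped as the default reserved-variable
#: list so pruning decisions are reproducible rather than heuristic.
DEFAULT_KEEP_LIST: tuple[str, ...] = (
    "BA#", "EO#", "LY", "LY#", "MCH", "MCHC", "MO",
    "MO#", "MPV", "PDW", "PLT", "RBC", "RDW", "WBC",
)


@dataclass
class FeatureTable:
    """Subjects-by-variables numeric matrix with a group label.

    Parameters
    ----------
    data:
        DataFrame with one column per variable (float dtype; NaN marks a
        missing cell) and one row per subject.
    group:
        Which diagnostic group the subjects belong to.
    """

    data: pd.DataFrame
    group: Group = Group.UNKNOWN

    def __post_init__(self) -> None:
        self.group = Group(self.group)
        cols = list(self.data.columns)
        if len(cols) == 0:
            raise FormatError("feature table has no variables")
        if any(not str(c).strip() for c in cols):
            raise FormatError("variable names must be non-empty")
        if len(set(cols)) != len(cols):
            dupes = sorted({c for c in cols if cols.count(c) > 1})
            raise FormatError(f"duplicate variable names: {dupes}")
        self.data = self.data.astype(float)

    @property
    def variable_names(self) -> list[str]:
        return [str(c) for c in self.data.columns]

    @property
    def subject_ids(self) -> list[str]:
        return [str(i) for i in self.data.index]

    @property
    def n_subjects(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_variables(self) -> int:
        return int(self.data.shape[1])

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def has_missing(self) -> bool:
        return bool(self.data.isna().to_numpy().any())

    def select(self, variables: Sequence[str]) -> "FeatureTable":
        """Return a table restricted to ``variables``, in the given order."""
        missing = [v for v in variables if v not in self.data.columns]
        if missing:
            raise FormatError(f"variables not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(variables)].copy(), self.group)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FeatureTable):
            return NotImplemented
        if self.group != other.group:
            return False
        if self.variable_names != other.variable_names:
            return False
        a, b = self.values, other.values
        if a.shape != b.shape:
            return False
        return bool(np.array_equal(a, b, equal_nan=True))


def _sniff_delimiter(sample: str) -> str:
    try:
        return csv.Sniffer().sniff(sample, delimiters=",\t").delimiter
    except csv.Error:
        return "\t" if "\t" in sample else ","


def read_feature_table(
    path: str | Path,
    group: Group | str = Group.UNKNOWN,
    delimiter: str | None = None,
) -> FeatureTable:
    """Read a CSV or TSV feature table (header row of variable names).

    Non-numeric or blank cells become the NaN missing marker.  Raises
    :class:`FormatError` for empty files, ragged rows (naming the 1-based
    data-row index), and duplicate header names.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty file")
    if delimiter is None:
        delimiter = _sniff_delimiter(text.splitlines()[0])
    rows = list(csv.reader(io.StringIO(text), delimiter=delimiter))
    rows = [r for r in rows if r]  # ignore fully blank lines
    header = [h.strip() for h in rows[0]]
    width = len(header)
    body: list[list[float]] = []
    for i, row in enumerate(rows[1:], start=1):
        if len(row) != width:
            raise FormatError(
                f"{path}: row {i} has {len(row)} cells, expected {width}"
            )
        body.append([_parse_cell(c) for c in row])
    if not body:
        raise FormatError(f"{path}: no data rows")
    frame = pd.DataFrame(body, columns=header, dtype=float)
    return FeatureTable(frame, Group(group))


def _parse_cell(cell: str) -> float:
    cell = cell.strip()
    if not cell:
        return math.nan
    try:
        value = float(cell)
    except ValueError:
        return math.nan
    return value if math.isfinite(value) else math.nan


def write_feature_table(table: FeatureTable, path: str | Path, delimiter: str = ",") -> None:
    """Write a feature table; missing cells are written as empty fields."""
    table.data.to_csv(path, sep=delimiter, index=False, na_rep="")


@dataclass
class RunConfig:
    """Knobs for a full diagnostic run.

    Attributes
    ----------
    correlation_threshold:
        Prune one variable of every pair with \\|r\\| strictly above this.
    refinement_max_passes:
        How many rounds of control-chart outlier screening to apply to the
        healthy reference set (1 = the single-pass default).
    cv_folds:
        Folds for the optional cross-validated evaluation.
    rng_seed:
        Seed for every random choice (fold assignment, simulation).
    reserved_variables:
        Ordered keep-list consulted when a correlated pair must lose a
        member; earlier names win.
    md_definition:
        ``"scaled"`` divides each Mahalanobis distance by the number of
        variables (healthy mean near 1); ``"unscaled"`` does not.
    condition_bound:
        Correlation-matrix condition number above which a Moore-Penrose
        pseudo-inverse is used instead of a plain inverse.
    """

    correlation_threshold: float = 0.80
    refinement_max_passes: int = 1
    cv_folds: int = 10
    rng_seed: int = 0
    reserved_variables: tuple[str, ...] = DEFAULT_KEEP_LIST
    md_definition: str = "scaled"
    condition_bound: float = 1e10

    def __post_init__(self) -> None:
        if not 0.0 < self.correlation_threshold <= 1.0:
            raise ConfigError(
                f"correlation_threshold must be in (0, 1], got {self.correlation_threshold}"
            )
        if self.refinement_max_passes < 0:
            raise ConfigError("refinement_max_passes must be non-negative")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be at least 2")
        if self.md_definition not in ("scaled", "unscaled"):
            raise ConfigError(
                f"md_definition must be 'scaled' or 'unscaled', got {self.md_definition!r}"
            )
        self.reserved_variables = tuple(self.reserved_variables)

    @property
    def scaled(self) -> bool:
        return self.md_definition == "scaled"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = dataclasses.asdict(self)
        payload["reserved_variables"] = list(self.reserved_variables)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))


def _jsonable(obj: Any) -> Any:
    """Recursively convert numpy scalars/arrays and dataclasses to JSON types."""
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        if hasattr(obj, "to_dict"):
            return _jsonable(obj.to_dict())
        return {f.name: _jsonable(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, Enum):
        return obj.value
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not math.isfinite(obj):
        return None
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    return obj


def write_report(result: Any, path: str | Path) -> None:
    """Serialize a pipeline result (or any result aggregate) as JSON.

    Accepts dataclasses, dicts, and numpy containers; field order follows
    declaration/input order for byte-reproducibility.
    """
    payload = _jsonable(result)
    Path(path).write_text(json.dumps(payload, indent=2) + "\n")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
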