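"""Tabular data model: tables, attribute roles and equivalence classes.

A :class:`DataTable` is an ordered table of opaque text cells backed by a
pandas DataFrame (``object`` dtype throughout; cells are never coerced to
numbers — numeric interpretation happens only inside operations that demand
it, such as interval generalization).  Row identity is positional: the index
holds each row's position in the *original* input, so suppression reporting
can name exactly which input rows were deleted.

A :class:`RoleSchema` classifies columns into the four standard disclosure
roles: identifiers (removed), quasi-identifiers (generalized), at most one
sensitive attribute (protected) and insensitive attributes (passed through).

An :class:`ECPartition` groups row indices into equivalence classes — maximal
sets of rows agreeing on every quasi-identifier.  Missing cells are kept as
the empty-string token and form their own equivalence key; silently merging
them with anything else would overstate anonymity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import EmptyTableError, SchemaError

__all__ = [
    "DataTable",
    "RoleSchema",
    "EquivalenceClass",
    "ECPartition",
    "partition_by_qi",
    "suppress_identifiers",
]

#: the token used for suppressed cells and starred identifiers
SUPPRESSED = "*"


def _to_token(value) -> str:
    """Render an arbitrary cell as its text token (None/NaN -> empty string)."""
    if value is None:
        return ""
    if isinstance(value, float) and value != value:  # NaN
        return ""
    return value if isinstance(value, str) else str(value)


class DataTable:
    """An immutable-by-convention table of text cells with stable row order.

    Parameters
    ----------
    df : pandas.DataFrame
        Backing frame.  All cells are coerced to text tokens on construction;
        the index is preserved (it carries original row positions).
    """

    def __init__(self, df: pd.DataFrame):
        if df.columns.duplicated().any():
            dup = df.columns[df.columns.duplicated()][0]
            raise SchemaError(f"duplicated column name: {dup!r}")
        self._df = df.astype(object).map(_to_token)

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_records(cls, columns: Sequence[str], rows: Iterable[Sequence]) -> "DataTable":
        """Build a table from a column list and row tuples (cells stringified)."""
        data = [list(r) for r in rows]
        for i, r in enumerate(data):
            if len(r) != len(columns):
                raise SchemaError(
                    f"row {i} has {len(r)} cells, expected {len(columns)}"
                )
        return cls(pd.DataFrame(data, columns=list(columns), dtype=object))

    @classmethod
    def from_pandas(cls, df: pd.DataFrame) -> "DataTable":
        """Wrap a pandas DataFrame, resetting the index to row positions."""
        return cls(df.reset_index(drop=True))

    # -- basic accessors ----------------------------------------------------

    @property
    def columns(self) -> list[str]:
        return list(self._df.columns)

    @property
    def n_rows(self) -> int:
        return len(self._df)

    @property
    def index(self) -> list[int]:
        """Original row positions of the retained rows, in table order."""
        return [int(i) for i in self._df.index]

    def column(self, name: str) -> list[str]:
        if name not in self._df.columns:
            raise SchemaError(f"unknown column: {name!r}")
        return list(self._df[name])

    def to_pandas(self) -> pd.DataFrame:
        return self._df.copy()

    def records(self) -> list[tuple[str, ...]]:
        return [tuple(r) for r in self._df.itertuples(index=False, name=None)]

    # -- derived tables -----------------------------------------------------

    def with_columns(self, replacements: Mapping[str, Sequence[str]]) -> "DataTable":
        """Return a copy with whole columns replaced (same order and index)."""
        df = self._df.copy()
        for name, values in replacements.items():
            if name not in df.columns:
                raise SchemaError(f"unknown column: {name!r}")
            df[name] = list(values)
        return DataTable(df)

    def drop_rows(self, original_indices: Iterable[int]) -> "DataTable":
        """Return a copy without the rows at the given original positions."""
        drop = set(original_indices)
        return DataTable(self._df.loc[[i for i in self._df.index if i not in drop]])

    # -- comparisons --------------------------------------------------------

    def __eq__(self, other) -> bool:
        if not isinstance(other, DataTable):
            return NotImplemented
        return self.columns == other.columns and self.records() == other.records()

    def equals_unordered(self, other: "DataTable") -> bool:
        """Cell-for-cell equality up to row order."""
        return self.columns == other.columns and sorted(self.records()) == sorted(
            other.records()
        )

    def __repr__(self) -> str:
        return f"DataTable({self.n_rows} rows x {len(self.columns)} columns)"


@dataclass(frozen=True)
class RoleSchema:
    """Disclosure-role assignment for the columns of one table.

    ``quasi_identifiers`` is ordered: position *i* of every transformation
    vector refers to the *i*-th quasi-identifier listed here.
    """

    identifiers: tuple[str, ...]
    quasi_identifiers: tuple[str, ...]
    sensitive_attribute: str | None = None
    insensitive: tuple[str, ...] = ()

    def __init__(self, identifiers, quasi_identifiers, sensitive_attribute=None,
                 insensitive=()):
        object.__setattr__(self, "identifiers", tuple(identifiers))
        object.__setattr__(self, "quasi_identifiers", tuple(quasi_identifiers))
        object.__setattr__(self, "sensitive_attribute", sensitive_attribute)
        object.__setattr__(self, "insensitive", tuple(insensitive))
        self._check()

    def _check(self) -> None:
        if not self.quasi_identifiers:
            raise SchemaError("at least one quasi-identifier is required")
        groups = {
            "identifiers": set(self.identifiers),
            "quasi_identifiers": set(self.quasi_identifiers),
            "sensitive_attribute": (
                {self.sensitive_attribute} if self.sensitive_attribute else set()
            ),
            "insensitive": set(self.insensitive),
        }
        names = list(groups)
        for i, a in enumerate(names):
            for b in names[i + 1:]:
                overlap = groups[a] & groups[b]
                if overlap:
                    raise SchemaError(
                        f"column(s) {sorted(overlap)} assigned to both {a} and {b}"
                    )

    @property
    def n_qi(self) -> int:
        return len(self.quasi_identifiers)

    def validate_against(self, table: DataTable) -> None:
        """Raise SchemaError if any role names a column absent from *table*."""
        cols = set(table.columns)
        for name in (*self.identifiers, *self.quasi_identifiers, *self.insensitive):
            if name not in cols:
                raise SchemaError(f"schema names unknown column: {name!r}")
        if self.sensitive_attribute and self.sensitive_attribute not in cols:
            raise SchemaError(
                f"schema names unknown column: {self.sensitive_attribute!r}"
            )


@dataclass(frozen=True)
class EquivalenceClass:
    """One equivalence class: its shared QI-value tuple and its row indices."""

    key: tuple[str, ...]
    rows: tuple[int, ...]

    @property
    def size(self) -> int:
        return len(self.rows)


@dataclass(frozen=True)
class ECPartition:
    """The maximal partition of a table's rows by quasi-identifier values."""

    qi: tuple[str, ...]
    classes: tuple[EquivalenceClass, ...] = field(default_factory=tuple)

    def sizes(self) -> list[int]:
        return [c.size for c in self.classes]

    @property
    def n_classes(self) -> int:
        return len(self.classes)

    def min_size(self) -> int:
        if not self.classes:
            raise EmptyTableError("partition of an empty table has no class sizes")
        return min(self.sizes())


def partition_by_qi(table: DataTable, qi: Sequence[str]) -> ECPartition:
    """Partition *table* into equivalence classes over the given QI columns.

    Classes appear in first-appearance order of their key; within a class,
    rows keep table order.  Cells compare as exact text tokens ("29" != "29.0").
    """
    if not qi:
        raise SchemaError("quasi-identifier list must be non-empty")
    for name in qi:
        if name not in table.columns:
            raise SchemaError(f"unknown column: {name!r}")
    df = table.to_pandas()
    groups: dict[tuple[str, ...], list[int]] = {}
    cols = [df[c] for c in qi]
    for idx, key in zip(df.index, zip(*cols)):
        groups.setdefault(key, []).append(int(idx))
    classes = tuple(
        EquivalenceClass(key=key, rows=tuple(rows)) for key, rows in groups.items()
    )
    return ECPartition(qi=tuple(qi), classes=classes)


def suppress_identifiers(table: DataTable, schema: RoleSchema) -> DataTable:
    """Replace every cell of every identifier column by ``*``.

    Columns are retained (starred, not dropped), so output tables keep the
    input's shape; all other columns are untouched.
    """
    schema.validate_against(table)
    return table.with_columns(
        {c: [SUPPRESSED] * table.n_rows for c in schema.identifiers}
    )
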