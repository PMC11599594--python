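"""Embedded example data and a synthetic microdata generator.

The 13-row hospital table is the standard worked example for hierarchy-based
anonymization: one identifier (name), three quasi-identifiers (age, gender,
city), one insensitive attribute (religion) and one sensitive attribute
(disease).  :func:`hospital_hierarchies` builds the matching generalization
hierarchies: 5- and 10-year age intervals over [0, 100), and plain
suppression for gender and city.

:func:`generate_synthetic` produces seeded random microdata tables from a
:class:`SyntheticSpec`, so the whole engine can be exercised at any size with
zero downloads.  The generator draws columns independently (categorical draws
with given weights, uniform or clipped-normal integers); it makes no attempt
to model correlated attributes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigError
from .hierarchy import Hierarchy, build_suppression_hierarchy, interval_hierarchy
from .model import DataTable, RoleSchema

__all__ = [
    "hospital_table",
    "hospital_schema",
    "hospital_hierarchies",
    "ColumnSpec",
    "SyntheticSpec",
    "generate_synthetic",
]

_HOSPITAL_COLUMNS = ("name", "age", "gender", "city", "religion", "disease")

_HOSPITAL_ROWS = (
    ("Ramsha", "29", "Female", "Tamil Nadu", "Hindu", "Cancer"),
    ("Gabu", "24", "Male", "Tamil Nadu", "Hindu", "Cancer"),
    ("Sabu", "23", "Male", "Tamil Nadu", "Hindu", "Cancer"),
    ("Jonas", "22", "Male", "Tamil Nadu", "Hindu", "Cancer"),
    ("Yadu", "24", "Female", "Kerala", "Hindu", "Viral infection"),
    ("Salima", "28", "Female", "Tamil Nadu", "Muslim", "TB"),
    ("Sunny", "27", "Male", "Karnataka", "Parsi", "No illness"),
    ("Joan", "24", "Female", "Kerala", "Christian", "Heart-related"),
    ("Bahuksana", "23", "Male", "Karnataka", "Buddhist", "TB"),
    ("Rambha", "19", "Male", "Kerala", "Hindu", "Cancer"),
    ("Kishor", "29", "Male", "Karnataka", "Hindu", "Heart-related"),
    ("Johnson", "17", "Male", "Kerala", "Christian", "Heart-related"),
    ("John", "19", "Male", "Kerala", "Christian", "Viral infection"),
)


def hospital_table() -> DataTable:
    """The 13-row hospital microdata example."""
    return DataTable.from_records(_HOSPITAL_COLUMNS, _HOSPITAL_ROWS)


def hospital_schema() -> RoleSchema:
    """Roles for the hospital table: name=ID; age,gender,city=QI; disease=SA."""
    return RoleSchema(
        identifiers=["name"],
        quasi_identifiers=["age", "gender", "city"],
        sensitive_attribute="disease",
        insensitive=["religion"],
    )


def hospital_hierarchies() -> dict[str, Hierarchy]:
    """The standard hierarchies for the hospital example.

    age: level 1 = 5-year intervals, level 2 = 10-year intervals (over
    [0, 100)); gender and city: suppression as the only level.
    """
    table = hospital_table()
    return {
        "age": interval_hierarchy(table.column("age"), 0, 100, steps=[5, 10]),
        "gender": build_suppression_hierarchy(table.column("gender")),
        "city": build_suppression_hierarchy(table.column("city")),
    }


# ---------------------------------------------------------------------------
# synthetic microdata


@dataclass(frozen=True)
class ColumnSpec:
    """Distribution of one synthetic column.

    kind='categorical' draws from ``values`` with ``weights`` (summing to 1);
    kind='uniform_int' draws integers uniformly from [lower, upper);
    kind='normal_int' draws round(N(mean, sd)) clipped into [lower, upper).
    Cells are rendered as text tokens, like every table cell.
    """

    kind: str
    values: tuple[str, ...] = ()
    weights: tuple[float, ...] = ()
    lower: float = 0.0
    upper: float = 1.0
    mean: float = 0.0
    sd: float = 1.0

    def __post_init__(self):
        if self.kind == "categorical":
            if not self.values:
                raise ConfigError("categorical column needs values")
            weights = self.weights or tuple(
                1.0 / len(self.values) for _ in self.values
            )
            if len(weights) != len(self.values):
                raise ConfigError("weights must match values")
            if abs(sum(weights) - 1.0) > 1e-9:
                raise ConfigError(f"weights must sum to 1, got {sum(weights)}")
            object.__setattr__(self, "weights", tuple(weights))
        elif self.kind in ("uniform_int", "normal_int"):
            if not self.lower < self.upper:
                raise ConfigError("lower must be < upper")
        else:
            raise ConfigError(f"unknown column kind {self.kind!r}")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic table: size, columns, roles and seed."""

    n_rows: int
    columns: Mapping[str, ColumnSpec]
    schema: RoleSchema
    seed: int = 0

    def __post_init__(self):
        if self.n_rows < 1:
            raise ConfigError("n_rows must be >= 1")
        if not self.columns:
            raise ConfigError("at least one column is required")


def _draw(spec: ColumnSpec, n: int, rng: np.random.Generator) -> list[str]:
    if spec.kind == "categorical":
        return list(rng.choice(list(spec.values), size=n, p=list(spec.weights)))
    if spec.kind == "uniform_int":
        return [str(int(v)) for v in rng.integers(int(spec.lower), int(spec.upper), n)]
    # normal_int
    draws = np.rint(rng.normal(spec.mean, spec.sd, n))
    clipped = np.clip(draws, spec.lower, spec.upper - 1)
    return [str(int(v)) for v in clipped]


def generate_synthetic(spec: SyntheticSpec) -> DataTable:
    """Generate a deterministic random table from *spec* (seed decides all)."""
    rng = np.random.default_rng(spec.seed)
    columns = {name: _draw(cs, spec.n_rows, rng) for name, cs in spec.columns.items()}
    table = DataTable.from_records(
        list(columns), rows=list(zip(*columns.values()))
    )
    spec.schema.validate_against(table)
    return table
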