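"""Generalization hierarchies: construction, application and inversion.

A hierarchy for one quasi-identifier is an ordered chain of total value
mappings h1..hn: level 0 is the raw value domain, level j maps every value of
the level j-1 domain to a coarser one.  The last level is often full
suppression, mapping everything to ``*``.

Hierarchies are stored row-wise in the ARX-style convention: one row per raw
value, column 0 the raw value, column j its level-j generalization.  Interval
hierarchies for numeric columns are generated from (lower, upper, step)
rules; labels render as ``[a, b)`` (half-open, single space after the comma,
integer bounds without a decimal point) so printed-table comparisons are
byte-exact.

A transformation vector records, per quasi-identifier in schema order, which
level was applied (0 = untouched); :func:`get_transformation` recovers it
from an anonymized table.
"""

from __future__ import annotations

import math
from typing import Mapping, Sequence

from .errors import (
    HierarchyCoverageError,
    HierarchyError,
    HierarchyInconsistencyError,
    RangeError,
    SchemaError,
)
from .model import SUPPRESSED, DataTable, RoleSchema

__all__ = [
    "Hierarchy",
    "generate_intervals",
    "build_suppression_hierarchy",
    "interval_hierarchy",
    "apply_levels",
    "get_transformation",
    "validate_transformation",
]

#: a hierarchy set maps quasi-identifier name -> Hierarchy; QIs absent from
#: the mapping are never generalized.
HierarchySet = Mapping[str, "Hierarchy"]

#: a transformation vector is one applied level per QI, in schema QI order.
TransformationVector = Sequence[int]


def _fmt_number(x: float) -> str:
    """Render a bound: integers without decimal point, otherwise plain float."""
    return str(int(x)) if float(x).is_integer() else str(x)


def interval_label(lower_bound: float, upper_bound: float) -> str:
    """The half-open bin label ``[a, b)``."""
    return f"[{_fmt_number(lower_bound)}, {_fmt_number(upper_bound)})"


def generate_intervals(
    values: Sequence, lower: float, upper: float, step: float
) -> list[str]:
    """Map each numeric value to the label of its half-open bin.

    Bins are ``[lower + m*step, lower + (m+1)*step)``; every value must
    satisfy ``lower <= v < upper``.  Returns one label per input value.
    """
    if not lower < upper:
        raise RangeError(f"lower bound {lower} must be < upper bound {upper}")
    if not step > 0:
        raise RangeError(f"step must be positive, got {step}")
    labels = []
    for v in values:
        try:
            x = float(v)
        except (TypeError, ValueError):
            raise RangeError(f"value {v!r} is not numeric") from None
        if not (lower <= x < upper):
            raise RangeError(f"value {v!r} outside [{lower}, {upper})")
        m = math.floor((x - lower) / step)
        # guard against floating error at exact bin edges
        lo = lower + m * step
        if x < lo:
            m -= 1
        elif x >= lower + (m + 1) * step:
            m += 1
        labels.append(interval_label(lower + m * step, lower + (m + 1) * step))
    return labels


class Hierarchy:
    """An ordered chain of level mappings for one quasi-identifier.

    ``levels[j-1]`` maps every level j-1 value to its level-j generalization;
    level 0 is the identity over the raw domain.
    """

    def __init__(self, raw_domain: Sequence[str], levels: Sequence[Mapping[str, str]]):
        self._raw = tuple(dict.fromkeys(str(v) for v in raw_domain))
        if not self._raw:
            raise HierarchyError("raw domain must be non-empty")
        self._levels = [dict(m) for m in levels]
        # totality: level j must cover the image of level j-1
        domain = set(self._raw)
        for j, mapping in enumerate(self._levels, start=1):
            missing = domain - set(mapping)
            if missing:
                raise HierarchyError(
                    f"level {j} does not map value(s) {sorted(missing)[:3]}"
                )
            domain = {mapping[v] for v in domain}

    @property
    def max_level(self) -> int:
        """Number of non-identity levels."""
        return len(self._levels)

    @property
    def raw_domain(self) -> tuple[str, ...]:
        return self._raw

    def image(self, level: int) -> set[str]:
        """The set of values the raw domain maps to at *level* (0 = raw)."""
        self._check_level(level)
        values = set(self._raw)
        for mapping in self._levels[:level]:
            values = {mapping[v] for v in values}
        return values

    def compose(self, level: int) -> dict[str, str]:
        """The single-valued map raw value -> level-*level* value."""
        self._check_level(level)
        comp = {v: v for v in self._raw}
        for mapping in self._levels[:level]:
            comp = {raw: mapping[v] for raw, v in comp.items()}
        return comp

    def _check_level(self, level: int) -> None:
        if not 0 <= level <= self.max_level:
            raise HierarchyError(
                f"level {level} out of range 0..{self.max_level}"
            )

    # -- constructors -------------------------------------------------------

    @classmethod
    def from_rows(cls, rows: Sequence[Sequence[str]]) -> "Hierarchy":
        """Build from ARX-style rows: [raw, level1, ..., levelN] per raw value.

        The per-level mapping derived from the rows must be functional: a
        value appearing twice at level j-1 must generalize identically at j.
        """
        if not rows:
            raise HierarchyError("hierarchy needs at least one row")
        width = len(rows[0])
        if width < 1 or any(len(r) != width for r in rows):
            raise HierarchyError("hierarchy rows must be non-empty and rectangular")
        str_rows = [[str(c) for c in r] for r in rows]
        raw = [r[0] for r in str_rows]
        if len(set(raw)) != len(raw):
            dup = next(v for v in raw if raw.count(v) > 1)
            raise HierarchyError(f"duplicate raw value in hierarchy: {dup!r}")
        levels: list[dict[str, str]] = []
        for j in range(1, width):
            mapping: dict[str, str] = {}
            for r in str_rows:
                prev, cur = r[j - 1], r[j]
                if mapping.setdefault(prev, cur) != cur:
                    raise HierarchyError(
                        f"level {j} is not a function: {prev!r} maps to both "
                        f"{mapping[prev]!r} and {cur!r}"
                    )
            levels.append(mapping)
        return cls(raw, levels)

    @classmethod
    def from_columns(cls, columns: Sequence[Sequence[str]]) -> "Hierarchy":
        """Build from parallel columns (column 0 = raw values)."""
        return cls.from_rows(list(zip(*columns)))


def build_suppression_hierarchy(raw_values) -> Hierarchy:
    """One-level hierarchy mapping every raw value to ``*``."""
    raw = [str(v) for v in raw_values]
    if not raw:
        raise HierarchyError("raw value set must be non-empty")
    return Hierarchy(raw, [{v: SUPPRESSED for v in dict.fromkeys(raw)}])


def interval_hierarchy(
    raw_values,
    lower: float,
    upper: float,
    steps: Sequence[float],
    suppress_last: bool = False,
) -> Hierarchy:
    """Interval-based hierarchy: level j bins raw values with ``steps[j-1]``.

    Steps must coarsen consistently (each label of one level must fall in a
    single bin of the next — e.g. steps 5 then 10); an optional final
    suppression level maps everything to ``*``.
    """
    raw = [str(v) for v in dict.fromkeys(str(v) for v in raw_values)]
    if not raw:
        raise HierarchyError("raw value set must be non-empty")
    columns: list[list[str]] = [raw]
    for step in steps:
        columns.append(generate_intervals(raw, lower, upper, step))
    if suppress_last:
        columns.append([SUPPRESSED] * len(raw))
    return Hierarchy.from_columns(columns)


def validate_transformation(
    tv: TransformationVector, hierarchies: HierarchySet, schema: RoleSchema
) -> None:
    """Check length and per-QI level bounds of a transformation vector."""
    qi = schema.quasi_identifiers
    if len(tv) != len(qi):
        raise SchemaError(
            f"transformation vector length {len(tv)} != number of QIs {len(qi)}"
        )
    for level, name in zip(tv, qi):
        if level < 0:
            raise HierarchyError(f"negative level for {name!r}")
        max_level = hierarchies[name].max_level if name in hierarchies else 0
        if level > max_level:
            raise HierarchyError(
                f"level {level} for {name!r} exceeds max level {max_level}"
            )


def apply_levels(
    table: DataTable,
    hierarchies: HierarchySet,
    tv: TransformationVector,
    schema: RoleSchema,
) -> DataTable:
    """Rewrite each QI column by its hierarchy composed up to ``tv[i]``.

    Level 0 leaves a column untouched; non-QI columns are never modified.  A
    raw cell absent from the hierarchy's domain raises a coverage error
    naming the column and value.
    """
    schema.validate_against(table)
    validate_transformation(tv, hierarchies, schema)
    replacements: dict[str, list[str]] = {}
    for name, level in zip(schema.quasi_identifiers, tv):
        if level == 0:
            continue
        comp = hierarchies[name].compose(level)
        new_col = []
        for value in table.column(name):
            if value not in comp:
                raise HierarchyCoverageError(
                    f"column {name!r}: value {value!r} not covered by the hierarchy"
                )
            new_col.append(comp[value])
        replacements[name] = new_col
    return table.with_columns(replacements)


def get_transformation(
    anon_table: DataTable, qi: Sequence[str], hierarchies: HierarchySet
) -> list[int]:
    """Recover the per-QI applied levels from an anonymized table.

    Entry *i* is the unique level whose image contains every observed value
    of QI *i*; if images collide across levels (e.g. ``*`` appearing twice)
    the lowest matching level wins.  Columns without a hierarchy must be
    untouched and report 0.
    """
    for name in qi:
        if name not in anon_table.columns:
            raise SchemaError(f"unknown column: {name!r}")
    levels = []
    for name in qi:
        observed = set(anon_table.column(name))
        if name not in hierarchies:
            levels.append(0)
            continue
        hier = hierarchies[name]
        found = None
        for j in range(hier.max_level + 1):
            if observed <= hier.image(j):
                found = j
                break
        if found is None:
            all_images: set[str] = set()
            for j in range(hier.max_level + 1):
                all_images |= hier.image(j)
            uncovered = observed - all_images
            if uncovered:
                raise HierarchyCoverageError(
                    f"column {name!r}: value {sorted(uncovered)[0]!r} appears in "
                    "no hierarchy level"
                )
            raise HierarchyInconsistencyError(
                f"column {name!r}: observed values span multiple hierarchy levels"
            )
        levels.append(found)
    return levels
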