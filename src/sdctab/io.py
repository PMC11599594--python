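"""CSV input/output and run configuration.

CSV is the only table format in v1 (RFC-4180 dialect, UTF-8, header row).
Cells are never coerced to numbers on read, so a write/read round trip is
byte-stable; ragged rows and duplicated headers are rejected with the
offending line, before any anonymization starts.

Hierarchies are declared in a YAML or JSON file mapping each quasi-identifier
to either

- a path to an ARX-style hierarchy CSV (no header; column 0 = raw value,
  column j = its level-j generalization), relative paths resolved against the
  config file,
- ``{type: interval, lower: .., upper: .., steps: [..], suppress: bool}`` for
  numeric binning (one level per step, optional final suppression level), or
- ``{type: suppression}`` to star the whole column as the only level.

Quasi-identifiers absent from the mapping are never generalized.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import yaml

from .engine import PrivacyRequirement
from .errors import ConfigError, ParseError, SchemaError
from .hierarchy import (
    Hierarchy,
    build_suppression_hierarchy,
    interval_hierarchy,
)
from .model import DataTable, RoleSchema

__all__ = [
    "read_table",
    "write_table",
    "read_hierarchy_csv",
    "write_hierarchy_csv",
    "load_hierarchy_config",
    "build_hierarchies",
    "RunConfig",
]


def read_table(path) -> DataTable:
    """Read a CSV file (header row) into a DataTable of text tokens."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ParseError(f"{path}: empty file, expected a header row") from None
        seen = set()
        for name in header:
            if name in seen:
                raise SchemaError(f"{path}: duplicated header name {name!r}")
            seen.add(name)
        rows = []
        for lineno, row in enumerate(reader, start=2):
            if len(row) != len(header):
                raise ParseError(
                    f"{path}, line {lineno}: expected {len(header)} fields, "
                    f"got {len(row)}"
                )
            rows.append(row)
    return DataTable.from_records(header, rows)


def write_table(table: DataTable, path) -> None:
    """Write a DataTable as CSV (header row, RFC-4180 quoting, UTF-8)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(table.columns)
        writer.writerows(table.records())


def read_hierarchy_csv(path) -> Hierarchy:
    """Read an ARX-style hierarchy table (no header row)."""
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = [row for row in csv.reader(fh) if row]
    if not rows:
        raise ParseError(f"{path}: empty hierarchy file")
    return Hierarchy.from_rows(rows)


def write_hierarchy_csv(hier: Hierarchy, path) -> None:
    """Write a hierarchy in the ARX-style row convention."""
    path = Path(path)
    compositions = [hier.compose(j) for j in range(hier.max_level + 1)]
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        for raw in hier.raw_domain:
            writer.writerow([comp[raw] for comp in compositions])


def load_hierarchy_config(path) -> dict:
    """Parse (not materialize) a YAML/JSON hierarchy mapping."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        spec = json.loads(text)
    else:
        spec = yaml.safe_load(text)
    if not isinstance(spec, dict):
        raise ConfigError(f"{path}: hierarchy config must be a mapping")
    for qi, entry in spec.items():
        if isinstance(entry, str):
            continue
        if not isinstance(entry, dict) or "type" not in entry:
            raise ConfigError(
                f"{path}: entry for {qi!r} must be a path or a mapping with 'type'"
            )
        if entry["type"] == "interval":
            for key in ("lower", "upper", "steps"):
                if key not in entry:
                    raise ConfigError(
                        f"{path}: interval hierarchy for {qi!r} needs {key!r}"
                    )
        elif entry["type"] != "suppression":
            raise ConfigError(
                f"{path}: unknown hierarchy type {entry['type']!r} for {qi!r}"
            )
    return spec


def build_hierarchies(
    spec: Mapping, table: DataTable, base_dir=None
) -> dict[str, Hierarchy]:
    """Materialize a hierarchy config against the table's raw columns."""
    base = Path(base_dir) if base_dir else Path(".")
    out: dict[str, Hierarchy] = {}
    for qi, entry in spec.items():
        if qi not in table.columns:
            raise SchemaError(f"hierarchy config names unknown column {qi!r}")
        values = table.column(qi)
        if isinstance(entry, str):
            p = Path(entry)
            out[qi] = read_hierarchy_csv(p if p.is_absolute() else base / p)
        elif entry["type"] == "interval":
            out[qi] = interval_hierarchy(
                values,
                float(entry["lower"]),
                float(entry["upper"]),
                [float(s) for s in entry["steps"]],
                suppress_last=bool(entry.get("suppress", False)),
            )
        else:  # suppression
            out[qi] = build_suppression_hierarchy(values)
    return out


@dataclass(frozen=True)
class RunConfig:
    """A fully validated anonymization run: roles, method, budget, hierarchies.

    Structural validation (roles disjoint, method parameters present and in
    range) happens on construction, before any data is read; hierarchy specs
    are materialized against the table later via :func:`build_hierarchies`.
    """

    input_path: Path
    output_path: Path | None
    schema: RoleSchema
    requirement: PrivacyRequirement
    hierarchy_spec: Mapping = field(default_factory=dict)
    hierarchy_base_dir: Path | None = None
    numeric_sa: bool = False
    report_path: Path | None = None
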