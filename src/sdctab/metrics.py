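"""Privacy auditing: achieved levels of the nine disclosure-control models.

All metrics are computed over the equivalence-class partition of the table by
its quasi-identifiers.  Writing p(s|EC) for the relative frequency of
sensitive value s inside one equivalence class and q(s) for its relative
frequency over all retained rows:

- k-anonymity            : k = minimum class size
- (alpha,k)-anonymity    : alpha = max p(s|EC) over classes and values
- l-diversity            : l = min number of distinct s per class
- entropy l-diversity    : largest integer l with min-class entropy >= ln l
- recursive (c,l)        : smallest integer c with r1 < c*(r_l+..+r_m) in
                           every class (r_i the descending value counts)
- t-closeness            : t = max earth-mover's distance between p(.|EC)
                           and q; categorical ground distance (default) gives
                           EMD = 1/2 * sum |p-q|; the ordered numeric variant
                           is opt-in
- delta-disclosure       : delta = max |ln(p/q)| over classes and values
                           with p > 0 (satisfied for requirements strictly
                           greater than this)
- beta-likeness          : beta = max (p-q)/q over pairs with p > q; the
                           enhanced criterion additionally caps the distance
                           at -ln q per value, reported as a feasibility flag

Natural logarithms everywhere.  The global distribution q is measured on the
retained (post-suppression) rows of the audited table, i.e. the table as it
would be published.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from typing import NamedTuple

from .errors import EmptyTableError, SchemaError
from .model import DataTable, ECPartition, RoleSchema, partition_by_qi

__all__ = [
    "calc_k",
    "calc_alpha",
    "calc_l",
    "calc_entropy_l",
    "calc_recursive_c",
    "calc_t",
    "calc_delta",
    "calc_beta",
    "BetaResult",
    "PrivacyReport",
    "privacy_report",
    "INFEASIBLE",
]

#: tolerance applied before flooring exp(entropy), so exp(ln 3) reports 3
_ENTROPY_EPS = 1e-9

#: marker returned when recursive (c,l)-diversity has no finite c
INFEASIBLE = None


def _partition(table: DataTable, schema: RoleSchema) -> ECPartition:
    schema.validate_against(table)
    if table.n_rows == 0:
        raise EmptyTableError("cannot audit an empty table")
    return partition_by_qi(table, schema.quasi_identifiers)


def _sa_column(table: DataTable, schema: RoleSchema) -> list[str]:
    if not schema.sensitive_attribute:
        raise SchemaError("this metric requires a sensitive attribute")
    return table.column(schema.sensitive_attribute)


def _ec_counters(
    table: DataTable, schema: RoleSchema
) -> tuple[list[Counter], Counter, int]:
    """Per-class and global sensitive-value counts over retained rows."""
    part = _partition(table, schema)
    sa = dict(zip(table.index, _sa_column(table, schema)))
    per_ec = [Counter(sa[i] for i in ec.rows) for ec in part.classes]
    return per_ec, Counter(sa.values()), table.n_rows


def calc_k(table: DataTable, schema: RoleSchema) -> int:
    """Minimum equivalence-class size (the achieved k-anonymity)."""
    return _partition(table, schema).min_size()


def calc_alpha(table: DataTable, schema: RoleSchema) -> float:
    """Maximum within-class relative frequency of any sensitive value."""
    per_ec, _, _ = _ec_counters(table, schema)
    return max(max(c.values()) / sum(c.values()) for c in per_ec)


def calc_l(table: DataTable, schema: RoleSchema) -> int:
    """Minimum number of distinct sensitive values per equivalence class."""
    per_ec, _, _ = _ec_counters(table, schema)
    return min(len(c) for c in per_ec)


def _entropy(counter: Counter) -> float:
    n = sum(counter.values())
    return -sum((c / n) * math.log(c / n) for c in counter.values())


def calc_entropy_l(table: DataTable, schema: RoleSchema) -> int:
    """Largest integer l such that every class has entropy >= ln l."""
    per_ec, _, _ = _ec_counters(table, schema)
    min_h = min(_entropy(c) for c in per_ec)
    return int(math.floor(math.exp(min_h) + _ENTROPY_EPS))


def calc_recursive_c(table: DataTable, schema: RoleSchema, l: int) -> int | None:
    """Smallest integer c >= 1 satisfying recursive (c,l)-diversity.

    Every class with descending sensitive-value counts r1 >= ... >= rm must
    satisfy r1 < c * (r_l + ... + r_m).  Returns ``INFEASIBLE`` (None) when
    some class has fewer than l distinct values (empty tail sum).
    """
    if l < 1:
        raise SchemaError(f"l must be >= 1, got {l}")
    per_ec, _, _ = _ec_counters(table, schema)
    c_needed = 1
    for counter in per_ec:
        counts = sorted(counter.values(), reverse=True)
        if len(counts) < l:
            return INFEASIBLE
        tail = sum(counts[l - 1:])
        # smallest integer c with r1 < c * tail
        c_needed = max(c_needed, counts[0] // tail + 1)
    return c_needed


def _emd_categorical(p: dict[str, float], q: dict[str, float]) -> float:
    support = set(p) | set(q)
    return 0.5 * sum(abs(p.get(s, 0.0) - q.get(s, 0.0)) for s in support)


def _emd_ordered(p: dict[str, float], q: dict[str, float]) -> float:
    """EMD with unit-normalized ordered ground distance over numeric support."""
    support = sorted(set(p) | set(q), key=float)
    m = len(support)
    if m == 1:
        return 0.0
    cum = 0.0
    total = 0.0
    for s in support:
        cum += p.get(s, 0.0) - q.get(s, 0.0)
        total += abs(cum)
    return total / (m - 1)


def calc_t(table: DataTable, schema: RoleSchema, numeric: bool = False) -> float:
    """Maximum earth-mover's distance of a class distribution from the global.

    With ``numeric=True`` the sensitive values are treated as ordered numbers
    and the ordered-distance EMD is used; the default treats them as
    categories with equal ground distance.
    """
    per_ec, global_counts, n = _ec_counters(table, schema)
    q = {s: c / n for s, c in global_counts.items()}
    emd = _emd_ordered if numeric else _emd_categorical
    best = 0.0
    for counter in per_ec:
        size = sum(counter.values())
        p = {s: c / size for s, c in counter.items()}
        best = max(best, emd(p, q))
    return best


def calc_delta(table: DataTable, schema: RoleSchema) -> float:
    """Maximum |ln(p(s|EC)/q(s))| over classes and observed sensitive values.

    The table satisfies delta-disclosure for any delta strictly greater than
    the returned value.
    """
    per_ec, global_counts, n = _ec_counters(table, schema)
    q = {s: c / n for s, c in global_counts.items()}
    best = 0.0
    for counter in per_ec:
        size = sum(counter.values())
        for s, c in counter.items():
            best = max(best, abs(math.log((c / size) / q[s])))
    return best


class BetaResult(NamedTuple):
    """Achieved beta plus feasibility of the enhanced criterion."""

    beta: float
    enhanced_feasible: bool


def calc_beta(table: DataTable, schema: RoleSchema, enhanced: bool = False):
    """Maximum relative excess D = (p-q)/q over pairs with p > q (0 if none).

    In enhanced mode the result also reports whether the enhanced criterion
    (D <= min(beta, -ln q) per value) is achievable for *any* beta, i.e.
    whether every pair satisfies D <= -ln q.
    """
    per_ec, global_counts, n = _ec_counters(table, schema)
    q = {s: c / n for s, c in global_counts.items()}
    best = 0.0
    feasible = True
    for counter in per_ec:
        size = sum(counter.values())
        for s, c in counter.items():
            p = c / size
            if p > q[s]:
                d = (p - q[s]) / q[s]
                best = max(best, d)
                if d > -math.log(q[s]) + 1e-12:
                    feasible = False
    if enhanced:
        return BetaResult(best, feasible)
    return best


@dataclass(frozen=True)
class PrivacyReport:
    """Achieved privacy levels of one table under every supported model.

    Sensitive-attribute metrics are None when the schema has no sensitive
    attribute.  ``recursive_c_for_l`` is the smallest feasible c at
    ``l`` = the achieved l-diversity of the table.
    """

    k: int
    n_classes: int
    class_sizes: tuple[int, ...]
    alpha: float | None = None
    l: int | None = None
    entropy_l: int | None = None
    recursive_c_for_l: int | None = None
    t: float | None = None
    delta: float | None = None
    beta_basic: float | None = None
    beta_enhanced: float | None = None
    enhanced_beta_feasible: bool | None = None

    def to_dict(self) -> dict:
        return {
            "k": self.k,
            "n_classes": self.n_classes,
            "class_sizes": list(self.class_sizes),
            "alpha": self.alpha,
            "l": self.l,
            "entropy_l": self.entropy_l,
            "recursive_c_for_l": self.recursive_c_for_l,
            "t": self.t,
            "delta": self.delta,
            "beta_basic": self.beta_basic,
            "beta_enhanced": self.beta_enhanced,
            "enhanced_beta_feasible": self.enhanced_beta_feasible,
        }


def privacy_report(
    table: DataTable, schema: RoleSchema, numeric_sa: bool = False
) -> PrivacyReport:
    """Audit *table*: compute the achieved level of every privacy model."""
    part = _partition(table, schema)
    base = {
        "k": part.min_size(),
        "n_classes": part.n_classes,
        "class_sizes": tuple(part.sizes()),
    }
    if not schema.sensitive_attribute:
        return PrivacyReport(**base)
    l = calc_l(table, schema)
    beta = calc_beta(table, schema, enhanced=True)
    return PrivacyReport(
        **base,
        alpha=calc_alpha(table, schema),
        l=l,
        entropy_l=calc_entropy_l(table, schema),
        recursive_c_for_l=calc_recursive_c(table, schema, l),
        t=calc_t(table, schema, numeric=numeric_sa),
        delta=calc_delta(table, schema),
        beta_basic=beta.beta,
        beta_enhanced=beta.beta,
        enhanced_beta_feasible=beta.enhanced_feasible,
    )
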