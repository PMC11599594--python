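"""The anonymization search engine.

Given a table, a role schema, per-QI generalization hierarchies, a privacy
requirement and a record-suppression budget, the engine finds a
transformation vector (one hierarchy level per quasi-identifier) plus a set
of whole equivalence classes to delete, such that the requirement holds on
the output.

Search strategy
---------------
Identifiers are starred first.  The walk is greedy, one level at a time: at
each step the engine checks whether deleting every violating equivalence
class (iterated to a fixpoint, because deleting classes shifts the global
sensitive-value distribution) closes the gap within the suppression budget;
if so it deletes and finishes, otherwise it generalizes one more level on the
quasi-identifier with the most distinct values in the current table state
(ties broken by schema QI order).  Composite requirements run in two phases:
plain k-anonymity first, then the sensitive-attribute criterion, sharing one
suppression budget measured against the *original* row count.

If the greedy path exhausts the lattice without success, the engine scans the
full lattice exhaustively (ordered by total generalization, then
lexicographically) before declaring the requirement unachievable, so a
feasible node is never missed on account of the heuristic.  The whole search
is deterministic; identical inputs give identical outputs.
"""

from __future__ import annotations

import itertools
import logging
import math
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .errors import EmptyTableError, SchemaError, UnachievableRequirementError
from .hierarchy import HierarchySet, apply_levels
from .metrics import PrivacyReport, _emd_categorical, _emd_ordered, _entropy, privacy_report
from .model import DataTable, RoleSchema, partition_by_qi, suppress_identifiers

__all__ = [
    "PrivacyRequirement",
    "AnonymizationResult",
    "violating_rows",
    "choose_next_generalization",
    "anonymize",
    "requirement_satisfied",
    "k_anonymity",
    "alpha_k_anonymity",
    "l_diversity",
    "entropy_l_diversity",
    "recursive_c_l_diversity",
    "t_closeness",
    "delta_disclosure",
    "basic_beta_likeness",
    "enhanced_beta_likeness",
]

logger = logging.getLogger(__name__)

_EPS = 1e-12

#: method name -> the extra parameters it requires beyond k and supp
METHOD_PARAMS = {
    "k_anonymity": (),
    "alpha_k": ("alpha",),
    "l_diversity": ("l",),
    "entropy_l": ("l",),
    "recursive_cl": ("c", "l"),
    "t_closeness": ("t",),
    "delta_disclosure": ("delta",),
    "beta_basic": ("beta",),
    "beta_enhanced": ("beta",),
}


@dataclass(frozen=True)
class PrivacyRequirement:
    """A privacy model plus its parameters and the suppression budget.

    ``k`` is always required (every composite model enforces k-anonymity
    first); ``supp`` is the maximum percentage of original records that may
    be deleted.
    """

    method: str
    k: int
    supp: float = 0.0
    alpha: float | None = None
    l: int | None = None
    c: int | None = None
    t: float | None = None
    delta: float | None = None
    beta: float | None = None

    def __post_init__(self):
        if self.method not in METHOD_PARAMS:
            raise SchemaError(
                f"unknown method {self.method!r}; expected one of "
                f"{sorted(METHOD_PARAMS)}"
            )
        if not (isinstance(self.k, int) and self.k >= 1):
            raise SchemaError(f"k must be an integer >= 1, got {self.k!r}")
        if not 0 <= self.supp <= 100:
            raise SchemaError(f"supp must be in [0, 100], got {self.supp!r}")
        for name in METHOD_PARAMS[self.method]:
            if getattr(self, name) is None:
                raise SchemaError(f"method {self.method!r} requires parameter {name!r}")
        if self.alpha is not None and not 0 < self.alpha <= 1:
            raise SchemaError(f"alpha must be in (0, 1], got {self.alpha!r}")
        if self.l is not None and not (isinstance(self.l, int) and self.l >= 1):
            raise SchemaError(f"l must be an integer >= 1, got {self.l!r}")
        if self.c is not None and not (isinstance(self.c, int) and self.c >= 1):
            raise SchemaError(f"c must be an integer >= 1, got {self.c!r}")
        if self.t is not None and self.t < 0:
            raise SchemaError(f"t must be >= 0, got {self.t!r}")
        if self.delta is not None and self.delta <= 0:
            raise SchemaError(f"delta must be > 0, got {self.delta!r}")
        if self.beta is not None and self.beta <= 0:
            raise SchemaError(f"beta must be > 0, got {self.beta!r}")

    @property
    def needs_sensitive(self) -> bool:
        return self.method != "k_anonymity"


@dataclass(frozen=True)
class AnonymizationResult:
    """Anonymized table plus the transformation and suppression applied."""

    table: DataTable
    transformation: tuple[int, ...]
    suppressed_fraction: float  # percent of original rows deleted
    suppressed_rows: tuple[int, ...]  # original row indices, sorted
    report: PrivacyReport


# ---------------------------------------------------------------------------
# per-equivalence-class criteria


def _ec_violates_sa(
    counter: Counter, q: dict[str, float], req: PrivacyRequirement, numeric_sa: bool
) -> bool:
    """Does one class breach the sensitive-attribute criterion of *req*?"""
    size = sum(counter.values())
    method = req.method
    if method == "alpha_k":
        return max(counter.values()) / size > req.alpha + _EPS
    if method == "l_diversity":
        return len(counter) < req.l
    if method == "entropy_l":
        return _entropy(counter) < math.log(req.l) - 1e-9
    if method == "recursive_cl":
        counts = sorted(counter.values(), reverse=True)
        if len(counts) < req.l:
            return True
        return counts[0] >= req.c * sum(counts[req.l - 1:])
    if method == "t_closeness":
        p = {s: c / size for s, c in counter.items()}
        emd = _emd_ordered if numeric_sa else _emd_categorical
        return emd(p, q) > req.t + _EPS
    if method == "delta_disclosure":
        worst = max(
            abs(math.log((c / size) / q[s])) for s, c in counter.items()
        )
        return worst >= req.delta
    if method in ("beta_basic", "beta_enhanced"):
        for s, c in counter.items():
            p = c / size
            if p > q[s]:
                d = (p - q[s]) / q[s]
                cap = req.beta
                if method == "beta_enhanced":
                    cap = min(cap, -math.log(q[s]))
                if d > cap + _EPS:
                    return True
        return False
    return False  # k_anonymity has no SA criterion


def _violating(
    table: DataTable,
    schema: RoleSchema,
    req: PrivacyRequirement,
    criterion: str,
    numeric_sa: bool,
) -> set[int]:
    """Rows of every class breaching the given criterion ('k', 'sa', 'both')."""
    part = partition_by_qi(table, schema.quasi_identifiers)
    bad: set[int] = set()
    check_sa = criterion in ("sa", "both") and req.needs_sensitive
    if check_sa:
        sa = dict(zip(table.index, table.column(schema.sensitive_attribute)))
        n = table.n_rows
        global_counts = Counter(sa.values())
        q = {s: c / n for s, c in global_counts.items()}
    for ec in part.classes:
        if criterion in ("k", "both") and ec.size < req.k:
            bad.update(ec.rows)
            continue
        if check_sa:
            counter = Counter(sa[i] for i in ec.rows)
            if _ec_violates_sa(counter, q, req, numeric_sa):
                bad.update(ec.rows)
    return bad


def violating_rows(
    table: DataTable,
    schema: RoleSchema,
    requirement: PrivacyRequirement,
    numeric_sa: bool = False,
) -> set[int]:
    """Union of all equivalence classes breaching the requirement.

    A class violates if its size is below k or, for sensitive-attribute
    methods, if it fails the method's per-class criterion against the global
    distribution of the retained rows.
    """
    schema.validate_against(table)
    if requirement.needs_sensitive and not schema.sensitive_attribute:
        raise SchemaError(
            f"method {requirement.method!r} requires a sensitive attribute"
        )
    return _violating(table, schema, requirement, "both", numeric_sa)


def _deletion_fixpoint(
    state: DataTable,
    schema: RoleSchema,
    req: PrivacyRequirement,
    criterion: str,
    numeric_sa: bool,
) -> set[int] | None:
    """Rows to delete so the criterion holds on what remains, or None.

    Deleting violating classes shifts the global sensitive-value
    distribution, which can expose new violations, so deletion is iterated to
    a fixpoint.  Returns None when the fixpoint would empty the table (an
    empty output is never considered a valid anonymization).
    """
    removed: set[int] = set()
    current = state
    while True:
        if current.n_rows == 0:
            return None
        bad = _violating(current, schema, req, criterion, numeric_sa)
        if not bad:
            return removed
        removed |= bad
        current = current.drop_rows(bad)


def choose_next_generalization(
    table: DataTable,
    schema: RoleSchema,
    hierarchies: HierarchySet,
    current: Sequence[int],
) -> int | None:
    """Index of the QI to generalize next, or None when all are maxed out.

    Among quasi-identifiers not yet at their hierarchy's top level, picks the
    one with the most distinct values in the current table state; ties break
    toward the earlier position in schema QI order.
    """
    best_idx, best_count = None, -1
    for i, name in enumerate(schema.quasi_identifiers):
        max_level = hierarchies[name].max_level if name in hierarchies else 0
        if current[i] >= max_level:
            continue
        count = len(set(table.column(name)))
        if count > best_count:
            best_idx, best_count = i, count
    return best_idx


def requirement_satisfied(
    table: DataTable,
    schema: RoleSchema,
    req: PrivacyRequirement,
    numeric_sa: bool = False,
) -> bool:
    """Audit: does *table* satisfy the requirement (k and SA criterion)?"""
    if table.n_rows == 0:
        return False
    return not _violating(table, schema, req, "both", numeric_sa)


def _lattice_nodes(
    schema: RoleSchema, hierarchies: HierarchySet
) -> list[tuple[int, ...]]:
    ranges = [
        range((hierarchies[name].max_level if name in hierarchies else 0) + 1)
        for name in schema.quasi_identifiers
    ]
    nodes = list(itertools.product(*ranges))
    nodes.sort(key=lambda tv: (sum(tv), tv))
    return nodes


def anonymize(
    table: DataTable,
    schema: RoleSchema,
    hierarchies: HierarchySet,
    requirement: PrivacyRequirement,
    numeric_sa: bool = False,
) -> AnonymizationResult:
    """Anonymize *table* until *requirement* holds, within the budget.

    Raises :class:`UnachievableRequirementError` when no transformation plus
    whole-class suppression within the budget can satisfy the requirement,
    reporting the best transformation found and its residual violation.
    """
    schema.validate_against(table)
    if requirement.needs_sensitive and not schema.sensitive_attribute:
        raise SchemaError(
            f"method {requirement.method!r} requires a sensitive attribute"
        )
    unknown = set(hierarchies) - set(schema.quasi_identifiers)
    if unknown:
        raise SchemaError(
            f"hierarchies given for non-quasi-identifier column(s): {sorted(unknown)}"
        )
    if table.n_rows == 0:
        raise EmptyTableError("cannot anonymize an empty table")

    orig_n = table.n_rows
    budget = requirement.supp / 100.0 * orig_n + 1e-9
    work = suppress_identifiers(table, schema)
    tv = [0] * schema.n_qi
    state = work
    suppressed: set[int] = set()
    best_tv, best_residual = tuple(tv), orig_n + 1

    phases = ("k",) if not requirement.needs_sensitive else ("k", "sa")
    exhausted = False
    for phase in phases:
        if exhausted:
            break
        while True:
            fix = _deletion_fixpoint(state, schema, requirement, phase, numeric_sa)
            if fix is not None and len(suppressed) + len(fix) <= budget:
                if fix:
                    logger.info(
                        "phase %s: suppressing %d row(s) at transformation %s",
                        phase, len(fix), tv,
                    )
                    state = state.drop_rows(fix)
                    suppressed |= fix
                else:
                    logger.info("phase %s satisfied at transformation %s", phase, tv)
                break
            residual = len(fix) if fix is not None else state.n_rows
            if residual < best_residual:
                best_tv, best_residual = tuple(tv), residual
            nxt = choose_next_generalization(state, schema, hierarchies, tv)
            if nxt is None:
                exhausted = True
                break
            tv[nxt] += 1
            logger.info(
                "generalizing %r to level %d (transformation %s)",
                schema.quasi_identifiers[nxt], tv[nxt], tv,
            )
            state = apply_levels(
                work.drop_rows(suppressed), hierarchies, tv, schema
            )

    if exhausted:
        # the greedy path is not complete for non-monotone criteria: scan the
        # whole lattice deterministically before giving up
        logger.info("greedy walk exhausted; scanning the full lattice")
        found = None
        for node in _lattice_nodes(schema, hierarchies):
            cand = apply_levels(work, hierarchies, node, schema)
            fix = _deletion_fixpoint(cand, schema, requirement, "both", numeric_sa)
            if fix is not None and len(fix) <= budget:
                found = (node, fix, cand.drop_rows(fix))
                break
            residual = len(fix) if fix is not None else cand.n_rows
            if residual < best_residual:
                best_tv, best_residual = tuple(node), residual
        if found is None:
            raise UnachievableRequirementError(
                f"requirement {requirement.method!r} cannot be satisfied with the "
                f"given hierarchies and a {requirement.supp}% suppression budget "
                f"(best transformation {list(best_tv)} leaves {best_residual} "
                "violating row(s))",
                best_transformation=list(best_tv),
                residual_rows=best_residual,
            )
        node, fix, state = found
        tv = list(node)
        suppressed = set(fix)
        if fix:
            logger.info(
                "lattice scan: suppressing %d row(s) at transformation %s",
                len(fix), tv,
            )

    assert requirement_satisfied(state, schema, requirement, numeric_sa), (
        "internal error: output fails its own audit"
    )
    return AnonymizationResult(
        table=state,
        transformation=tuple(tv),
        suppressed_fraction=100.0 * len(suppressed) / orig_n,
        suppressed_rows=tuple(sorted(suppressed)),
        report=privacy_report(state, schema, numeric_sa=numeric_sa),
    )


# ---------------------------------------------------------------------------
# named entry points, one per privacy model


def _coerce_table(data) -> DataTable:
    if isinstance(data, DataTable):
        return data
    if isinstance(data, pd.DataFrame):
        return DataTable.from_pandas(data)
    raise SchemaError(f"expected DataTable or pandas DataFrame, got {type(data)}")


def _make_schema(table: DataTable, ids, qi, sa) -> RoleSchema:
    assigned = set(ids) | set(qi) | ({sa} if sa else set())
    insensitive = [c for c in table.columns if c not in assigned]
    return RoleSchema(ids, qi, sa, insensitive)


def _run(data, ids, qi, sa, hier, numeric_sa=False, **params) -> AnonymizationResult:
    table = _coerce_table(data)
    schema = _make_schema(table, ids, qi, sa)
    return anonymize(
        table, schema, hier, PrivacyRequirement(**params), numeric_sa=numeric_sa
    )


def k_anonymity(data, ids, qi, k, supp, hier) -> AnonymizationResult:
    """Anonymize until every equivalence class has at least k rows."""
    return _run(data, ids, qi, None, hier, method="k_anonymity", k=k, supp=supp)


def alpha_k_anonymity(data, ids, qi, sa, alpha, k, supp, hier) -> AnonymizationResult:
    """k-anonymity plus: no sensitive value exceeds frequency alpha in a class."""
    return _run(
        data, ids, qi, sa, hier, method="alpha_k", k=k, alpha=alpha, supp=supp
    )


def l_diversity(data, ids, qi, sa, k, l, supp, hier) -> AnonymizationResult:
    """k-anonymity plus: at least l distinct sensitive values per class."""
    return _run(data, ids, qi, sa, hier, method="l_diversity", k=k, l=l, supp=supp)


def entropy_l_diversity(data, ids, qi, sa, k, l, supp, hier) -> AnonymizationResult:
    """k-anonymity plus: every class's sensitive entropy is at least ln l."""
    return _run(data, ids, qi, sa, hier, method="entropy_l", k=k, l=l, supp=supp)


def recursive_c_l_diversity(
    data, ids, qi, sa, k, c, l, supp, hier
) -> AnonymizationResult:
    """k-anonymity plus recursive (c,l)-diversity on the sensitive counts."""
    return _run(
        data, ids, qi, sa, hier, method="recursive_cl", k=k, c=c, l=l, supp=supp
    )


def t_closeness(
    data, ids, qi, sa, k, t, supp, hier, numeric_sa: bool = False
) -> AnonymizationResult:
    """k-anonymity plus: every class's EMD from the global distribution <= t."""
    return _run(
        data, ids, qi, sa, hier,
        numeric_sa=numeric_sa, method="t_closeness", k=k, t=t, supp=supp,
    )


def delta_disclosure(data, ids, qi, sa, k, delta, supp, hier) -> AnonymizationResult:
    """k-anonymity plus: every |ln(p/q)| strictly below delta."""
    return _run(
        data, ids, qi, sa, hier, method="delta_disclosure", k=k, delta=delta, supp=supp
    )


def basic_beta_likeness(data, ids, qi, sa, k, beta, supp, hier) -> AnonymizationResult:
    """k-anonymity plus: relative excess (p-q)/q at most beta."""
    return _run(
        data, ids, qi, sa, hier, method="beta_basic", k=k, beta=beta, supp=supp
    )


def enhanced_beta_likeness(
    data, ids, qi, sa, k, beta, supp, hier
) -> AnonymizationResult:
    """k-anonymity plus: (p-q)/q at most min(beta, -ln q) per sensitive value."""
    return _run(
        data, ids, qi, sa, hier, method="beta_enhanced", k=k, beta=beta, supp=supp
    )
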