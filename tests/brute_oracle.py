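"""Independent brute-force re-computation of every privacy metric.

Deliberately naive: plain dict grouping over row tuples, exhaustive
enumeration of every (equivalence class, sensitive value) pair, and direct
formula evaluation with the math module.  Shares no code path with
sdctab.metrics; used to validate it on random tables.
"""

import itertools
import math


def group_rows(records, columns, qi):
    """Group full row tuples by their QI sub-tuple, first-appearance order."""
    pos = [columns.index(q) for q in qi]
    groups = {}
    for row in records:
        key = tuple(row[p] for p in pos)
        groups.setdefault(key, []).append(row)
    return groups


def sa_histograms(records, columns, qi, sa):
    """(per-class counts, global counts) of sensitive values."""
    s = columns.index(sa)
    groups = group_rows(records, columns, qi)
    per_ec = []
    for rows in groups.values():
        counts = {}
        for row in rows:
            counts[row[s]] = counts.get(row[s], 0) + 1
        per_ec.append(counts)
    global_counts = {}
    for row in records:
        global_counts[row[s]] = global_counts.get(row[s], 0) + 1
    return per_ec, global_counts


def brute_k(records, columns, qi):
    return min(len(rows) for rows in group_rows(records, columns, qi).values())


def brute_alpha(records, columns, qi, sa):
    per_ec, _ = sa_histograms(records, columns, qi, sa)
    return max(max(c.values()) / sum(c.values()) for c in per_ec)


def brute_l(records, columns, qi, sa):
    per_ec, _ = sa_histograms(records, columns, qi, sa)
    return min(len(c) for c in per_ec)


def brute_entropy_l(records, columns, qi, sa):
    per_ec, _ = sa_histograms(records, columns, qi, sa)
    min_h = math.inf
    for counts in per_ec:
        n = sum(counts.values())
        h = -sum(c / n * math.log(c / n) for c in counts.values())
        min_h = min(min_h, h)
    return math.floor(math.exp(min_h) + 1e-9)


def brute_recursive_c(records, columns, qi, sa, l):
    per_ec, _ = sa_histograms(records, columns, qi, sa)
    needed = 1
    for counts in per_ec:
        ordered = sorted(counts.values(), reverse=True)
        if len(ordered) < l:
            return None
        tail = sum(ordered[l - 1:])
        c = 1
        while not ordered[0] < c * tail:
            c += 1
        needed = max(needed, c)
    return needed


def brute_t(records, columns, qi, sa, numeric=False):
    per_ec, global_counts = sa_histograms(records, columns, qi, sa)
    n = sum(global_counts.values())
    worst = 0.0
    for counts in per_ec:
        size = sum(counts.values())
        support = set(counts) | set(global_counts)
        if numeric:
            ordered = sorted(support, key=float)
            m = len(ordered)
            if m == 1:
                continue
            total, cum = 0.0, 0.0
            for s in ordered:
                cum += counts.get(s, 0) / size - global_counts.get(s, 0) / n
                total += abs(cum)
            worst = max(worst, total / (m - 1))
        else:
            worst = max(
                worst,
                0.5 * sum(
                    abs(counts.get(s, 0) / size - global_counts.get(s, 0) / n)
                    for s in support
                ),
            )
    return worst


def brute_delta(records, columns, qi, sa):
    per_ec, global_counts = sa_histograms(records, columns, qi, sa)
    n = sum(global_counts.values())
    worst = 0.0
    for counts in per_ec:
        size = sum(counts.values())
        for s, c in counts.items():
            worst = max(worst, abs(math.log((c / size) / (global_counts[s] / n))))
    return worst


def brute_beta(records, columns, qi, sa):
    per_ec, global_counts = sa_histograms(records, columns, qi, sa)
    n = sum(global_counts.values())
    worst = 0.0
    feasible = True
    for counts in per_ec:
        size = sum(counts.values())
        for s, c in counts.items():
            p, q = c / size, global_counts[s] / n
            if p > q:
                d = (p - q) / q
                worst = max(worst, d)
                if d > -math.log(q) + 1e-12:
                    feasible = False
    return worst, feasible


# ---------------------------------------------------------------------------
# exhaustive feasibility oracle for the anonymization engine


def ec_violates(counts, global_counts, n, req, numeric_sa=False):
    """Naive check of one class against a PrivacyRequirement's SA criterion."""
    size = sum(counts.values())
    m = req.method
    if m == "alpha_k":
        return max(counts.values()) / size > req.alpha + 1e-12
    if m == "l_diversity":
        return len(counts) < req.l
    if m == "entropy_l":
        h = -sum(c / size * math.log(c / size) for c in counts.values())
        return h < math.log(req.l) - 1e-9
    if m == "recursive_cl":
        ordered = sorted(counts.values(), reverse=True)
        if len(ordered) < req.l:
            return True
        return not ordered[0] < req.c * sum(ordered[req.l - 1:])
    if m == "t_closeness":
        support = set(counts) | set(global_counts)
        if numeric_sa:
            ordered = sorted(support, key=float)
            if len(ordered) == 1:
                return 0.0 > req.t + 1e-12
            total, cum = 0.0, 0.0
            for s in ordered:
                cum += counts.get(s, 0) / size - global_counts.get(s, 0) / n
                total += abs(cum)
            return total / (len(ordered) - 1) > req.t + 1e-12
        emd = 0.5 * sum(
            abs(counts.get(s, 0) / size - global_counts.get(s, 0) / n)
            for s in support
        )
        return emd > req.t + 1e-12
    if m == "delta_disclosure":
        worst = max(
            abs(math.log((c / size) / (global_counts[s] / n)))
            for s, c in counts.items()
        )
        return worst >= req.delta
    if m in ("beta_basic", "beta_enhanced"):
        for s, c in counts.items():
            p, q = c / size, global_counts[s] / n
            if p > q:
                cap = req.beta
                if m == "beta_enhanced":
                    cap = min(cap, -math.log(q))
                if (p - q) / q > cap + 1e-12:
                    return True
        return False
    return False


def node_feasible(records, columns, qi, sa, req, numeric_sa=False):
    """Can iterated whole-class deletion within budget fix this lattice node?

    *records* are the rows already generalized to the node's levels.  Returns
    the number of rows deleted, or None when infeasible.
    """
    budget = req.supp / 100.0 * len(records) + 1e-9
    retained = list(records)
    deleted = 0
    while True:
        if not retained:
            return None
        groups = group_rows(retained, columns, qi)
        n = len(retained)
        if sa is not None:
            s_idx = columns.index(sa)
            global_counts = {}
            for row in retained:
                global_counts[row[s_idx]] = global_counts.get(row[s_idx], 0) + 1
        bad = []
        for rows in groups.values():
            violates = len(rows) < req.k
            if not violates and req.method != "k_anonymity":
                counts = {}
                for row in rows:
                    counts[row[s_idx]] = counts.get(row[s_idx], 0) + 1
                violates = ec_violates(counts, global_counts, n, req, numeric_sa)
            if violates:
                bad.extend(rows)
        if not bad:
            return deleted if deleted <= budget else None
        deleted += len(bad)
        if deleted > budget:
            return None
        bad_ids = {id(r) for r in bad}
        retained = [r for r in retained if id(r) not in bad_ids]


def exhaustive_feasible(table, schema, hierarchies, req, numeric_sa=False):
    """Does ANY lattice node satisfy the requirement within budget?"""
    from sdctab.hierarchy import apply_levels
    from sdctab.model import suppress_identifiers

    work = suppress_identifiers(table, schema)
    qi = list(schema.quasi_identifiers)
    ranges = [
        range((hierarchies[q].max_level if q in hierarchies else 0) + 1)
        for q in qi
    ]
    for node in itertools.product(*ranges):
        generalized = apply_levels(work, hierarchies, node, schema)
        records = generalized.records()
        # rows must be distinct objects for node_feasible's identity filter
        records = [tuple(r) + (i,) for i, r in enumerate(records)]
        cols = generalized.columns + ["__rowid__"]
        if node_feasible(
            records, cols, qi, schema.sensitive_attribute, req, numeric_sa
        ) is not None:
            return True
    return False
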