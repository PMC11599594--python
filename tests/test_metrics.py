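"""Privacy auditor: frozen fixture values, oracle agreement, invariants.

The frozen expected values are exact fractions derived by exhaustively
enumerating every (equivalence class, sensitive value) pair of the 13-row
hospital fixtures by hand; the derivations are noted inline.
"""

import math

import pytest

from sdctab import (
    EmptyTableError,
    RoleSchema,
    SchemaError,
    calc_alpha,
    calc_beta,
    calc_delta,
    calc_entropy_l,
    calc_k,
    calc_l,
    calc_recursive_c,
    calc_t,
    partition_by_qi,
    privacy_report,
)
from sdctab.fixtures import ColumnSpec, SyntheticSpec, generate_synthetic
from sdctab.model import DataTable

import brute_oracle as bo

QI = ["age", "gender", "city"]


class TestFixtureValues:
    def test_k(self, hospital, table5, table6, schema):
        assert calc_k(hospital, schema) == 1  # (29,Female,Tamil Nadu) is unique
        assert calc_k(table5, schema) == 2
        assert calc_k(table6, schema) == 3

    def test_alpha(self, table5, table6, schema):
        # table5: the {Gabu,Sabu,Jonas} class is all Cancer -> 1.0
        assert calc_alpha(table5, schema) == 1.0
        # table6: 6-male class holds 3 Cancer out of 6 -> 0.5
        assert calc_alpha(table6, schema) == 0.5

    def test_l(self, table5, table6, schema):
        assert calc_l(table5, schema) == 1  # all-Cancer class
        assert calc_l(table6, schema) == 3  # per-class distinct counts 4,4,3

    def test_l_single_value_table(self):
        t = DataTable.from_records(["q", "s"], [("a", "v"), ("a", "v")])
        sch = RoleSchema([], ["q"], "s")
        assert calc_l(t, sch) == 1

    def test_entropy_l(self, table5, table6, schema):
        assert calc_entropy_l(table5, schema) == 1  # a class with H = 0
        # table6: min entropy = ln 3 at the uniform 3-value class; the 1e-9
        # pre-floor tolerance must keep exp(ln 3) at 3
        assert calc_entropy_l(table6, schema) == 3

    def test_entropy_l_fifty_fifty(self):
        t = DataTable.from_records(["q", "s"], [("a", "x"), ("a", "y")])
        assert calc_entropy_l(t, RoleSchema([], ["q"], "s")) == 2

    def test_recursive_c(self, table5, table6, schema):
        # table6 at l=2: binding class counts [3,1,1,1] need 3 < c*3 -> c=2
        assert calc_recursive_c(table6, schema, l=2) == 2
        # table5 at l=2: a class with a single sensitive value -> infeasible
        assert calc_recursive_c(table5, schema, l=2) is None

    def test_recursive_c_uniform_counts(self):
        t = DataTable.from_records(
            ["q", "s"], [("a", "x"), ("a", "y"), ("a", "z")]
        )
        assert calc_recursive_c(t, RoleSchema([], ["q"], "s"), l=2) == 1

    def test_t(self, table5, table6, schema):
        # table5: all-Cancer class vs global Cancer 5/13 -> EMD 8/13
        assert calc_t(table5, schema) == pytest.approx(8 / 13, abs=1e-12)
        # table6: binding class is the 3-row [10, 20) class -> 11/39
        assert calc_t(table6, schema) == pytest.approx(11 / 39, abs=1e-12)

    def test_t_zero_iff_classes_match_global(self):
        rows = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")]
        t = DataTable.from_records(["q", "s"], rows)
        assert calc_t(t, RoleSchema([], ["q"], "s")) == 0.0

    def test_delta(self, table5, table6, schema):
        # table5: No-illness at 1/3 in its class vs 1/13 globally
        assert calc_delta(table5, schema) == pytest.approx(math.log(13 / 3), abs=1e-12)
        assert calc_delta(table6, schema) == pytest.approx(math.log(13 / 6), abs=1e-12)

    def test_delta_zero_when_classes_match_global(self):
        rows = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")]
        t = DataTable.from_records(["q", "s"], rows)
        assert calc_delta(t, RoleSchema([], ["q"], "s")) == 0.0

    def test_beta_basic(self, table5, table6, schema):
        # table6: No-illness at 1/6 vs 1/13 (= Viral at 1/3 vs 2/13) -> 7/6
        assert calc_beta(table6, schema) == pytest.approx(7 / 6, abs=1e-12)
        # table5: No-illness at 1/3 vs 1/13 -> 10/3
        assert calc_beta(table5, schema) == pytest.approx(10 / 3, abs=1e-12)

    def test_beta_zero_when_no_excess(self):
        rows = [("a", "x"), ("a", "y"), ("b", "x"), ("b", "y")]
        t = DataTable.from_records(["q", "s"], rows)
        assert calc_beta(t, RoleSchema([], ["q"], "s")) == 0.0

    def test_beta_enhanced_feasibility(self, table5, table6, schema):
        res6 = calc_beta(table6, schema, enhanced=True)
        assert res6.beta == pytest.approx(7 / 6, abs=1e-12)
        assert res6.enhanced_feasible  # -ln(1/13) = 2.565 >= 7/6
        res5 = calc_beta(table5, schema, enhanced=True)
        assert not res5.enhanced_feasible  # 10/3 > -ln(1/13)

    def test_report_bundles_everything(self, table6, schema):
        rep = privacy_report(table6, schema)
        assert rep.k == 3 and rep.l == 3 and rep.entropy_l == 3
        assert rep.t == pytest.approx(11 / 39)
        # at the achieved l=3 the [1,1,1] class needs 1 < c*1 -> c=2
        assert rep.recursive_c_for_l == 2
        assert sorted(rep.class_sizes) == [3, 4, 6]

    def test_report_without_sensitive_attribute(self, hospital):
        sch = RoleSchema(["name"], QI, None, ["religion", "disease"])
        rep = privacy_report(hospital, sch)
        assert rep.k == 1 and rep.alpha is None and rep.t is None

    def test_errors(self, hospital, schema):
        empty = hospital.drop_rows(range(13))
        with pytest.raises(EmptyTableError):
            calc_k(empty, schema)
        no_sa = RoleSchema(["name"], QI, None, [])
        with pytest.raises(SchemaError):
            calc_alpha(hospital, no_sa)


class TestNumericEMD:
    def test_ordered_distance_on_sorted_support(self):
        # one class {1:2}, other {3:2}; global {1:.5, 3:.5}; support {1,3}
        rows = [("a", "1"), ("a", "1"), ("b", "3"), ("b", "3")]
        t = DataTable.from_records(["q", "s"], rows)
        sch = RoleSchema([], ["q"], "s")
        # cumulative |p-q| = 0.5 at step 1, /(m-1)=1 -> 0.5
        assert calc_t(t, sch, numeric=True) == pytest.approx(0.5)
        assert calc_t(t, sch, numeric=False) == pytest.approx(0.5)

    def test_numeric_emd_sees_order(self):
        # moving mass to adjacent values is cheap under the ordered distance:
        # class a concentrates on the middle value 2 -> numeric t 2/7 while
        # the categorical t is 4/7
        rows = [("a", "2")] * 3 + [("b", "1"), ("b", "1"), ("b", "3"), ("b", "3")]
        t = DataTable.from_records(["q", "s"], rows)
        sch = RoleSchema([], ["q"], "s")
        assert calc_t(t, sch, numeric=True) == pytest.approx(2 / 7)
        assert calc_t(t, sch, numeric=False) == pytest.approx(4 / 7)

    def test_matches_scipy_transport(self):
        """Ordered EMD agrees with scipy's Wasserstein distance (scaled)."""
        scipy_stats = pytest.importorskip("scipy.stats")
        rows = [("a", "0"), ("a", "0"), ("a", "4"), ("b", "2"),
                ("b", "4"), ("b", "4"), ("b", "8")]
        t = DataTable.from_records(["q", "s"], rows)
        sch = RoleSchema([], ["q"], "s")
        support = sorted({r[1] for r in rows}, key=float)
        spread = len(support) - 1
        per_class = []
        for cls in ("a", "b"):
            vals = [float(s) for q, s in rows if q == cls]
            allv = [float(s) for _, s in rows]
            # ranks in the sorted support = the unit ground distance used here
            rank = {v: i for i, v in enumerate(sorted({float(s) for s in support}))}
            per_class.append(
                scipy_stats.wasserstein_distance(
                    [rank[v] for v in vals], [rank[v] for v in allv]
                ) / spread
            )
        assert calc_t(t, sch, numeric=True) == pytest.approx(max(per_class))


def _random_spec(seed: int) -> SyntheticSpec:
    import numpy as np

    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 51))
    n_qi = int(rng.integers(1, 4))
    cols = {}
    for i in range(n_qi):
        card = int(rng.integers(1, 5))
        cols[f"q{i}"] = ColumnSpec(
            "categorical", values=tuple(f"v{j}" for j in range(card))
        )
    sa_card = int(rng.integers(1, 5))
    w = rng.dirichlet([1.0] * sa_card)
    w = tuple(float(x) / float(sum(w)) for x in w)
    cols["s"] = ColumnSpec(
        "categorical", values=tuple(str(j) for j in range(sa_card)), weights=w
    )
    schema = RoleSchema([], [f"q{i}" for i in range(n_qi)], "s")
    return SyntheticSpec(n_rows=n, columns=cols, schema=schema, seed=seed)


@pytest.mark.parametrize("seed", range(40))
def test_metrics_agree_with_brute_force(seed):
    """Every metric matches a naive exhaustive re-computation to 1e-9."""
    spec = _random_spec(seed)
    table = generate_synthetic(spec)
    sch = spec.schema
    recs, cols, qi = table.records(), table.columns, list(sch.quasi_identifiers)
    assert calc_k(table, sch) == bo.brute_k(recs, cols, qi)
    assert calc_alpha(table, sch) == pytest.approx(
        bo.brute_alpha(recs, cols, qi, "s"), abs=1e-9)
    assert calc_l(table, sch) == bo.brute_l(recs, cols, qi, "s")
    assert calc_entropy_l(table, sch) == bo.brute_entropy_l(recs, cols, qi, "s")
    for l in (1, 2, 3):
        assert calc_recursive_c(table, sch, l) == bo.brute_recursive_c(
            recs, cols, qi, "s", l)
    for numeric in (False, True):
        assert calc_t(table, sch, numeric=numeric) == pytest.approx(
            bo.brute_t(recs, cols, qi, "s", numeric=numeric), abs=1e-9)
    assert calc_delta(table, sch) == pytest.approx(
        bo.brute_delta(recs, cols, qi, "s"), abs=1e-9)
    b, feasible = calc_beta(table, sch, enhanced=True)
    ob, ofeasible = bo.brute_beta(recs, cols, qi, "s")
    assert b == pytest.approx(ob, abs=1e-9)
    assert feasible == ofeasible


@pytest.mark.parametrize("seed", range(12))
def test_metric_invariants(seed):
    """alpha >= 1/l, entropy_l <= l, and k equals the min class size."""
    spec = _random_spec(seed + 1000)
    table = generate_synthetic(spec)
    sch = spec.schema
    l = calc_l(table, sch)
    assert calc_alpha(table, sch) >= 1 / l - 1e-12
    assert calc_entropy_l(table, sch) <= l
    part = partition_by_qi(table, sch.quasi_identifiers)
    assert calc_k(table, sch) == min(part.sizes())
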