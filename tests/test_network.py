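import itertools

import numpy as np
import pandas as pd
import pytest

from cistronet.compendium import ExpressionDataset
from cistronet.features import GeneRecord
from cistronet.network import (CistronExpression, MutualInfoNetwork,
                               NetworkConfig, RegulatoryNetwork,
                               aggregate_cistron_expression, apply_dpi,
                               build_network, estimate_mi, extract_modules,
                               fit_degree_powerlaw, fit_exponential_tail,
                               mi_threshold_from_pvalue,
                               powerlaw_fit_from_degrees,
                               select_regulator_cistrons)
from cistronet.operons import OperonMap
from conftest import make_dataset


def _cistron_matrix(arr, ids):
    values = pd.DataFrame(arr, index=ids,
                          columns=[f"s{j}" for j in range(arr.shape[1])])
    return CistronExpression(values=values, members={c: [c] for c in ids})


class TestAggregate:
    def test_mean_of_member_rows(self):
        omap = OperonMap([["ga", "gb"], ["gc"]])
        expr = make_dataset([[1, -1, 0], [3, 1, 0], [5, 5, 5]],
                            ["ga", "gb", "gc"], ["s1", "s2", "s3"])
        out = aggregate_cistron_expression(omap, expr, {"ga", "gb", "gc"})
        assert np.allclose(out.values.loc["TU00001"], [2, 0, 0])
        assert np.allclose(out.values.loc["TU00002"], [5, 5, 5])

    def test_unselected_members_and_empty_units_dropped(self):
        omap = OperonMap([["ga", "gb"], ["gc"]])
        expr = make_dataset([[1, 1, 1], [3, 3, 3], [5, 5, 5]],
                            ["ga", "gb", "gc"], ["s1", "s2", "s3"])
        out = aggregate_cistron_expression(omap, expr, {"gb"})
        assert out.cistron_ids == ["TU00001"]
        assert np.allclose(out.values.loc["TU00001"], [3, 3, 3])


def test_regulator_cistron_flagging():
    genes = [GeneRecord("ga", "chr", 1, 10, "+", regulator=True),
             GeneRecord("gb", "chr", 20, 30, "+"),
             GeneRecord("gc", "chr", 40, 50, "+")]
    cist = CistronExpression(
        values=pd.DataFrame(np.zeros((2, 3)), index=["c1", "c2"],
                            columns=["s0", "s1", "s2"]),
        members={"c1": ["ga", "gb"], "c2": ["gc"]})
    assert select_regulator_cistrons(cist, genes) == {"c1"}


class TestEstimateMi:
    def test_symmetry(self):
        rng = np.random.default_rng(0)
        x, y = rng.standard_normal(100), rng.standard_normal(100)
        assert abs(estimate_mi(x, y) - estimate_mi(y, x)) < 1e-9

    def test_gaussian_closed_form(self):
        rng = np.random.default_rng(1)
        z = rng.multivariate_normal([0, 0], [[1, 0.9], [0.9, 1]], size=524)
        assert estimate_mi(z[:, 0], z[:, 1]) == pytest.approx(
            -0.5 * np.log(1 - 0.81), abs=0.15)

    def test_permutation_below_null_quantile(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(524)
        mi_perm = estimate_mi(x, x[rng.permutation(524)])
        null = [estimate_mi(rng.standard_normal(524), rng.standard_normal(524))
                for _ in range(40)]
        assert mi_perm < np.quantile(null, 0.95) + 0.02

    def test_invariance_under_monotone_transforms(self):
        rng = np.random.default_rng(3)
        z = rng.multivariate_normal([0, 0], [[1, 0.7], [0.7, 1]], size=200)
        base = estimate_mi(z[:, 0], z[:, 1])
        assert estimate_mi(np.exp(z[:, 0]), z[:, 1]) == pytest.approx(base, abs=0.02)
        assert estimate_mi(z[:, 0], z[:, 1] ** 3) == pytest.approx(base, abs=0.02)

    def test_self_dependency_dominates(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((6, 120))
        self_mi = estimate_mi(X[0], X[0])
        others = [estimate_mi(X[0], X[i]) for i in range(1, 6)]
        assert self_mi > max(others)

    def test_constant_profile_rejected(self):
        with pytest.raises(ValueError):
            estimate_mi(np.ones(50), np.arange(50.0))


class TestMiThreshold:
    def _matrix(self, seed=0, n=8, m=120):
        rng = np.random.default_rng(seed)
        return _cistron_matrix(rng.standard_normal((n, m)), [f"c{i}" for i in range(n)])

    def test_p_one_boundary_and_monotonicity(self):
        mat = self._matrix()
        t1 = mi_threshold_from_pvalue(mat, 1.0, n_perm=500, seed=1)
        t2 = mi_threshold_from_pvalue(mat, 1e-3, n_perm=500, seed=1)
        t3 = mi_threshold_from_pvalue(mat, 1e-6, n_perm=500, seed=1)
        assert t1 <= t2 < t3

    def test_known_exponential_tail_recovery(self):
        rng = np.random.default_rng(6)
        null = rng.exponential(scale=0.02, size=100_000)
        got = fit_exponential_tail(null, 1e-6)
        assert got == pytest.approx(-0.02 * np.log(1e-6), rel=0.20)

    def test_degenerate_null_rejected(self):
        mat = _cistron_matrix(np.ones((3, 40)), ["c0", "c1", "c2"])
        with pytest.raises(ValueError):
            mi_threshold_from_pvalue(mat, 1e-3, n_perm=100)


def _brute_force_dpi(edges, eps):
    nodes = sorted({n for k in edges for n in k})
    doomed = set()
    for i, j, k in itertools.combinations(nodes, 3):
        tri = [frozenset((i, j)), frozenset((i, k)), frozenset((j, k))]
        if not all(t in edges for t in tri):
            continue
        for t in tri:
            others = [edges[o] for o in tri if o != t]
            if edges[t] < (1 - eps) * min(others):
                doomed.add(t)
    return {k: v for k, v in edges.items() if k not in doomed}


class TestDpi:
    def test_triangle_examples(self):
        tri = {frozenset("ab"): 0.5, frozenset("bc"): 0.4, frozenset("ac"): 0.1}
        out = apply_dpi(tri, 0.05)
        assert frozenset("ac") not in out and len(out) == 2

    def test_boundary_equality_is_kept(self):
        tri = {frozenset("ab"): 0.95 * 0.4, frozenset("bc"): 0.4, frozenset("ac"): 0.5}
        assert len(apply_dpi(tri, 0.05)) == 3

    def test_triangle_free_graph_unchanged(self):
        chain = {frozenset("ab"): 0.3, frozenset("bc"): 0.2, frozenset("cd"): 0.1}
        for eps in (0.0, 0.05, 0.5):
            assert apply_dpi(chain, eps) == chain

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(5, 25))
            nodes = [f"n{i}" for i in range(n)]
            edges = {}
            for a, b in itertools.combinations(nodes, 2):
                if rng.random() < 0.25:
                    edges[frozenset((a, b))] = float(rng.random())
            for eps in (0.0, 0.05, 0.2):
                assert apply_dpi(edges, eps) == _brute_force_dpi(edges, eps)

    def test_zero_tolerance_prunes_superset(self):
        rng = np.random.default_rng(14)
        nodes = [f"n{i}" for i in range(15)]
        edges = {frozenset(p): float(rng.random())
                 for p in itertools.combinations(nodes, 2) if rng.random() < 0.4}
        kept0 = set(apply_dpi(edges, 0.0))
        kept5 = set(apply_dpi(edges, 0.05))
        assert kept0 <= kept5


class TestBuildNetwork:
    def test_hub_and_targets_recovered(self):
        rng = np.random.default_rng(8)
        n = 200
        hub = rng.standard_normal(n)
        profiles = [hub]
        for _ in range(5):
            profiles.append(hub + 0.3 * rng.standard_normal(n))
        for _ in range(6):
            profiles.append(rng.standard_normal(n))
        ids = ["hub"] + [f"t{i}" for i in range(5)] + [f"x{i}" for i in range(6)]
        mat = _cistron_matrix(np.array(profiles), ids)
        net = build_network(mat, {"hub"},
                            NetworkConfig(p_threshold=1e-4, n_null_permutations=2000),
                            seed=5)
        hub_edges = {tuple(sorted(k)) for k in net.edges if "hub" in k}
        for i in range(5):
            assert ("hub", f"t{i}") in hub_edges

    def test_independent_profiles_calibration(self):
        rng = np.random.default_rng(9)
        mat = _cistron_matrix(rng.standard_normal((30, 150)),
                              [f"c{i}" for i in range(30)])
        regs = {f"c{i}" for i in range(10)}
        net = build_network(mat, regs,
                            NetworkConfig(p_threshold=0.01, n_null_permutations=4000),
                            seed=10)
        n_pairs = 10 * 29 - (10 * 9) // 2  # regulator-incident unordered pairs
        assert net.n_edges <= 3 * 0.01 * n_pairs + 2

    def test_identical_regulators_keep_their_edge(self):
        rng = np.random.default_rng(10)
        x = rng.standard_normal(120)
        mat = _cistron_matrix(np.array([x, x.copy(), rng.standard_normal(120)]),
                              ["r1", "r2", "c"])
        net = build_network(mat, {"r1", "r2"},
                            NetworkConfig(p_threshold=0.05, n_null_permutations=1000),
                            seed=11)
        assert frozenset(("r1", "r2")) in net.edges

    def test_empty_network_is_not_an_error(self):
        rng = np.random.default_rng(12)
        mat = _cistron_matrix(rng.standard_normal((5, 100)),
                              [f"c{i}" for i in range(5)])
        net = build_network(mat, {"c0"},
                            NetworkConfig(p_threshold=1e-8, n_null_permutations=1000),
                            seed=13)
        assert isinstance(net.n_edges, int)


class TestModulesAndDegreeFit:
    def _net(self):
        edges = {frozenset(("r1", "a")): 1.0, frozenset(("r1", "b")): 0.9,
                 frozenset(("r1", "c")): 0.8, frozenset(("r2", "a")): 0.7}
        return RegulatoryNetwork(nodes=["r1", "r2", "r3", "a", "b", "c"],
                                 regulators={"r1", "r2", "r3"}, edges=edges)

    def test_module_membership(self):
        mods = {m.hub: m for m in extract_modules(self._net())}
        assert mods["r1"].size == 4
        assert set(mods["r1"].members) == {"r1", "a", "b", "c"}
        assert "r3" not in mods  # no surviving edge -> no module
        assert "a" in mods["r1"].members and "a" in mods["r2"].members

    def test_exact_powerlaw_histogram(self):
        degrees = []
        for k in (1, 2, 4, 5, 10, 20):
            degrees += [k] * (400 // (k * k))  # counts exactly proportional to k^-2
        fit = powerlaw_fit_from_degrees(degrees)
        assert fit.exponent == pytest.approx(-2.0, abs=0.01)

    def test_single_support_point_rejected(self):
        with pytest.raises(ValueError):
            powerlaw_fit_from_degrees([3, 3, 3, 3])

    def test_preferential_attachment_regime(self):
        import networkx as nx
        g = nx.barabasi_albert_graph(500, 2, seed=7)
        fit = powerlaw_fit_from_degrees([d for _, d in g.degree()])
        assert -3.5 <= fit.exponent <= -1.5

    def test_network_invariants(self):
        with pytest.raises(ValueError, match="regulator"):
            RegulatoryNetwork(nodes=["a", "b"], regulators=set(),
                              edges={frozenset(("a", "b")): 1.0})
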