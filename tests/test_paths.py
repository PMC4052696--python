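import networkx as nx
import numpy as np
import pytest

from _oracles import all_paths_sorted
from conftest import random_des, random_graph
from pbmoo.bridge import Bridge
from pbmoo.expression import DESTable
from pbmoo.paths import (EDGE_SUM, NoFeasiblePathError, attach_orphan,
                         k_min_cost_paths, min_cost_path, path_cost)
from pbmoo.simulate import gen_expression


def des_of(**values):
    return DESTable(p_values={g: [p] for g, p in values.items()})


class TestPathCost:
    def test_node_sum(self):
        des = des_of(A=0.1, B=0.2, C=0.3)
        assert path_cost(["A", "B", "C"], des) == pytest.approx(0.6)
        assert path_cost(["A", "B", "C"], des, lam=1.0) == pytest.approx(3.6)

    def test_repeated_node_errors(self):
        with pytest.raises(ValueError):
            path_cost(["A", "B", "A"], des_of(A=0.1, B=0.2))

    @pytest.mark.parametrize("seed", range(10))
    def test_edge_sum_identity(self, seed):
        """edge-sum = node-sum + duplicated interior contributions."""
        rng = np.random.default_rng(seed)
        nodes = [f"G{i}" for i in range(rng.integers(2, 8))]
        des = DESTable(p_values={g: [float(rng.uniform())] for g in nodes})
        lam = float(rng.uniform(0, 2))
        interior = sum(des.des(v) for v in nodes[1:-1])
        assert path_cost(nodes, des, lam, form=EDGE_SUM) == pytest.approx(
            path_cost(nodes, des, lam) + interior)


class TestMinCostPath:
    def test_single_edge(self):
        g = nx.Graph([("s", "t")])
        sol = min_cost_path(g, des_of(s=0.1, t=0.2), "s", "t")
        assert sol.nodes == ("s", "t")
        assert sol.cost == pytest.approx(0.3)
        assert sol.length == 2

    def test_lambda_switches_route(self):
        # short route s-m-t (DES sum 0.9) vs long route s-a-b-t (sum 0.4)
        g = nx.Graph([("s", "m"), ("m", "t"), ("s", "a"), ("a", "b"),
                      ("b", "t")])
        des = des_of(s=0.1, t=0.1, m=0.7, a=0.1, b=0.1)
        assert min_cost_path(g, des, "s", "t", lam=0.0).nodes == \
            ("s", "a", "b", "t")
        assert min_cost_path(g, des, "s", "t", lam=1.0).nodes == \
            ("s", "m", "t")

    def test_no_feasible_path_raises(self):
        g = nx.relabel_nodes(nx.path_graph(9), str)  # 9 nodes > L_max
        des = random_des(g, 0)
        with pytest.raises(NoFeasiblePathError):
            min_cost_path(g, des, "0", "8")

    def test_length_bounds_respected(self):
        g = nx.relabel_nodes(nx.path_graph(9), str)
        des = random_des(g, 0)
        sol = min_cost_path(g, des, "0", "6")
        assert sol.length == 7

    def test_indicator_vector(self):
        g = nx.Graph([("s", "t")])
        sol = min_cost_path(g, des_of(s=0.1, t=0.2), "s", "t")
        assert list(sol.indicator(["s", "x", "t"])) == [1, 0, 1]

    @pytest.mark.parametrize("seed", range(25))
    def test_matches_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 13))
        g = random_graph(n, int(rng.integers(n, 3 * n)), seed + 50)
        des = random_des(g, seed + 500)
        nodes = sorted(g.nodes())
        s, t = nodes[0], nodes[-1]
        lam = float(rng.choice([0.0, 0.3, 1.0]))
        oracle = all_paths_sorted(g, des, s, t, lam=lam)
        if not oracle:
            with pytest.raises(NoFeasiblePathError):
                min_cost_path(g, des, s, t, lam=lam)
            return
        sol = min_cost_path(g, des, s, t, lam=lam)
        assert sol.cost == pytest.approx(oracle[0][0], abs=1e-9)
        assert sol.nodes == oracle[0][1]
        assert sol.cost == pytest.approx(
            path_cost(sol.nodes, des, lam), abs=1e-12)


class TestKMinCostPaths:
    def test_k1_equals_min_cost_path(self):
        g = random_graph(8, 14, 2)
        des = random_des(g, 3)
        nodes = sorted(g.nodes())
        try:
            best = min_cost_path(g, des, nodes[0], nodes[-1])
        except NoFeasiblePathError:
            pytest.skip("disconnected draw")
        (only,) = k_min_cost_paths(g, des, nodes[0], nodes[-1], k=1)
        assert only == best

    def test_fewer_paths_than_k(self):
        g = nx.Graph([("s", "a"), ("a", "t"), ("s", "b"), ("b", "t")])
        sols = k_min_cost_paths(g, random_des(g, 1), "s", "t", k=5)
        assert len(sols) == 2  # only s-a-t and s-b-t exist

    @pytest.mark.parametrize("seed", range(25))
    def test_ranked_list_matches_oracle(self, seed):
        rng = np.random.default_rng(seed + 1000)
        n = int(rng.integers(5, 13))
        g = random_graph(n, int(rng.integers(n, 3 * n)), seed + 77)
        des = random_des(g, seed + 99)
        nodes = sorted(g.nodes())
        s, t = nodes[0], nodes[-1]
        oracle = all_paths_sorted(g, des, s, t)
        if not oracle:
            return
        k = min(8, len(oracle))
        sols = k_min_cost_paths(g, des, s, t, k=8)
        assert len(sols) == k
        for sol, (cost, path) in zip(sols, oracle[:k]):
            assert sol.cost == pytest.approx(cost, abs=1e-9)
            assert sol.nodes == path
        costs = [sol.cost for sol in sols]
        assert costs == sorted(costs)


class TestOptimalityProperties:
    @pytest.mark.parametrize("seed", range(8))
    def test_cost_nondecreasing_and_length_nonincreasing_in_lambda(self, seed):
        g = random_graph(10, 22, seed + 7)
        des = random_des(g, seed + 13)
        nodes = sorted(g.nodes())
        s, t = nodes[0], nodes[-1]
        prev_cost, prev_len = -np.inf, np.inf
        try:
            for lam in (0.0, 0.25, 0.5, 1.0, 2.0):
                sol = min_cost_path(g, des, s, t, lam=lam)
                assert sol.cost >= prev_cost - 1e-12
                assert sol.length <= prev_len
                prev_cost, prev_len = sol.cost, sol.length
        except NoFeasiblePathError:
            pytest.skip("disconnected draw")

    @pytest.mark.parametrize("seed", range(6))
    def test_deleting_off_path_node_never_helps(self, seed):
        g = random_graph(9, 20, seed + 31)
        des = random_des(g, seed + 41)
        nodes = sorted(g.nodes())
        s, t = nodes[0], nodes[-1]
        try:
            sol = min_cost_path(g, des, s, t)
        except NoFeasiblePathError:
            pytest.skip("disconnected draw")
        for v in nodes:
            if v in sol.nodes:
                continue
            h = g.copy()
            h.remove_node(v)
            try:
                sol2 = min_cost_path(h, des, s, t)
                assert sol2.cost >= sol.cost - 1e-12
            except NoFeasiblePathError:
                pass


class TestAttachOrphan:
    def _bridge(self):
        g = nx.Graph([("A", "B"), ("B", "C"), ("A", "C")])
        return Bridge(subnetwork=g)

    def test_perfectly_correlated_single_partner(self):
        rng = np.random.default_rng(0)
        base = rng.normal(size=8)
        ds = gen_expression(["A", "B", "C", "ORF"], 4, 4, [], 0.0, 1.0,
                            seed=1)
        ds.values[ds.genes.index("ORF")] = ds.values[ds.genes.index("A")]
        ds.values[ds.genes.index("B")] = base  # decorrelate from ORF
        graph, pseudo = attach_orphan(self._bridge(), "ORF", [ds],
                                      r_threshold=0.99)
        assert [e.partner for e in pseudo] == ["A"]
        assert graph.has_edge("ORF", "A")
        assert graph.edges["ORF", "A"]["pseudo"]

    def test_below_threshold_errors(self):
        ds = gen_expression(["A", "B", "C", "ORF"], 10, 10, [], 0.0, 1.0,
                            seed=3)
        with pytest.raises(ValueError, match="r_threshold"):
            attach_orphan(self._bridge(), "ORF", [ds], r_threshold=0.999)

    def test_orphan_with_real_edges_errors(self):
        ds = gen_expression(["A", "B", "C"], 4, 4, [], 0.0, 1.0, seed=4)
        with pytest.raises(ValueError, match="interactions"):
            attach_orphan(self._bridge(), "A", [ds])

    def test_planted_high_correlation_partners(self):
        """3 genes built as noisy copies of the orphan attach; 17 others
        (independent noise) do not."""
        rng = np.random.default_rng(42)
        genes = [f"G{i:02d}" for i in range(20)] + ["ORF"]
        g = nx.Graph()
        for a, b in zip(genes[:20], genes[1:20]):
            g.add_edge(a, b)
        ds = gen_expression(genes, 10, 10, [], 0.0, 1.0, seed=5)
        orf = ds.values[ds.genes.index("ORF")]
        planted = ["G03", "G07", "G11"]
        for p in planted:
            ds.values[ds.genes.index(p)] = orf + rng.normal(
                0, 0.35, size=orf.size)  # r ~ 0.94
        graph, pseudo = attach_orphan(Bridge(subnetwork=g), "ORF", [ds],
                                      r_threshold=0.75)
        assert sorted(e.partner for e in pseudo) == planted

    def test_max_partners_caps_attachments(self):
        rng = np.random.default_rng(7)
        genes = ["A", "B", "C", "ORF"]
        ds = gen_expression(genes, 10, 10, [], 0.0, 1.0, seed=8)
        orf = ds.values[-1]
        for gname in "ABC":
            ds.values[genes.index(gname)] = orf + rng.normal(
                0, 0.1, size=orf.size)
        _, pseudo = attach_orphan(self._bridge(), "ORF", [ds],
                                  r_threshold=0.5, max_partners=2)
        assert len(pseudo) == 2
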