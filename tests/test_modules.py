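import itertools
import math

import numpy as np
import pytest

from skullnet import (
    AnatomicalNetwork,
    mann_whitney_one_sided,
    newman_girvan_q,
    q_modules,
    s_modules,
)
from skullnet.gtom import network_dendrogram
from skullnet.modules import module_report, significance_tier
from skullnet.synthetic import SkullNetSpec, generate_skull_network

from conftest import complete_net, er_net


def net_from_edges(n, edges, name="g"):
    adj = np.zeros((n, n), dtype=int)
    for i, j in edges:
        adj[i, j] = adj[j, i] = 1
    return AnatomicalNetwork(name, tuple(f"v{i}" for i in range(n)), adj)


def brute_force_q(net, partition):
    """Q from first principles: per-module edge and endpoint fractions."""
    edges = net.edges()
    k = len(edges)
    mods = set(partition.values())
    q = 0.0
    for s in mods:
        inside = sum(1 for u, v in edges if partition[u] == s and partition[v] == s)
        ends = sum((partition[u] == s) + (partition[v] == s) for u, v in edges)
        q += inside / k - (ends / (2 * k)) ** 2
    return q


def set_partitions(items):
    """All partitions of a list (Bell-number enumeration)."""
    if len(items) == 1:
        yield [items]
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [[first] + smaller[i]] + smaller[i + 1:]
        yield [[first]] + smaller


class TestNewmanGirvanQ:
    def test_single_module_is_zero(self, two_cliques):
        part = {v: 0 for v in two_cliques.nodes}
        assert newman_girvan_q(two_cliques, part) == pytest.approx(0.0)

    def test_two_disjoint_triangles(self):
        net = net_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        part = {f"v{i}": (0 if i < 3 else 1) for i in range(6)}
        assert newman_girvan_q(net, part) == pytest.approx(0.5)

    def test_all_singletons_negative_on_connected_graph(self):
        net = complete_net(5)
        part = {v: i for i, v in enumerate(net.nodes)}
        assert newman_girvan_q(net, part) < 0

    def test_matches_brute_force_on_all_small_partitions(self):
        """Against an independent edge-counting Q on every partition, n<=6."""
        for seed in range(3):
            net = er_net(6, 0.4, seed=seed)
            if net.n_edges == 0:
                continue
            for blocks in set_partitions(list(net.nodes)):
                part = {v: i for i, block in enumerate(blocks) for v in block}
                assert newman_girvan_q(net, part) == pytest.approx(
                    brute_force_q(net, part), abs=1e-12
                )

    def test_invariant_under_module_relabeling(self, two_cliques):
        part = {v: (0 if v.startswith("a") else 1) for v in two_cliques.nodes}
        swapped = {v: 1 - m for v, m in part.items()}
        assert newman_girvan_q(two_cliques, part) == pytest.approx(
            newman_girvan_q(two_cliques, swapped)
        )

    def test_empty_network_rejected(self):
        net = net_from_edges(3, [])
        with pytest.raises(ValueError):
            newman_girvan_q(net, {v: 0 for v in net.nodes})


class TestQModules:
    def test_two_cliques_cut_recovers_cliques(self, two_cliques):
        dend = network_dendrogram(two_cliques)
        res = q_modules(two_cliques, dend)
        groups = {}
        for v, m in res.partition.items():
            groups.setdefault(m, set()).add(v)
        assert {frozenset(g) for g in groups.values()} == {
            frozenset(v for v in two_cliques.nodes if v.startswith("a")),
            frozenset(v for v in two_cliques.nodes if v.startswith("b")),
        }
        # and the profile's maximum is the returned Q
        assert res.q_value == pytest.approx(max(q for _, q in res.q_profile))

    def test_complete_graph_single_module(self):
        net = complete_net(5)
        res = q_modules(net, network_dendrogram(net))
        assert len(set(res.partition.values())) == 1
        assert res.q_value == pytest.approx(0.0)

    def test_best_cut_beats_every_other_cut(self):
        for seed in range(4):
            net = er_net(12, 0.3, seed=seed)
            dend = network_dendrogram(net)
            res = q_modules(net, dend)
            for k, q in res.q_profile:
                assert res.q_value >= q - 1e-12

    def test_ties_broken_toward_fewer_clusters(self):
        # an edgeless-modularity tie: complete graph has Q=0 at every level
        # that keeps modules balanced; k=1 must win
        net = complete_net(4)
        res = q_modules(net, network_dendrogram(net))
        assert len(set(res.partition.values())) == 1

    def test_planted_modules_recovered(self):
        from sklearn.metrics import adjusted_rand_score

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            net, _, planted = generate_skull_network(
                SkullNetSpec(p_in=0.8, p_out=0.05, seed=seed)
            )
            res = q_modules(net, network_dendrogram(net))
            nodes = [v for v in net.nodes if planted[v] >= 0]
            ari = adjusted_rand_score(
                [planted[v] for v in nodes], [res.partition[v] for v in nodes]
            )
            hits += ari >= 0.9
        assert hits >= 0.8 * n_seeds


class TestMannWhitney:
    def test_fully_separated_small_sample(self):
        u, p = mann_whitney_one_sided([5, 6, 7], [1, 1, 2])
        assert u == 9.0
        assert p == pytest.approx(0.05)  # 1 / C(6,3)

    def test_identical_samples_not_significant(self):
        _, p = mann_whitney_one_sided([3, 3, 3], [3, 3, 3])
        assert p >= 0.4

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_one_sided([], [1, 2])

    @pytest.mark.parametrize("tied", [False, True], ids=["tie-free", "tied"])
    @pytest.mark.parametrize("n1,n2", [(2, 2), (3, 2), (3, 3), (4, 3), (4, 4)])
    def test_exact_p_matches_enumeration(self, n1, n2, tied):
        """Exact one-sided p equals brute-force enumeration of rank splits."""
        rng = np.random.default_rng(n1 * 10 + n2 + 100 * tied)
        for _ in range(5):
            if tied:
                x = rng.integers(1, 4, size=n1 + n2)  # heavy ties
            else:
                x = rng.permutation(np.arange(1, n1 + n2 + 1))  # tie-free ranks
            internal, external = x[:n1], x[n1:]
            u_obs, p = mann_whitney_one_sided(internal, external)
            pooled = np.concatenate([internal, external])
            count = 0
            total = 0
            for combo in itertools.combinations(range(n1 + n2), n1):
                xs = pooled[list(combo)]
                ys = pooled[[i for i in range(n1 + n2) if i not in combo]]
                u = sum(
                    (xi > yj) + 0.5 * (xi == yj) for xi in xs for yj in ys
                )
                count += u >= u_obs
                total += 1
            assert total == math.comb(n1 + n2, n1)
            assert p == pytest.approx(count / total, abs=1e-12)


class TestSModules:
    def test_root_cluster_flagged_degenerate(self, two_cliques):
        dend = network_dendrogram(two_cliques)
        res = s_modules(two_cliques, dend)
        roots = [r for r in res if r.cluster == frozenset(two_cliques.nodes)]
        assert len(roots) == 1 and roots[0].degenerate
        assert all(c == 0 for c in roots[0].external_counts)

    def test_embedded_clique_is_detected(self):
        # an 8-clique inside a 20-node sparse background
        rng = np.random.default_rng(0)
        n = 20
        adj = np.triu((rng.random((n, n)) < 0.08).astype(int), 1)
        adj = adj + adj.T
        adj[:8, :8] = 1 - np.eye(8, dtype=int)
        net = AnatomicalNetwork("embed", tuple(f"v{i}" for i in range(n)), adj)
        res = s_modules(net, network_dendrogram(net))
        clique = set(f"v{i}" for i in range(8))

        def jaccard(a, b):
            return len(a & b) / len(a | b)

        best = max(
            (r for r in res if not r.degenerate),
            key=lambda r: jaccard(set(r.cluster), clique),
        )
        assert jaccard(set(best.cluster), clique) >= 0.75
        assert best.p_value < 0.001

    def test_planted_two_module_network_significance(self):
        hits = 0
        n_seeds = 25
        for seed in range(n_seeds):
            net, _, planted = generate_skull_network(
                SkullNetSpec(n_modules=2, p_in=0.8, p_out=0.05, seed=seed)
            )
            res = s_modules(net, network_dendrogram(net))
            modules = {
                frozenset(v for v in net.nodes if planted[v] == m)
                for m in (0, 1)
            }
            found = {
                r.cluster for r in res if not r.degenerate and r.p_value < 0.05
            }
            hits += modules <= found
        assert hits >= 0.9 * n_seeds

    def test_tiers_consistent_with_p(self):
        assert significance_tier(0.0005) == "p<0.001"
        assert significance_tier(0.005) == "0.001<=p<0.01"
        assert significance_tier(0.02) == "0.01<=p<0.05"
        assert significance_tier(0.2) == "ns"

    def test_module_report_is_json_ready(self, two_cliques):
        report = module_report(two_cliques, network_dendrogram(two_cliques))
        assert report["specimen"] == "two_cliques"
        assert len(report["modules"]) == 2
        assert all({"members", "p", "tier"} <= set(s) for s in report["s_modules"])


def test_null_calibration_is_super_uniform():
    """For clusters chosen independently of the edges in Erdos-Renyi networks,
    the one-sided internal>external test is conservative."""
    rng = np.random.default_rng(42)
    ps = []
    for _ in range(250):
        n = 20
        upper = np.triu((rng.random((n, n)) < 0.3).astype(int), 1)
        adj = upper + upper.T
        size = int(rng.integers(3, n // 2 + 1))
        idx = rng.choice(n, size=size, replace=False)
        internal = adj[np.ix_(idx, idx)].sum(axis=1)
        external = adj[idx, :].sum(axis=1) - internal
        if internal.sum() + external.sum() == 0:
            continue
        _, p = mann_whitney_one_sided(internal, external)
        ps.append(p)
    ps = np.asarray(ps)
    for alpha in (0.01, 0.05, 0.1, 0.25):
        assert (ps <= alpha).mean() <= alpha + 0.02
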