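"""Network enrichment: link counting, degree-preserving null, z-scores."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from amlstack import (
    DrugResponseTable,
    DrugTargetMap,
    GeneSetCollection,
    count_cross_links,
    generate_planted_nea_instance,
    nea_zscore,
    null_moments,
    subtype_drug_table,
)
from amlstack.io import network_from_edges
from amlstack.nea import _rewire, null_count_matrix


def exhaustive_null(network, A, F):
    """Oracle: enumerate every simple graph on the same nodes with the
    identical degree sequence and count A-F cross links."""
    nodes = sorted(network.graph.nodes)
    deg = dict(network.graph.degree())
    m = network.graph.number_of_edges()
    vals = []
    for combo in itertools.combinations(itertools.combinations(nodes, 2), m):
        g = nx.Graph()
        g.add_nodes_from(nodes)
        g.add_edges_from(combo)
        if g.number_of_edges() == m and dict(g.degree()) == deg:
            d = sum(
                1
                for u, v in combo
                if (u in A and v in F) or (u in F and v in A)
            )
            vals.append(d)
    return np.array(vals)


class TestCrossLinks:
    @pytest.mark.parametrize(
        "edges,A,F,expected",
        [
            ([("a", "b"), ("b", "c")], {"a"}, {"b", "c"}, 1),
            ([("a", "b"), ("b", "c")], {"x"}, {"y"}, 0),
            ([("a", "b")], {"a", "b"}, {"a", "b"}, 1),  # overlap edge counts once
            ([("a", "b"), ("c", "d")], {"a", "c"}, {"b", "d"}, 2),
        ],
    )
    def test_hand_counts(self, edges, A, F, expected):
        assert count_cross_links(A, F, network_from_edges(edges)) == expected

    def test_empty_set_rejected(self, path_network):
        with pytest.raises(ValueError):
            count_cross_links(set(), {"a"}, path_network)

    def test_matches_brute_force_double_loop(self, rng):
        nodes = [f"n{i}" for i in range(15)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(15)
            for j in range(i + 1, 15)
            if rng.random() < 0.3
        ]
        net = network_from_edges(edges)
        for _ in range(10):
            A = set(rng.choice(nodes, size=4, replace=False))
            F = set(rng.choice(nodes, size=5, replace=False))
            brute = 0
            for u, v in net.edges:
                if (u in A and v in F) or (u in F and v in A):
                    brute += 1
            assert count_cross_links(A, F, net) == brute


class TestRandomization:
    def test_degree_sequence_preserved_every_time(self, rng):
        nodes = [f"n{i}" for i in range(20)]
        edges = [
            (nodes[i], nodes[j])
            for i in range(20)
            for j in range(i + 1, 20)
            if rng.random() < 0.2
        ]
        net = network_from_edges(edges)
        idx = {n: i for i, n in enumerate(net.graph.nodes)}
        arr = np.array([(idx[u], idx[v]) for u, v in net.graph.edges])
        deg0 = np.bincount(arr.ravel(), minlength=len(idx))
        for _ in range(25):
            rew = _rewire(arr, rng)
            assert np.array_equal(np.bincount(rew.ravel(), minlength=len(idx)), deg0)
            # still simple: no loops, no duplicates
            assert (rew[:, 0] != rew[:, 1]).all()
            canon = {tuple(sorted(e)) for e in rew.tolist()}
            assert len(canon) == len(rew)

    def test_null_moments_match_exhaustive_enumeration(self):
        net = network_from_edges(
            [("a", "b"), ("a", "c"), ("b", "c"), ("c", "d"), ("d", "e"), ("e", "f"), ("b", "f")]
        )
        A, F = {"a", "b"}, {"d", "e"}
        exact = exhaustive_null(net, A, F)
        # the enumeration is the exact null distribution, so its
        # population (ddof=0) moments are the reference
        mc_mean, mc_sd = null_moments(A, F, net, n_perm=1000, seed=3)
        tol = 3 * exact.std() / np.sqrt(1000)
        assert abs(mc_mean - exact.mean()) < tol
        assert abs(mc_sd - exact.std()) < 0.1

    def test_too_small_network_rejected(self):
        net = network_from_edges([("a", "b")])
        with pytest.raises(Exception):
            null_moments({"a"}, {"b"}, net, n_perm=100)

    def test_nperm_minimum(self, path_network):
        with pytest.raises(ValueError):
            null_moments({"a"}, {"b"}, path_network, n_perm=10)


class TestZScore:
    def test_rigid_complete_graph_degenerate(self):
        k4 = network_from_edges(
            [(a, b) for a, b in itertools.combinations("abcd", 2)]
        )
        res = nea_zscore({"a"}, {"b", "c"}, k4, n_perm=200, seed=0)
        assert res.degenerate and np.isnan(res.z)

    def test_planted_block_significant(self):
        net, A, F, _ = generate_planted_nea_instance(
            n_nodes=60, background_p=0.08, block_excess=20, seed=2
        )
        res = nea_zscore(A, F, net, n_perm=500, seed=1)
        assert res.z > 1.96 and res.significant

    def test_null_z_centered(self):
        net, A, F, _ = generate_planted_nea_instance(
            n_nodes=50, background_p=0.1, block_excess=0, seed=4, set_size=5
        )
        nodes = list(net.graph.nodes)
        rng = np.random.default_rng(9)
        pairs = []
        for _ in range(50):
            pick = rng.permutation(len(nodes))
            pairs.append(
                ({nodes[i] for i in pick[:5]}, {nodes[i] for i in pick[5:10]})
            )
        null = null_count_matrix(net, pairs, n_perm=300, seed=5)
        zs = []
        for i, (A2, F2) in enumerate(pairs):
            sd = null[i].std(ddof=1)
            if sd > 0:
                zs.append((count_cross_links(A2, F2, net) - null[i].mean()) / sd)
        assert abs(np.mean(zs)) < 0.3

    def test_relabeling_invariance(self):
        edges = [("a", "b"), ("b", "c"), ("c", "d"), ("d", "a"), ("a", "c")]
        mapping = {"a": "w", "b": "x", "c": "y", "d": "z"}
        net1 = network_from_edges(edges)
        net2 = network_from_edges([(mapping[u], mapping[v]) for u, v in edges])
        r1 = nea_zscore({"a"}, {"c", "d"}, net1, n_perm=300, seed=7)
        r2 = nea_zscore({"w"}, {"y", "z"}, net2, n_perm=300, seed=7)
        assert r1.d_AF == r2.d_AF
        assert r1.z == pytest.approx(r2.z, nan_ok=True)

    def test_z_zero_when_centered(self):
        # d_AF == null mean => z == 0 exactly by construction of the formula
        net, A, F, _ = generate_planted_nea_instance(
            n_nodes=40, background_p=0.15, block_excess=0, seed=6
        )
        res = nea_zscore(A, F, net, n_perm=300, seed=8)
        reconstructed = (res.d_AF - res.d_bar_AF) / res.sigma_AF
        assert res.z == pytest.approx(reconstructed)


class TestSubtypeDrugTable:
    def _inputs(self):
        net, A, F, _ = generate_planted_nea_instance(
            n_nodes=50, background_p=0.08, block_excess=18, seed=3, set_size=6
        )
        sets = GeneSetCollection({"ST1": sorted(A), "ST2": sorted(set(net.nodes) - A - F)[:6]})
        targets = DrugTargetMap({"dX": sorted(F), "dNoTarget": []})
        labels = pd.Series(
            {"p1": "ST1", "p2": "ST1", "p3": "ST2", "p4": "ST2", "p5": "ST3"}
        )
        rows = [
            ("p1", "dX", "AUC", 90.0),
            ("p2", "dX", "AUC", 100.0),
            ("p3", "dX", "AUC", 180.0),
            ("p4", "dX", "AUC", 190.0),
        ]
        responses = DrugResponseTable(
            pd.DataFrame(rows, columns=["sample", "drug", "metric", "value"])
        )
        return sets, targets, net, responses, labels

    def test_planted_association_found(self, caplog):
        sets, targets, net, responses, labels = self._inputs()
        table, rho = subtype_drug_table(
            sets, targets, net, responses, labels, n_perm=400, seed=1
        )
        row = table[(table["subtype"] == "ST1") & (table["drug"] == "dX")].iloc[0]
        assert row["z"] > 1.96 and row["significant"]
        assert row["median_response"] == 95.0
        # ST3 has no labelled patients in the gene sets -> excluded quietly
        assert set(table["subtype"]) == {"ST1", "ST2"}

    def test_zero_target_drug_flagged(self):
        sets, targets, net, responses, labels = self._inputs()
        table, _ = subtype_drug_table(
            sets, targets, net, responses, labels, n_perm=400, seed=1
        )
        row = table[table["drug"] == "dNoTarget"].iloc[0]
        assert np.isnan(row["z"]) and row["degenerate"] and not row["significant"]
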