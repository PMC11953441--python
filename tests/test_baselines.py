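"""The eight comparison indices against hand expansions and peeling/path oracles."""

import itertools
import math

import networkx as nx
import pytest

from conftest import random_weighted_graph
from rwinf.baselines import (
    h_index,
    hic_scores,
    kshell_decomposition,
    ksd_w_scores,
    ngsc_scores,
    node_features,
    weighted_betweenness,
    weighted_closeness,
    weighted_degree,
    weighted_kshell,
    wks_scores,
    compute_index,
)
from rwinf.influence import neighborhood_weighted_influence


def brute_kshell(G):
    """Naive peeling: repeatedly strip nodes at the running minimum degree."""
    H = G.copy()
    ks = {}
    k = 0
    while H.number_of_nodes():
        k = max(k, min(d for _, d in H.degree()))
        doomed = [v for v, d in H.degree() if d <= k]
        for v in doomed:
            ks[v] = k
        H.remove_nodes_from(doomed)
    return ks


def brute_h_index(G, v):
    degs = [G.degree(u) for u in G[v]]
    best = 0
    for h in range(0, G.degree(v) + 1):
        if sum(d >= h for d in degs) >= h:
            best = h
    return best


def all_shortest_paths_unit_oracle(G, lengths):
    """Exhaustive path enumeration for betweenness on tiny graphs."""
    nodes = list(G.nodes)
    bet = {v: 0.0 for v in nodes}
    for s, t in itertools.combinations(nodes, 2):
        paths = []
        best = math.inf
        for perm_len in range(0, len(nodes) - 1):
            for mids in itertools.permutations([n for n in nodes if n not in (s, t)], perm_len):
                seq = (s,) + mids + (t,)
                if all(G.has_edge(a, b) for a, b in zip(seq, seq[1:])):
                    cost = sum(lengths[tuple(sorted((a, b)))] for a, b in zip(seq, seq[1:]))
                    if cost < best - 1e-12:
                        best, paths = cost, [seq]
                    elif abs(cost - best) <= 1e-12:
                        paths.append(seq)
        if not paths:
            continue
        for p in paths:
            for mid in p[1:-1]:
                bet[mid] += 1.0 / len(paths)
    return bet


class TestKshell:
    def test_path_is_all_shell_one(self, path_graph):
        shells = kshell_decomposition(path_graph)
        assert all(ks == 1 for ks, _, _ in shells.values())

    def test_k4_is_shell_three_single_round(self):
        shells = kshell_decomposition(nx.complete_graph(4))
        assert all(v == (3, 1, 1) for v in shells.values())

    def test_star_center_removed_last(self):
        G = nx.star_graph(4)
        shells = kshell_decomposition(G)
        assert shells[0] == (1, 2, 2)  # center survives one round longer
        assert all(shells[leaf] == (1, 1, 2) for leaf in range(1, 5))

    def test_matches_peeling_oracle_and_core_number(self, rng):
        for _ in range(25):
            G = random_weighted_graph(rng)
            shells = {v: ks for v, (ks, _, _) in kshell_decomposition(G).items()}
            assert shells == brute_kshell(G)
            assert shells == nx.core_number(G)


class TestWeightedKshell:
    def test_unit_weights_reduce_to_kshell(self, rng):
        for _ in range(10):
            G = random_weighted_graph(rng)
            for u, v in G.edges:
                G[u][v]["weight"] = 1.0
            scores = weighted_kshell(G)
            assert scores.scores == {
                v: float(ks) for v, ks in nx.core_number(G).items()
            }

    def test_kprime_closed_form_enters_peeling(self):
        # star center: k=4, strength=9 -> k' = sqrt(36) = 6; leaves k'<=~1.7 -> 2
        G = nx.Graph()
        for leaf, w in zip("wxyz", (2.0, 3.0, 1.0, 3.0)):
            G.add_edge("c", leaf, weight=w)
        scores = weighted_kshell(G, alpha1=1.0, beta1=1.0)
        # every leaf has rounded k' <= 2, removed first at shell = min k'
        assert scores["c"] >= max(scores[leaf] for leaf in "wxyz")

    def test_matches_rounded_peeling_oracle(self, rng):
        def oracle(G):
            H = G.copy()
            out = {}
            shell = 0
            while H.number_of_nodes():
                kp = {
                    v: round((H.degree(v) ** 1.0
                              * sum(d["weight"] for _, _, d in H.edges(v, data=True)) ** 1.0)
                             ** 0.5)
                    for v in H.nodes
                }
                shell = max(shell, min(kp.values()))
                doomed = [v for v, val in kp.items() if val <= shell]
                for v in doomed:
                    out[v] = float(shell)
                H.remove_nodes_from(doomed)
            return out

        for _ in range(15):
            G = random_weighted_graph(rng)
            assert weighted_kshell(G).scores == oracle(G)


class TestStructuralIndices:
    def test_wks_hand_expansion_on_path(self, path_graph):
        scores = wks_scores(path_graph)
        assert scores["B"] == pytest.approx(4.0)
        assert scores["A"] == pytest.approx(2.0)

    def test_ksdw_hand_expansion_on_path(self, path_graph):
        scores = ksd_w_scores(path_graph)
        assert scores["B"] == pytest.approx(3.0)
        assert scores["A"] == pytest.approx(1.5)

    def test_ngsc_hand_expansion_on_triangle(self, triangle_graph):
        scores = ngsc_scores(triangle_graph)
        assert all(scores[v] == pytest.approx(8.0) for v in "ABC")

    def test_isolated_node_scores_zero_everywhere(self):
        G = nx.Graph()
        G.add_edge("a", "b", weight=2.0)
        G.add_node("iso")
        for fn in (wks_scores, ksd_w_scores, ngsc_scores, hic_scores):
            assert fn(G)["iso"] == 0.0

    def test_structural_indices_match_neighbor_loop_oracles(self, rng):
        for _ in range(20):
            G = random_weighted_graph(rng)
            deg = dict(G.degree())
            ks = brute_kshell(G)
            wks = wks_scores(G)
            ksdw = ksd_w_scores(G)
            ngsc = ngsc_scores(G)
            for v in G.nodes:
                assert wks[v] == pytest.approx(
                    0.5 * deg[v] + 0.5 * sum(deg[v] + deg[u] for u in G[v]))
                mix = lambda x: 0.5 * deg[x] + 0.5 * ks[x]
                assert ksdw[v] == pytest.approx(sum(mix(v) * mix(u) for u in G[v]))
                nmix = lambda x: 0.5 * ks[x] + 0.5 * deg[x]
                assert ngsc[v] == pytest.approx(sum(nmix(v) + nmix(u) for u in G[v]))

    def test_weight_rescaling_leaves_structural_indices_unchanged(self, rng):
        G = random_weighted_graph(rng, n_max=10)
        H = G.copy()
        for u, v in H.edges:
            H[u][v]["weight"] *= 321.5
        for fn in (wks_scores, ksd_w_scores, ngsc_scores, hic_scores):
            assert fn(G).scores == fn(H).scores


class TestHIndexAndHic:
    def test_triangle_and_star_h_index(self, triangle_graph, star_graph):
        assert h_index(triangle_graph, "A") == 2
        assert h_index(star_graph, "c") == 1

    def test_h_index_matches_scan_oracle(self, rng):
        for _ in range(25):
            G = random_weighted_graph(rng)
            for v in G.nodes:
                assert h_index(G, v) == brute_h_index(G, v)

    def test_feature_invariants(self, rng):
        for _ in range(15):
            G = random_weighted_graph(rng)
            for v, f in node_features(G).items():
                assert f.ks <= f.k and f.H <= f.k and 0.0 <= f.C <= 1.0

    def test_hic_triangle_hand_computation(self, triangle_graph):
        # H=2, C=1, one pruning round: I = 2*(1+1/1) = 4
        # per-edge weight = 2*4/2 + 2*4/2 = 8; two edges per node -> 16
        scores = hic_scores(triangle_graph)
        assert all(scores[v] == pytest.approx(16.0) for v in "ABC")

    def test_hic_matches_loop_oracle(self, rng):
        for _ in range(15):
            G = random_weighted_graph(rng)
            feats = node_features(G)
            term = {v: feats[v].H * feats[v].I / (1 + feats[v].C) for v in G.nodes}
            scores = hic_scores(G)
            for v in G.nodes:
                assert scores[v] == pytest.approx(sum(term[v] + term[u] for u in G[v]))


class TestWeightedCentralities:
    def test_weighted_degree_on_star(self, star_graph):
        scores = weighted_degree(star_graph)
        assert scores["c"] == 14.0
        assert scores["w"] == 2.0

    def test_weighted_degree_equals_nwi(self, rng):
        G = random_weighted_graph(rng, n_max=20)
        assert weighted_degree(G).scores == neighborhood_weighted_influence(G).scores

    def test_betweenness_path_and_clique(self, path_graph):
        scores = weighted_betweenness(path_graph)
        assert scores["B"] == 1.0 and scores["A"] == scores["C"] == 0.0
        K = nx.complete_graph(5)
        for u, v in K.edges:
            K[u][v]["weight"] = 3.0
        assert all(s == 0.0 for s in weighted_betweenness(K).scores.values())

    def test_betweenness_matches_exhaustive_path_oracle(self, rng):
        for _ in range(8):
            G = random_weighted_graph(rng, n_max=6)
            lengths = {tuple(sorted((u, v))): 1.0 / d["weight"]
                       for u, v, d in G.edges(data=True)}
            oracle = all_shortest_paths_unit_oracle(G, lengths)
            scores = weighted_betweenness(G)
            for v in G.nodes:
                assert scores[v] == pytest.approx(oracle[v], abs=1e-9)

    def test_closeness_closed_forms(self, path_graph, triangle_graph):
        for u, v in triangle_graph.edges:
            triangle_graph[u][v]["weight"] = 2.0
        assert all(
            s == pytest.approx(1.0)
            for s in weighted_closeness(triangle_graph).scores.values()
        )
        assert weighted_closeness(path_graph)["B"] == pytest.approx(0.5)

    def test_closeness_matches_dijkstra_oracle(self, rng):
        for _ in range(10):
            G = random_weighted_graph(rng)
            scores = weighted_closeness(G)
            for v in G.nodes:
                H = nx.Graph()
                H.add_nodes_from(G)
                for a, b, d in G.edges(data=True):
                    H.add_edge(a, b, length=1.0 / d["weight"])
                dist = nx.single_source_dijkstra_path_length(H, v, weight="length")
                total = sum(d for u, d in dist.items() if u != v)
                expected = 1.0 / total if total > 0 else 0.0
                assert scores[v] == pytest.approx(expected, rel=1e-12)

    def test_unit_weight_reduction_to_unweighted(self, rng):
        G = random_weighted_graph(rng, n_max=10)
        for u, v in G.edges:
            G[u][v]["weight"] = 1.0
        bet = weighted_betweenness(G)
        ref = nx.betweenness_centrality(G, normalized=False)
        for v in G.nodes:
            assert bet[v] == pytest.approx(ref[v], abs=1e-9)


class TestDispatch:
    def test_every_named_index_runs_and_covers_all_nodes(self, rng):
        G = random_weighted_graph(rng, n_max=10)
        for name in ("wkshell", "wks", "ksdw", "ngsc", "hic",
                     "wdeg", "wbet", "wclo", "rwinf"):
            table = compute_index(G, name)
            assert set(table.scores) == set(G.nodes)

    def test_unknown_index_rejected(self, path_graph):
        with pytest.raises(ValueError, match="unknown index"):
            compute_index(path_graph, "pagerank")
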