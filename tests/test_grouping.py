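from __future__ import annotations

import random

import networkx as nx
import pytest

from dmcompare import (
    CanonicalId,
    ComparisonConfig,
    SimConfig,
    build_reaction_graph,
    disease_specific_clusters,
    element_group_frequency,
    find_similarity_groups,
    generate_map_pair,
    group_coverage,
    match_interactions,
    pair_components,
    strongly_connected_components,
)
from dmcompare.grouping import SCC
from dmcompare.matching import InteractionMatch

from conftest import chain_interactions, make_map, protein
from oracles import scc_oracle


def linear_map(map_id: str, n: int, cyclic=False):
    elements = [protein(f"e{j}", f"{map_id}G{j}") for j in range(n)]
    return make_map(
        map_id, elements, chain_interactions(map_id, [e.element_id for e in elements],
                                             cyclic=cyclic)
    )


class TestReactionGraph:
    def test_chain_gives_two_edges_three_singleton_sccs(self):
        m = linear_map("A", 4)  # 3 interactions in a chain
        g = build_reaction_graph(m)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 2
        sccs = strongly_connected_components(g)
        assert len(sccs) == 3
        assert all(len(s.members) == 1 for s in sccs)

    def test_cycle_gives_single_scc(self):
        m = linear_map("A", 3, cyclic=True)
        g = build_reaction_graph(m)
        (scc,) = strongly_connected_components(g)
        assert len(scc.members) == 3

    def test_edges_connect_across_diagrams_via_canonical_id(self):
        # same symbol as element of two diagrams: target in d1, source in d2
        elements = [
            protein("e1", "G1", "d1"), protein("e2", "G2", "d1"),
            protein("e3", "G2", "d2"), protein("e4", "G3", "d2"),
        ]
        from dmcompare import Interaction
        interactions = [
            Interaction("i1", "d1", sources=("e1",), targets=("e2",)),
            Interaction("i2", "d2", sources=("e3",), targets=("e4",)),
        ]
        g = build_reaction_graph(make_map("A", elements, interactions))
        assert g.has_edge("i1", "i2")

    def test_restrict_to_limits_nodes(self):
        m = linear_map("A", 5)
        g = build_reaction_graph(m, ["A.i0", "A.i1"])
        assert set(g.nodes) == {"A.i0", "A.i1"}


class TestSCC:
    def test_empty_graph(self):
        g = nx.DiGraph(map_id="X")
        assert strongly_connected_components(g) == []

    def test_complete_digraph_single_scc(self):
        g = nx.complete_graph(4, nx.DiGraph())
        g.graph["map_id"] = "X"
        (scc,) = strongly_connected_components(g)
        assert len(scc.members) == 4

    def test_partition_property(self):
        rng = random.Random(0)
        g = nx.gnp_random_graph(10, 0.3, seed=1, directed=True)
        g.graph["map_id"] = "X"
        sccs = strongly_connected_components(g)
        all_members = [m for s in sccs for m in s.members]
        assert len(all_members) == len(set(all_members)) == g.number_of_nodes()

    @pytest.mark.parametrize("seed", range(50))
    def test_against_mutual_reachability_oracle(self, seed):
        rng = random.Random(seed)
        n = rng.randint(1, 12)
        nodes = list(range(n))
        edges = [
            (a, b) for a in nodes for b in nodes
            if a != b and rng.random() < 0.25
        ]
        g = nx.DiGraph(map_id="X")
        g.add_nodes_from(nodes)
        g.add_edges_from(edges)
        got = {s.members for s in strongly_connected_components(g)}
        assert got == scc_oracle(nodes, edges)

    def test_weak_mode_merges_cascade(self):
        m = linear_map("A", 4)
        g = build_reaction_graph(m)
        weak = strongly_connected_components(g, mode="weak")
        assert len(weak) == 1 and len(weak[0].members) == 3


class TestPairComponents:
    def _scc(self, map_id, members, i=0):
        return SCC(f"{map_id}.c{i}", map_id, frozenset(members))

    def _matches(self, pairs):
        return [
            InteractionMatch(a, b, 1.0, frozenset({CanonicalId("HGNC", "X"),
                                                   CanonicalId("HGNC", "Y")}))
            for a, b in pairs
        ]

    def test_four_matches_no_group_five_matches_group(self):
        sa = [self._scc("A", [f"a{i}" for i in range(5)])]
        sb = [self._scc("B", [f"b{i}" for i in range(5)])]
        four = self._matches([(f"a{i}", f"b{i}") for i in range(4)])
        five = self._matches([(f"a{i}", f"b{i}") for i in range(5)])
        assert pair_components(sa, sb, four) == []
        groups = pair_components(sa, sb, five)
        assert len(groups) == 1
        assert groups[0].n_similar == 5

    def test_no_matches_no_groups(self):
        assert pair_components([], [], []) == []

    def test_planted_six_cycle_gives_one_group_with_all_matches(self):
        cfg = SimConfig(seed=9, n_planted_modules=1, module_size=6)
        a, b, truth = generate_map_pair(cfg)
        matches = match_interactions(a, b)
        groups = find_similarity_groups(a, b, matches)
        assert len(groups) == 1
        assert groups[0].n_similar == 6
        assert {(m.interaction_a, m.interaction_b) for m in groups[0].matches} == set(
            truth.planted_pairs("mod0")
        )

    def test_group_matches_subset_of_global(self, sim_pair):
        a, b, _ = sim_pair
        matches = match_interactions(a, b)
        groups = find_similarity_groups(a, b, matches)
        global_pairs = {(m.interaction_a, m.interaction_b) for m in matches}
        for g in groups:
            assert {(m.interaction_a, m.interaction_b) for m in g.matches} <= global_pairs
            assert g.n_similar >= 5


class TestCoverageAndFrequency:
    def test_single_planted_module_coverage(self):
        cfg = SimConfig(seed=2, n_planted_modules=1, module_size=6)
        a, b, _ = generate_map_pair(cfg)
        matches = match_interactions(a, b)
        groups = find_similarity_groups(a, b, matches)
        cov_a, tot_a, cov_b, tot_b = group_coverage(groups, a, b)
        assert (cov_a, cov_b) == (6, 6)
        assert tot_a == len(a.interactions) and tot_b == len(b.interactions)

    def test_empty_groups_zero_coverage(self, sim_pair):
        a, b, _ = sim_pair
        assert group_coverage([], a, b) == (0, len(a.interactions), 0, len(b.interactions))

    def test_coverage_monotone_in_min_similar_reactions(self, sim_pair):
        a, b, _ = sim_pair
        matches = match_interactions(a, b)
        cov = []
        for thr in (7, 5, 3, 1):
            cfg = ComparisonConfig(min_similar_reactions=thr)
            groups = find_similarity_groups(a, b, matches, cfg)
            cov.append(group_coverage(groups, a, b)[0])
        assert cov == sorted(cov)

    def test_one_group_frequency_all_ones(self):
        cfg = SimConfig(seed=2, n_planted_modules=1, module_size=6)
        a, b, _ = generate_map_pair(cfg)
        groups = find_similarity_groups(a, b, match_interactions(a, b))
        freq = element_group_frequency(groups, a, b)
        assert freq and all(n == 1 for _, n in freq)

    def test_frequency_counts_groups_containing_symbol(self):
        cfg = SimConfig(seed=2, n_planted_modules=3, module_size=5)
        a, b, _ = generate_map_pair(cfg)
        groups = find_similarity_groups(a, b, match_interactions(a, b))
        assert len(groups) == 3
        freq = dict(element_group_frequency(groups, a, b))
        # module vocabularies are disjoint: every id sits in exactly 1 group
        assert set(freq.values()) == {1}
        ranked = element_group_frequency(groups, a, b)
        keys = [(-n, cid) for cid, n in ranked]
        assert keys == sorted(keys)


class TestDiseaseSpecificClusters:
    def test_background_cycle_is_a_cluster(self, sim_pair, sim_cfg):
        a, b, _ = sim_pair
        matches = match_interactions(a, b)
        clusters = disease_specific_clusters(a, matches, side="a")
        assert clusters
        assert len(clusters[0].members) == sim_cfg.n_background_interactions
        assert all(m.startswith("A.bg.") for m in clusters[0].members)

    def test_matched_module_absent_from_clusters(self, sim_pair):
        a, b, _ = sim_pair
        matches = match_interactions(a, b)
        clusters = disease_specific_clusters(a, matches, side="a")
        members = {m for c in clusters for m in c.members}
        assert not any(m.startswith("A.mod") for m in members)

    def test_all_matched_gives_empty_list(self):
        cfg = SimConfig(seed=4, n_planted_modules=1, module_size=5,
                        n_background_interactions=0, n_cell_types_per_map=0,
                        n_shared_cell_types=0)
        a, b, _ = generate_map_pair(cfg)
        matches = match_interactions(a, b)
        assert disease_specific_clusters(a, matches, side="a") == []

    def test_sorted_by_size_desc(self, sim_pair):
        a, b, _ = sim_pair
        clusters = disease_specific_clusters(a, match_interactions(a, b), side="a")
        sizes = [len(c.members) for c in clusters]
        assert sizes == sorted(sizes, reverse=True)
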