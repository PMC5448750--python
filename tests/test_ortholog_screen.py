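import networkx as nx
import numpy as np
import pytest

from connscreen.ortholog_screen import (
    ClusterSet,
    MclParams,
    ProteinNode,
    filter_candidate_clusters,
    mcl,
    top_n_edges,
)
from connscreen.synthetic_data import simulate_similarity_graph


def _node(nid, taxon, tm=True, motifs=("Ig",), family=None):
    return ProteinNode(id=nid, taxon=taxon, has_tm=tm,
                       motifs=frozenset(motifs), known_family=family)


class TestTopNEdges:
    def test_few_hits_all_kept(self):
        g = top_n_edges([("q", "a", 1.0), ("q", "b", 2.0), ("q", "c", 3.0)], n=200)
        assert g.number_of_edges() == 3

    def test_top_n_cutoff_with_ties_kept(self):
        hits = [("q", f"h{i}", float(i)) for i in range(300)]
        hits += [("q", "tie", 100.0)]  # same score as the rank-200 hit
        g = top_n_edges(hits, n=200)
        assert g.number_of_edges() == 201
        assert not g.has_edge("q", "h99")
        assert g.has_edge("q", "tie")

    def test_max_symmetrization(self):
        g = top_n_edges([("a", "b", 5.0), ("b", "a", 7.0)], n=10)
        assert g.edges["a", "b"]["weight"] == 7.0

    def test_self_hits_dropped_negative_scores_rejected(self):
        g = top_n_edges([("a", "a", 9.0), ("a", "b", 1.0)], n=10)
        assert not g.has_edge("a", "a")
        with pytest.raises(ValueError, match="negative"):
            top_n_edges([("a", "b", -1.0)], n=10)


class TestMcl:
    def test_two_disjoint_triangles(self):
        g = nx.Graph()
        for off in (0, 3):
            for i, j in [(0, 1), (1, 2), (0, 2)]:
                g.add_edge(f"n{i+off}", f"n{j+off}", weight=1.0)
        cs = mcl(g)
        assert sorted(cs.as_sets(), key=min) == [
            frozenset({"n0", "n1", "n2"}), frozenset({"n3", "n4", "n5"})]

    def test_single_node_singleton(self):
        g = nx.Graph()
        g.add_node("only")
        assert mcl(g).clusters == [["only"]]

    def test_bridged_triangles_split_at_default_inflation(self):
        """Two unit-weight triangles joined by one bridge edge: random-walk
        flow concentrates within the triangles, so MCL at inflation 2 returns
        them as separate clusters (verified by direct numerical iteration of
        the 6-node column-stochastic matrix)."""
        g = nx.Graph()
        for off in (0, 3):
            for i, j in [(0, 1), (1, 2), (0, 2)]:
                g.add_edge(f"n{i+off}", f"n{j+off}", weight=1.0)
        g.add_edge("n2", "n3", weight=1.0)
        cs = mcl(g, MclParams(inflation=2.0))
        assert cs.converged
        assert sorted(cs.as_sets(), key=min) == [
            frozenset({"n0", "n1", "n2"}), frozenset({"n3", "n4", "n5"})]

    def test_output_is_partition_and_deterministic(self):
        rng = np.random.default_rng(4)
        g = nx.gnp_random_graph(30, 0.15, seed=4)
        g = nx.relabel_nodes(g, {i: f"p{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(
            g, {e: float(rng.uniform(1, 10)) for e in g.edges}, "weight")
        a, b = mcl(g), mcl(g)
        members = sorted(m for c in a.clusters for m in c)
        assert members == sorted(g.nodes)  # disjoint cover
        assert a.clusters == b.clusters

    def test_disconnected_components_never_merge(self):
        for seed in range(3):
            g1, _, fam1 = simulate_similarity_graph(n_families=3, family_size=5,
                                                    p_inter=0.5, seed=seed)
            g2 = nx.relabel_nodes(g1, {n: "x" + n for n in g1.nodes})
            g = nx.union(g1, g2)
            cs = mcl(g)
            for cluster in cs.clusters:
                prefixes = {m.startswith("x") for m in cluster}
                assert len(prefixes) == 1

    def test_higher_inflation_does_not_coarsen(self):
        # finer granularity with growing inflation, on a fixed random graph
        g = nx.connected_watts_strogatz_graph(24, 4, 0.2, seed=1)
        g = nx.relabel_nodes(g, {i: f"p{i:02d}" for i in g.nodes})
        nx.set_edge_attributes(g, 1.0, "weight")
        counts = [len(mcl(g, MclParams(inflation=r)).clusters)
                  for r in (1.5, 2.0, 3.0, 5.0)]
        assert counts == sorted(counts)

    def test_column_stochastic_invariant(self):
        from connscreen.ortholog_screen import _flow_matrix
        g, _, _ = simulate_similarity_graph(n_families=4, family_size=6, seed=0)
        m = _flow_matrix(g, sorted(g.nodes), MclParams())
        assert np.allclose(m.sum(axis=0), 1.0, atol=1e-12)

    def test_planted_families_recovered(self):
        for seed in range(5):
            g, _, families = simulate_similarity_graph(
                n_families=10, family_size=8, p_intra=0.9, p_inter=0.02, seed=seed)
            cs = mcl(g, MclParams(inflation=2.0))
            want = {}
            for nid, f in families.items():
                want.setdefault(f, set()).add(nid)
            assert sorted(cs.as_sets(), key=min) == sorted(
                (frozenset(s) for s in want.values()), key=min)


class TestClusterFilter:
    def test_conserved_tm_ig_pair_passes(self):
        nodes = {"m": _node("m", "mouse"), "f": _node("f", "fly")}
        cs = ClusterSet(clusters=[["m", "f"]])
        passing, report = filter_candidate_clusters(cs, nodes)
        assert passing == [["m", "f"]]
        assert report[0]["passes"]

    def test_mammal_only_fails_invertebrate_criterion(self):
        nodes = {"m": _node("m", "mouse")}
        passing, report = filter_candidate_clusters(ClusterSet(clusters=[["m"]]), nodes)
        assert passing == []
        assert "no invertebrate member" in report[0]["reasons"]

    def test_blacklisted_family_fails_with_reason(self):
        nodes = {
            "m": _node("m", "mouse", motifs=("Ig",), family="Eph-receptor"),
            "w": _node("w", "worm", motifs=("LRR",)),
        }
        passing, report = filter_candidate_clusters(ClusterSet(clusters=[["m", "w"]]), nodes)
        assert passing == []
        assert any("blacklisted family" in r for r in report[0]["reasons"])

    def test_motif_must_sit_on_mammalian_tm_member(self):
        nodes = {
            "m": _node("m", "mouse", tm=False, motifs=("Ig",)),
            "f": _node("f", "fly", tm=True, motifs=("Ig",)),
        }
        passing, report = filter_candidate_clusters(ClusterSet(clusters=[["m", "f"]]), nodes)
        assert passing == []
        assert "no mammalian TM member with whitelisted motif" in report[0]["reasons"]

    def test_strict_variant_requires_invertebrate_motif(self):
        nodes = {
            "m": _node("m", "mouse", motifs=("Ig",)),
            "f": _node("f", "fly", motifs=("kinase",)),
        }
        cs = ClusterSet(clusters=[["m", "f"]])
        lax, _ = filter_candidate_clusters(cs, nodes)
        strict, _ = filter_candidate_clusters(cs, nodes, require_invertebrate_motif=True)
        assert lax and not strict

    def test_unannotated_node_is_error(self):
        with pytest.raises(ValueError, match="unannotated"):
            filter_candidate_clusters(ClusterSet(clusters=[["ghost"]]), {})
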