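"""Association graph construction, components, communities, classification."""

import networkx as nx
import pandas as pd
import pytest

from crosstrait.coloc import ColocResult
from crosstrait.graph import (build_graph, candidate_pairs,
                              classify_cluster, cluster_recovery_ari,
                              components, detect_communities)


def nodes_df(rows):
    return pd.DataFrame(rows, columns=["node_id", "study_id", "lead_variant_id",
                                       "chrom", "position", "pvalue", "trait",
                                       "has_sumstats"])


def simple_nodes(specs):
    """specs: (node_id, chrom, pos, trait, has_sumstats)"""
    return nodes_df([(nid, f"st_{nid}", f"v_{nid}", ch, pos, 1e-10, tr, ss)
                     for nid, ch, pos, tr, ss in specs])


def coloc_res(a, b, h4, n_shared=3):
    rest = (1 - h4) / 4
    return ColocResult(a, "l", b, "l", (rest, rest, rest, rest, h4), n_shared)


class TestBuildGraph:
    def test_distance_gate_blocks_identical_tagsets(self):
        nodes = simple_nodes([("n1", "1", 1_000_000, "A", False),
                              ("n2", "1", 1_600_000, "B", False)])
        tags = {"n1": {"x", "y"}, "n2": {"x", "y"}}
        G = build_graph(nodes, tags)
        assert G.number_of_edges() == 0

    def test_single_shared_tag_within_500kb_makes_edge(self):
        nodes = simple_nodes([("n1", "1", 1_000_000, "A", False),
                              ("n2", "1", 1_100_000, "B", False)])
        G = build_graph(nodes, {"n1": {"x", "y"}, "n2": {"x", "z"}})
        assert G.has_edge("n1", "n2")
        assert G.edges["n1", "n2"]["kind"] == "tag_overlap"

    def test_coloc_pair_uses_h4_threshold(self):
        nodes = simple_nodes([("n1", "1", 1_000_000, "A", True),
                              ("n2", "1", 1_100_000, "B", True)])
        tags = {"n1": {"x"}, "n2": {"x"}}
        hi = build_graph(nodes, tags, {("n1", "n2"): coloc_res("n1", "n2", 0.9)})
        assert hi.edges["n1", "n2"]["kind"] == "coloc"
        # below threshold: coloc is authoritative, tag overlap cannot rescue
        lo = build_graph(nodes, tags, {("n1", "n2"): coloc_res("n1", "n2", 0.5)})
        assert lo.number_of_edges() == 0

    def test_not_colocalisable_falls_back_to_tags(self):
        nodes = simple_nodes([("n1", "1", 1_000_000, "A", True),
                              ("n2", "1", 1_100_000, "B", True)])
        res = ColocResult("n1", "l", "n2", "l", None, 0)
        G = build_graph(nodes, {"n1": {"x"}, "n2": {"x"}}, {("n1", "n2"): res})
        assert G.edges["n1", "n2"]["kind"] == "tag_overlap"

    def test_cross_chromosome_never_connects(self):
        nodes = simple_nodes([("n1", "1", 1_000_000, "A", False),
                              ("n2", "2", 1_000_000, "B", False)])
        G = build_graph(nodes, {"n1": {"x"}, "n2": {"x"}})
        assert G.number_of_edges() == 0

    def test_missing_tag_set_is_consistency_error(self):
        nodes = simple_nodes([("n1", "1", 1_000_000, "A", False)])
        with pytest.raises(ValueError, match="without tag sets"):
            build_graph(nodes, {})

    def test_rebuild_is_idempotent(self, small_bundle):
        from crosstrait.pipeline import RunConfig, analyse_bundle
        r1 = analyse_bundle(small_bundle, RunConfig(seed=1))
        r2 = analyse_bundle(small_bundle, RunConfig(seed=1))
        pd.testing.assert_frame_equal(r1.edges, r2.edges)

    def test_component_count_monotone_in_stringency(self):
        """Stricter overlap criteria (higher r2 floor, more shared tags)
        never merge components, so the signal count never drops."""
        import numpy as np
        rng = np.random.default_rng(17)
        nodes, tag_r2 = [], {}
        for i in range(40):
            nid = f"n{i:02d}"
            nodes.append((nid, "1", 1_000_000 + (i // 4) * 50_000, "A", False))
            tag_r2[nid] = {f"t{rng.integers(0, 25)}": float(rng.uniform(0.7, 1.0))
                           for _ in range(rng.integers(1, 6))}
        ndf = simple_nodes(nodes)
        prev = -1
        for r2_min in (0.7, 0.8, 0.9, 0.95, 1.0):
            tags = {n: {t for t, r2 in d.items() if r2 >= r2_min} | {f"lead{n}"}
                    for n, d in tag_r2.items()}
            G = build_graph(ndf, tags)
            n_comp = nx.number_connected_components(G)
            assert n_comp >= prev
            prev = n_comp
        full = {n: set(d) | {f"lead{n}"} for n, d in tag_r2.items()}
        n1 = nx.number_connected_components(build_graph(ndf, full, min_shared_tags=1))
        n2 = nx.number_connected_components(build_graph(ndf, full, min_shared_tags=2))
        assert n2 >= n1


class TestComponents:
    def test_no_edges_all_singletons(self):
        G = nx.empty_graph(5)
        clusters, singles = components(G)
        assert clusters == [] and len(singles) == 5

    def test_path_is_one_cluster(self):
        clusters, singles = components(nx.path_graph(["a", "b", "c", "d"]))
        assert clusters == [["a", "b", "c", "d"]] and singles == []

    def test_cluster_ids_ordered_by_smallest_member(self):
        G = nx.Graph([("z1", "z2"), ("a1", "a2")])
        clusters, _ = components(G)
        assert clusters[0][0] == "a1"


class TestCommunities:
    def test_triangle_is_one_community(self):
        assignment, _ = detect_communities(nx.complete_graph(3))
        assert len(set(assignment.values())) == 1

    def test_two_cliques_one_bridge_split_in_two(self):
        G = nx.complete_graph(6)
        H = nx.relabel_nodes(nx.complete_graph(6), {i: i + 6 for i in range(6)})
        G = nx.union(G, H)
        G.add_edge(0, 6)
        assignment, mod = detect_communities(G, seed=0)
        groups = {}
        for n, c in assignment.items():
            groups.setdefault(c, set()).add(n)
        assert sorted(map(sorted, groups.values())) == [list(range(6)),
                                                        list(range(6, 12))]
        assert mod > 0.3

    def test_same_seed_reproduces_assignment(self):
        G = nx.gnm_random_graph(30, 60, seed=5)
        a1, m1 = detect_communities(G, seed=3)
        a2, m2 = detect_communities(G, seed=3)
        assert a1 == a2 and m1 == m2


class TestClassification:
    def test_single_and_multi_trait(self):
        assert classify_cluster(["osteoarthritis"]) == "single_trait"
        assert classify_cluster(["osteoarthritis", "glaucoma"]) == "multi_trait"

    def test_empty_trait_set_is_error(self):
        with pytest.raises(ValueError):
            classify_cluster([])


class TestClusterAccounting:
    def test_sizes_plus_singletons_cover_all_nodes(self, small_bundle):
        from crosstrait.pipeline import RunConfig, analyse_bundle
        res = analyse_bundle(small_bundle, RunConfig(seed=0))
        covered = sum(c.size for c in res.clusters) + len(res.singletons)
        assert covered == len(res.nodes)
        for c in res.clusters:
            if c.category == "multi_trait":
                assert len(c.traits) >= 2
            assert set(c.communities) == set(c.nodes)

    def test_planted_partition_recovered(self, small_bundle):
        from crosstrait.pipeline import RunConfig, analyse_bundle
        res = analyse_bundle(small_bundle, RunConfig(seed=0))
        truth = dict(zip(small_bundle.truth["node_id"],
                         small_bundle.truth["signal_id"]))
        assert cluster_recovery_ari(truth, res.clusters, res.singletons) >= 0.95


def test_candidate_pairs_sorted_and_strictly_within_distance():
    nodes = simple_nodes([("b", "1", 1_000_000, "A", False),
                          ("a", "1", 1_499_999, "A", False),
                          ("c", "1", 1_500_000, "A", False)])
    pairs = candidate_pairs(nodes)
    assert ("a", "b") in pairs          # 499,999 apart: in
    assert ("b", "c") not in pairs      # exactly 500,000 apart: out
    assert pairs == sorted(pairs)
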