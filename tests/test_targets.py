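"""L2G gene assignment, target profiles, tractability classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from crosstrait.graph import SignalCluster
from crosstrait.targets import (assign_locus_gene, build_target_profiles,
                                classify_tractability, cluster_genes,
                                percent, summarize_targets, tractability_tier)

EV_NONE = dict(approved_drug=False, clinical_drug=False, ligand_binding=False,
               drugebility=np.nan, druggable_genome=False,
               location_confidence="none", signal_peptide_or_tm=False,
               protac_literature=False, ubiquitylation_site=False,
               half_life_data=False, ligand_10uM=False,
               protac_location_ok=False, probe_quality="none")


class TestAssignLocusGene:
    @pytest.mark.parametrize("records,expected", [
        ([("A", 0.6), ("B", 0.55)], "A"),
        ([("A", 0.49)], None),          # below the inclusive 0.5 floor
        ([("A", 0.5)], "A"),            # exactly at the floor
        ([], None),
        ([("B", 0.8), ("A", 0.8)], "A"),  # tie -> lexicographically smallest
    ])
    def test_argmax_with_floor(self, records, expected):
        assert assign_locus_gene(records) == expected

    @given(st.permutations([("A", 0.9), ("B", 0.7), ("C", 0.55), ("D", 0.2)]))
    def test_order_invariant(self, records):
        assert assign_locus_gene(records) == "A"


class TestClusterGenes:
    def test_union_with_set_semantics(self):
        assignment = {"n1": "G1", "n2": "G1", "n3": None}
        assert cluster_genes(["n1", "n2", "n3"], assignment) == {"G1"}

    def test_all_unassigned_is_empty(self):
        assert cluster_genes(["n1"], {"n1": None}) == frozenset()


def make_cluster(cid, nodes, traits):
    return SignalCluster(cluster_id=cid, nodes=tuple(nodes),
                         traits=frozenset(traits),
                         communities={n: 0 for n in nodes},
                         category="multi_trait" if len(set(traits)) > 1
                         else "single_trait", modularity=0.0)


def gene_table(rows):
    base = dict(symbol="S", biotype="protein_coding", genage=False,
                cellage=False, go_terms=np.nan, qtl_support=False, **EV_NONE)
    recs = []
    for gid, over in rows:
        r = dict(base, gene_id=gid)
        r.update(over)
        recs.append(r)
    return pd.DataFrame(recs)


class TestBuildTargetProfiles:
    def test_counts_and_biotype_filter(self):
        clusters = [make_cluster(1, ["n1"], ["A", "B"]),
                    make_cluster(2, ["n2"], ["A", "C"]),
                    make_cluster(3, ["n3"], ["B", "C"]),
                    make_cluster(4, ["n4"], ["A"])]
        gene_sets = {1: {"G1", "G2"}, 2: {"G1"}, 3: {"G1"}, 4: {"G3"}}
        genes = gene_table([("G1", {}), ("G2", {"biotype": "lncRNA"}),
                            ("G3", {})])
        profiles, linked = build_target_profiles(clusters, gene_sets, genes)
        assert linked == ["G1", "G2"]  # G3 only in a single-trait cluster
        assert [p.gene_id for p in profiles] == ["G1"]  # G2 non-coding
        assert profiles[0].n_clusters == 3
        assert profiles[0].traits == {"A", "B", "C"}

    def test_unknown_gene_is_consistency_error(self):
        clusters = [make_cluster(1, ["n1"], ["A", "B"])]
        with pytest.raises(ValueError, match="GX"):
            build_target_profiles(clusters, {1: {"GX"}}, gene_table([("G1", {})]))


class TestClassifyTractability:
    def test_approved_drug_is_clinical_precedence(self):
        cats = classify_tractability(dict(EV_NONE, approved_drug=True))
        assert cats["small_molecule"] == "ClinicalPrecedence"

    def test_drugebility_boundary_inclusive(self):
        cats = classify_tractability(dict(EV_NONE, drugebility=0.7))
        assert cats["small_molecule"] == "PredictedTractable"
        cats = classify_tractability(dict(EV_NONE, drugebility=0.69))
        assert cats["small_molecule"] == "Unknown"

    def test_ligand_binding_is_discovery_precedence(self):
        cats = classify_tractability(dict(EV_NONE, ligand_binding=True,
                                          druggable_genome=True))
        assert cats["small_molecule"] == "DiscoveryPrecedence"

    def test_antibody_levels(self):
        assert classify_tractability(dict(EV_NONE, location_confidence="high")
                                     )["antibody"] == "PredictedTractableHigh"
        assert classify_tractability(dict(EV_NONE, signal_peptide_or_tm=True)
                                     )["antibody"] == "PredictedTractableMedLow"
        assert classify_tractability(EV_NONE)["antibody"] == "Unknown"

    def test_protac_discovery_opportunity_needs_full_conjunction(self):
        full = dict(EV_NONE, ubiquitylation_site=True, half_life_data=True,
                    ligand_10uM=True, protac_location_ok=True)
        assert classify_tractability(full)["protac"] == "DiscoveryOpportunity"
        for key in ("ubiquitylation_site", "half_life_data", "ligand_10uM",
                    "protac_location_ok"):
            partial = dict(full)
            partial[key] = False
            assert classify_tractability(partial)["protac"] == "Unknown"

    def test_protac_literature_precedence(self):
        cats = classify_tractability(dict(EV_NONE, protac_literature=True))
        assert cats["protac"] == "LiteraturePrecedence"

    def test_malformed_location_rejected(self):
        with pytest.raises(ValueError):
            classify_tractability(dict(EV_NONE, location_confidence="sideways"))


class TestTiering:
    def test_tiers_partition_profiles(self, default_bundle):
        from crosstrait.pipeline import RunConfig, analyse_bundle
        res = analyse_bundle(default_bundle, RunConfig(seed=0))
        s = res.summary["targets"]
        assert (s["clinical_precedence"] + s["tractable_evidence"]
                + s["no_evidence"]) == s["n_targets"]
        tiers = {p.tier for p in res.profiles}
        assert tiers <= {"clinical_precedence", "tractable_evidence", "no_evidence"}

    def test_clinical_wins_over_everything(self):
        cats = classify_tractability(dict(EV_NONE, approved_drug=True,
                                          ligand_binding=True,
                                          location_confidence="high"))
        assert tractability_tier(cats) == "clinical_precedence"


class TestSummaries:
    @pytest.mark.parametrize("k,n,decimals,expected", [
        (128, 995, 0, 13.0),
        (34, 995, 1, 3.4),
        (0, 100, 0, 0.0),
        (1, 8, 0, 13.0),  # 12.5 rounds half-up
    ])
    def test_percent_half_up(self, k, n, decimals, expected):
        assert percent(k, n, decimals) == expected

    def test_empty_profile_list_warns(self):
        s = summarize_targets([])
        assert s["n_targets"] == 0 and "warning" in s


def test_end_to_end_gene_recovery_across_seeds():
    """With a strong L2G generator the recovered target set matches the
    planted protein-coding multi-trait genes in >= 18 of 20 seeds."""
    from crosstrait.pipeline import RunConfig, analyse_bundle
    from crosstrait.synthetic import make_truth_config, simulate_bundle
    exact = 0
    for seed in range(20):
        cfg = make_truth_config(n_traits=4, studies_per_trait=2, n_loci=12,
                                n_shared=4, n_shared_pairs=2, seed=seed,
                                score_true=0.9, score_noise=0.05,
                                singleton_rate=0.0)
        b = simulate_bundle(cfg)
        res = analyse_bundle(b, RunConfig(seed=seed))
        coding = set(b.genes.loc[b.genes["biotype"] == "protein_coding", "gene_id"])
        truth_multi = b.truth[b.truth["n_planted_traits"] >= 2]
        planted = set(truth_multi["true_gene_id"]) & coding
        got = {p.gene_id for p in res.profiles}
        exact += got == planted
    assert exact >= 18
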