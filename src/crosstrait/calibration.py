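"""Simulation-based calibration utilities.

Two study designs drive the package's parameter-recovery and calibration
checks:

* the planted-sharing design (:func:`crosstrait.synthetic.make_truth_config`)
  — scores how well clustering recovers the planted signal partition
  (adjusted Rand index) and whether the planted trait pairs surface at
  the top of the overlap ranking;
* the null-pair design (:func:`crosstrait.synthetic.make_null_pair_config`)
  — two traits with signals at the same loci but never a shared causal
  variant, used to estimate the one-sided overlap test's type-I error.
"""

from __future__ import annotations

import itertools

from .graph import build_graph, components, cluster_recovery_ari
from .pipeline import RunConfig, _node_table, analyse_bundle
from .stats import fisher_one_sided, overlap_table
from .synthetic import (TruthConfig, make_null_pair_config, make_truth_config,
                        simulate_bundle)

__all__ = ["planted_trait_pairs", "recovery_metrics", "null_pair_pvalue",
           "null_type1_error"]


def planted_trait_pairs(cfg: TruthConfig) -> list[tuple[str, str]]:
    """Trait-name pairs that genuinely share >= 1 planted causal variant."""
    pairs = set()
    for _, _, traits in cfg.sharing:
        for a, b in itertools.combinations(sorted(traits), 2):
            pairs.add((f"TRAIT_{a:02d}", f"TRAIT_{b:02d}"))
    return sorted(pairs)


def recovery_metrics(seed: int, run_config: RunConfig | None = None,
                     **config_kw) -> dict:
    """Simulate one planted-sharing bundle, analyse it, score recovery.

    Returns the adjusted Rand index between recovered signals (clusters
    plus singletons) and planted truth labels, and the worst rank of any
    planted trait pair when pairs are ordered by (adjusted p, raw p).
    """
    cfg = make_truth_config(seed=seed, **config_kw)
    bundle = simulate_bundle(cfg)
    rc = run_config or RunConfig(seed=seed)
    result = analyse_bundle(bundle, rc)
    truth = dict(zip(bundle.truth["node_id"], bundle.truth["signal_id"]))
    ari = cluster_recovery_ari(truth, result.clusters, result.singletons)

    planted = planted_trait_pairs(cfg)
    ov = result.trait_overlap.sort_values(["p_adj", "p"], kind="stable")
    order = list(zip(ov["trait_a"], ov["trait_b"]))
    ranks = [order.index(p) + 1 for p in planted]
    return dict(seed=seed, ari=ari, planted_pairs=planted,
                planted_pair_max_rank=max(ranks) if ranks else 0,
                n_pairs=len(order),
                n_clusters=len(result.clusters),
                n_singletons=len(result.singletons))


def null_pair_pvalue(seed: int, lead_distance_bp: int = 500_000,
                     **config_kw) -> float:
    """Raw one-sided overlap p-value for the designed-null trait pair.

    Simulates one null-pair bundle, builds the tag-overlap graph and
    returns the Fisher p for (TRAIT_00, TRAIT_01) over the universe of
    clusters plus singletons. Under the null the two traits never share a
    planted causal variant, so any overlap counted in cell ``a`` is a
    chance tag-set collision.
    """
    cfg = make_null_pair_config(seed=seed, **config_kw)
    bundle = simulate_bundle(cfg)
    tables = dict(studies=bundle.studies, associations=bundle.associations)
    nodes = _node_table(tables)
    tag_sets: dict[str, frozenset[str]] = {
        f"{sid}::{lead}": frozenset(grp["tag_variant_id"])
        for (sid, lead), grp in bundle.tags.groupby(["study_id", "lead_variant_id"])
    }
    G = build_graph(nodes, tag_sets, lead_distance_bp=lead_distance_bp)
    clusters, singletons = components(G)
    trait_of = dict(zip(nodes["node_id"], nodes["trait"]))
    universe = [{trait_of[n] for n in c} for c in clusters]
    universe += [{trait_of[s]} for s in singletons]
    table = overlap_table(universe, "TRAIT_00", "TRAIT_01")
    _, p = fisher_one_sided(table)
    return p


def null_type1_error(n_replicates: int = 400, alpha: float = 0.05,
                     seed: int = 0, **config_kw) -> float:
    """Rejection rate of the one-sided overlap test across null replicates."""
    hits = sum(null_pair_pvalue(seed * 100_003 + i, **config_kw) < alpha
               for i in range(n_replicates))
    return hits / n_replicates
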