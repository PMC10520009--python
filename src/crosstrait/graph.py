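"""Association graph: independent genetic signals across traits.

Each node is one genome-wide-significant locus in one GWAS study,
identified by (study id, lead variant). Two nodes on the same chromosome
with leads less than 500 kb apart are joined when they plausibly share a
causal variant: by colocalisation (posterior of a shared causal variant
>= 0.8) when both studies carry summary statistics, otherwise when their
tag sets share at least one variant. Maximal connected components of
size >= 2 are the independent multi-study signals ("clusters");
degree-zero nodes are singleton signals. Louvain community detection
flags possible substructure inside a cluster.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .coloc import H4_MIN, ColocResult

__all__ = [
    "SignalCluster",
    "candidate_pairs",
    "build_graph",
    "components",
    "detect_communities",
    "classify_cluster",
    "build_clusters",
    "cluster_recovery_ari",
]

LEAD_DISTANCE_BP = 500_000


@dataclass(frozen=True)
class SignalCluster:
    """A maximal connected component of size >= 2: one independent signal."""

    cluster_id: int
    nodes: tuple[str, ...]
    traits: frozenset[str]
    communities: dict[str, int]
    category: str  # "single_trait" | "multi_trait"
    modularity: float

    @property
    def size(self) -> int:
        return len(self.nodes)

    @property
    def n_communities(self) -> int:
        return len(set(self.communities.values()))


def candidate_pairs(nodes: pd.DataFrame,
                    lead_distance_bp: int = LEAD_DISTANCE_BP) -> list[tuple[str, str]]:
    """Unordered node pairs on the same chromosome with leads < 500 kb apart.

    The distance gate is strict (< lead_distance_bp), applied before any
    evidence is consulted. Pairs are returned with node ids sorted within
    the pair and the list sorted overall, so downstream edge construction
    is order-independent.
    """
    pairs: list[tuple[str, str]] = []
    for _, grp in nodes.groupby("chrom", sort=True):
        grp = grp.sort_values(["position", "node_id"])
        ids = grp["node_id"].to_numpy()
        pos = grp["position"].to_numpy()
        for i in range(len(ids)):
            j = i + 1
            while j < len(ids) and pos[j] - pos[i] < lead_distance_bp:
                a, b = sorted((ids[i], ids[j]))
                pairs.append((a, b))
                j += 1
    return sorted(set(pairs))


def build_graph(
    nodes: pd.DataFrame,
    tag_sets: Mapping[str, frozenset[str] | set[str]],
    coloc_results: Mapping[tuple[str, str], ColocResult] | None = None,
    *,
    lead_distance_bp: int = LEAD_DISTANCE_BP,
    h4_min: float = H4_MIN,
    min_shared_tags: int = 1,
) -> nx.Graph:
    """Build the undirected, unweighted association graph.

    ``nodes`` needs columns node_id, study_id, chrom, position, trait,
    has_sumstats. ``tag_sets`` maps every node id to its tag-variant set.
    ``coloc_results`` maps sorted (node_a, node_b) pairs to colocalisation
    results for pairs where both studies have summary statistics.

    Edge rule per candidate pair: if both studies carry summary statistics
    and a colocalisable result exists, the colocalisation verdict is
    authoritative (edge iff pp_h4 >= h4_min); when the pair is not
    colocalisable (no shared window variants, or no result supplied) it
    falls back to tag overlap; pairs without two-sided summary statistics
    use tag overlap (>= min_shared_tags shared tag variants). No
    self-loops or parallel edges arise by construction.
    """
    missing = [n for n in nodes["node_id"] if n not in tag_sets]
    if missing:
        raise ValueError(f"nodes without tag sets: {missing[:5]}{'...' if len(missing) > 5 else ''}")
    coloc_results = coloc_results or {}
    has_ss = dict(zip(nodes["node_id"], nodes["has_sumstats"]))
    traits = dict(zip(nodes["node_id"], nodes["trait"]))

    G = nx.Graph()
    for row in nodes.itertuples(index=False):
        G.add_node(row.node_id, trait=row.trait, chrom=row.chrom,
                   position=row.position, has_sumstats=bool(row.has_sumstats))

    for a, b in candidate_pairs(nodes, lead_distance_bp):
        if has_ss[a] and has_ss[b]:
            res = coloc_results.get((a, b))
            if res is not None and res.colocalisable:
                if res.pp_h4 >= h4_min:
                    G.add_edge(a, b, kind="coloc", evidence=float(res.pp_h4))
                continue  # coloc is authoritative below threshold
        shared = len(set(tag_sets[a]) & set(tag_sets[b]))
        if shared >= min_shared_tags:
            G.add_edge(a, b, kind="tag_overlap", evidence=float(shared))
    return G


def components(G: nx.Graph) -> tuple[list[list[str]], list[str]]:
    """Maximal connected components split into clusters and singletons.

    Components of size >= 2 are returned as sorted node lists, ordered by
    their smallest member node id; size-1 components are the singleton
    signals, sorted.
    """
    clusters, singletons = [], []
    for comp in nx.connected_components(G):
        members = sorted(comp)
        if len(members) >= 2:
            clusters.append(members)
        else:
            singletons.extend(members)
    clusters.sort(key=lambda m: m[0])
    return clusters, sorted(singletons)


def detect_communities(sub: nx.Graph, seed: int = 0) -> tuple[dict[str, int], float]:
    """Louvain community partition of one connected cluster subgraph.

    Nodes are fed to the algorithm in canonical (sorted) order and the
    seed fixes the randomised sweeps, so repeat calls reproduce the same
    assignment. Returns (node -> community index, modularity); community
    indices are ordered by each community's smallest node id.
    """
    H = nx.Graph()
    H.add_nodes_from(sorted(sub.nodes))
    H.add_edges_from(sorted(tuple(sorted(e)) for e in sub.edges))
    comms = nx.community.louvain_communities(H, seed=seed)
    comms = sorted((sorted(c) for c in comms), key=lambda c: c[0])
    assignment = {n: i for i, c in enumerate(comms) for n in c}
    mod = nx.community.modularity(H, [set(c) for c in comms]) if H.number_of_edges() else 0.0
    return assignment, float(mod)


def classify_cluster(traits: Iterable[str]) -> str:
    """single_trait iff exactly one distinct mapped trait, else multi_trait."""
    tset = set(traits)
    if not tset:
        raise ValueError("cluster with empty trait set")
    return "single_trait" if len(tset) == 1 else "multi_trait"


def build_clusters(G: nx.Graph, seed: int = 0) -> tuple[list[SignalCluster], list[str]]:
    """Assemble :class:`SignalCluster` records (with communities) plus singletons."""
    comp_lists, singletons = components(G)
    clusters = []
    for cid, members in enumerate(comp_lists, start=1):
        sub = G.subgraph(members)
        assignment, mod = detect_communities(sub, seed=seed)
        traits = frozenset(G.nodes[n]["trait"] for n in members)
        clusters.append(SignalCluster(
            cluster_id=cid, nodes=tuple(members), traits=traits,
            communities=assignment, category=classify_cluster(traits),
            modularity=mod))
    return clusters, singletons


def cluster_recovery_ari(truth_labels: Mapping[str, str],
                         clusters: Sequence[SignalCluster],
                         singletons: Sequence[str]) -> float:
    """Adjusted Rand index between planted signals and recovered partition.

    Every singleton counts as its own group; nodes are compared over the
    truth-label key set.
    """
    assign: dict[str, str] = {}
    for c in clusters:
        for n in c.nodes:
            assign[n] = f"C{c.cluster_id}"
    for s in singletons:
        assign[s] = f"S::{s}"
    keys = sorted(truth_labels)
    return float(adjusted_rand_score([truth_labels[k] for k in keys],
                                     [assign[k] for k in keys]))
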