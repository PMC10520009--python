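"""Map multi-trait signal clusters to candidate causal genes and annotate
them as drug targets.

A locus (study, lead variant) is assigned to the gene with the highest
locus-to-gene (L2G) score, provided that score is at least 0.5; a cluster
inherits the union of its loci's genes. Protein-coding genes linked to at
least one multi-trait cluster form the target set, which is then flagged
for membership of curated ageing gene sets (GenAge, CellAge, hallmark GO
annotation) and classified for drug-target tractability by small
molecule, antibody and PROTAC modalities using simple precedence rules
over the supplied evidence columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .graph import SignalCluster

__all__ = [
    "TargetProfile",
    "assign_locus_gene",
    "cluster_genes",
    "build_target_profiles",
    "classify_tractability",
    "tractability_tier",
    "annotate_hallmarks",
    "summarize_targets",
    "percent",
]

L2G_MIN = 0.5
DRUGEBILITY_MIN = 0.7

TIERS = ("clinical_precedence", "tractable_evidence", "no_evidence")


@dataclass(frozen=True)
class TargetProfile:
    """One protein-coding gene linked to >= 1 multi-trait cluster."""

    gene_id: str
    symbol: str
    cluster_ids: tuple[int, ...]
    traits: frozenset[str]
    best_l2g: float
    qtl_support: bool
    genage: bool
    cellage: bool
    hallmarks: frozenset[str]
    sm_category: str
    ab_category: str
    protac_category: str
    probe_quality: str
    tier: str

    @property
    def n_clusters(self) -> int:
        return len(self.cluster_ids)


def assign_locus_gene(records: Iterable[tuple[str, float]],
                      min_score: float = L2G_MIN) -> str | None:
    """Highest-scoring gene at one locus, if it reaches the score floor.

    ``records`` are (gene id, L2G score) for a single (study, lead).
    The floor is inclusive (score = 0.5 qualifies). Ties on the maximal
    score resolve to the lexicographically smallest gene id, so the
    result is invariant to record order. Empty input yields None.
    """
    best: tuple[float, str] | None = None
    for gene, score in records:
        key = (-float(score), gene)
        if best is None or key < best:
            best = key
    if best is None or -best[0] < min_score:
        return None
    return best[1]


def cluster_genes(cluster_nodes: Iterable[str],
                  locus_assignment: Mapping[str, str | None]) -> frozenset[str]:
    """Union of assigned genes over a cluster's loci (empty set allowed)."""
    out = {locus_assignment.get(n) for n in cluster_nodes}
    out.discard(None)
    return frozenset(out)  # type: ignore[arg-type]


def annotate_hallmarks(go_terms: str | float | None,
                       go_map: Mapping[str, str]) -> frozenset[str]:
    """Map a ';'-separated GO term list onto hallmark-of-ageing labels."""
    if go_terms is None or (isinstance(go_terms, float) and pd.isna(go_terms)) or go_terms == "":
        return frozenset()
    return frozenset(go_map[t] for t in str(go_terms).split(";") if t in go_map)


def classify_tractability(ev: Mapping[str, object]) -> dict[str, str]:
    """Rule-based tractability categories per modality.

    Small molecule: ClinicalPrecedence with an approved or clinical-stage
    drug; else DiscoveryPrecedence with ligand-binding evidence; else
    PredictedTractable with a predicted binding pocket (drugEBIlity score
    >= 0.7, inclusive) and/or druggable-genome membership; else Unknown.

    Antibody: PredictedTractableHigh when the protein is confidently
    localised to an antibody-accessible compartment; PredictedTractableMedLow
    with medium-confidence location or a signal peptide / transmembrane
    region; else Unknown.

    PROTAC: LiteraturePrecedence with a published degrader; else
    DiscoveryOpportunity when a ubiquitylation site, half-life data, a
    <= 10 uM ligand and a compatible subcellular location all co-occur;
    else Unknown.
    """
    def flag(key: str) -> bool:
        return bool(ev.get(key, False))

    drugebility = ev.get("drugebility")
    try:
        drugebility = None if drugebility is None or pd.isna(drugebility) else float(drugebility)
    except TypeError:
        raise ValueError(f"malformed drugebility value {drugebility!r}")

    if flag("approved_drug") or flag("clinical_drug"):
        sm = "ClinicalPrecedence"
    elif flag("ligand_binding"):
        sm = "DiscoveryPrecedence"
    elif (drugebility is not None and drugebility >= DRUGEBILITY_MIN) or flag("druggable_genome"):
        sm = "PredictedTractable"
    else:
        sm = "Unknown"

    loc = ev.get("location_confidence", "none")
    if loc not in ("high", "medium", "none"):
        raise ValueError(f"malformed location_confidence {loc!r}")
    if loc == "high":
        ab = "PredictedTractableHigh"
    elif loc == "medium" or flag("signal_peptide_or_tm"):
        ab = "PredictedTractableMedLow"
    else:
        ab = "Unknown"

    if flag("protac_literature"):
        protac = "LiteraturePrecedence"
    elif (flag("ubiquitylation_site") and flag("half_life_data")
          and flag("ligand_10uM") and flag("protac_location_ok")):
        protac = "DiscoveryOpportunity"
    else:
        protac = "Unknown"

    probe = ev.get("probe_quality", "none")
    if probe not in ("curated", "predicted", "none"):
        raise ValueError(f"malformed probe_quality {probe!r}")
    return dict(small_molecule=sm, antibody=ab, protac=protac, probe=str(probe))


def tractability_tier(categories: Mapping[str, str]) -> str:
    """Three-way actionability tier: a partition over all profiles.

    ``clinical_precedence`` — an approved or investigational drug exists
    (small-molecule ClinicalPrecedence). ``tractable_evidence`` —
    experimental binding evidence or predicted tractability by small
    molecule or antibody (DiscoveryPrecedence, PredictedTractable, or any
    antibody PredictedTractable level), without clinical precedence.
    ``no_evidence`` — none of the above.
    """
    if categories["small_molecule"] == "ClinicalPrecedence":
        return "clinical_precedence"
    if categories["small_molecule"] in ("DiscoveryPrecedence", "PredictedTractable"):
        return "tractable_evidence"
    if categories["antibody"] in ("PredictedTractableHigh", "PredictedTractableMedLow"):
        return "tractable_evidence"
    return "no_evidence"


def build_target_profiles(
    clusters: Sequence[SignalCluster],
    cluster_gene_sets: Mapping[int, frozenset[str] | set[str]],
    genes: pd.DataFrame,
    best_l2g: Mapping[tuple[int, str], float] | None = None,
    go_map: Mapping[str, str] | None = None,
) -> tuple[list[TargetProfile], list[str]]:
    """Profiles for protein-coding genes in >= 1 multi-trait cluster.

    Returns (profiles, all linked gene ids including non-protein-coding),
    the latter so callers can report the full tally alongside the
    protein-coding subset. Genes referenced by a cluster but absent from
    the gene table raise a consistency error naming the offenders.
    """
    go_map = go_map or {}
    gene_rows = genes.set_index("gene_id")
    linked: dict[str, list[SignalCluster]] = {}
    for cl in clusters:
        if cl.category != "multi_trait":
            continue
        for g in sorted(cluster_gene_sets.get(cl.cluster_id, ())):
            linked.setdefault(g, []).append(cl)

    unknown = sorted(g for g in linked if g not in gene_rows.index)
    if unknown:
        raise ValueError(f"genes linked to clusters but missing from the gene table: {unknown}")

    profiles: list[TargetProfile] = []
    for g in sorted(linked):
        rec = gene_rows.loc[g]
        if rec["biotype"] != "protein_coding":
            continue
        cls = linked[g]
        cids = tuple(sorted(c.cluster_id for c in cls))
        traits = frozenset().union(*(c.traits for c in cls))
        if best_l2g:
            best = max(best_l2g.get((cid, g), 0.0) for cid in cids)
        else:
            best = float("nan")
        cats = classify_tractability(rec.to_dict())
        profiles.append(TargetProfile(
            gene_id=g, symbol=str(rec["symbol"]), cluster_ids=cids,
            traits=traits, best_l2g=float(best),
            qtl_support=bool(rec.get("qtl_support", False)),
            genage=bool(rec.get("genage", False)),
            cellage=bool(rec.get("cellage", False)),
            hallmarks=annotate_hallmarks(rec.get("go_terms"), go_map),
            sm_category=cats["small_molecule"], ab_category=cats["antibody"],
            protac_category=cats["protac"], probe_quality=cats["probe"],
            tier=tractability_tier(cats)))
    return profiles, sorted(linked)


def percent(k: int, n: int, decimals: int = 0) -> float:
    """Percentage rounded half-up to the requested number of decimals."""
    if n == 0:
        return 0.0
    q = Decimal(1).scaleb(-decimals)
    return float((Decimal(k) * 100 / Decimal(n)).quantize(q, rounding=ROUND_HALF_UP))


def summarize_targets(profiles: Sequence[TargetProfile]) -> dict:
    """Headline counts and percentages over the target gene set.

    Percentages use half-up rounding to whole percents (one decimal for
    the sub-5% ageing-set overlaps, where a whole percent would lose the
    signal). Tier counts partition the profiles.
    """
    n = len(profiles)
    if n == 0:
        return dict(n_targets=0, warning="empty target set")
    tiers = {t: sum(1 for p in profiles if p.tier == t) for t in TIERS}
    genage = sum(1 for p in profiles if p.genage)
    cellage = sum(1 for p in profiles if p.cellage)
    hallmark = sum(1 for p in profiles if p.hallmarks)
    probes = sum(1 for p in profiles if p.probe_quality == "curated")
    hist: dict[int, int] = {}
    for p in profiles:
        hist[p.n_clusters] = hist.get(p.n_clusters, 0) + 1
    return dict(
        n_targets=n,
        clinical_precedence=tiers["clinical_precedence"],
        clinical_precedence_pct=percent(tiers["clinical_precedence"], n),
        tractable_evidence=tiers["tractable_evidence"],
        tractable_evidence_pct=percent(tiers["tractable_evidence"], n),
        no_evidence=tiers["no_evidence"],
        no_evidence_pct=percent(tiers["no_evidence"], n),
        genage=genage, genage_pct=percent(genage, n, decimals=1),
        cellage=cellage, cellage_pct=percent(cellage, n, decimals=1),
        hallmark_annotated=hallmark, hallmark_annotated_pct=percent(hallmark, n),
        curated_probes=probes,
        cluster_count_histogram={str(k): v for k, v in sorted(hist.items())},
    )
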