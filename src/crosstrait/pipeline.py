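"""End-to-end orchestration: validate -> expand -> coloc -> cluster ->
overlap -> map genes -> annotate -> report.

The pipeline consumes the TSV bundle documented in :mod:`crosstrait.io`
(studies, associations, tags, sumstats, l2g, genes) and emits every
intermediate interface table plus a JSON summary and a run manifest.
``analyse_bundle`` runs the same stages on in-memory tables, which is
what the tests and simulation studies use.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .coloc import ColocPriors, ColocResult, coloc_abf
from .expansion import SummaryStatsWindow, expand_association
from .graph import (SignalCluster, build_clusters, build_graph,
                    candidate_pairs)
from .stats import enrichment_test, trait_overlap_tests
from .synthetic import SimulatedBundle, hallmark_go_map
from .targets import (TargetProfile, assign_locus_gene, build_target_profiles,
                      cluster_genes, summarize_targets)

log = logging.getLogger("crosstrait")

__all__ = ["RunConfig", "IntegrityError", "validate_inputs", "analyse_bundle",
           "run_pipeline", "PipelineResult"]


class IntegrityError(ValueError):
    """A table references a key that does not exist anywhere upstream."""


@dataclass(frozen=True)
class RunConfig:
    """All thresholds and priors of one run; defaults are the analysis
    values used throughout (r^2 >= 0.7 tags, credible-set pp > 0.1%,
    coloc H4 >= 0.8, 500 kb lead windows, L2G >= 0.5, genome-wide
    significance p < 5e-8, study inclusion n >= 2000, alpha = 0.05)."""

    r2_min: float = 0.7
    pp_min: float = 0.001
    h4_min: float = 0.8
    lead_distance_bp: int = 500_000
    l2g_min: float = 0.5
    gwas_p_max: float = 5e-8
    min_n: int = 2000
    alpha: float = 0.05
    p1: float = 1e-4
    p2: float = 1e-4
    p12: float = 1e-5
    w_quant: float = 0.15
    w_binary: float = 0.2
    universe_mode: str = "all"  # "all" | "clusters_only"
    min_shared_tags: int = 1
    renormalise_pp: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name, v in (("r2_min", self.r2_min), ("h4_min", self.h4_min),
                        ("alpha", self.alpha)):
            if not (0 <= v <= 1):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not (0 <= self.pp_min < 1):
            raise ValueError("pp_min must be in [0, 1)")
        if not (0 <= self.l2g_min <= 1):
            raise ValueError("l2g_min must be in [0, 1]")
        if not (0 < self.gwas_p_max <= 1):
            raise ValueError("gwas_p_max must be in (0, 1]")
        if self.lead_distance_bp <= 0 or self.min_n < 0 or self.min_shared_tags < 1:
            raise ValueError("invalid size threshold in config")
        if self.universe_mode not in ("all", "clusters_only"):
            raise ValueError(f"unknown universe_mode {self.universe_mode!r}")
        ColocPriors(self.p1, self.p2, self.p12)

    def priors(self) -> ColocPriors:
        return ColocPriors(self.p1, self.p2, self.p12)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class PipelineResult:
    nodes: pd.DataFrame
    tags: pd.DataFrame
    tag_sets: dict[str, frozenset[str]]
    coloc: pd.DataFrame
    clusters: list[SignalCluster]
    singletons: list[str]
    edges: pd.DataFrame
    trait_overlap: pd.DataFrame
    locus_genes: dict[str, str | None]
    cluster_gene_sets: dict[int, frozenset[str]]
    profiles: list[TargetProfile]
    linked_genes: list[str]
    enrichment: pd.DataFrame
    summary: dict
    rejections: pd.DataFrame


def validate_inputs(tables: dict[str, pd.DataFrame],
                    config: RunConfig) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Schema + referential-integrity checks and inclusion filters.

    Studies below the sample-size floor (number of cases for case-control
    studies, else total n) and associations at or above the genome-wide
    significance threshold are excluded and logged with reasons; rows in
    downstream tables that reference excluded rows are dropped with them.
    A reference to a key that never existed raises :class:`IntegrityError`.
    """
    rejects: list[dict] = []
    for name in ("studies", "associations", "tags", "l2g", "genes"):
        if name not in tables:
            raise ValueError(f"missing required input table {name!r}")
        missing = [c for c in io.SCHEMAS[name] if c not in tables[name].columns]
        if missing:
            raise ValueError(f"table {name!r} missing required column(s) {missing}")

    studies = tables["studies"].copy()
    eff_n = studies["n_cases"].where(studies["n_cases"].notna(), studies["n_total"])
    keep = eff_n >= config.min_n
    for sid in studies.loc[~keep, "study_id"]:
        rejects.append(dict(table="studies", key=sid,
                            reason=f"effective sample size below {config.min_n}"))
    studies = studies[keep]
    known_studies = set(tables["studies"]["study_id"])
    kept_studies = set(studies["study_id"])

    assoc = tables["associations"].copy()
    dangling = set(assoc["study_id"]) - known_studies
    if dangling:
        raise IntegrityError(f"associations reference unknown studies: {sorted(dangling)[:5]}")
    keep = assoc["study_id"].isin(kept_studies)
    for _, r in assoc[~keep].iterrows():
        rejects.append(dict(table="associations",
                            key=f"{r.study_id}::{r.lead_variant_id}",
                            reason="study excluded"))
    assoc = assoc[keep]
    sig = assoc["pvalue"] < config.gwas_p_max  # strict: p == 5e-8 is excluded
    for _, r in assoc[~sig].iterrows():
        rejects.append(dict(table="associations",
                            key=f"{r.study_id}::{r.lead_variant_id}",
                            reason=f"p-value not below {config.gwas_p_max}"))
    assoc = assoc[sig]
    known_pairs = set(zip(tables["associations"]["study_id"],
                          tables["associations"]["lead_variant_id"]))
    kept_pairs = set(zip(assoc["study_id"], assoc["lead_variant_id"]))

    out = dict(tables)
    out["studies"], out["associations"] = studies, assoc
    for name in ("tags", "sumstats", "l2g"):
        if name not in tables or tables[name].empty:
            out[name] = tables.get(name, pd.DataFrame(columns=list(io.SCHEMAS[name])))
            continue
        df = tables[name]
        pairs = list(zip(df["study_id"], df["lead_variant_id"]))
        bad = {p for p in pairs if p not in known_pairs}
        if bad:
            raise IntegrityError(
                f"{name} references unknown associations: {sorted(bad)[:5]}")
        mask = pd.Series([p in kept_pairs for p in pairs], index=df.index)
        out[name] = df[mask]
    rejections = pd.DataFrame(rejects, columns=list(io.SCHEMAS["rejections"]))
    log.info("[validate] studies kept %d/%d, associations kept %d/%d",
             len(studies), len(tables["studies"]), len(assoc),
             len(tables["associations"]))
    return out, rejections


def _node_table(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    assoc = tables["associations"]
    studies = tables["studies"].set_index("study_id")
    nodes = assoc.copy()
    nodes["node_id"] = nodes["study_id"] + "::" + nodes["lead_variant_id"]
    if nodes["node_id"].duplicated().any():
        dup = nodes.loc[nodes["node_id"].duplicated(), "node_id"].tolist()
        raise IntegrityError(f"duplicate association node ids: {dup[:5]}")
    nodes["trait"] = studies.loc[nodes["study_id"], "trait"].to_numpy()
    nodes["has_sumstats"] = studies.loc[nodes["study_id"], "has_sumstats"].to_numpy()
    return nodes[list(io.SCHEMAS["nodes"])]


def _windows(tables: dict[str, pd.DataFrame]) -> dict[str, SummaryStatsWindow]:
    """Per-node summary-statistics windows keyed by node id."""
    ss = tables.get("sumstats")
    if ss is None or ss.empty:
        return {}
    out = {}
    for (sid, lead), grp in ss.groupby(["study_id", "lead_variant_id"], sort=True):
        out[f"{sid}::{lead}"] = SummaryStatsWindow(
            study_id=sid, lead=lead,
            variants=tuple(grp["variant_id"]),
            positions=tuple(int(p) for p in grp["position"]),
            beta=tuple(float(b) for b in grp["beta"]),
            se=tuple(float(s) for s in grp["se"]))
    return out


def expand_stage(tables: dict[str, pd.DataFrame], config: RunConfig,
                 ) -> tuple[pd.DataFrame, dict[str, frozenset[str]]]:
    """Tag sets for every node: ABF fine-mapping where summary statistics
    exist, otherwise the supplied LD tags filtered at r^2 >= r2_min."""
    nodes = _node_table(tables)
    windows = _windows(tables)
    tag_in = tables["tags"]
    by_pair = {k: g for k, g in tag_in.groupby(["study_id", "lead_variant_id"])} if not tag_in.empty else {}
    rows = []
    tag_sets: dict[str, frozenset[str]] = {}
    for n in nodes.itertuples(index=False):
        win = windows.get(n.node_id) if n.has_sumstats else None
        if win is not None:
            ts = expand_association(n.study_id, n.lead_variant_id, window=win,
                                    W=config.w_quant, pp_min=config.pp_min,
                                    renormalise=config.renormalise_pp)
            for v, _, pp in ts.tags:
                rows.append(dict(study_id=n.study_id, lead_variant_id=n.lead_variant_id,
                                 tag_variant_id=v, r2=np.nan, posterior_prob=pp,
                                 source="abf"))
            tag_sets[n.node_id] = ts.variants
            continue
        grp = by_pair.get((n.study_id, n.lead_variant_id))
        kept = {n.lead_variant_id}
        lead_row_seen = False
        if grp is not None:
            for r in grp.itertuples(index=False):
                r2 = r.r2
                if pd.isna(r2) or float(r2) >= config.r2_min:
                    kept.add(r.tag_variant_id)
                    lead_row_seen = lead_row_seen or r.tag_variant_id == n.lead_variant_id
                    rows.append(dict(study_id=n.study_id,
                                     lead_variant_id=n.lead_variant_id,
                                     tag_variant_id=r.tag_variant_id,
                                     r2=(np.nan if pd.isna(r2) else float(r2)),
                                     posterior_prob=np.nan, source=r.source))
        if not lead_row_seen:
            rows.append(dict(study_id=n.study_id, lead_variant_id=n.lead_variant_id,
                             tag_variant_id=n.lead_variant_id, r2=1.0,
                             posterior_prob=np.nan, source="ld"))
        tag_sets[n.node_id] = frozenset(kept)
    tags_out = pd.DataFrame(rows, columns=list(io.SCHEMAS["tags"]))
    log.info("[expand] %d nodes, %d tag rows", len(nodes), len(tags_out))
    return tags_out, tag_sets


def coloc_stage(nodes: pd.DataFrame, windows: dict[str, SummaryStatsWindow],
                config: RunConfig) -> tuple[pd.DataFrame, dict[tuple[str, str], ColocResult]]:
    """Colocalise every candidate pair where both nodes carry windows."""
    results: dict[tuple[str, str], ColocResult] = {}
    rows = []
    for a, b in candidate_pairs(nodes, config.lead_distance_bp):
        wa, wb = windows.get(a), windows.get(b)
        if wa is None or wb is None:
            continue
        res = coloc_abf(wa, wb, config.priors(), W1=config.w_quant, W2=config.w_quant)
        results[(a, b)] = res
        pp = res.pp or (np.nan,) * 5
        rows.append(dict(study_a=res.study_a, lead_a=res.lead_a,
                         study_b=res.study_b, lead_b=res.lead_b,
                         pp_h0=pp[0], pp_h1=pp[1], pp_h2=pp[2],
                         pp_h3=pp[3], pp_h4=pp[4], n_shared=res.n_shared))
    coloc_df = pd.DataFrame(rows, columns=list(io.SCHEMAS["coloc"]))
    log.info("[coloc] %d pairs tested", len(coloc_df))
    return coloc_df, results


def analyse_bundle(bundle: SimulatedBundle | dict[str, pd.DataFrame],
                   config: RunConfig | None = None) -> PipelineResult:
    """Run every analysis stage on in-memory tables."""
    config = config or RunConfig()
    config.validate()
    if isinstance(bundle, SimulatedBundle):
        tables = {name: getattr(bundle, name) for name in
                  ("studies", "associations", "tags", "sumstats", "l2g", "genes")}
    else:
        tables = dict(bundle)
    tables.setdefault("sumstats", pd.DataFrame(columns=list(io.SCHEMAS["sumstats"])))

    tables, rejections = validate_inputs(tables, config)
    nodes = _node_table(tables)
    tags_out, tag_sets = expand_stage(tables, config)
    windows = _windows(tables)
    coloc_df, coloc_results = coloc_stage(nodes, windows, config)

    G = build_graph(nodes, tag_sets, coloc_results,
                    lead_distance_bp=config.lead_distance_bp,
                    h4_min=config.h4_min, min_shared_tags=config.min_shared_tags)
    clusters, singletons = build_clusters(G, seed=config.seed)
    edges = pd.DataFrame(
        [dict(node_a=a, node_b=b, kind=d["kind"], evidence=d["evidence"])
         for a, b, d in sorted(G.edges(data=True))],
        columns=list(io.SCHEMAS["edges"]))
    log.info("[cluster] %d clusters, %d singletons, %d edges",
             len(clusters), len(singletons), len(edges))

    node_trait = dict(zip(nodes["node_id"], nodes["trait"]))
    universe = [set(c.traits) for c in clusters]
    if config.universe_mode == "all":
        universe += [{node_trait[s]} for s in singletons]
    if len(set().union(*universe) if universe else set()) >= 2:
        overlap = trait_overlap_tests(universe, alpha=config.alpha)
    else:
        overlap = pd.DataFrame(columns=list(io.SCHEMAS["trait_overlap"]))
    log.info("[overlap] %d trait pairs tested, %d significant",
             len(overlap), int(overlap["significant"].sum()) if len(overlap) else 0)

    l2g = tables["l2g"]
    locus_genes: dict[str, str | None] = {}
    scores: dict[str, dict[str, float]] = {}
    for (sid, lead), grp in (l2g.groupby(["study_id", "lead_variant_id"]) if not l2g.empty else []):
        nid = f"{sid}::{lead}"
        scores[nid] = dict(zip(grp["gene_id"], grp["score"].astype(float)))
        locus_genes[nid] = assign_locus_gene(scores[nid].items(), min_score=config.l2g_min)
    for nid in nodes["node_id"]:
        locus_genes.setdefault(nid, None)

    cluster_gene_sets = {c.cluster_id: cluster_genes(c.nodes, locus_genes)
                         for c in clusters}
    best_l2g: dict[tuple[int, str], float] = {}
    for c in clusters:
        for n in c.nodes:
            g = locus_genes.get(n)
            if g is not None:
                key = (c.cluster_id, g)
                best_l2g[key] = max(best_l2g.get(key, 0.0), scores[n][g])

    go_map_df = hallmark_go_map()
    go_map = dict(zip(go_map_df["go_id"], go_map_df["hallmark"]))
    profiles, linked = build_target_profiles(clusters, cluster_gene_sets,
                                             tables["genes"], best_l2g, go_map)
    log.info("[targets] %d linked genes, %d protein-coding profiles",
             len(linked), len(profiles))

    genes = tables["genes"]
    coding = genes.loc[genes["biotype"] == "protein_coding", "gene_id"]
    universe_genes = set(coding)
    target_ids = {p.gene_id for p in profiles}
    enrich_rows = []
    ref_sets = {
        "genage": set(genes.loc[genes["genage"].astype(bool), "gene_id"]) & universe_genes,
        "cellage": set(genes.loc[genes["cellage"].astype(bool), "gene_id"]) & universe_genes,
        "hallmark_go": set(genes.loc[genes["go_terms"].notna() & (genes["go_terms"] != ""),
                                     "gene_id"]) & universe_genes,
    }
    for name, ref in ref_sets.items():
        if not ref or not target_ids:
            continue
        er = enrichment_test(target_ids, ref, universe_genes,
                             target_name="multi_trait_targets", reference_name=name)
        enrich_rows.append(dataclasses.asdict(er))
    enrichment = pd.DataFrame(enrich_rows, columns=list(io.SCHEMAS["enrichment"]))

    summary = dict(
        n_studies=int(len(tables["studies"])),
        n_nodes=int(len(nodes)),
        n_edges=int(len(edges)),
        n_clusters=len(clusters),
        n_singletons=len(singletons),
        n_single_trait_clusters=sum(1 for c in clusters if c.category == "single_trait"),
        n_multi_trait_clusters=sum(1 for c in clusters if c.category == "multi_trait"),
        n_trait_pairs=int(len(overlap)),
        n_significant_pairs=int(overlap["significant"].sum()) if len(overlap) else 0,
        n_linked_genes=len(linked),
        targets=summarize_targets(profiles),
    )
    return PipelineResult(nodes=nodes, tags=tags_out, tag_sets=tag_sets,
                          coloc=coloc_df, clusters=clusters,
                          singletons=singletons, edges=edges,
                          trait_overlap=overlap, locus_genes=locus_genes,
                          cluster_gene_sets=cluster_gene_sets,
                          profiles=profiles, linked_genes=linked,
                          enrichment=enrichment, summary=summary,
                          rejections=rejections)


def _profiles_table(result: PipelineResult) -> pd.DataFrame:
    rows = []
    for p in result.profiles:
        rows.append(dict(
            gene_id=p.gene_id, symbol=p.symbol, n_clusters=p.n_clusters,
            cluster_ids=";".join(str(c) for c in p.cluster_ids),
            traits=";".join(sorted(p.traits)), best_l2g=p.best_l2g,
            qtl_support=p.qtl_support, genage=p.genage, cellage=p.cellage,
            hallmarks=";".join(sorted(p.hallmarks)),
            sm_category=p.sm_category, ab_category=p.ab_category,
            protac_category=p.protac_category, probe_quality=p.probe_quality,
            tier=p.tier))
    return pd.DataFrame(rows, columns=list(io.SCHEMAS["targets"]))


def run_pipeline(input_dir: str | Path, output_dir: str | Path,
                 config: RunConfig | None = None) -> dict:
    """File-level pipeline: read the TSV bundle, run all stages, write
    every interface table plus summary.json and manifest.json. Returns
    the manifest."""
    config = config or RunConfig()
    config.validate()
    input_dir, output_dir = Path(input_dir), Path(output_dir)
    tables = {}
    for name in ("studies", "associations", "tags", "sumstats", "l2g", "genes"):
        path = input_dir / f"{name}.tsv"
        if name == "sumstats" and not path.exists():
            continue
        tables[name] = io.read_tsv(path, schema=name)
    result = analyse_bundle(tables, config)

    output_dir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(result.nodes, output_dir / "nodes.tsv")
    io.write_tsv(result.tags, output_dir / "tags.tsv")
    io.write_tsv(result.coloc, output_dir / "coloc.tsv")
    io.write_tsv(result.edges, output_dir / "edges.tsv")
    cl_rows = [dict(cluster_id=c.cluster_id, node_id=n,
                    community=c.communities[n],
                    trait=result.nodes.set_index("node_id").loc[n, "trait"])
               for c in result.clusters for n in c.nodes]
    io.write_tsv(pd.DataFrame(cl_rows, columns=list(io.SCHEMAS["clusters"])),
                 output_dir / "clusters.tsv")
    node_trait = dict(zip(result.nodes["node_id"], result.nodes["trait"]))
    io.write_tsv(pd.DataFrame(
        [dict(node_id=s, trait=node_trait[s]) for s in result.singletons],
        columns=list(io.SCHEMAS["singletons"])), output_dir / "singletons.tsv")
    io.write_tsv(result.trait_overlap, output_dir / "trait_overlap.tsv")
    io.write_tsv(result.enrichment, output_dir / "enrichment.tsv")
    io.write_tsv(_profiles_table(result), output_dir / "targets.tsv")
    io.write_tsv(result.rejections, output_dir / "rejections.tsv")
    io.write_json(result.summary, output_dir / "summary.json")

    from . import __version__
    manifest = dict(
        config=config.to_dict(),
        seed=config.seed,
        version=__version__,
        inputs={f.name: io.sha256_file(f)
                for f in sorted(input_dir.glob("*.tsv"))},
        row_counts=dict(
            nodes=int(len(result.nodes)), tags=int(len(result.tags)),
            coloc=int(len(result.coloc)), edges=int(len(result.edges)),
            clusters=len(result.clusters), singletons=len(result.singletons),
            trait_overlap=int(len(result.trait_overlap)),
            targets=len(result.profiles)),
        summary=result.summary,
    )
    io.write_json(manifest, output_dir / "manifest.json")
    log.info("[report] outputs written to %s", output_dir)
    return manifest
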