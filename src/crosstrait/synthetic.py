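"""Synthetic GWAS fixtures with planted cross-trait sharing structure.

The generator emulates the study design the pipeline is built for:
multiple GWAS per trait, genome-wide significant lead variants
(p < 5e-8), LD-correlated variants within well-separated loci on one
synthetic chromosome, full summary statistics available for only a
fraction (~10%) of studies, and locus-to-gene tables that concentrate
score mass on one true causal gene per locus. Every planted signal is
recorded in a truth table so downstream clustering, overlap testing and
gene mapping can be scored against known ground truth.

Associations are drawn at the z-score level: for a study of size n and a
planted causal variant c with per-allele effect b, the window's z vector

    z = sqrt(n) * b * r[:, c] + eps,     eps ~ N(0, R)

where R is the LD correlation matrix, so the expected lead z is
sqrt(n) * b at the causal variant and decays with LD. Betas and standard
errors follow as beta = z / sqrt(n), se = 1 / sqrt(n).
"""

from __future__ import annotations

import importlib.resources
import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as _st

from . import io

__all__ = [
    "LDMatrix",
    "TruthConfig",
    "SimulatedBundle",
    "simulate_ld_matrix",
    "block_ld_matrix",
    "simulate_bundle",
    "simulate_l2g",
    "make_truth_config",
    "make_null_pair_config",
]

CHROM = "chrS"
LOCUS_START = 1_000_000
LOCUS_SPACING = 3_000_000  # keeps loci > 2 Mb apart for any realistic width
VARIANT_SPACING = 1_000
GWAS_P_MAX = 5e-8

HALLMARKS = (
    "genomic_instability", "telomere_attrition", "epigenetic_alterations",
    "loss_of_proteostasis", "deregulated_nutrient_sensing",
    "mitochondrial_dysfunction", "cellular_senescence",
    "stem_cell_exhaustion", "altered_intercellular_communication",
)


def hallmark_go_map() -> pd.DataFrame:
    """The bundled (editable) GO biological-process -> hallmark mapping."""
    ref = importlib.resources.files("crosstrait.data") / "hallmark_go_map.tsv"
    with importlib.resources.as_file(ref) as p:
        return pd.read_csv(p, sep="\t", dtype=str)


@dataclass(frozen=True)
class LDMatrix:
    """Ordered variant ids plus their pairwise Pearson correlation matrix."""

    variants: tuple[str, ...]
    r: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.r, dtype=float)
        if r.shape != (len(self.variants), len(self.variants)):
            raise ValueError("correlation matrix shape does not match variant list")
        object.__setattr__(self, "r", r)

    def validate(self, psd_tol: float = 1e-9) -> None:
        r = self.r
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=1e-12):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(r < -1 - 1e-12) or np.any(r > 1 + 1e-12):
            raise ValueError("LD entries outside [-1, 1]")
        if np.linalg.eigvalsh(r).min() < -psd_tol:
            raise ValueError("LD matrix is not positive semi-definite")

    def index(self, variant: str) -> int:
        return self.variants.index(variant)

    def r2(self, a: str, b: str) -> float:
        return float(self.r[self.index(a), self.index(b)] ** 2)

    def relabel(self, variants: tuple[str, ...]) -> "LDMatrix":
        return LDMatrix(tuple(variants), self.r)


def _default_variant_names(n: int) -> tuple[str, ...]:
    return tuple(f"v{i}" for i in range(n))


def simulate_ld_matrix(n_variants: int, rho: float, seed: int = 0,
                       variants: tuple[str, ...] | None = None) -> LDMatrix:
    """AR(1) LD: r[i, j] = rho^|i - j|. Deterministic given its arguments.

    An autoregressive decay is an analytically transparent stand-in for
    reference-panel LD: tag-set sizes under an r^2 cut-off follow directly
    from rho.
    """
    if not (0 <= rho < 1):
        raise ValueError(f"rho must be in [0, 1), got {rho}")
    idx = np.arange(n_variants)
    r = rho ** np.abs(idx[:, None] - idx[None, :])
    return LDMatrix(variants or _default_variant_names(n_variants), r)


def block_ld_matrix(n_variants: int, r2_within: float,
                    variants: tuple[str, ...] | None = None) -> LDMatrix:
    """Uniform-block LD: r^2 = r2_within for every distinct pair in the block."""
    if not (0 <= r2_within <= 1):
        raise ValueError("r2_within must be in [0, 1]")
    r = np.full((n_variants, n_variants), float(np.sqrt(r2_within)))
    np.fill_diagonal(r, 1.0)
    return LDMatrix(variants or _default_variant_names(n_variants), r)


@dataclass(frozen=True)
class TruthConfig:
    """Ground-truth design of a simulated bundle.

    ``sharing`` plants the signals: each entry ``(locus, causal_index,
    traits)`` puts one causal variant at ``causal_index`` of ``locus``,
    associated with every listed trait. ``singleton_rate`` is the
    probability that a planted signal surfaces in exactly one study
    (emulating single-GWAS hits); ``sumstats_fraction`` is the share of
    studies carrying full summary statistics.
    """

    n_traits: int
    studies_per_trait: int | tuple[int, int]
    n_loci: int
    variants_per_locus: int
    sharing: tuple[tuple[int, int, frozenset[int]], ...]
    ld_decay_rho: float = 0.9
    effect_size: float = 0.05
    sample_size: int = 50_000
    sumstats_fraction: float = 0.1
    singleton_rate: float = 0.1
    seed: int = 0
    ld_kind: str = "ar1"          # "ar1" | "block"
    block_r2: float = 0.8         # used when ld_kind == "block"
    score_true: float = 0.9       # L2G score centre for the true gene
    score_noise: float = 0.05
    noncoding_rate: float = 0.025  # chance a planted true gene is non-coding
    max_resample: int = 20

    def validate(self) -> None:
        if not (0 <= self.ld_decay_rho < 1):
            raise ValueError("ld_decay_rho must be in [0, 1)")
        for frac, name in ((self.sumstats_fraction, "sumstats_fraction"),
                           (self.singleton_rate, "singleton_rate")):
            if not (0 <= frac <= 1):
                raise ValueError(f"{name} must be in [0, 1]")
        if not self.sharing:
            raise ValueError("sharing must plant at least one signal")
        for locus, cv, traits in self.sharing:
            if not (0 <= locus < self.n_loci):
                raise ValueError(f"sharing references undefined locus {locus}")
            if not (0 <= cv < self.variants_per_locus):
                raise ValueError(f"sharing references undefined variant index {cv}")
            if not traits:
                raise ValueError("sharing entry with empty trait set")
            if any(t < 0 or t >= self.n_traits for t in traits):
                raise ValueError(f"sharing references undefined trait in {sorted(traits)}")


@dataclass
class SimulatedBundle:
    """All pipeline input tables plus the planted truth labels."""

    studies: pd.DataFrame
    associations: pd.DataFrame
    tags: pd.DataFrame
    sumstats: pd.DataFrame
    l2g: pd.DataFrame
    genes: pd.DataFrame
    truth: pd.DataFrame
    config: TruthConfig | None = None

    TABLES = ("studies", "associations", "tags", "sumstats", "l2g", "genes", "truth")

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        for name in self.TABLES:
            io.write_tsv(getattr(self, name), directory / f"{name}.tsv")

    @classmethod
    def read(cls, directory: str | Path) -> "SimulatedBundle":
        directory = Path(directory)
        return cls(**{name: io.read_tsv(directory / f"{name}.tsv", schema=name)
                      for name in cls.TABLES})


def _locus_positions(locus: int, m: int) -> np.ndarray:
    start = LOCUS_START + locus * LOCUS_SPACING
    return start + np.arange(m) * VARIANT_SPACING


def _locus_variants(locus: int, m: int) -> tuple[str, ...]:
    return tuple(f"{CHROM}_{p}_A_G" for p in _locus_positions(locus, m))


def node_id(study_id: str, lead: str) -> str:
    return f"{study_id}::{lead}"


def _locus_ld(cfg: TruthConfig) -> LDMatrix:
    if cfg.ld_kind == "ar1":
        return simulate_ld_matrix(cfg.variants_per_locus, cfg.ld_decay_rho)
    if cfg.ld_kind == "block":
        return block_ld_matrix(cfg.variants_per_locus, cfg.block_r2)
    raise ValueError(f"unknown ld_kind {cfg.ld_kind!r}")


def simulate_bundle(config: TruthConfig) -> SimulatedBundle:
    """Draw one bundle of GWAS tables under the planted-truth design.

    Reproducible: identical configs (including the seed) give identical
    tables. Leads that fail genome-wide significance are redrawn up to
    ``max_resample`` times and then dropped.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    traits = [f"TRAIT_{i:02d}" for i in range(cfg.n_traits)]
    studies_of: dict[int, list[str]] = {}
    study_rows = []
    counter = itertools.count(1)
    for t in range(cfg.n_traits):
        if isinstance(cfg.studies_per_trait, tuple):
            lo, hi = cfg.studies_per_trait
            k = int(rng.integers(lo, hi + 1))
        else:
            k = cfg.studies_per_trait
        ids = [f"GCST{next(counter):06d}" for _ in range(k)]
        studies_of[t] = ids
        for sid in ids:
            study_rows.append(dict(study_id=sid, trait=traits[t],
                                   reported_trait=traits[t].lower(),
                                   n_total=cfg.sample_size, n_cases=np.nan,
                                   ancestry="European", has_sumstats=False))
    studies = pd.DataFrame(study_rows)
    n_ss = int(round(cfg.sumstats_fraction * len(studies)))
    if n_ss > 0:
        chosen = rng.choice(studies["study_id"].to_numpy(), size=n_ss, replace=False)
        studies.loc[studies["study_id"].isin(chosen), "has_sumstats"] = True
    has_ss = dict(zip(studies["study_id"], studies["has_sumstats"]))

    ld = _locus_ld(cfg)
    # tiny jitter keeps Cholesky happy for rho -> 1 or uniform blocks
    chol = np.linalg.cholesky(ld.r + 1e-10 * np.eye(cfg.variants_per_locus))
    sqrt_n = np.sqrt(cfg.sample_size)
    se = 1.0 / sqrt_n

    assoc_rows, tag_rows, ss_rows, truth_rows = [], [], [], []
    for sig_idx, (locus, cv, trait_set) in enumerate(cfg.sharing):
        sig_id = f"SIG{sig_idx:03d}"
        positions = _locus_positions(locus, cfg.variants_per_locus)
        variants = _locus_variants(locus, cfg.variants_per_locus)
        mean = sqrt_n * cfg.effect_size * ld.r[:, cv]
        carriers = [(t, sid) for t in sorted(trait_set) for sid in studies_of[t]]
        if len(carriers) > 1 and rng.random() < cfg.singleton_rate:
            carriers = [carriers[int(rng.integers(len(carriers)))]]
        for t, sid in carriers:
            z = None
            for _ in range(cfg.max_resample + 1):
                cand = mean + chol @ rng.standard_normal(cfg.variants_per_locus)
                lead_idx = int(np.argmax(np.abs(cand)))
                pval = float(2.0 * _st.norm.sf(abs(cand[lead_idx])))
                if pval < GWAS_P_MAX:
                    z = cand
                    break
            if z is None:
                continue  # signal too weak in this study; dropped
            lead = variants[lead_idx]
            assoc_rows.append(dict(
                study_id=sid, lead_variant_id=lead, chrom=CHROM,
                position=int(positions[lead_idx]), pvalue=pval,
                beta=float(z[lead_idx] * se), se=se))
            truth_rows.append(dict(
                node_id=node_id(sid, lead), study_id=sid, lead_variant_id=lead,
                signal_id=sig_id, locus_index=locus, causal_variant_id=variants[cv],
                trait=traits[t], n_planted_traits=len(trait_set),
                true_gene_id=_true_gene_id(locus)))
            r2_lead = ld.r[lead_idx] ** 2
            for j in np.flatnonzero(r2_lead >= 0.7):
                tag_rows.append(dict(
                    study_id=sid, lead_variant_id=lead, tag_variant_id=variants[j],
                    r2=float(r2_lead[j]), posterior_prob=np.nan, source="ld"))
            if has_ss[sid]:
                for j, v in enumerate(variants):
                    ss_rows.append(dict(
                        study_id=sid, lead_variant_id=lead, variant_id=v,
                        position=int(positions[j]), beta=float(z[j] * se), se=se))

    associations = pd.DataFrame(
        assoc_rows, columns=list(io.SCHEMAS["associations"]))
    tags = pd.DataFrame(tag_rows, columns=list(io.SCHEMAS["tags"]))
    sumstats = pd.DataFrame(ss_rows, columns=list(io.SCHEMAS["sumstats"]))
    truth = pd.DataFrame(truth_rows, columns=list(io.SCHEMAS["truth"]))

    genes = _simulate_genes(cfg, np.random.default_rng([cfg.seed, 11]))
    l2g = simulate_l2g(associations, cfg.score_true, cfg.score_noise,
                       seed=[cfg.seed, 13], variants_per_locus=cfg.variants_per_locus)
    return SimulatedBundle(studies, associations, tags, sumstats, l2g, genes,
                           truth, config=cfg)


def _true_gene_id(locus: int) -> str:
    return f"ENSG{locus:05d}"


def _decoy_gene_ids(locus: int, n: int = 3) -> list[str]:
    return [f"ENSG{locus:05d}D{k}" for k in range(1, n + 1)]


def locus_of_variant(variant_id: str) -> int:
    """Recover the locus index encoded in a synthetic variant id."""
    pos = int(variant_id.split("_")[1])
    return (pos - LOCUS_START) // LOCUS_SPACING


def simulate_l2g(associations: pd.DataFrame, score_true: float = 0.9,
                 score_noise: float = 0.05, seed=0,
                 variants_per_locus: int | None = None) -> pd.DataFrame:
    """L2G table concentrating score mass on the true gene at each locus.

    For every distinct (study, lead) the designated true gene of its locus
    gets a score drawn from N(score_true, score_noise) clipped to [0, 1];
    decoy genes get scores uniform on [0, min(0.45, score_true)), i.e.
    strictly below the true-gene centre.
    """
    if not (0 <= score_true <= 1):
        raise ValueError("score_true must be in [0, 1]")
    if score_noise < 0:
        raise ValueError("score_noise must be non-negative")
    rng = np.random.default_rng(seed)
    decoy_max = min(0.45, score_true) if score_true > 0 else 0.0
    rows = []
    pairs = associations[["study_id", "lead_variant_id"]].drop_duplicates()
    for sid, lead in pairs.itertuples(index=False):
        locus = locus_of_variant(lead)
        true = float(np.clip(rng.normal(score_true, score_noise), 0.0, 1.0))
        rows.append(dict(study_id=sid, lead_variant_id=lead,
                         gene_id=_true_gene_id(locus), score=true))
        for g in _decoy_gene_ids(locus):
            rows.append(dict(study_id=sid, lead_variant_id=lead, gene_id=g,
                             score=float(rng.uniform(0.0, decoy_max))))
    return pd.DataFrame(rows, columns=list(io.SCHEMAS["l2g"]))


# annotation base rates for the simulated gene universe; chosen to echo the
# composition of real target annotation tables (a minority with clinical
# drugs, ~1/5 with ligand-binding evidence, rare curated ageing genes)
_GENE_RATES = dict(
    genage=0.016, cellage=0.015, hallmark_gene=0.24, qtl_support=0.18,
    approved_drug=0.09, clinical_drug=0.05, ligand_binding=0.20,
    drugebility_known=0.5, druggable_genome=0.10,
    location_high=0.33, location_medium=0.16, signal_peptide_or_tm=0.20,
    protac_literature=0.03, ubiquitylation_site=0.6, half_life_data=0.3,
    ligand_10uM=0.3, protac_location_ok=0.6,
    probe_curated=0.04, probe_predicted=0.14,
)


def _simulate_genes(cfg: TruthConfig, rng: np.random.Generator) -> pd.DataFrame:
    go_map = hallmark_go_map()
    go_ids = go_map["go_id"].to_numpy()
    R = _GENE_RATES
    rows = []
    for locus in range(cfg.n_loci):
        for gid in [_true_gene_id(locus)] + _decoy_gene_ids(locus):
            is_true = not gid.endswith(("D1", "D2", "D3"))
            biotype = "protein_coding"
            if rng.random() < cfg.noncoding_rate:
                biotype = "lncRNA"
            go_terms = ""
            if rng.random() < R["hallmark_gene"]:
                k = int(rng.integers(1, 4))
                go_terms = ";".join(sorted(rng.choice(go_ids, size=k, replace=False)))
            u = rng.random()
            if u < R["location_high"]:
                loc = "high"
            elif u < R["location_high"] + R["location_medium"]:
                loc = "medium"
            else:
                loc = "none"
            u = rng.random()
            if u < R["probe_curated"]:
                probe = "curated"
            elif u < R["probe_curated"] + R["probe_predicted"]:
                probe = "predicted"
            else:
                probe = "none"
            rows.append(dict(
                gene_id=gid, symbol=f"GENE{locus}" + ("" if is_true else gid[-2:]),
                biotype=biotype,
                genage=bool(rng.random() < R["genage"]),
                cellage=bool(rng.random() < R["cellage"]),
                go_terms=go_terms if go_terms else np.nan,
                qtl_support=bool(rng.random() < R["qtl_support"]),
                approved_drug=bool(rng.random() < R["approved_drug"]),
                clinical_drug=bool(rng.random() < R["clinical_drug"]),
                ligand_binding=bool(rng.random() < R["ligand_binding"]),
                drugebility=(float(rng.uniform()) if rng.random() < R["drugebility_known"] else np.nan),
                druggable_genome=bool(rng.random() < R["druggable_genome"]),
                location_confidence=loc,
                signal_peptide_or_tm=bool(rng.random() < R["signal_peptide_or_tm"]),
                protac_literature=bool(rng.random() < R["protac_literature"]),
                ubiquitylation_site=bool(rng.random() < R["ubiquitylation_site"]),
                half_life_data=bool(rng.random() < R["half_life_data"]),
                ligand_10uM=bool(rng.random() < R["ligand_10uM"]),
                protac_location_ok=bool(rng.random() < R["protac_location_ok"]),
                probe_quality=probe,
            ))
    return pd.DataFrame(rows, columns=list(io.SCHEMAS["genes"]))


def make_truth_config(
    n_traits: int = 10,
    studies_per_trait: int | tuple[int, int] = 4,
    n_loci: int = 60,
    n_shared: int = 15,
    n_shared_pairs: int = 3,
    variants_per_locus: int = 10,
    seed: int = 0,
    **overrides,
) -> TruthConfig:
    """Build the standard planted-sharing design.

    The first ``n_shared`` loci carry signals shared by one of
    ``n_shared_pairs`` randomly chosen trait pairs (shared loci split
    evenly among the pairs); the remaining loci carry single-trait signals
    assigned round-robin. The causal variant sits mid-locus.
    """
    if n_shared > n_loci:
        raise ValueError("n_shared cannot exceed n_loci")
    rng = np.random.default_rng([seed, 29])
    all_pairs = list(itertools.combinations(range(n_traits), 2))
    pick = rng.choice(len(all_pairs), size=n_shared_pairs, replace=False)
    shared_pairs = [all_pairs[i] for i in sorted(pick)]
    cv = variants_per_locus // 2
    sharing = []
    for locus in range(n_shared):
        pair = shared_pairs[locus % n_shared_pairs]
        sharing.append((locus, cv, frozenset(pair)))
    for locus in range(n_shared, n_loci):
        sharing.append((locus, cv, frozenset({(locus - n_shared) % n_traits})))
    return TruthConfig(
        n_traits=n_traits, studies_per_trait=studies_per_trait, n_loci=n_loci,
        variants_per_locus=variants_per_locus, sharing=tuple(sharing),
        seed=seed, **overrides)


def make_null_pair_config(
    n_loci_per_trait: int = 8,
    studies_per_trait: int = 3,
    n_filler_traits: int = 2,
    variants_per_locus: int = 10,
    seed: int = 0,
    **overrides,
) -> TruthConfig:
    """Null design for overlap-test calibration: traits 0 and 1 never share
    a causal variant.

    Traits 0 and 1 each carry a signal at the *same* first
    ``n_loci_per_trait`` loci but at causal variants far apart within the
    locus, so any cluster joining them is a chance artefact of tag-set
    overlap, not a planted signal. Filler traits occupy their own loci to
    give the contingency table a non-degenerate "neither" cell.
    """
    cv_a, cv_b = 2, variants_per_locus - 3
    if cv_b <= cv_a:
        raise ValueError("variants_per_locus too small to separate the null causal variants")
    sharing = []
    for locus in range(n_loci_per_trait):
        sharing.append((locus, cv_a, frozenset({0})))
        sharing.append((locus, cv_b, frozenset({1})))
    n_loci = n_loci_per_trait
    for f in range(n_filler_traits):
        for k in range(n_loci_per_trait):
            sharing.append((n_loci, variants_per_locus // 2, frozenset({2 + f})))
            n_loci += 1
    defaults = dict(sumstats_fraction=0.0, singleton_rate=0.0)
    defaults.update(overrides)
    return TruthConfig(
        n_traits=2 + n_filler_traits, studies_per_trait=studies_per_trait,
        n_loci=n_loci, variants_per_locus=variants_per_locus,
        sharing=tuple(sharing), seed=seed, **defaults)
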