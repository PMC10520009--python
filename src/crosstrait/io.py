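"""TSV readers/writers for the pipeline's tabular interfaces.

All tables are UTF-8 TSV with a header row; missing values are written as
a single ``.``. Booleans are serialised as ``True``/``False`` and parsed
back on read using per-table schemas, so a write/read round trip is
lossless.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import pandas as pd

NULL = "."

#: column -> dtype ("str", "int", "float", "bool") per table name
SCHEMAS: dict[str, dict[str, str]] = {
    "studies": {
        "study_id": "str", "trait": "str", "reported_trait": "str",
        "n_total": "int", "n_cases": "float", "ancestry": "str",
        "has_sumstats": "bool",
    },
    "associations": {
        "study_id": "str", "lead_variant_id": "str", "chrom": "str",
        "position": "int", "pvalue": "float", "beta": "float", "se": "float",
    },
    "tags": {
        "study_id": "str", "lead_variant_id": "str", "tag_variant_id": "str",
        "r2": "float", "posterior_prob": "float", "source": "str",
    },
    "sumstats": {
        "study_id": "str", "lead_variant_id": "str", "variant_id": "str",
        "position": "int", "beta": "float", "se": "float",
    },
    "l2g": {
        "study_id": "str", "lead_variant_id": "str", "gene_id": "str",
        "score": "float",
    },
    "genes": {
        "gene_id": "str", "symbol": "str", "biotype": "str",
        "genage": "bool", "cellage": "bool", "go_terms": "str",
        "qtl_support": "bool",
        "approved_drug": "bool", "clinical_drug": "bool",
        "ligand_binding": "bool", "drugebility": "float",
        "druggable_genome": "bool", "location_confidence": "str",
        "signal_peptide_or_tm": "bool", "protac_literature": "bool",
        "ubiquitylation_site": "bool", "half_life_data": "bool",
        "ligand_10uM": "bool", "protac_location_ok": "bool",
        "probe_quality": "str",
    },
    "truth": {
        "node_id": "str", "study_id": "str", "lead_variant_id": "str",
        "signal_id": "str", "locus_index": "int", "causal_variant_id": "str",
        "trait": "str", "n_planted_traits": "int", "true_gene_id": "str",
    },
    "nodes": {
        "node_id": "str", "study_id": "str", "lead_variant_id": "str",
        "chrom": "str", "position": "int", "pvalue": "float",
        "trait": "str", "has_sumstats": "bool",
    },
    "edges": {
        "node_a": "str", "node_b": "str", "kind": "str", "evidence": "float",
    },
    "clusters": {
        "cluster_id": "int", "node_id": "str", "community": "int",
        "trait": "str",
    },
    "singletons": {"node_id": "str", "trait": "str"},
    "coloc": {
        "study_a": "str", "lead_a": "str", "study_b": "str", "lead_b": "str",
        "pp_h0": "float", "pp_h1": "float", "pp_h2": "float",
        "pp_h3": "float", "pp_h4": "float", "n_shared": "int",
    },
    "trait_overlap": {
        "trait_a": "str", "trait_b": "str", "a": "int", "b": "int",
        "c": "int", "d": "int", "odds_ratio": "float", "p": "float",
        "p_adj": "float", "significant": "bool",
    },
    "enrichment": {
        "target_set": "str", "reference_set": "str", "universe_size": "int",
        "reference_size": "int", "target_size": "int", "overlap": "int",
        "p": "float",
    },
    "targets": {
        "gene_id": "str", "symbol": "str", "n_clusters": "int",
        "cluster_ids": "str", "traits": "str", "best_l2g": "float",
        "qtl_support": "bool", "genage": "bool", "cellage": "bool",
        "hallmarks": "str", "sm_category": "str", "ab_category": "str",
        "protac_category": "str", "probe_quality": "str", "tier": "str",
    },
    "rejections": {
        "table": "str", "key": "str", "reason": "str",
    },
}


def write_tsv(df: pd.DataFrame, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, na_rep=NULL)


def read_tsv(path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Read a pipeline TSV; ``schema`` names an entry in :data:`SCHEMAS`."""
    df = pd.read_csv(path, sep="\t", na_values=[NULL], keep_default_na=False, dtype=str)
    if schema is not None:
        spec = SCHEMAS[schema]
        missing = [c for c in spec if c not in df.columns]
        if missing:
            raise ValueError(f"{path}: missing required column(s) {missing} for table {schema!r}")
        for col, kind in spec.items():
            if kind == "int":
                df[col] = df[col].astype("int64")
            elif kind == "float":
                df[col] = df[col].astype(float)
            elif kind == "bool":
                df[col] = df[col].map({"True": True, "False": False}).astype(bool)
    return df


def write_json(obj, path: str | Path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_json(path: str | Path):
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()
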