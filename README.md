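# crosstrait

Cross-trait GWAS signal clustering, colocalisation, and drug-target
annotation.

Genome-wide association studies of related traits often implicate the
same locus, but a shared *locus* is not a shared *signal*: two
associations only reflect common biology if they plausibly share a
causal variant. `crosstrait` takes per-study GWAS lead variants for a
set of traits (for example, a curated panel of age-related diseases and
biomarkers), decides which pairs of associations may share a causal
variant, groups them into independent multi-trait genetic signals,
quantifies which trait pairs overlap more than chance predicts, and maps
the multi-trait signals to candidate causal genes annotated with ageing
gene-set membership and drug-target tractability. It is aimed at
target-identification and statistical-genetics analysts who want this
whole chain as a reusable, testable pipeline rather than a one-off
script, and it ships a synthetic-data generator with planted ground
truth so every stage can be validated end to end without any downloads.

## The method

**Lead-to-tag expansion.** Each association's lead variant is expanded
to the set of variants that could be the causal one. With full summary
statistics, single-causal fine-mapping uses Wakefield's approximate
Bayes factor per variant,

    log ABF = 1/2 [ ln( V / (V + W²) ) + z² · W² / (V + W²) ],
    V = se²,  z = β/se,

normalised over a ±500 kb window to posterior probabilities
PP_j = ABF_j / Σ_k ABF_k; variants with PP > 0.1% are retained. Without
summary statistics, PICS estimates posteriors from the lead's −log₁₀ p
and LD to the lead, or plain LD expansion keeps all variants with
r² ≥ 0.7.

**Colocalisation.** For a pair of loci with summary statistics on both
sides, an enumeration-based posterior over five hypotheses (H0 neither
trait associated; H1/H2 one trait only; H3 two distinct causal variants;
H4 one shared causal variant) is computed from the per-variant log ABFs
with per-SNP priors p1 = p2 = 10⁻⁴, p12 = 10⁻⁵. H4 ≥ 0.8 calls the pair
the same signal.

**Signal graph.** Nodes are (study, lead variant) associations with
p < 5 × 10⁻⁸ from studies with n ≥ 2000. Nodes on the same chromosome
with leads < 500 kb apart are joined by an edge when colocalisation says
so (both studies with summary statistics) or when their tag sets share
at least one variant. Maximal connected components of size ≥ 2 are the
independent signals; degree-zero nodes are singleton signals; Louvain
community detection flags possible substructure inside a cluster.

**Overlap statistics.** For every trait pair, a 2×2 table over the
signal universe (signals with both traits / one / the other / neither)
is tested with a one-sided Fisher exact test; Benjamini–Hochberg
corrects across all C(T, 2) pairs. Gene-set overlaps use the one-sided
hypergeometric tail.

**Gene mapping and tractability.** Each locus is assigned the gene with
the highest locus-to-gene (L2G) score if that score is ≥ 0.5.
Protein-coding genes linked to ≥ 1 multi-trait cluster form the target
set, flagged for GenAge/CellAge membership and hallmark-of-ageing GO
annotation, and classified for small-molecule, antibody and PROTAC
tractability into a three-tier partition (clinical precedence /
tractable evidence / no evidence).

## Worked example

```python
import crosstrait as ct

cfg = ct.make_truth_config(seed=1)          # 10 traits, 40 studies, 60 planted
bundle = ct.simulate_bundle(cfg)            # signals, 15 shared by trait pairs
res = ct.analyse_bundle(bundle, ct.RunConfig(seed=1))

s = res.summary
print(s["n_nodes"], s["n_clusters"], s["n_singletons"],
      s["n_multi_trait_clusters"])

truth = dict(zip(bundle.truth.node_id, bundle.truth.signal_id))
print(ct.cluster_recovery_ari(truth, res.clusters, res.singletons))
print(res.trait_overlap.nsmallest(2, "p")[
    ["trait_a", "trait_b", "a", "p", "p_adj"]])
```

prints

```
284 56 4 14
1.0
     trait_a   trait_b  a         p     p_adj
33  TRAIT_06  TRAIT_08  5  0.002251  0.101314
7   TRAIT_00  TRAIT_07  5  0.025433  0.572234
```

The 284 genome-wide-significant associations collapse into 56
multi-study clusters plus 4 singletons — exactly the 60 planted signals
(adjusted Rand index 1.0) — of which 14 involve more than one trait.
The two most-overlapping trait pairs are planted sharing pairs: each
shares a = 5 independent signals, far more than any non-planted pair
(which share none), though at this problem size the adjusted p-values do
not reach 0.05.

The same pipeline runs from the shell on TSV bundles:

```sh
crosstrait simulate --out bundle/ --seed 1
crosstrait run-all --in bundle/ --out results/ --seed 1
```

writing `nodes/edges/clusters/singletons/coloc/trait_overlap/targets
.tsv`, `summary.json` and a reproducibility manifest. Real data can be
supplied in the same six input TSV schemas (`studies`, `associations`,
`tags`, `sumstats`, `l2g`, `genes`; see `crosstrait/io.py` for the
column lists) — variant ids are `chrom_pos_ref_alt`, nulls are `.`.

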