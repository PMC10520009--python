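# Methods

## Model and assumptions

The pipeline treats each GWAS association as a (study, lead variant)
node and asks a single question pairwise: could these two associations
be driven by the same causal variant? Everything downstream — cluster
counts, trait-overlap tests, gene mapping — is built on the answer, so
the assumptions live mostly in that step:

* **Single causal variant per window.** Fine-mapping (Wakefield ABF and
  PICS) and colocalisation both assume exactly one causal variant per
  trait per ±500 kb window. Conditional analysis to split multiple
  signals in one window is out of scope; a region with two genuine
  signals for one trait will be treated as one, which biases clusters
  toward merging (deliberately inclusive, as is the tag-overlap rule).
* **Harmonised variant ids.** Variants are compared by string id
  (`chrom_pos_ref_alt`); ids are assumed pre-harmonised, so no strand
  flipping or allele alignment is attempted.
* **Distance gate before evidence.** Two nodes can only be linked when
  their leads are on the same chromosome and strictly less than 500 kb
  apart. Cross-chromosome edges never occur.
* **Coloc is authoritative for summary-statistics pairs.** When both
  studies carry summary statistics and the pair is colocalisable, the
  H4 ≥ 0.8 verdict decides the edge; tag overlap cannot rescue a pair
  that colocalisation rejects. When the windows share no variants the
  pair falls back to tag overlap rather than being dropped. The
  alternative (tag overlap as a floor under coloc) is a one-line change
  in `build_graph` but is not exposed as a switch because it changes the
  meaning of the H4 threshold.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| `r2_min` | 0.7 | LD-expansion floor, inclusive (r² with the lead) |
| `pp_min` | 0.001 | credible-set retention floor, exclusive (posterior probability) |
| `h4_min` | 0.8 | shared-causal posterior needed for a coloc edge, inclusive |
| `lead_distance_bp` | 500 000 | strict upper bound on lead separation for any edge; also the fine-mapping window half-width |
| `l2g_min` | 0.5 | locus-to-gene score floor, inclusive |
| `gwas_p_max` | 5 × 10⁻⁸ | genome-wide significance, strict upper bound |
| `min_n` | 2000 | study inclusion floor on cases (case-control) or total n |
| `W` (`w_quant` / `w_binary`) | 0.15 / 0.2 | prior SD of the effect size in the ABF; the conventional single-causal values for quantitative / binary traits |
| `p1, p2, p12` | 10⁻⁴, 10⁻⁴, 10⁻⁵ | per-SNP coloc priors (standard enumeration defaults) |
| `alpha` | 0.05 | significance level on BH-adjusted overlap p-values |

Boundary semantics are deliberate and tested: the r², H4, L2G and
drugEBIlity thresholds are inclusive; the GWAS p and lead-distance
thresholds are strict.

Thresholded credible sets are **not** re-normalised: a variant retained
at PP > 0.1% keeps its window-normalised posterior, and downstream
overlap uses the retained variant set only. `renormalise_pp=True`
switches this off.

The PICS parametrisation is fixed as mean r²·S and standard deviation
max(10⁻⁴, √(1 − |r|³·²)·√S / 2) where S is the lead's −log₁₀ p. The
exact constants in production fine-mapping pipelines vary; the whole
parametrisation is isolated in `pics_posteriors` for easy substitution.

## What the synthetic generator emulates — and what it does not

`simulate_bundle` draws association z-scores directly:
z = √n·β·r[:,c] + ε with ε ~ N(0, R), R the locus LD matrix, so the
expected lead z is √n·β at the causal variant. Defaults are chosen to
mirror the study design the pipeline targets: 10 traits × 4 studies,
60 well-separated loci (3 Mb spacing on one synthetic chromosome,
10 variants 1 kb apart per locus), β = 0.05 with n = 50 000 per study
(√n·β ≈ 11, comfortably genome-wide significant), AR(1) LD with
ρ = 0.9, summary statistics for 10% of studies, a 10% chance that a
planted signal surfaces in only one study (emulating single-GWAS hits),
and L2G tables whose true gene scores centre on 0.9 (σ = 0.05) with
decoys below 0.45. Gene annotation flags (ageing sets, tractability
evidence) are Bernoulli draws at base rates echoing the composition of
real target-annotation tables; they are listed in
`synthetic._GENE_RATES`.

Not emulated: real human LD panels and allele frequencies, multi-ancestry
LD weighting, liability-scale case-control effects (case-control studies
enter only through an effective sample size), study heterogeneity beyond
the n ≥ 2000 filter, and genuinely overlapping loci (loci are spaced so
no spurious < 500 kb adjacency exists unless a design plants two signals
at one locus). Passing recovery tests therefore show that the pipeline's
logic is correct under its own assumptions — clean LD, one causal
variant per signal, strong effects — not that it is robust to the
messiness of real GWAS data, where low-recombination regions and weak
effects will blur cluster boundaries.

Two ready-made designs drive calibration (`crosstrait.calibration`):

* **Planted sharing** (`make_truth_config`): 15 of 60 loci are shared,
  split evenly across 3 randomly chosen trait pairs. Recovery is scored
  as the adjusted Rand index between the recovered partition (clusters +
  singletons) and the planted signal labels, and by the rank of the
  planted pairs in the overlap-test ordering.
* **Null pair** (`make_null_pair_config`): two traits carry signals at
  the *same* loci but at causal variants far apart in LD, so any edge
  between them is a chance tag collision; two filler traits populate the
  "neither" cell of the contingency table. This estimates the overlap
  test's type-I error. The Fisher test is conservative here (the
  observed rejection rate at α = 0.05 is essentially zero), which is the
  expected behaviour of an exact conditional test on sparse tables.

## Numerical choices

* All posterior computations (credible sets, coloc) run in log space via
  log-sum-exp; the H3 term uses a guarded log-difference that returns
  −∞ when the independent-causal sum does not exceed the shared-causal
  sum within rounding (degenerate single-variant windows).
* LD matrices get a 10⁻¹⁰ diagonal jitter before Cholesky so ρ → 1 and
  uniform-block designs stay factorable.
* Louvain community detection receives nodes in sorted order and a fixed
  seed, making assignments reproducible; community and cluster indices
  are ordered by smallest member node id. Ties in L2G argmax resolve to
  the lexicographically smallest gene id.
* Printed percentages round half-up (isolated in `targets.percent`),
  with one decimal used for the sub-5% ageing-set overlaps.
* BH adjustment delegates to statsmodels' step-up implementation after
  validating the input range; Fisher p-values come from the exact
  conditional (hypergeometric) tail, with the sample odds ratio a·d/b·c
  reported as +∞ when b·c = 0.

## Design decisions

* The signal universe for trait-overlap tables defaults to clusters
  **plus** singletons — every independent signal linked to a trait —
  with a clusters-only mode (`universe_mode`) since the choice is
  genuinely ambiguous and changes the "neither" cell.
* Singleton components are accounted separately from clusters (clusters
  require ≥ 2 nodes), matching how single-GWAS hits are usually
  reported.
* The "tractable evidence" tier is the union of small-molecule
  DiscoveryPrecedence/PredictedTractable and any antibody
  PredictedTractable level, minus clinical precedence; the grouping
  lives in one function (`tractability_tier`) because reasonable
  alternatives exist.
* In the file pipeline, LD tag sets arrive pre-computed in `tags.tsv`
  (as upstream GWAS portals provide them) and are filtered at `r2_min`;
  ABF fine-mapping replaces them whenever a node has summary statistics.
  PICS is available through `expand_association` (precedence
  ABF > PICS > LD) for callers who have lead p-values and LD-to-lead
  but no per-variant betas.
* The enrichment module always reports the universe size N alongside
  its hypergeometric p, because published enrichment p-values are
  frequently irreproducible precisely when N is unstated.
* The GO-to-hallmark mapping ships as a small editable TSV
  (`crosstrait/data/hallmark_go_map.tsv`) with two representative GO
  biological-process terms per hallmark; it is a default to be replaced
  by a user's own curation, not a curated resource.

## Known limitations

* One signal per window: allelic heterogeneity inflates cluster sizes.
* Tag overlap is binary (≥ k shared variants, default 1); it ignores
  how probable the shared tags are, so a marginal PICS tail variant
  counts as much as a lead.
* The overlap test conditions on the realised signal counts; it does
  not model the graph-construction uncertainty that produced them.
* Community detection is descriptive: communities are reported, not
  used to split clusters.
* At the default desk scale (60 signals, 45 trait pairs) the BH-adjusted
  overlap p-values rarely cross 0.05 even for genuinely shared pairs —
  the planted pairs are found by rank, not by significance. Detecting
  significance requires the signal counts of a full-size study.
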