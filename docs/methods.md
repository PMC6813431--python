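# Methods

## The analysis model

`crossortho` compares cell-type expression between two species through an
ortholog map rather than through joint normalisation. The two species'
RPKM values come from different genomes, annotations and libraries and are
not quantitatively equivalent, so no step ever places them on one scale:
all cross-species statements are set-level (expressed / up / down /
uniquely expressed per species, then intersected via ortholog pairs).

### Ortholog table

Input is a homology export in the Biomart dialect (one row per reference
transcript variant per pair). Processing order:

1. **Transcript deduplication** — first occurrence of each
   (reference gene, query gene) kept. Scores in Biomart exports are
   identical across a gene's transcript rows, so the choice of occurrence
   is immaterial.
2. **Relationship classification** — connected components of the bipartite
   gene graph. A component where every gene has degree 1 is one-to-one;
   degree > 1 genes on exactly one side make the component many-to-one; on
   both sides, many-to-many. The input's own homology-type column is never
   trusted. Per-species tallies count distinct genes per class; collapsing
   query redundancy (distinct query genes) makes the reference ortholog
   total ≥ the query total, as expected when one mammalian gene matches
   several fish paralogs.
3. **GOC score** — for each of the gene's ≤ 4 neighbours (2 up, 2 down on
   its chromosome), 25 points if any of the neighbour's orthologs lies in
   the partner's own 2-up/2-down window; chromosome-end genes have fewer
   candidate neighbours but the denominator stays 4, keeping the score on
   {0, 25, 50, 75, 100}.
4. **WGA score** — `100·(w·exon + (1−w)·intron)` coverage per gene, pair
   score the arithmetic mean. w defaults to 0.75 ("heavier" exon weight,
   constrained to (0.5, 1]).
5. **High-confidence call** — %ID ≥ 50 AND (GOC ≥ 75 OR WGA ≥ 75).

Design choices where the rules were genuinely open:

* **Neighbourhood membership, not mirrored position.** A neighbour matches
  if its ortholog is anywhere in the partner's window; this is the reading
  consistent with "a match of all four neighbouring genes" and with how
  synteny support is usually counted.
* **Orthologous gene order.** Windows are taken over the gene order
  restricted to genes that participate in the homology map, so
  species-unique genes interleaved in the annotation do not consume
  neighbour slots. This matches comparative-genomics practice and makes
  the score invariant to annotation completeness of non-orthologous genes.
* **Strand ignored by default.** Orientation is not part of the score's
  definition here; a `match_strand` flag adds the requirement that the
  matched ortholog lie on the neighbour's strand.
* **Missing scores fail their clause.** A pair with neither GOC nor WGA is
  never high-confidence; the conservative choice avoids inflating the
  high-confidence set.
* **All thresholds inclusive**, matching the ≥ notation of the rules.
* **Ordering ties** broken by gene id after (chromosome, start), making
  all derived orders deterministic.

### Expression calls

RPKM = count · 10⁹ / (L · N), with L the union of exon intervals across all
transcripts (from the GTF) and N the column's total mapped reads. Replicate
aggregation is the arithmetic mean.

Per-gene testing is a one-way ANOVA on log₂(RPKM + pseudocount), pseudocount
0.01 RPKM (shared with the fold-change computation, both configurable). Two
variants are used:

* **contrast test** — the cell type's replicates vs the species' reference
  hair-cell type (two groups; equivalent to a t-test), BH-adjusted within
  each contrast; feeds the up/down calls;
* **omnibus test** — across all of the species' cell types, BH-adjusted
  per gene; this is the gene-level FDR paired with the RPKM cutoff in the
  expressed-gene call. Whether the published expressed-call FDR refers to
  an expression-above-background test or to the DE test is not decidable
  from its description; the omnibus reading is implemented, and
  `use_fdr=False` gives pure RPKM-cutoff calling.

The original analysis used a proprietary workbench's "two-way ANOVA" with
unstated factors; this package deliberately substitutes the standard,
reproducible per-gene ANOVA above. The thresholds — where the scientific
content lives — are preserved exactly: expressed at mean RPKM ≥ 0.10 and
FDR ≤ 0.10; up at log₂FC ≥ +1.0, down at log₂FC < −1.0 (the asymmetric
bounds are intentional and preserved), both gated at FDR ≤ 0.10. The FDR
cutoff is a per-analysis parameter because the transcription-factor
analyses use 0.05 where the genome-wide ones use 0.10.

Degenerate-data conventions: both groups constant and equal → p = 1; groups
constant but different → p = 0; equal means with within-group variance →
p = 1 (F = 0). Benjamini–Hochberg is the step-up
`q₍ᵢ₎ = min_{j≥i} (m·p₍ⱼ₎/j)` clipped at 1, input order preserved.

### Merged table and set algebra

The merge is an inner join of both species' per-gene results onto the
ortholog table, keyed by ortholog-pair id (`ref|query`) so many-to-one
mappings survive; pairs lacking expression data in either species are
flagged, counted and excluded from every downstream set analysis. On the
merged table: exact 7-region three-set Venn partitions; common-regulated
sets (call equal in all listed populations — by default nsSC, PC, DC, each
against its species' hair-cell reference; the mammalian reference is the
inner hair cell, with outer hair cells participating only in the
unique-expression analysis); high-confidence filtering (which provably
commutes with intersection); unique expression (expressed in exactly one of
the listed cell types — the list is explicit so control tissues can be
included or excluded); and annotation overlays (TF / deafness lists, keyed
by gene id or name with a match-rate warning against id-vs-name mix-ups,
ranked by descending log₂FC with gene-id tie-break).

### Enrichment

One-sided hypergeometric upper tail P(overlap ≥ k) per gene set, BH across
the collection, sorted by (q, p, set id). The universe defaults to all
analysed ortholog pairs and is always explicit. This is a functional, not
numerical, stand-in for web GO tools, whose exact backgrounds and term
hierarchies are out of scope; an optional greedy Jaccard grouping of
result sets (overlap ≥ 0.5) is offered instead of a term-clustering tree.

## The synthetic-data generator

The generator emulates the *downstream products* of the real study — an
annotation pair, a homology export, replicate expression tables — not reads
or sequences. Defaults (all in `SimConfig`):

| parameter | default | rationale |
|---|---|---|
| `n_base_genes` | 300 | desk-scale ancestral gene count; genome scale is out of scope |
| `paralog_expansion_prob` / `_b` | 0.20 / 0.05 | species A carries the duplication excess, as the fish lineage does; rare B-side duplication creates many-to-many components |
| `orphan_prob_a` / `_b` | 0.15 each | species-unique genes with no homology edge |
| `rearrangement_rate` | 0.10 | fraction of B's ortholog genes relocated; spans the full GOC lattice |
| `pid_distribution`, `wga_distribution` | Beta(6,2), Beta(5,2) ×100 | right-skewed score distributions straddling the 50/75 thresholds |
| cell types | A: HC\*, nsSC; B: IHC\*, OHC, PC, DC (\* = reference) | the six analysed inner-ear populations |
| `n_replicates` | 3 | matches the two-to-three biological replicates of the source datasets |
| `de_fraction`, `unique_expression_fraction`, `tf_fraction` | 0.10 / 0.05 / 0.10 | TF fraction ≈ the ~2,800 regulators among ~25,000 genes; DE/unique fractions small enough to leave a null majority |
| `log2fc_effect` | 2.0 | clearly-regulated but not trivial planted shift |
| `expression_lognormal_mu_sigma` | (3.0, 1.0) | log-normal baseline of *detected* genes (median ≈ 20 RPKM); the merged ortholog table the generator emulates contains genes with expression data, not the undetected tail |
| `nb_dispersion` | 0.10 | negative-binomial var = μ + d·μ²; bulk-replicate-like |
| `library_size` | 2×10⁷ | typical bulk RNA-seq depth; per-column sizes drawn ±20% |
| `multi_variant_prob` | 0.25 | genes with extra transcript variants, so homology exports carry per-transcript redundant rows |
| `missing_expression_prob` | 0.02 | ortholog pairs lacking expression data, exercising merge-time exclusion |

Replicate-level variance of the original RPKM data is not published, so the
dispersion and baseline are free parameters chosen once as above.

Structural choices:

* **Tandem duplication.** Paralog copies sit adjacent to their source gene.
  Randomly placed duplicates would degrade innocent neighbours' GOC;
  tandem placement leaves every one-to-one gene's orthologous 2+2
  neighbourhood intact (the duplicated genes themselves score 75 — their
  own partner cannot appear in its own window).
* **Orphans interleaved at random positions.** Harmless to GOC because
  windows are taken over ortholog-participating genes.
* **Rearrangement as relocation**, not inversion: sufficient to produce
  GOC values across {0, 25, 50, 75, 100}.
* **WGA is drawn, not computed** — no sequences exist; the WGA formula is
  unit-tested separately.
* Counts are negative-binomial around length- and depth-scaled means so
  both the counts and the RPKM entry points are exercised; RPKM-only input
  is also accepted directly.
* Base-gene expression means are drawn in a fixed order independent of
  which genes end up in the matrices, so planting missing-expression genes
  cannot shift any other gene's draw; identical seeds give byte-identical
  outputs.

What passing the recovery tests does *not* show about real data: the
generator's genes are independent (no co-expression structure, no
correlated replicates or batch effects), its fold changes are homogeneous,
its score distributions are parametric, and its synteny is block-free. The
tests certify the *rules* (thresholds, classifications, set algebra) and
their implementations, not statistical power on real transcriptomes.

One caveat discovered during construction: "no rearrangement implies full
GOC for every internal one-to-one gene" holds exactly only when paralog
expansion is disabled (orphans may be present). With tandem duplicates on
*both* sides near the same window, an A-side duplicate's ortholog can be
pushed outside the partner window by an unrelated B-side duplicate. The
invariant test pins the exact regime; all other configurations are covered
by the oracle-equivalence tests instead.

## Problem sizes and numerics

The test-suite simulations use 120–300 base genes, 2–6 cell types and 3–5
replicates — large enough that every relationship class, GOC value and
planted-label category is populated many times over, while the whole suite
runs in seconds. Null calibration uses 20 independent seeds. Exhaustive
oracles run over all 512 edge-subsets of the complete 3×3 bipartite graph,
all permutations of p-value vectors up to length 6, and hypergeometric
configurations up to universe size 25.

Floating-point comparisons in tests use absolute tolerances of 1e-12 for
pure-arithmetic identities; BH is also cross-checked against
`statsmodels.stats.multitest.multipletests(method="fdr_bh")`. All
randomness flows from explicit `numpy.random.default_rng` seeds.

## Known limitations

* Orthology is consumed, never inferred: no alignment, no tree
  reconciliation, no reproduction of the upstream database pipeline beyond
  the documented scores.
* The per-gene ANOVA is a documented substitute for the original
  proprietary two-factor analysis whose factors are unknowable; numerical
  agreement with the original p-values is not claimed.
* Enrichment reproduces the statistic, not any specific web tool's
  backgrounds, term hierarchy or clustering trees.
* The unique-expression call is threshold-based; a gene expressed at
  0.11 RPKM in a second cell type is not unique, however dominant its
  primary cell type (by design — this mirrors how near-cutoff cases such
  as highly skewed but not exclusive genes are excluded in practice).
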