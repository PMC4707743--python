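# Methods

This note documents the models, numerical choices and limitations behind
spongelinc's five analysis stages and its synthetic-data generator.

## Classification cascade

A transcript is classified by the first rule that fires, in fixed order:

1. longest ORF ≥ `min_orf` (default 300 nt) → **coding**;
2. length < `min_nc_len` (default 600 nt) → discarded `too_short`;
3. any BLASTX hit with e-value < 10 → discarded `blastx_hit`;
4. any Pfam domain hit with e-value < 0.01 → discarded `pfam_hit`;
5. any BLASTP hit with e-value < 10 → discarded `blastp_hit`;
6. coding-potential score > `cp_threshold` (default 1) → discarded
   `coding_potential`;

otherwise **lncRNA candidate**. Homology searches are consumed as
BLAST-outfmt-6-like TSV files, never executed: live database searches are
irreproducible inputs, so the cascade treats them as data. The very
permissive e-value 10 gates are deliberate — any hint of protein homology
disqualifies a non-coding call.

**ORF convention.** An ORF is ATG-initiated with a required in-frame stop;
length is counted in nucleotides *including* the stop codon, so the
minimum is 6 nt. Every ATG is paired with its first in-frame stop (nested
starts are reported too; only the longest matters for the cascade).
`allow_no_stop=True` relaxes the stop requirement for truncated
assemblies. Codons containing N are treated as neither start nor stop.

**Coding-potential score.** The score is a fixed linear combination of
three per-transcript features, each reported individually:

- *ORF coverage* — longest ORF length / transcript length ∈ [0, 1];
- *hexamer log-odds* — mean log2-odds of the longest ORF's in-frame codon
  pairs under a generic eukaryotic codon-usage prior versus a background
  derived from the transcript's own base composition (positive for
  codon-usage-biased ORFs, negative for random sequence);
- *Fickett-style TESTCODE* — positional asymmetry and base content mapped
  through empirical coding-probability lookup tables.

`score = 2.0·coverage + 0.35·hexamer + 0.30·(fickett − 0.95)`, calibrated
so the decision point sits at 1: transcripts dominated by one long
codon-biased ORF land well above 1, random long non-coding sequence well
below. The weights are fixed constants, not fitted per dataset. This is a
deterministic stand-in for SVM-based coding-potential tools that require a
live protein database; an externally computed per-transcript score table
can override it (`cp_scores` / `--cp-scores`), preserving the cascade's
decision point while swapping the scorer.

## Genomic context

Coordinates are 0-based half-open internally; GFF3 I/O converts to/from
that format's 1-based inclusive convention and round-trips losslessly
(asserted by tests). Introns are the gaps between consecutive exons.

The **intergenic filter** removes a candidate when any of its exons
intersects (≥ 1 bp) a coding gene's CDS-covered exonic region or intron.
Overlap is strand-agnostic: with non-strand-specific libraries a genuine
antisense transcript cannot be told apart from a misassembled fragment of
the coding gene, so both are excluded. UTR-only exon overlap is flagged in
the evidence output but does not remove a candidate (the criterion is
"ORFs and introns", not exons); `strict_exon_overlap=True` enables the
conservative variant. Candidate–candidate (lncRNA–lncRNA) overlap is not
penalized.

**Nearest neighbours** are defined on the genome forward axis (left =
upstream, right = downstream, irrespective of the lincRNA's strand),
distance being the gap between closest interval ends (0 when abutting or
overlapping); ties break toward the lexicographically smaller gene id.

## Expression statistics

**Normalization** is median-of-ratios: size factor of library *j* is the
median over all-positive genes of count/geometric-mean. Downstream
transforms are normalized counts (count/sf) and log2(count/sf + 1); the
latter single transform serves PCA, the independence filter and module
detection. PCA runs on the 500 most variable genes with a fixed sign
convention (largest-magnitude loading positive) so coordinates are
reproducible.

**Differential expression** is a per-gene negative-binomial Wald test of
one stage versus the non-reproductive baseline:

- gene-wise dispersion α by pooled within-group method of moments on
  normalized counts, floored at 1e-8, with no shrinkage across genes;
- group means fitted by Newton iterations on the log scale with
  size-factor offsets (an all-zero group receives a half-count
  pseudo-mean so the fold change stays finite);
- z = log2FC / SE with SE from per-group Fisher information, two-sided p
  from the normal reference.

Because the plug-in dispersion is estimated from very few replicates, the
raw Wald statistic has heavier-than-normal tails (empirically a t with
n₁+n₂−2 degrees of freedom; measured type-I ≈ 0.12 at n = 3 vs 3). The SE
therefore carries a small-sample inflation factor
κ = t_{ν,0.975}/z_{0.975}, ν = n₁+n₂−2 (κ ≈ 1.42 at ν = 4, → 1 as ν
grows). With it the measured type-I error is 0.04–0.05 across dispersions
0.05–0.4 at n = 3 vs 3, with power ≈ 0.99 for a 4-fold change at
dispersion 0.1 — the behaviour the acceptance suite asserts. Engines with
cross-gene dispersion shrinkage achieve calibration differently; an
externally computed DE table can be substituted upstream of the stage-set
logic. BH adjustment is applied per stage contrast across genes; a gene is
upregulated when p_adj < 0.1 and log2FC > 0.

**Independence filter.** Spearman ρ (average ranks for ties) between each
lincRNA and its ≤ 2 nearest coding neighbours over all libraries;
p-values from the t-approximation by default, exact permutation
enumeration available for n ≤ 9. BH runs jointly across all tested pairs;
a lincRNA is discarded when any pair has ρ ≥ 0.6 and p_adj < 0.05.
Constant profiles are skipped and logged rather than failing the run.

**Stage-set clustering** uses d(S,T) = 1 − Jaccard(S,T) on per-stage
upregulated sets (0 when both are empty) with average linkage; the exact
functional form of "distance from shared upregulated genes" is a free
choice and Jaccard was picked for its metric properties (the triangle
inequality is tested). **ISH candidates** need a normalized count ≥ 40 in
some library and (max stage mean + 1)/(min stage mean + 1) ≥ 20 — the
pseudocount of 1 defines fold change at zero; normalized (not raw) counts
are used so library depth cannot manufacture candidates.

## Co-expression modules

The network is built on the genes worth clustering: DE-upregulated coding
genes plus independent lincRNAs, then filtered to genes with normalized
counts > 5 in ≥ 3 libraries and log-scale variance in the top 75% (ties at
the quantile kept). Unsigned adjacency a_ij = |pearson|^β with β = 18 and
zero diagonal; the standard unsigned topological overlap

  t_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 − a_ij),
  t_ii = 1

is the canonical formula of the weighted-network literature. Modules come
from average-linkage clustering of 1 − TOM with a deterministic dynamic
cut: candidate cut heights are the dendrogram's merge heights; the chosen
height maximizes the number of clusters of size ≥ 30, and among ties the
*deepest* cut wins. The deep tie-break matters: loosely attached
background genes join module branches just below the top of the tree, so
cutting at the shallowest qualifying height absorbs them (measured planted
recovery ARI 0.71), while the deepest qualifying cut keeps tight cores
(ARI 0.89) and leaves stragglers unassigned. Clusters under the size floor
become `unassigned`; labels are letters by decreasing module size. Module
profiles are median-of-stage-means (median over member genes of the mean
normalized count per stage) — medians of per-library values would mix
replicate noise into the profile. Enrichment is a one-sided Fisher exact
test per term with BH across terms; GO-graph topology weighting is out of
scope.

## Synthetic data

The generator emulates the data regime the pipeline targets, not any real
genome:

- **Genome**: 10 scaffolds × 250 kb of uniform random sequence; loci
  placed left to right with 300–1500 nt gaps (packing failure raises).
- **Coding genes** (200): ORFs of 300–1203 nt with codons drawn from a
  generic eukaryotic usage prior, 50–150 nt UTRs, 1–3 exons; 50 host a
  long intron carrying an embedded decoy.
- **lincRNA loci** (200): 600–2000 nt, rejection-sampled to contain no
  ORF ≥ 300 nt, 1–2 exons, strictly intergenic, no homology hits.
- **Decoys**: 50 pseudogene-like (intergenic, no long ORF, 1–3 planted
  BLASTX hits with e < 10, half also a Pfam hit < 0.01); 50 intron-embedded
  (each inside a host coding gene's intron); 50 short (200–599 nt).
- **Counts**: 8 stages (non-reproductive baseline first) × 3 replicates;
  gamma base means (shape 2, scale 150), NB noise at dispersion 0.1
  (Poisson at dispersion 0), library depths varying ±30% to exercise size
  factors. 30% of coding and lincRNA genes carry a 4-fold upregulation in
  a contiguous 1–3-stage window; 4 planted modules of 40 genes share
  Gaussian-bump stage profiles peaking at distinct stages; 30
  lincRNA/nearest-neighbour pairs share a log-normal stage profile
  (σ = 0.8), with neighbours unique per pair and pair members excluded
  from modules so plantings never overwrite each other.

Replicate count per stage (3) and the DE fraction (0.3) are generator
choices for a realistic small study, not inferences about any particular
dataset. What the generator does **not** emulate: isoform structure and
multi-transcript genes (one transcript per gene), read-level noise and
mapping ambiguity, GC/length biases, batch effects, splice-site motifs,
and sequence-composition differences between real coding and non-coding
DNA beyond codon-usage bias. Passing tests therefore demonstrate that the
machinery is correct and calibrated under its stated model — not that the
thresholds are optimal for any real transcriptome.

## Problem sizes and determinism

Test and acceptance runs use the default 550-transcript dataset, 2000-gene
null/1000-gene alternative calibration simulations and a 240-gene module
recovery design; these sizes give stable Monte-Carlo estimates while
keeping the whole suite under a minute. All randomness flows from
numpy `default_rng` seeds carried in the configuration objects; identical
configurations produce byte-identical output files (asserted by tests).

## Known limitations

- The built-in coding-potential score is calibrated for the synthetic
  regime; real transcriptomes should supply scores from a trained tool via
  the override hook, or at least re-examine the threshold.
- Per-gene moment dispersion without shrinkage is noisy at 2–3 replicates;
  the κ correction fixes calibration but costs a little power relative to
  shrinkage-based engines at very low counts.
- The independence filter tests only the two nearest neighbours and linear
  genomic proximity; enhancer-like long-range relationships are invisible.
- The dynamic cut is single-pass; it does not reassign unassigned genes to
  the module with the highest TOM affinity afterwards.
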