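# Methods

This note documents the models, conventions and numerical choices behind
`chlamycomp`, and what the synthetic-data tests do and do not establish
about behaviour on real data.

## Coordinates and formats

All internal coordinates are 0-based half-open; conversion to the
1-based inclusive conventions of GFF3 and VCF happens only in the
readers/writers. Soft-masked (lower-case) bases are preserved and
compared case-insensitively where identity matters; non-ACGT characters
are uncallable in every site computation. When several isoforms exist,
the longest spliced CDS is kept, ties broken by lexicographically
smallest transcript id. MAF blocks without a reference row are dropped
with a counted warning; this is a deliberate resolution of an otherwise
unspecified case.

## Site classes and degeneracy

The genome is partitioned exclusively with precedence
CDS > 5′UTR > 3′UTR > intron > intergenic; overlapping genes carry no
precedence among themselves — only the class hierarchy decides.
Intergenic tracts split at 250 bp (a "short" tract is < 250 bp);
contig-terminal tracts are counted but flagged, since they bound at most
one gene.

Degeneracy is computed on the spliced CDS (transcription order,
reverse-complemented on the minus strand), so codons spanning exon
junctions classify correctly. The fold of a codon position counts the
synonymous members among its three possible substitutions. Stop codons
use stop-preservation: a substitution is synonymous only if it yields
another stop, which makes the "0D positions of stop codons" well defined
(TAA → position 1; TGA → 1 and 3; TAG → 1 and 2). Codons containing N
are wholly uncallable rather than per-offset, avoiding asymmetric
classification. Genes with internal stops are flagged but still mapped:
the audit pipeline needs statistics for dubious models, not their
absence.

High-impact sites are the start-codon bases, the stop-preservation 0D
stop bases, and the two terminal dinucleotides at each intron end.

## Diversity

Per-site π is the unbiased haploid heterozygosity
(n/(n−1))(1 − Σp²) over called alleles, using the full multiallelic form.
Region π averages over callable sites; monomorphic callable sites enter
the denominator. When no callable mask is provided, every non-N
reference position is assumed callable with all samples called — an
explicit, overridable default, since variant filtering is upstream of
this package. Sites with fewer than two called alleles are excluded from
numerator and denominator alike (a pairwise difference needs two
sequences). The per-gene ratio π₀D/π₄D is undefined when π₄D = 0 or
either site count is zero; undefinedness is propagated because the
classifier treats it as threshold-exceeding.

## Codon adaptation (I_TE-like)

The index follows the CAI family but adjusts for background mutation
bias. Synonymous families are split into sub-families sharing their
first two codon positions (Leu → TTR + CTN, Ser → TCN + AGY,
Arg → CGN + AGR) — the standard code has no eight-codon family, so only
the six-codon families actually split. For codon *c* in sub-family *F*,
the weight is w_c = r_c / max r with r_c = F_hi(c)/F_bg(c), the
within-sub-family frequency in a highly expressed reference set over
that in the background (all other genes). A pseudocount of ½ is applied
only to sub-families containing a zero count in either set; with all
codons observed, weights are exactly invariant to rescaling the
reference counts. A sub-family unused in the reference set gets uniform
weights and a flag; its codons are excluded from scoring. A gene's score
is the geometric mean of weights over its codons, excluding Met, Trp and
stops (no synonymous choice), so scores lie in (0, 1] and equal 1 exactly
when every scored codon is its sub-family optimum. This is documented as
"I_TE-like": it preserves the intent of the published index (mutation
bias aware, CAI-interpretable) without reproducing a specific tool's
internals; within-dataset percentiles, the only way scores are consumed,
are insensitive to that choice.

The reference set is the 5% of genes at one extreme of correspondence-
analysis axis 1 of the gene × 59-codon count matrix (standardised
residuals, SVD, row principal coordinates). The pole is chosen by
hypergeometric enrichment of caller-supplied marker genes (histone and
ribosomal-protein genes on real data); a tie is an error demanding an
explicit pole rather than a silent guess.

## Kozak model

Ten sites flank the start codon (−5..−1, +4..+8; the ATG itself is
excluded). The model stores per-site base frequencies, information
R_s = 2 − H_s bits, and the consensus base (ties resolve to the
alphabetically first base and are flagged). A query scores
Σ f_consensus·R_s over sites where it matches the consensus; the
alternative reading — credit the query base's own height everywhere —
is available behind `match_only=False`. No small-sample entropy
correction is applied; training sets are large and the correction would
complicate the hand-checkable examples. Contexts are taken from genomic
(pre-mRNA) sequence; genes whose downstream window leaves the
start-codon exon are flagged so either convention can be audited.

## Whole-genome-alignment analyses

All analyses run on a stitched per-position view: for each species, the
base aligned to every reference position (0 when gapped/unaligned).
Reference positions covered by more than one block keep the first
block's columns; occurrences are counted. Column characters are compared
as displayed — MAF semantics make them comparable across rows regardless
of row strand.

The duplicate-row filter keeps, per species, the row with the most
matches to the column-wise majority-base consensus (consensus ties to
the alphabetically first base; row ties to file order). It is idempotent
and never touches single-copy species.

4D column extraction keeps a reference four-fold third position when all
three codon positions are covered and every species shows gap-free bases
whose triplet, read on the gene's coding strand, is itself 4D at the
same offset. Because the stitched view erases block boundaries, a codon
whose reference positions fall in adjacent blocks is retained rather
than dropped — boundaries are an artefact of block chunking, not of the
alignment; only genuinely uncovered positions drop a codon (counted).

UCEs are maximal runs ≥ 50 bp where every strict-trio species is
aligned, gap-free and base-identical to the reference
(case-insensitive). Identity is measured against the reference base, not
mutual pairwise identity, matching the reference-anchored reporting of
the elements. The broad filter keeps UCEs whose fraction of
all-species-identical columns is ≥ 0.95. Soft-masked columns are
included (conservation is conservation); repeat overlap can be flagged
downstream.

The intron/conservation analysis orders introns by length (ties by
genomic position), splits them into 50 contiguous bins differing in size
by at most one, and reports per-bin mean length and CE base fraction,
their Pearson correlation, the < 100 bp vs ≥ 100 bp CE-fraction
contrast, and a Welch t test on relative intron position.

## Synthetic data

The generator defines the study conditions; its defaults are fixed, not
tuning knobs. Default scale is 2 sequences × 1 Mb with 300 genes and 8
species; the test suite and acceptance script run a scaled form (2 ×
250 kb / 60 genes for alignment analyses, 500 kb / 150 genes for the
classifier) chosen so the full suite completes in minutes on one CPU.

*Genome.* i.i.d. bases at GC 0.64. Genes are packed without overlap,
separated by intergenic tracts from a short/long mixture (63.5% of
tracts < 250 bp by count). Genuine genes: ~8 exons, lognormal CDS
(median 600 codons); spurious genes (20%): ~2 exons, median 110 codons —
both scales follow the contrast reported between ordinary and
low-coding-potential gene models in compact algal annotations. Introns
mix a short uniform component (55–95 bp) with a lognormal long component
(median 230 bp); the short component has weight 0.6 for first introns
and 0.08 otherwise, planting the first-intron enrichment. Telomere
arrays ((TTTTAGGG)₂₅ by default) are written at contig termini, a
clustered LINE-like repeat region marks one designated centromere per
contig, and splice sites are written GT..AG. Genuine CDSs draw codons
with sub-family-optimal probability q = 0.8 and Kozak contexts from a
planted position model (consensus probability 0.7); spurious CDSs are
GC-matched random codons with random contexts. Evidence tables (per-exon
scores, orthogroups, domains) are emitted so the control/test partition
reconstructs the labels exactly.

*Alignment.* The reference sequence is evolved down a fixed species tree
(nearest species at 0.34 substitutions/site, next at 0.45, five more to
0.95) under site-independent HKY (κ = 2.5, stationary frequencies at
genome GC), with per-site rate multipliers: 1 in neutral sequence, 0.2
in planted conserved elements, 0 on the trio branches inside planted
UCEs (0 on all branches for the "deep" subset). Indels are confined to
unconstrained sequence as per-species block deletions whose density
grows with divergence (aligned fraction e^(−2.7d)), so genuine-gene
codon frame is never disturbed. Deterministic guards make the planted
UCE truth exact: each UCE's flanking column is forced to mismatch in the
nearest species, any accidental trio-conserved run ≥ 50 bp outside the
planted set is broken, and non-deep UCEs are forced below the broad
identity cutoff if sampling ever leaves them above it. Occasional decoy
"paralog" rows (30% mutated copies, never matching reference or source
base at mutated columns) exercise the duplicate filter. Conserved
elements are planted per site class at fixed coverage (CDS 0.60, 5′UTR
0.25, 3′UTR 0.11, intergenic 0.04) and per intron as a fixed 28-bp
budget, which makes intronic CE density ∝ 1/length.

*Variants.* Each site segregates independently with probability
target/E[π | segregating], where the expectation is taken over the
neutral frequency spectrum (derived-allele count ∝ 1/i, n = 17
haploids); allele counts are drawn from that spectrum. Class targets
default to CDS 0.0144, intron 0.0248, intergenic 0.022. Gene-level
planting overrides CDS sites: 4D sites at π = 0.03; 0D sites at 0.2 ×
that level in genuine genes but the full 4D level in spurious ones;
high-impact sites at 0.001 (genuine) vs 0.02 (spurious). Only E[π]
matters to the consumers, so no coalescent machinery is used.

What passing tests show — and do not. The generator is site-independent
and recombination-free, plants clean two-regime contrasts, and evolves
no realistic TE sequence. Exact UCE/4D recovery therefore demonstrates
correctness of the scanning and filtering logic, not robustness to
alignment error; classifier sensitivity/FPR demonstrate that the
threshold machinery recovers a planted signal of the published shape,
not field performance on a real annotation, where gene-level evidence is
correlated and intermediate cases abound.

## Numerical choices

Percentile thresholds use linear interpolation. Classifier rules are
boundary-faithful: a coding-potential score of exactly 1 passes; repeat
filters fire at exactly 30%/70%; a 250-bp tract is long; 45-bp exons
qualify for score aggregation. Correspondence-analysis axis signs are
arbitrary (SVD); everything downstream is sign-aware. Infinite
gene-family log2 ratios are reported as ±inf markers rather than
pseudocounted. All randomness flows through `numpy.random.default_rng`
seeds carried in the spec objects; generation never iterates over
unordered containers, so outputs are byte-identical across processes.

## Limitations

No BAM/CRAM or HAL input; no non-standard genetic codes; no variant
calling or SFS statistics beyond π; phylo-HMM conserved-element calling
and the external coding-potential scorer are consumed as inputs, never
recomputed. The per-module command-line interfaces are consolidated into
one `chlamycomp` entry point with subcommands.
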