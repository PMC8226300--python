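# chlamycomp

Comparative-genomics auditing for compact algal genomes, built around the
kind of analysis stack used for *Chlamydomonas reinhardtii* and its
unicellular relatives. The package covers three connected problems:

1. **Gene-model auditing.** Given externally computed coding-potential
   scores (e.g. PhyloCSF per-exon output), haploid resequencing variants,
   and orthology/domain evidence, decide which annotated gene models are
   likely false positives. Genes with neither an ortholog nor a functional
   domain form a *test* set; per-gene statistics — the diversity ratio
   π₀D/π₄D at zero-fold vs four-fold degenerate sites, a
   mutation-bias-adjusted codon-adaptation index (I_TE-like), and a Kozak
   context bit score — are compared against thresholds derived from the
   *control* distribution (95th percentile of π₀D/π₄D, 5th percentile of
   I_TE). Test genes failing the score cutoff and both thresholds are
   `low_coding_potential_1`; score plus exactly one threshold is
   `low_coding_potential_2`.
2. **Conservation landscape.** From a reference-anchored multi-species
   whole-genome alignment (MAF): per-site-class alignability, duplicate
   (paralog) row filtering by consensus similarity, extraction of
   four-fold-degenerate codon columns that are gap-free and 4D in every
   species, scanning for ultraconserved elements (runs ≥ 50 bp with 100%
   identity across a strict species trio, plus a ≥ 95%-identity filter
   over all species), and overlap tables between conserved elements and
   the exclusive site-class partition (CDS > 5′UTR > 3′UTR > intron >
   intergenic, intergenic tracts split at 250 bp).
3. **Genome screens.** Telomere motif arrays (e.g. (TTTTAGGG)ₙ) at contig
   termini, terminal repeat-family calls within 20 kb of contig ends,
   50-kb window density tracks for clustered repeat families,
   repeat-overlap gene filtering (≥ 30% TE / ≥ 70% simple-repeat CDS
   overlap), gene-family expansion calls (log₂ focal/mean-others > 1),
   and the domain→orthogroup assignment rule (≥ 20% of genes, ≥ 50% of
   species).

Key definitions: the per-site nucleotide diversity is the unbiased
haploid heterozygosity π = (n/(n−1))(1 − Σᵢpᵢ²), averaged over callable
sites with monomorphic sites in the denominator; a codon position is
k-fold degenerate when k of the three possible substitutions at it are
synonymous (stop codons count only stop→stop as synonymous); the Kozak
score of a 10-mer context (−5..−1, +4..+8 around the ATG) is
Σ f<sub>consensus,s</sub>·R_s over matching sites, with R_s = 2 − H_s bits.

A first-class synthetic-data generator (`chlamycomp.simulate`) produces
every input — genome FASTA, GFF3 with the atypical intron-length mixture,
repeat BED, a MAF evolved on a fixed species tree under HKY with planted
conserved/ultraconserved intervals, a haploid VCF hitting per-site-class
diversity targets, and external-evidence tables — together with a truth
manifest, so every analysis can be tested against known ground truth.

## Worked example

```python
from chlamycomp.simulate import GenomeSpec, AlignmentSpec, \
    simulate_genome, simulate_alignment
from chlamycomp.wga import ReferenceAlignment, filter_duplicates, scan_uces
from chlamycomp.siteclass import call_site_classes

sim = simulate_genome(GenomeSpec(seed=1, n_genes=60, seq_length=250_000))
aln = simulate_alignment(sim, AlignmentSpec(seed=2))
blocks = [filter_duplicates(b) for b in aln.blocks]
refaln = ReferenceAlignment(blocks, {k: len(v) for k, v in sim.sequences.items()})
uces = scan_uces(refaln, aln.truth["trio"])
print(len(uces), "UCEs;", "planted:", len(aln.uce_intervals))
print("longest:", max(u.length for u in uces), "bp")
```

prints

```
40 UCEs; planted: 40
longest: 119 bp
```

— the scanner recovers every element planted by the generator (40 of 40),
and the longest recovered run is the longest planted interval (119 bp;
planted lengths are drawn from 50–120 bp).

The same objects drive the CLI:

```bash
chlamycomp simulate --seed 1 --out dataset/
chlamycomp wga --maf dataset/alignment.maf --reference crei_sim \
    --fasta dataset/genome.fa --gff3 dataset/genes.gff3 \
    --ces dataset/conserved_elements.bed \
    --trio crei_sim,cinc_sim,cschl_sim --out wga_out/
chlamycomp diversity --fasta dataset/genome.fa --gff3 dataset/genes.gff3 \
    --vcf dataset/variants.vcf --out ratios.tsv
```

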