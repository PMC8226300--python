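"""Readers and writers for the standard formats the toolkit consumes.

All internal coordinates are 0-based half-open; conversion to/from the
1-based inclusive conventions of GFF3 and VCF happens only in this module.
Soft-masking (lower case) is preserved verbatim — repeat-aware operations
decide for themselves whether to honour it.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "Interval",
    "GeneModel",
    "MafRow",
    "AlignmentBlock",
    "VariantTable",
    "read_fasta",
    "write_fasta",
    "read_gff3_models",
    "write_gff3",
    "read_maf",
    "write_maf",
    "read_bed",
    "write_bed",
    "read_vcf_haploid",
    "write_vcf",
]

COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def _open(path, mode: str = "rt") -> IO:
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open genomic interval: ``[start, end)`` on ``seq_id``."""

    seq_id: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"degenerate interval {self.seq_id}:{self.start}-{self.end}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "Interval") -> bool:
        return (
            self.seq_id == other.seq_id
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """One transcript of one gene: ordered exons, phase-aware CDS, UTRs.

    ``exons`` and ``cds_segments`` are sorted by genomic start; transcription
    order is derived from ``strand``.  ``cds_phases`` parallels
    ``cds_segments`` (GFF3 semantics: bases to skip to reach a codon start).
    """

    gene_id: str
    transcript_id: str
    seq_id: str
    strand: str
    exons: list[Interval]
    cds_segments: list[Interval]
    cds_phases: list[int]
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)
    flags: set[str] = field(default_factory=set)

    @property
    def start(self) -> int:
        return min(iv.start for iv in self.exons)

    @property
    def end(self) -> int:
        return max(iv.end for iv in self.exons)

    @property
    def cds_len(self) -> int:
        return sum(len(iv) for iv in self.cds_segments)

    def cds_in_transcription_order(self) -> list[Interval]:
        segs = sorted(self.cds_segments, key=lambda iv: iv.start)
        return segs if self.strand != "-" else segs[::-1]

    def exons_in_transcription_order(self) -> list[Interval]:
        exs = sorted(self.exons, key=lambda iv: iv.start)
        return exs if self.strand != "-" else exs[::-1]

    def spliced_cds(self, genome) -> str:
        """Spliced CDS sequence, 5'→3' on the coding strand.

        The phase of the first CDS segment (in transcription order) trims
        leading bases of incomplete models.
        """
        parts = []
        for iv in self.cds_in_transcription_order():
            s = genome[self.seq_id][iv.start : iv.end]
            parts.append(revcomp(s) if self.strand == "-" else s)
        seq = "".join(parts)
        phase = self._first_phase()
        return seq[phase:] if phase else seq

    def _first_phase(self) -> int:
        if not self.cds_segments:
            return 0
        segs = self.cds_in_transcription_order()
        idx = self.cds_segments.index(segs[0])
        return self.cds_phases[idx]

    def cds_positions_in_transcription_order(self) -> np.ndarray:
        """Genomic positions of spliced CDS bases, in transcription order."""
        chunks = []
        for iv in self.cds_in_transcription_order():
            pos = np.arange(iv.start, iv.end)
            chunks.append(pos[::-1] if self.strand == "-" else pos)
        if not chunks:
            return np.empty(0, dtype=int)
        out = np.concatenate(chunks)
        phase = self._first_phase()
        return out[phase:] if phase else out

    def introns(self) -> list[Interval]:
        """Introns in genomic order (gaps between consecutive exons)."""
        exs = sorted(self.exons, key=lambda iv: iv.start)
        out = []
        for a, b in zip(exs, exs[1:]):
            if b.start > a.end:
                out.append(Interval(self.seq_id, a.end, b.start, self.strand))
        return out


@dataclass
class MafRow:
    species: str
    src: str  # full source name, e.g. "reinhardtii.chromosome_1"
    start: int  # 0-based on the named strand (MAF semantics)
    size: int  # aligned (non-gap) length
    strand: str
    src_size: int
    text: str  # gapped alignment text

    @property
    def seq_name(self) -> str:
        parts = self.src.split(".", 1)
        return parts[1] if len(parts) == 2 else self.src

    def forward_start(self) -> int:
        """Start on the forward strand regardless of row strand."""
        if self.strand == "-":
            return self.src_size - self.start - self.size
        return self.start


@dataclass
class AlignmentBlock:
    rows: list[MafRow]
    reference: str

    def __post_init__(self):
        lens = {len(r.text) for r in self.rows}
        if len(lens) > 1:
            raise ValueError("row texts differ in length within block")
        for r in self.rows:
            ungapped = sum(1 for c in r.text if c != "-")
            if ungapped != r.size:
                raise ValueError(
                    f"row {r.src}: non-gap count {ungapped} != declared size {r.size}"
                )

    @property
    def width(self) -> int:
        return len(self.rows[0].text) if self.rows else 0

    def reference_rows(self) -> list[MafRow]:
        return [r for r in self.rows if r.species == self.reference]

    def species(self) -> list[str]:
        seen = []
        for r in self.rows:
            if r.species not in seen:
                seen.append(r.species)
        return seen


class VariantTable:
    """Haploid genotype calls for ``n_samples`` isolates.

    ``records`` maps ``(seq_id, pos)`` (0-based) to ``(alleles, genotypes)``
    where ``alleles`` is a tuple of allele strings (ref first) and
    ``genotypes`` an int array of allele indices, -1 for missing.
    ``callable_mask`` (optional) maps seq_id to a boolean array of trusted
    invariant positions; when absent, downstream estimators assume all
    non-N reference positions are callable.
    """

    def __init__(self, samples: Sequence[str]):
        self.samples = list(samples)
        self.records: dict[tuple[str, int], tuple[tuple[str, ...], np.ndarray]] = {}
        self.callable_mask: dict[str, np.ndarray] | None = None

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def add(self, seq_id: str, pos: int, alleles, genotypes) -> None:
        gt = np.asarray(genotypes, dtype=np.int16)
        if gt.size != self.n_samples:
            raise ValueError("genotype vector length != n_samples")
        if (gt >= len(alleles)).any():
            raise ValueError("genotype index out of allele range")
        self.records[(seq_id, pos)] = (tuple(alleles), gt)

    def allele_counts(self, seq_id: str, pos: int) -> np.ndarray | None:
        rec = self.records.get((seq_id, pos))
        if rec is None:
            return None
        alleles, gt = rec
        called = gt[gt >= 0]
        return np.bincount(called, minlength=len(alleles))

    def __len__(self) -> int:
        return len(self.records)


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class FastaDict(dict):
    """id → sequence mapping that also retains record descriptions."""

    def __init__(self):
        super().__init__()
        self.descriptions: dict[str, str] = {}


def read_fasta(path) -> FastaDict:
    """Read FASTA into an id → sequence map; case preserved.

    Ids are the first whitespace token; the remainder of the header is kept
    in ``.descriptions``.  Duplicate ids and empty records are errors.
    """
    out = FastaDict()
    with _open(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in out:
                raise ValueError(f"duplicate FASTA id {rec.id!r}")
            seq = str(rec.seq)
            if not seq:
                raise ValueError(f"empty FASTA record {rec.id!r}")
            out[rec.id] = seq
            desc = rec.description
            if desc.startswith(rec.id):
                desc = desc[len(rec.id) :].strip()
            out.descriptions[rec.id] = desc
    if not out:
        raise ValueError(f"no FASTA records in {path}")
    return out


def write_fasta(path, sequences: dict[str, str], width: int = 60) -> None:
    recs = [
        SeqRecord(Seq(s), id=name, description="") for name, s in sequences.items()
    ]
    with _open(path, "wt") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def read_gff3_models(path, longest_isoform_only: bool = False) -> list[GeneModel]:
    """Parse gene/mRNA/exon/CDS(/UTR) features into :class:`GeneModel` s.

    Coordinates are converted 1-based inclusive → 0-based half-open.  With
    ``longest_isoform_only`` exactly one transcript per gene is kept: the
    one with the longest spliced CDS, ties broken by lexicographically
    smallest transcript id.  UTRs absent from the file are inferred as
    exon minus CDS span.  A CDS segment outside its transcript's exon span
    is an error; missing phases are recomputed with a warning.
    """
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    transcripts: dict[str, dict] = {}
    for mrna in db.features_of_type(("mRNA", "transcript")):
        tid = mrna.id
        gid = mrna.attributes.get("Parent", [tid])[0]
        t = {
            "gene": gid,
            "seq": mrna.seqid,
            "strand": mrna.strand,
            "exon": [],
            "cds": [],
            "utr5": [],
            "utr3": [],
        }
        keymap = {
            "exon": "exon",
            "CDS": "cds",
            "five_prime_UTR": "utr5",
            "three_prime_UTR": "utr3",
        }
        for child in db.children(mrna, level=1):
            key = keymap.get(child.featuretype)
            if key is None:
                continue
            t[key].append(
                (child.seqid, child.start - 1, child.end, child.strand, child.frame)
            )
        transcripts[tid] = t

    genes: dict[str, list[str]] = {}
    for tid, t in transcripts.items():
        genes.setdefault(t["gene"], []).append(tid)

    models = []
    for tid, t in transcripts.items():
        exons = sorted(
            Interval(t["seq"], s, e, t["strand"]) for _, s, e, _, _ in t["exon"]
        )
        cds_raw = sorted(t["cds"], key=lambda x: x[1])
        cds = [Interval(t["seq"], s, e, t["strand"]) for _, s, e, _, _ in cds_raw]
        if not exons and cds:
            exons = list(cds)
        exon_cover = [(iv.start, iv.end) for iv in exons]
        for iv in cds:
            if not any(s <= iv.start and iv.end <= e for s, e in exon_cover):
                raise ValueError(
                    f"transcript {tid}: CDS {iv.start}-{iv.end} outside exon span"
                )
        phases = _resolve_phases(tid, cds_raw, t["strand"])
        model = GeneModel(
            gene_id=t["gene"],
            transcript_id=tid,
            seq_id=t["seq"],
            strand=t["strand"],
            exons=exons,
            cds_segments=cds,
            cds_phases=phases,
            utr5=[Interval(t["seq"], s, e, t["strand"]) for _, s, e, _, _ in t["utr5"]],
            utr3=[Interval(t["seq"], s, e, t["strand"]) for _, s, e, _, _ in t["utr3"]],
        )
        if not model.utr5 and not model.utr3 and cds:
            u5, u3 = _infer_utrs(model)
            model.utr5, model.utr3 = u5, u3
        models.append(model)

    if longest_isoform_only:
        keep = []
        for gid, tids in genes.items():
            cands = [m for m in models if m.gene_id == gid]
            if not cands:
                continue
            best = sorted(cands, key=lambda m: (-m.cds_len, m.transcript_id))[0]
            keep.append(best)
        models = keep
    return sorted(models, key=lambda m: (m.seq_id, m.start, m.transcript_id))


def _resolve_phases(tid, cds_raw, strand) -> list[int]:
    declared = [p for *_, p in cds_raw]
    if all(p in ("0", "1", "2") for p in declared):
        return [int(p) for p in declared]
    warnings.warn(f"transcript {tid}: missing CDS phase, recomputed")
    order = range(len(cds_raw)) if strand != "-" else range(len(cds_raw) - 1, -1, -1)
    phases = [0] * len(cds_raw)
    running = 0
    for i in order:
        _, s, e, _, _ = cds_raw[i]
        phases[i] = (3 - running % 3) % 3
        running += e - s
    return phases


def _infer_utrs(model: GeneModel):
    """UTRs = exon bases outside the CDS span, sided by transcription order."""
    cds_start = min(iv.start for iv in model.cds_segments)
    cds_end = max(iv.end for iv in model.cds_segments)
    left, right = [], []
    for ex in model.exons:
        if ex.start < cds_start:
            left.append(
                Interval(model.seq_id, ex.start, min(ex.end, cds_start), model.strand)
            )
        if ex.end > cds_end:
            right.append(
                Interval(model.seq_id, max(ex.start, cds_end), ex.end, model.strand)
            )
    if model.strand == "-":
        return right, left
    return left, right


def write_gff3(path, models: Iterable[GeneModel]) -> None:
    """Write models as gene/mRNA/exon/CDS/UTR features (1-based inclusive)."""
    with _open(path, "wt") as fh:
        fh.write("##gff-version 3\n")
        by_gene: dict[str, list[GeneModel]] = {}
        for m in sorted(models, key=lambda m: (m.seq_id, m.start, m.gene_id)):
            by_gene.setdefault(m.gene_id, []).append(m)
        for gid, ms in by_gene.items():
            g_start = min(m.start for m in ms)
            g_end = max(m.end for m in ms)
            m0 = ms[0]
            fh.write(
                f"{m0.seq_id}\tchlamycomp\tgene\t{g_start + 1}\t{g_end}\t.\t"
                f"{m0.strand}\t.\tID={gid}\n"
            )
            for m in ms:
                fh.write(
                    f"{m.seq_id}\tchlamycomp\tmRNA\t{m.start + 1}\t{m.end}\t.\t"
                    f"{m.strand}\t.\tID={m.transcript_id};Parent={gid}\n"
                )
                for iv in m.exons:
                    fh.write(
                        f"{m.seq_id}\tchlamycomp\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{m.strand}\t.\tParent={m.transcript_id}\n"
                    )
                for iv, ph in zip(m.cds_segments, m.cds_phases):
                    fh.write(
                        f"{m.seq_id}\tchlamycomp\tCDS\t{iv.start + 1}\t{iv.end}\t.\t"
                        f"{m.strand}\t{ph}\tParent={m.transcript_id}\n"
                    )
                for kind, ivs in (("five_prime_UTR", m.utr5), ("three_prime_UTR", m.utr3)):
                    for iv in ivs:
                        fh.write(
                            f"{m.seq_id}\tchlamycomp\t{kind}\t{iv.start + 1}\t{iv.end}"
                            f"\t.\t{m.strand}\t.\tParent={m.transcript_id}\n"
                        )


# ---------------------------------------------------------------------------
# MAF
# ---------------------------------------------------------------------------


def read_maf(path, reference_species: str) -> list[AlignmentBlock]:
    """Read MAF blocks anchored to ``reference_species``.

    Blocks lacking a reference row are dropped with a counted warning
    (the count is issued once at the end).  Minus-strand rows keep MAF
    semantics: ``start`` is on the named strand, ``src_size`` recorded.
    """
    blocks = []
    dropped = 0
    with _open(path) as fh:
        for bi, aln in enumerate(AlignIO.parse(fh, "maf")):
            rows = []
            for rec in aln:
                ann = rec.annotations
                src = rec.id
                rows.append(
                    MafRow(
                        species=src.split(".", 1)[0],
                        src=src,
                        start=int(ann["start"]),
                        size=int(ann["size"]),
                        strand="+" if ann["strand"] in (1, "+") else "-",
                        src_size=int(ann["srcSize"]),
                        text=str(rec.seq),
                    )
                )
            try:
                block = AlignmentBlock(rows, reference_species)
            except ValueError as exc:
                raise ValueError(f"block {bi}: {exc}") from exc
            if not block.reference_rows():
                dropped += 1
                continue
            blocks.append(block)
    if dropped:
        warnings.warn(f"dropped {dropped} MAF block(s) lacking the reference row")
    return blocks


def write_maf(path, blocks: Iterable[AlignmentBlock]) -> None:
    alns = []
    for b in blocks:
        recs = []
        for r in b.rows:
            rec = SeqRecord(Seq(r.text), id=r.src, description="")
            rec.annotations.update(
                start=r.start,
                size=r.size,
                strand=1 if r.strand == "+" else -1,
                srcSize=r.src_size,
            )
            recs.append(rec)
        alns.append(MultipleSeqAlignment(recs))
    with _open(path, "wt") as fh:
        AlignIO.write(alns, fh, "maf")


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def read_bed(path, merge: bool = False) -> list[Interval]:
    """Read BED3+ into sorted Intervals; strand taken from column 6 if present."""
    out = []
    with _open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t") if "\t" in line else line.split()
            seq, start, end = f[0], int(f[1]), int(f[2])
            if start >= end:
                raise ValueError(f"line {ln}: start >= end ({start} >= {end})")
            strand = f[5] if len(f) >= 6 and f[5] in "+-" else "."
            out.append(Interval(seq, start, end, strand))
    out.sort(key=lambda iv: (iv.seq_id, iv.start, iv.end))
    if merge:
        out = merge_intervals(out)
    return out


def merge_intervals(ivs: Sequence[Interval]) -> list[Interval]:
    """Merge overlapping/adjacent intervals per sequence (strand discarded)."""
    merged: list[Interval] = []
    for iv in sorted(ivs, key=lambda x: (x.seq_id, x.start)):
        if merged and merged[-1].seq_id == iv.seq_id and iv.start <= merged[-1].end:
            last = merged.pop()
            merged.append(Interval(iv.seq_id, last.start, max(last.end, iv.end)))
        else:
            merged.append(Interval(iv.seq_id, iv.start, iv.end))
    return merged


def write_bed(path, intervals: Iterable, names: Iterable[str] | None = None,
              scores: Iterable | None = None) -> None:
    names = list(names) if names is not None else None
    scores = list(scores) if scores is not None else None
    with _open(path, "wt") as fh:
        for i, iv in enumerate(intervals):
            cols = [iv.seq_id, str(iv.start), str(iv.end)]
            if names is not None or scores is not None:
                cols.append(names[i] if names is not None else ".")
                cols.append(str(scores[i]) if scores is not None else "0")
                cols.append(iv.strand if iv.strand in "+-" else ".")
            fh.write("\t".join(cols) + "\n")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------


def read_vcf_haploid(path, sample_ids: Sequence[str] | None = None) -> VariantTable:
    """Read haploid (or homozygous-diploid) calls into a VariantTable.

    Homozygous diploid genotypes collapse to a single allele; heterozygous
    diploid calls become missing with a warning.  Multiallelic sites are
    retained with all alleles.  A requested sample absent from the header
    is an error.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    present = list(vcf.samples)
    if sample_ids is None:
        sample_ids = present
    missing = [s for s in sample_ids if s not in present]
    if missing:
        raise ValueError(f"samples absent from VCF: {missing}")
    idx = [present.index(s) for s in sample_ids]
    table = VariantTable(sample_ids)
    n_het = 0
    for v in vcf:
        alleles = (v.REF, *v.ALT)
        gts = []
        for i in idx:
            g = v.genotypes[i]
            calls = [a for a in g[:-1] if a is not None]
            calls = [a for a in calls]
            if len(calls) == 1:
                gts.append(calls[0] if calls[0] >= 0 else -1)
            elif len(calls) == 2:
                a, b = calls
                if a < 0 or b < 0:
                    gts.append(-1)
                elif a == b:
                    gts.append(a)
                else:
                    n_het += 1
                    gts.append(-1)
            else:
                gts.append(-1)
        table.add(v.CHROM, v.POS - 1, alleles, gts)
    if n_het:
        warnings.warn(f"{n_het} heterozygous diploid call(s) set to missing")
    return table


def write_vcf(path, table: VariantTable, contig_lengths: dict[str, int] | None = None) -> None:
    """Write a minimal haploid VCF (GT-only)."""
    with _open(path, "wt") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=chlamycomp\n")
        if contig_lengths:
            for name, length in contig_lengths.items():
                fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(table.samples)
            + "\n"
        )
        for (seq, pos), (alleles, gt) in sorted(table.records.items()):
            alt = ",".join(alleles[1:]) if len(alleles) > 1 else "."
            gts = "\t".join("." if g < 0 else str(g) for g in gt)
            fh.write(f"{seq}\t{pos + 1}\t.\t{alleles[0]}\t{alt}\t.\tPASS\t.\tGT\t{gts}\n")
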