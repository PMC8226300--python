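"""Codon degeneracy and the exclusive genomic site-class partition.

Every CDS base of a complete gene model is assigned a degeneracy fold
(0D/2D/3D/4D) on the coding strand, and every genomic base exactly one
site class under the fixed hierarchy CDS > 5'UTR > 3'UTR > intron >
intergenic.  Intron and intergenic-tract tables feed the conservation
analyses downstream.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Data import CodonTable

from .io import GeneModel, Interval

__all__ = [
    "CLASS_CODES",
    "CLASS_NAMES",
    "classify_codon_degeneracy",
    "DegeneracyMap",
    "map_gene_degeneracy",
    "SiteClassMap",
    "call_site_classes",
    "IntergenicTract",
    "extract_intergenic_tracts",
    "IntronRecord",
    "intron_table",
    "high_impact_sites",
    "summarize_annotation",
]

BASES = "ACGT"

# class codes in hierarchy order; higher code = higher precedence
CLASS_CODES = {"intergenic": 0, "intron": 1, "UTR3": 2, "UTR5": 3, "CDS": 4}
CLASS_NAMES = {v: k for k, v in CLASS_CODES.items()}

_STANDARD = CodonTable.unambiguous_dna_by_id[1]
_STOPS = set(_STANDARD.stop_codons)


def _amino(codon: str) -> str:
    """Amino acid for a sense codon, or '*' for a stop."""
    if codon in _STOPS:
        return "*"
    return _STANDARD.forward_table[codon]


# Degeneracy lookup built once from the standard code.  A substitution is
# synonymous iff it preserves the amino acid; for stop codons iff it yields
# another stop (stop-preservation convention).
_DEGENERACY: dict[tuple[str, int], int] = {}
for _codon in map("".join, itertools.product(BASES, repeat=3)):
    for _off in (1, 2, 3):
        _aa = _amino(_codon)
        _syn = 0
        for _b in BASES:
            if _b == _codon[_off - 1]:
                continue
            _alt = _codon[: _off - 1] + _b + _codon[_off:]
            if _amino(_alt) == _aa or (_aa == "*" and _alt in _STOPS):
                _syn += 1
        _DEGENERACY[(_codon, _off)] = {0: 0, 1: 2, 2: 3, 3: 4}[_syn]


def classify_codon_degeneracy(codon: str, offset: int) -> int | None:
    """Degeneracy fold (0, 2, 3 or 4) of ``codon`` at ``offset`` (1..3).

    Fold counts the synonymous members among the three possible point
    substitutions at the offset (0 synonymous → 0D, ..., 3 → 4D).  Stop
    codons count a substitution as synonymous only when it yields another
    stop.  Codons containing non-ACGT characters are uncallable (``None``).
    """
    if offset not in (1, 2, 3):
        raise ValueError(f"offset must be 1..3, got {offset}")
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        return None
    return _DEGENERACY[(codon, offset)]


@dataclass
class DegeneracyMap:
    """Per-genomic-position degeneracy of one gene's CDS.

    Arrays are parallel, ordered by transcription: ``positions`` are
    genomic coordinates, ``fold`` is -1 for uncallable codons, ``offset``
    the within-codon position 1..3 on the coding strand.
    """

    gene_id: str
    seq_id: str
    strand: str
    positions: np.ndarray
    fold: np.ndarray
    offset: np.ndarray
    codons: list[str]
    flags: set[str] = field(default_factory=set)

    def positions_with_fold(self, fold: int) -> np.ndarray:
        return self.positions[self.fold == fold]


def map_gene_degeneracy(gene: GeneModel, genome) -> DegeneracyMap:
    """Map each CDS base of ``gene`` to its degeneracy fold.

    The CDS is spliced in transcription order (reverse-complemented on the
    minus strand) and walked codon by codon, so codons spanning exon
    junctions classify from the spliced sequence.  Internal stops flag the
    gene but the map is still produced; a trailing partial codon (CDS not
    a multiple of 3) is left unclassified and flags the gene incomplete.
    """
    flags: set[str] = set()
    cds = gene.spliced_cds(genome).upper()
    pos = gene.cds_positions_in_transcription_order()
    n_full = len(cds) // 3
    if len(cds) % 3:
        flags.add("incomplete_cds")
    folds = np.full(3 * n_full, -1, dtype=np.int8)
    offsets = np.tile([1, 2, 3], n_full).astype(np.int8)
    codons = []
    for ci in range(n_full):
        codon = cds[3 * ci : 3 * ci + 3]
        codons.append(codon)
        if ci < n_full - 1 and codon in _STOPS:
            flags.add("internal_stop")
        for off in (1, 2, 3):
            f = classify_codon_degeneracy(codon, off)
            folds[3 * ci + off - 1] = -1 if f is None else f
    return DegeneracyMap(
        gene_id=gene.gene_id,
        seq_id=gene.seq_id,
        strand=gene.strand,
        positions=pos[: 3 * n_full],
        fold=folds,
        offset=offsets,
        codons=codons,
        flags=flags,
    )


class SiteClassMap:
    """Exclusive per-base partition of a genome into site classes."""

    def __init__(self, lengths: dict[str, int]):
        self.arrays: dict[str, np.ndarray] = {
            name: np.zeros(n, dtype=np.uint8) for name, n in lengths.items()
        }

    def class_of(self, seq_id: str, pos: int) -> str:
        return CLASS_NAMES[int(self.arrays[seq_id][pos])]

    def class_lengths(self) -> dict[str, int]:
        out = {name: 0 for name in CLASS_CODES}
        for arr in self.arrays.values():
            counts = np.bincount(arr, minlength=5)
            for code, n in enumerate(counts[:5]):
                out[CLASS_NAMES[code]] += int(n)
        return out

    def genome_length(self) -> int:
        return sum(arr.size for arr in self.arrays.values())

    def positions_of(self, seq_id: str, class_name: str) -> np.ndarray:
        return np.flatnonzero(self.arrays[seq_id] == CLASS_CODES[class_name])

    def runs(self, seq_id: str):
        """Maximal (start, end, class_name) runs along one sequence."""
        arr = self.arrays[seq_id]
        if arr.size == 0:
            return
        change = np.flatnonzero(np.diff(arr)) + 1
        bounds = np.concatenate([[0], change, [arr.size]])
        for s, e in zip(bounds[:-1], bounds[1:]):
            yield int(s), int(e), CLASS_NAMES[int(arr[s])]


def call_site_classes(genes: list[GeneModel], genome) -> SiteClassMap:
    """Partition the genome with precedence CDS > UTR5 > UTR3 > intron.

    Classes are painted in ascending precedence so that the highest-ranking
    annotation covering a base wins; unannotated bases stay intergenic.
    Overlapping genes carry no precedence among themselves — only the class
    hierarchy decides.
    """
    scm = SiteClassMap({name: len(seq) for name, seq in genome.items()})
    layers = (
        ("intron", lambda g: g.introns()),
        ("UTR3", lambda g: g.utr3),
        ("UTR5", lambda g: g.utr5),
        ("CDS", lambda g: g.cds_segments),
    )
    for class_name, getter in layers:
        code = CLASS_CODES[class_name]
        for g in genes:
            arr = scm.arrays[g.seq_id]
            for iv in getter(g):
                lo, hi = max(iv.start, 0), min(iv.end, arr.size)
                if lo < hi:
                    seg = arr[lo:hi]
                    seg[seg < code] = code
    return scm


@dataclass
class IntergenicTract:
    interval: Interval
    length: int
    is_short: bool  # < 250 bp
    at_contig_end: bool  # bounds only one gene


SHORT_TRACT_BP = 250


def extract_intergenic_tracts(scm: SiteClassMap) -> list[IntergenicTract]:
    """Maximal intergenic runs, split short (<250 bp) vs long (≥250 bp).

    Contig-terminal runs are included but flagged, as they bound only one
    gene (or none).
    """
    out = []
    for seq_id, arr in scm.arrays.items():
        for s, e, cname in scm.runs(seq_id):
            if cname != "intergenic":
                continue
            out.append(
                IntergenicTract(
                    interval=Interval(seq_id, s, e),
                    length=e - s,
                    is_short=(e - s) < SHORT_TRACT_BP,
                    at_contig_end=(s == 0 or e == arr.size),
                )
            )
    return out


@dataclass
class IntronRecord:
    gene_id: str
    transcript_id: str
    interval: Interval
    length: int
    ordinal: int  # 1 = first intron in transcription order
    relative_position: float  # % offset of intron start from transcript 5' end
    within_cds: bool


def intron_table(genes: list[GeneModel], cds_internal_only: bool = False) -> list[IntronRecord]:
    """One record per intron of each (longest-isoform) model.

    Ordinals follow transcription order: on the minus strand the first
    intron is the one with the highest genomic coordinate.  Relative
    position is the intron's 5' offset from the transcript start as a
    percentage of transcript span.  ``cds_internal_only`` restricts to
    introns lying between CDS segments.
    """
    out = []
    for g in genes:
        introns = g.introns()
        if not introns:
            continue
        if g.strand == "-":
            ordered = introns[::-1]
        else:
            ordered = introns
        span = g.end - g.start
        cds_lo = min((iv.start for iv in g.cds_segments), default=None)
        cds_hi = max((iv.end for iv in g.cds_segments), default=None)
        for k, iv in enumerate(ordered, start=1):
            within = (
                cds_lo is not None and iv.start >= cds_lo and iv.end <= cds_hi
            )
            if cds_internal_only and not within:
                continue
            if g.strand == "-":
                offset = g.end - iv.end
            else:
                offset = iv.start - g.start
            out.append(
                IntronRecord(
                    gene_id=g.gene_id,
                    transcript_id=g.transcript_id,
                    interval=iv,
                    length=len(iv),
                    ordinal=k,
                    relative_position=100.0 * offset / span,
                    within_cds=within,
                )
            )
    return out


# stop-codon positions where no substitution yields another stop
_STOP_0D = {"TAA": (1,), "TGA": (1, 3), "TAG": (1, 2)}


def high_impact_sites(gene: GeneModel, genome) -> set[tuple[str, int]]:
    """Positions where point mutations disrupt the gene outright.

    Union of the three start-codon bases, the stop-preservation 0D bases of
    the stop codon, and the two terminal dinucleotides at each end of every
    intron.  Missing or unexpected start/stop codons drop that component
    and flag the gene.
    """
    pos = gene.cds_positions_in_transcription_order()
    cds = gene.spliced_cds(genome).upper()
    sites: set[tuple[str, int]] = set()
    if len(cds) >= 3 and cds[:3] == "ATG":
        for p in pos[:3]:
            sites.add((gene.seq_id, int(p)))
    else:
        gene.flags.add("no_start_codon")
    if len(cds) >= 3 and cds[-3:] in _STOP_0D:
        stop = cds[-3:]
        tail = pos[-3:]
        for off in _STOP_0D[stop]:
            sites.add((gene.seq_id, int(tail[off - 1])))
    else:
        gene.flags.add("no_stop_codon")
    for iv in gene.introns():
        for p in (iv.start, iv.start + 1, iv.end - 2, iv.end - 1):
            sites.add((gene.seq_id, int(p)))
    return sites


def summarize_annotation(genes: list[GeneModel], genome, repeats=None) -> pd.Series:
    """Headline annotation metrics for one genome.

    Gene/UTR coverage (Mb and %), mean intron count per CDS, median intron
    length, median intergenic distance between adjacent genes, and GC% over
    non-N bases.  Repeats (if given) add repeat coverage.
    """
    glen = sum(len(s) for s in genome.values())
    cover = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.items()}
    utr_cover = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.items()}
    for g in genes:
        cover[g.seq_id][g.start : g.end] = True
        for iv in [*g.utr5, *g.utr3]:
            utr_cover[g.seq_id][iv.start : iv.end] = True
    gene_bp = int(sum(c.sum() for c in cover.values()))
    utr_bp = int(sum(c.sum() for c in utr_cover.values()))

    introns = intron_table(genes, cds_internal_only=True)
    per_gene_counts = pd.Series([r.gene_id for r in introns]).value_counts()
    all_gene_ids = [g.gene_id for g in genes]
    mean_introns = (
        per_gene_counts.reindex(all_gene_ids).fillna(0).mean() if genes else np.nan
    )
    median_intron = (
        float(np.median([r.length for r in introns])) if introns else np.nan
    )

    distances = []
    for seq_id in genome:
        spans = sorted((g.start, g.end) for g in genes if g.seq_id == seq_id)
        for (s1, e1), (s2, e2) in zip(spans, spans[1:]):
            if s2 > e1:
                distances.append(s2 - e1)
    median_intergenic = float(np.median(distances)) if distances else np.nan

    gc = at = 0
    for seq in genome.values():
        up = seq.upper()
        gc += up.count("G") + up.count("C")
        at += up.count("A") + up.count("T")
    gc_pct = 100.0 * gc / (gc + at) if gc + at else np.nan

    metrics = {
        "genome_mb": glen / 1e6,
        "n_genes": len({g.gene_id for g in genes}),
        "gene_mb": gene_bp / 1e6,
        "gene_pct": 100.0 * gene_bp / glen if glen else np.nan,
        "utr_mb": utr_bp / 1e6,
        "utr_pct": 100.0 * utr_bp / glen if glen else np.nan,
        "mean_introns_per_cds": float(mean_introns) if genes else np.nan,
        "median_intron_bp": median_intron,
        "median_intergenic_bp": median_intergenic,
        "gc_pct": gc_pct,
    }
    if repeats is not None:
        rcov = {name: np.zeros(len(seq), dtype=bool) for name, seq in genome.items()}
        for iv in repeats:
            if iv.seq_id in rcov:
                rcov[iv.seq_id][iv.start : iv.end] = True
        rep_bp = int(sum(c.sum() for c in rcov.values()))
        metrics["repeat_mb"] = rep_bp / 1e6
        metrics["repeat_pct"] = 100.0 * rep_bp / glen if glen else np.nan
    return pd.Series(metrics)
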