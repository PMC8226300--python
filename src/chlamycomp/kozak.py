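"""Kozak-context model: per-site information content and bit-score matching.

The model covers the ten sites flanking a start codon (−5..−1 and +4..+8,
numbering the A of ATG as +1; the ATG itself carries no information about
context quality).  Each site holds base frequencies, information content
R_s = 2 − H_s bits, and a consensus base; a query scores the sum of
``f_consensus * R_s`` over sites where it matches the consensus.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import GeneModel, revcomp

__all__ = [
    "SITE_LABELS",
    "KozakModel",
    "build_kozak_model",
    "kozak_score",
    "random_contexts",
    "gene_kozak_context",
]

BASES = "ACGT"
SITE_LABELS = [-5, -4, -3, -2, -1, 4, 5, 6, 7, 8]


@dataclass
class KozakModel:
    freqs: np.ndarray  # 10 × 4, rows sum to 1
    info_bits: np.ndarray  # R_s = 2 − H_s per site
    consensus: str  # 10-mer
    n_training: int
    tie_sites: list[int] = field(default_factory=list)

    @property
    def max_score(self) -> float:
        """Score of the consensus sequence itself: Σ f_consensus·R_s."""
        idx = [BASES.index(b) for b in self.consensus]
        return float(sum(self.freqs[s, idx[s]] * self.info_bits[s] for s in range(10)))


def build_kozak_model(contexts) -> KozakModel:
    """Train per-site frequencies from 10-mer contexts (5 up + 5 down of ATG).

    Contexts containing non-ACGT characters are dropped.  No small-sample
    entropy correction is applied — training sets are expected to be large,
    and a warning marks models built from fewer than 50 contexts.
    Consensus ties resolve to the lexicographically first base and are
    flagged.
    """
    clean = []
    for ctx in contexts:
        ctx = ctx.upper()
        if len(ctx) != 10:
            raise ValueError(f"context length {len(ctx)} != 10")
        if all(b in BASES for b in ctx):
            clean.append(ctx)
    if not clean:
        raise ValueError("no usable training contexts")
    if len(clean) < 50:
        warnings.warn(f"only {len(clean)} training contexts: model may be unstable")
    counts = np.zeros((10, 4))
    for ctx in clean:
        for s, b in enumerate(ctx):
            counts[s, BASES.index(b)] += 1
    freqs = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(freqs > 0, freqs * np.log2(freqs), 0.0)
    entropy = -plogp.sum(axis=1)
    info = 2.0 - entropy
    consensus = []
    ties = []
    for s in range(10):
        best = freqs[s].max()
        winners = [BASES[i] for i in range(4) if freqs[s, i] == best]
        if len(winners) > 1:
            ties.append(SITE_LABELS[s])
        consensus.append(winners[0])
    return KozakModel(
        freqs=freqs,
        info_bits=info,
        consensus="".join(consensus),
        n_training=len(clean),
        tie_sites=ties,
    )


@dataclass
class KozakScore:
    gene_id: str
    score: float
    n_matching: int


def kozak_score(
    model: KozakModel, context: str, gene_id: str = "", match_only: bool = True
) -> KozakScore:
    """Score a 10-mer context against the model.

    Default scoring credits ``f_consensus·R_s`` only where the query base
    equals the consensus ("matching base" reading); ``match_only=False``
    instead credits the query base's own height ``f_query·R_s`` at every
    site.  N at a site contributes 0 either way.
    """
    context = context.upper()
    if len(context) != 10:
        raise ValueError(f"context length {len(context)} != 10")
    total = 0.0
    matches = 0
    for s, b in enumerate(context):
        if b not in BASES:
            continue
        if match_only:
            if b == model.consensus[s]:
                total += model.freqs[s, BASES.index(b)] * model.info_bits[s]
                matches += 1
        else:
            total += model.freqs[s, BASES.index(b)] * model.info_bits[s]
            if b == model.consensus[s]:
                matches += 1
    return KozakScore(gene_id, float(total), matches)


def random_contexts(n: int, gc_fraction: float, seed) -> list[str]:
    """i.i.d. 10-mers with P(G)=P(C)=gc/2 and P(A)=P(T)=(1−gc)/2."""
    if not (0.0 < gc_fraction <= 1.0):
        raise ValueError("gc_fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    p = [
        (1 - gc_fraction) / 2,
        gc_fraction / 2,
        gc_fraction / 2,
        (1 - gc_fraction) / 2,
    ]
    draws = rng.choice(4, size=(n, 10), p=p)
    lut = np.array(list(BASES))
    return ["".join(row) for row in lut[draws]]


def gene_kozak_context(gene: GeneModel, genome) -> tuple[str | None, set[str]]:
    """Genomic (pre-mRNA) 10-mer around a gene's start codon.

    Returns (context, flags).  The context is the 5 bases upstream of the
    ATG plus the 5 bases immediately downstream of it, read on the coding
    strand from the unspliced sequence.  Windows truncated by contig edges
    return None; windows that extend past the start codon's exon are
    flagged ``crosses_intron``.
    """
    flags: set[str] = set()
    pos = gene.cds_positions_in_transcription_order()
    if pos.size < 3:
        return None, {"no_cds"}
    seq = genome[gene.seq_id]
    atg_first = int(pos[0])
    if gene.strand == "-":
        up = seq[atg_first + 1 : atg_first + 6]
        down = seq[atg_first - 7 : atg_first - 2] if atg_first - 7 >= 0 else ""
        if len(up) < 5 or len(down) < 5:
            return None, {"truncated"}
        ctx = revcomp(up) + revcomp(down)
        window = [atg_first + k for k in range(1, 6)] + [
            atg_first - k for k in range(3, 8)
        ]
    else:
        up = seq[atg_first - 5 : atg_first]
        down = seq[atg_first + 3 : atg_first + 8]
        if atg_first - 5 < 0 or len(up) < 5 or len(down) < 5:
            return None, {"truncated"}
        ctx = up + down
        window = [atg_first - k for k in range(1, 6)] + [
            atg_first + k for k in range(3, 8)
        ]
    exon_of_start = next(
        (iv for iv in gene.exons if iv.start <= atg_first < iv.end), None
    )
    if exon_of_start is not None:
        down_positions = window[5:]
        if any(not (exon_of_start.start <= p < exon_of_start.end) for p in down_positions):
            flags.add("crosses_intron")
    return ctx, flags
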