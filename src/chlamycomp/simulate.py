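"""Seeded generators for every input the analysis pipeline consumes.

The generator plants known structure — gene models with an atypical
intron-length mixture, two codon-usage regimes, Kozak contexts from a
known position model, a multi-species alignment evolved on a fixed tree
with planted conserved/ultraconserved intervals, and haploid variants
with per-site-class diversity targets — and records everything in a truth
manifest so the analysis modules can be tested against exact or
statistical ground truth.  Everything is deterministic given (spec, seed).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.linalg import expm

from .io import (
    GeneModel,
    Interval,
    VariantTable,
    revcomp,
    write_bed,
    write_fasta,
    write_gff3,
    write_maf,
    write_vcf,
    AlignmentBlock,
    MafRow,
)
from .codon import SENSE_CODONS, subfamily_map
from .siteclass import CLASS_CODES, call_site_classes, high_impact_sites, map_gene_degeneracy
from .kozak import BASES

__all__ = [
    "GenomeSpec",
    "AlignmentSpec",
    "SimulatedGenome",
    "SimulatedAlignment",
    "simulate_genome",
    "simulate_alignment",
    "simulate_variants",
    "write_dataset",
    "DEFAULT_PI_TARGETS",
]

AA_CODONS: dict[str, list[str]] = {}
for _c in SENSE_CODONS + ["ATG", "TGG"]:
    from .siteclass import _amino

    AA_CODONS.setdefault(_amino(_c), []).append(_c)
AMINO_ACIDS = sorted(AA_CODONS)


def optimal_codon_set(split_families: bool = True) -> dict[str, str]:
    """One designated optimal codon per sub-family (prefers -C, then -G)."""
    fam = subfamily_map(split_families)
    out = {}
    for sub in sorted(set(fam.values())):
        members = sorted(c for c in fam if fam[c] == sub)
        members.sort(key=lambda c: ("CGTA".index(c[2]), c))
        out[sub] = members[0]
    return out


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------


@dataclass
class GenomeSpec:
    """Study conditions for the synthetic genome.

    Defaults emulate a compact algal genome: GC-rich sequence, ~8 exons
    per gene, an intron-length mixture lacking the short-intron peak of
    most compact genomes (long component with median ~230 bp), intergenic
    tracts mostly shorter than 250 bp by count, telomeric motif arrays at
    contig termini, and one clustered LINE-like repeat region per contig
    standing in for a centromere.
    """

    n_sequences: int = 2
    seq_length: int = 1_000_000
    gc: float = 0.64
    n_genes: int = 300
    spurious_fraction: float = 0.2
    mean_exons_genuine: float = 8.0
    mean_exons_spurious: float = 2.1
    median_cds_codons_genuine: int = 600
    cds_sigma_genuine: float = 0.35
    median_cds_codons_spurious: int = 110
    cds_sigma_spurious: float = 0.35
    min_cds_codons: int = 40
    # intron mixture: short uniform [55, 95], long lognormal median 230
    intron_short_weight_first: float = 0.6
    intron_short_weight_rest: float = 0.08
    intron_long_median: float = 230.0
    intron_long_sigma: float = 0.45
    # intergenic tract mixture (short < 250 bp dominates by count)
    tract_short_weight: float = 0.635
    tract_long_median: float = 700.0
    tract_long_sigma: float = 0.9
    utr5_range: tuple[int, int] = (30, 150)
    utr3_range: tuple[int, int] = (50, 400)
    # codon regimes
    q_optimal: float = 0.8  # P(sub-family-optimal codon) in genuine genes
    # Kozak position model: consensus with this per-site probability
    kozak_consensus: str = "CAACAGCCGC"
    kozak_consensus_prob: float = 0.7
    telomere_motif: str = "TTTTAGGG"
    telomere_copies: int = 25
    centromere_window: int = 80_000
    centromere_te_count: int = 25
    centromere_te_length: int = 2_000
    scattered_te_count: int = 30
    scattered_te_length: int = 1_500
    simple_repeat_count: int = 50
    simple_repeat_length: int = 200
    te_family: str = "ZeppL_sim"
    seed: int = 0


# species tree: reference at the root, a Chlamydomonas-like trio clade and
# a ladder of five increasingly divergent species (substitutions/site)
REFERENCE_SPECIES = "crei_sim"
TRIO_SPECIES = ["cinc_sim", "cschl_sim"]
DEFAULT_TREE: list[tuple[str, str, float]] = [
    ("anc_trio", "REF", 0.17),
    ("cinc_sim", "anc_trio", 0.17),
    ("cschl_sim", "anc_trio", 0.28),
    ("anc_a", "REF", 0.25),
    ("sp4_sim", "anc_a", 0.30),
    ("anc_b", "anc_a", 0.10),
    ("sp5_sim", "anc_b", 0.30),
    ("anc_c", "anc_b", 0.10),
    ("sp6_sim", "anc_c", 0.30),
    ("anc_d", "anc_c", 0.10),
    ("sp7_sim", "anc_d", 0.30),
    ("sp8_sim", "anc_d", 0.40),
]


@dataclass
class AlignmentSpec:
    """Conditions for the simulated whole-genome alignment."""

    tree: list[tuple[str, str, float]] = field(default_factory=lambda: list(DEFAULT_TREE))
    kappa: float = 2.5  # HKY transition/transversion rate ratio
    rho_ce: float = 0.2  # rate multiplier inside planted conserved elements
    # per-class CE coverage targets (intron uses the 1/length rule instead)
    ce_coverage: dict = field(
        default_factory=lambda: {
            "CDS": 0.60,
            "UTR5": 0.25,
            "UTR3": 0.11,
            "intergenic": 0.04,
        }
    )
    intron_ce_bases: int = 28  # per-intron planted CE bases (density ∝ 1/length)
    n_uces: int = 40
    n_deep_uces: int = 8
    uce_len_range: tuple[int, int] = (50, 120)
    uce_min_len: int = 50
    deletion_rate_scale: float = 2.7  # aligned fraction = exp(-scale · distance)
    deletion_mean_len: int = 200
    block_length: int = 1000
    duplicate_row_rate: float = 0.05  # per-block chance of a paralog row
    seed: int = 0


DEFAULT_PI_TARGETS = {
    "CDS": 0.0144,
    "UTR5": 0.02,
    "UTR3": 0.02,
    "intron": 0.0248,
    "intergenic": 0.022,
}


# ---------------------------------------------------------------------------
# Genome simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedGenome:
    spec: GenomeSpec
    sequences: dict[str, str]
    genes: list[GeneModel]
    labels: dict[str, str]  # gene_id -> genuine | spurious
    repeats: list[tuple[Interval, str, str]]  # (interval, family, class)
    kozak_freqs: np.ndarray  # planted 10 × 4 position model
    optimal_codons: dict[str, str]
    exon_scores: pd.DataFrame  # gene_id, exon_index, exon_bp, score
    cds_scores: pd.DataFrame  # gene_id, score
    orthogroups: pd.DataFrame  # orthogroup, species, gene_id
    domains: pd.DataFrame  # gene_id, domain
    truth: dict


def _random_bases(n: int, gc: float, rng) -> np.ndarray:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=p)


def _draw_codons_biased(aa_seq: list[str], q: float, optimal: dict[str, str], rng) -> list[str]:
    """Codon per amino acid: sub-family optimum w.p. q, others uniform."""
    fam = subfamily_map(True)
    out = [""] * len(aa_seq)
    arr = np.array(aa_seq)
    for aa in sorted(set(aa_seq)):  # sorted: draw order must not depend on hashing
        idx = np.flatnonzero(arr == aa)
        codons = AA_CODONS[aa]
        if len(codons) == 1:
            for i in idx:
                out[i] = codons[0]
            continue
        opt = optimal[fam[codons[0]]]
        # families split into sub-families keep one global optimum: the
        # optimum of the first codon's sub-family
        rest = [c for c in codons if c != opt]
        probs = [q] + [(1 - q) / len(rest)] * len(rest)
        draw = rng.choice(len(probs), size=idx.size, p=probs)
        pool = [opt] + rest
        for i, d in zip(idx, draw):
            out[i] = pool[d]
    return out


def _draw_codons_background(n: int, gc: float, rng) -> list[str]:
    """GC-matched random codons, stops excluded."""
    base_p = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    codons = SENSE_CODONS + ["ATG", "TGG"]
    w = np.array([base_p[c[0]] * base_p[c[1]] * base_p[c[2]] for c in codons])
    w /= w.sum()
    draw = rng.choice(len(codons), size=n, p=w)
    return [codons[d] for d in draw]


def _draw_kozak_context(freqs: np.ndarray, rng) -> str:
    return "".join(BASES[rng.choice(4, p=freqs[s])] for s in range(10))


@dataclass
class _GeneLayout:
    sequence: str  # gene-local sequence (forward/coding orientation)
    exons: list[tuple[int, int]]  # gene-local coordinates
    cds: list[tuple[int, int]]
    phases: list[int]
    utr5: tuple[int, int]
    utr3: tuple[int, int]
    intron_lengths: list[int]


def _intron_length(rng, spec: GenomeSpec, first: bool) -> int:
    w = spec.intron_short_weight_first if first else spec.intron_short_weight_rest
    if rng.random() < w:
        return int(rng.integers(55, 96))
    ln = rng.lognormal(math.log(spec.intron_long_median), spec.intron_long_sigma)
    return int(max(105, min(ln, 3000)))


def _build_gene(rng, spec: GenomeSpec, label: str, kozak_freqs: np.ndarray,
                optimal: dict[str, str]) -> _GeneLayout:
    genuine = label == "genuine"
    med = spec.median_cds_codons_genuine if genuine else spec.median_cds_codons_spurious
    sigma = spec.cds_sigma_genuine if genuine else spec.cds_sigma_spurious
    n_codons = max(spec.min_cds_codons, int(rng.lognormal(math.log(med), sigma)))
    mean_ex = spec.mean_exons_genuine if genuine else spec.mean_exons_spurious
    n_exons = max(1, 1 + rng.poisson(mean_ex - 1))

    # codon sequence: ATG + internal codons + stop
    n_internal = n_codons - 2
    if genuine:
        aa = [AMINO_ACIDS[i] for i in rng.integers(0, len(AMINO_ACIDS), n_internal)]
        internal = _draw_codons_biased(aa, spec.q_optimal, optimal, rng)
    else:
        internal = _draw_codons_background(n_internal, spec.gc, rng)
    stop = ["TAA", "TAG", "TGA"][rng.integers(0, 3)]
    cds = "ATG" + "".join(internal) + stop

    # Kozak context: genuine genes from the planted model, spurious from
    # GC-matched noise; bases +4..+8 overwrite CDS positions 3..7
    while True:
        if genuine:
            ctx = _draw_kozak_context(kozak_freqs, rng)
        else:
            ctx = "".join(
                chr(b) for b in _random_bases(10, spec.gc, rng)
            )
        trial = cds[:3] + ctx[5:] + cds[8:]
        if trial[3:6] not in ("TAA", "TAG", "TGA") and trial[6:9] not in (
            "TAA",
            "TAG",
            "TGA",
        ):
            cds = trial
            break

    u5 = int(rng.integers(*spec.utr5_range))
    u3 = int(rng.integers(*spec.utr3_range))
    utr5_seq = "".join(chr(b) for b in _random_bases(u5, spec.gc, rng))
    utr5_seq = utr5_seq[:-5] + ctx[:5]  # upstream half of the context
    utr3_seq = "".join(chr(b) for b in _random_bases(u3, spec.gc, rng))

    cds_len = len(cds)
    n_exons = min(n_exons, cds_len // 9)
    rem = cds_len - 9 * n_exons
    alloc = rng.multinomial(rem, [1.0 / n_exons] * n_exons)
    parts = [9 + int(a) for a in alloc]
    introns = [
        _intron_length(rng, spec, first=(k == 0)) for k in range(n_exons - 1)
    ]

    seq_parts = [utr5_seq]
    exons: list[tuple[int, int]] = []
    cds_ivs: list[tuple[int, int]] = []
    phases: list[int] = []
    pos = u5
    cds_cursor = 0
    exon_start = 0
    for k, part in enumerate(parts):
        seq_parts.append(cds[cds_cursor : cds_cursor + part])
        phases.append((3 - cds_cursor % 3) % 3)
        cds_ivs.append((pos, pos + part))
        cds_cursor += part
        pos += part
        if k < len(parts) - 1:
            exons.append((exon_start, pos))
            ilen = introns[k]
            # canonical-ish splice dinucleotides
            inner = "".join(chr(b) for b in _random_bases(ilen - 4, spec.gc, rng))
            seq_parts.append("GT" + inner + "AG")
            pos += ilen
            exon_start = pos
    seq_parts.append(utr3_seq)
    pos += u3
    exons.append((exon_start, pos))
    return _GeneLayout(
        sequence="".join(seq_parts),
        exons=exons,
        cds=cds_ivs,
        phases=phases,
        utr5=(0, u5),
        utr3=(pos - u3, pos),
        intron_lengths=introns,
    )


def _tract_length(rng, spec: GenomeSpec) -> int:
    if rng.random() < spec.tract_short_weight:
        return int(rng.integers(20, 250))
    ln = rng.lognormal(math.log(spec.tract_long_median), spec.tract_long_sigma)
    return int(max(250, min(ln, 20000)))


def _kozak_freq_matrix(spec: GenomeSpec) -> np.ndarray:
    freqs = np.zeros((10, 4))
    p = spec.kozak_consensus_prob
    for s in range(10):
        freqs[s, :] = (1 - p) / 3
        freqs[s, BASES.index(spec.kozak_consensus[s])] = p
    return freqs


def simulate_genome(spec: GenomeSpec | None = None, seed: int | None = None) -> SimulatedGenome:
    """Generate genome FASTA content, gene models, repeats and evidence.

    Genes are placed without overlap, separated by intergenic tracts drawn
    from the short/long mixture; telomere arrays are written at contig
    termini and a clustered repeat region marks a designated centromere
    per contig.  Raises if the requested genes cannot be packed.
    """
    spec = spec or GenomeSpec()
    if seed is not None:
        spec = dataclass_replace(spec, seed=seed)
    rng = np.random.default_rng(spec.seed)
    kozak_freqs = _kozak_freq_matrix(spec)
    optimal = optimal_codon_set(True)

    seq_names = [f"chr_{i + 1}" for i in range(spec.n_sequences)]
    telo = spec.telomere_motif * spec.telomere_copies
    telo_rc = revcomp(telo)
    L = spec.seq_length

    arrays = {name: _random_bases(L, spec.gc, rng) for name in seq_names}
    for name in seq_names:
        arrays[name][: len(telo_rc)] = np.frombuffer(telo_rc.encode(), dtype=np.uint8)
        arrays[name][L - len(telo) :] = np.frombuffer(telo.encode(), dtype=np.uint8)

    cen_start = {name: L // 2 - spec.centromere_window // 2 for name in seq_names}
    n_spurious = int(round(spec.n_genes * spec.spurious_fraction))
    labels_list = ["spurious"] * n_spurious + ["genuine"] * (spec.n_genes - n_spurious)
    rng.shuffle(labels_list)

    genes: list[GeneModel] = []
    labels: dict[str, str] = {}
    margin = len(telo) + 100
    cursors = {name: margin for name in seq_names}
    seq_cycle = 0
    for gi, label in enumerate(labels_list):
        layout = _build_gene(rng, spec, label, kozak_freqs, optimal)
        strand = "+" if rng.random() < 0.5 else "-"
        glen = len(layout.sequence)
        placed = False
        for _ in range(spec.n_sequences):
            name = seq_names[seq_cycle % spec.n_sequences]
            seq_cycle += 1
            start = cursors[name] + _tract_length(rng, spec)
            cs, cw = cen_start[name], spec.centromere_window
            if start < cs + cw and start + glen > cs:
                start = cs + cw + 200  # keep genes off the centromere cluster
            if start + glen <= L - margin:
                placed = True
                break
        if not placed:
            raise ValueError(
                f"infeasible packing: gene {gi + 1}/{spec.n_genes} does not fit"
            )
        cursors[name] = start + glen
        gene_seq = layout.sequence if strand == "+" else revcomp(layout.sequence)
        arrays[name][start : start + glen] = np.frombuffer(
            gene_seq.encode(), dtype=np.uint8
        )

        def to_genomic(a: int, b: int) -> tuple[int, int]:
            if strand == "+":
                return start + a, start + b
            return start + glen - b, start + glen - a

        gid = f"g{gi + 1:04d}"
        tid = f"{gid}.t1"
        exons = sorted(
            Interval(name, *to_genomic(a, b), strand) for a, b in layout.exons
        )
        cds_pairs = [
            (Interval(name, *to_genomic(a, b), strand), ph)
            for (a, b), ph in zip(layout.cds, layout.phases)
        ]
        cds_pairs.sort(key=lambda t: t[0].start)
        u5a, u5b = layout.utr5
        u3a, u3b = layout.utr3
        model = GeneModel(
            gene_id=gid,
            transcript_id=tid,
            seq_id=name,
            strand=strand,
            exons=exons,
            cds_segments=[iv for iv, _ in cds_pairs],
            cds_phases=[ph for _, ph in cds_pairs],
            utr5=[Interval(name, *to_genomic(u5a, u5b), strand)] if u5b > u5a else [],
            utr3=[Interval(name, *to_genomic(u3a, u3b), strand)] if u3b > u3a else [],
        )
        genes.append(model)
        labels[gid] = label

    repeats: list[tuple[Interval, str, str]] = []
    for name in seq_names:
        cs = cen_start[name]
        for _ in range(spec.centromere_te_count):
            s = int(rng.integers(cs, cs + spec.centromere_window - spec.centromere_te_length))
            repeats.append(
                (Interval(name, s, s + spec.centromere_te_length), spec.te_family, "TE")
            )
        for _ in range(spec.scattered_te_count):
            s = int(rng.integers(margin, L - margin - spec.scattered_te_length))
            repeats.append(
                (Interval(name, s, s + spec.scattered_te_length), "TE_other_sim", "TE")
            )
        for _ in range(spec.simple_repeat_count):
            s = int(rng.integers(margin, L - margin - spec.simple_repeat_length))
            repeats.append(
                (Interval(name, s, s + spec.simple_repeat_length), "simple_sim", "simple")
            )

    sequences = {name: bytes(arrays[name]).decode() for name in seq_names}
    ev = _simulate_evidence(rng, genes, labels)
    truth = {
        "seed": spec.seed,
        "labels": labels,
        "optimal_codons": optimal,
        "kozak_consensus": spec.kozak_consensus,
        "kozak_consensus_prob": spec.kozak_consensus_prob,
        "telomere_motif": spec.telomere_motif,
        "telomere_copies": spec.telomere_copies,
        "centromere_windows": {
            name: [cen_start[name], cen_start[name] + spec.centromere_window]
            for name in seq_names
        },
        "gc": spec.gc,
    }
    return SimulatedGenome(
        spec=spec,
        sequences=sequences,
        genes=genes,
        labels=labels,
        repeats=repeats,
        kozak_freqs=kozak_freqs,
        optimal_codons=optimal,
        exon_scores=ev[0],
        cds_scores=ev[1],
        orthogroups=ev[2],
        domains=ev[3],
        truth=truth,
    )


def dataclass_replace(spec, **kw):
    from dataclasses import replace

    return replace(spec, **kw)


def _simulate_evidence(rng, genes: list[GeneModel], labels: dict[str, str]):
    """External-evidence tables: per-exon scores, orthogroups, domains.

    Genuine genes receive clearly positive exon scores, an orthogroup
    row and/or a domain; spurious genes get zero/negative scores and no
    ortholog or domain evidence, mirroring how external scorers see them.
    """
    other_species = ["spA", "spB", "spC", "spD", "spE"]
    exon_rows, cds_rows, og_rows, dom_rows = [], [], [], []
    og_counter = 0
    for g in genes:
        genuine = labels[g.gene_id] == "genuine"
        exons = g.exons_in_transcription_order()
        for k, iv in enumerate(exons, start=1):
            bp = len(iv)
            if bp < 45:
                continue  # upstream scorer skips short exons
            if genuine:
                score = float(max(2.0, rng.normal(45.0, 15.0)))
            else:
                score = 0.0 if rng.random() < 0.7 else float(min(-0.5, rng.normal(-8.0, 3.0)))
            exon_rows.append(
                {"gene_id": g.gene_id, "exon_index": k, "exon_bp": bp, "score": score}
            )
        cds_rows.append(
            {
                "gene_id": g.gene_id,
                "score": float(max(2.0, rng.normal(40.0, 10.0))) if genuine else 0.0,
            }
        )
        if genuine:
            has_domain = rng.random() < 0.5
            has_ortholog = (not has_domain) or rng.random() < 0.9
            if has_ortholog:
                og_counter += 1
                og = f"OG{og_counter:05d}"
                og_rows.append(
                    {"orthogroup": og, "species": "focal", "gene_id": g.gene_id}
                )
                for sp in other_species:
                    for j in range(int(rng.integers(1, 3))):
                        og_rows.append(
                            {
                                "orthogroup": og,
                                "species": sp,
                                "gene_id": f"{sp}_{g.gene_id}_{j}",
                            }
                        )
            if has_domain:
                dom_rows.append(
                    {"gene_id": g.gene_id, "domain": f"DOM{int(rng.integers(1, 40)):04d}"}
                )
    return (
        pd.DataFrame(exon_rows),
        pd.DataFrame(cds_rows),
        pd.DataFrame(og_rows),
        pd.DataFrame(dom_rows),
    )


# ---------------------------------------------------------------------------
# Alignment simulation
# ---------------------------------------------------------------------------


@dataclass
class SimulatedAlignment:
    spec: AlignmentSpec
    blocks: list[AlignmentBlock]
    species: list[str]
    ce_intervals: list[Interval]
    uce_intervals: list[tuple[Interval, bool]]  # (interval, is_deep)
    truth: dict


_B2I = np.full(256, -1, dtype=np.int8)
for _i, _b in enumerate(b"ACGT"):
    _B2I[_b] = _i
for _i, _b in enumerate(b"acgt"):
    _B2I[_b] = _i


def _hky_matrix(kappa: float, pi: np.ndarray) -> np.ndarray:
    """HKY85 rate matrix (A,C,G,T order), scaled to 1 substitution/site."""
    Q = np.zeros((4, 4))
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kappa if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -(pi * np.diag(Q)).sum()
    return Q / rate


def _evolve(parent: np.ndarray, branch: float, rates: np.ndarray, Q: np.ndarray, rng) -> np.ndarray:
    """Evolve base-index array one branch under per-site rate multipliers."""
    child = parent.copy()
    for mult in np.unique(rates):
        if mult == 0:
            continue
        P = expm(Q * branch * mult)
        cum = np.cumsum(P, axis=1)
        mask = rates == mult
        u = rng.random(int(mask.sum()))
        sub = parent[mask]
        out = np.empty_like(sub)
        for b in range(4):
            sel = sub == b
            if sel.any():
                out[sel] = np.searchsorted(cum[b], u[sel], side="right")
        child[mask] = np.clip(out, 0, 3)
    return child


def _plant_ces(rng, scm, aspec: AlignmentSpec, introns) -> tuple[list[Interval], dict]:
    """Plant CE intervals per site class; introns get a fixed CE budget each."""
    ces: list[Interval] = []
    realized: dict[str, float] = {}
    for cname, target in aspec.ce_coverage.items():
        code = CLASS_CODES[cname]
        covered = 0
        class_bp = 0
        for seq, arr in scm.arrays.items():
            mask = arr == code
            class_bp += int(mask.sum())
            for s, e, name in scm.runs(seq):
                if name != cname:
                    continue
                m = e - s
                want = int(round(target * m))
                if want < 3:
                    continue
                off = int(rng.integers(0, m - want + 1))
                ces.append(Interval(seq, s + off, s + off + want))
                covered += want
        realized[cname] = covered / class_bp if class_bp else 0.0
    covered = 0
    class_bp = 0
    for rec in introns:
        iv = rec.interval
        m = rec.length
        class_bp += m
        want = min(int(0.9 * m), aspec.intron_ce_bases)
        if want < 3:
            continue
        off = int(rng.integers(0, m - want + 1))
        ces.append(Interval(iv.seq_id, iv.start + off, iv.start + off + want))
        covered += want
    realized["intron"] = covered / class_bp if class_bp else 0.0
    return ces, realized


def _plant_uces(rng, sim: SimulatedGenome, scm, aspec: AlignmentSpec):
    """Choose UCE intervals inside genuine-gene CDS and long introns."""
    candidates: list[Interval] = []
    for g in sim.genes:
        if sim.labels[g.gene_id] != "genuine":
            continue
        for iv in g.cds_segments:
            if len(iv) >= aspec.uce_len_range[1] + 10:
                candidates.append(iv)
        for iv in g.introns():
            if len(iv) >= aspec.uce_len_range[1] + 10:
                candidates.append(iv)
    rng.shuffle(candidates)
    chosen: list[tuple[Interval, bool]] = []
    used: list[Interval] = []
    for host in candidates:
        if len(chosen) >= aspec.n_uces:
            break
        length = int(rng.integers(*aspec.uce_len_range))
        if len(host) < length + 4:
            continue
        off = int(rng.integers(2, len(host) - length - 1))
        iv = Interval(host.seq_id, host.start + off, host.start + off + length)
        if any(iv.overlaps(u) for u in used):
            continue
        used.append(iv)
        chosen.append((iv, len(chosen) < aspec.n_deep_uces))
    return chosen


def simulate_alignment(
    sim: SimulatedGenome, aspec: AlignmentSpec | None = None, seed: int | None = None
) -> SimulatedAlignment:
    """Evolve the reference down the species tree and emit MAF blocks.

    Site-independent HKY with per-site rate multipliers: 1 in neutral
    sequence, ``rho_ce`` inside planted CEs, 0 on trio branches inside
    planted UCEs (0 everywhere for the deep subset).  Per-species block
    deletions thin unconstrained sequence with probability increasing
    with divergence; genuine-gene CDS is never deleted, so codon frame
    survives.  Deterministic guards break any accidental trio-conserved
    run that would blur the planted UCE truth.
    """
    aspec = aspec or AlignmentSpec()
    if seed is not None:
        aspec = dataclass_replace(aspec, seed=seed)
    rng = np.random.default_rng(aspec.seed)

    from .siteclass import intron_table

    scm = call_site_classes(sim.genes, sim.sequences)
    introns = intron_table(sim.genes)
    ces, realized_ce = _plant_ces(rng, scm, aspec, introns)
    uces = _plant_uces(rng, sim, scm, aspec)

    pi = np.array(
        [(1 - sim.spec.gc) / 2, sim.spec.gc / 2, sim.spec.gc / 2, (1 - sim.spec.gc) / 2]
    )
    Q = _hky_matrix(aspec.kappa, pi)

    leaf_names = [n for n, _, _ in aspec.tree if not any(p == n for _, p, _ in aspec.tree)]
    species = [REFERENCE_SPECIES] + leaf_names
    trio_branch_nodes = {"anc_trio", *TRIO_SPECIES}

    seq_names = list(sim.sequences)
    leaf_bases: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in leaf_names}
    ref_idx: dict[str, np.ndarray] = {}
    ce_mask: dict[str, np.ndarray] = {}
    uce_mask: dict[str, np.ndarray] = {}
    deep_mask: dict[str, np.ndarray] = {}
    for seq in seq_names:
        L = len(sim.sequences[seq])
        ref_idx[seq] = _B2I[np.frombuffer(sim.sequences[seq].encode(), dtype=np.uint8)].astype(np.int8)
        ce_mask[seq] = np.zeros(L, dtype=bool)
        uce_mask[seq] = np.zeros(L, dtype=bool)
        deep_mask[seq] = np.zeros(L, dtype=bool)
    for iv in ces:
        ce_mask[iv.seq_id][iv.start : iv.end] = True
    for iv, deep in uces:
        uce_mask[iv.seq_id][iv.start : iv.end] = True
        if deep:
            deep_mask[iv.seq_id][iv.start : iv.end] = True

    for seq in seq_names:
        base_rates = np.ones(ref_idx[seq].size)
        base_rates[ce_mask[seq]] = aspec.rho_ce
        node_seqs: dict[str, np.ndarray] = {"REF": np.clip(ref_idx[seq], 0, 3)}
        for name, parent, brlen in aspec.tree:
            rates = base_rates.copy()
            rates[deep_mask[seq]] = 0.0
            if name in trio_branch_nodes:
                rates[uce_mask[seq]] = 0.0
            node_seqs[name] = _evolve(node_seqs[parent], brlen, rates, Q, rng)
        for sp in leaf_names:
            leaf_bases[sp][seq] = node_seqs[sp]

    _apply_uce_guards(rng, sim, aspec, leaf_bases, ref_idx, uces, uce_mask)

    # per-species deletion masks over unconstrained sequence
    protected = {seq: ce_mask[seq] | uce_mask[seq] for seq in seq_names}
    for g in sim.genes:
        if sim.labels[g.gene_id] == "genuine":
            for iv in g.cds_segments:
                protected[g.seq_id][iv.start : iv.end] = True
    dist = _leaf_distances(aspec.tree)
    deleted: dict[str, dict[str, np.ndarray]] = {sp: {} for sp in leaf_names}
    for sp in leaf_names:
        aligned_frac = math.exp(-aspec.deletion_rate_scale * dist[sp])
        for seq in seq_names:
            L = ref_idx[seq].size
            mask = np.zeros(L, dtype=bool)
            eligible = ~protected[seq]
            # Poisson-coverage correction: random intervals overlap, so the
            # count is chosen from the target *retained* fraction directly
            n_intervals = max(
                1, int(-math.log(aligned_frac) * L / aspec.deletion_mean_len)
            )
            starts = rng.integers(0, L, size=n_intervals)
            lens = rng.geometric(1.0 / aspec.deletion_mean_len, size=n_intervals)
            for s, ln in zip(starts, lens):
                mask[s : s + int(ln)] = True
            mask &= eligible
            deleted[sp][seq] = mask

    blocks = _emit_blocks(rng, sim, aspec, leaf_bases, deleted, leaf_names)

    truth_4d = _truth_4d_columns(sim, leaf_bases, deleted, leaf_names)
    truth = {
        "seed": aspec.seed,
        "species": species,
        "reference": REFERENCE_SPECIES,
        "trio": [REFERENCE_SPECIES, *TRIO_SPECIES],
        "leaf_distances": dist,
        "ce_realized_coverage": realized_ce,
        "uces": [
            {"seq": iv.seq_id, "start": iv.start, "end": iv.end, "deep": deep}
            for iv, deep in uces
        ],
        "n_4d_columns": len(truth_4d),
        "four_d_columns": [[s, int(p)] for s, p in truth_4d],
    }
    return SimulatedAlignment(
        spec=aspec,
        blocks=blocks,
        species=species,
        ce_intervals=ces,
        uce_intervals=uces,
        truth=truth,
    )


def _leaf_distances(tree) -> dict[str, float]:
    parents = {n: (p, b) for n, p, b in tree}
    leaves = [n for n in parents if not any(p == n for _, (p, _) in parents.items())]
    out = {}
    for leaf in leaves:
        d = 0.0
        node = leaf
        while node != "REF":
            p, b = parents[node]
            d += b
            node = p
        out[leaf] = d
    return out


def _apply_uce_guards(rng, sim, aspec, leaf_bases, ref_idx, uces, uce_mask):
    """Make planted UCE truth exact.

    1. Break the trio-conserved run at each UCE flank (force a nearest-
       species mismatch just outside the interval).
    2. Break any accidental trio-conserved run of ≥ min_len outside
       planted UCEs.
    3. Ensure non-deep UCEs stay below the broad-conservation identity
       cutoff by forcing divergence in the farthest species if needed.
    """
    near = TRIO_SPECIES[0]
    far = "sp8_sim"
    min_len = aspec.uce_min_len
    for iv, deep in uces:
        seq = iv.seq_id
        for pos in (iv.start - 1, iv.end):
            if 0 <= pos < ref_idx[seq].size and not uce_mask[seq][pos]:
                leaf_bases[near][seq][pos] = (ref_idx[seq][pos] + 1) % 4
        if not deep:
            sl = slice(iv.start, iv.end)
            conform = np.ones(iv.end - iv.start, dtype=bool)
            for sp in leaf_bases:
                if sp in TRIO_SPECIES:
                    continue
                conform &= leaf_bases[sp][seq][sl] == ref_idx[seq][sl]
            max_ok = int(0.90 * (iv.end - iv.start))
            if conform.sum() > max_ok:
                flip = np.flatnonzero(conform)[max_ok:]
                leaf_bases[far][seq][iv.start + flip] = (
                    ref_idx[seq][iv.start + flip] + 1
                ) % 4
    # accidental conserved runs outside planted UCEs
    for seq in ref_idx:
        conform = np.ones(ref_idx[seq].size, dtype=bool)
        for sp in TRIO_SPECIES:
            conform &= leaf_bases[sp][seq] == ref_idx[seq]
        conform &= ~uce_mask[seq]
        run_start = None
        n = conform.size
        idx = np.flatnonzero(conform)
        if idx.size == 0:
            continue
        splits = np.flatnonzero(np.diff(idx) > 1)
        run_bounds = np.split(idx, splits + 1)
        for run in run_bounds:
            if run.size >= min_len:
                for pos in run[min_len - 10 :: min_len - 10]:
                    leaf_bases[near][seq][pos] = (ref_idx[seq][pos] + 1) % 4


_IDX2BASE = np.frombuffer(b"ACGT", dtype=np.uint8)


def _emit_blocks(rng, sim, aspec, leaf_bases, deleted, leaf_names) -> list[AlignmentBlock]:
    blocks = []
    dup_counter = 0
    for seq, refseq in sim.sequences.items():
        L = len(refseq)
        src_sizes = {
            sp: int((~deleted[sp][seq]).sum()) for sp in leaf_names
        }
        prefix = {
            sp: np.concatenate([[0], np.cumsum(~deleted[sp][seq])]) for sp in leaf_names
        }
        for ws in range(0, L, aspec.block_length):
            we = min(ws + aspec.block_length, L)
            rows = [
                MafRow(
                    species=REFERENCE_SPECIES,
                    src=f"{REFERENCE_SPECIES}.{seq}",
                    start=ws,
                    size=we - ws,
                    strand="+",
                    src_size=L,
                    text=refseq[ws:we],
                )
            ]
            for sp in leaf_names:
                del_mask = deleted[sp][seq][ws:we]
                if del_mask.all():
                    continue
                chars = _IDX2BASE[leaf_bases[sp][seq][ws:we]].copy()
                chars[del_mask] = ord("-")
                text = bytes(chars).decode()
                rows.append(
                    MafRow(
                        species=sp,
                        src=f"{sp}.{seq}",
                        start=int(prefix[sp][ws]),
                        size=int((~del_mask).sum()),
                        strand="+",
                        src_size=src_sizes[sp],
                        text=text,
                    )
                )
                if sp == TRIO_SPECIES[0] and rng.random() < aspec.duplicate_row_rate:
                    # decoy paralog row: heavily diverged copy that the
                    # duplicate filter must discard
                    decoy = chars.copy()
                    non_gap = np.flatnonzero(~del_mask)
                    n_mut = max(1, int(0.3 * non_gap.size))
                    picks = rng.choice(non_gap, size=n_mut, replace=False)
                    for p in picks:
                        ref_b = ord(refseq[ws + p].upper())
                        real_b = decoy[p]
                        for cand in b"ACGT":
                            if cand != ref_b and cand != real_b:
                                decoy[p] = cand
                                break
                    dup_counter += 1
                    rows.append(
                        MafRow(
                            species=sp,
                            src=f"{sp}.paralog_{seq}",
                            start=int(prefix[sp][ws]),
                            size=int((~del_mask).sum()),
                            strand="+",
                            src_size=src_sizes[sp],
                            text=bytes(decoy).decode(),
                        )
                    )
            blocks.append(AlignmentBlock(rows, REFERENCE_SPECIES))
    return blocks


def _truth_4d_columns(sim, leaf_bases, deleted, leaf_names) -> list[tuple[str, int]]:
    """Ground-truth 4D columns from the simulator's own base matrices."""
    from .siteclass import classify_codon_degeneracy

    comp = {0: 3, 1: 2, 2: 1, 3: 0}
    out = []
    for g in sim.genes:
        dmap = map_gene_degeneracy(g, sim.sequences)
        minus = g.strand == "-"
        seq = g.seq_id
        for ci, codon in enumerate(dmap.codons):
            if dmap.fold[3 * ci + 2] != 4:
                continue
            p123 = dmap.positions[3 * ci : 3 * ci + 3]
            ok = True
            for sp in leaf_names:
                if deleted[sp][seq][p123].any():
                    ok = False
                    break
                idxs = leaf_bases[sp][seq][p123]
                if minus:
                    idxs = np.array([comp[int(i)] for i in idxs])
                trip = "".join("ACGT"[int(i)] for i in idxs)
                if classify_codon_degeneracy(trip, 3) != 4:
                    ok = False
                    break
            if ok:
                out.append((seq, int(p123[2])))
    return out


# ---------------------------------------------------------------------------
# Variant simulation
# ---------------------------------------------------------------------------


def expected_pi_per_segregating_site(n: int) -> float:
    """E[site π] for a segregating site under the neutral SFS (∝ 1/i)."""
    weights = np.array([1.0 / i for i in range(1, n)])
    weights /= weights.sum()
    pis = np.array(
        [(n / (n - 1)) * 2 * i * (n - i) / n**2 for i in range(1, n)]
    )
    return float((weights * pis).sum())


def simulate_variants(
    sim: SimulatedGenome,
    targets: dict[str, float] | None = None,
    n_samples: int = 17,
    seed: int = 0,
    gene_planting: bool = True,
    pi_4d: float = 0.03,
    ratio_genuine: float = 0.2,
    pi_high_impact_spurious: float = 0.02,
    pi_high_impact_genuine: float = 0.001,
) -> tuple[VariantTable, dict]:
    """Haploid variants hitting per-site-class diversity targets.

    Each site segregates independently with probability target/E[π|seg];
    derived-allele counts follow the neutral frequency spectrum (∝ 1/i).
    With ``gene_planting``, CDS targets are overridden per gene: 4D sites
    at ``pi_4d``; 0D sites at ``ratio_genuine × pi_4d`` in genuine genes
    but at the full 4D level in spurious ones; high-impact sites elevated
    in spurious genes only.
    """
    targets = dict(targets or DEFAULT_PI_TARGETS)
    rng = np.random.default_rng(seed)
    e_seg = expected_pi_per_segregating_site(n_samples)
    for cname, t in targets.items():
        if t > e_seg:
            raise ValueError(f"target π {t} for {cname} unreachable (max {e_seg:.3f})")

    scm = call_site_classes(sim.genes, sim.sequences)
    target_arr: dict[str, np.ndarray] = {}
    for seq, arr in scm.arrays.items():
        t = np.zeros(arr.size, dtype=np.float64)
        for cname, code in CLASS_CODES.items():
            t[arr == code] = targets.get(cname, 0.0)
        target_arr[seq] = t

    if gene_planting:
        for g in sim.genes:
            dmap = map_gene_degeneracy(g, sim.sequences)
            genuine = sim.labels[g.gene_id] == "genuine"
            t = target_arr[g.seq_id]
            t[dmap.positions_with_fold(4)] = pi_4d
            t[dmap.positions_with_fold(0)] = (
                ratio_genuine * pi_4d if genuine else pi_4d
            )
            hi = high_impact_sites(g, sim.sequences)
            hi_target = pi_high_impact_genuine if genuine else pi_high_impact_spurious
            for _, p in hi:
                t[p] = hi_target

    samples = [f"iso{k + 1:02d}" for k in range(n_samples)]
    table = VariantTable(samples)
    sfs_w = np.array([1.0 / i for i in range(1, n_samples)])
    sfs_w /= sfs_w.sum()
    for seq, t in target_arr.items():
        p_seg = t / e_seg
        seg = np.flatnonzero(rng.random(t.size) < p_seg)
        if seg.size == 0:
            continue
        counts = rng.choice(np.arange(1, n_samples), size=seg.size, p=sfs_w)
        carrier_rank = np.argsort(rng.random((seg.size, n_samples)), axis=1)
        refseq = sim.sequences[seq]
        for k, pos in enumerate(seg):
            ref = refseq[pos].upper()
            if ref not in "ACGT":
                continue
            alt = "ACGT"[("ACGT".index(ref) + 1 + int(rng.integers(0, 3))) % 4]
            gt = np.zeros(n_samples, dtype=np.int16)
            gt[carrier_rank[k] < counts[k]] = 1
            table.add(seq, int(pos), (ref, alt), gt)
    truth = {
        "seed": seed,
        "n_samples": n_samples,
        "targets": targets,
        "gene_planting": gene_planting,
        "pi_4d": pi_4d,
        "ratio_genuine": ratio_genuine,
        "e_pi_per_segregating_site": e_seg,
    }
    return table, truth


# ---------------------------------------------------------------------------
# Dataset writer
# ---------------------------------------------------------------------------


def write_dataset(
    outdir,
    sim: SimulatedGenome,
    aln: SimulatedAlignment | None = None,
    variants: tuple[VariantTable, dict] | None = None,
) -> dict[str, str]:
    """Write the full synthetic dataset as plain-text standard formats."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    write_fasta(out / "genome.fa", sim.sequences)
    paths["genome"] = str(out / "genome.fa")
    write_gff3(out / "genes.gff3", sim.genes)
    paths["genes"] = str(out / "genes.gff3")
    with open(out / "repeats.bed", "w") as fh:
        for iv, fam, cls in sorted(sim.repeats, key=lambda r: (r[0].seq_id, r[0].start)):
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{fam}:{cls}\t0\t+\n")
    paths["repeats"] = str(out / "repeats.bed")
    sim.exon_scores.to_csv(out / "scores_exon.tsv", sep="\t", index=False)
    sim.cds_scores.to_csv(out / "scores_cds.tsv", sep="\t", index=False)
    sim.orthogroups.to_csv(out / "orthogroups.tsv", sep="\t", index=False)
    sim.domains.to_csv(out / "domains.tsv", sep="\t", index=False)

    truth = dict(sim.truth)
    if aln is not None:
        write_maf(out / "alignment.maf", aln.blocks)
        paths["alignment"] = str(out / "alignment.maf")
        write_bed(out / "conserved_elements.bed", aln.ce_intervals)
        paths["ces"] = str(out / "conserved_elements.bed")
        truth["alignment"] = aln.truth
    if variants is not None:
        table, vtruth = variants
        write_vcf(
            out / "variants.vcf",
            table,
            {name: len(seq) for name, seq in sim.sequences.items()},
        )
        paths["variants"] = str(out / "variants.vcf")
        truth["variants"] = vtruth
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1)
    paths["truth"] = str(out / "truth.json")
    return paths
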