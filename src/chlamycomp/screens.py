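"""Sequence- and annotation-level genome screens.

Telomere-motif detection at contig termini, terminal repeat-family calls
(the 20-kb rule used for centromere-proximal LINE clusters), windowed
element density tracks, repeat-overlap gene filtering, gene-family
log2-ratio expansion/contraction calls, and the orthogroup domain
assignment rule.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import GeneModel, Interval, merge_intervals, revcomp

__all__ = [
    "TerminalFeatureCall",
    "detect_terminal_motif",
    "detect_terminal_feature",
    "WindowDensityTrack",
    "window_density",
    "gene_repeat_filter",
    "FamilyRatio",
    "family_log2_ratio",
    "assign_domains_to_orthogroups",
]


@dataclass
class TerminalFeatureCall:
    contig: str
    end: str  # "start" | "end"
    kind: str  # "motif" | "annotated-element"
    family: str
    copies: int | None = None
    distance_to_end: int | None = None


def _rotations(motif: str) -> list[str]:
    return [motif[i:] + motif[:i] for i in range(len(motif))]


def detect_terminal_motif(
    contig: str,
    sequence: str,
    motif: str,
    window: int = 1000,
    min_copies: int = 2,
    edge_slack: int = 100,
) -> list[TerminalFeatureCall]:
    """Tandem telomere-motif arrays at contig termini.

    The contig end is scanned for tandem repeats of any rotation of the
    motif; the start is scanned for rotations of the reverse complement
    (telomere arrays read outward).  A call requires at least
    ``min_copies`` consecutive copies within the terminal ``window`` and
    the array reaching within ``edge_slack`` bases of the terminus.
    """
    if len(motif) < 4:
        raise ValueError("motif too short (< 4 bp)")
    seq = sequence.upper()
    calls = []

    def scan(segment: str, variants: list[str], at_start: bool):
        best = None
        for rot in variants:
            pattern = re.compile(f"(?:{re.escape(rot)}){{{min_copies},}}")
            for m in pattern.finditer(segment):
                copies = (m.end() - m.start()) // len(rot)
                dist = m.start() if at_start else len(segment) - m.end()
                if dist > edge_slack:
                    continue
                if best is None or copies > best[0]:
                    best = (copies, dist)
        return best

    n = len(seq)
    start_seg = seq[: min(window, n)]
    hit = scan(start_seg, _rotations(revcomp(motif).upper()), at_start=True)
    if hit:
        calls.append(
            TerminalFeatureCall(contig, "start", "motif", motif, hit[0], hit[1])
        )
    end_seg = seq[max(0, n - window) :]
    hit = scan(end_seg, _rotations(motif.upper()), at_start=False)
    if hit:
        calls.append(
            TerminalFeatureCall(contig, "end", "motif", motif, hit[0], hit[1])
        )
    return calls


def detect_terminal_feature(
    annotations: list[tuple[Interval, str]],
    family: str,
    contig_lengths: dict[str, int],
    terminal_window: int = 20000,
) -> list[TerminalFeatureCall]:
    """Contigs with an element of ``family`` within their terminal window."""
    calls = []
    seen: set[tuple[str, str]] = set()
    for iv, fam in annotations:
        if fam != family or iv.seq_id not in contig_lengths:
            continue
        n = contig_lengths[iv.seq_id]
        if iv.start < terminal_window and ("start", iv.seq_id) not in seen:
            seen.add(("start", iv.seq_id))
            calls.append(
                TerminalFeatureCall(
                    iv.seq_id, "start", "annotated-element", family,
                    distance_to_end=iv.start,
                )
            )
        if iv.end > n - terminal_window and ("end", iv.seq_id) not in seen:
            seen.add(("end", iv.seq_id))
            calls.append(
                TerminalFeatureCall(
                    iv.seq_id, "end", "annotated-element", family,
                    distance_to_end=n - iv.end,
                )
            )
    return calls


@dataclass
class WindowDensityTrack:
    window: int
    table: pd.DataFrame  # seq_id, start, end, pct_covered


def window_density(
    annotations: list[Interval],
    contig_lengths: dict[str, int],
    window: int = 50000,
) -> WindowDensityTrack:
    """Percent of each fixed window covered by the (merged) annotation.

    The last window of a contig may be short; its true length is the
    denominator.
    """
    merged = merge_intervals(annotations)
    cov = {name: np.zeros(n, dtype=bool) for name, n in contig_lengths.items()}
    for iv in merged:
        if iv.seq_id in cov:
            cov[iv.seq_id][iv.start : iv.end] = True
    rows = []
    for name, n in contig_lengths.items():
        for ws in range(0, n, window):
            we = min(ws + window, n)
            covered = int(cov[name][ws:we].sum())
            rows.append(
                {
                    "seq_id": name,
                    "start": ws,
                    "end": we,
                    "pct_covered": 100.0 * covered / (we - ws),
                }
            )
    return WindowDensityTrack(window, pd.DataFrame(rows))


TE_FILTER_FRACTION = 0.30
SIMPLE_FILTER_FRACTION = 0.70
MIN_PROTEIN_AA = 30


def gene_repeat_filter(
    genes: list[GeneModel],
    repeats: list[tuple[Interval, str]],
    genome=None,
) -> pd.DataFrame:
    """Repeat-overlap and sanity filters over spliced CDS.

    ``repeats`` items carry a class label: 'TE' (TEs/satellites) or
    'simple' (low-complexity/simple repeats).  Flags: te_filter (≥30%
    CDS overlap with TEs), simple_filter (≥70% with simple repeats),
    short_protein (<30 aa), internal_stop (needs ``genome``); a gene is
    filtered when any flag fires.
    """
    lengths: dict[str, int] = {}
    for g in genes:
        lengths[g.seq_id] = max(lengths.get(g.seq_id, 0), g.end)
    for iv, _ in repeats:
        lengths[iv.seq_id] = max(lengths.get(iv.seq_id, 0), iv.end)
    cov = {
        cls: {name: np.zeros(n, dtype=bool) for name, n in lengths.items()}
        for cls in ("TE", "simple")
    }
    for iv, cls in repeats:
        if cls in cov:
            cov[cls][iv.seq_id][iv.start : iv.end] = True
    rows = []
    for g in genes:
        cds_bp = g.cds_len
        frac = {}
        for cls in ("TE", "simple"):
            overlap = sum(
                int(cov[cls][g.seq_id][iv.start : iv.end].sum())
                for iv in g.cds_segments
            )
            frac[cls] = overlap / cds_bp if cds_bp else 0.0
        aa = cds_bp // 3 - 1  # minus stop
        internal_stop = False
        if genome is not None:
            from .siteclass import map_gene_degeneracy

            internal_stop = "internal_stop" in map_gene_degeneracy(g, genome).flags
        flags = {
            "te_filter": frac["TE"] >= TE_FILTER_FRACTION,
            "simple_filter": frac["simple"] >= SIMPLE_FILTER_FRACTION,
            "short_protein": aa < MIN_PROTEIN_AA,
            "internal_stop": internal_stop,
        }
        rows.append(
            {
                "gene_id": g.gene_id,
                "cds_bp": cds_bp,
                "te_fraction": frac["TE"],
                "simple_fraction": frac["simple"],
                **flags,
                "filtered": any(flags.values()),
            }
        )
    return pd.DataFrame(rows).set_index("gene_id")


@dataclass
class FamilyRatio:
    orthogroup: str
    focal_count: int
    mean_other: float
    log2_ratio: float  # ±inf markers allowed
    call: str  # expansion | contraction | neither


def family_log2_ratio(
    counts: pd.DataFrame, focal_species: str
) -> list[FamilyRatio]:
    """Expansion/contraction calls from per-orthogroup gene counts.

    ``counts`` is orthogroups × species.  ratio = log2(focal / mean of the
    others); expansion iff ratio > 1, contraction iff ratio < −1.  A zero
    denominator with focal genes present is an infinite-expansion marker;
    zero focal with others present an infinite contraction; both zero is
    'neither'.
    """
    if focal_species not in counts.columns:
        raise ValueError(f"focal species {focal_species!r} not in table")
    others = [c for c in counts.columns if c != focal_species]
    if len(others) < 2:
        raise ValueError("need at least 2 non-focal species")
    out = []
    for og, row in counts.iterrows():
        focal = int(row[focal_species])
        mean_other = float(np.mean([row[c] for c in others]))
        if focal == 0 and mean_other == 0:
            ratio, call = np.nan, "neither"
        elif mean_other == 0:
            ratio, call = math.inf, "expansion"
        elif focal == 0:
            ratio, call = -math.inf, "contraction"
        else:
            ratio = math.log2(focal / mean_other)
            call = (
                "expansion" if ratio > 1 else "contraction" if ratio < -1 else "neither"
            )
        out.append(FamilyRatio(str(og), focal, mean_other, ratio, call))
    return out


def assign_domains_to_orthogroups(
    gene_domains: pd.DataFrame,
    orthogroups: pd.DataFrame,
    min_gene_fraction: float = 0.20,
    min_species_fraction: float = 0.50,
) -> pd.DataFrame:
    """Domain → orthogroup assignment by the double-threshold rule.

    ``gene_domains`` has columns (gene_id, domain); ``orthogroups`` has
    columns (orthogroup, species, gene_id).  A domain is kept for an
    orthogroup iff it is carried by ≥20% of the orthogroup's genes and
    occurs in ≥50% of the species represented in the orthogroup.
    """
    dom_by_gene: dict[str, set[str]] = {}
    for _, r in gene_domains.iterrows():
        dom_by_gene.setdefault(str(r["gene_id"]), set()).add(str(r["domain"]))
    rows = []
    for og, grp in orthogroups.groupby("orthogroup"):
        genes = list(grp["gene_id"].astype(str))
        species_of_gene = dict(zip(grp["gene_id"].astype(str), grp["species"]))
        n_species = grp["species"].nunique()
        domain_genes: dict[str, list[str]] = {}
        for gene in genes:
            for d in dom_by_gene.get(gene, ()):
                domain_genes.setdefault(d, []).append(gene)
        for d, carriers in sorted(domain_genes.items()):
            gene_frac = len(carriers) / len(genes)
            sp_frac = len({species_of_gene[g] for g in carriers}) / n_species
            if gene_frac >= min_gene_fraction and sp_frac >= min_species_fraction:
                rows.append(
                    {
                        "orthogroup": og,
                        "domain": d,
                        "gene_fraction": gene_frac,
                        "species_fraction": sp_frac,
                    }
                )
    return pd.DataFrame(rows, columns=["orthogroup", "domain", "gene_fraction", "species_fraction"])
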