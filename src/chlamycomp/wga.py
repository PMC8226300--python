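"""Reference-anchored analyses of a multi-species whole-genome alignment.

All operations work on a stitched per-position view of the alignment: for
every species, the base aligned to each reference position (0 where the
species is gapped or unaligned).  Reference positions covered by more than
one block keep the first block's columns — the duplicate-row filter makes
multiple coverage rare, and determinism matters more than the choice.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import COMPLEMENT, AlignmentBlock, GeneModel, Interval, MafRow


def _complement_str(s: str) -> str:
    return s.translate(COMPLEMENT)
from .siteclass import (
    CLASS_CODES,
    SiteClassMap,
    classify_codon_degeneracy,
    extract_intergenic_tracts,
)
from .diversity import region_pi

__all__ = [
    "filter_duplicates",
    "ReferenceAlignment",
    "alignability",
    "FourDAlignment",
    "extract_4d_columns",
    "ConservedElement",
    "scan_uces",
    "broad_conservation_filter",
    "ce_overlap_table",
    "intron_ce_bins",
]


def _column_consensus(rows: list[MafRow], col: int) -> str:
    """Majority base over non-gap characters; ties lexicographic; all-gap '-'."""
    counts = Counter()
    for r in rows:
        c = r.text[col].upper()
        if c != "-":
            counts[c] += 1
    if not counts:
        return "-"
    best = max(counts.values())
    return min(b for b, n in counts.items() if n == best)


def filter_duplicates(block: AlignmentBlock) -> AlignmentBlock:
    """Reduce each species to one row: the best match to the block consensus.

    The consensus is the column-wise majority base over all rows (ties to
    the lexicographically smallest base); each row scores the number of
    columns where its base equals the consensus.  Row-score ties keep the
    first row in file order.  Idempotent; single-row species untouched.
    """
    per_species: dict[str, list[int]] = {}
    for i, r in enumerate(block.rows):
        per_species.setdefault(r.species, []).append(i)
    if all(len(v) == 1 for v in per_species.values()):
        return block
    consensus = [_column_consensus(block.rows, c) for c in range(block.width)]
    keep = set()
    for sp, idxs in per_species.items():
        if len(idxs) == 1:
            keep.add(idxs[0])
            continue
        scores = []
        for i in idxs:
            text = block.rows[i].text.upper()
            scores.append(
                sum(1 for c in range(block.width) if text[c] == consensus[c] != "-")
            )
        best = max(scores)
        keep.add(idxs[scores.index(best)])  # first in file order on ties
    rows = [r for i, r in enumerate(block.rows) if i in keep]
    return AlignmentBlock(rows, block.reference)


class ReferenceAlignment:
    """Per-species aligned base at every reference position.

    ``bases[species][seq]`` is a uint8 array of ASCII codes (0 = gap or
    unaligned).  The reference species maps to its own sequence wherever a
    block covers it.  Built from duplicate-filtered blocks; when a species
    still has several rows in one block, the first is used.
    """

    def __init__(self, blocks: list[AlignmentBlock], seq_lengths: dict[str, int] | None = None):
        if not blocks:
            raise ValueError("no alignment blocks")
        self.reference = blocks[0].reference
        lengths: dict[str, int] = dict(seq_lengths or {})
        species: list[str] = []
        for b in blocks:
            ref = b.reference_rows()[0]
            lengths.setdefault(ref.seq_name, ref.src_size)
            for sp in b.species():
                if sp not in species:
                    species.append(sp)
        self.species = species
        self.seq_lengths = lengths
        self.bases: dict[str, dict[str, np.ndarray]] = {
            sp: {name: np.zeros(n, dtype=np.uint8) for name, n in lengths.items()}
            for sp in species
        }
        self.covered: dict[str, np.ndarray] = {
            name: np.zeros(n, dtype=bool) for name, n in lengths.items()
        }
        self.n_multi_covered = 0
        for b in blocks:
            self._ingest(b)

    def _ingest(self, block: AlignmentBlock) -> None:
        ref = block.reference_rows()[0]
        seq = ref.seq_name
        text = ref.text
        width = len(text)
        # reference position of each column (-1 where reference is gapped)
        ref_pos = np.full(width, -1, dtype=np.int64)
        pos = ref.forward_start()
        step = 1
        if ref.strand == "-":
            pos = self.seq_lengths[seq] - ref.start - 1
            step = -1
        for c, ch in enumerate(text):
            if ch != "-":
                ref_pos[c] = pos
                pos += step
        cols = ref_pos >= 0
        target = ref_pos[cols]
        fresh = ~self.covered[seq][target]
        self.n_multi_covered += int((~fresh).sum())
        use_cols = np.flatnonzero(cols)[fresh]
        use_pos = target[fresh]
        if use_pos.size == 0:
            return
        self.covered[seq][use_pos] = True
        seen = set()
        for r in block.rows:
            if r.species in seen:
                continue
            seen.add(r.species)
            # MAF column characters are directly comparable across rows
            # whatever each row's strand; store them verbatim.
            row_bytes = np.frombuffer(r.text.encode(), dtype=np.uint8)
            vals = row_bytes[use_cols].copy()
            vals[vals == ord("-")] = 0
            self.bases[r.species][seq][use_pos] = vals

    def aligned_mask(self, species: str, seq: str) -> np.ndarray:
        """True where ``species`` has a non-gap base at the reference position."""
        if species == self.reference:
            return np.ones(self.seq_lengths[seq], dtype=bool)
        return self.bases[species][seq] != 0


def alignability(
    refaln: ReferenceAlignment, scm: SiteClassMap
) -> pd.DataFrame:
    """Fraction of reference bases of each site class aligned per species.

    A reference base counts as aligned to a species iff some block column
    pairs it with a non-gap base of that species; multiply covered
    positions count once.  The reference is 100% aligned to itself.
    """
    rows = []
    for sp in refaln.species:
        for cname, code in CLASS_CODES.items():
            aligned = 0
            size = 0
            for seq, arr in scm.arrays.items():
                mask = arr == code
                size += int(mask.sum())
                aligned += int((mask & refaln.aligned_mask(sp, seq)).sum())
            rows.append(
                {
                    "species": sp,
                    "site_class": cname,
                    "aligned_bp": aligned,
                    "class_bp": size,
                    "fraction": aligned / size if size else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class FourDAlignment:
    """Gap-free, degeneracy-consistent 4D third-position columns."""

    positions: list[tuple[str, int]]  # reference (seq, pos) of the 4D site
    bases: pd.DataFrame  # species × columns, coding-strand bases
    n_dropped_uncovered: int = 0
    n_dropped_gap: int = 0
    n_dropped_not4d: int = 0


def extract_4d_columns(
    refaln: ReferenceAlignment,
    genes: list[GeneModel],
    degeneracy_maps: dict,
    species: list[str] | None = None,
) -> FourDAlignment:
    """Reference 4D sites where every species has an aligned 4D codon.

    For each codon whose third position is 4D in the reference, the three
    reference positions must be covered by the alignment and every species
    must show gap-free bases there whose triplet (read on the gene's coding
    strand) is itself 4D at the third position.  Codons touching uncovered
    reference positions are dropped and counted.
    """
    species = [s for s in (species or refaln.species) if s != refaln.reference]
    positions: list[tuple[str, int]] = []
    per_species: dict[str, list[str]] = {sp: [] for sp in species}
    n_unc = n_gap = n_not = 0
    for gene in genes:
        dmap = degeneracy_maps.get(gene.gene_id)
        if dmap is None:
            continue
        pos = dmap.positions
        seq = gene.seq_id
        minus = gene.strand == "-"
        for ci, codon in enumerate(dmap.codons):
            if dmap.fold[3 * ci + 2] != 4:
                continue
            p123 = pos[3 * ci : 3 * ci + 3]
            if not refaln.covered[seq][p123].all():
                n_unc += 1
                continue
            # dmap positions are already in transcription order; on the minus
            # strand the coding-strand codon is the per-base complement of
            # the aligned column characters (no reversal needed).
            triplets = {}
            ok = True
            for sp in species:
                vals = refaln.bases[sp][seq][p123]
                if (vals == 0).any():
                    ok = False
                    n_gap += 1
                    break
                trip = bytes(vals).decode().upper()
                if minus:
                    trip = _complement_str(trip)
                triplets[sp] = trip
            if not ok:
                continue
            bad = False
            for sp, trip in triplets.items():
                if classify_codon_degeneracy(trip, 3) != 4:
                    bad = True
                    break
            if bad:
                n_not += 1
                continue
            positions.append((seq, int(p123[2])))
            for sp in species:
                per_species[sp].append(triplets[sp][2])
    bases = pd.DataFrame.from_dict(
        {sp: per_species[sp] for sp in species}, orient="index"
    )
    return FourDAlignment(positions, bases, n_unc, n_gap, n_not)


@dataclass
class ConservedElement:
    interval: Interval
    length: int
    source: str  # "external-CE" or "UCE"
    info: dict = field(default_factory=dict)


def scan_uces(
    refaln: ReferenceAlignment,
    strict_species: list[str],
    min_len: int = 50,
) -> list[ConservedElement]:
    """Ultraconserved elements against a strict species set.

    Maximal runs of reference positions where every strict species is
    aligned, gap-free and base-identical to the reference
    (case-insensitive); runs of at least ``min_len`` are reported.  The
    stitched per-position view merges runs across block boundaries
    automatically.
    """
    others = [s for s in strict_species if s != refaln.reference]
    out = []
    for seq, length in refaln.seq_lengths.items():
        ref = refaln.bases[refaln.reference][seq]
        conforming = refaln.covered[seq] & _is_base(ref)
        for sp in others:
            sp_arr = refaln.bases[sp][seq]
            conforming &= _is_base(sp_arr) & (_upper(sp_arr) == _upper(ref))
        for s, e in _true_runs(conforming):
            if e - s >= min_len:
                out.append(
                    ConservedElement(Interval(seq, s, e), e - s, "UCE")
                )
    return out


def _upper(vals: np.ndarray) -> np.ndarray:
    out = vals.copy()
    lower = (out >= ord("a")) & (out <= ord("z"))
    out[lower] -= 32
    return out


def _is_base(vals: np.ndarray) -> np.ndarray:
    up = _upper(vals)
    return (up == ord("A")) | (up == ord("C")) | (up == ord("G")) | (up == ord("T"))


def _true_runs(mask: np.ndarray):
    if mask.size == 0:
        return
    diff = np.diff(mask.astype(np.int8))
    starts = list(np.flatnonzero(diff == 1) + 1)
    ends = list(np.flatnonzero(diff == -1) + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        ends.append(mask.size)
    yield from zip(starts, ends)


def broad_conservation_filter(
    uces: list[ConservedElement],
    refaln: ReferenceAlignment,
    all_species: list[str],
    min_identity: float = 0.95,
) -> list[ConservedElement]:
    """UCEs conserved across the full species set.

    Keeps UCEs where at least ``min_identity`` of reference positions have
    every species aligned, gap-free and identical to the reference
    (column-wise identity — the default; see ``mode`` of the per-position
    fraction recorded in ``info``).
    """
    others = [s for s in all_species if s != refaln.reference]
    kept = []
    for uce in uces:
        seq = uce.interval.seq_id
        sl = slice(uce.interval.start, uce.interval.end)
        ref = refaln.bases[refaln.reference][seq][sl]
        conform = refaln.covered[seq][sl] & _is_base(ref)
        for sp in others:
            arr = refaln.bases[sp][seq][sl]
            conform = conform & _is_base(arr) & (_upper(arr) == _upper(ref))
        frac = float(conform.mean()) if conform.size else 0.0
        if frac >= min_identity:
            kept.append(
                ConservedElement(
                    uce.interval, uce.length, uce.source, {**uce.info, "broad_identity": frac}
                )
            )
    return kept


def _coverage_arrays(intervals, lengths: dict[str, int]) -> dict[str, np.ndarray]:
    cov = {name: np.zeros(n, dtype=bool) for name, n in lengths.items()}
    for iv in intervals:
        if iv.seq_id not in cov:
            raise ValueError(f"interval on unknown sequence {iv.seq_id!r}")
        if iv.end > lengths[iv.seq_id]:
            raise ValueError(
                f"interval {iv.seq_id}:{iv.start}-{iv.end} outside genome bounds"
            )
        cov[iv.seq_id][iv.start : iv.end] = True
    return cov


def ce_overlap_table(
    ces,
    scm: SiteClassMap,
    variants=None,
    genome=None,
    split_intergenic: bool = True,
) -> pd.DataFrame:
    """Per-site-class overlap with conserved elements (and optionally π).

    Rows are site classes (intergenic split at 250 bp into short/long
    tracts); columns give CE-overlap bases, the share of all CE bases in
    the class, the share of the class covered by CEs, and π over CE,
    non-CE and all sites of the class when variants are supplied.
    """
    lengths = {name: arr.size for name, arr in scm.arrays.items()}
    intervals = [ce.interval if isinstance(ce, ConservedElement) else ce for ce in ces]
    cov = _coverage_arrays(intervals, lengths)
    total_ce = sum(int(c.sum()) for c in cov.values())

    class_masks: dict[str, dict[str, np.ndarray]] = {}
    for cname, code in CLASS_CODES.items():
        if cname == "intergenic" and split_intergenic:
            continue
        class_masks[cname] = {
            seq: scm.arrays[seq] == code for seq in scm.arrays
        }
    if split_intergenic:
        short = {seq: np.zeros(n, dtype=bool) for seq, n in lengths.items()}
        long_ = {seq: np.zeros(n, dtype=bool) for seq, n in lengths.items()}
        for tract in extract_intergenic_tracts(scm):
            target = short if tract.is_short else long_
            target[tract.interval.seq_id][tract.interval.start : tract.interval.end] = True
        class_masks["intergenic_short"] = short
        class_masks["intergenic_long"] = long_

    rows = []
    for cname, masks in class_masks.items():
        class_bp = sum(int(m.sum()) for m in masks.values())
        overlap = sum(int((m & cov[seq]).sum()) for seq, m in masks.items())
        row = {
            "site_class": cname,
            "ce_overlap_bp": overlap,
            "pct_of_ce_bases": 100.0 * overlap / total_ce if total_ce else np.nan,
            "pct_of_class": 100.0 * overlap / class_bp if class_bp else np.nan,
            "class_bp": class_bp,
        }
        if variants is not None:
            for label, select in (
                ("pi_ce", lambda m, c: m & c),
                ("pi_non_ce", lambda m, c: m & ~c),
                ("pi_all", lambda m, c: m),
            ):
                sites = []
                for seq, m in masks.items():
                    for p in np.flatnonzero(select(m, cov[seq])):
                        sites.append((seq, int(p)))
                est = region_pi(sites, variants, genome, label=label)
                row[label] = est.pi if est.defined else np.nan
        rows.append(row)
    return pd.DataFrame(rows).set_index("site_class")


def intron_ce_bins(introns, ces, n_bins: int = 50) -> tuple[pd.DataFrame, dict]:
    """Intron length vs conserved-element density in equal-count bins.

    Introns are ordered by length (ties by genomic position) and split
    into ``n_bins`` contiguous bins whose sizes differ by at most one;
    each bin reports mean intron length and the fraction of its intronic
    bases overlapped by CEs.  Returns the bin table plus summary
    statistics: the Pearson correlation of the two per-bin vectors, the
    CE-fraction contrast between introns <100 bp and ≥100 bp, and an
    independent-samples t test on relative position within the transcript.
    """
    if len(introns) < n_bins:
        raise ValueError(f"{len(introns)} introns < {n_bins} bins")
    intervals = [ce.interval if isinstance(ce, ConservedElement) else ce for ce in ces]
    lengths: dict[str, int] = {}
    for iv in [r.interval for r in introns] + intervals:
        lengths[iv.seq_id] = max(lengths.get(iv.seq_id, 0), iv.end)
    cov = _coverage_arrays(intervals, lengths)

    def ce_bases(rec) -> int:
        iv = rec.interval
        return int(cov[iv.seq_id][iv.start : iv.end].sum())

    ordered = sorted(
        introns, key=lambda r: (r.length, r.interval.seq_id, r.interval.start)
    )
    bins = np.array_split(np.arange(len(ordered)), n_bins)
    rows = []
    for bi, idxs in enumerate(bins):
        members = [ordered[i] for i in idxs]
        total = sum(r.length for r in members)
        ce = sum(ce_bases(r) for r in members)
        rows.append(
            {
                "bin": bi,
                "n_introns": len(members),
                "mean_length": float(np.mean([r.length for r in members])),
                "ce_fraction": ce / total if total else np.nan,
            }
        )
    table = pd.DataFrame(rows).set_index("bin")

    stats_out: dict = {}
    x, y = table["mean_length"].to_numpy(), table["ce_fraction"].to_numpy()
    if np.std(y) == 0 or np.std(x) == 0:
        stats_out["pearson_r"] = np.nan
        stats_out["pearson_p"] = np.nan
        stats_out["zero_variance"] = True
    else:
        r, p = stats.pearsonr(x, y)
        stats_out["pearson_r"] = float(r)
        stats_out["pearson_p"] = float(p)
        stats_out["zero_variance"] = False

    short = [r for r in ordered if r.length < 100]
    long_ = [r for r in ordered if r.length >= 100]
    for label, group in (("short", short), ("long", long_)):
        total = sum(r.length for r in group)
        ce = sum(ce_bases(r) for r in group)
        stats_out[f"ce_fraction_{label}"] = ce / total if total else np.nan
    if short and long_:
        t, p = stats.ttest_ind(
            [r.relative_position for r in short],
            [r.relative_position for r in long_],
            equal_var=False,
        )
        stats_out["relpos_t"] = float(t)
        stats_out["relpos_p"] = float(p)
    return table, stats_out
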