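"""Whole-genome-alignment analyses against brute-force oracles and truth."""

from collections import Counter

import numpy as np
import pytest

from chlamycomp.io import AlignmentBlock, Interval, MafRow
from chlamycomp.siteclass import call_site_classes, intron_table, map_gene_degeneracy
from chlamycomp.wga import (
    ReferenceAlignment,
    alignability,
    broad_conservation_filter,
    ce_overlap_table,
    extract_4d_columns,
    filter_duplicates,
    intron_ce_bins,
    scan_uces,
)

from test_siteclass import make_gene

BASES = "ACGT"


def random_block(rng, n_species=3, max_copies=3, width=40):
    """Random toy block with duplicated species rows."""
    rows = []
    ref_text = "".join(rng.choice(list(BASES), width))
    rows.append(MafRow("ref", "ref.c", 0, width, "+", 10000, ref_text))
    for si in range(n_species):
        sp = f"sp{si}"
        for ci in range(rng.integers(1, max_copies + 1)):
            chars = []
            for c in ref_text:
                r = rng.random()
                if r < 0.1:
                    chars.append("-")
                elif r < 0.5:
                    chars.append(str(rng.choice(list(BASES))))
                else:
                    chars.append(c)
            text = "".join(chars)
            size = sum(ch != "-" for ch in text)
            if size == 0:
                text = ref_text
                size = width
            rows.append(MafRow(sp, f"{sp}.c{ci}", 0, size, "+", 10000, text))
    return AlignmentBlock(rows, "ref")


def brute_force_best_rows(block):
    """Exhaustive best-row choice per species (the oracle)."""
    width = block.width
    consensus = []
    for c in range(width):
        counts = Counter(
            r.text[c].upper() for r in block.rows if r.text[c] != "-"
        )
        if not counts:
            consensus.append("-")
            continue
        m = max(counts.values())
        consensus.append(min(b for b, n in counts.items() if n == m))
    kept = {}
    for i, r in enumerate(block.rows):
        score = sum(
            1
            for c in range(width)
            if consensus[c] != "-" and r.text[c].upper() == consensus[c]
        )
        if r.species not in kept or score > kept[r.species][0]:
            kept[r.species] = (score, i)
    return {i for _, i in kept.values()}


class TestDuplicateFilter:
    def test_matches_exhaustive_oracle_on_random_blocks(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            block = random_block(rng)
            got = filter_duplicates(block)
            want_idx = brute_force_best_rows(block)
            want_srcs = {block.rows[i].src for i in want_idx}
            assert {r.src for r in got.rows} == want_srcs

    def test_idempotent_and_single_copy_untouched(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            block = random_block(rng)
            once = filter_duplicates(block)
            twice = filter_duplicates(once)
            assert [r.src for r in once.rows] == [r.src for r in twice.rows]
        single = AlignmentBlock(
            [
                MafRow("ref", "ref.c", 0, 4, "+", 100, "ACGT"),
                MafRow("sp", "sp.c", 0, 4, "+", 100, "ACGA"),
            ],
            "ref",
        )
        assert filter_duplicates(single) is single

    def test_higher_scoring_row_kept(self):
        rows = [
            MafRow("ref", "ref.c", 0, 6, "+", 100, "ACGTAC"),
            MafRow("sp", "sp.good", 0, 6, "+", 100, "ACGTAA"),
            MafRow("sp", "sp.bad", 0, 6, "+", 100, "TTTTAC"),
        ]
        got = filter_duplicates(AlignmentBlock(rows, "ref"))
        assert {r.src for r in got.rows} == {"ref.c", "sp.good"}


def blocks_from_arrays(ref_seq, species_arrays, block_len=25):
    """Emit reference-anchored blocks from per-position species bases.

    ``species_arrays`` maps species → string with '-' for unaligned; used
    so tests can build alignments from an explicit per-column ground truth.
    """
    L = len(ref_seq)
    blocks = []
    for ws in range(0, L, block_len):
        we = min(ws + block_len, L)
        rows = [MafRow("ref", "ref.c", ws, we - ws, "+", L, ref_seq[ws:we])]
        for sp, arr in species_arrays.items():
            text = arr[ws:we]
            size = sum(c != "-" for c in text)
            if size == 0:
                continue
            start = sum(c != "-" for c in arr[:ws])
            total = sum(c != "-" for c in arr)
            rows.append(MafRow(sp, f"{sp}.c", start, size, "+", L if total == 0 else total, text))
        blocks.append(AlignmentBlock(rows, "ref"))
    return blocks


def oracle_uce_scan(ref_seq, species_arrays, strict, min_len=50):
    """Brute-force per-column scanner over the ground-truth arrays."""
    L = len(ref_seq)
    conform = [
        all(
            species_arrays[sp][i] != "-"
            and species_arrays[sp][i].upper() == ref_seq[i].upper()
            for sp in strict
        )
        for i in range(L)
    ]
    out = []
    i = 0
    while i < L:
        if conform[i]:
            j = i
            while j < L and conform[j]:
                j += 1
            if j - i >= min_len:
                out.append((i, j))
            i = j
        else:
            i += 1
    return out


class TestUceScan:
    def _random_case(self, rng, L=220):
        ref = "".join(rng.choice(list(BASES), L))
        species = {}
        for sp in ("a", "b"):
            arr = list(ref)
            # plant long conserved stretches, then sprinkle mismatches/gaps
            n_noise = rng.integers(0, 12)
            for p in rng.integers(0, L, n_noise):
                arr[p] = "-" if rng.random() < 0.3 else str(rng.choice(list(BASES)))
            species[sp] = "".join(arr)
        return ref, species

    def test_matches_brute_force_on_200_random_alignments(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            ref, species = self._random_case(rng)
            blocks = blocks_from_arrays(ref, species, block_len=int(rng.integers(10, 60)))
            refaln = ReferenceAlignment(blocks, {"c": len(ref)})
            got = [
                (u.interval.start, u.interval.end)
                for u in scan_uces(refaln, ["ref", "a", "b"])
            ]
            want = oracle_uce_scan(ref, species, ["a", "b"])
            assert got == want

    @pytest.mark.parametrize("run_len,expected", [(49, 0), (50, 1), (60, 1)])
    def test_minimum_length_boundary(self, run_len, expected):
        rng = np.random.default_rng(3)
        L = run_len + 20
        ref = "".join(rng.choice(list(BASES), L))
        arr = list("-" * L)
        arr[10 : 10 + run_len] = ref[10 : 10 + run_len]
        species = {"a": "".join(arr)}
        blocks = blocks_from_arrays(ref, species)
        refaln = ReferenceAlignment(blocks, {"c": L})
        uces = scan_uces(refaln, ["ref", "a"])
        assert len(uces) == expected
        if expected:
            assert uces[0].length == run_len

    def test_block_split_at_conforming_column_is_invisible(self):
        rng = np.random.default_rng(4)
        ref, species = self._random_case(rng)
        a = blocks_from_arrays(ref, species, block_len=200)
        b = blocks_from_arrays(ref, species, block_len=13)
        ra = ReferenceAlignment(a, {"c": len(ref)})
        rb = ReferenceAlignment(b, {"c": len(ref)})
        assert [
            (u.interval.start, u.interval.end) for u in scan_uces(ra, ["ref", "a", "b"])
        ] == [(u.interval.start, u.interval.end) for u in scan_uces(rb, ["ref", "a", "b"])]

    def test_planted_uces_recovered_exactly(self, sim_small, aln_small):
        blocks = [filter_duplicates(b) for b in aln_small.blocks]
        refaln = ReferenceAlignment(
            blocks, {k: len(v) for k, v in sim_small.sequences.items()}
        )
        uces = scan_uces(refaln, aln_small.truth["trio"])
        got = {(u.interval.seq_id, u.interval.start, u.interval.end) for u in uces}
        want = {
            (iv.seq_id, iv.start, iv.end) for iv, _deep in aln_small.uce_intervals
        }
        assert got == want

    def test_deep_subset_recovered_exactly(self, sim_small, aln_small):
        blocks = [filter_duplicates(b) for b in aln_small.blocks]
        refaln = ReferenceAlignment(
            blocks, {k: len(v) for k, v in sim_small.sequences.items()}
        )
        uces = scan_uces(refaln, aln_small.truth["trio"])
        deep = broad_conservation_filter(uces, refaln, aln_small.species)
        got = {(u.interval.seq_id, u.interval.start, u.interval.end) for u in deep}
        want = {
            (iv.seq_id, iv.start, iv.end) for iv, d in aln_small.uce_intervals if d
        }
        assert got == want

    def test_broad_filter_identity_boundary(self):
        # 100 bp UCE with 6 nonconforming far-species positions: 94% < 95%
        rng = np.random.default_rng(5)
        L = 140
        ref = "".join(rng.choice(list(BASES), L))
        near = ref[:100] + "-" * 40  # confine the UCE to exactly 100 bp
        far = list(ref)
        for p in range(20, 26):
            far[p] = BASES[(BASES.index(far[p]) + 1) % 4]
        species = {"near": near, "far": "".join(far)}
        refaln = ReferenceAlignment(
            blocks_from_arrays(ref, species), {"c": L}
        )
        uces = scan_uces(refaln, ["ref", "near"], min_len=50)
        kept = broad_conservation_filter(
            uces, refaln, ["ref", "near", "far"], min_identity=0.95
        )
        spanning = [u for u in uces if u.interval.start <= 20 < u.interval.end]
        assert spanning and not any(
            u.interval.start <= 20 < u.interval.end for u in kept
        )


class TestAlignability:
    def test_reference_is_fully_aligned_to_itself(self, sim_small, aln_small):
        blocks = [filter_duplicates(b) for b in aln_small.blocks]
        refaln = ReferenceAlignment(
            blocks, {k: len(v) for k, v in sim_small.sequences.items()}
        )
        scm = call_site_classes(sim_small.genes, sim_small.sequences)
        tab = alignability(refaln, scm)
        ref_rows = tab[tab.species == "crei_sim"]
        assert np.allclose(ref_rows.fraction.dropna(), 1.0)

    def test_gap_column_counts_only_nongap_species(self):
        ref = "ACGTACGTACGT"
        species = {"a": "----ACGTACGT", "b": "ACGT--GTACGT"}
        refaln = ReferenceAlignment(
            blocks_from_arrays(ref, species, block_len=12), {"c": 12}
        )
        assert not refaln.aligned_mask("a", "c")[0]
        assert refaln.aligned_mask("b", "c")[0]
        assert not refaln.aligned_mask("b", "c")[4]

    def test_constrained_classes_align_further(self, sim_small, aln_small):
        blocks = [filter_duplicates(b) for b in aln_small.blocks]
        refaln = ReferenceAlignment(
            blocks, {k: len(v) for k, v in sim_small.sequences.items()}
        )
        scm = call_site_classes(sim_small.genes, sim_small.sequences)
        piv = alignability(refaln, scm).pivot(
            index="species", columns="site_class", values="fraction"
        )
        for sp in aln_small.species:
            if sp == "crei_sim":
                continue
            assert piv.loc[sp, "CDS"] > piv.loc[sp, "intergenic"]
        # alignability decays with divergence
        far = piv.loc["sp8_sim", "intergenic"]
        near = piv.loc["cinc_sim", "intergenic"]
        assert near > far


class TestFourD:
    def test_toy_retention_and_gap_rules(self):
        # ref gene ATG GGA TAA on plus strand; codon 2 third position is 4D
        ref = "ATGGGATAA" + "C" * 16
        aligned_ggt = "ATGGGT" + "TAA" + "C" * 16  # species codon GGT: 4D kept
        gap_mid = "ATGG-A" + "TAA" + "C" * 16  # gap inside codon: dropped
        not4d = "ATGATG" + "TAA" + "C" * 16  # ATG offset 3 is 0D: dropped
        genome = {"c": ref}
        gene = make_gene("c", [(0, 9)], [(0, 9)])
        dmaps = {"g": map_gene_degeneracy(gene, genome)}
        for arr, expected in ((aligned_ggt, 1), (gap_mid, 0), (not4d, 0)):
            refaln = ReferenceAlignment(
                blocks_from_arrays(ref, {"a": arr}), {"c": len(ref)}
            )
            out = extract_4d_columns(refaln, [gene], dmaps)
            assert len(out.positions) == expected
            if expected:
                assert out.positions == [("c", 5)]
                assert out.bases.loc["a", 0] == "T"

    def test_synthetic_truth_recovered_exactly(self, sim_small, aln_small):
        blocks = [filter_duplicates(b) for b in aln_small.blocks]
        refaln = ReferenceAlignment(
            blocks, {k: len(v) for k, v in sim_small.sequences.items()}
        )
        dmaps = {
            g.gene_id: map_gene_degeneracy(g, sim_small.sequences)
            for g in sim_small.genes
        }
        out = extract_4d_columns(refaln, sim_small.genes, dmaps)
        assert set(out.positions) == {
            (s, p) for s, p in aln_small.truth["four_d_columns"]
        }


class TestCeOverlap:
    def test_overlap_conservation_and_split_classes(self):
        genome = {"c": "A" * 1000}
        g = make_gene("c", [(100, 400)], [(100, 400)])
        scm = call_site_classes([g], genome)
        ces = [Interval("c", 370, 450)]  # 30 CDS + 50 intergenic bases
        tab = ce_overlap_table(ces, scm)
        assert tab.ce_overlap_bp.sum() == 80
        assert tab.loc["CDS", "ce_overlap_bp"] == 30

    def test_out_of_bounds_ce_errors(self):
        genome = {"c": "A" * 100}
        scm = call_site_classes([], genome)
        with pytest.raises(ValueError, match="bounds"):
            ce_overlap_table([Interval("c", 50, 150)], scm)

    def test_planted_class_coverage_recovered(self, sim_small, aln_small):
        scm = call_site_classes(sim_small.genes, sim_small.sequences)
        tab = ce_overlap_table(aln_small.ce_intervals, scm)
        planted = aln_small.truth["ce_realized_coverage"]
        for cname in ("CDS", "UTR5", "UTR3", "intron"):
            got = tab.loc[cname, "pct_of_class"] / 100
            assert got == pytest.approx(planted[cname], abs=0.02)
        assert tab.ce_overlap_bp.sum() == sum(len(iv) for iv in aln_small.ce_intervals)


class TestIntronBins:
    def test_bin_sizes_differ_by_at_most_one(self):
        genome_len = {"c": 100000}
        recs = intron_table(
            [
                make_gene(
                    "c",
                    [(i * 400, i * 400 + 50), (i * 400 + 50 + 60 + i, i * 400 + 300)],
                    [(i * 400, i * 400 + 50), (i * 400 + 50 + 60 + i, i * 400 + 300)],
                    gene_id=f"g{i}",
                )
                for i in range(120)
            ]
        )
        table, _ = intron_ce_bins(recs, [Interval("c", 0, 5)], n_bins=50)
        sizes = table.n_introns
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == len(recs)

    def test_fewer_introns_than_bins_errors(self):
        recs = intron_table(
            [make_gene("c", [(0, 50), (150, 200)], [(0, 50), (150, 200)])]
        )
        with pytest.raises(ValueError):
            intron_ce_bins(recs, [], n_bins=50)

    def test_zero_variance_flagged(self):
        recs = intron_table(
            [
                make_gene(
                    "c",
                    [(i * 300, i * 300 + 50), (i * 300 + 150, i * 300 + 250)],
                    [(i * 300, i * 300 + 50), (i * 300 + 150, i * 300 + 250)],
                    gene_id=f"g{i}",
                )
                for i in range(60)
            ]
        )
        table, stats = intron_ce_bins(recs, [], n_bins=50)
        assert stats["zero_variance"] or np.isnan(stats["pearson_r"])

    def test_inverse_length_planting_gives_negative_correlation(
        self, sim_small, aln_small
    ):
        recs = intron_table(sim_small.genes)
        table, stats = intron_ce_bins(recs, aln_small.ce_intervals, n_bins=50)
        assert stats["pearson_r"] < 0
        assert stats["pearson_p"] < 0.01
        assert stats["ce_fraction_short"] > stats["ce_fraction_long"]
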