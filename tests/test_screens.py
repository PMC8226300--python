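"""Telomere/terminal screens, window density, repeat filters, family calls."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chlamycomp.io import Interval, revcomp
from chlamycomp.screens import (
    assign_domains_to_orthogroups,
    detect_terminal_feature,
    detect_terminal_motif,
    family_log2_ratio,
    gene_repeat_filter,
    window_density,
)

from test_siteclass import make_gene

MOTIF = "TTTTAGGG"


class TestTerminalMotif:
    def test_tandem_array_at_end(self):
        seq = "ACGT" * 100 + MOTIF * 3
        calls = detect_terminal_motif("c", seq, MOTIF)
        assert [(c.end, c.copies) for c in calls] == [("end", 3)]

    def test_revcomp_array_at_start(self):
        seq = revcomp(MOTIF) * 4 + "ACGT" * 100
        calls = detect_terminal_motif("c", seq, MOTIF)
        assert [(c.end, c.copies) for c in calls] == [("start", 4)]

    def test_rotated_phase_still_called(self):
        rot = MOTIF[3:] + MOTIF[:3]
        seq = "ACGT" * 100 + rot * 5
        calls = detect_terminal_motif("c", seq, MOTIF)
        assert calls and calls[0].end == "end" and calls[0].copies == 5

    def test_motif_free_contig_no_calls(self):
        assert detect_terminal_motif("c", "ACGT" * 300, MOTIF) == []

    def test_interior_array_not_called(self):
        seq = "ACGT" * 100 + MOTIF * 5 + "ACGT" * 100
        assert detect_terminal_motif("c", seq, MOTIF) == []

    def test_single_copy_below_min_copies(self):
        seq = "ACGT" * 100 + MOTIF
        assert detect_terminal_motif("c", seq, MOTIF) == []

    def test_strand_consistency_revcomp_swaps_ends(self):
        rng = np.random.default_rng(0)
        seq = (
            revcomp(MOTIF) * 3
            + "".join(rng.choice(list("ACGT"), 500))
            + MOTIF * 6
        )
        fwd = detect_terminal_motif("c", seq, MOTIF)
        rev = detect_terminal_motif("c", revcomp(seq), MOTIF)
        swap = {"start": "end", "end": "start"}
        assert sorted((swap[c.end], c.copies) for c in fwd) == sorted(
            (c.end, c.copies) for c in rev
        )

    def test_telomeres_recovered_on_synthetic_genome(self, sim_small):
        spec = sim_small.spec
        for name, seq in sim_small.sequences.items():
            calls = detect_terminal_motif(name, seq, spec.telomere_motif)
            assert {(c.end, c.copies) for c in calls} == {
                ("start", spec.telomere_copies),
                ("end", spec.telomere_copies),
            }


class TestTerminalFeature:
    def test_window_rule(self):
        ann = [
            (Interval("c", 5000, 7000), "ZeppL"),
            (Interval("c", 500_000, 502_000), "ZeppL"),
            (Interval("c", 990_000, 991_000), "other"),
        ]
        calls = detect_terminal_feature(ann, "ZeppL", {"c": 1_000_000})
        assert [(c.contig, c.end) for c in calls] == [("c", "start")]

    def test_element_near_far_end(self):
        ann = [(Interval("c", 995_000, 996_000), "ZeppL")]
        calls = detect_terminal_feature(ann, "ZeppL", {"c": 1_000_000})
        assert calls[0].end == "end" and calls[0].distance_to_end == 4000


class TestWindowDensity:
    def test_full_and_union_coverage(self):
        ivs = [Interval("c", 0, 50_000), Interval("c", 60_000, 70_000),
               Interval("c", 65_000, 75_000)]
        track = window_density(ivs, {"c": 100_000})
        assert track.table.pct_covered.tolist() == [100.0, 30.0]

    def test_short_last_window_uses_true_length(self):
        track = window_density([Interval("c", 100_000, 110_000)], {"c": 110_000})
        assert track.table.iloc[-1].pct_covered == 100.0
        assert track.table.iloc[-1].end - track.table.iloc[-1].start == 10_000

    def test_empty_annotation_zero_track(self):
        track = window_density([], {"c": 120_000})
        assert (track.table.pct_covered == 0).all()

    def test_covered_bases_conserved(self):
        rng = np.random.default_rng(1)
        ivs = [
            Interval("c", int(s), int(s) + int(l))
            for s, l in zip(rng.integers(0, 90_000, 40), rng.integers(1, 5000, 40))
        ]
        from chlamycomp.io import merge_intervals

        merged_bp = sum(len(iv) for iv in merge_intervals(ivs))
        track = window_density(ivs, {"c": 100_000})
        covered = sum(
            r.pct_covered / 100 * (r.end - r.start) for _, r in track.table.iterrows()
        )
        assert round(covered) == merged_bp

    def test_density_peaks_at_planted_centromere(self, sim_small):
        fam = [iv for iv, f, _ in sim_small.repeats if f == sim_small.spec.te_family]
        lengths = {k: len(v) for k, v in sim_small.sequences.items()}
        track = window_density(fam, lengths)
        for name in lengths:
            cen_lo, cen_hi = sim_small.truth["centromere_windows"][name]
            sub = track.table[track.table.seq_id == name]
            peak = sub.loc[sub.pct_covered.idxmax()]
            assert cen_lo - 50_000 <= peak.start <= cen_hi


class TestGeneRepeatFilter:
    def _setup(self, te_frac, simple_frac, cds_bp=1000):
        genome = {"c": "ATG" + "GCA" * ((cds_bp - 6) // 3) + "TAA" + "T" * 100}
        g = make_gene("c", [(0, cds_bp)], [(0, cds_bp)])
        reps = []
        if te_frac:
            reps.append((Interval("c", 0, int(te_frac * cds_bp)), "TE"))
        if simple_frac:
            reps.append((Interval("c", 0, int(simple_frac * cds_bp)), "simple"))
        return [g], reps, genome

    def test_te_fraction_and_flag(self):
        genes, reps, genome = self._setup(0.85, 0)
        out = gene_repeat_filter(genes, reps)
        assert out.iloc[0].te_fraction == pytest.approx(0.85)
        assert out.iloc[0].te_filter and out.iloc[0].filtered

    def test_boundaries_29_and_69_pct_do_not_fire(self):
        genes, reps, genome = self._setup(0.29, 0.69)
        out = gene_repeat_filter(genes, reps)
        assert not out.iloc[0].te_filter and not out.iloc[0].simple_filter

    def test_thresholds_inclusive(self):
        genes, reps, genome = self._setup(0.30, 0.70)
        out = gene_repeat_filter(genes, reps)
        assert out.iloc[0].te_filter and out.iloc[0].simple_filter

    def test_short_protein_boundary(self):
        genes, _, genome = self._setup(0, 0, cds_bp=90)  # 29 aa + stop
        out = gene_repeat_filter(genes, [])
        assert out.iloc[0].short_protein
        genes, _, genome = self._setup(0, 0, cds_bp=93)  # 30 aa + stop
        assert not gene_repeat_filter(genes, []).iloc[0].short_protein

    def test_internal_stop_needs_genome(self):
        genome = {"c": "ATGTAAGGCTAA" + "T" * 50}
        g = make_gene("c", [(0, 12)], [(0, 12)])
        out = gene_repeat_filter([g], [], genome=genome)
        assert out.iloc[0].internal_stop and out.iloc[0].filtered


class TestFamilyRatio:
    def _counts(self, focal, others):
        cols = {"focal": [focal]}
        for i, c in enumerate(others):
            cols[f"sp{i}"] = [c]
        return pd.DataFrame(cols, index=["og1"])

    def test_sixteen_vs_sparse_is_expansion(self):
        out = family_log2_ratio(self._counts(16, [1, 1, 0, 1, 1]), "focal")[0]
        assert out.log2_ratio == pytest.approx(math.log2(16 / 0.8))
        assert out.call == "expansion"

    def test_ratio_exactly_one_is_neither(self):
        out = family_log2_ratio(self._counts(2, [1, 1]), "focal")[0]
        assert out.log2_ratio == pytest.approx(1.0) and out.call == "neither"

    def test_contraction(self):
        out = family_log2_ratio(self._counts(1, [4, 4]), "focal")[0]
        assert out.log2_ratio == pytest.approx(-2.0) and out.call == "contraction"

    def test_infinite_markers(self):
        assert family_log2_ratio(self._counts(3, [0, 0]), "focal")[0].call == "expansion"
        assert math.isinf(family_log2_ratio(self._counts(3, [0, 0]), "focal")[0].log2_ratio)
        assert family_log2_ratio(self._counts(0, [2, 2]), "focal")[0].call == "contraction"
        assert family_log2_ratio(self._counts(0, [0, 0]), "focal")[0].call == "neither"

    def test_needs_two_other_species(self):
        with pytest.raises(ValueError):
            family_log2_ratio(self._counts(1, [1]), "focal")

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(a=st.integers(1, 40), b=st.integers(1, 40))
    def test_antisymmetry_on_swap(self, a, b):
        df = pd.DataFrame({"x": [a], "y": [b], "z": [b]}, index=["og"])
        fwd = family_log2_ratio(df, "x")[0].log2_ratio
        df2 = pd.DataFrame({"x": [b], "y": [a], "z": [a]}, index=["og"])
        rev = family_log2_ratio(df2, "x")[0].log2_ratio
        assert fwd == pytest.approx(-rev)


class TestDomainAssignment:
    def _og(self, genes_species):
        return pd.DataFrame(
            [
                {"orthogroup": "og1", "species": sp, "gene_id": g}
                for g, sp in genes_species
            ]
        )

    def test_rule_arithmetic_30pct_66pct_kept(self):
        og = self._og([(f"g{i}", f"s{i % 3}") for i in range(10)])
        dom = pd.DataFrame(
            [{"gene_id": g, "domain": "D1"} for g in ("g0", "g1", "g4")]
        )
        out = assign_domains_to_orthogroups(dom, og)
        assert list(out.domain) == ["D1"]
        assert out.iloc[0].gene_fraction == pytest.approx(0.3)

    def test_rare_domain_dropped(self):
        og = self._og([(f"g{i}", f"s{i % 3}") for i in range(10)])
        dom = pd.DataFrame([{"gene_id": "g0", "domain": "D1"}])
        assert assign_domains_to_orthogroups(dom, og).empty

    def test_species_breadth_required(self):
        og = self._og([(f"g{i}", f"s{i % 3}") for i in range(9)])
        # 5/9 genes but all from one species (s0 holds g0,g3,g6 → use 3)
        dom = pd.DataFrame(
            [{"gene_id": g, "domain": "D1"} for g in ("g0", "g3", "g6")]
        )
        out = assign_domains_to_orthogroups(dom, og)
        assert out.empty  # 33% of genes but 1/3 species
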