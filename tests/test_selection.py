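"""NG86 counting against brute-force oracles, distances, the neutrality
test and the per-site scan."""

import math

import numpy as np
import pytest

from abc_evolve.selection import (
    CodonAlignment,
    count_differences,
    count_sites,
    jukes_cantor,
    ng86_pair,
    ng_tables,
    nucleotide_diversity,
    slac_scan,
    subfamily_selection,
)
from abc_evolve.synthetic_data import balanced_tree, simulate_codon_alignment
from oracles import SENSE_CODONS, oracle_count_differences, oracle_count_sites


class TestCountSites:
    @pytest.mark.parametrize("codon, s", [
        ("TTT", 1 / 3),   # Phe: only TTC synonymous among 9 mutants
        ("TGG", 0.0),     # Trp: no synonymous single-nucleotide change
        ("CTC", 1.0),     # Leu: fourfold-degenerate third position
    ])
    def test_enumerated_examples(self, codon, s):
        got_s, got_n = count_sites(codon)
        assert got_s == pytest.approx(s)
        assert got_s + got_n == pytest.approx(3.0)

    def test_all_codons_match_nine_mutant_oracle(self):
        for codon in SENSE_CODONS:
            assert count_sites(codon)[0] == pytest.approx(
                oracle_count_sites(codon)[0]
            ), codon

    def test_stop_codon_rejected(self):
        with pytest.raises(ValueError):
            count_sites("TAA")


class TestCountDifferences:
    @pytest.mark.parametrize("a, b, sd, nd", [
        ("TTT", "TTA", 0.0, 1.0),    # Phe -> Leu, single nonsynonymous step
        ("TTT", "GTA", 0.5, 1.5),    # two pathways averaged
        ("TTT", "TTT", 0.0, 0.0),
    ])
    def test_pathway_examples(self, a, b, sd, nd):
        assert count_differences(a, b) == (pytest.approx(sd), pytest.approx(nd))

    def test_sample_against_pathway_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(300):
            a, b = rng.choice(SENSE_CODONS, 2)
            sd, nd = count_differences(a, b)
            osd, ond = oracle_count_differences(a, b)
            assert sd == pytest.approx(osd), (a, b)
            assert nd == pytest.approx(ond), (a, b)

    def test_symmetry_and_conservation(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            a, b = rng.choice(SENSE_CODONS, 2)
            sd, nd = count_differences(a, b)
            assert (sd, nd) == pytest.approx(count_differences(b, a))
            assert sd + nd == pytest.approx(sum(x != y for x, y in zip(a, b)))


class TestPairDistances:
    def test_identical_rows_zero(self):
        row = "ATGAAATTTCCC"
        res = ng86_pair(row, row)
        assert res.dN == 0.0 and res.dS == 0.0

    def test_jc_closed_form(self):
        assert jukes_cantor(0.1) == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
        assert jukes_cantor(0.1) == pytest.approx(0.107326, abs=1e-5)

    def test_jc_saturated_is_nan(self):
        assert math.isnan(jukes_cantor(0.75))

    def test_symmetric_in_arguments(self):
        a = "ATGAAATTTCCCGGGAAATTTCCC"
        b = "ATGAAGTTTCCCGGGAAATTACCC"
        ra, rb = ng86_pair(a, b), ng86_pair(b, a)
        assert not ra.saturated
        assert ra.dN == pytest.approx(rb.dN)
        assert ra.dS == pytest.approx(rb.dS)

    def test_sum_sd_nd_equals_total_nt_differences(self):
        tree = balanced_tree(4, 0.15)
        aln, _ = simulate_codon_alignment(tree, omega=0.7, n_codons=80, seed=9)
        tbl = ng_tables()
        enc = aln.encoded()
        for i in range(aln.n_seqs):
            for j in range(i + 1, aln.n_seqs):
                sd = tbl["SD"][enc[i], enc[j]].sum()
                nd = tbl["ND"][enc[i], enc[j]].sum()
                nt_diffs = sum(
                    x != y for x, y in zip(aln.rows[i], aln.rows[j])
                )
                assert sd + nd == pytest.approx(nt_diffs)


class TestCodonAlignment:
    def test_internal_stop_row_dropped(self):
        aln = CodonAlignment(["a", "b"], ["ATGTAAAAA", "ATGAAAAAA"])
        assert aln.ids == ["b"]

    def test_gapped_codon_masked(self):
        aln = CodonAlignment(["a", "b"], ["ATG-AAAAA", "ATGAAAAAA"])
        enc = aln.encoded()
        assert enc[0, 1] == -1 and enc[0, 0] >= 0

    def test_length_not_multiple_of_three_rejected(self):
        with pytest.raises(ValueError):
            CodonAlignment(["a"], ["ATGA"])

    def test_coverage_filter(self):
        rows = ["ATGAAA", "ATG---", "ATGAAA", "ATGAAA", "ATGAAA"]
        aln = CodonAlignment(list("abcde"), rows)
        keep = aln.coverage_filter(0.80)
        assert list(keep) == [True, True]   # 4/5 = 0.8 inclusive
        keep_strict = aln.coverage_filter(0.81)
        assert list(keep_strict) == [True, False]


class TestNucleotideDiversity:
    def test_one_of_ten_differs(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAATTTCCC", "ATGAAATTTCCA"])
        assert nucleotide_diversity(aln) == pytest.approx(1 / 12)

    def test_identical_rows_zero(self):
        aln = CodonAlignment(["a", "b"], ["ATGAAA", "ATGAAA"])
        assert nucleotide_diversity(aln) == 0.0

    def test_mean_of_pairwise_distances(self):
        # pairwise p-distances 0.1, 0.2, 0.3 over 30 nt -> mean 0.2
        base = "ATGAAATTTCCCGGGATGAAATTTCCCGGG"
        def mut(s, k):
            s = list(s)
            for i in range(k):
                s[3 * i + 2] = "A" if s[3 * i + 2] != "A" else "G"
            return "".join(s)
        a = base
        b = mut(base, 3)
        rows = [a, b]
        aln = CodonAlignment(["a", "b"], rows)
        assert nucleotide_diversity(aln) == pytest.approx(0.1)


class TestSubfamilySelection:
    def test_invariant_alignment_is_neutral_with_zero_delta(self):
        aln = CodonAlignment(["a", "b", "c"], ["ATGAAATTT"] * 3)
        res = subfamily_selection(aln, n_boot=50, seed=0)
        assert res.delta == 0.0
        assert res.verdict == "neutral"

    def test_purifying_simulation_yields_negative_verdict(self):
        aln, _ = simulate_codon_alignment(
            balanced_tree(8, 0.1), omega=0.2, n_codons=300, seed=4
        )
        res = subfamily_selection(aln, n_boot=300, seed=1)
        assert res.verdict == "negative"
        assert 0.1 <= res.omega <= 0.35

    def test_determinism(self):
        aln, _ = simulate_codon_alignment(
            balanced_tree(4, 0.1), omega=1.0, n_codons=100, seed=6
        )
        r1 = subfamily_selection(aln, n_boot=100, seed=3)
        r2 = subfamily_selection(aln, n_boot=100, seed=3)
        assert r1 == r2

    def test_delta_omega_consistent_with_dn_ds(self):
        aln, _ = simulate_codon_alignment(
            balanced_tree(4, 0.1), omega=0.5, n_codons=150, seed=8
        )
        res = subfamily_selection(aln, n_boot=100, seed=0)
        assert res.delta == pytest.approx(res.dN - res.dS)
        assert res.omega == pytest.approx(res.dN / res.dS)
        assert 0.0 <= res.p_value <= 1.0


class TestSlacScan:
    def test_invariant_columns_class_none(self):
        tree = balanced_tree(4, 0.1)
        aln = CodonAlignment(
            [f"t{i}" for i in range(1, 5)], ["ATGAAATTT"] * 4
        )
        res = slac_scan(aln, tree)
        assert all(s.klass == "none" and s.n_subs == 0 for s in res)

    def test_missing_tip_is_error(self):
        tree = balanced_tree(4, 0.1)
        aln = CodonAlignment(["t1", "t2"], ["ATGAAA", "ATGAAA"])
        with pytest.raises(ValueError):
            slac_scan(aln, tree)

    def test_neutral_type_one_error_within_ceiling(self):
        """At alpha=0.05, at most ~10% of neutral sites may be flagged."""
        tree = balanced_tree(16, 0.06)
        flagged = total = 0
        for rep in range(10):
            aln, _ = simulate_codon_alignment(
                tree, omega=1.0, n_codons=60, seed=40 + rep
            )
            res = slac_scan(aln, tree)
            flagged += sum(1 for s in res if s.klass != "none")
            total += len(res)
        assert flagged / total <= 0.10

    def test_planted_site_most_frequently_flagged_positive(self):
        """The high-omega site must be flagged positive more often than any
        background site across replicates."""
        tree = balanced_tree(16, 0.06)
        n_sites = 40
        counts = np.zeros(n_sites)
        for rep in range(25):
            site_om = np.full(n_sites, 0.2)
            site_om[7] = 5.0
            aln, _ = simulate_codon_alignment(
                tree, omega=0.2, n_codons=n_sites, seed=700 + rep,
                site_omegas=site_om,
            )
            for s in slac_scan(aln, tree):
                if s.klass == "positive":
                    counts[s.site] += 1
        assert counts[7] == counts.max()
        assert counts[7] >= 1
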