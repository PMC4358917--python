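"""Generator contracts: determinism, planted ground truth, degenerate
limits."""

import numpy as np
import pytest

from abc_evolve.phylo import pairwise_identity
from abc_evolve.selection import genetic_code
from abc_evolve.synthetic_data import (
    balanced_tree,
    plant_gene_family,
    simulate_architecture_table,
    simulate_codon_alignment,
    simulate_expression,
)

CHROMS = {"chr1": 30_000_000, "chr2": 20_000_000, "chr3": 12_000_000}


class TestCodonSimulator:
    def test_no_stop_codons_emitted(self):
        aln, _ = simulate_codon_alignment(balanced_tree(8, 0.3), omega=1.0,
                                          n_codons=100, seed=0)
        stops = genetic_code()["stops"]
        for row in aln.rows:
            for k in range(0, len(row), 3):
                assert row[k:k + 3] not in stops

    def test_identical_seed_identical_output(self):
        t = balanced_tree(4, 0.2)
        a1, _ = simulate_codon_alignment(t, omega=0.5, n_codons=50, seed=42)
        a2, _ = simulate_codon_alignment(t, omega=0.5, n_codons=50, seed=42)
        assert a1.rows == a2.rows
        a3, _ = simulate_codon_alignment(t, omega=0.5, n_codons=50, seed=43)
        assert a1.rows != a3.rows

    def test_zero_branch_lengths_give_identical_tips(self):
        t = balanced_tree(2, 0.0)
        aln, _ = simulate_codon_alignment(t, omega=1.0, n_codons=30, seed=1)
        assert aln.rows[0] == aln.rows[1]

    def test_near_zero_omega_suppresses_nonsynonymous_events(self):
        t = balanced_tree(4, 0.5)
        _, truth = simulate_codon_alignment(t, omega=1e-9, n_codons=100, seed=2)
        assert truth.n_nonsyn_events == 0
        assert truth.n_syn_events > 0

    def test_invalid_parameters_rejected(self):
        t = balanced_tree(4, 0.1)
        with pytest.raises(ValueError):
            simulate_codon_alignment(t, omega=0.0, n_codons=10, seed=0)
        with pytest.raises(ValueError):
            simulate_codon_alignment(t, omega=1.0, n_codons=0, seed=0)

    def test_branch_length_scaling_matches_event_count(self):
        """One unit of branch length ~ one substitution per codon at the
        dataset omega."""
        t = balanced_tree(2, 0.5)  # total path 1.0 per codon
        _, truth = simulate_codon_alignment(t, omega=1.0, n_codons=2000, seed=3)
        events = truth.n_syn_events + truth.n_nonsyn_events
        assert events / 2000 == pytest.approx(1.0, rel=0.1)


class TestPlantGeneFamily:
    def test_tandem_pair_identity_within_band(self):
        records, loci, truth = plant_gene_family(
            n_background=4, dup_spec=[(2, "tandem", 0.90)],
            chrom_lengths=CHROMS, seed=1)
        (planted,) = truth.planted_duplications
        a, b = sorted(planted.members)
        seqs = {r.id: r.seq for r in records}
        ident = pairwise_identity(seqs[a], seqs[b])
        assert 0.88 <= ident <= 0.92
        loc = {l.gene_id: l for l in loci}
        assert loc[a].chrom == loc[b].chrom
        assert abs(loc[b].start - loc[a].end) < 100_000

    def test_background_genes_mutually_below_60_percent(self):
        records, _, truth = plant_gene_family(
            n_background=6, dup_spec=[], chrom_lengths=CHROMS, seed=2)
        assert truth.planted_duplications == []
        seqs = [r.seq for r in records]
        for i in range(len(seqs)):
            for j in range(i + 1, len(seqs)):
                assert pairwise_identity(seqs[i], seqs[j]) < 0.60

    def test_block_group_members_all_pairs_above_target(self):
        records, loci, truth = plant_gene_family(
            n_background=2, dup_spec=[(4, "block", 0.88)],
            chrom_lengths=CHROMS, seed=3)
        (planted,) = truth.planted_duplications
        members = sorted(planted.members)
        seqs = {r.id: r.seq for r in records}
        for i in range(len(members)):
            for j in range(i + 1, len(members)):
                ident = pairwise_identity(seqs[members[i]], seqs[members[j]])
                assert 0.86 <= ident <= 0.92
        chroms = {l.chrom for l in loci if l.gene_id in planted.members}
        assert len(chroms) == 2

    def test_block_smaller_than_four_rejected(self):
        with pytest.raises(ValueError):
            plant_gene_family(2, [(3, "block", 0.9)], CHROMS, seed=0)

    def test_determinism(self):
        r1, l1, _ = plant_gene_family(5, [(2, "tandem", 0.9)], CHROMS, seed=7)
        r2, l2, _ = plant_gene_family(5, [(2, "tandem", 0.9)], CHROMS, seed=7)
        assert [r.seq for r in r1] == [r.seq for r in r2]
        assert l1 == l2

    def test_infeasible_placement_is_error(self):
        with pytest.raises(ValueError, match="infeasible|short"):
            plant_gene_family(50, [], {"c1": 10_000}, seed=0)


class TestArchitectureTable:
    def test_half_size_d_template(self):
        hits, truth = simulate_architecture_table({"D": 3}, seed=0)
        pids = sorted(truth.true_subfamily)
        for pid in pids:
            mine = [h for h in hits if h.protein_id == pid]
            core = [h.category for h in mine if not h.category.startswith("DIAG")]
            assert core == ["TMD", "NBD"]
            assert any(h.category == "DIAG:ABCD" for h in mine)

    def test_soluble_e_template(self):
        hits, truth = simulate_architecture_table({"E": 2}, seed=1)
        for pid in truth.true_subfamily:
            core = [h.category for h in hits
                    if h.protein_id == pid and not h.category.startswith("DIAG")]
            assert core == ["NBD", "NBD"]

    def test_pdr_template_reverse_full_with_diag(self):
        hits, truth = simulate_architecture_table({"G_PDR": 1}, seed=2)
        (pid,) = truth.true_subfamily
        core = [h.category for h in hits
                if h.protein_id == pid and not h.category.startswith("DIAG")]
        assert core == ["NBD", "TMD", "NBD", "TMD"]
        assert any(h.category == "DIAG:PDR" for h in hits)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError):
            simulate_architecture_table({"Z": 1}, seed=0)


class TestExpressionGenerator:
    TISSUES = ["root", "leaf", "flower", "fruit", "bud"]

    def test_all_silent_targets_never_called(self):
        from abc_evolve.expression import ExpressionMatrix, call_expressed, rpkm_to_tpm
        rpkm, truth = simulate_expression(20, self.TISSUES, frac_silent=1.0, seed=0)
        calls = call_expressed(rpkm_to_tpm(ExpressionMatrix(rpkm, "RPKM")))
        assert not calls.calls.loc[truth.target_genes].any().any()

    def test_single_tissue_gene_lands_in_singleton_region(self):
        from abc_evolve.expression import (
            ExpressionMatrix, call_expressed, rpkm_to_tpm, tissue_sets,
        )
        rpkm, truth = simulate_expression(
            30, self.TISSUES, frac_silent=0.0, frac_broad=0.0, seed=1)
        calls = call_expressed(rpkm_to_tpm(ExpressionMatrix(rpkm, "RPKM")))
        regions = tissue_sets(calls)
        for gene in truth.target_genes:
            tset = frozenset(
                t for t in self.TISSUES if truth.expressed_truth.loc[gene, t]
            )
            assert len(tset) == 1
            assert regions.get(tset, 0) >= 1

    def test_broad_gene_counted_in_full_intersection(self):
        from abc_evolve.expression import (
            ExpressionMatrix, call_expressed, rpkm_to_tpm, tissue_sets,
        )
        rpkm, truth = simulate_expression(
            10, self.TISSUES, frac_silent=0.0, frac_broad=1.0, seed=2)
        calls = call_expressed(rpkm_to_tpm(ExpressionMatrix(rpkm, "RPKM")))
        regions = tissue_sets(calls)
        full = frozenset(self.TISSUES)
        # all targets plus housekeeping genes are broad
        assert regions[full] == len(truth.target_genes) + len(truth.background_genes)

    def test_determinism(self):
        m1, _ = simulate_expression(15, self.TISSUES, 0.5, seed=9)
        m2, _ = simulate_expression(15, self.TISSUES, 0.5, seed=9)
        assert m1.equals(m2)
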