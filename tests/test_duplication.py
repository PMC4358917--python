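"""Four-criteria duplication caller: planted-truth recovery, boundary
behaviour, co-localization typing, monotonicity, summaries."""

import dendropy
import numpy as np
import pytest

from abc_evolve.classify import SubfamilyAssignment
from abc_evolve.duplication import (
    classify_event,
    detect_duplications,
    summarize,
)
from abc_evolve.io_formats import GeneLocus, RunConfig, SequenceRecord
from abc_evolve.phylo import Alignment, bootstrap_supports, pairwise_identity
from abc_evolve.synthetic_data import plant_gene_family

CHROMS = {"chr1": 30_000_000, "chr2": 20_000_000, "chr3": 12_000_000}


def supported_tree(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for node in tree.preorder_node_iter():
        if not node.is_leaf() and node.label:
            node.support = int(node.label)
    return tree


def loci_map(*specs):
    """specs: (gene_id, chrom, start_kb)."""
    return {
        g: GeneLocus(g, c, int(s * 1000), int(s * 1000) + 599, "+")
        for g, c, s in specs
    }


class TestClassifyEvent:
    def test_adjacent_pair_is_tandem(self):
        loci = loci_map(("a", "chr1", 100), ("b", "chr1", 108))
        assert classify_event(["a", "b"], loci) == "tandem"

    def test_distant_runs_with_intervening_genes_are_block(self):
        # two 3-gene runs 2 Mb apart with 6 unrelated genes in between
        specs = [("a1", "chr1", 100), ("a2", "chr1", 110), ("a3", "chr1", 120)]
        specs += [(f"x{i}", "chr1", 400 + 200 * i) for i in range(6)]
        specs += [("b1", "chr1", 2200), ("b2", "chr1", 2210), ("b3", "chr1", 2220)]
        loci = loci_map(*specs)
        members = ["a1", "a2", "a3", "b1", "b2", "b3"]
        assert classify_event(members, loci) == "block"

    def test_cross_chromosome_singletons_rejected(self):
        loci = loci_map(("a", "chr1", 100), ("b", "chr2", 100))
        assert classify_event(["a", "b"], loci) == "rejected"

    def test_runs_on_two_chromosomes_are_block(self):
        loci = loci_map(("a1", "chr1", 100), ("a2", "chr1", 108),
                        ("b1", "chr2", 500), ("b2", "chr2", 508))
        assert classify_event(["a1", "a2", "b1", "b2"], loci) == "block"

    def test_sparse_same_chromosome_distant_pair_links_via_gene_budget(self):
        # 2 Mb apart but no intervening annotated genes: the
        # intervening-gene arm of the linkage rule applies
        loci = loci_map(("a", "chr1", 100), ("b", "chr1", 2100))
        assert classify_event(["a", "b"], loci) == "tandem"


class TestDetectDuplications:
    def _scenario(self, seed=11):
        records, loci, truth = plant_gene_family(
            n_background=10,
            dup_spec=[(2, "tandem", 0.90), (4, "block", 0.88)],
            chrom_lengths=CHROMS, seed=seed,
            decoy_cross_chrom_identity=0.90,
            decoy_colocated_identity=0.60,
        )
        aln = Alignment.from_records(records)
        tree = bootstrap_supports(aln, n_reps=100, seed=seed)
        return records, loci, tree, truth

    def test_planted_events_recovered_with_types(self):
        records, loci, tree, truth = self._scenario()
        events = detect_duplications(records, loci, tree, RunConfig())
        called = {(e.members, e.dtype) for e in events}
        expected = {(p.members, p.dtype) for p in truth.planted_duplications}
        assert called == expected

    def test_decoys_never_reported(self):
        records, loci, tree, truth = self._scenario()
        events = detect_duplications(records, loci, tree, RunConfig())
        called_genes = set().union(*(e.members for e in events))
        for a, b, _kind in truth.decoy_pairs:
            assert a not in called_genes and b not in called_genes

    def test_no_gene_in_two_events(self):
        records, loci, tree, _ = self._scenario()
        events = detect_duplications(records, loci, tree, RunConfig())
        genes = [g for e in events for g in e.members]
        assert len(genes) == len(set(genes))

    def test_identity_threshold_monotonicity(self):
        records, loci, tree, _ = self._scenario()
        low = detect_duplications(records, loci, tree, RunConfig(dup_identity_min=0.50))
        mid = detect_duplications(records, loci, tree, RunConfig(dup_identity_min=0.70))
        high = detect_duplications(records, loci, tree, RunConfig(dup_identity_min=0.95))
        def genes(evs):
            return set().union(*(e.members for e in evs)) if evs else set()
        assert genes(high) <= genes(mid) <= genes(low)

    def test_support_exactly_80_rejected_81_accepted(self):
        seqs = {
            "a": "ATGAAATTTCCCGGG" * 10,
            "b": "ATGAAATTTCCCGGG" * 10,
            "c": "TGGCATCAGCGATCA" * 10,
            "d": "CAGTGGACTTGACCA" * 10,
        }
        records = [SequenceRecord(i, s, "cds") for i, s in seqs.items()]
        loci = list(loci_map(("a", "chr1", 100), ("b", "chr1", 110),
                             ("c", "chr2", 100), ("d", "chr3", 100)).values())
        for support, n_expected in ((80, 0), (81, 1)):
            tree = supported_tree(f"((a:0.01,b:0.01){support}:0.2,(c:0.2,d:0.2)99:0.2);")
            events = detect_duplications(records, loci, tree, RunConfig())
            assert len(events) == n_expected, support

    def test_identity_exactly_070_accepted_inclusive(self):
        rng = np.random.default_rng(5)
        base = "".join(rng.choice(list("ACGT"), 200))
        other = list(base)
        pos = rng.choice(200, 60, replace=False)  # 140/200 = 0.70
        for p in pos:
            other[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[other[p]]
        other = "".join(other)
        assert pairwise_identity(base, other) == pytest.approx(0.70)
        records = [SequenceRecord("a", base, "cds"), SequenceRecord("b", other, "cds")]
        loci = list(loci_map(("a", "chr1", 100), ("b", "chr1", 110)).values())
        tree = supported_tree("((a:0.1,b:0.1)99:0.2,(a2:0.2,b2:0.2)10:0.1);")
        # prune helper tips absent from loci/cds are skipped by the caller
        events = detect_duplications(records, loci, tree, RunConfig())
        assert len(events) == 1
        assert events[0].min_pairwise_identity == pytest.approx(0.70)


class TestSummarize:
    def _event(self, members, dtype):
        from abc_evolve.duplication import DuplicationEvent
        return DuplicationEvent(frozenset(members), 95, 0.9, dtype,
                                ("chr1",))

    def test_percentage_arithmetic(self):
        events = [self._event(["g1", "g2", "g3"], "tandem"),
                  self._event(["g4", "g5"], "block")]
        assigns = [SubfamilyAssignment(f"g{i}", "G_PDR", "x") for i in range(1, 6)]
        df = summarize(events, assigns, total_genes=20)
        total = df[df.subfamily == "Total"].iloc[0]
        assert total.duplicate_genes == 5
        assert total.pct_of_annotated == 25

    def test_tandem_and_block_counted_per_subfamily(self):
        events = [self._event(["g1", "g2"], "tandem"),
                  self._event(["g3", "g4"], "block")]
        assigns = [SubfamilyAssignment(f"g{i}", "G_WBC", "x") for i in range(1, 5)]
        df = summarize(events, assigns, total_genes=10)
        row = df[df.subfamily == "G_WBC"].iloc[0]
        assert row.tandem_events == 1 and row.block_events == 1

    def test_zero_events_all_zero_table(self):
        df = summarize([], [], total_genes=10)
        assert (df[["tandem_events", "block_events", "duplicate_genes"]].values == 0).all()

    def test_unassigned_member_counted_unclassified(self):
        events = [self._event(["g1", "g2"], "tandem")]
        df = summarize(events, [], total_genes=4)
        row = df[df.subfamily == "unclassified"].iloc[0]
        assert row.duplicate_genes == 2
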