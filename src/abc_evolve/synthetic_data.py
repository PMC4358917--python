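"""Synthetic inputs with known ground truth for every pipeline stage.

Four generators emulate the study's input classes:

* codon alignments evolved along a tree under a Muse-Gaut-style codon model
  with a dN/dS ratio omega and transition/transversion ratio kappa
  (validation substrate for the selection statistics);
* gene families with planted recent duplications — tandem arrays and
  dispersed blocks — on synthetic chromosomes, plus decoy pairs
  (validation substrate for the duplication caller);
* domain-architecture tables with known subfamily ground truth
  (validation substrate for the classifier);
* RPKM expression matrices with known expressed/silent gene sets
  (validation substrate for the expression layer).

All generators are deterministic for a fixed (parameters, seed).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .io_formats import DomainHit, GeneLocus, SequenceRecord
from .selection import NUCS, CodonAlignment, genetic_code

logger = logging.getLogger("abc_evolve")

_TRANSITION = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


@dataclass(frozen=True)
class PlantedDuplication:
    members: frozenset
    dtype: str            # "tandem" | "block"
    identity_target: float


@dataclass
class SimTruth:
    """Ground truth emitted alongside every synthetic dataset."""

    true_omega: float | None = None
    site_omegas: np.ndarray | None = None
    true_tree: dendropy.Tree | None = None
    n_syn_events: int = 0
    n_nonsyn_events: int = 0
    planted_duplications: list[PlantedDuplication] = field(default_factory=list)
    decoy_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    true_subfamily: dict[str, str] = field(default_factory=dict)
    expressed_truth: pd.DataFrame | None = None  # bool gene x tissue
    target_genes: list[str] = field(default_factory=list)
    background_genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# Codon-model simulator

@lru_cache(maxsize=None)
def _neighbor_table(code_id: int = 1):
    """For each sense codon: arrays of neighbor index, is_transition, is_syn.

    Neighbors are the single-nucleotide mutants that are sense codons;
    mutants that would create a stop codon are rejected (not listed).
    """
    gc = genetic_code(code_id)
    sense, index, translate = gc["sense"], gc["index"], gc["translate"]
    nbr, ts, syn = [], [], []
    for codon in sense:
        n_i, t_i, s_i = [], [], []
        for pos in range(3):
            for nuc in NUCS:
                if nuc == codon[pos]:
                    continue
                mut = codon[:pos] + nuc + codon[pos + 1:]
                if mut not in index:
                    continue  # stop codon: proposal rejected
                n_i.append(index[mut])
                t_i.append((codon[pos], nuc) in _TRANSITION)
                s_i.append(translate[mut] == translate[codon])
        nbr.append(np.array(n_i, dtype=np.int16))
        ts.append(np.array(t_i, dtype=bool))
        syn.append(np.array(s_i, dtype=bool))
    return nbr, ts, syn


def _rate_tables(omega: float, kappa: float, scale_omega: float, code_id: int = 1):
    """Per-codon neighbor substitution rates and totals.

    Rate of a single-nucleotide change = (kappa if transition else 1) x
    (omega if nonsynonymous else 1), normalized so that one unit of branch
    length equals one expected substitution per codon at ``scale_omega``
    (uniform codon frequencies). Using a scale_omega different from omega
    lets planted high-omega sites evolve genuinely faster than background.
    """
    nbr, ts, syn = _neighbor_table(code_id)

    def raw(om):
        rates = []
        for t_i, s_i in zip(ts, syn):
            r = np.where(t_i, kappa, 1.0) * np.where(s_i, 1.0, om)
            rates.append(r)
        return rates

    z = float(np.mean([r.sum() for r in raw(scale_omega)]))
    rates = [r / z for r in raw(omega)]
    totals = np.array([r.sum() for r in rates])
    return nbr, syn, rates, totals


def simulate_codon_alignment(
    tree: dendropy.Tree,
    omega: float,
    kappa: float = 1.0,
    n_codons: int = 300,
    seed: int = 0,
    site_omegas: Sequence[float] | None = None,
    code_id: int = 1,
) -> tuple[CodonAlignment, SimTruth]:
    """Evolve coding sequences along a tree under a codon model.

    Nonsynonymous changes occur at omega times the synonymous rate,
    transitions at kappa times the transversion rate; proposals to stop
    codons are rejected so no stop codon is ever emitted. Branch lengths
    are expected substitutions per codon at the dataset-level omega.
    ``site_omegas`` overrides omega per codon site (same branch-length
    scale), e.g. to plant positively selected sites.
    """
    if omega <= 0:
        raise ValueError("omega must be > 0")
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    tips = list(tree.leaf_node_iter())
    if len(tips) < 2:
        raise ValueError("tree needs >= 2 tips")
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and (edge.length or 0.0) < 0:
            raise ValueError("negative branch length")

    rng = np.random.default_rng(seed)
    gc = genetic_code(code_id)
    n_sense = len(gc["sense"])

    if site_omegas is None:
        site_omega_arr = np.full(n_codons, float(omega))
    else:
        site_omega_arr = np.asarray(site_omegas, dtype=float)
        if site_omega_arr.shape != (n_codons,):
            raise ValueError("site_omegas must have length n_codons")
        if (site_omega_arr <= 0).any():
            raise ValueError("site omegas must be > 0")

    tables = {
        om: _rate_tables(om, kappa, scale_omega=omega, code_id=code_id)
        for om in np.unique(site_omega_arr)
    }

    root_states = rng.integers(0, n_sense, size=n_codons)
    states: dict = {}
    n_syn = n_nonsyn = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[node] = root_states.copy()
            continue
        parent_seq = states[node.parent_node]
        b = node.edge.length or 0.0
        seq = parent_seq.copy()
        for k in range(n_codons):
            nbr, syn, rates, totals = tables[site_omega_arr[k]]
            s = int(seq[k])
            t = 0.0
            while True:
                total = totals[s]
                if total <= 0:
                    break
                t += rng.exponential(1.0 / total)
                if t >= b:
                    break
                r = rates[s]
                choice = rng.choice(len(r), p=r / r.sum())
                if syn[s][choice]:
                    n_syn += 1
                else:
                    n_nonsyn += 1
                s = int(nbr[s][choice])
            seq[k] = s
        states[node] = seq

    sense = gc["sense"]
    ids, rows = [], []
    for leaf in tips:
        ids.append(leaf.taxon.label)
        rows.append("".join(sense[s] for s in states[leaf]))
    aln = CodonAlignment(ids, rows, code_id)
    truth = SimTruth(
        true_omega=float(omega),
        site_omegas=site_omega_arr,
        true_tree=tree,
        n_syn_events=n_syn,
        n_nonsyn_events=n_nonsyn,
    )
    return aln, truth


def balanced_tree(n_tips: int, branch_length: float) -> dendropy.Tree:
    """A balanced binary tree with equal branch lengths, tips t1..tn."""
    if n_tips < 2 or n_tips & (n_tips - 1):
        raise ValueError("n_tips must be a power of two >= 2")
    labels = [f"t{i + 1}" for i in range(n_tips)]

    def build(names):
        if len(names) == 1:
            return names[0]
        half = len(names) // 2
        return f"({build(names[:half])}:{branch_length},{build(names[half:])}:{branch_length})"

    newick = build(labels) + ";"
    return dendropy.Tree.get(data=newick, schema="newick")


# ---------------------------------------------------------------------------
# Gene families with planted duplications

def _random_cds(n_codons: int, rng: np.random.Generator, code_id: int = 1) -> str:
    sense = genetic_code(code_id)["sense"]
    return "".join(sense[i] for i in rng.integers(0, len(sense), size=n_codons))


def _mutate_positions(
    cds: str, positions: Sequence[int], rng: np.random.Generator, code_id: int = 1
) -> str:
    """Point-mutate the given nucleotide positions without creating stops."""
    stops = genetic_code(code_id)["stops"]
    seq = list(cds)
    for pos in positions:
        codon_start = (pos // 3) * 3
        alternatives = [n for n in NUCS if n != seq[pos]]
        rng.shuffle(alternatives)
        for nuc in alternatives:
            trial = seq.copy()
            trial[pos] = nuc
            if "".join(trial[codon_start: codon_start + 3]) not in stops:
                seq = trial
                break
    return "".join(seq)


def _derive_family(
    ancestor: str,
    size: int,
    identity: float,
    rng: np.random.Generator,
    code_id: int = 1,
) -> list[str]:
    """Copies of an ancestor with all pairwise identities ~= identity.

    Each member receives point mutations at a private (disjoint) set of
    positions of size round((1-identity)/2 * L), so every pair differs at
    ~ (1-identity) * L positions.
    """
    L = len(ancestor)
    m = int(round((1.0 - identity) / 2.0 * L))
    if size * m > L:
        raise ValueError("identity target infeasible for group size")
    pool = rng.permutation(L)
    members = []
    for i in range(size):
        positions = pool[i * m: (i + 1) * m]
        members.append(_mutate_positions(ancestor, positions, rng, code_id))
    return members


def plant_gene_family(
    n_background: int,
    dup_spec: Sequence[tuple[int, str, float]],
    chrom_lengths: Mapping[str, int],
    seed: int = 0,
    n_codons: int = 200,
    decoy_cross_chrom_identity: float | None = None,
    decoy_colocated_identity: float | None = None,
    code_id: int = 1,
) -> tuple[list[SequenceRecord], list[GeneLocus], SimTruth]:
    """Synthetic gene family with planted recent duplications.

    ``dup_spec`` lists (group size, "tandem"|"block", identity target)
    triples. Tandem groups are placed as adjacent runs on one chromosome;
    block groups (size >= 4) as two distant >= 2-gene runs. Background
    genes are mutually unrelated random CDS (< 60% identity). Optional
    decoys: a high-identity pair split across chromosomes, and a
    co-located pair below the identity criterion. All CDS share one length
    so the set is trivially alignable.
    """
    rng = np.random.default_rng(seed)
    for size, dtype, ident in dup_spec:
        if dtype not in ("tandem", "block"):
            raise ValueError(f"unknown duplication type {dtype!r}")
        if not 0.0 < ident < 1.0:
            raise ValueError("identity target must be in (0, 1)")
        if size < 2:
            raise ValueError("group size must be >= 2")
        if dtype == "block" and size < 4:
            raise ValueError("block groups need >= 4 members (two >=2-gene runs)")

    gene_bp = 3 * n_codons
    records: list[SequenceRecord] = []
    truth = SimTruth()

    # units to place: ("run", [gene ids in order]) laid out adjacently,
    # singles get their own unit
    units: list[tuple[str, list[tuple[str, str]]]] = []  # (chrom_hint, [(gid, seq)])
    counter = itertools.count(1)
    chroms = list(chrom_lengths)

    def new_gid() -> str:
        return f"g{next(counter):03d}"

    for size, dtype, ident in dup_spec:
        ancestor = _random_cds(n_codons, rng, code_id)
        seqs = _derive_family(ancestor, size, ident, rng, code_id)
        gids = [new_gid() for _ in range(size)]
        truth.planted_duplications.append(
            PlantedDuplication(frozenset(gids), dtype, ident)
        )
        pairs = list(zip(gids, seqs))
        if dtype == "tandem":
            units.append(("", pairs))
        else:
            # the duplicated run goes to a second chromosome: on these
            # sparse synthetic chromosomes a same-chromosome distant run
            # would still fall within the intervening-gene linkage arm
            if len(chroms) < 2:
                raise ValueError("block groups need >= 2 chromosomes")
            half = (size + 1) // 2
            i = int(rng.integers(len(chroms)))
            j = (i + 1 + int(rng.integers(len(chroms) - 1))) % len(chroms)
            units.append((chroms[i] + ":near", pairs[:half]))
            units.append((chroms[j] + ":near", pairs[half:]))

    if decoy_cross_chrom_identity is not None:
        if len(chroms) < 2:
            raise ValueError("cross-chromosome decoy needs >= 2 chromosomes")
        ancestor = _random_cds(n_codons, rng, code_id)
        seqs = _derive_family(ancestor, 2, decoy_cross_chrom_identity, rng, code_id)
        gids = [new_gid(), new_gid()]
        truth.decoy_pairs.append((gids[0], gids[1], "cross_chromosome"))
        units.append((chroms[0], [(gids[0], seqs[0])]))
        units.append((chroms[1], [(gids[1], seqs[1])]))

    if decoy_colocated_identity is not None:
        ancestor = _random_cds(n_codons, rng, code_id)
        seqs = _derive_family(ancestor, 2, decoy_colocated_identity, rng, code_id)
        gids = [new_gid(), new_gid()]
        truth.decoy_pairs.append((gids[0], gids[1], "colocated_low_identity"))
        units.append(("", [(gids[0], seqs[0]), (gids[1], seqs[1])]))

    for _ in range(n_background):
        units.append(("", [(new_gid(), _random_cds(n_codons, rng, code_id))]))

    # Placement: per-chromosome cursor; large gaps between units, small gaps
    # within a run; ":far" units forced >= 2 Mb beyond the cursor.
    cursors = {c: 1 for c in chroms}
    loci: list[GeneLocus] = []

    def place(chrom: str, run: list[tuple[str, str]], far: bool) -> None:
        pos = cursors[chrom]
        pos += int(2_000_000 if far else rng.integers(150_000, 400_000))
        for gid, seq in run:
            end = pos + gene_bp - 1
            if end > chrom_lengths[chrom]:
                raise ValueError(
                    f"placement infeasible: chromosome {chrom} too short"
                )
            loci.append(GeneLocus(gid, chrom, pos, end, "+"))
            records.append(SequenceRecord(id=gid, seq=seq, moltype="cds"))
            pos = end + 1 + int(rng.integers(2_000, 10_000))
        cursors[chrom] = pos

    order = rng.permutation(len(units))
    for idx in order:
        hint, run = units[idx]
        far = hint.endswith(":far")
        chrom = hint.split(":")[0] if hint else chroms[int(rng.integers(len(chroms)))]
        place(chrom, run, far)

    records.sort(key=lambda r: r.id)
    loci.sort(key=lambda l: l.gene_id)
    return records, loci, truth


# ---------------------------------------------------------------------------
# Domain-architecture tables

#: topology and diagnostic label emitted per subfamily ground-truth label
_ARCH_TEMPLATES: dict[str, tuple[tuple[str, ...], str | None]] = {
    "A": (("TMD", "NBD", "TMD", "NBD"), "ABCA"),
    "B": (("TMD", "NBD", "TMD", "NBD"), "ABCB"),
    "C": (("TMD", "NBD", "TMD", "NBD"), "ABCC"),
    "D": (("TMD", "NBD"), "ABCD"),       # half-size, forward
    "E": (("NBD", "NBD"), "ABCE"),       # soluble
    "F": (("NBD", "NBD"), "ABCF"),       # soluble
    "G_WBC": (("NBD", "TMD"), None),     # reverse half, topology suffices
    "G_PDR": (("NBD", "TMD", "NBD", "TMD"), "PDR"),  # reverse full
    "I": (("NBD",), "ABCI"),             # prokaryotic-type single domain
    "unclassified": (("TMD", "NBD", "TMD", "NBD"), None),  # forward, no DIAG
}

_DOMAIN_IDS = {"NBD": "PF00005", "TMD": "PF00664"}


def simulate_architecture_table(
    counts: Mapping[str, int], seed: int = 0
) -> tuple[list[DomainHit], SimTruth]:
    """Domain tables whose architectures map to known subfamily labels.

    ``counts`` maps subfamily labels (including "unclassified" for
    forward-full proteins without a diagnostic hit) to the number of
    proteins to emit. Domain coordinates are jittered but keep the
    template order.
    """
    rng = np.random.default_rng(seed)
    hits: list[DomainHit] = []
    truth = SimTruth()
    counter = itertools.count(1)
    for label in sorted(counts):
        if label not in _ARCH_TEMPLATES:
            raise ValueError(f"unknown subfamily label {label!r}")
        n = counts[label]
        if n < 0:
            raise ValueError("counts must be >= 0")
        topology, diag = _ARCH_TEMPLATES[label]
        for _ in range(n):
            pid = f"p{next(counter):04d}"
            truth.true_subfamily[pid] = label
            pos = int(rng.integers(5, 30))
            for dom in topology:
                length = int(rng.integers(180, 230)) if dom == "NBD" else int(
                    rng.integers(200, 280)
                )
                hits.append(
                    DomainHit(pid, _DOMAIN_IDS[dom], pos, pos + length - 1, dom)
                )
                pos += length + int(rng.integers(20, 60))
            if diag is not None:
                hits.append(DomainHit(pid, diag, 1, pos, f"DIAG:{diag}"))
    hits.sort(key=lambda h: (h.protein_id, h.start))
    return hits, truth


# ---------------------------------------------------------------------------
# Expression matrices

def simulate_expression(
    n_genes: int,
    tissues: Sequence[str],
    frac_silent: float,
    seed: int = 0,
    frac_broad: float = 0.5,
    n_housekeeping: int = 30,
    threshold: float = 2.0,
    margin: float = 0.5,
) -> tuple[pd.DataFrame, SimTruth]:
    """RPKM matrix with known expressed/silent target genes.

    Target genes are silent with probability ``frac_silent`` (TPM below
    threshold - margin in every tissue after normalization); expressed
    targets are broad (all tissues) with probability ``frac_broad``, else
    specific to one tissue. A block of always-expressed housekeeping genes
    carries the bulk of each column's mass — as in a real transcriptome the
    profiled family is a small subset of the matrix — so silent calls stay
    below threshold after TPM renormalization even when every target gene
    is silent. Truth records the intended call for every emitted gene.
    """
    if not tissues:
        raise ValueError("tissues must be non-empty")
    if not 0.0 <= frac_silent <= 1.0:
        raise ValueError("frac_silent must be in [0, 1]")
    if n_housekeeping < 1:
        raise ValueError("need >= 1 housekeeping gene to carry column mass")
    rng = np.random.default_rng(seed)
    tissues = list(tissues)
    targets = [f"abc{i + 1:03d}" for i in range(n_genes)]
    housekeeping = [f"hk{i + 1:03d}" for i in range(n_housekeeping)]
    genes = targets + housekeeping

    n_silent = int(round(frac_silent * n_genes))
    silent_flags = np.zeros(n_genes, dtype=bool)
    silent_flags[rng.permutation(n_genes)[:n_silent]] = True

    expressed = pd.DataFrame(False, index=genes, columns=tissues)
    for gi, gene in enumerate(targets):
        if silent_flags[gi]:
            continue
        if rng.random() < frac_broad:
            expressed.loc[gene, :] = True
        else:
            expressed.loc[gene, tissues[int(rng.integers(len(tissues)))]] = True
    expressed.loc[housekeeping, :] = True

    # Build the TPM matrix column by column (sums exactly 1e6), then scale
    # columns by arbitrary positive factors to express it in RPKM units.
    tpm = pd.DataFrame(0.0, index=genes, columns=tissues)
    lo_exp = threshold + margin  # expressed entries at least this
    hi_sil = threshold - margin  # silent entries at most this
    for tissue in tissues:
        on = expressed[tissue].values
        k_on = int(on.sum())
        off_vals = rng.uniform(0.05, hi_sil, size=len(genes) - k_on)
        mass = 1e6 - off_vals.sum() - lo_exp * k_on
        if mass <= 0:
            raise ValueError("cannot reach the TPM column sum with these settings")
        weights = rng.dirichlet(np.full(k_on, 1.0))
        col = np.empty(len(genes))
        col[on] = lo_exp + weights * mass
        col[~on] = off_vals
        tpm[tissue] = col
    scales = rng.uniform(0.5, 3.0, size=len(tissues))
    rpkm = tpm * scales  # per-column scale: RPKM is TPM up to a column factor

    truth = SimTruth(
        expressed_truth=expressed,
        target_genes=targets,
        background_genes=housekeeping,
    )
    return rpkm, truth
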