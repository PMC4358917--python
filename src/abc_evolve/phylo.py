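"""Distance-based phylogenetics: NJ trees, bootstrap supports, clade
extraction under the clade rule (support >= 70, >= 4 members), and pairwise
sequence identity.

The tree engine is neighbor joining on p-distances or Jukes-Cantor corrected
distances; an externally computed tree (e.g. maximum likelihood) can be
imported from Newick and used anywhere a tree is consumed — the downstream
decision rules only read supports and clades.
"""

from __future__ import annotations

import io as _io
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import numpy as np
from Bio import Align
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .io_formats import SequenceRecord

logger = logging.getLogger("abc_evolve")

GAP_CHARS = set("-.")


@dataclass
class Alignment:
    """Equal-length gapped rows with unique ids."""

    ids: list[str]
    rows: list[str]
    moltype: str = "cds"  # "cds" | "protein"

    def __post_init__(self) -> None:
        if len(self.ids) != len(set(self.ids)):
            raise ValueError("duplicate ids in alignment")
        if len({len(r) for r in self.rows} | {0} if not self.rows else {len(r) for r in self.rows}) > 1:
            raise ValueError("rows must all have the same length")
        if len(self.rows) < 2:
            raise ValueError("alignment needs >= 2 rows")
        self.rows = [r.upper() for r in self.rows]

    @classmethod
    def from_records(cls, records: Iterable[SequenceRecord], moltype: str | None = None) -> "Alignment":
        recs = list(records)
        mt = moltype or (recs[0].moltype if recs else "cds")
        return cls([r.id for r in recs], [r.seq for r in recs], mt)

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_cols(self) -> int:
        return len(self.rows[0])

    def resample_columns(self, rng: np.random.Generator) -> "Alignment":
        cols = rng.integers(0, self.n_cols, size=self.n_cols)
        rows = ["".join(r[c] for c in cols) for r in self.rows]
        aln = Alignment.__new__(Alignment)
        aln.ids, aln.rows, aln.moltype = list(self.ids), rows, self.moltype
        return aln


@dataclass(frozen=True)
class Clade:
    members: frozenset
    support: int

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("a clade needs >= 2 members")
        if not 0 <= self.support <= 100:
            raise ValueError("support must be in [0, 100]")


# ---------------------------------------------------------------------------
# Pairwise identity

def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner(
        mode="global",
        match_score=1,
        mismatch_score=0,
        open_gap_score=-10,
        extend_gap_score=-0.5,
    )
    return aligner


def _identity_from_gapped(row_a: str, row_b: str) -> float:
    """Identity over aligned columns, excluding both-gap columns and
    terminal-gap overhangs; one-sided internal gaps count as mismatches."""
    n = len(row_a)
    def core(row: str) -> tuple[int, int]:
        first = next((i for i, c in enumerate(row) if c not in GAP_CHARS), n)
        last = next((i for i in range(n - 1, -1, -1) if row[i] not in GAP_CHARS), -1)
        return first, last
    a0, a1 = core(row_a)
    b0, b1 = core(row_b)
    lo, hi = max(a0, b0), min(a1, b1)
    matches = counted = 0
    for i in range(lo, hi + 1):
        ca, cb = row_a[i], row_b[i]
        if ca in GAP_CHARS and cb in GAP_CHARS:
            continue
        counted += 1
        if ca == cb and ca not in GAP_CHARS:
            matches += 1
    if counted == 0:
        raise ValueError("no alignable columns between the two sequences")
    return matches / counted


def pairwise_identity(a: str, b: str, prealigned: bool = False) -> float:
    """Fraction of identical residues between two sequences in [0, 1].

    With ``prealigned=False`` a global alignment (match 1, mismatch 0, gap
    open -10, gap extend -0.5) is computed first. Columns gapped in both
    sequences and terminal-gap overhangs are excluded from the denominator.
    """
    if not a or not b:
        raise ValueError("empty sequence")
    a, b = a.upper(), b.upper()
    if prealigned:
        if len(a) != len(b):
            raise ValueError("prealigned sequences must have equal length")
        return _identity_from_gapped(a, b)
    aln = _make_aligner().align(
        a.replace("-", ""), b.replace("-", "")
    )[0]
    return _identity_from_gapped(str(aln[0]), str(aln[1]))


# ---------------------------------------------------------------------------
# Distances

def p_distance(row_a: str, row_b: str) -> float:
    """Proportion of differing sites, pairwise deletion of gapped columns."""
    diffs = comp = 0
    for ca, cb in zip(row_a, row_b):
        if ca in GAP_CHARS or cb in GAP_CHARS:
            continue
        comp += 1
        if ca != cb:
            diffs += 1
    if comp == 0:
        raise ValueError("no comparable columns")
    return diffs / comp


def distance_matrix(aln: Alignment, model: str = "p-distance") -> np.ndarray:
    """Pairwise distance matrix under p-distance or JC correction.

    JC uses b = 3/4 for nucleotides and 19/20 for proteins; pairs at or
    beyond the correction's domain (p >= b) fall back to the p-distance,
    logged.
    """
    if model not in ("p-distance", "JC"):
        raise ValueError(f"unknown model {model!r}")
    n = aln.n_seqs
    b = 0.75 if aln.moltype == "cds" else 19.0 / 20.0
    dm = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(aln.rows[i], aln.rows[j])
            if model == "JC":
                if p >= b:
                    logger.info(
                        "JC undefined for pair (%s, %s): p=%.3f; using p-distance",
                        aln.ids[i], aln.ids[j], p,
                    )
                    d = p
                else:
                    d = -b * np.log(1.0 - p / b)
            else:
                d = p
            dm[i, j] = dm[j, i] = d
    return dm


# ---------------------------------------------------------------------------
# Neighbor joining and bootstrap

def nj_tree(aln: Alignment, model: str = "p-distance") -> dendropy.Tree:
    """Neighbor-joining tree; negative branch lengths clamped to 0."""
    if aln.n_seqs < 3:
        raise ValueError("NJ needs >= 3 sequences")
    dm = distance_matrix(aln, model)
    tree = nj_from_distances(dm, aln.ids)
    return tree


def nj_from_distances(dm: np.ndarray, ids: Sequence[str]) -> dendropy.Tree:
    """NJ on an explicit distance matrix (ids label rows/columns)."""
    skb = DistanceMatrix(dm, list(ids))
    newick = str(_skbio_nj(skb))
    tree = dendropy.Tree.get(data=newick, schema="newick")
    n_clamped = 0
    for edge in tree.preorder_edge_iter():
        if edge.length is not None and edge.length < 0:
            edge.length = 0.0
            n_clamped += 1
    if n_clamped:
        logger.info("clamped %d negative NJ branch lengths to 0", n_clamped)
    return tree


def _bipartitions(tree: dendropy.Tree, ref: str, all_tips: frozenset) -> dict:
    """Map from canonical internal split -> node. Splits are keyed by the
    tip set on the side NOT containing the reference tip."""
    out = {}
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = all_tips - side
        if 2 <= len(side) <= len(all_tips) - 2:
            out[side] = node
    return out


def bootstrap_supports(
    aln: Alignment, n_reps: int = 100, seed: int = 0, model: str = "p-distance"
) -> dendropy.Tree:
    """NJ point-estimate tree with bootstrap supports on internal edges.

    Column-resampling replicates; every internal bipartition of the point
    tree is annotated with its replicate frequency x 100, rounded, stored
    both as ``node.label`` and ``node.support``.
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    point = nj_tree(aln, model)
    all_tips = frozenset(aln.ids)
    ref = sorted(aln.ids)[0]
    point_splits = _bipartitions(point, ref, all_tips)
    counts = {split: 0 for split in point_splits}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        rep_tree = nj_tree(aln.resample_columns(rng), model)
        for split in _bipartitions(rep_tree, ref, all_tips):
            if split in counts:
                counts[split] += 1
    for split, node in point_splits.items():
        support = int(round(100.0 * counts[split] / n_reps))
        node.label = str(support)
        node.support = support
    return point


def extract_clades(
    tree: dendropy.Tree, min_support: int = 70, min_size: int = 4
) -> list[Clade]:
    """All internal nodes with support >= min_support and >= min_size tips.

    Both thresholds are inclusive; nested qualifying clades are all
    reported. Supports are read from ``node.support`` or a numeric
    ``node.label``.
    """
    clades = []
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        support = getattr(node, "support", None)
        if support is None:
            try:
                support = int(float(node.label)) if node.label else None
            except (TypeError, ValueError):
                support = None
        if support is None:
            continue
        members = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if support >= min_support and len(members) >= min_size:
            clades.append(Clade(members=members, support=int(support)))
    return clades


# ---------------------------------------------------------------------------
# Newick I/O

def read_newick(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick")
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.label is None:
            continue
        try:
            node.support = int(float(node.label))
        except ValueError:
            pass
    return tree


def write_newick(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True)
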