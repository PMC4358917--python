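"""Independent brute-force oracles used by unit and acceptance tests.

These deliberately avoid the package's own lookup tables: translation goes
through Bio.Seq, pathways are materialized as explicit codon sequences, and
tree fitting enumerates topologies exhaustively.
"""

from itertools import combinations, permutations, product

import numpy as np
from Bio.Seq import Seq

NUCS = "ACGT"
STOPS = {"TAA", "TAG", "TGA"}
SENSE_CODONS = sorted(
    "".join(c) for c in product(NUCS, repeat=3) if "".join(c) not in STOPS
)


def translate(codon: str) -> str:
    return str(Seq(codon).translate())


def oracle_count_sites(codon: str) -> tuple[float, float]:
    """9-mutant enumeration of synonymous/nonsynonymous site fractions."""
    aa = translate(codon)
    s = 0.0
    for pos in range(3):
        syn = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            mut = codon[:pos] + nuc + codon[pos + 1:]
            if mut not in STOPS and translate(mut) == aa:
                syn += 1
        s += syn / 3.0
    return s, 3.0 - s


def oracle_count_differences(a: str, b: str) -> tuple[float, float]:
    """Explicit pathway enumeration with stop-codon exclusion."""
    diff = [i for i in range(3) if a[i] != b[i]]
    if not diff:
        return 0.0, 0.0
    all_paths = []
    for order in permutations(diff):
        path = [a]
        cur = a
        for pos in order:
            cur = cur[:pos] + b[pos] + cur[pos + 1:]
            path.append(cur)
        all_paths.append(path)
    ok = [p for p in all_paths if not any(c in STOPS for c in p[1:-1])]
    paths = ok if ok else all_paths
    sds = []
    for path in paths:
        sd = 0
        for x, y in zip(path, path[1:]):
            if x not in STOPS and y not in STOPS and translate(x) == translate(y):
                sd += 1
        sds.append(sd)
    sd = float(np.mean(sds))
    return sd, len(diff) - sd


def enumerate_unrooted_topologies(labels):
    """All unrooted binary topologies over the labels, by stepwise addition
    (1, 3, 15, 105 ... topologies for 4, 5, 6, 7 taxa).

    Each topology is a list of edge frozensets, where an edge is the
    frozenset of tip labels on one of its sides (computed from an explicit
    graph by component split)."""
    labels = list(labels)
    n = len(labels)
    if n < 3:
        raise ValueError("need >= 3 labels")

    # graph form: dict node -> set of neighbors; internal nodes are ints
    def initial():
        g = {0: set(labels[:3])}
        for lab in labels[:3]:
            g[lab] = {0}
        return g

    graphs = [initial()]
    next_internal = 1
    for k in range(3, n):
        tip = labels[k]
        nxt = []
        for g in graphs:
            edges = sorted(
                {tuple(sorted((str(u), str(v)))) for u in g for v in g[u]}
            )
            seen = set()
            for u in g:
                for v in g[u]:
                    key = frozenset((u, v))
                    if key in seen:
                        continue
                    seen.add(key)
                    h = {node: set(nb) for node, nb in g.items()}
                    w = ("i", next_internal, len(nxt))  # unique-ish label
                    h[u].discard(v)
                    h[v].discard(u)
                    h[w] = {u, v, tip}
                    h[u].add(w)
                    h[v].add(w)
                    h[tip] = {w}
                    nxt.append(h)
        graphs = nxt
        next_internal += 1

    label_set = set(labels)

    def graph_edges_as_splits(g):
        splits = []
        seen = set()
        for u in g:
            for v in g[u]:
                key = frozenset((u, v))
                if key in seen:
                    continue
                seen.add(key)
                # tips reachable from v without crossing (u, v)
                stack, comp, visited = [v], set(), {u, v}
                if v in label_set:
                    comp.add(v)
                while stack:
                    cur = stack.pop()
                    for nb in g[cur]:
                        if nb in visited:
                            continue
                        visited.add(nb)
                        if nb in label_set:
                            comp.add(nb)
                        stack.append(nb)
                splits.append(frozenset(comp))
        return splits

    return [graph_edges_as_splits(g) for g in graphs]


def topology_splits(topo, all_labels):
    """Canonical internal splits of an enumerated topology."""
    ref = sorted(all_labels)[0]
    out = set()
    for side in topo:
        s = frozenset(side)
        if ref in s:
            s = frozenset(all_labels) - s
        if 2 <= len(s) <= len(all_labels) - 2:
            out.add(s)
    return out


def tree_splits(tree, all_labels):
    """Canonical internal splits of a dendropy tree."""
    ref = sorted(all_labels)[0]
    out = set()
    for node in tree.preorder_node_iter():
        if node.is_leaf() or node.parent_node is None:
            continue
        side = frozenset(lf.taxon.label for lf in node.leaf_iter())
        if ref in side:
            side = frozenset(all_labels) - side
        if 2 <= len(side) <= len(all_labels) - 2:
            out.add(side)
    return out


def least_squares_fit(topo, labels, dm) -> float:
    """Residual of fitting edge lengths of a topology to a distance matrix."""
    labels = list(labels)
    idx = {lab: i for i, lab in enumerate(labels)}
    edges = list(topo)
    rows, rhs = [], []
    for a, b in combinations(labels, 2):
        row = [1.0 if (a in e) != (b in e) else 0.0 for e in edges]
        rows.append(row)
        rhs.append(dm[idx[a], idx[b]])
    A = np.array(rows)
    y = np.array(rhs)
    sol, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(np.sum((A @ sol - y) ** 2))


def random_additive_matrix(labels, rng):
    """Distance matrix from a random binary tree with random positive
    branch lengths; returns (dm, true splits)."""
    labels = list(labels)
    topo = enumerate_unrooted_topologies(labels)
    choice = topo[int(rng.integers(len(topo)))]
    lengths = {e: float(rng.uniform(0.05, 0.4)) for e in choice}
    idx = {lab: i for i, lab in enumerate(labels)}
    dm = np.zeros((len(labels), len(labels)))
    for a, b in combinations(labels, 2):
        d = sum(L for e, L in lengths.items() if (a in e) != (b in e))
        dm[idx[a], idx[b]] = dm[idx[b], idx[a]] = d
    return dm, topology_splits(choice, labels), choice
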