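"""Codon-level selection-pressure analysis.

Implements the Nei-Gojobori (1986) counting method for synonymous and
nonsynonymous substitution rates — approximate site counting, equal-weight
pathway averaging for multi-step codon differences, Jukes-Cantor correction —
together with a codon-column bootstrap test of strict neutrality
(H0: dN = dS) and a SLAC-style per-codon selection scan (Fitch parsimony
ancestors + binomial test of the observed synonymous fraction).

Conventions: dN and dS are distances per nonsynonymous / synonymous site;
delta = dN - dS; omega = dN / dS. omega < 1 indicates purifying selection,
omega > 1 positive selection.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Sequence

import numpy as np
from Bio.Data import CodonTable
from scipy import stats

from .io_formats import SequenceRecord

logger = logging.getLogger("abc_evolve")

NUCS = "ACGT"
_TRANSITIONS = {("A", "G"), ("G", "A"), ("C", "T"), ("T", "C")}


# ---------------------------------------------------------------------------
# Genetic-code tables

@lru_cache(maxsize=None)
def genetic_code(code_id: int = 1) -> dict:
    """Sense codons, stop codons and the translation map for an NCBI code."""
    table = CodonTable.unambiguous_dna_by_id[code_id]
    stops = set(table.stop_codons)
    sense = sorted(c for c in table.forward_table if c not in stops)
    # forward_table may omit codons with ambiguity; rebuild explicitly
    sense = sorted(
        "".join(c)
        for c in itertools.product(NUCS, repeat=3)
        if "".join(c) not in stops
    )
    translate = {c: table.forward_table[c] for c in sense}
    return {
        "sense": sense,
        "index": {c: i for i, c in enumerate(sense)},
        "stops": stops,
        "translate": translate,
    }


def count_sites(codon: str, code_id: int = 1, stops_nonsyn: bool = True) -> tuple[float, float]:
    """Synonymous and nonsynonymous site counts of one sense codon.

    Each of the 9 single-nucleotide changes contributes 1/3 of a site to the
    synonymous count if it preserves the amino acid, otherwise to the
    nonsynonymous count. Changes to stop codons count as nonsynonymous under
    the default policy (``stops_nonsyn=True``); with ``stops_nonsyn=False``
    they are excluded and the position's fractions renormalized over the
    remaining changes.

    Returns (s, n) with s + n = 3.
    """
    gc = genetic_code(code_id)
    if codon not in gc["index"]:
        raise ValueError(f"not a sense codon: {codon!r}")
    aa = gc["translate"][codon]
    s = 0.0
    for pos in range(3):
        syn = 0
        counted = 0
        for nuc in NUCS:
            if nuc == codon[pos]:
                continue
            mutant = codon[:pos] + nuc + codon[pos + 1:]
            if mutant in gc["stops"]:
                if stops_nonsyn:
                    counted += 1
                continue
            counted += 1
            if gc["translate"][mutant] == aa:
                syn += 1
        s += syn / counted if counted else 0.0
    return s, 3.0 - s


def count_differences(
    codon_a: str, codon_b: str, code_id: int = 1
) -> tuple[float, float]:
    """Pathway-averaged synonymous/nonsynonymous differences between codons.

    For codons differing at k positions, the k! orderings of single-step
    pathways are weighted equally; pathways passing through a stop codon are
    excluded and the average renormalized over the rest. If every pathway
    hits a stop (cannot happen between sense codons under the standard code,
    but guarded), all pathways are kept with stop-involving steps counted as
    nonsynonymous, and the event is logged.

    Returns (sd, nd) with sd + nd = number of differing positions.
    """
    gc = genetic_code(code_id)
    for c in (codon_a, codon_b):
        if c not in gc["index"]:
            raise ValueError(f"not a sense codon: {c!r}")
    diff_pos = [i for i in range(3) if codon_a[i] != codon_b[i]]
    if not diff_pos:
        return 0.0, 0.0

    def walk(order: Sequence[int], allow_stops: bool):
        """Steps of one pathway, or None if it passes through a stop."""
        cur = codon_a
        steps = []
        for pos in order:
            nxt = cur[:pos] + codon_b[pos] + cur[pos + 1:]
            if nxt in gc["stops"] and nxt != codon_b and not allow_stops:
                return None
            syn = (
                nxt not in gc["stops"]
                and cur not in gc["stops"]
                and gc["translate"][cur] == gc["translate"][nxt]
            )
            steps.append(syn)
            cur = nxt
        return steps

    paths = [
        steps
        for order in itertools.permutations(diff_pos)
        if (steps := walk(order, allow_stops=False)) is not None
    ]
    if not paths:
        logger.warning(
            "all pathways %s->%s pass through stop codons; including them",
            codon_a,
            codon_b,
        )
        paths = [walk(order, allow_stops=True) for order in itertools.permutations(diff_pos)]
    sd = sum(sum(p) for p in paths) / len(paths)
    return sd, len(diff_pos) - sd


@lru_cache(maxsize=None)
def ng_tables(code_id: int = 1) -> dict:
    """Precomputed NG86 lookup tables over the 61 sense codons.

    S, N: per-codon site counts. SD, ND: pathway-averaged difference counts
    for every ordered codon pair. NDIFF: nucleotide Hamming distance.
    """
    gc = genetic_code(code_id)
    sense = gc["sense"]
    n = len(sense)
    S = np.array([count_sites(c, code_id)[0] for c in sense])
    SD = np.zeros((n, n))
    ND = np.zeros((n, n))
    NDIFF = np.zeros((n, n), dtype=int)
    for i, a in enumerate(sense):
        for j, b in enumerate(sense):
            if i == j:
                continue
            sd, nd = count_differences(a, b, code_id)
            SD[i, j] = sd
            ND[i, j] = nd
            NDIFF[i, j] = sum(x != y for x, y in zip(a, b))
    return {"S": S, "N": 3.0 - S, "SD": SD, "ND": ND, "NDIFF": NDIFF}


# ---------------------------------------------------------------------------
# Codon alignments

@dataclass
class CodonAlignment:
    """Gap-aware aligned coding sequences read in codon frame.

    Rows containing internal stop codons are dropped at construction (with a
    log entry); codons containing gaps or ambiguity codes are masked per
    site. A trailing stop codon is masked rather than dropping the row.
    """

    ids: list[str]
    rows: list[str]
    code_id: int = 1
    _encoded: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ValueError("ids and rows length mismatch")
        lengths = {len(r) for r in self.rows}
        if len(lengths) > 1:
            raise ValueError("aligned rows must all have the same length")
        if self.rows and len(self.rows[0]) % 3 != 0:
            raise ValueError("alignment length must be divisible by 3")
        gc = genetic_code(self.code_id)
        keep_ids, keep_rows = [], []
        n_cod = len(self.rows[0]) // 3 if self.rows else 0
        for rid, row in zip(self.ids, self.rows):
            row = row.upper()
            internal_stop = False
            for k in range(n_cod - 1):
                if row[3 * k: 3 * k + 3] in gc["stops"]:
                    internal_stop = True
                    break
            if internal_stop:
                logger.warning("dropping row %s: internal stop codon", rid)
                continue
            keep_ids.append(rid)
            keep_rows.append(row)
        self.ids = keep_ids
        self.rows = keep_rows

    @classmethod
    def from_records(
        cls, records: Iterable[SequenceRecord], code_id: int = 1
    ) -> "CodonAlignment":
        recs = list(records)
        return cls([r.id for r in recs], [r.seq for r in recs], code_id)

    @property
    def n_seqs(self) -> int:
        return len(self.rows)

    @property
    def n_codons(self) -> int:
        return len(self.rows[0]) // 3 if self.rows else 0

    def encoded(self) -> np.ndarray:
        """(n_seqs, n_codons) sense-codon indices; -1 = masked codon."""
        if self._encoded is not None:
            return self._encoded
        gc = genetic_code(self.code_id)
        idx = gc["index"]
        out = np.full((self.n_seqs, self.n_codons), -1, dtype=np.int16)
        for i, row in enumerate(self.rows):
            for k in range(self.n_codons):
                codon = row[3 * k: 3 * k + 3]
                out[i, k] = idx.get(codon, -1)
        self._encoded = out
        return out

    def coverage_filter(self, site_coverage_min: float = 0.80) -> np.ndarray:
        """Boolean mask of codon columns with >= the required ungapped share."""
        enc = self.encoded()
        cov = (enc >= 0).mean(axis=0)
        return cov >= site_coverage_min


# ---------------------------------------------------------------------------
# Pairwise distances

def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); NaN when saturated (p >= 0.75)."""
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class PairDistances:
    dN: float
    dS: float
    pN: float
    pS: float
    N: float
    S: float
    saturated: bool


def _pair_columns(enc_a: np.ndarray, enc_b: np.ndarray, tbl: dict):
    """Per-column NG86 contributions for one sequence pair.

    Returns (sd, nd, s_sites, n_sites) arrays over codon columns; masked
    columns (either member unreadable) contribute zeros everywhere.
    """
    valid = (enc_a >= 0) & (enc_b >= 0)
    a = np.where(valid, enc_a, 0)
    b = np.where(valid, enc_b, 0)
    sd = np.where(valid, tbl["SD"][a, b], 0.0)
    nd = np.where(valid, tbl["ND"][a, b], 0.0)
    s_sites = np.where(valid, 0.5 * (tbl["S"][a] + tbl["S"][b]), 0.0)
    n_sites = np.where(valid, 0.5 * (tbl["N"][a] + tbl["N"][b]), 0.0)
    return sd, nd, s_sites, n_sites


def ng86_pair(
    row_a: str | np.ndarray,
    row_b: str | np.ndarray,
    site_coverage_min: float = 0.80,
    code_id: int = 1,
) -> PairDistances:
    """Nei-Gojobori dN and dS for one pair of codon-framed rows.

    Codon columns below the coverage threshold (over the two rows this means
    either row gapped/ambiguous) are eliminated first. Proportions are
    Jukes-Cantor corrected; pS or pN >= 0.75 flags the pair saturated and
    the corresponding distance is NaN.
    """
    if isinstance(row_a, str):
        aln = CodonAlignment(["a", "b"], [row_a, row_b], code_id)
        if aln.n_seqs != 2:
            raise ValueError("row with internal stop codon")
        enc = aln.encoded()
        enc_a, enc_b = enc[0], enc[1]
    else:
        enc_a, enc_b = row_a, row_b
    tbl = ng_tables(code_id)
    keep = ((enc_a >= 0).astype(float) + (enc_b >= 0).astype(float)) / 2.0 >= site_coverage_min
    sd, nd, s_sites, n_sites = _pair_columns(enc_a[keep], enc_b[keep], tbl)
    S, N = s_sites.sum(), n_sites.sum()
    if S <= 0 or N <= 0:
        raise ValueError("no comparable codon columns")
    pS, pN = sd.sum() / S, nd.sum() / N
    dS, dN = jukes_cantor(pS), jukes_cantor(pN)
    saturated = math.isnan(dS) or math.isnan(dN)
    return PairDistances(dN=dN, dS=dS, pN=pN, pS=pS, N=N, S=S, saturated=saturated)


def nucleotide_diversity(aln: CodonAlignment) -> float:
    """Mean pairwise nucleotide p-distance (pi), pairwise deletion of gaps."""
    if aln.n_seqs < 2:
        raise ValueError("need >= 2 rows")
    rows = [np.frombuffer(r.encode(), dtype="S1") for r in aln.rows]
    valid = [np.isin(r, np.frombuffer(b"ACGT", dtype="S1")) for r in rows]
    total, n_pairs = 0.0, 0
    for i in range(len(rows)):
        for j in range(i + 1, len(rows)):
            both = valid[i] & valid[j]
            n_comp = int(both.sum())
            if n_comp == 0:
                continue
            n_diff = int((rows[i][both] != rows[j][both]).sum())
            total += n_diff / n_comp
            n_pairs += 1
    if n_pairs == 0:
        raise ValueError("no comparable sites in any pair")
    return total / n_pairs


# ---------------------------------------------------------------------------
# Subfamily-level neutrality test

@dataclass(frozen=True)
class SelectionResult:
    """One subfamily row of the selection analysis.

    delta = dN - dS, omega = dN/dS, both computed from the subfamily-mean
    dN and dS (not means of per-pair ratios). The p-value is the smaller of
    the two one-tailed bootstrap-Z tails, doubled and capped at 1.
    """

    n_seqs: int
    pi: float
    dN: float
    dS: float
    delta: float
    omega: float  # NaN when dS == 0
    omega_defined: bool
    var_delta: float
    z: float
    p_value: float
    verdict: str  # positive | negative | neutral
    n_pairs: int
    n_pairs_saturated: int


def subfamily_selection(
    aln: CodonAlignment,
    n_boot: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
    site_coverage_min: float = 0.80,
) -> SelectionResult:
    """Average NG86 selection statistics over all sequence pairs.

    Codon columns with less than the required site coverage across the whole
    alignment are eliminated first. The variance of delta = dN - dS comes
    from codon-column bootstrap resampling (n_boot replicates); the verdict
    at level alpha is positive (dN > dS), negative (dN < dS) or neutral.
    """
    if aln.n_seqs < 2:
        raise ValueError("need >= 2 sequences")
    enc = aln.encoded()[:, aln.coverage_filter(site_coverage_min)]
    n, L = enc.shape
    if L == 0:
        raise ValueError("no codon columns pass the coverage filter")
    tbl = ng_tables(aln.code_id)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    per_pair = [_pair_columns(enc[i], enc[j], tbl) for i, j in pairs]

    def distances(col_weights: np.ndarray | None):
        """Mean dN and dS over non-saturated pairs for one column weighting."""
        dNs, dSs = [], []
        n_sat = 0
        for sd, nd, s_sites, n_sites in per_pair:
            if col_weights is None:
                SD, ND, S, N = sd.sum(), nd.sum(), s_sites.sum(), n_sites.sum()
            else:
                SD, ND = sd @ col_weights, nd @ col_weights
                S, N = s_sites @ col_weights, n_sites @ col_weights
            if S <= 0 or N <= 0:
                n_sat += 1
                continue
            dS, dN = jukes_cantor(SD / S), jukes_cantor(ND / N)
            if math.isnan(dS) or math.isnan(dN):
                n_sat += 1
                continue
            dNs.append(dN)
            dSs.append(dS)
        if not dNs:
            return float("nan"), float("nan"), n_sat
        return float(np.mean(dNs)), float(np.mean(dSs)), n_sat

    dN, dS, n_sat = distances(None)
    if math.isnan(dN):
        raise ValueError("all sequence pairs are saturated")
    delta = dN - dS
    omega_defined = dS > 0
    omega = dN / dS if omega_defined else float("nan")

    rng = np.random.default_rng(seed)
    counts = rng.multinomial(L, np.full(L, 1.0 / L), size=n_boot).astype(float)
    deltas = np.empty(n_boot)
    for b in range(n_boot):
        bdN, bdS, _ = distances(counts[b])
        deltas[b] = bdN - bdS
    deltas = deltas[np.isfinite(deltas)]
    var_delta = float(np.var(deltas, ddof=1)) if len(deltas) > 1 else 0.0

    if var_delta > 0:
        z = delta / math.sqrt(var_delta)
        tail = stats.norm.sf(abs(z))
        p_value = min(1.0, 2.0 * float(tail))
    else:
        z, p_value = 0.0, 1.0
    if p_value < alpha:
        verdict = "positive" if delta > 0 else "negative"
    else:
        verdict = "neutral"

    # pi on the same coverage-filtered columns, nucleotide level
    gc = genetic_code(aln.code_id)
    keep = aln.coverage_filter(site_coverage_min)
    filt_rows = [
        "".join(
            row[3 * k: 3 * k + 3] for k in range(aln.n_codons) if keep[k]
        )
        for row in aln.rows
    ]
    pi = nucleotide_diversity(CodonAlignment(list(aln.ids), filt_rows, aln.code_id))

    return SelectionResult(
        n_seqs=n,
        pi=pi,
        dN=dN,
        dS=dS,
        delta=delta,
        omega=omega,
        omega_defined=omega_defined,
        var_delta=var_delta,
        z=z,
        p_value=p_value,
        verdict=verdict,
        n_pairs=len(pairs),
        n_pairs_saturated=n_sat,
    )


# ---------------------------------------------------------------------------
# SLAC-style per-codon scan

@dataclass(frozen=True)
class SiteSelectionResult:
    site: int              # 0-based codon column
    exp_syn_fraction: float
    obs_syn: float         # pathway-averaged, fractional
    obs_nonsyn: float
    n_subs: int            # integer nucleotide substitutions on the tree
    p_value: float
    klass: str             # positive | negative | none


def slac_scan(aln: CodonAlignment, tree, alpha: float = 0.05) -> list[SiteSelectionResult]:
    """SLAC-style per-codon selection scan.

    Ancestral codon states are reconstructed per column by Fitch parsimony
    (ties broken toward the lexically first codon); substitutions along each
    branch are split into synonymous/nonsynonymous via pathway-averaged
    counting; the observed synonymous count is compared to its expectation
    (mean synonymous site fraction over all reconstructed states) with a
    two-tailed binomial test. This is a counting re-implementation in the
    SLAC spirit, not the Datamonkey pipeline.
    """
    import dendropy

    if not isinstance(tree, dendropy.Tree):
        raise TypeError("tree must be a dendropy.Tree")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    missing = tips - set(aln.ids)
    if missing:
        raise ValueError(f"tree tips missing from alignment: {sorted(missing)}")

    tbl = ng_tables(aln.code_id)
    enc = aln.encoded()
    row_of = {rid: i for i, rid in enumerate(aln.ids)}
    post = list(tree.postorder_node_iter())
    pre = list(tree.preorder_node_iter())

    results = []
    for col in range(aln.n_codons):
        state_sets: dict = {}
        for node in post:
            if node.is_leaf():
                s = enc[row_of[node.taxon.label], col]
                state_sets[node] = {int(s)} if s >= 0 else None
            else:
                child_sets = [state_sets[c] for c in node.child_nodes() if state_sets[c]]
                if not child_sets:
                    state_sets[node] = None
                    continue
                inter = set.intersection(*child_sets)
                state_sets[node] = inter if inter else set.union(*child_sets)
        assigned: dict = {}
        for node in pre:
            ss = state_sets[node]
            if ss is None:
                parent = node.parent_node
                assigned[node] = assigned.get(parent)
                continue
            parent = node.parent_node
            if parent is not None and assigned.get(parent) in ss:
                assigned[node] = assigned[parent]
            else:
                assigned[node] = min(ss)  # lexical tie-break (codons sorted)
        obs_syn = obs_nonsyn = 0.0
        n_subs = 0
        states_seen = []
        for node in pre:
            st = assigned.get(node)
            if st is not None:
                states_seen.append(st)
            parent = node.parent_node
            if parent is None:
                continue
            a, b = assigned.get(parent), st
            if a is None or b is None or a == b:
                continue
            obs_syn += tbl["SD"][a, b]
            obs_nonsyn += tbl["ND"][a, b]
            n_subs += int(tbl["NDIFF"][a, b])
        if not states_seen or n_subs == 0:
            results.append(
                SiteSelectionResult(col, float("nan"), 0.0, 0.0, 0, 1.0, "none")
            )
            continue
        exp_syn = float(np.mean([tbl["S"][s] for s in states_seen])) / 3.0
        k = int(np.clip(round(obs_syn), 0, n_subs))
        p = stats.binomtest(k, n_subs, exp_syn, alternative="two-sided").pvalue
        if p < alpha:
            klass = "positive" if obs_syn / n_subs < exp_syn else "negative"
        else:
            klass = "none"
        results.append(
            SiteSelectionResult(col, exp_syn, obs_syn, obs_nonsyn, n_subs, float(p), klass)
        )
    return results
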