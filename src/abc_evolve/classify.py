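"""Domain-architecture classification of ABC proteins into plant subfamilies.

The topology of nucleotide-binding domains (NBD) and transmembrane domains
(TMD) along the polypeptide determines orientation and size class:

* forward  — TMD before NBD (subfamilies A-D),
* reverse  — NBD before TMD (subfamily G: half-size WBC, full-size PDR),
* soluble  — no TMD at all (subfamilies E and F, and the prokaryotic-type I).

Topology alone cannot separate A from B from C from D (all forward); a
diagnostic-label table (domain id -> subfamily), standing in for
family-level profile databases such as Pfam/PANTHER models, carries that
discrimination and is shipped as an editable mapping.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .io_formats import DomainHit

logger = logging.getLogger("abc_evolve")

SUBFAMILIES = ("A", "B", "C", "D", "E", "F", "G_WBC", "G_PDR", "I", "unclassified")

#: Default diagnostic-label -> subfamily mapping. Labels arrive as
#: DIAG:<label> hits in the domain table.
DEFAULT_DIAG_TABLE: dict[str, str] = {
    "ABCA": "A",
    "ABCB": "B",
    "ABCC": "C",
    "ABCD": "D",
    "ABCE": "E",
    "ABCF": "F",
    "WBC": "G_WBC",
    "PDR": "G_PDR",
    "ABCI": "I",
}

# ABC signature (C motif / LSGGQ motif) between the Walker boxes:
# [LIVMFY] S [SG] G x(3) [RKA] [LIVMYA] x [LIVFM] [AG]
SIGNATURE_RE = re.compile(
    r"(?=([LIVMFY]S[SG]G.{3}[RKA][LIVMYA].[LIVFM][AG]))"
)


@dataclass(frozen=True)
class Architecture:
    """Ordered NBD/TMD topology of one protein plus diagnostic labels."""

    protein_id: str
    topology: tuple[str, ...]          # ("TMD", "NBD", ...) by start coord
    orientation: str                   # forward | reverse | soluble | other
    size_class: str                    # full | half | soluble | other
    diag_labels: frozenset = frozenset()

    @property
    def n_nbd(self) -> int:
        return sum(1 for t in self.topology if t == "NBD")

    @property
    def n_tmd(self) -> int:
        return sum(1 for t in self.topology if t == "TMD")

    @property
    def topology_string(self) -> str:
        return "-".join(self.topology)


@dataclass(frozen=True)
class SubfamilyAssignment:
    protein_id: str
    subfamily: str
    evidence: str

    def __post_init__(self) -> None:
        if self.subfamily not in SUBFAMILIES:
            raise ValueError(f"unknown subfamily {self.subfamily!r}")
        if self.subfamily != "unclassified" and not self.evidence:
            raise ValueError("non-unclassified assignment requires evidence")


class NotAnABCProtein(ValueError):
    """Raised when a protein has no ATP-binding cassette at all."""


def build_architecture(
    hits: Sequence[DomainHit], min_tmd_len: int = 60
) -> Architecture:
    """Derive the domain topology of one protein from its located domains.

    Hits are ordered by start coordinate; TMD hits shorter than
    ``min_tmd_len`` residues are ignored for the topology (logged) to avoid
    spurious orientation calls from stray fragments; DIAG hits contribute
    labels only. At least one NBD hit is required.
    """
    if not hits:
        raise NotAnABCProtein("no domain hits")
    pids = {h.protein_id for h in hits}
    if len(pids) != 1:
        raise ValueError(f"hits span multiple proteins: {sorted(pids)}")
    protein_id = hits[0].protein_id

    core: list[DomainHit] = []
    diag: set[str] = set()
    for h in sorted(hits, key=lambda h: h.start):
        if h.category.startswith("DIAG:"):
            diag.add(h.category[5:])
        elif h.category == "TMD" and (h.end - h.start + 1) < min_tmd_len:
            logger.info(
                "%s: ignoring short TMD hit %s (%d aa) for topology",
                protein_id, h.domain_id, h.end - h.start + 1,
            )
        else:
            core.append(h)
    topology = tuple(h.category for h in core)
    if "NBD" not in topology:
        raise NotAnABCProtein(
            f"{protein_id}: no ATP-binding cassette (no NBD hit)"
        )

    n_nbd = topology.count("NBD")
    n_tmd = topology.count("TMD")
    if n_tmd == 0:
        orientation = "soluble"
    elif topology[0] == "TMD" and n_nbd >= 1:
        orientation = "forward"
    elif topology[0] == "NBD" and n_tmd >= 1:
        orientation = "reverse"
    else:  # unreachable with two categories, kept for safety
        orientation = "other"

    if n_tmd == 0:
        size_class = "soluble"
    elif n_nbd >= 2 and n_tmd >= 2:
        size_class = "full"
    elif n_nbd == 1 and n_tmd >= 1:
        size_class = "half"
    else:
        size_class = "other"

    return Architecture(
        protein_id=protein_id,
        topology=topology,
        orientation=orientation,
        size_class=size_class,
        diag_labels=frozenset(diag),
    )


def _diag_compatible(subfamily: str, arch: Architecture) -> bool:
    """Is a diagnostic label's subfamily consistent with the topology?"""
    if subfamily in ("A", "B", "C", "D"):
        return arch.orientation == "forward"
    if subfamily in ("E", "F"):
        return arch.orientation == "soluble"
    if subfamily == "G_PDR":
        return arch.orientation == "reverse" and arch.size_class == "full"
    if subfamily == "G_WBC":
        return arch.orientation == "reverse" and arch.size_class == "half"
    return True  # I: prokaryotic-type, any arrangement


def assign_subfamily(
    arch: Architecture, diag_table: Mapping[str, str] | None = None
) -> SubfamilyAssignment:
    """Assign one subfamily label from a domain architecture.

    Decision order: (1) a single topology-compatible diagnostic label wins;
    contradictory labels yield unclassified with the conflict named;
    (2) topology rules — reverse half -> G_WBC, reverse full -> G_PDR,
    soluble single-NBD -> I (prokaryotic type); (3) everything else
    (forward without diagnostic, soluble multi-NBD without diagnostic)
    stays unclassified with its topology string as evidence.
    """
    table = DEFAULT_DIAG_TABLE if diag_table is None else dict(diag_table)
    evidence: list[str] = [f"topology={arch.topology_string or '(none)'}",
                           f"orientation={arch.orientation}",
                           f"size={arch.size_class}"]

    mapped = sorted(
        {table[lab] for lab in arch.diag_labels if lab in table}
    )
    unknown = sorted(lab for lab in arch.diag_labels if lab not in table)
    if unknown:
        evidence.append(f"unmapped_diag={','.join(unknown)}")
    if len(mapped) > 1:
        evidence.append(f"conflicting_diag={','.join(mapped)}")
        return SubfamilyAssignment(arch.protein_id, "unclassified", "; ".join(evidence))
    if len(mapped) == 1:
        sub = mapped[0]
        if _diag_compatible(sub, arch):
            evidence.append(f"diag->{sub}")
            return SubfamilyAssignment(arch.protein_id, sub, "; ".join(evidence))
        evidence.append(f"diag {sub} incompatible with topology")

    if arch.orientation == "reverse":
        sub = "G_PDR" if arch.size_class == "full" else "G_WBC"
        evidence.append(f"reverse {arch.size_class}->{sub}")
        return SubfamilyAssignment(arch.protein_id, sub, "; ".join(evidence))
    if arch.orientation == "soluble" and arch.n_nbd == 1:
        evidence.append("detached single NBD (prokaryotic type)->I")
        return SubfamilyAssignment(arch.protein_id, "I", "; ".join(evidence))
    # forward full/half without diagnostic: A-D not separable by topology
    return SubfamilyAssignment(arch.protein_id, "unclassified", "; ".join(evidence))


def classify_proteins(
    hits: Iterable[DomainHit],
    diag_table: Mapping[str, str] | None = None,
    min_tmd_len: int = 60,
) -> list[SubfamilyAssignment]:
    """Group a domain table by protein and assign every protein one label.

    Proteins without any NBD hit are reported as unclassified with the
    rejection reason as evidence (they are not ABC candidates).
    """
    by_protein: dict[str, list[DomainHit]] = defaultdict(list)
    for h in hits:
        by_protein[h.protein_id].append(h)
    out = []
    for pid in sorted(by_protein):
        try:
            arch = build_architecture(by_protein[pid], min_tmd_len=min_tmd_len)
        except NotAnABCProtein as exc:
            out.append(SubfamilyAssignment(pid, "unclassified", str(exc)))
            continue
        out.append(assign_subfamily(arch, diag_table))
    return out


def scan_abc_signature(seq: str) -> list[tuple[int, str]]:
    """All matches of the 12-residue ABC signature motif.

    Pattern: [LIVMFY] S [SG] G x(3) [RKA] [LIVMYA] x [LIVFM] [AG].
    Returns (1-based start, matched 12-mer) pairs; overlaps are reported.
    The signature marks the ABC superfamily, not any subfamily, so it is
    supporting evidence only.
    """
    return [
        (m.start() + 1, m.group(1)) for m in SIGNATURE_RE.finditer(seq.upper())
    ]


def read_diag_table(path: str | Path) -> dict[str, str]:
    """Read an editable 2-column (diag label, subfamily) TSV."""
    table = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 2:
            raise ValueError(f"{path}:{lineno}: expected 2 columns")
        label, sub = cols
        if sub not in SUBFAMILIES:
            raise ValueError(f"{path}:{lineno}: unknown subfamily {sub!r}")
        table[label] = sub
    return table


def write_assignments_tsv(
    assignments: Iterable[SubfamilyAssignment], path: str | Path
) -> None:
    lines = ["protein_id\tsubfamily\tevidence"]
    for a in assignments:
        lines.append(f"{a.protein_id}\t{a.subfamily}\t{a.evidence}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_assignments_tsv(path: str | Path) -> list[SubfamilyAssignment]:
    lines = Path(path).read_text().splitlines()
    out = []
    for raw in lines[1:]:
        if not raw.strip():
            continue
        pid, sub, ev = raw.split("\t", 2)
        out.append(SubfamilyAssignment(pid, sub, ev))
    return out
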