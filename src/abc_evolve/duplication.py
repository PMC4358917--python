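"""Recent gene-duplication detection by four criteria.

A duplication event is called when (1) the genes form a clade with
bootstrap support strictly greater than 80, (2) every pair in the group has
alignable CDS identity of at least 70%, (3) the members are physically
co-localized (a tandem array, or matching multi-gene runs), and
(4) tightly linked genes collapse into a single event. Events are typed
tandem (one adjacent run) or block (>= 2 distant runs of >= 2 genes each,
on at most two chromosomes).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .classify import SubfamilyAssignment
from .io_formats import GeneLocus, RunConfig, SequenceRecord
from .phylo import extract_clades, pairwise_identity

logger = logging.getLogger("abc_evolve")


@dataclass(frozen=True)
class DuplicationEvent:
    members: frozenset
    support: int
    min_pairwise_identity: float
    dtype: str                      # "tandem" | "block"
    chroms: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) < 2:
            raise ValueError("an event needs >= 2 members")
        if self.dtype not in ("tandem", "block"):
            raise ValueError(f"bad duplication type {self.dtype!r}")


def _linked(a: GeneLocus, b: GeneLocus, order: Mapping[str, int], cfg: RunConfig) -> bool:
    """Tight linkage: same chromosome and within the distance OR the
    intervening-gene budget (a, b consecutive by start)."""
    if a.chrom != b.chrom:
        return False
    gap_kb = (b.start - a.end) / 1000.0
    intervening = abs(order[b.gene_id] - order[a.gene_id]) - 1
    return gap_kb <= cfg.tandem_max_kb or intervening <= cfg.tandem_max_intervening


def _runs(
    members: Sequence[str], loci: Mapping[str, GeneLocus],
    order: Mapping[str, int], cfg: RunConfig,
) -> list[list[str]]:
    """Partition members into maximal tightly-linked runs (per chromosome,
    consecutive by start coordinate)."""
    by_chrom: dict[str, list[str]] = {}
    for gid in members:
        by_chrom.setdefault(loci[gid].chrom, []).append(gid)
    runs: list[list[str]] = []
    for chrom_members in by_chrom.values():
        chrom_members.sort(key=lambda g: loci[g].start)
        run = [chrom_members[0]]
        for prev, cur in zip(chrom_members, chrom_members[1:]):
            if _linked(loci[prev], loci[cur], order, cfg):
                run.append(cur)
            else:
                runs.append(run)
                run = [cur]
        runs.append(run)
    return runs


def classify_event(
    members: Sequence[str],
    loci: Mapping[str, GeneLocus],
    cfg: RunConfig | None = None,
    all_loci: Iterable[GeneLocus] | None = None,
) -> str:
    """Co-localization type of a candidate group: tandem, block or rejected.

    tandem — every member in one tightly linked run on one chromosome;
    block — members form >= 2 runs of >= 2 genes each, on at most two
    chromosomes, beyond tandem range; rejected — no such run structure
    (e.g. two genes on different chromosomes).
    """
    cfg = cfg or RunConfig()
    universe = list(all_loci) if all_loci is not None else list(loci.values())
    by_chrom: dict[str, list[GeneLocus]] = {}
    for loc in universe:
        by_chrom.setdefault(loc.chrom, []).append(loc)
    order: dict[str, int] = {}
    for locs in by_chrom.values():
        for rank, loc in enumerate(sorted(locs, key=lambda l: l.start)):
            order[loc.gene_id] = rank

    runs = _runs(members, loci, order, cfg)
    if len(runs) == 1:
        return "tandem"
    chroms = {loci[run[0]].chrom for run in runs}
    if len(runs) >= 2 and all(len(r) >= 2 for r in runs) and len(chroms) <= 2:
        return "block"
    return "rejected"


def detect_duplications(
    cds: Iterable[SequenceRecord],
    loci: Iterable[GeneLocus],
    tree,
    cfg: RunConfig | None = None,
) -> list[DuplicationEvent]:
    """Call recent duplication events from a supported tree, CDS and loci.

    Clades with support > cfg.dup_bootstrap_min (strict) seed candidate
    groups; within each clade the maximal subsets whose all-pairs CDS
    identity >= cfg.dup_identity_min (inclusive) are kept; each subset must
    pass co-localization; tightly linked genes yield one event and no gene
    appears in two events (smaller clades take precedence).
    """
    cfg = cfg or RunConfig()
    seqs = {r.id: r.seq for r in cds}
    loci_list = list(loci)
    loci_map = {l.gene_id: l for l in loci_list}

    clades = extract_clades(tree, min_support=cfg.dup_bootstrap_min + 1, min_size=2)
    # strict > threshold: min_support is inclusive, so shift by one
    clades = [c for c in clades if c.support > cfg.dup_bootstrap_min]
    clades.sort(key=lambda c: len(c.members))  # smaller clades first

    identity_cache: dict[frozenset, float] = {}

    def ident(a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in identity_cache:
            identity_cache[key] = pairwise_identity(seqs[a], seqs[b])
        return identity_cache[key]

    events: list[DuplicationEvent] = []
    used: set[str] = set()
    for clade in clades:
        members = []
        for gid in clade.members:
            if gid in used:
                continue
            if gid not in loci_map:
                logger.warning("tree tip %s has no locus; excluded", gid)
                continue
            if gid not in seqs:
                logger.warning("tree tip %s has no CDS; excluded", gid)
                continue
            members.append(gid)
        if len(members) < 2:
            continue
        graph = nx.Graph()
        graph.add_nodes_from(members)
        for a, b in combinations(members, 2):
            if ident(a, b) >= cfg.dup_identity_min:
                graph.add_edge(a, b)
        for clique in nx.find_cliques(graph):
            if len(clique) < 2:
                continue
            clique = sorted(clique)
            dtype = classify_event(clique, loci_map, cfg, all_loci=loci_list)
            if dtype == "rejected":
                continue
            if any(g in used for g in clique):
                continue
            min_ident = min(ident(a, b) for a, b in combinations(clique, 2))
            chroms = tuple(sorted({loci_map[g].chrom for g in clique}))
            events.append(
                DuplicationEvent(
                    members=frozenset(clique),
                    support=clade.support,
                    min_pairwise_identity=min_ident,
                    dtype=dtype,
                    chroms=chroms,
                )
            )
            used.update(clique)
    events.sort(key=lambda e: sorted(e.members)[0])
    return events


def summarize(
    events: Sequence[DuplicationEvent],
    assignments: Sequence[SubfamilyAssignment],
    total_genes: int,
    species: str = "synthetic",
) -> pd.DataFrame:
    """Per-subfamily counts of tandem/block events and duplicate genes.

    The percentage column is duplicate genes over the total annotated
    genes, rounded to integer percent. Event members without a subfamily
    assignment are counted under "unclassified" (logged).
    """
    sub_of = {a.protein_id: a.subfamily for a in assignments}
    rows: dict[str, dict] = {}

    def row(sub: str) -> dict:
        return rows.setdefault(
            sub,
            {"species": species, "subfamily": sub, "tandem_events": 0,
             "block_events": 0, "duplicate_genes": 0},
        )

    for ev in events:
        subs = set()
        for gid in ev.members:
            if gid not in sub_of:
                logger.warning("event member %s has no assignment", gid)
            sub = sub_of.get(gid, "unclassified")
            subs.add(sub)
            row(sub)["duplicate_genes"] += 1
        for sub in subs:
            row(sub)["tandem_events" if ev.dtype == "tandem" else "block_events"] += 1

    df = pd.DataFrame(rows.values()) if rows else pd.DataFrame(
        columns=["species", "subfamily", "tandem_events", "block_events", "duplicate_genes"]
    )
    total_dup = int(df["duplicate_genes"].sum()) if len(df) else 0
    total_row = {
        "species": species, "subfamily": "Total",
        "tandem_events": int(df["tandem_events"].sum()) if len(df) else 0,
        "block_events": int(df["block_events"].sum()) if len(df) else 0,
        "duplicate_genes": total_dup,
    }
    df = pd.concat([df, pd.DataFrame([total_row])], ignore_index=True)
    dup = df["duplicate_genes"].astype(float)
    df["pct_of_annotated"] = (
        (dup / total_genes * 100).round().astype(int) if total_genes > 0 else 0
    )
    return df


def write_events_tsv(events: Sequence[DuplicationEvent], path: str | Path) -> None:
    lines = ["members\tsupport\tmin_identity\ttype\tchromosomes"]
    for ev in events:
        lines.append(
            "\t".join(
                [
                    ",".join(sorted(ev.members)),
                    str(ev.support),
                    f"{ev.min_pairwise_identity:.4f}",
                    ev.dtype,
                    ",".join(ev.chroms),
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")
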