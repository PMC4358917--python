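"""Readers and writers for the external formats the pipeline touches.

Formats: FASTA (protein/CDS), GFF3 gene features, 5-column domain TSV,
2-column chromosome-length TSV, gene x tissue RPKM TSV, flat key-value run
configuration. All genomic coordinates are 1-based inclusive (GFF3 native)
throughout the package; no module converts.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

logger = logging.getLogger("abc_evolve")

# IUPAC alphabets, ambiguity codes included.
PROTEIN_ALPHABET = set("ACDEFGHIKLMNPQRSTVWYBXZJUO*-")
NUCLEOTIDE_ALPHABET = set("ACGTURYSWKMBDHVN-")
PROTEIN_AMBIGUOUS = set("BXZJUO")
NUCLEOTIDE_AMBIGUOUS = set("URYSWKMBDHVN")

DOMAIN_CATEGORIES = ("NBD", "TMD")  # plus DIAG:<label>


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA entry: a protein or coding sequence with a unique id."""

    id: str
    seq: str
    moltype: str  # "protein" | "cds"
    species: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GeneLocus:
    """A gene's chromosomal placement, 1-based inclusive coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 1:
            raise FormatError(f"{self.gene_id}: start {self.start} < 1")
        if self.end < self.start:
            raise FormatError(
                f"{self.gene_id}: start {self.start} > end {self.end}"
            )
        if self.strand not in ("+", "-", "."):
            raise FormatError(f"{self.gene_id}: bad strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class DomainHit:
    """A located domain on a protein (1-based inclusive residue coords)."""

    protein_id: str
    domain_id: str
    start: int
    end: int
    category: str  # NBD | TMD | DIAG:<label>

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise FormatError(
                f"{self.protein_id}/{self.domain_id}: start > end"
            )
        if self.category not in DOMAIN_CATEGORIES and not self.category.startswith(
            "DIAG:"
        ):
            raise FormatError(
                f"{self.protein_id}: unknown domain category "
                f"{self.category!r} (expected NBD, TMD or DIAG:<label>)"
            )


@dataclass
class RunConfig:
    """All thresholds and knobs of the pipeline, with the published defaults.

    Clade rule: bootstrap >= 70 and >= 4 members. Duplication criteria:
    clade bootstrap strictly > 80, alignable CDS identity >= 0.70,
    co-localization, one event per tightly linked run. Expression call:
    TPM strictly > 2. Selection: codon columns with < 80% ungapped rows
    are eliminated.
    """

    bootstrap_clade_min: int = 70
    clade_min_size: int = 4
    dup_bootstrap_min: int = 80      # strict: support must exceed this
    dup_identity_min: float = 0.70   # inclusive
    tpm_expressed_min: float = 2.0   # strict: TPM must exceed this
    site_coverage_min: float = 0.80
    tandem_max_kb: float = 100.0
    tandem_max_intervening: int = 5
    genetic_code: int = 1
    n_bootstrap_reps: int = 100
    n_selection_boot: int = 1000
    n_mc: int = 10000
    min_tmd_len: int = 60            # shorter TMD hits ignored for orientation
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.bootstrap_clade_min <= 100:
            raise ValueError("bootstrap_clade_min must be in [0, 100]")
        if not 0 <= self.dup_bootstrap_min <= 100:
            raise ValueError("dup_bootstrap_min must be in [0, 100]")
        if not 0.0 <= self.dup_identity_min <= 1.0:
            raise ValueError("dup_identity_min must be in [0, 1]")
        if not 0.0 < self.site_coverage_min <= 1.0:
            raise ValueError("site_coverage_min must be in (0, 1]")
        if self.clade_min_size < 2:
            raise ValueError("clade_min_size must be >= 2")
        if self.tpm_expressed_min < 0:
            raise ValueError("tpm_expressed_min must be >= 0")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        """Read a flat ``key = value`` text file; unknown keys are errors."""
        fields = {f.name: f.type for f in dataclasses.fields(cls)}
        kwargs = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            if "=" not in line:
                raise FormatError(f"{path}:{lineno}: expected key = value")
            key, _, value = line.partition("=")
            key, value = key.strip(), value.strip()
            if key not in fields:
                raise FormatError(f"{path}:{lineno}: unknown key {key!r}")
            typ = fields[key]
            caster = float if "float" in str(typ) else int
            kwargs[key] = caster(value)
        return cls(**kwargs)

    def to_file(self, path: str | Path) -> None:
        lines = [
            f"{f.name} = {getattr(self, f.name)}"
            for f in dataclasses.fields(self)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# FASTA

def _validate_residues(rec_id: str, seq: str, moltype: str) -> None:
    alphabet = PROTEIN_ALPHABET if moltype == "protein" else NUCLEOTIDE_ALPHABET
    ambiguous = PROTEIN_AMBIGUOUS if moltype == "protein" else NUCLEOTIDE_AMBIGUOUS
    for pos, ch in enumerate(seq, 1):
        if ch not in alphabet:
            raise FormatError(
                f"record {rec_id!r}: non-{moltype} character {ch!r} "
                f"at position {pos}"
            )
        if ch in ambiguous:
            logger.debug("record %s: ambiguity code %s at %d", rec_id, ch, pos)


def read_fasta(path: str | Path, moltype: str) -> list[SequenceRecord]:
    """Read a FASTA file into SequenceRecords.

    The header token before the first whitespace becomes the id; residues
    are upper-cased; duplicate ids, empty files and non-alphabet characters
    are hard errors.
    """
    if moltype not in ("protein", "cds"):
        raise ValueError(f"moltype must be 'protein' or 'cds', got {moltype!r}")
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        rec_id = bio_rec.id
        if rec_id in seen:
            raise FormatError(f"duplicate FASTA id {rec_id!r} in {path}")
        seen.add(rec_id)
        seq = str(bio_rec.seq).upper()
        if moltype == "cds" and len(seq) == 0:
            raise FormatError(f"record {rec_id!r}: empty CDS")
        _validate_residues(rec_id, seq, moltype)
        records.append(SequenceRecord(id=rec_id, seq=seq, moltype=moltype))
    if not records:
        raise FormatError(f"empty or non-FASTA file: {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    bio = [
        _BioSeqRecord(Seq(r.seq), id=r.id, description="") for r in records
    ]
    SeqIO.write(bio, str(path), "fasta")


# ---------------------------------------------------------------------------
# GFF3 (gene features only)

def read_gff3(path: str | Path) -> list[GeneLocus]:
    """Read gene-level features from a GFF3 file.

    Only rows with feature type ``gene`` are kept (mRNA, exon, CDS ... are
    ignored); the ID attribute is mandatory and must be unique.
    """
    loci: list[GeneLocus] = []
    seen: set[str] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 9:
            raise FormatError(f"{path}:{lineno}: expected 9 tab-separated columns")
        chrom, _source, ftype, start, end, _score, strand, _phase, attrs = cols
        if ftype != "gene":
            continue
        attr_map = dict(
            kv.split("=", 1) for kv in attrs.split(";") if "=" in kv
        )
        if "ID" not in attr_map:
            raise FormatError(f"{path}:{lineno}: gene feature missing ID attribute")
        gene_id = attr_map["ID"]
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene ID {gene_id!r}")
        seen.add(gene_id)
        try:
            locus = GeneLocus(gene_id, chrom, int(start), int(end), strand)
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
        loci.append(locus)
    return loci


def write_gff3(loci: Iterable[GeneLocus], path: str | Path) -> None:
    lines = ["##gff-version 3"]
    for loc in loci:
        lines.append(
            "\t".join(
                [
                    loc.chrom,
                    "abc_evolve",
                    "gene",
                    str(loc.start),
                    str(loc.end),
                    ".",
                    loc.strand,
                    ".",
                    f"ID={loc.gene_id}",
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Domain TSV (normalized 5-column: protein_id, domain_id, start, end, category)

def read_domain_tsv(path: str | Path) -> list[DomainHit]:
    """Read a normalized 5-column domain table, sorted by (protein, start).

    Exact duplicate rows are collapsed to a single hit (logged); unknown
    category tokens are hard errors.
    """
    hits: list[DomainHit] = []
    seen: set[tuple] = set()
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.rstrip("\n").split("\t")
        if len(cols) != 5:
            raise FormatError(f"{path}:{lineno}: expected 5 tab-separated columns")
        protein_id, domain_id, start, end, category = cols
        key = (protein_id, domain_id, int(start), int(end), category)
        if key in seen:
            logger.info("%s:%d: duplicate domain row deduplicated", path, lineno)
            continue
        seen.add(key)
        try:
            hits.append(DomainHit(protein_id, domain_id, int(start), int(end), category))
        except FormatError as exc:
            raise FormatError(f"{path}:{lineno}: {exc}") from exc
    hits.sort(key=lambda h: (h.protein_id, h.start))
    return hits


def write_domain_tsv(hits: Iterable[DomainHit], path: str | Path) -> None:
    lines = [
        "\t".join([h.protein_id, h.domain_id, str(h.start), str(h.end), h.category])
        for h in hits
    ]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Chromosome lengths and expression matrices

def read_chrom_lengths(path: str | Path) -> dict[str, int]:
    """Read a 2-column (chrom, length-bp) TSV into an ordered mapping."""
    lengths: dict[str, int] = {}
    for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
        if not raw.strip() or raw.startswith("#"):
            continue
        cols = raw.split("\t")
        if len(cols) != 2:
            raise FormatError(f"{path}:{lineno}: expected 2 columns")
        chrom, length = cols[0], int(cols[1])
        if chrom in lengths:
            raise FormatError(f"{path}:{lineno}: duplicate chromosome {chrom!r}")
        if length <= 0:
            raise FormatError(f"{path}:{lineno}: non-positive length for {chrom!r}")
        lengths[chrom] = length
    if not lengths:
        raise FormatError(f"empty chromosome-length table: {path}")
    return lengths


def write_chrom_lengths(lengths: dict[str, int], path: str | Path) -> None:
    Path(path).write_text(
        "\n".join(f"{c}\t{l}" for c, l in lengths.items()) + "\n"
    )


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    """Read a gene x tissue abundance TSV (genes as index)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.has_duplicates:
        raise FormatError(f"duplicate gene ids in {path}")
    if (df.values < 0).any():
        raise FormatError(f"negative abundance values in {path}")
    return df


def write_expression_tsv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t")
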