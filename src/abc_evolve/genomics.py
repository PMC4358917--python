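"""Genomic distribution tests and subfamily abundance profiles.

The chromosome-distribution test asks whether gene placement is random
with respect to chromosome size: under the null, each gene lands on a
chromosome with probability proportional to its length, and a Monte-Carlo
chi-square test compares the observed per-chromosome counts with that
expectation. The k-value profile normalizes subfamily counts by proteome
size so family expansions are comparable across species.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import SUBFAMILIES, SubfamilyAssignment
from .io_formats import GeneLocus

logger = logging.getLogger("abc_evolve")


@dataclass(frozen=True)
class ChromDistributionTest:
    chroms: tuple[str, ...]
    observed: tuple[int, ...]
    expected: tuple[float, ...]
    statistic: float
    p_value: float
    n_mc: int
    excluded_chroms: tuple[str, ...] = ()


def chrom_distribution_test(
    loci: Iterable[GeneLocus],
    chrom_lengths: Mapping[str, int],
    n_mc: int = 10000,
    seed: int = 0,
    exclude_unanchored: bool = True,
) -> ChromDistributionTest:
    """Monte-Carlo chi-square test of length-proportional gene placement.

    Expected count per chromosome = n_genes x (length / genome length);
    statistic = sum (obs - exp)^2 / exp; the p-value uses the +1-corrected
    estimator p = (1 + #{replicate >= observed}) / (n_mc + 1) with
    replicates drawn by multinomial placement. Chromosome "0" entries
    (unanchored scaffolds) are excluded from the test by default (flagged).
    """
    loci = list(loci)
    lengths = dict(chrom_lengths)
    for c, L in lengths.items():
        if L <= 0:
            raise ValueError(f"zero-length chromosome {c!r}")
    excluded = tuple(
        c for c in lengths
        if exclude_unanchored and (c == "0" or c.endswith("chr0") or c.endswith("ch00"))
    )
    for c in excluded:
        logger.info("excluding unanchored chromosome %r from the test", c)
        del lengths[c]
    if len(lengths) < 2:
        raise ValueError("need >= 2 chromosomes")
    for loc in loci:
        if loc.chrom not in lengths and loc.chrom not in excluded:
            raise ValueError(f"locus {loc.gene_id} on unknown chromosome {loc.chrom!r}")

    chroms = list(lengths)
    counted = [l for l in loci if l.chrom in lengths]
    n = len(counted)
    obs = np.array([sum(1 for l in counted if l.chrom == c) for c in chroms])
    probs = np.array([lengths[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    exp = n * probs
    stat = float((((obs - exp) ** 2) / exp).sum())

    rng = np.random.default_rng(seed)
    reps = rng.multinomial(n, probs, size=n_mc)
    rep_stats = (((reps - exp) ** 2) / exp).sum(axis=1)
    p = (1 + int((rep_stats >= stat - 1e-12).sum())) / (n_mc + 1)
    return ChromDistributionTest(
        chroms=tuple(chroms),
        observed=tuple(int(o) for o in obs),
        expected=tuple(float(e) for e in exp),
        statistic=stat,
        p_value=float(p),
        n_mc=n_mc,
        excluded_chroms=excluded,
    )


def k_profile(
    assignments: Sequence[SubfamilyAssignment],
    proteome_size: int,
    species: str = "synthetic",
) -> pd.DataFrame:
    """Per-subfamily counts and k = count / proteome size, with a total row."""
    if proteome_size <= 0:
        raise ValueError("proteome_size must be > 0")
    counts = {sub: 0 for sub in SUBFAMILIES}
    for a in assignments:
        counts[a.subfamily] += 1
    rows = [
        {"species": species, "subfamily": sub, "count": c, "k": c / proteome_size}
        for sub, c in counts.items()
    ]
    total = sum(counts.values())
    rows.append(
        {"species": species, "subfamily": "Total", "count": total,
         "k": total / proteome_size}
    )
    return pd.DataFrame(rows)
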