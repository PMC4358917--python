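"""Tissue expression profiling: RPKM -> TPM, expressed calls, Venn regions
and per-subfamily expression tables.

TPM (transcripts per million) from RPKM is a per-tissue renormalization:
TPM_g = RPKM_g / sum_g RPKM x 1e6, so every tissue column sums to one
million. A gene counts as expressed in a tissue when its TPM strictly
exceeds the threshold (default 2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from itertools import chain, combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import SUBFAMILIES, SubfamilyAssignment

logger = logging.getLogger("abc_evolve")

TPM_SUM = 1e6


@dataclass
class ExpressionMatrix:
    """Gene x tissue abundance with an explicit unit flag."""

    values: pd.DataFrame
    unit: str  # "RPKM" | "TPM"

    def __post_init__(self) -> None:
        if self.unit not in ("RPKM", "TPM"):
            raise ValueError(f"unit must be RPKM or TPM, got {self.unit!r}")
        if (self.values.values < 0).any():
            raise ValueError("negative abundance values")
        if self.unit == "TPM":
            sums = self.values.sum(axis=0)
            bad = sums[(sums - TPM_SUM).abs() > 1e-6 * TPM_SUM]
            if len(bad):
                raise ValueError(
                    f"TPM columns must sum to 1e6; off: {list(bad.index)}"
                )


@dataclass
class ExpressionCalls:
    calls: pd.DataFrame  # boolean gene x tissue
    threshold: float

    @property
    def any_tissue(self) -> pd.Series:
        return self.calls.any(axis=1)


def rpkm_to_tpm(m: ExpressionMatrix) -> ExpressionMatrix:
    """Renormalize each tissue column of an RPKM matrix to sum to 1e6."""
    if m.unit != "RPKM":
        raise ValueError("input must be in RPKM units")
    sums = m.values.sum(axis=0)
    zero = sums[sums <= 0]
    if len(zero):
        raise ValueError(f"all-zero RPKM column for tissue(s): {list(zero.index)}")
    return ExpressionMatrix(m.values / sums * TPM_SUM, "TPM")


def call_expressed(m: ExpressionMatrix, threshold: float = 2.0) -> ExpressionCalls:
    """Expressed calls: TPM strictly greater than the threshold."""
    if m.unit != "TPM":
        raise ValueError("calls are defined on TPM matrices")
    return ExpressionCalls(calls=m.values > threshold, threshold=threshold)


def tissue_sets(calls: ExpressionCalls) -> dict[frozenset, int]:
    """Venn-region counts: each expressed gene goes to exactly one region,
    its exact expressed-tissue set; genes expressed nowhere are absent."""
    if calls.calls.shape[1] < 1:
        raise ValueError("need >= 1 tissue")
    regions: dict[frozenset, int] = {}
    for _, row in calls.calls.iterrows():
        tset = frozenset(row.index[row])
        if not tset:
            continue
        regions[tset] = regions.get(tset, 0) + 1
    return regions


def all_venn_regions(tissues: Sequence[str]) -> list[frozenset]:
    """All non-empty tissue subsets, for exhaustive region listing."""
    return [
        frozenset(c)
        for r in range(1, len(tissues) + 1)
        for c in combinations(tissues, r)
    ]


def subfamily_expression_table(
    calls: ExpressionCalls,
    assignments: Sequence[SubfamilyAssignment],
) -> pd.DataFrame:
    """Per-subfamily x tissue expressed-gene counts, plus any-tissue and
    per-subfamily totals; genes without an assignment count as
    unclassified."""
    sub_of = {a.protein_id: a.subfamily for a in assignments}
    tissues = list(calls.calls.columns)
    subs = [s for s in SUBFAMILIES]
    table = pd.DataFrame(0, index=subs + ["Total"], columns=tissues + ["any_tissue", "n_genes"])
    for gene, row in calls.calls.iterrows():
        sub = sub_of.get(gene, "unclassified")
        table.loc[sub, "n_genes"] += 1
        if row.any():
            table.loc[sub, "any_tissue"] += 1
        for tissue in tissues:
            if row[tissue]:
                table.loc[sub, tissue] += 1
    table.loc["Total"] = table.loc[subs].sum()
    return table


def write_venn_tsv(regions: Mapping[frozenset, int], path) -> None:
    lines = ["tissues\tcount"]
    for tset in sorted(regions, key=lambda s: (len(s), sorted(s))):
        lines.append(f"{','.join(sorted(tset))}\t{regions[tset]}")
    from pathlib import Path

    Path(path).write_text("\n".join(lines) + "\n")
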