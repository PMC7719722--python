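"""Fold-change DEG calling per mutant and cross-mutant intersection.

Significance is purely fold-change based: a gene is called *up* in a mutant
when its mean log2 intensity exceeds the wildtype mean by more than
``log2(fold_threshold)`` (strictly more than fourfold by default), *down* for
the mirror-image contrast, and *unchanged* otherwise.  The intersection of
the two avascular mutants' calls defines the candidate ncEC signature set.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .category_stats import CategoryMap
from .config import OTHER, WT
from .matrix import DEFAULT_PSEUDOCOUNT, ExpressionMatrix

__all__ = [
    "DegError",
    "DegCalls",
    "DegIntersection",
    "call_degs",
    "intersect_degs",
    "signature_category_breakdown",
    "build_deg_report",
]

UP = "up"
DOWN = "down"
UNCHANGED = "unchanged"


class DegError(ValueError):
    """Raised on inconsistent DEG inputs (missing genotype, mixed universes)."""


@dataclass
class DegCalls:
    """Per-gene log2 ratios and direction calls for one mutant vs wildtype."""

    mutant: str
    wt_label: str
    fold_threshold: float
    table: pd.DataFrame  # index gene; columns log2_ratio, call

    @property
    def up(self) -> FrozenSet[str]:
        return frozenset(self.table.index[self.table["call"] == UP])

    @property
    def down(self) -> FrozenSet[str]:
        return frozenset(self.table.index[self.table["call"] == DOWN])

    @property
    def genes(self) -> FrozenSet[str]:
        return frozenset(self.table.index)


@dataclass
class DegIntersection:
    """Shared direction-consistent calls of two mutants."""

    mutants: tuple
    shared_up: FrozenSet[str]
    shared_down: FrozenSet[str]

    @property
    def total(self) -> int:
        return len(self.shared_up) + len(self.shared_down)


def call_degs(
    m: ExpressionMatrix,
    wt_label: str = WT,
    mutant_label: str = "npas4l_mut",
    fold_threshold: float = 4.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> DegCalls:
    """Call up/down/unchanged per gene by the strict fold-change rule."""
    if fold_threshold <= 1:
        raise DegError(f"fold_threshold must be > 1, got {fold_threshold}")
    for label in (wt_label, mutant_label):
        try:
            m.columns_for(label)
        except KeyError as exc:
            raise DegError(str(exc)) from None
    log2m = m.to_log2(pseudocount)
    ratio = log2m.genotype_mean(mutant_label) - log2m.genotype_mean(wt_label)
    cut = np.log2(fold_threshold)
    call = pd.Series(UNCHANGED, index=ratio.index, dtype=object)
    call[ratio > cut] = UP
    call[ratio < -cut] = DOWN
    table = pd.DataFrame({"log2_ratio": ratio, "call": call}).rename_axis("gene")
    return DegCalls(
        mutant=mutant_label,
        wt_label=wt_label,
        fold_threshold=fold_threshold,
        table=table,
    )


def intersect_degs(a: DegCalls, b: DegCalls) -> DegIntersection:
    """Direction-consistent intersection of two per-mutant call sets."""
    if a.genes != b.genes:
        diff = len(a.genes ^ b.genes)
        raise DegError(
            f"DEG reports cover different gene universes (symmetric difference "
            f"of {diff} genes)"
        )
    return DegIntersection(
        mutants=(a.mutant, b.mutant),
        shared_up=a.up & b.up,
        shared_down=a.down & b.down,
    )


def signature_category_breakdown(
    shared: Iterable[str],
    cats: CategoryMap,
    categories: Optional[Sequence[str]] = None,
) -> Dict[str, int]:
    """Count shared-signature genes per functional category.

    Genes absent from the category map count under ``"other"``.
    """
    shared = set(shared)
    counts: Dict[str, int] = {}
    if categories:
        counts = {c: 0 for c in list(categories) + [OTHER]}
    for gene in shared:
        labels = cats.get(gene, OTHER)
        if isinstance(labels, str):
            labels = [labels]
        for label in labels:
            counts[label] = counts.get(label, 0) + 1
    return counts


def build_deg_report(
    calls: Mapping[str, DegCalls],
    intersection: DegIntersection,
) -> pd.DataFrame:
    """Assemble the per-gene report TSV: ratios, calls and shared flags."""
    mutants = list(calls)
    first = calls[mutants[0]]
    frame: Dict[str, pd.Series] = {}
    for mut in mutants:
        frame[f"log2_ratio_{mut}"] = calls[mut].table["log2_ratio"]
        frame[f"call_{mut}"] = calls[mut].table["call"]
    report = pd.DataFrame(frame, index=first.table.index).rename_axis("gene")
    shared = pd.Series("", index=report.index, dtype=object)
    shared[list(intersection.shared_up)] = UP
    shared[list(intersection.shared_down)] = DOWN
    report["shared"] = shared
    return report.sort_index()
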