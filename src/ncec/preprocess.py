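"""Spot-level filtering, annotation collapse, quantile normalization and
pharyngeal-endoderm exclusion.

The chain mirrors the microarray analysis it models: identifiable spots are
kept if their detection p-value falls below the threshold (0.5 by default,
taken literally), control and unannotated spots are removed and remaining
spots collapse to one row per gene (median across a gene's spots), columns
are quantile-normalized, and genes enriched in wildtype over the
endoderm-free *sox32* mutant beyond a fold threshold are excluded as
pharyngeal-endoderm contamination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from .matrix import (
    DEFAULT_PSEUDOCOUNT,
    ExpressionMatrix,
    QUANTILE_NORMALIZED,
    RAW,
)
from .config import SOX32, WT
from .synthetic import SPOT_COLUMNS

__all__ = [
    "FilterReport",
    "filter_spots",
    "collapse_and_annotate",
    "quantile_normalize",
    "exclude_endoderm",
    "preprocess_chain",
]

_MISSING_SYMBOLS = {"", "NA", "nan", "None"}


class PreprocessError(ValueError):
    """Raised on malformed inputs to a preprocessing stage."""


@dataclass
class FilterReport:
    """Record counts along the filter chain (monotone non-increasing)."""

    n_total: int = 0
    n_identifiable: int = 0
    n_pass_pvalue: int = 0
    n_annotated_genes: Optional[int] = None
    n_non_endoderm: Optional[int] = None

    def as_dict(self) -> Dict[str, Optional[int]]:
        return asdict(self)

    def chain(self) -> List[int]:
        counts = [self.n_total, self.n_identifiable, self.n_pass_pvalue]
        for c in (self.n_annotated_genes, self.n_non_endoderm):
            if c is not None:
                counts.append(c)
        return counts


def _sample_columns(spots: pd.DataFrame) -> List[str]:
    return [c for c in spots.columns if c not in SPOT_COLUMNS]


def filter_spots(
    spots: pd.DataFrame,
    p_threshold: float = 0.5,
    report: Optional[FilterReport] = None,
) -> Tuple[pd.DataFrame, FilterReport]:
    """Keep identifiable spots with detection p-value below the threshold.

    Row order is preserved.  Returns the retained spot table and a
    :class:`FilterReport` with the total / identifiable / passing counts.
    """
    if not 0 < p_threshold <= 1:
        raise PreprocessError(f"p_threshold must be in (0, 1], got {p_threshold}")
    identifiable = spots["is_identifiable"].astype(int) == 1
    passing = identifiable & (spots["detection_p"] < p_threshold)
    report = report or FilterReport()
    report.n_total = len(spots)
    report.n_identifiable = int(identifiable.sum())
    report.n_pass_pvalue = int(passing.sum())
    if report.n_pass_pvalue == 0:
        warnings.warn("no spots pass the detection p-value filter", stacklevel=2)
    return spots.loc[passing].copy(), report


def collapse_and_annotate(
    spots: pd.DataFrame,
    report: Optional[FilterReport] = None,
) -> Tuple[ExpressionMatrix, FilterReport]:
    """Drop control / unannotated spots and collapse spots to one row per gene.

    Multiple spots of a gene collapse to their per-sample median.  A gene
    symbol carried by both control and non-control spots is a conflicting
    annotation and raises :class:`PreprocessError`.
    """
    samples = _sample_columns(spots)
    if not samples:
        raise PreprocessError("spot table has no intensity columns")
    symbol = spots["gene_symbol"].astype(str)
    annotated = ~symbol.isin(_MISSING_SYMBOLS) & symbol.notna()

    flags = spots.loc[annotated].groupby(symbol[annotated])["is_control"].nunique()
    conflicts = sorted(flags.index[flags > 1])
    if conflicts:
        raise PreprocessError(
            f"gene symbols with conflicting control annotation: {conflicts[:10]}"
        )

    keep = annotated & (spots["is_control"].astype(int) == 0)
    collapsed = (
        spots.loc[keep, samples]
        .groupby(symbol[keep])
        .median()
        .sort_index()
        .rename_axis("gene")
    )
    report = report or FilterReport()
    report.n_annotated_genes = len(collapsed)
    return ExpressionMatrix(collapsed, normalization_state=RAW), report


def quantile_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Force identical value distributions across sample columns.

    Each column's sorted values are replaced by the across-column means of
    order statistics; ties within a column receive the mean of the rank-means
    they span.  For tie-free columns the transform is idempotent and leaves
    every column with the identical value multiset.
    """
    if m.normalization_state == QUANTILE_NORMALIZED:
        raise PreprocessError("matrix is already quantile normalized")
    if m.values.isna().any().any():
        raise PreprocessError("missing values must be resolved before normalization")
    X = m.values.to_numpy(dtype=float)
    n, k = X.shape
    if k == 1:
        warnings.warn(
            "single-sample matrix: quantile normalization is the identity",
            stacklevel=2,
        )
        return ExpressionMatrix(
            m.values.copy(),
            normalization_state=QUANTILE_NORMALIZED,
            log_state=m.log_state,
        )
    reference = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(k):
        col = X[:, j]
        assigned = np.empty(n)
        assigned[np.argsort(col, kind="stable")] = reference
        # tied values receive the mean of the rank-means they span
        out[:, j] = pd.Series(assigned).groupby(pd.Series(col)).transform("mean").to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return ExpressionMatrix(
        values, normalization_state=QUANTILE_NORMALIZED, log_state=m.log_state
    )


def exclude_endoderm(
    m: ExpressionMatrix,
    wt_label: str = WT,
    sox32_label: str = SOX32,
    fold_threshold: float = 2.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    report: Optional[FilterReport] = None,
) -> Tuple[ExpressionMatrix, List[str], FilterReport]:
    """Remove genes enriched in wildtype over the endoderm-free mutant.

    A gene is excluded when its mean log2 wildtype intensity exceeds the mean
    log2 *sox32*-mutant intensity by at least ``log2(fold_threshold)``.
    Returns ``(filtered_matrix, excluded_gene_ids, report)``.
    """
    if fold_threshold <= 1:
        raise PreprocessError("fold_threshold must be > 1")
    for label in (wt_label, sox32_label):
        try:
            m.columns_for(label)
        except KeyError as exc:
            raise PreprocessError(str(exc)) from None
    log2m = m.to_log2(pseudocount)
    contrast = log2m.genotype_mean(wt_label) - log2m.genotype_mean(sox32_label)
    excluded_mask = contrast >= np.log2(fold_threshold)
    excluded = sorted(m.gene_ids[excluded_mask])
    kept = ExpressionMatrix(
        m.values.loc[~excluded_mask],
        normalization_state=m.normalization_state,
        log_state=m.log_state,
    )
    report = report or FilterReport()
    report.n_non_endoderm = len(kept.gene_ids)
    return kept, excluded, report


def preprocess_chain(
    spots: pd.DataFrame,
    p_threshold: float = 0.5,
    fold_threshold: float = 2.0,
    wt_label: str = WT,
    sox32_label: str = SOX32,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> Tuple[ExpressionMatrix, List[str], FilterReport]:
    """Full chain: p-filter -> collapse -> quantile-normalize -> endoderm filter."""
    filtered, report = filter_spots(spots, p_threshold)
    collapsed, report = collapse_and_annotate(filtered, report)
    normalized = quantile_normalize(collapsed)
    return exclude_endoderm(
        normalized,
        wt_label=wt_label,
        sox32_label=sox32_label,
        fold_threshold=fold_threshold,
        pseudocount=pseudocount,
        report=report,
    )
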