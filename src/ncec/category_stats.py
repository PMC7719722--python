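"""Category-wise correlation matrices, the quantile-shift matrix, and the
normalized ("modified") rank-binned correlation histogram.

These are the three bespoke comparison statistics of the analysis:

* **MVA-correlation matrices** — pairwise Pearson correlation of log2
  expression profiles across samples, restricted to a functional gene
  category, scaled by the mean within-wildtype replicate correlation to a
  0–1 range.
* **Quantile-shift matrix** — genes ranked by mean wildtype expression and
  split into quartiles Q1 (lowest) to Q4 (highest); each mutant's re-ranking
  yields per-gene rank shifts and a quartile transition table.
* **Modified histogram** — wildtype-rank-ordered genes partitioned into
  consecutive bins; the per-bin Pearson correlation between wildtype and
  mutant mean profiles is divided by that mutant's whole-transcriptome
  MVA correlation against wildtype:

  ``normalized = corr(ranked transcripts in category) / MVA(whole transcriptome, mutant vs WT)``

All correlations are computed on log2-transformed intensities.  Rank ties are
broken by gene identifier so results are deterministic across platforms.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .config import MUTANT_LABELS, WT
from .matrix import DEFAULT_PSEUDOCOUNT, ExpressionMatrix, genotype_of_sample

__all__ = [
    "CategoryMap",
    "StatsError",
    "UndefinedCorrelationError",
    "pearson",
    "genes_in_category",
    "category_correlation_matrix",
    "CorrelationMatrix",
    "quantile_shift",
    "QuantileShiftResult",
    "whole_transcriptome_mva",
    "modified_histogram",
    "ModifiedHistogram",
    "QUANTILE_LABELS",
]

#: gene -> category label, or gene -> iterable of labels (overlap allowed)
CategoryMap = Mapping[str, Union[str, Iterable[str]]]

QUANTILE_LABELS = ("Q1", "Q2", "Q3", "Q4")


class StatsError(ValueError):
    """Raised on ill-posed statistic requests (too few genes, bad inputs)."""


class UndefinedCorrelationError(StatsError):
    """Pearson correlation of a constant vector is undefined."""


def pearson(x: Sequence[float], y: Sequence[float]) -> float:
    """Pearson product-moment correlation of two equal-length vectors."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or x.shape != y.shape:
        raise StatsError(f"vectors must be 1-D of equal length, got {x.shape}, {y.shape}")
    if x.size < 2:
        raise StatsError("pearson requires at least 2 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    sxx = float(xc @ xc)
    syy = float(yc @ yc)
    if sxx == 0.0 or syy == 0.0:
        raise UndefinedCorrelationError("correlation of a constant vector is undefined")
    return float(np.clip((xc @ yc) / np.sqrt(sxx * syy), -1.0, 1.0))


def genes_in_category(
    cats: CategoryMap, category: str, universe: Optional[Iterable[str]] = None
) -> List[str]:
    """Genes carrying ``category``, lexicographically sorted; optionally
    intersected with ``universe``."""
    allowed = None if universe is None else set(universe)
    out = []
    for gene, labels in cats.items():
        member = labels == category if isinstance(labels, str) else category in labels
        if member and (allowed is None or gene in allowed):
            out.append(gene)
    return sorted(out)


def _log2_values(m: ExpressionMatrix, pseudocount: float) -> pd.DataFrame:
    return m.to_log2(pseudocount).values


# ---------------------------------------------------------------------------
# correlation matrices
# ---------------------------------------------------------------------------

@dataclass
class CorrelationMatrix:
    """Sample x sample Pearson matrix over one category, scaled on wildtype."""

    category: str
    raw: pd.DataFrame
    scaled: pd.DataFrame
    reference: float          # mean within-wildtype replicate correlation
    n_genes: int
    n_clipped: int = 0

    def block_mean(self, genotype_a: str, genotype_b: str, scaled: bool = True) -> float:
        """Mean entry of the (genotype_a x genotype_b) block, excluding the
        diagonal when the two genotypes coincide."""
        mat = self.scaled if scaled else self.raw
        rows = [s for s in mat.index if genotype_of_sample(s) == genotype_a]
        cols = [s for s in mat.columns if genotype_of_sample(s) == genotype_b]
        block = mat.loc[rows, cols]
        if genotype_a == genotype_b:
            vals = block.to_numpy()[~np.eye(len(rows), dtype=bool)]
        else:
            vals = block.to_numpy().ravel()
        return float(vals.mean())


def category_correlation_matrix(
    m: ExpressionMatrix,
    cats: CategoryMap,
    category: str,
    wt_label: str = WT,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> CorrelationMatrix:
    """Pairwise sample correlations over a category, scaled on wildtype.

    The scaled entries divide each raw Pearson coefficient by the mean
    correlation among wildtype replicates and clip to [0, 1], so the
    within-wildtype block averages 1 by construction.
    """
    genes = genes_in_category(cats, category, universe=m.gene_ids)
    if len(genes) < 3:
        raise StatsError(
            f"category {category!r} has {len(genes)} genes in the matrix; "
            "need at least 3 for sample correlations"
        )
    profile = _log2_values(m.subset_genes(genes), pseudocount)
    samples = list(profile.columns)
    raw = pd.DataFrame(np.eye(len(samples)), index=samples, columns=samples)
    for a, b in itertools.combinations(samples, 2):
        r = pearson(profile[a], profile[b])
        raw.loc[a, b] = raw.loc[b, a] = r

    wt_cols = m.columns_for(wt_label)
    if len(wt_cols) < 2:
        raise StatsError("scaling on wildtype requires at least 2 WT replicates")
    wt_pairs = [raw.loc[a, b] for a, b in itertools.combinations(wt_cols, 2)]
    reference = float(np.mean(wt_pairs))
    if reference <= 0:
        raise StatsError("mean within-wildtype correlation is non-positive")
    scaled_unclipped = raw / reference
    scaled = scaled_unclipped.clip(0.0, 1.0)
    n_clipped = int(((scaled_unclipped < 0) | (scaled_unclipped > 1)).to_numpy().sum())
    if n_clipped:
        warnings.warn(
            f"{n_clipped} scaled correlation entries clipped to [0, 1] "
            f"for category {category!r}",
            stacklevel=2,
        )
    return CorrelationMatrix(
        category=category,
        raw=raw,
        scaled=scaled,
        reference=reference,
        n_genes=len(genes),
        n_clipped=n_clipped,
    )


# ---------------------------------------------------------------------------
# quantile shift
# ---------------------------------------------------------------------------

def _rank_genes(means: pd.Series) -> pd.Series:
    """1-based ascending ranks; ties broken by gene identifier."""
    order = means.sort_index().sort_values(kind="stable").index
    return pd.Series(np.arange(1, len(order) + 1), index=order).loc[means.index]

def quantile_sizes(n: int) -> List[int]:
    """Quartile sizes differing by at most one; lower quartiles get the extra."""
    base, rem = divmod(n, 4)
    return [base + (1 if i < rem else 0) for i in range(4)]


def _quantile_of_rank(n: int) -> np.ndarray:
    """Map rank-1 .. rank-n to quartile indices 0..3 (Q1 = lowest ranks)."""
    bounds = np.cumsum(quantile_sizes(n))
    return np.searchsorted(bounds, np.arange(1, n + 1), side="left")


@dataclass
class QuantileShiftResult:
    """Per-gene quartile placement in wildtype and each mutant."""

    category: str
    per_gene: pd.DataFrame
    transitions: Dict[str, pd.DataFrame]
    sizes: List[int]

    def departure_rate(self, mutant: str) -> pd.Series:
        """Fraction of each wildtype quartile leaving its quartile in the mutant."""
        t = self.transitions[mutant]
        diag = np.diag(t.to_numpy())
        sizes = np.asarray(self.sizes, dtype=float)
        with np.errstate(invalid="ignore"):
            rate = 1.0 - diag / sizes
        return pd.Series(rate, index=QUANTILE_LABELS)


def quantile_shift(
    m: ExpressionMatrix,
    cats: CategoryMap,
    category: str,
    wt_label: str = WT,
    mutant_labels: Sequence[str] = MUTANT_LABELS,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> QuantileShiftResult:
    """Rank category genes by wildtype expression, split into quartiles, and
    tabulate where each mutant's re-ranking places them."""
    genes = genes_in_category(cats, category, universe=m.gene_ids)
    if len(genes) < 4:
        raise StatsError(
            f"category {category!r} has {len(genes)} genes; quartiles need >= 4"
        )
    log2m = _log2_values(m.subset_genes(genes), pseudocount)
    n = len(genes)
    sizes = quantile_sizes(n)
    quart_of_rank = _quantile_of_rank(n)

    wt_mean = log2m[m.columns_for(wt_label)].mean(axis=1)
    wt_rank = _rank_genes(wt_mean)
    per_gene = pd.DataFrame(
        {
            "wt_mean_log2": wt_mean,
            "wt_rank": wt_rank,
            "wt_quantile": [QUANTILE_LABELS[quart_of_rank[r - 1]] for r in wt_rank],
        }
    )
    transitions: Dict[str, pd.DataFrame] = {}
    for mutant in mutant_labels:
        mut_mean = log2m[m.columns_for(mutant)].mean(axis=1)
        mut_rank = _rank_genes(mut_mean)
        mut_quart = [QUANTILE_LABELS[quart_of_rank[r - 1]] for r in mut_rank]
        per_gene[f"{mutant}_rank"] = mut_rank
        per_gene[f"{mutant}_quantile"] = mut_quart
        per_gene[f"{mutant}_rank_shift"] = mut_rank - wt_rank
        counts = pd.DataFrame(
            0, index=list(QUANTILE_LABELS), columns=list(QUANTILE_LABELS)
        )
        for wq, mq in zip(per_gene["wt_quantile"], mut_quart):
            counts.loc[wq, mq] += 1
        transitions[mutant] = counts
    per_gene = per_gene.rename_axis("gene")
    return QuantileShiftResult(
        category=category, per_gene=per_gene, transitions=transitions, sizes=sizes
    )


# ---------------------------------------------------------------------------
# modified histogram
# ---------------------------------------------------------------------------

def whole_transcriptome_mva(
    m: ExpressionMatrix,
    label_a: str,
    label_b: str,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> float:
    """Mean pairwise Pearson correlation of replicate log2 profiles between
    two genotypes over all genes of the matrix (within-genotype when the two
    labels coincide)."""
    log2m = _log2_values(m, pseudocount)
    cols_a = m.columns_for(label_a)
    cols_b = m.columns_for(label_b)
    if label_a == label_b:
        pairs = list(itertools.combinations(cols_a, 2))
        if not pairs:
            raise StatsError("within-genotype MVA requires >= 2 replicates")
    else:
        pairs = [(a, b) for a in cols_a for b in cols_b]
    return float(np.mean([pearson(log2m[a], log2m[b]) for a, b in pairs]))


@dataclass
class ModifiedHistogram:
    """Rank-binned WT-vs-mutant correlations, normalized per mutant."""

    category: str
    table: pd.DataFrame
    denominators: Dict[str, float]
    bin_size: int
    mode: str = "binned"

    def normalized(self, mutant: str) -> pd.Series:
        return self.table[f"norm_{mutant}"]


def modified_histogram(
    m: ExpressionMatrix,
    cats: CategoryMap,
    category: str,
    bin_size: int = 50,
    wt_label: str = WT,
    mutant_labels: Sequence[str] = MUTANT_LABELS,
    mode: str = "binned",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ModifiedHistogram:
    """Correlation of ranked category transcripts, normalized by the
    whole-transcriptome mutant-vs-wildtype MVA correlation.

    In the default ``"binned"`` mode, genes in wildtype-rank order are
    partitioned into consecutive bins of ``bin_size`` (a trailing bin smaller
    than 3 is dropped) and each bin contributes the Pearson correlation
    between the wildtype and mutant mean log2 profiles over its genes.  The
    alternative ``"per_gene"`` mode correlates the wildtype and mutant
    replicate vectors of each transcript individually (undefined correlations
    become NaN).  Every raw value is divided by that mutant's
    whole-transcriptome MVA correlation against wildtype, computed over all
    genes of ``m``.
    """
    if mode not in ("binned", "per_gene"):
        raise StatsError(f"unknown mode {mode!r}")
    if mode == "binned" and bin_size < 3:
        raise StatsError("bin_size must be >= 3")
    genes = genes_in_category(cats, category, universe=m.gene_ids)
    if len(genes) < 4:
        raise StatsError(f"category {category!r} has too few genes ({len(genes)})")
    sub = m.subset_genes(genes)
    log2m = _log2_values(sub, pseudocount)
    wt_cols = m.columns_for(wt_label)
    wt_mean = log2m[wt_cols].mean(axis=1)
    ordered = list(_rank_genes(wt_mean).sort_values().index)

    denominators = {
        mut: whole_transcriptome_mva(m, wt_label, mut, pseudocount)
        for mut in mutant_labels
    }
    for mut, d in denominators.items():
        if d <= 0:
            raise StatsError(
                f"whole-transcriptome MVA correlation for {mut} is {d:.4f} <= 0; "
                "normalization undefined"
            )

    rows = []
    if mode == "binned":
        for start in range(0, len(ordered), bin_size):
            chunk = ordered[start : start + bin_size]
            if len(chunk) < 3:
                continue
            row: Dict[str, object] = {
                "bin": start // bin_size,
                "start_rank": start + 1,
                "n_genes": len(chunk),
            }
            wt_vec = wt_mean.loc[chunk]
            for mut in mutant_labels:
                raw = pearson(wt_vec, log2m.loc[chunk, m.columns_for(mut)].mean(axis=1))
                row[f"raw_{mut}"] = raw
                row[f"norm_{mut}"] = raw / denominators[mut]
            rows.append(row)
        table = pd.DataFrame(rows).set_index("bin")
    else:
        for rank, gene in enumerate(ordered, start=1):
            row = {"gene": gene, "wt_rank": rank}
            for mut in mutant_labels:
                try:
                    raw = pearson(
                        log2m.loc[gene, wt_cols], log2m.loc[gene, m.columns_for(mut)]
                    )
                except UndefinedCorrelationError:
                    raw = np.nan
                row[f"raw_{mut}"] = raw
                row[f"norm_{mut}"] = raw / denominators[mut]
            rows.append(row)
        table = pd.DataFrame(rows).set_index("gene")
    return ModifiedHistogram(
        category=category,
        table=table,
        denominators=denominators,
        bin_size=bin_size,
        mode=mode,
    )
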