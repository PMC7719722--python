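"""Gene x sample expression container shared by all pipeline stages.

Samples are named ``<genotype>_<replicate>`` (e.g. ``etsrp_mut_2``); genotype
labels themselves may contain underscores, so the replicate index is always
the final underscore-separated token.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, List

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "genotype_of_sample"]

RAW = "raw"
QUANTILE_NORMALIZED = "quantile_normalized"
LINEAR = "linear"
LOG2 = "log2"

#: fixed pseudocount guarding log2 of linear intensities against zeros
DEFAULT_PSEUDOCOUNT = 1.0


def genotype_of_sample(sample: str) -> str:
    """Genotype label of a ``<genotype>_<replicate>`` sample name."""
    genotype, _, rep = sample.rpartition("_")
    if not genotype or not rep.isdigit():
        raise ValueError(f"sample name {sample!r} is not '<genotype>_<replicate>'")
    return genotype


@dataclass
class ExpressionMatrix:
    """Genes x samples intensity matrix with normalization/log state flags.

    Parameters
    ----------
    values
        DataFrame indexed by gene identifier with one column per sample.
    normalization_state
        ``"raw"`` or ``"quantile_normalized"``.
    log_state
        ``"linear"`` (positive intensities) or ``"log2"``.
    """

    values: pd.DataFrame
    normalization_state: str = RAW
    log_state: str = LINEAR

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique()
            raise ValueError(f"duplicate gene identifiers: {list(dupes)[:5]}")
        if self.normalization_state not in (RAW, QUANTILE_NORMALIZED):
            raise ValueError(f"bad normalization_state {self.normalization_state!r}")
        if self.log_state not in (LINEAR, LOG2):
            raise ValueError(f"bad log_state {self.log_state!r}")

    # ------------------------------------------------------------------ basics
    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> List[str]:
        return list(self.values.columns)

    @property
    def genotypes(self) -> List[str]:
        seen: List[str] = []
        for s in self.samples:
            g = genotype_of_sample(s)
            if g not in seen:
                seen.append(g)
        return seen

    def columns_for(self, genotype: str) -> List[str]:
        cols = [s for s in self.samples if genotype_of_sample(s) == genotype]
        if not cols:
            raise KeyError(f"genotype {genotype!r} has no sample columns")
        return cols

    def genotype_mean(self, genotype: str) -> pd.Series:
        return self.values[self.columns_for(genotype)].mean(axis=1)

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes absent from matrix: {missing[:5]}")
        return replace(self, values=self.values.loc[genes])

    # ------------------------------------------------------------------ scale
    def to_log2(self, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> "ExpressionMatrix":
        """Log2 view of the matrix; linear intensities get a pseudocount."""
        if self.log_state == LOG2:
            return self
        return replace(
            self, values=np.log2(self.values + pseudocount), log_state=LOG2
        )

    # ------------------------------------------------------------------ io
    def write_tsv(self, path: str | Path, float_format: str = "%.10g") -> None:
        self.values.to_csv(
            path, sep="\t", index_label="gene", float_format=float_format
        )

    @classmethod
    def read_tsv(
        cls,
        path: str | Path,
        normalization_state: str = RAW,
        log_state: str = LINEAR,
    ) -> "ExpressionMatrix":
        df = pd.read_csv(path, sep="\t", index_col="gene")
        return cls(df, normalization_state=normalization_state, log_state=log_state)
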