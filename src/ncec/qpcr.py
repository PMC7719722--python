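"""Relative qPCR quantification by the 2^-ddCt method.

Target cycle thresholds are normalized against the mean Ct of the reference
genes (the housekeeping 18S rRNA and the endothelial kdrl by default), then
against a calibrator condition:

    dCt   = Ct_target - mean(Ct_references)          (per condition)
    ddCt  = dCt_condition - dCt_calibrator
    fold  = 2 ** (-ddCt)

Input is a long-format table with columns ``gene, condition, replicate, ct``;
replicate Ct values are averaged before normalization.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = ["QpcrError", "ddct", "DEFAULT_REFERENCES"]

DEFAULT_REFERENCES = ("18S_rRNA", "kdrl")


class QpcrError(ValueError):
    """Raised when the Ct table lacks required references or conditions."""


def ddct(
    table: pd.DataFrame,
    references: Sequence[str] = DEFAULT_REFERENCES,
    calibrator: str = "control",
    targets: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Compute dCt, ddCt and 2^-ddCt fold change per target and condition.

    Returns a DataFrame with one row per (gene, condition) and columns
    ``mean_ct, ref_mean_ct, delta_ct, delta_delta_ct, fold_change``.
    """
    required = {"gene", "condition", "ct"}
    if not required <= set(table.columns):
        raise QpcrError(f"Ct table must have columns {sorted(required)}")
    references = list(references)
    mean_ct = table.groupby(["gene", "condition"])["ct"].mean()
    conditions = sorted(table["condition"].unique())
    if calibrator not in conditions:
        raise QpcrError(f"calibrator condition {calibrator!r} absent from table")
    for cond in conditions:
        missing = [r for r in references if (r, cond) not in mean_ct.index]
        if missing:
            raise QpcrError(
                f"reference gene(s) {missing} missing in condition {cond!r}"
            )
    ref_mean = {
        cond: float(np.mean([mean_ct[(r, cond)] for r in references]))
        for cond in conditions
    }
    if targets is None:
        targets = sorted(set(table["gene"]) - set(references))
    rows = []
    dct_cal = {}
    for gene in targets:
        if (gene, calibrator) not in mean_ct.index:
            raise QpcrError(f"target {gene!r} has no Ct in calibrator condition")
        dct_cal[gene] = mean_ct[(gene, calibrator)] - ref_mean[calibrator]
    for gene in targets:
        for cond in conditions:
            if (gene, cond) not in mean_ct.index:
                continue
            dct = mean_ct[(gene, cond)] - ref_mean[cond]
            ddct_val = dct - dct_cal[gene]
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "mean_ct": mean_ct[(gene, cond)],
                    "ref_mean_ct": ref_mean[cond],
                    "delta_ct": dct,
                    "delta_delta_ct": ddct_val,
                    "fold_change": float(2.0 ** (-ddct_val)),
                }
            )
    return pd.DataFrame(rows)
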