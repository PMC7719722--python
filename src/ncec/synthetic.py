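"""Planted-truth synthetic data emulating the four-genotype microarray design.

The generator produces every input the pipeline consumes — spot-level
intensity tables, gene x sample expression matrices, promoter FASTA records,
TSS coordinates and qPCR Ct tables — together with a :class:`SyntheticTruth`
object recording exactly what was planted, so every downstream stage can be
tested against known ground truth.

Intensity model
---------------
Gene baselines sit on a deterministic log2 grid spanning
``baseline_log2_range`` (~4 decades), with the gene-to-grid assignment drawn
from the seeded RNG.  Effects are additive on the log2 scale:

* endoderm-enriched genes gain ``log2(endoderm_fold)`` in every genotype that
  retains endoderm (all but the *sox32* mutant); they are placed in the lower
  65% of the baseline grid so the wildtype-vs-*sox32* contrast survives
  quantile normalization with a wide margin,
* planted DEGs gain/lose exactly ``deg_effect_log2`` in the affected mutant,
* non-DEG members of a perturbed category receive a uniform(-s, s) log2 shift
  in each avascular mutant (the "rank noise" that makes mid-rank transcripts
  cross quantile boundaries),
* replicates add i.i.d. Gaussian log2 noise of SD ``replicate_noise_sd``.

All randomness derives from one master seed; each artifact uses its own
spawned stream so any single file can be regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, FrozenSet, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .config import (
    CATEGORIES,
    ETSRP,
    GeneratorConfig,
    ConfigurationError,
    MUTANT_LABELS,
    NPAS4L,
    NPAS4L_MOTIF,
    OTHER,
    SOX32,
    WT,
)
from .matrix import ExpressionMatrix

__all__ = [
    "SyntheticTruth",
    "generate_expression_truth",
    "generate_spot_table",
    "generate_promoters",
    "generate_ct_table",
    "promoters_to_genome",
    "write_spot_table",
    "write_truth",
    "SPOT_COLUMNS",
]

# independent sub-streams of the master seed
_STREAM_EXPR = 101
_STREAM_SPOTS = 202
_STREAM_PROMOTERS = 303
_STREAM_CT = 404

#: fraction of the baseline grid (from the bottom) eligible to host
#: endoderm-enriched genes; keeps >= one endoderm-fold of grid headroom above
#: every planted gene so the WT/sox32 contrast survives quantile normalization
_ENDODERM_RANK_CEILING = 0.65

# how planted shared DEGs distribute over functional categories: the shared-up
# (ncEC signature) set is biased into somitogenesis / neurogenesis, mirroring
# the tailbud origin of the non-conventional endothelial cells
_SHARED_UP_QUOTA = {"angiogenesis": 0.05, "somitogenesis": 0.30, "neurogenesis": 0.30}
_SHARED_DOWN_QUOTA = {"angiogenesis": 0.05, "somitogenesis": 0.20, "neurogenesis": 0.20}

SPOT_COLUMNS = [
    "spot_id",
    "probe_id",
    "gene_symbol",
    "is_control",
    "is_identifiable",
    "detection_p",
]

_CT_REFERENCES = ("18S_rRNA", "kdrl")
_CT_CONDITIONS = ("control", "npas4l_MO")


def _rng(config: GeneratorConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed), stream]))


@dataclass
class SyntheticTruth:
    """Record of everything the generator planted (the recovery oracle)."""

    seed: int
    gene_ids: List[str]
    baseline_log2: pd.Series
    endoderm_gene_ids: FrozenSet[str]
    category_of_gene: Dict[str, str]
    deg_up: Dict[str, FrozenSet[str]]
    deg_down: Dict[str, FrozenSet[str]]
    shared_up_ids: FrozenSet[str]
    shared_down_ids: FrozenSet[str]
    motif_positive_genes: FrozenSet[str] = frozenset()
    motif_negative_genes: FrozenSet[str] = frozenset()
    ct_fold_truth: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        universe = set(self.gene_ids)
        for name, ids in [
            ("endoderm_gene_ids", self.endoderm_gene_ids),
            ("shared_up_ids", self.shared_up_ids),
            ("shared_down_ids", self.shared_down_ids),
        ]:
            if not set(ids) <= universe:
                raise ValueError(f"truth set {name} contains unknown gene ids")
        for mutant in self.deg_up:
            if self.deg_up[mutant] & self.deg_down[mutant]:
                raise ValueError(
                    f"a gene is planted both up and down in {mutant}"
                )

    @property
    def non_endoderm_gene_ids(self) -> FrozenSet[str]:
        return frozenset(set(self.gene_ids) - self.endoderm_gene_ids)


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------

def _plant_structure(
    config: GeneratorConfig, rng: np.random.Generator
) -> Tuple[List[str], np.ndarray, SyntheticTruth]:
    """Assign baselines, endoderm membership, categories and DEG sets."""
    G = config.n_annotated_genes
    gene_ids = [f"g{i:05d}" for i in range(G)]
    ranks = rng.permutation(G)
    lo, hi = config.baseline_log2_range
    baseline = lo + (hi - lo) * ranks / max(G - 1, 1)

    # endoderm genes only in the lower part of the grid (see module docstring)
    ceiling = int(np.floor(_ENDODERM_RANK_CEILING * G))
    low_pool = [gene_ids[i] for i in range(G) if ranks[i] < ceiling]
    if config.n_endoderm > len(low_pool):
        raise ConfigurationError(
            "n_annotated_genes - n_non_endoderm endoderm genes must fit in the "
            f"lower {_ENDODERM_RANK_CEILING:.0%} of the baseline grid: "
            f"{config.n_endoderm} > {len(low_pool)}"
        )
    endoderm = frozenset(rng.choice(low_pool, config.n_endoderm, replace=False))
    non_endoderm = [g for g in gene_ids if g not in endoderm]

    # planted DEG effects must not run off the intensity dynamic range:
    # saturated (floor/ceiling) values would distort the quantile-normalization
    # reference curve at its extremes, so DEGs are drawn from genes whose
    # baseline +- effect stays strictly inside the grid
    margin = config.deg_effect_log2 + 0.1 if config.deg_effect_log2 > 0 else 0.0
    idx_of = {g: i for i, g in enumerate(gene_ids)}
    eligible = {
        g
        for g in non_endoderm
        if lo + margin <= baseline[idx_of[g]] <= hi - margin
    }
    if config.n_planted_degs > len(eligible):
        raise ConfigurationError(
            "planted DEG counts exceed the genes whose baseline +- "
            f"deg_effect_log2 fits the intensity range: {config.n_planted_degs} "
            f"> {len(eligible)}"
        )

    # disjoint category assignment within the non-endoderm set
    shuffled = list(rng.permutation(non_endoderm))
    category_of: Dict[str, str] = {}
    cursor = 0
    members: Dict[str, List[str]] = {}
    for cat in config.category_sizes:
        size = config.category_sizes[cat]
        members[cat] = shuffled[cursor : cursor + size]
        for g in members[cat]:
            category_of[g] = cat
        cursor += size
    other_pool = shuffled[cursor:]
    for g in other_pool:
        category_of[g] = OTHER

    # shared DEG sets with per-category quotas (biased into somito/neuro)
    def _draw_shared(total: int, quota: Dict[str, float], taken: set) -> List[str]:
        chosen: List[str] = []
        for cat, frac in quota.items():
            if cat not in members:
                continue
            pool = [g for g in members[cat] if g not in taken and g in eligible]
            k = min(int(round(frac * total)), len(pool), total - len(chosen))
            if k > 0:
                chosen.extend(rng.choice(pool, k, replace=False))
        pool = [
            g for g in other_pool if g not in taken and g not in chosen and g in eligible
        ]
        remaining = total - len(chosen)
        if remaining > len(pool):
            # fall back to any untaken eligible non-endoderm gene
            pool = [
                g
                for g in non_endoderm
                if g not in taken and g not in chosen and g in eligible
            ]
        if remaining > 0:
            chosen.extend(rng.choice(pool, remaining, replace=False))
        return chosen

    taken: set = set()
    shared_up = _draw_shared(config.shared_up, _SHARED_UP_QUOTA, taken)
    taken |= set(shared_up)
    shared_down = _draw_shared(config.shared_down, _SHARED_DOWN_QUOTA, taken)
    taken |= set(shared_down)

    # mutant-unique DEGs, preferentially outside the named categories so the
    # angiogenesis correlation stays coherent
    def _draw_unique(total: int) -> List[str]:
        nonlocal taken
        pool = [g for g in other_pool if g not in taken and g in eligible]
        if total > len(pool):
            pool = [g for g in non_endoderm if g not in taken and g in eligible]
        if total > len(pool):
            raise ConfigurationError(
                "planted DEG sets exhaust the eligible non-endoderm gene pool"
            )
        drawn = list(rng.choice(pool, total, replace=False)) if total else []
        taken |= set(drawn)
        return drawn

    uniq_up_e = _draw_unique(config.unique_up_etsrp)
    uniq_down_e = _draw_unique(config.unique_down_etsrp)
    uniq_up_n = _draw_unique(config.unique_up_npas4l)
    uniq_down_n = _draw_unique(config.unique_down_npas4l)

    truth = SyntheticTruth(
        seed=config.seed,
        gene_ids=gene_ids,
        baseline_log2=pd.Series(baseline, index=gene_ids, name="baseline_log2"),
        endoderm_gene_ids=endoderm,
        category_of_gene=category_of,
        deg_up={
            ETSRP: frozenset(shared_up) | frozenset(uniq_up_e),
            NPAS4L: frozenset(shared_up) | frozenset(uniq_up_n),
        },
        deg_down={
            ETSRP: frozenset(shared_down) | frozenset(uniq_down_e),
            NPAS4L: frozenset(shared_down) | frozenset(uniq_down_n),
        },
        shared_up_ids=frozenset(shared_up),
        shared_down_ids=frozenset(shared_down),
    )
    return gene_ids, baseline, truth


def generate_expression_truth(
    config: GeneratorConfig,
) -> Tuple[ExpressionMatrix, SyntheticTruth]:
    """Generate the annotated gene x sample intensity matrix plus truth.

    The matrix stands in for the collapsed, annotated (pre-normalization)
    expression of FACS-sorted *kdrl*:eGFP+ cells.  Planted DEGs differ from
    wildtype by exactly ``±deg_effect_log2`` on the log2 scale before
    replicate noise; endoderm genes exceed their *sox32* value by
    ``log2(endoderm_fold)``.
    """
    config.validate()
    rng = _rng(config, _STREAM_EXPR)
    gene_ids, baseline, truth = _plant_structure(config, rng)
    G = len(gene_ids)
    index = pd.Index(gene_ids, name="gene")
    endo_mask = np.array([g in truth.endoderm_gene_ids for g in gene_ids])
    log2_endoderm = float(np.log2(config.endoderm_fold))

    columns: Dict[str, np.ndarray] = {}
    for genotype in config.genotypes:
        base = baseline.copy()
        if genotype != SOX32:
            base[endo_mask] += log2_endoderm
        if genotype in MUTANT_LABELS:
            up = truth.deg_up[genotype]
            down = truth.deg_down[genotype]
            base[[g in up for g in gene_ids]] += config.deg_effect_log2
            base[[g in down for g in gene_ids]] -= config.deg_effect_log2
            for cat, scale in config.category_rank_noise.items():
                if scale <= 0:
                    continue
                mask = np.array(
                    [
                        truth.category_of_gene.get(g) == cat
                        and g not in up
                        and g not in down
                        for g in gene_ids
                    ]
                )
                if mask.any():
                    base[mask] += rng.uniform(-scale, scale, int(mask.sum()))
        for rep in range(config.replicates_per_genotype):
            col = base
            if config.replicate_noise_sd > 0:
                col = base + rng.normal(0.0, config.replicate_noise_sd, G)
            columns[f"{genotype}_{rep + 1}"] = np.exp2(col)

    values = pd.DataFrame(columns, index=index)
    return ExpressionMatrix(values), truth


# ---------------------------------------------------------------------------
# spot table
# ---------------------------------------------------------------------------

def generate_spot_table(
    config: GeneratorConfig,
) -> Tuple[pd.DataFrame, SyntheticTruth]:
    """Generate the raw spot-level TSV table feeding the preprocessing chain.

    Counts are realized exactly: ``n_spots`` records, of which
    ``n_identifiable`` are flagged identifiable, of which ``n_pass_pvalue``
    carry detection p-value < 0.5; the passing, annotated, non-control spots
    collapse to exactly ``n_annotated_genes`` distinct gene symbols whose
    intensities embed the expression matrix of
    :func:`generate_expression_truth` (duplicate spots of a gene share its
    intensity, so a median collapse is lossless).
    """
    config.validate()
    expr, truth = generate_expression_truth(config)
    rng = _rng(config, _STREAM_SPOTS)
    samples = expr.samples
    n_samples = len(samples)

    n_fail = config.n_identifiable - config.n_pass_pvalue
    n_unident = config.n_spots - config.n_identifiable
    n_dup = config.n_annotated_spots - config.n_annotated_genes

    gene_ids = list(expr.gene_ids)
    dup_genes = list(rng.choice(gene_ids, n_dup, replace=False)) if n_dup else []
    annotated_genes = gene_ids + dup_genes

    # block layout: [annotated | control | unannotated | failing | unidentifiable]
    n = config.n_spots
    gene_symbol = np.full(n, "NA", dtype=object)
    is_control = np.zeros(n, dtype=int)
    is_identifiable = np.zeros(n, dtype=int)
    detection_p = np.empty(n)

    a = len(annotated_genes)
    c = config.n_control_pass
    u = config.n_unannotated_pass
    gene_symbol[:a] = annotated_genes
    is_control[a : a + c] = 1
    gene_symbol[a : a + c] = [f"spikein_{i % 20:02d}" for i in range(c)]
    is_identifiable[: config.n_identifiable] = 1
    detection_p[: config.n_pass_pvalue] = rng.uniform(0.0, 0.5, config.n_pass_pvalue)
    detection_p[config.n_pass_pvalue : config.n_identifiable] = rng.uniform(
        0.5, 1.0, n_fail
    )
    detection_p[config.n_identifiable :] = rng.uniform(0.0, 1.0, n_unident)

    lo, hi = config.baseline_log2_range
    intensities = np.empty((n, n_samples))
    intensities[:a] = expr.values.loc[annotated_genes].to_numpy()
    n_other = n - a
    junk_base = rng.uniform(lo, hi, n_other)[:, None]
    intensities[a:] = np.exp2(junk_base + rng.normal(0.0, 0.25, (n_other, n_samples)))

    order = rng.permutation(n)
    table = pd.DataFrame(
        {
            "spot_id": [f"spot_{i:06d}" for i in range(n)],
            "probe_id": [f"probe_{i:06d}" for i in order],
            "gene_symbol": gene_symbol[order],
            "is_control": is_control[order],
            "is_identifiable": is_identifiable[order],
            "detection_p": detection_p[order],
        }
    )
    for j, s in enumerate(samples):
        table[s] = intensities[order, j]
    return table, truth


def write_spot_table(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_spot_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", keep_default_na=False, na_values=[])


# ---------------------------------------------------------------------------
# promoters
# ---------------------------------------------------------------------------

_BASES = np.array(list("ACGT"))
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def generate_promoters(
    config: GeneratorConfig,
    truth: Optional[SyntheticTruth] = None,
    positive_ids: Optional[Sequence[str]] = None,
    negative_ids: Optional[Sequence[str]] = None,
    motif: str = NPAS4L_MOTIF,
) -> Tuple[Dict[str, str], SyntheticTruth]:
    """Emit proximal-regulatory sequences with planted motif presence/absence.

    Motif-positive promoters carry at least one exact occurrence of ``motif``
    (an occurrence of its reverse complement on the minus strand also counts);
    motif-negative promoters contain neither the motif nor its reverse
    complement anywhere.  By default positives model conventional endothelial
    genes (non-DEG background genes) and negatives model the ncEC signature
    (shared upregulated genes), mirroring the presence/absence contrast of the
    study design.
    """
    config.validate()
    L = config.promoter_length
    if L < len(motif):
        raise ConfigurationError(
            f"promoter_length {L} is shorter than the motif ({len(motif)} bp)"
        )
    if truth is None:
        _, truth = generate_expression_truth(config)
    rng = _rng(config, _STREAM_PROMOTERS)

    if positive_ids is None:
        deg_any = (
            truth.deg_up[ETSRP]
            | truth.deg_down[ETSRP]
            | truth.deg_up[NPAS4L]
            | truth.deg_down[NPAS4L]
        )
        pool = sorted(truth.non_endoderm_gene_ids - deg_any)
        if config.n_motif_positive > len(pool):
            raise ConfigurationError("not enough background genes for motif positives")
        positive_ids = list(rng.choice(pool, config.n_motif_positive, replace=False))
    if negative_ids is None:
        pool = sorted(truth.shared_up_ids)
        if config.n_motif_negative > len(pool):
            pool = sorted(truth.non_endoderm_gene_ids - set(positive_ids))
        if config.n_motif_negative > len(pool):
            raise ConfigurationError("not enough genes for motif negatives")
        negative_ids = list(rng.choice(pool, config.n_motif_negative, replace=False))
    overlap = set(positive_ids) & set(negative_ids)
    if overlap:
        raise ConfigurationError(
            f"motif positive and negative sets overlap: {sorted(overlap)[:5]}"
        )

    rc = _revcomp(motif)

    def _background() -> str:
        return "".join(_BASES[rng.integers(0, 4, L)])

    promoters: Dict[str, str] = {}
    for gene in positive_ids:
        seq = _background()
        pos = int(rng.integers(0, L - len(motif) + 1))
        promoters[gene] = seq[:pos] + motif + seq[pos + len(motif) :]
    for gene in negative_ids:
        seq = _background()
        while motif in seq or rc in seq:  # rejection resampling
            seq = _background()
        promoters[gene] = seq

    truth.motif_positive_genes = frozenset(positive_ids)
    truth.motif_negative_genes = frozenset(negative_ids)
    return promoters, truth


def promoters_to_genome(
    promoters: Dict[str, str],
    upstream: int,
    spacer: int = 50,
    contig: str = "chrS",
) -> Tuple[Dict[str, str], List[Tuple[str, int, int, str, int, str]]]:
    """Embed promoter sequences in a synthetic contig with BED6 TSS records.

    Genes alternate between strands; extracting ``[tss - upstream, tss)`` on
    '+' (or the mirrored, reverse-complemented window on '-') recovers each
    promoter exactly.  Returns ``(genome, bed_records)`` with BED records as
    ``(chrom, start, end, name, score, strand)`` in 0-based half-open
    coordinates.
    """
    pieces: List[str] = []
    bed: List[Tuple[str, int, int, str, int, str]] = []
    offset = 0
    pad = "T" * spacer  # poly-T spacer cannot create TCGTGA/TCACGA junctions
    for i, (gene, seq) in enumerate(sorted(promoters.items())):
        if len(seq) != upstream:
            raise ValueError(
                f"promoter of {gene} has length {len(seq)}, expected {upstream}"
            )
        pieces.append(pad)
        offset += spacer
        strand = "+" if i % 2 == 0 else "-"
        if strand == "+":
            pieces.append(seq)
            tss = offset + len(seq)  # window [tss - upstream, tss)
        else:
            pieces.append(_revcomp(seq))
            tss = offset - 1  # window [tss + 1, tss + 1 + upstream), revcomp
        bed.append((contig, tss, tss + 1, gene, 0, strand))
        offset += len(seq)
    pieces.append(pad)
    return {contig: "".join(pieces)}, bed


# ---------------------------------------------------------------------------
# qPCR Ct table
# ---------------------------------------------------------------------------

def generate_ct_table(
    config: GeneratorConfig,
    truth: Optional[SyntheticTruth] = None,
) -> Tuple[pd.DataFrame, Optional[SyntheticTruth]]:
    """Synthetic raw Ct table (gene, condition, replicate, ct), long format.

    Reference genes (18S rRNA, kdrl) keep constant Ct across conditions;
    each target's knockdown Ct is shifted by -log2(planted fold), so the
    2^-ddCt analysis recovers ``config.ct_folds`` exactly at zero Ct noise.
    """
    config.validate()
    rng = _rng(config, _STREAM_CT)
    base_ct = {"18S_rRNA": 10.0, "kdrl": 22.0}
    for i, gene in enumerate(config.ct_folds):
        base_ct[gene] = 24.0 + i
    rows = []
    for gene, base in base_ct.items():
        for condition in _CT_CONDITIONS:
            ct = base
            if condition == "npas4l_MO" and gene in config.ct_folds:
                ct = base - float(np.log2(config.ct_folds[gene]))
            for rep in range(config.replicates_per_genotype):
                noise = (
                    rng.normal(0.0, config.ct_noise_sd)
                    if config.ct_noise_sd > 0
                    else 0.0
                )
                rows.append((gene, condition, rep + 1, ct + noise))
    table = pd.DataFrame(rows, columns=["gene", "condition", "replicate", "ct"])
    if truth is not None:
        truth.ct_fold_truth = dict(config.ct_folds)
    return table, truth


# ---------------------------------------------------------------------------
# truth sidecars
# ---------------------------------------------------------------------------

def write_truth(truth: SyntheticTruth, outdir: str | Path) -> List[Path]:
    """Write the planted truth as TSV sidecar files; returns written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: List[Path] = []

    def _w(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        written.append(path)

    _w(
        "truth_endoderm.tsv",
        pd.DataFrame({"gene": sorted(truth.endoderm_gene_ids)}),
    )
    rows = []
    for mutant in sorted(truth.deg_up):
        for gene in sorted(truth.deg_up[mutant]):
            rows.append((gene, mutant, "up", int(gene in truth.shared_up_ids)))
        for gene in sorted(truth.deg_down[mutant]):
            rows.append((gene, mutant, "down", int(gene in truth.shared_down_ids)))
    _w(
        "truth_degs.tsv",
        pd.DataFrame(rows, columns=["gene", "mutant", "direction", "shared"]),
    )
    _w(
        "truth_categories.tsv",
        pd.DataFrame(
            sorted(truth.category_of_gene.items()), columns=["gene", "category"]
        ),
    )
    _w(
        "truth_baseline.tsv",
        truth.baseline_log2.rename_axis("gene").reset_index(),
    )
    if truth.motif_positive_genes or truth.motif_negative_genes:
        rows = [(g, 1) for g in sorted(truth.motif_positive_genes)] + [
            (g, 0) for g in sorted(truth.motif_negative_genes)
        ]
        _w("truth_motif.tsv", pd.DataFrame(rows, columns=["gene", "motif_positive"]))
    if truth.ct_fold_truth:
        _w(
            "truth_ct_folds.tsv",
            pd.DataFrame(
                sorted(truth.ct_fold_truth.items()), columns=["gene", "fold"]
            ),
        )
    return written
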