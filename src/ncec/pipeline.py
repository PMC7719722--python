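"""End-to-end orchestration: simulate -> preprocess -> stats -> DEG -> motif.

Stages communicate through documented file formats only; re-running with the
same configuration and seed reproduces byte-identical artifacts, and every
emitted file is listed in a manifest with its SHA-256 checksum.
"""

from __future__ import annotations

import dataclasses
import hashlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

import pandas as pd

from . import __version__
from .category_stats import (
    category_correlation_matrix,
    modified_histogram,
    quantile_shift,
    whole_transcriptome_mva,
)
from .config import CATEGORIES, ETSRP, GeneratorConfig, MUTANT_LABELS, NPAS4L, NPAS4L_MOTIF, WT
from .deg import build_deg_report, call_degs, intersect_degs, signature_category_breakdown
from .io import write_bed6, write_fasta, write_json, write_yaml
from .matrix import DEFAULT_PSEUDOCOUNT
from .motif import classify_gene_sets, scan_motif
from .preprocess import (
    collapse_and_annotate,
    exclude_endoderm,
    filter_spots,
    quantile_normalize,
)
from .qpcr import ddct
from .synthetic import (
    generate_ct_table,
    generate_promoters,
    generate_spot_table,
    promoters_to_genome,
    write_spot_table,
    write_truth,
)

__all__ = ["RunConfig", "RunSummary", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending context."""


@dataclass(frozen=True)
class RunConfig:
    """All pipeline parameters with the package's declared defaults."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    p_threshold: float = 0.5
    endoderm_fold_threshold: float = 2.0
    deg_fold_threshold: float = 4.0
    bin_size: int = 50
    motif: str = NPAS4L_MOTIF
    pseudocount: float = DEFAULT_PSEUDOCOUNT
    categories: tuple = CATEGORIES

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["categories"] = list(self.categories)
        gen = d["generator"]
        gen["genotypes"] = list(self.generator.genotypes)
        gen["baseline_log2_range"] = list(self.generator.baseline_log2_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        gen = dict(d.pop("generator", {}))
        if "genotypes" in gen:
            gen["genotypes"] = tuple(gen["genotypes"])
        if "baseline_log2_range" in gen:
            gen["baseline_log2_range"] = tuple(gen["baseline_log2_range"])
        if "categories" in d:
            d["categories"] = tuple(d["categories"])
        return cls(generator=GeneratorConfig(**gen), **d)

    def config_hash(self) -> str:
        import json

        canonical = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canonical.encode()).hexdigest()


@dataclass
class RunSummary:
    """Machine-readable record of one pipeline run."""

    version: str
    seed: int
    config_hash: str
    filter_chain: Dict[str, Optional[int]]
    deg_counts: Dict[str, Dict[str, int]]
    intersection: Dict[str, int]
    category_breakdown: Dict[str, int]
    category_correlation: Dict[str, Dict[str, float]]
    whole_transcriptome_mva: Dict[str, float]
    motif_classification: Optional[dict] = None

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()


def _write_df(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: RunConfig, outdir: str | Path) -> RunSummary:
    """Run every stage under ``outdir``; returns the run summary.

    Artifacts are written to ``outdir`` along with ``summary.json`` and a
    ``manifest.json`` listing each file's SHA-256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    gen = config.generator
    written: List[Path] = []

    def _stage(name: str):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name!r} failed: {exc}") from exc

        return _Ctx()

    # ---------------------------------------------------------------- simulate
    with _stage("simulate"):
        spots, truth = generate_spot_table(gen)
        promoters, truth = generate_promoters(gen, truth=truth, motif=config.motif)
        ct_table, truth = generate_ct_table(gen, truth=truth)
        write_spot_table(spots, outdir / "spots.tsv")
        written.append(outdir / "spots.tsv")
        write_fasta(promoters, outdir / "promoters.fasta")
        written.append(outdir / "promoters.fasta")
        genome, bed = promoters_to_genome(promoters, upstream=gen.promoter_length)
        write_fasta(genome, outdir / "genome.fasta")
        written.append(outdir / "genome.fasta")
        write_bed6(bed, outdir / "tss.bed")
        written.append(outdir / "tss.bed")
        _write_df(ct_table, outdir / "ct.tsv", index=False)
        written.append(outdir / "ct.tsv")
        written.extend(write_truth(truth, outdir))

    # -------------------------------------------------------------- preprocess
    with _stage("preprocess"):
        filtered_spots, report = filter_spots(spots, config.p_threshold)
        collapsed, report = collapse_and_annotate(filtered_spots, report)
        normalized = quantile_normalize(collapsed)
        matrix, excluded, report = exclude_endoderm(
            normalized,
            fold_threshold=config.endoderm_fold_threshold,
            pseudocount=config.pseudocount,
            report=report,
        )
        normalized.write_tsv(outdir / "matrix_normalized.tsv")
        written.append(outdir / "matrix_normalized.tsv")
        matrix.write_tsv(outdir / "matrix_filtered.tsv")
        written.append(outdir / "matrix_filtered.tsv")
        _write_df(pd.DataFrame({"gene": excluded}), outdir / "excluded_endoderm.tsv", index=False)
        written.append(outdir / "excluded_endoderm.tsv")
        write_json(report.as_dict(), outdir / "filter_report.json")
        written.append(outdir / "filter_report.json")

    # ------------------------------------------------------------------- stats
    cat_corr_summary: Dict[str, Dict[str, float]] = {}
    with _stage("category_stats"):
        cats = truth.category_of_gene
        for category in config.categories:
            corr = category_correlation_matrix(
                matrix, cats, category, pseudocount=config.pseudocount
            )
            _write_df(corr.scaled, outdir / f"correlation_{category}.tsv")
            written.append(outdir / f"correlation_{category}.tsv")
            shift = quantile_shift(matrix, cats, category, pseudocount=config.pseudocount)
            _write_df(shift.per_gene, outdir / f"quantile_shift_{category}.tsv")
            written.append(outdir / f"quantile_shift_{category}.tsv")
            hist = modified_histogram(
                matrix,
                cats,
                category,
                bin_size=config.bin_size,
                pseudocount=config.pseudocount,
            )
            _write_df(hist.table, outdir / f"histogram_{category}.tsv")
            written.append(outdir / f"histogram_{category}.tsv")
            cat_corr_summary[category] = {
                mut: corr.block_mean(WT, mut) for mut in MUTANT_LABELS
            }
        mva = {
            mut: whole_transcriptome_mva(matrix, WT, mut, config.pseudocount)
            for mut in MUTANT_LABELS
        }
        mva[WT] = whole_transcriptome_mva(matrix, WT, WT, config.pseudocount)

    # --------------------------------------------------------------------- deg
    with _stage("deg"):
        calls = {
            mut: call_degs(
                matrix,
                mutant_label=mut,
                fold_threshold=config.deg_fold_threshold,
                pseudocount=config.pseudocount,
            )
            for mut in MUTANT_LABELS
        }
        inter = intersect_degs(calls[ETSRP], calls[NPAS4L])
        deg_report = build_deg_report(calls, inter)
        _write_df(deg_report, outdir / "deg_report.tsv")
        written.append(outdir / "deg_report.tsv")
        breakdown = signature_category_breakdown(
            inter.shared_up, truth.category_of_gene, categories=config.categories
        )
        ddct_table = ddct(ct_table)
        _write_df(ddct_table, outdir / "ddct.tsv", index=False)
        written.append(outdir / "ddct.tsv")

    # ------------------------------------------------------------------- motif
    with _stage("motif"):
        motif_report = scan_motif(promoters, motif=config.motif, both_strands=True)
        _write_df(motif_report.to_frame(), outdir / "motif_report.tsv", index=False)
        written.append(outdir / "motif_report.tsv")
        classification = classify_gene_sets(
            motif_report,
            truth.motif_positive_genes,
            truth.motif_negative_genes,
            labels=("endothelial_markers", "ncec_signature"),
        )
        _write_df(classification, outdir / "motif_classification.tsv")
        written.append(outdir / "motif_classification.tsv")

    # ----------------------------------------------------------------- summary
    summary = RunSummary(
        version=__version__,
        seed=gen.seed,
        config_hash=config.config_hash(),
        filter_chain=report.as_dict(),
        deg_counts={
            mut: {"up": len(calls[mut].up), "down": len(calls[mut].down)}
            for mut in MUTANT_LABELS
        },
        intersection={
            "shared_up": len(inter.shared_up),
            "shared_down": len(inter.shared_down),
            "total": inter.total,
        },
        category_breakdown=breakdown,
        category_correlation=cat_corr_summary,
        whole_transcriptome_mva=mva,
        motif_classification=classification.to_dict(),
    )
    write_json(summary.to_dict(), outdir / "summary.json")
    written.append(outdir / "summary.json")
    write_yaml(config.to_dict(), outdir / "run_config.yaml")
    written.append(outdir / "run_config.yaml")

    manifest = {
        str(p.relative_to(outdir)): _sha256(p) for p in sorted(set(written))
    }
    write_json(manifest, outdir / "manifest.json")
    return summary
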