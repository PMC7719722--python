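"""Configuration objects for the synthetic four-genotype microarray design.

The default parameter set encodes the study design this package models: a
zebrafish endothelial-cell microarray with triplicate samples of wildtype and
three mutants (*etsrp*, *npas4l*, *sox32*), 37,598 spots of which 11,849 are
identifiable, 11,036 pass the detection p-value filter, 9,713 collapse to
annotated genes, and 7,020 survive the pharyngeal-endoderm exclusion.
Differential-expression truth is planted so that per-mutant calls total
786 up / 1,037 down (etsrp) and 918 up / 1,475 down (npas4l), with an
intersection of 376 up + 555 down = 931 shared transcripts.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, Tuple

__all__ = [
    "ConfigurationError",
    "GeneratorConfig",
    "GENOTYPES",
    "WT",
    "ETSRP",
    "NPAS4L",
    "SOX32",
    "CATEGORIES",
    "OTHER",
    "MUTANT_LABELS",
]

GENOTYPES: Tuple[str, ...] = ("WT", "etsrp_mut", "npas4l_mut", "sox32_mut")
WT, ETSRP, NPAS4L, SOX32 = GENOTYPES
#: the two avascular mutants contrasted against wildtype in the DEG analysis
MUTANT_LABELS: Tuple[str, str] = (ETSRP, NPAS4L)

CATEGORIES: Tuple[str, ...] = ("angiogenesis", "somitogenesis", "neurogenesis")
OTHER = "other"

#: Npas4l consensus binding sequence
NPAS4L_MOTIF = "TCGTGA"


class ConfigurationError(ValueError):
    """Raised when a generator or pipeline configuration is inconsistent."""


def _default_category_sizes() -> Dict[str, int]:
    return {"angiogenesis": 360, "somitogenesis": 420, "neurogenesis": 400}


def _default_category_rank_noise() -> Dict[str, float]:
    # mutant-only perturbation of category members, log2 half-width; the
    # somitogenesis / neurogenesis programmes are the ones destabilised in
    # avascular mutants, angiogenesis is left coherent
    return {"angiogenesis": 0.0, "somitogenesis": 1.2, "neurogenesis": 1.2}


def _default_ct_folds() -> Dict[str, float]:
    # planted qPCR fold changes (knockdown vs control) for the tailbud /
    # ncEC marker genes validated by qRT-PCR; magnitudes are generator
    # conventions, not measured values
    return {"sox3": 2.5, "isl2a": 3.0, "dlx5a": 2.0, "hoxd12a": 4.0}


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the planted-truth synthetic data generator.

    Counts default to the filter-chain and DEG totals of the modelled study
    design (see module docstring).  Effect sizes are on the log2 scale.
    """

    # --- spot-level structure -------------------------------------------------
    n_spots: int = 37598
    n_identifiable: int = 11849
    n_pass_pvalue: int = 11036
    #: passing identifiable spots that are internal controls / lack annotation
    n_control_pass: int = 400
    n_unannotated_pass: int = 423
    n_annotated_genes: int = 9713
    n_non_endoderm: int = 7020

    # --- design ---------------------------------------------------------------
    genotypes: Tuple[str, ...] = GENOTYPES
    replicates_per_genotype: int = 3
    category_sizes: Dict[str, int] = field(default_factory=_default_category_sizes)

    # --- planted DEG truth ----------------------------------------------------
    shared_up: int = 376
    shared_down: int = 555
    unique_up_etsrp: int = 410       # 786 total up in etsrp
    unique_down_etsrp: int = 482     # 1,037 total down in etsrp
    unique_up_npas4l: int = 542      # 918 total up in npas4l
    unique_down_npas4l: int = 920    # 1,475 total down in npas4l
    deg_effect_log2: float = 2.5

    # --- noise / effect model -------------------------------------------------
    category_rank_noise: Dict[str, float] = field(
        default_factory=_default_category_rank_noise
    )
    replicate_noise_sd: float = 0.1
    endoderm_fold: float = 16.0
    #: log2-intensity range of the gene baseline grid (~4 decades)
    baseline_log2_range: Tuple[float, float] = (4.0, 17.3)

    # --- promoters ------------------------------------------------------------
    promoter_length: int = 1000
    n_motif_positive: int = 5
    n_motif_negative: int = 5

    # --- qPCR -----------------------------------------------------------------
    ct_folds: Dict[str, float] = field(default_factory=_default_ct_folds)
    ct_noise_sd: float = 0.15

    seed: int = 0

    # ------------------------------------------------------------------------
    @property
    def n_endoderm(self) -> int:
        return self.n_annotated_genes - self.n_non_endoderm

    @property
    def n_annotated_spots(self) -> int:
        return self.n_pass_pvalue - self.n_control_pass - self.n_unannotated_pass

    @property
    def n_planted_degs(self) -> int:
        return (
            self.shared_up
            + self.shared_down
            + self.unique_up_etsrp
            + self.unique_down_etsrp
            + self.unique_up_npas4l
            + self.unique_down_npas4l
        )

    def sample_labels(self) -> list[str]:
        return [
            f"{g}_{r + 1}"
            for g in self.genotypes
            for r in range(self.replicates_per_genotype)
        ]

    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    # ------------------------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`ConfigurationError` naming the violated constraint."""
        counts = {
            "n_spots": self.n_spots,
            "n_identifiable": self.n_identifiable,
            "n_pass_pvalue": self.n_pass_pvalue,
            "n_control_pass": self.n_control_pass,
            "n_unannotated_pass": self.n_unannotated_pass,
            "n_annotated_genes": self.n_annotated_genes,
            "n_non_endoderm": self.n_non_endoderm,
            "shared_up": self.shared_up,
            "shared_down": self.shared_down,
            "unique_up_etsrp": self.unique_up_etsrp,
            "unique_down_etsrp": self.unique_down_etsrp,
            "unique_up_npas4l": self.unique_up_npas4l,
            "unique_down_npas4l": self.unique_down_npas4l,
        }
        for name, value in counts.items():
            if value < 0:
                raise ConfigurationError(f"{name} must be non-negative, got {value}")
        if self.n_identifiable > self.n_spots:
            raise ConfigurationError(
                "n_identifiable <= n_spots violated: "
                f"{self.n_identifiable} > {self.n_spots}"
            )
        if self.n_pass_pvalue > self.n_identifiable:
            raise ConfigurationError(
                "n_pass_pvalue <= n_identifiable violated: "
                f"{self.n_pass_pvalue} > {self.n_identifiable}"
            )
        if self.n_annotated_spots < self.n_annotated_genes:
            raise ConfigurationError(
                "n_pass_pvalue - n_control_pass - n_unannotated_pass >= "
                "n_annotated_genes violated: "
                f"{self.n_annotated_spots} < {self.n_annotated_genes}"
            )
        if self.n_non_endoderm > self.n_annotated_genes:
            raise ConfigurationError(
                "n_non_endoderm <= n_annotated_genes violated: "
                f"{self.n_non_endoderm} > {self.n_annotated_genes}"
            )
        if sum(self.category_sizes.values()) > self.n_non_endoderm:
            raise ConfigurationError(
                "sum of category_sizes must not exceed n_non_endoderm: "
                f"{sum(self.category_sizes.values())} > {self.n_non_endoderm}"
            )
        if self.n_planted_degs > self.n_non_endoderm:
            raise ConfigurationError(
                "total planted DEGs must not exceed n_non_endoderm: "
                f"{self.n_planted_degs} > {self.n_non_endoderm}"
            )
        if self.replicates_per_genotype < 1:
            raise ConfigurationError("replicates_per_genotype must be >= 1")
        if len(self.genotypes) != len(set(self.genotypes)):
            raise ConfigurationError("genotype labels must be unique")
        if self.deg_effect_log2 < 0:
            raise ConfigurationError("deg_effect_log2 must be >= 0")
        if self.replicate_noise_sd < 0:
            raise ConfigurationError("replicate_noise_sd must be >= 0")
        if self.endoderm_fold < 1:
            raise ConfigurationError("endoderm_fold must be >= 1")
        lo, hi = self.baseline_log2_range
        if not hi > lo:
            raise ConfigurationError("baseline_log2_range must satisfy hi > lo")
        for cat, s in self.category_rank_noise.items():
            if s < 0:
                raise ConfigurationError(
                    f"category_rank_noise[{cat!r}] must be >= 0, got {s}"
                )
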