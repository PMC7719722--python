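"""Consensus-motif scanning of proximal regulatory sequences.

The Npas4l consensus binding site is the hexamer TCGTGA; scanning is exact
substring matching (no position weight matrix), optionally on both strands —
a minus-strand hit is an occurrence of the reverse complement (TCACGA)
reported at its plus-strand offset.  ``N`` bases never match.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, NamedTuple, Optional, Sequence, Tuple

import pandas as pd
from pyfaidx import Fasta

from .config import NPAS4L_MOTIF

__all__ = [
    "MotifError",
    "MotifHit",
    "MotifReport",
    "PromoterSet",
    "scan_motif",
    "extract_promoters",
    "classify_gene_sets",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_SEQ_ALPHABET = re.compile(r"^[ACGTN]+$")
_MOTIF_ALPHABET = re.compile(r"^[ACGT]+$")


class MotifError(ValueError):
    """Raised on malformed sequences, motifs or BED records."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class MotifHit(NamedTuple):
    offset: int      # 0-based plus-strand offset of the matched hexamer
    strand: str      # '+' or '-'
    matched: str     # the plus-strand sequence at the hit


@dataclass
class PromoterSet:
    """Gene -> proximal regulatory sequence, with optional genomic intervals
    (0-based half-open) and truncation flags for contig-edge windows."""

    sequences: Dict[str, str]
    intervals: Dict[str, Tuple[str, int, int, str]] = field(default_factory=dict)
    truncated: frozenset = frozenset()

    def __post_init__(self) -> None:
        for gene, seq in self.sequences.items():
            if not seq:
                raise MotifError(f"promoter of {gene!r} is empty")
            if not _SEQ_ALPHABET.match(seq.upper()):
                raise MotifError(f"promoter of {gene!r} has characters outside ACGTN")
        for gene, (_, start, end, _) in self.intervals.items():
            if end <= start:
                raise MotifError(f"interval of {gene!r} has end <= start")

    def __iter__(self):
        return iter(self.sequences)

    def __len__(self) -> int:
        return len(self.sequences)

    def __getitem__(self, gene: str) -> str:
        return self.sequences[gene]


@dataclass
class MotifReport:
    """Hits per scanned gene plus the scan parameters."""

    motif: str
    both_strands: bool
    hits: Dict[str, List[MotifHit]]

    def present(self, gene: str) -> bool:
        return bool(self.hits[gene])

    @property
    def positive_genes(self) -> frozenset:
        return frozenset(g for g, h in self.hits.items() if h)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for gene in sorted(self.hits):
            hits = self.hits[gene]
            rows.append(
                {
                    "gene": gene,
                    "n_hits": len(hits),
                    "presence": int(bool(hits)),
                    "offsets": ",".join(str(h.offset) for h in hits),
                    "strands": ",".join(h.strand for h in hits),
                }
            )
        return pd.DataFrame(rows, columns=["gene", "n_hits", "presence", "offsets", "strands"])


def _find_all(haystack: str, needle: str) -> List[int]:
    """All (overlapping) occurrence offsets of needle in haystack."""
    out, start = [], haystack.find(needle)
    while start != -1:
        out.append(start)
        start = haystack.find(needle, start + 1)
    return out


def scan_motif(
    promoters: PromoterSet | Mapping[str, str],
    motif: str = NPAS4L_MOTIF,
    both_strands: bool = True,
) -> MotifReport:
    """Report every exact occurrence of the motif in each promoter.

    Overlapping occurrences are all reported; sequences shorter than the
    motif yield zero hits.  With ``both_strands``, occurrences of the reverse
    complement are reported with strand ``'-'`` at their plus-strand offset.
    """
    motif = motif.upper()
    if not motif or not _MOTIF_ALPHABET.match(motif):
        raise MotifError(f"motif must be non-empty over ACGT, got {motif!r}")
    sequences = (
        promoters.sequences if isinstance(promoters, PromoterSet) else dict(promoters)
    )
    rc = reverse_complement(motif)
    hits: Dict[str, List[MotifHit]] = {}
    for gene, seq in sequences.items():
        seq_u = seq.upper()
        gene_hits = [MotifHit(o, "+", motif) for o in _find_all(seq_u, motif)]
        if both_strands and rc != motif:
            gene_hits += [MotifHit(o, "-", rc) for o in _find_all(seq_u, rc)]
        elif both_strands and rc == motif:
            # palindromic motif: each site is one physical occurrence
            pass
        hits[gene] = sorted(gene_hits)
    return MotifReport(motif=motif, both_strands=both_strands, hits=hits)


# ---------------------------------------------------------------------------
# promoter extraction
# ---------------------------------------------------------------------------

BedRecord = Tuple[str, int, int, str, int, str]


def read_bed6(path: str | Path) -> List[BedRecord]:
    records: List[BedRecord] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise MotifError(f"BED6 record has {len(parts)} fields: {line!r}")
            chrom, start, end, name, score, strand = parts[:6]
            records.append((chrom, int(start), int(end), name, int(float(score)), strand))
    return records


def extract_promoters(
    tss: Sequence[BedRecord] | str | Path,
    genome: Mapping[str, str] | str | Path,
    upstream: int = 5000,
    downstream: int = 1000,
) -> PromoterSet:
    """Extract proximal windows around TSS records (BED, 0-based half-open).

    A plus-strand TSS at position *t* yields ``[t - upstream, t + downstream)``;
    a minus-strand TSS yields the mirrored window
    ``[t - downstream + 1, t + upstream + 1)``, reverse-complemented.  Windows
    are clamped at contig edges and flagged as truncated.
    """
    if upstream < 0 or downstream < 0:
        raise MotifError("upstream and downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise MotifError("upstream and downstream cannot both be 0")
    if isinstance(tss, (str, Path)):
        tss = read_bed6(tss)
    if isinstance(genome, (str, Path)):
        fasta = Fasta(str(genome), as_raw=True, sequence_always_upper=True)
        contigs: Mapping[str, str] = {name: str(fasta[name][:]) for name in fasta.keys()}
    else:
        contigs = {k: v.upper() for k, v in genome.items()}

    sequences: Dict[str, str] = {}
    intervals: Dict[str, Tuple[str, int, int, str]] = {}
    truncated = set()
    for chrom, start, end, name, _score, strand in tss:
        if chrom not in contigs:
            raise MotifError(f"TSS record {name!r}: contig {chrom!r} not in genome")
        contig = contigs[chrom]
        t = start if strand == "+" else end - 1
        if not 0 <= t < len(contig):
            raise MotifError(
                f"TSS record {name!r}: position {t} outside contig {chrom!r} "
                f"of length {len(contig)}"
            )
        if strand == "+":
            lo, hi = t - upstream, t + downstream
        elif strand == "-":
            lo, hi = t - downstream + 1, t + upstream + 1
        else:
            raise MotifError(f"TSS record {name!r}: bad strand {strand!r}")
        clo, chi = max(lo, 0), min(hi, len(contig))
        if (clo, chi) != (lo, hi):
            truncated.add(name)
        seq = contig[clo:chi]
        if strand == "-":
            seq = reverse_complement(seq)
        sequences[name] = seq
        intervals[name] = (chrom, clo, chi, strand)
    return PromoterSet(
        sequences=sequences, intervals=intervals, truncated=frozenset(truncated)
    )


# ---------------------------------------------------------------------------
# presence classification
# ---------------------------------------------------------------------------

def classify_gene_sets(
    report: MotifReport,
    set_a: Iterable[str],
    set_b: Iterable[str],
    labels: Tuple[str, str] = ("set_a", "set_b"),
) -> pd.DataFrame:
    """2x2 motif presence/absence table for two gene sets.

    Rows are the sets, columns ``motif_positive`` / ``motif_negative`` plus a
    ``fraction_positive`` column.  Genes missing from the scan report raise
    :class:`MotifError`.
    """
    rows = []
    for label, genes in zip(labels, (set_a, set_b)):
        genes = sorted(set(genes))
        missing = [g for g in genes if g not in report.hits]
        if missing:
            raise MotifError(f"genes absent from motif report: {missing[:10]}")
        pos = sum(1 for g in genes if report.present(g))
        neg = len(genes) - pos
        rows.append(
            {
                "set": label,
                "motif_positive": pos,
                "motif_negative": neg,
                "fraction_positive": pos / len(genes) if genes else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("set")
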