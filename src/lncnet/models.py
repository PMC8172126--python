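"""Genomic feature models shared across modules.

Coordinates are 0-based half-open internally; GTF I/O converts at the
boundary (see :mod:`lncnet.gtf`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded interval on a chromosome (0-based, half-open)."""

    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.strand not in STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_bp(self, other: "GenomicInterval") -> int:
        """Overlapping base pairs with ``other``, ignoring strand."""
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )


@dataclass
class TranscriptModel:
    """An exon-structured transcript.

    Exons are normalized to ascending start order and must be disjoint,
    on a single chromosome and strand.
    """

    transcript_id: str
    gene_id: str
    exons: list[GenomicInterval]
    biotype: str = "coding"

    def __post_init__(self) -> None:
        if not self.exons:
            raise ValueError(f"{self.transcript_id}: transcript has no exons")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        chroms = {e.chrom for e in self.exons}
        strands = {e.strand for e in self.exons}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(
                f"{self.transcript_id}: exons span multiple chromosomes/strands"
            )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValueError(
                    f"{self.transcript_id}: overlapping exons "
                    f"{a.start}-{a.end} and {b.start}-{b.end}"
                )

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def strand(self) -> str:
        return self.exons[0].strand

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def length(self) -> int:
        """Total exonic length (mature transcript length)."""
        return sum(e.length for e in self.exons)

    @property
    def span(self) -> GenomicInterval:
        """Genomic footprint from first to last exon."""
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        """Transcription start position (strand-aware, 0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def introns(self) -> list[GenomicInterval]:
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


@dataclass
class GeneModel:
    """A gene as the union of its transcripts."""

    gene_id: str
    transcripts: list[TranscriptModel] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.transcripts:
            raise ValueError(f"{self.gene_id}: gene has no transcripts")
        chroms = {t.chrom for t in self.transcripts}
        strands = {t.strand for t in self.transcripts}
        if len(chroms) != 1 or len(strands) != 1:
            raise ValueError(f"{self.gene_id}: transcripts disagree on locus")

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom

    @property
    def strand(self) -> str:
        return self.transcripts[0].strand

    @property
    def start(self) -> int:
        return min(t.start for t in self.transcripts)

    @property
    def end(self) -> int:
        return max(t.end for t in self.transcripts)

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)

    @property
    def tss(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    def merged_exons(self) -> list[GenomicInterval]:
        """Union of exons over transcripts, merged into disjoint intervals."""
        exons = sorted(
            (e for t in self.transcripts for e in t.exons), key=lambda e: e.start
        )
        merged: list[list[int]] = []
        for e in exons:
            if merged and e.start <= merged[-1][1]:
                merged[-1][1] = max(merged[-1][1], e.end)
            else:
                merged.append([e.start, e.end])
        return [
            GenomicInterval(self.chrom, s, e, self.strand) for s, e in merged
        ]

    def introns(self) -> list[GenomicInterval]:
        """Gaps between merged exons (gene-level introns)."""
        merged = self.merged_exons()
        out = []
        for a, b in zip(merged, merged[1:]):
            out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return out


def genes_from_transcripts(
    transcripts: Iterable[TranscriptModel],
) -> list[GeneModel]:
    """Group transcripts by ``gene_id`` into :class:`GeneModel` objects.

    Output is sorted by (chrom, start, gene_id) so downstream consumers
    are independent of input order.
    """
    by_gene: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_gene.setdefault(t.gene_id, []).append(t)
    genes = [GeneModel(gid, ts) for gid, ts in by_gene.items()]
    genes.sort(key=lambda g: (g.chrom, g.start, g.gene_id))
    return genes


def exonic_overlap_bp(
    a_exons: Sequence[GenomicInterval], b_exons: Sequence[GenomicInterval]
) -> int:
    """Total overlapping bp between two exon chains (strand-blind)."""
    total = 0
    for ea in a_exons:
        for eb in b_exons:
            total += ea.overlap_bp(eb)
    return total
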