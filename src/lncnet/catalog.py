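"""Novel-transcript filtering, consensus lncRNA calling and positional
classification of lncRNAs relative to coding genes.

Classification applies a fixed precedence of geometric rules; the first
match wins:

1. ``intronic``           wholly inside one intron of a coding gene, any strand
2. ``antisense``          exonic overlap >= 1 bp, opposite strand
3. ``sense_overlapping``  exonic overlap >= 1 bp, same strand, lncRNA not
                          contained within the gene's exons
4. ``bidirectional``      no gene-body overlap, divergent orientation,
                          TSS-to-TSS distance <= window (default 1 kb)
5. ``intergenic``         no gene-body overlap, not bidirectional
6. ``other``              anything remaining (e.g. same-strand gene-body
                          overlap that touches no exon)

Genes are sorted internally, so results never depend on input order.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

from .models import GeneModel, TranscriptModel, exonic_overlap_bp

POSITIONAL_CLASSES = (
    "intergenic",
    "bidirectional",
    "intronic",
    "antisense",
    "sense_overlapping",
    "other",
)

#: Classes planted by the synthetic generator (everything but "other").
PLANTABLE_CLASSES = POSITIONAL_CLASSES[:5]


@dataclass(frozen=True)
class CodingPotentialCall:
    """Consensus inputs for one candidate transcript."""

    transcript_id: str
    cnci_noncoding: bool
    cpc_noncoding: bool
    swissprot_hit: bool


@dataclass(frozen=True)
class LncRNAAnnotation:
    transcript_id: str
    positional_class: str
    partner_gene_id: Optional[str] = None
    partner_distance_bp: Optional[int] = None


def filter_novel_transcripts(
    transcripts: Iterable[TranscriptModel],
    min_length_bp: int = 200,
    min_exons: int = 2,
) -> list[TranscriptModel]:
    """Keep transcripts with exonic length >= ``min_length_bp`` and exon
    count >= ``min_exons`` (both boundaries inclusive)."""
    return [
        t
        for t in transcripts
        if t.length >= min_length_bp and t.n_exons >= min_exons
    ]


def consensus_lncrna_call(calls: Iterable[CodingPotentialCall]) -> set[str]:
    """Ids called non-coding by both predictors and lacking a protein hit."""
    seen: set[str] = set()
    out: set[str] = set()
    for c in calls:
        if c.transcript_id in seen:
            raise ValueError(f"duplicate coding-potential call: {c.transcript_id}")
        seen.add(c.transcript_id)
        if c.cnci_noncoding and c.cpc_noncoding and not c.swissprot_hit:
            out.add(c.transcript_id)
    return out


def _sorted_genes(genes: Iterable[GeneModel]) -> list[GeneModel]:
    return sorted(genes, key=lambda g: (g.chrom, g.start, g.gene_id))


def _is_divergent(gene: GeneModel, lnc: TranscriptModel) -> bool:
    """Head-to-head orientation: the two transcribe away from each other."""
    if gene.strand == lnc.strand:
        return False
    if gene.strand == "+":
        return lnc.tss <= gene.tss
    return lnc.tss >= gene.tss


def classify_lncrna(
    lncrna: TranscriptModel,
    coding_genes: Sequence[GeneModel],
    bidirectional_window_bp: int = 1000,
) -> LncRNAAnnotation:
    """Assign exactly one positional class (total function)."""
    genes = [
        g for g in _sorted_genes(coding_genes) if g.chrom == lncrna.chrom
    ]
    span = None if not genes else lncrna.span

    # 1. intronic: wholly inside one gene-level intron, any strand
    for g in genes:
        for intron in g.introns():
            if intron.start <= lncrna.start and lncrna.end <= intron.end:
                return LncRNAAnnotation(
                    lncrna.transcript_id, "intronic", g.gene_id, None
                )

    # 2. antisense / 3. sense_overlapping: exon-level overlap
    for g in genes:
        if g.strand == lncrna.strand:
            continue
        if exonic_overlap_bp(lncrna.exons, g.merged_exons()) >= 1:
            return LncRNAAnnotation(
                lncrna.transcript_id, "antisense", g.gene_id, None
            )
    for g in genes:
        if g.strand != lncrna.strand:
            continue
        gene_exons = g.merged_exons()
        if exonic_overlap_bp(lncrna.exons, gene_exons) >= 1:
            contained = all(
                any(ge.contains(le) for ge in gene_exons) for le in lncrna.exons
            )
            if not contained:
                return LncRNAAnnotation(
                    lncrna.transcript_id, "sense_overlapping", g.gene_id, None
                )

    overlaps_body = any(span.overlap_bp(g.span) > 0 for g in genes) if genes else False

    # 4. bidirectional: divergent promoter pair within the window
    if not overlaps_body:
        for g in genes:
            d = abs(lncrna.tss - g.tss)
            if d <= bidirectional_window_bp and _is_divergent(g, lncrna):
                return LncRNAAnnotation(
                    lncrna.transcript_id, "bidirectional", g.gene_id, d
                )
        # 5. intergenic
        return LncRNAAnnotation(lncrna.transcript_id, "intergenic", None, None)

    # 6. other: gene-body overlap not matching any rule above
    return LncRNAAnnotation(lncrna.transcript_id, "other", None, None)


def classify_catalog(
    lncrnas: Iterable[TranscriptModel],
    coding_genes: Sequence[GeneModel],
    bidirectional_window_bp: int = 1000,
) -> list[LncRNAAnnotation]:
    return [
        classify_lncrna(t, coding_genes, bidirectional_window_bp)
        for t in sorted(lncrnas, key=lambda t: t.transcript_id)
    ]


# -- TSV plumbing -----------------------------------------------------------

def read_coding_calls(path: str | Path) -> list[CodingPotentialCall]:
    """Read a TSV with columns transcript_id, cnci_noncoding, cpc_noncoding,
    swissprot_hit (boolean-ish values: 1/0/true/false)."""

    def _bool(v: str) -> bool:
        return v.strip().lower() in {"1", "true", "t", "yes"}

    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                CodingPotentialCall(
                    row["transcript_id"],
                    _bool(row["cnci_noncoding"]),
                    _bool(row["cpc_noncoding"]),
                    _bool(row["swissprot_hit"]),
                )
            )
    return out


def write_catalog(annotations: Iterable[LncRNAAnnotation], path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["transcript_id", "class", "partner_gene", "distance"])
        for a in annotations:
            w.writerow(
                [
                    a.transcript_id,
                    a.positional_class,
                    a.partner_gene_id or "",
                    "" if a.partner_distance_bp is None else a.partner_distance_bp,
                ]
            )


def read_catalog(path: str | Path) -> list[LncRNAAnnotation]:
    out = []
    with open(path) as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        for row in reader:
            out.append(
                LncRNAAnnotation(
                    row["transcript_id"],
                    row["class"],
                    row["partner_gene"] or None,
                    int(row["distance"]) if row["distance"] else None,
                )
            )
    return out
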