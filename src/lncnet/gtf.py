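"""Minimal GTF reader/writer for exon features.

Only ``exon`` records are consumed; attributes ``gene_id`` and
``transcript_id`` are required, ``transcript_biotype`` is honored when
present. GTF coordinates (1-based, closed) are converted to the internal
0-based half-open convention on read and back on write, so a
write -> read round trip is the identity.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable

from .models import GenomicInterval, TranscriptModel

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')


class GtfParseError(ValueError):
    """Raised on malformed GTF records that cannot be skipped safely."""


def parse_attributes(field: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(field))


def read_gtf(path: str | Path) -> list[TranscriptModel]:
    """Read exon features from a GTF file into transcript models.

    Raises
    ------
    GtfParseError
        If an exon record lacks a ``transcript_id`` attribute (the line
        number is reported). Records with ``end < start`` are rejected
        and logged, not fatal.
    """
    exons: dict[str, list[GenomicInterval]] = {}
    meta: dict[str, tuple[str, str]] = {}
    order: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GtfParseError(f"line {lineno}: expected 9 fields")
            chrom, _source, feature, start, end, _score, strand, _frame, attrs = fields
            if feature != "exon":
                continue
            attributes = parse_attributes(attrs)
            if "transcript_id" not in attributes:
                raise GtfParseError(
                    f"line {lineno}: exon record missing transcript_id"
                )
            start_i, end_i = int(start), int(end)
            if end_i < start_i:
                logger.warning(
                    "line %d: rejected exon with end < start (%d < %d)",
                    lineno,
                    end_i,
                    start_i,
                )
                continue
            tid = attributes["transcript_id"]
            gid = attributes.get("gene_id", tid)
            biotype = attributes.get("transcript_biotype", "coding")
            # GTF 1-based closed -> 0-based half-open
            iv = GenomicInterval(chrom, start_i - 1, end_i, strand)
            if tid not in exons:
                exons[tid] = []
                order.append(tid)
            exons[tid].append(iv)
            meta[tid] = (gid, biotype)
    return [
        TranscriptModel(tid, meta[tid][0], exons[tid], biotype=meta[tid][1])
        for tid in order
    ]


def write_gtf(
    transcripts: Iterable[TranscriptModel],
    path: str | Path,
    source: str = "lncnet",
) -> None:
    """Write exon features; output order is sorted, hence deterministic."""
    ts = sorted(transcripts, key=lambda t: (t.chrom, t.start, t.transcript_id))
    with open(path, "w") as fh:
        for t in ts:
            for e in t.exons:
                attrs = (
                    f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}"; '
                    f'transcript_biotype "{t.biotype}";'
                )
                fh.write(
                    "\t".join(
                        [
                            e.chrom,
                            source,
                            "exon",
                            str(e.start + 1),
                            str(e.end),
                            ".",
                            e.strand,
                            ".",
                            attrs,
                        ]
                    )
                    + "\n"
                )
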