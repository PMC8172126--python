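"""lncRNA target prediction by three mechanisms.

antisense : exon-level overlap on the opposite strand (>= 1 bp)
cis       : same chromosome, no gene-body overlap, boundary-to-boundary
            distance strictly below the window (default 100 kb)
trans     : |Pearson r| >= r_min (default 0.9) on log2(FPKM + 1)

antisense and cis are disjoint by construction because cis excludes
overlapping pairs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .models import GeneModel, TranscriptModel, exonic_overlap_bp

logger = logging.getLogger(__name__)

MECHANISMS = ("antisense", "cis", "trans")


@dataclass(frozen=True)
class TargetPair:
    lncrna_id: str
    gene_id: str
    mechanism: str
    evidence: float  # overlap bp | distance bp | correlation r
    sign: Optional[str] = None  # trans only: "positive"/"negative"


def antisense_pairs(
    lncrnas: Iterable[TranscriptModel],
    coding_genes: Sequence[GeneModel],
) -> list[TargetPair]:
    """Pairs with >= 1 bp exonic overlap on opposite strands."""
    out = []
    genes = sorted(coding_genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    for lnc in sorted(lncrnas, key=lambda t: t.transcript_id):
        for g in genes:
            if g.chrom != lnc.chrom or g.strand == lnc.strand:
                continue
            ov = exonic_overlap_bp(lnc.exons, g.merged_exons())
            if ov >= 1:
                out.append(
                    TargetPair(lnc.transcript_id, g.gene_id, "antisense", float(ov))
                )
    return out


def cis_pairs(
    lncrnas: Iterable[TranscriptModel],
    coding_genes: Sequence[GeneModel],
    window_bp: int = 100_000,
) -> list[TargetPair]:
    """Non-overlapping neighbors with boundary distance < window (strict)."""
    out = []
    genes = sorted(coding_genes, key=lambda g: (g.chrom, g.start, g.gene_id))
    for lnc in sorted(lncrnas, key=lambda t: t.transcript_id):
        for g in genes:
            if g.chrom != lnc.chrom:
                continue
            if lnc.span.overlap_bp(g.span) > 0:
                continue
            if lnc.end <= g.start:
                dist = g.start - lnc.end
            else:
                dist = lnc.start - g.end
            if dist < window_bp:
                out.append(
                    TargetPair(lnc.transcript_id, g.gene_id, "cis", float(dist))
                )
    return out


def trans_pairs(
    lncrna_fpkm: pd.DataFrame,
    mrna_fpkm: pd.DataFrame,
    r_min: float = 0.9,
    log_transform: bool = True,
) -> list[TargetPair]:
    """Expression-correlated pairs with |r| >= r_min (inclusive).

    Pearson correlation is computed across matched sample columns on
    log2(FPKM + 1) by default. Zero-variance series are skipped (logged).
    """
    common = [c for c in lncrna_fpkm.columns if c in set(mrna_fpkm.columns)]
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples for trans correlation")
    x = lncrna_fpkm[common].to_numpy(dtype=float)
    y = mrna_fpkm[common].to_numpy(dtype=float)
    if log_transform:
        x, y = np.log2(x + 1.0), np.log2(y + 1.0)

    sx = x.std(axis=1)
    sy = y.std(axis=1)
    for which, ids, sd in (
        ("lncRNA", lncrna_fpkm.index, sx),
        ("mRNA", mrna_fpkm.index, sy),
    ):
        flat = [i for i, s in zip(ids, sd) if s == 0]
        if flat:
            logger.warning("skipping %d zero-variance %s series", len(flat), which)

    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc @ yc.T) / np.outer(
            np.sqrt((xc**2).sum(axis=1)), np.sqrt((yc**2).sum(axis=1))
        )

    out = []
    lnc_ids = lncrna_fpkm.index.to_numpy(dtype=object)
    mrna_ids = mrna_fpkm.index.to_numpy(dtype=object)
    for i in range(len(lnc_ids)):
        if sx[i] == 0:
            continue
        for j in range(len(mrna_ids)):
            if sy[j] == 0:
                continue
            rij = r[i, j]
            if np.isfinite(rij) and abs(rij) >= r_min:
                out.append(
                    TargetPair(
                        str(lnc_ids[i]),
                        str(mrna_ids[j]),
                        "trans",
                        float(rij),
                        "positive" if rij > 0 else "negative",
                    )
                )
    return out


def pairs_to_frame(pairs: Iterable[TargetPair]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "lncrna_id": p.lncrna_id,
                "gene_id": p.gene_id,
                "mechanism": p.mechanism,
                "evidence": p.evidence,
                "sign": p.sign or "",
            }
            for p in pairs
        ],
        columns=["lncrna_id", "gene_id", "mechanism", "evidence", "sign"],
    )
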