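"""Relative quantification (2^-ddCt) and read-retention summaries."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import pandas as pd

from .stats import round_half_up


def ddct_quantify(
    records: pd.DataFrame,
    calibrator_sample: str,
) -> pd.DataFrame:
    """2^-ddCt relative quantities per sample.

    ``records`` needs columns sample_id, ct_target, ct_reference; rows
    with the same sample_id are treated as technical replicates and
    averaged before dCt. dCt = ct_target - ct_reference,
    ddCt = dCt_sample - dCt_calibrator, RQ = 2^-ddCt; the calibrator's
    RQ is 1 by construction.
    """
    for col in ("ct_target", "ct_reference"):
        missing = records.loc[records[col].isna(), "sample_id"]
        if len(missing):
            raise ValueError(
                f"missing {col} for sample(s): {sorted(set(missing))}"
            )
    means = records.groupby("sample_id")[["ct_target", "ct_reference"]].mean()
    if calibrator_sample not in means.index:
        raise ValueError(f"calibrator sample {calibrator_sample!r} not present")
    dct = means["ct_target"] - means["ct_reference"]
    ddct = dct - dct.loc[calibrator_sample]
    out = pd.DataFrame(
        {"delta_ct": dct, "ddct": ddct, "rq": 2.0 ** (-ddct)}
    )
    out.index.name = "sample_id"
    return out


@dataclass(frozen=True)
class ReadStats:
    raw_reads: int
    clean_reads: int
    hq_reads: int
    retained_pct: float
    rrna_free_pct: Optional[float] = None
    mapped_pct: Optional[float] = None


def _pct(num: int, den: int) -> float:
    return round_half_up(100.0 * num / den, 2)


def summarize_read_stats(
    raw_reads: int,
    clean_reads: int,
    hq_reads: int,
    rrna_free_reads: Optional[int] = None,
    mapped_reads: Optional[int] = None,
) -> ReadStats:
    """Sequencing overview percentages, rounded half-up to 2 decimals.

    retained_pct  = 100 * hq / clean
    rrna_free_pct = 100 * rrna_free / hq    (when supplied)
    mapped_pct    = 100 * mapped / rrna_free (when supplied)
    """
    if clean_reads <= 0:
        raise ValueError("clean_reads must be positive")
    if raw_reads <= 0 or hq_reads <= 0:
        raise ValueError("read counts must be positive")
    if hq_reads > clean_reads:
        raise ValueError("hq_reads cannot exceed clean_reads")
    rrna_pct = (
        _pct(rrna_free_reads, hq_reads) if rrna_free_reads is not None else None
    )
    mapped_pct = None
    if mapped_reads is not None:
        den = rrna_free_reads if rrna_free_reads is not None else hq_reads
        mapped_pct = _pct(mapped_reads, den)
    return ReadStats(
        raw_reads=raw_reads,
        clean_reads=clean_reads,
        hq_reads=hq_reads,
        retained_pct=_pct(hq_reads, clean_reads),
        rrna_free_pct=rrna_pct,
        mapped_pct=mapped_pct,
    )
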