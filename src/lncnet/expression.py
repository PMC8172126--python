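"""FPKM normalization, a documented stand-in differential test, and the
fold-change / FDR gates.

The differential test is deliberately simple and isolated behind
:func:`de_test`: a Welch two-sample comparison on log2(FPKM + 1), not a
negative-binomial GLM. It is a stand-in suitable for the planted-effect
recovery experiments this package ships with; swap in another test via
the same interface if calibrated inference on real data is needed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

STAGES = ("IV", "V", "VI")

#: pseudocount used for fold-change ratios
FC_EPSILON = 0.01


@dataclass
class CountMatrix:
    """Integer fragment counts (transcripts x samples) plus lengths.

    ``counts`` index = transcript ids, columns = sample ids;
    ``lengths`` maps transcript id -> mature length in bp.
    ``library_sizes`` defaults to the column sums of ``counts``; pass the
    whole-library per-sample totals instead when this matrix is one
    biotype's slice of a larger library (the "per million mapped"
    denominator then reflects the full sample).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    library_sizes: pd.Series | None = None

    def __post_init__(self) -> None:
        c = self.counts
        if (c.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        missing = c.index.difference(self.lengths.index)
        if len(missing):
            raise ValueError(f"lengths missing for {list(missing)[:5]}")
        if (self.lengths.loc[c.index] <= 0).any():
            raise ValueError("transcript lengths must be positive")
        self.lengths = self.lengths.loc[c.index].astype(float)
        if self.library_sizes is None:
            self.library_sizes = c.sum(axis=0)
        else:
            missing_cols = c.columns.difference(self.library_sizes.index)
            if len(missing_cols):
                raise ValueError(f"library sizes missing for {list(missing_cols)}")
            self.library_sizes = self.library_sizes.loc[c.columns].astype(float)


def compute_fpkm(matrix: CountMatrix) -> pd.DataFrame:
    """FPKM_ts = 1e9 * C_ts / (N_s * L_t)."""
    N = matrix.library_sizes
    zero = N[N == 0]
    if len(zero):
        raise ValueError(f"zero library size for sample(s): {list(zero.index)}")
    return 1e9 * matrix.counts.div(N, axis=1).div(matrix.lengths, axis=0)


def _stage_columns(design: pd.DataFrame, stage: str) -> list[str]:
    cols = design.loc[design["stage"] == stage, "sample_id"].tolist()
    if not cols:
        raise ValueError(f"unknown stage label: {stage!r}")
    return cols


def de_test(
    fpkm: pd.DataFrame,
    design: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    epsilon: float = FC_EPSILON,
) -> pd.DataFrame:
    """Per-transcript log2 fold change (B over A) and Welch p-value.

    log2fc = log2((mean_B FPKM + eps) / (mean_A FPKM + eps)); the p-value
    comes from a Welch comparison of log2(FPKM + 1) between the groups.
    Transcripts with zero variance in both groups get p = 1 when the
    group means agree and p = 0 otherwise.
    """
    cols_a = _stage_columns(design, stage_a)
    cols_b = _stage_columns(design, stage_b)
    if len(cols_a) < 2 or len(cols_b) < 2:
        raise ValueError("both stages need >= 2 replicates")

    a = fpkm[cols_a].to_numpy(dtype=float)
    b = fpkm[cols_b].to_numpy(dtype=float)

    log2fc = np.log2((b.mean(axis=1) + epsilon) / (a.mean(axis=1) + epsilon))

    la, lb = np.log2(a + 1.0), np.log2(b + 1.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.ttest_ind(lb, la, axis=1, equal_var=False)
        pvals = np.asarray(res.pvalue, dtype=float)

    both_flat = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
    pvals = np.where(both_flat & equal_means, 1.0, pvals)
    pvals = np.where(both_flat & ~equal_means, 0.0, pvals)
    pvals = np.nan_to_num(pvals, nan=1.0)

    return pd.DataFrame(
        {"log2fc": log2fc, "pvalue": pvals}, index=fpkm.index
    )


def classify_de(
    records: pd.DataFrame,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    use_pvalue: bool = False,
    p_max: float = 0.05,
) -> pd.Series:
    """Status labels: up / down / ns.

    up iff log2fc >= log2(fc_min) (inclusive) and the gate passes;
    down mirrors with <= -log2(fc_min). The gate is fdr < fdr_max
    (strict), or pvalue < p_max in ``use_pvalue`` mode (the miRNA rule).
    """
    lfc_min = np.log2(fc_min)
    if use_pvalue:
        gate = records["pvalue"] < p_max
    else:
        gate = records["fdr"] < fdr_max
    status = np.where(
        gate & (records["log2fc"] >= lfc_min),
        "up",
        np.where(gate & (records["log2fc"] <= -lfc_min), "down", "ns"),
    )
    return pd.Series(status, index=records.index, name="status")


def de_analysis(
    matrix: CountMatrix,
    design: pd.DataFrame,
    stage_a: str,
    stage_b: str,
    fc_min: float = 2.0,
    fdr_max: float = 0.05,
    use_pvalue: bool = False,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Full DE table for one comparison: FPKM -> test -> BH -> gates."""
    fpkm = compute_fpkm(matrix)
    rec = de_test(fpkm, design, stage_a, stage_b)
    rec["fdr"] = bh_adjust(rec["pvalue"].to_numpy())
    rec["status"] = classify_de(
        rec, fc_min=fc_min, fdr_max=fdr_max, use_pvalue=use_pvalue, p_max=p_max
    )
    rec.insert(0, "comparison", f"{stage_a}_vs_{stage_b}")
    rec.index.name = "transcript_id"
    return rec


# -- I/O --------------------------------------------------------------------

def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "stage": str})
    validate_design(design)
    return design


def validate_design(design: pd.DataFrame) -> None:
    if design["sample_id"].duplicated().any():
        raise ValueError("duplicate sample ids in design")
    counts = design["stage"].value_counts()
    if (counts < 2).any():
        bad = counts[counts < 2].index.tolist()
        raise ValueError(f"stage(s) with < 2 replicates: {bad}")


def write_de_table(records: pd.DataFrame, path) -> None:
    records.to_csv(path, sep="\t")
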