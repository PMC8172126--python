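"""Competing-endogenous-RNA network inference.

Candidate miRNA-target interactions come from a canonical seed match
(8mer / 7mer-m8 / 7mer-A1), optionally replaced by an externally supplied
candidate table. Candidates are filtered by Spearman correlation
(SCC < -0.7, strict), lncRNA-mRNA pairs by Pearson correlation
(PCC > 0.9, strict), and shared-miRNA sponging is scored with the same
hypergeometric upper-tail engine used for over-representation analysis.
All thresholds are strict inequalities, as printed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import hypergeom_tail

logger = logging.getLogger(__name__)

SITE_TYPES = ("8mer", "7mer-m8", "7mer-A1")
_SITE_RANK = {s: i for i, s in enumerate(SITE_TYPES)}

_IUPAC = set("ACGTUNRYSWKMBDHV")
_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def _normalize_seq(seq: str, label: str) -> str:
    s = seq.upper().replace("U", "T")
    bad = set(s) - _IUPAC
    if bad:
        raise ValueError(f"{label}: non-IUPAC characters {sorted(bad)}")
    return s


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def seed_sites(mirna_seq: str) -> dict[str, str]:
    """Target-strand site motifs for one miRNA (DNA alphabet).

    8mer    reverse complement of miRNA positions 2-8, followed by A
            (the A pairs opposite miRNA position 1)
    7mer-m8 reverse complement of positions 2-8
    7mer-A1 reverse complement of positions 2-7, followed by A
    """
    m = _normalize_seq(mirna_seq, "miRNA")
    if len(m) < 8:
        raise ValueError("miRNA shorter than 8 nt")
    rc28 = _revcomp(m[1:8])
    rc27 = _revcomp(m[1:7])
    return {"8mer": rc28 + "A", "7mer-m8": rc28, "7mer-A1": rc27 + "A"}


def seed_match(
    mirna_seqs: Mapping[str, str],
    target_seqs: Mapping[str, str],
    target_kind: str = "mRNA",
) -> pd.DataFrame:
    """Scan targets for canonical seed sites.

    One row per (miRNA, target) pair, keeping the strongest site type
    (8mer > 7mer-m8 > 7mer-A1).
    """
    rows = []
    for mir_id in sorted(mirna_seqs):
        sites = seed_sites(mirna_seqs[mir_id])
        for tgt_id in sorted(target_seqs):
            t = _normalize_seq(target_seqs[tgt_id], tgt_id)
            best = None
            for site_type in SITE_TYPES:
                if sites[site_type] in t:
                    best = site_type
                    break
            if best is not None:
                rows.append(
                    {
                        "mirna_id": mir_id,
                        "target_id": tgt_id,
                        "target_kind": target_kind,
                        "site_type": best,
                    }
                )
    return pd.DataFrame(
        rows, columns=["mirna_id", "target_id", "target_kind", "site_type"]
    )


# -- coexpression filters ---------------------------------------------------

def _series(expr: pd.DataFrame, key: str, cols: list[str]) -> np.ndarray:
    return expr.loc[key, cols].to_numpy(dtype=float)


def scc_filter(
    candidates: pd.DataFrame,
    mirna_expr: pd.DataFrame,
    target_expr: pd.DataFrame,
    scc_max: float = -0.7,
) -> pd.DataFrame:
    """Keep candidates with Spearman rho < scc_max (strict).

    Ties get average ranks (scipy's convention); constant series are
    dropped and logged.
    """
    common = [c for c in mirna_expr.columns if c in set(target_expr.columns)]
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples for correlation")
    kept = []
    for row in candidates.itertuples(index=False):
        x = _series(mirna_expr, row.mirna_id, common)
        y = _series(target_expr, row.target_id, common)
        if x.std() == 0 or y.std() == 0:
            logger.warning(
                "dropping constant series pair (%s, %s)", row.mirna_id, row.target_id
            )
            continue
        rho = sps.spearmanr(x, y).statistic
        if np.isfinite(rho) and rho < scc_max:
            kept.append({**row._asdict(), "scc": float(rho)})
    return pd.DataFrame(
        kept,
        columns=[*candidates.columns, "scc"],
    )


def pcc_filter(
    pairs: pd.DataFrame,
    lncrna_expr: pd.DataFrame,
    mrna_expr: pd.DataFrame,
    pcc_min: float = 0.9,
    log_transform: bool = True,
) -> pd.DataFrame:
    """Keep lncRNA-mRNA pairs with Pearson r > pcc_min (strict)."""
    common = [c for c in lncrna_expr.columns if c in set(mrna_expr.columns)]
    if len(common) < 3:
        raise ValueError("need >= 3 matched samples for correlation")
    kept = []
    for row in pairs.itertuples(index=False):
        x = _series(lncrna_expr, row.lncrna_id, common)
        y = _series(mrna_expr, row.mrna_id, common)
        if log_transform:
            x, y = np.log2(x + 1.0), np.log2(y + 1.0)
        if x.std() == 0 or y.std() == 0:
            logger.warning(
                "dropping constant series pair (%s, %s)", row.lncrna_id, row.mrna_id
            )
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if np.isfinite(r) and r > pcc_min:
            kept.append({**row._asdict(), "pcc": r})
    return pd.DataFrame(kept, columns=[*pairs.columns, "pcc"])


# -- sponge test ------------------------------------------------------------

@dataclass(frozen=True)
class SpongeResult:
    k: int  # shared miRNAs
    K: int  # miRNAs targeting the lncRNA
    n: int  # miRNAs targeting the mRNA
    M: int  # miRNA universe size
    pvalue: float


def sponge_test(
    lncrna_mirnas: Iterable[str],
    mrna_mirnas: Iterable[str],
    universe: Iterable[str],
) -> SpongeResult:
    """Hypergeometric upper-tail test of shared-miRNA overlap."""
    uni = set(universe)
    if not uni:
        raise ValueError("empty miRNA universe")
    a, b = set(lncrna_mirnas), set(mrna_mirnas)
    if not a <= uni or not b <= uni:
        raise ValueError("miRNA sets must be subsets of the universe")
    k, K, n, M = len(a & b), len(a), len(b), len(uni)
    return SpongeResult(k, K, n, M, hypergeom_tail(k, M, K, n))


def sponge_pairs(
    candidates: pd.DataFrame,
    universe: Optional[Iterable[str]] = None,
    p_max: float = 0.05,
) -> pd.DataFrame:
    """Score every lncRNA-mRNA pair sharing >= 1 candidate miRNA.

    ``universe`` defaults to all miRNAs present in the candidate table.
    Pairs with p < p_max (strict) are returned.
    """
    if universe is None:
        universe = candidates["mirna_id"].unique()
    uni = set(universe)
    lnc_map: dict[str, set[str]] = {}
    mrna_map: dict[str, set[str]] = {}
    for row in candidates.itertuples(index=False):
        target = lnc_map if row.target_kind == "lncRNA" else mrna_map
        target.setdefault(row.target_id, set()).add(row.mirna_id)
    rows = []
    for lnc_id in sorted(lnc_map):
        for mrna_id in sorted(mrna_map):
            shared = lnc_map[lnc_id] & mrna_map[mrna_id]
            if not shared:
                continue
            res = sponge_test(lnc_map[lnc_id], mrna_map[mrna_id], uni)
            if res.pvalue < p_max:
                rows.append(
                    {
                        "lncrna_id": lnc_id,
                        "mrna_id": mrna_id,
                        "shared_k": res.k,
                        "K": res.K,
                        "n": res.n,
                        "M": res.M,
                        "pvalue": res.pvalue,
                        "shared_mirnas": ",".join(sorted(shared)),
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "lncrna_id",
            "mrna_id",
            "shared_k",
            "K",
            "n",
            "M",
            "pvalue",
            "shared_mirnas",
        ],
    )


# -- network assembly -------------------------------------------------------

def build_network(
    sponge: pd.DataFrame,
    candidates: pd.DataFrame,
) -> nx.Graph:
    """Assemble the typed ceRNA graph from certified pairs.

    Every lncRNA-mRNA edge is backed by >= 1 shared miRNA whose two
    candidate edges survived the correlation filter; only nodes incident
    to an edge are added, so the graph has no isolates.
    """
    g = nx.Graph()
    cand_idx: dict[tuple[str, str], dict] = {}
    for row in candidates.itertuples(index=False):
        cand_idx[(row.mirna_id, row.target_id)] = row._asdict()

    if sponge.empty:
        logger.warning("no certified sponge pairs; network is empty")
        return g

    for row in sponge.itertuples(index=False):
        shared = [m for m in row.shared_mirnas.split(",") if m]
        shared = [
            m
            for m in shared
            if (m, row.lncrna_id) in cand_idx and (m, row.mrna_id) in cand_idx
        ]
        if not shared:
            continue
        g.add_node(row.lncrna_id, kind="lncRNA")
        g.add_node(row.mrna_id, kind="mRNA")
        g.add_edge(
            row.lncrna_id,
            row.mrna_id,
            interaction="lncRNA-mRNA",
            pvalue=float(row.pvalue),
            pcc=float(getattr(row, "pcc", np.nan)),
        )
        for m in shared:
            g.add_node(m, kind="miRNA")
            lnc_edge = cand_idx[(m, row.lncrna_id)]
            mrna_edge = cand_idx[(m, row.mrna_id)]
            g.add_edge(
                row.lncrna_id,
                m,
                interaction="lncRNA-miRNA",
                scc=float(lnc_edge.get("scc", np.nan)),
            )
            g.add_edge(
                m,
                row.mrna_id,
                interaction="miRNA-mRNA",
                scc=float(mrna_edge.get("scc", np.nan)),
            )
    return g


def write_sif(g: nx.Graph, path: str | Path) -> None:
    """Simple interaction format: source<TAB>relation<TAB>target."""
    with open(path, "w") as fh:
        for u, v, data in sorted(g.edges(data=True)):
            fh.write(f"{u}\t{data.get('interaction', 'pp')}\t{v}\n")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    h = g.copy()
    for _u, _v, data in h.edges(data=True):
        for key, val in list(data.items()):
            if isinstance(val, float) and np.isnan(val):
                del data[key]
    nx.write_graphml(h, path)


def cerna_analysis(
    candidates: pd.DataFrame,
    mirna_fpkm: pd.DataFrame,
    lncrna_fpkm: pd.DataFrame,
    mrna_fpkm: pd.DataFrame,
    de_mirna_ids: Optional[Iterable[str]] = None,
    de_lncrna_ids: Optional[Iterable[str]] = None,
    de_mrna_ids: Optional[Iterable[str]] = None,
    scc_max: float = -0.7,
    pcc_min: float = 0.9,
    sponge_p_max: float = 0.05,
    universe: str | Iterable[str] = "candidates",
) -> tuple[pd.DataFrame, pd.DataFrame, nx.Graph]:
    """Full ceRNA pipeline from a candidate table and expression matrices.

    ``universe`` is either "candidates" (miRNAs in the filtered candidate
    table), "expressed" (all miRNAs in ``mirna_fpkm``), or an explicit
    id collection.

    Returns (filtered candidates, certified sponge pairs, network).
    """
    cand = candidates.copy()
    if de_mirna_ids is not None:
        cand = cand[cand["mirna_id"].isin(set(de_mirna_ids))]
    if de_lncrna_ids is not None:
        keep = cand["target_kind"] != "lncRNA"
        cand = cand[keep | cand["target_id"].isin(set(de_lncrna_ids))]
    if de_mrna_ids is not None:
        keep = cand["target_kind"] != "mRNA"
        cand = cand[keep | cand["target_id"].isin(set(de_mrna_ids))]

    lnc_cand = cand[cand["target_kind"] == "lncRNA"]
    mrna_cand = cand[cand["target_kind"] == "mRNA"]
    lnc_kept = scc_filter(lnc_cand, mirna_fpkm, lncrna_fpkm, scc_max=scc_max)
    mrna_kept = scc_filter(mrna_cand, mirna_fpkm, mrna_fpkm, scc_max=scc_max)
    filtered = pd.concat([lnc_kept, mrna_kept], ignore_index=True)

    if isinstance(universe, str):
        if universe == "candidates":
            uni: Iterable[str] = filtered["mirna_id"].unique()
        elif universe == "expressed":
            uni = mirna_fpkm.index
        else:
            raise ValueError(f"unknown universe mode {universe!r}")
    else:
        uni = universe

    pairs = sponge_pairs(filtered, universe=uni, p_max=sponge_p_max)
    if len(pairs):
        pairs = pcc_filter(pairs, lncrna_fpkm, mrna_fpkm, pcc_min=pcc_min)
    else:
        pairs = pairs.assign(pcc=pd.Series(dtype=float))
    network = build_network(pairs, filtered)
    return filtered, pairs, network
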