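"""One-config orchestration: synth -> catalog -> DE -> enrichment ->
targets -> ceRNA -> qPCR -> report.

Every stage is a pure function of (inputs, config, seed); the JSON run
report carries per-stage record counts that equal the line counts of the
emitted files. Timings go to the log only, so rerunning with the same
seed yields a byte-identical report.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import pandas as pd
import yaml

from . import __version__, catalog, cerna, enrichment, expression, qpcr, synthetic
from .gtf import read_gtf, write_gtf
from .models import genes_from_transcripts
from .targets import antisense_pairs, cis_pairs, pairs_to_frame, trans_pairs

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS: dict[str, float] = {
    "fc_min": 2.0,
    "fdr_max": 0.05,
    "mirna_p_max": 0.05,
    "cis_window_bp": 100_000,
    "trans_r_min": 0.9,
    "scc_max": -0.7,
    "pcc_min": 0.9,
    "sponge_p_max": 0.05,
    "nes_min": 1.0,
    "gsea_p_max": 0.05,
    "gsea_q_max": 0.25,
    "bidirectional_window_bp": 1000,
}


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "lncnet_run"
    synthetic: Optional[synthetic.SyntheticConfig] = None
    thresholds: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_THRESHOLDS)
    )
    gsea_n_perm: int = 1000
    gsea_min_size: int = 2
    gsea_max_size: int = 500
    cerna_universe: str = "expressed"

    def validate(self) -> None:
        if self.synthetic is None:
            raise ValueError("config must include a synthetic block")
        t = self.thresholds
        if not (0 < t["fdr_max"] <= 1 and 0 < t["sponge_p_max"] <= 1):
            raise ValueError("p/FDR thresholds must be in (0, 1]")
        if t["fc_min"] < 1:
            raise ValueError("fc_min must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(
            seed=raw.get("seed", 0),
            outdir=raw.get("outdir", "lncnet_run"),
        )
        cfg.thresholds.update(raw.get("thresholds", {}))
        for key in ("gsea_n_perm", "gsea_min_size", "gsea_max_size", "cerna_universe"):
            if key in raw:
                setattr(cfg, key, raw[key])
        syn = raw.get("synthetic", "default")
        if syn == "default" or syn is None:
            cfg.synthetic = synthetic.default_scenario(seed=cfg.seed)
        else:
            base = synthetic.default_scenario(seed=cfg.seed)
            for key, val in syn.items():
                if not hasattr(base, key):
                    raise ValueError(f"unknown synthetic config key: {key}")
                setattr(base, key, val)
            cfg.synthetic = base
        return cfg


def _count_lines(path: Path) -> int:
    with open(path) as fh:
        return sum(1 for _ in fh)


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute all stages; returns the run report (also written to disk)."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(message)s"))
    root = logging.getLogger("lncnet")
    root.addHandler(handler)
    try:
        return _run(config, outdir)
    finally:
        root.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, outdir: Path) -> dict[str, Any]:
    th = config.thresholds
    syn = config.synthetic
    syn.seed = config.seed
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": dict(sorted(th.items())),
        "stages": {},
    }

    def stage(name):
        logger.info("stage %s starting", name)
        return time.perf_counter()

    def done(name, t0, **counts):
        logger.info("stage %s finished in %.2fs", name, time.perf_counter() - t0)
        report["stages"][name] = counts

    # -- synth
    t0 = stage("synth")
    annotation, truth = synthetic.generate_annotation(syn)
    mrna_cm, lnc_cm, mir_cm = synthetic.generate_counts(annotation, truth, syn)
    target_seqs, mirna_seqs = synthetic.generate_sequences(annotation, truth, syn)
    design = syn.design_frame()

    write_gtf(annotation.transcripts, outdir / "annotation.gtf")
    synthetic.write_fasta(target_seqs, outdir / "transcripts.fa")
    synthetic.write_fasta(mirna_seqs, outdir / "mirna.fa")
    for name, cm in (
        ("counts_mrna", mrna_cm),
        ("counts_lncrna", lnc_cm),
        ("counts_mirna", mir_cm),
    ):
        cm.counts.to_csv(outdir / f"{name}.tsv", sep="\t")
    design.to_csv(outdir / "design.tsv", sep="\t", index=False)
    calls_df = synthetic.generate_coding_calls(annotation)
    calls_df.to_csv(outdir / "coding_calls.tsv", sep="\t", index=False)
    synthetic.write_truth(truth, outdir)
    done(
        "synth",
        t0,
        transcripts=len(annotation.transcripts),
        mirnas=len(annotation.mirna_ids),
        samples=len(design),
    )

    # -- catalog
    t0 = stage("catalog")
    transcripts = read_gtf(outdir / "annotation.gtf")
    genes = genes_from_transcripts([t for t in transcripts if t.biotype == "coding"])
    calls = catalog.read_coding_calls(outdir / "coding_calls.tsv")
    lnc_ids = catalog.consensus_lncrna_call(calls)
    candidates = [t for t in transcripts if t.transcript_id in lnc_ids]
    novel = catalog.filter_novel_transcripts(candidates)
    annotations = catalog.classify_catalog(
        novel, genes, int(th["bidirectional_window_bp"])
    )
    catalog.write_catalog(annotations, outdir / "catalog.tsv")
    class_counts = pd.Series(
        [a.positional_class for a in annotations]
    ).value_counts().to_dict()
    done(
        "catalog",
        t0,
        lncrnas=len(annotations),
        **{f"class_{k}": int(v) for k, v in sorted(class_counts.items())},
    )

    # -- differential expression
    t0 = stage("de")
    comparisons = [
        (a, b)
        for (a, _), (b, _) in zip(syn.design, syn.design[1:])
    ]
    de_tables: dict[str, dict[str, pd.DataFrame]] = {"mrna": {}, "lncrna": {}, "mirna": {}}
    de_counts = {}
    for a, b in comparisons:
        label = f"{a}_vs_{b}"
        for kind, cm, use_p in (
            ("mrna", mrna_cm, False),
            ("lncrna", lnc_cm, False),
            ("mirna", mir_cm, True),
        ):
            table = expression.de_analysis(
                cm,
                design,
                a,
                b,
                fc_min=th["fc_min"],
                fdr_max=th["fdr_max"],
                use_pvalue=use_p,
                p_max=th["mirna_p_max"],
            )
            expression.write_de_table(table, outdir / f"de_{kind}_{label}.tsv")
            de_tables[kind][label] = table
            de_counts[f"{kind}_{label}_up"] = int((table["status"] == "up").sum())
            de_counts[f"{kind}_{label}_down"] = int((table["status"] == "down").sum())
    done("de", t0, **de_counts)

    # -- enrichment
    t0 = stage("enrichment")
    sets = enrichment.GeneSetCollection(
        synthetic.generate_gene_sets(truth, annotation, syn)
    )
    enrichment.write_gmt(sets, outdir / "gene_sets.gmt")
    mrna_fpkm = expression.compute_fpkm(mrna_cm)
    background = [t.transcript_id for t in annotation.coding]
    ora_enriched = 0
    gsea_tested = 0
    gsea_significant = 0
    for a, b in comparisons:
        label = f"{a}_vs_{b}"
        de_genes = de_tables["mrna"][label].query("status != 'ns'").index.tolist()
        ora = enrichment.ora_hypergeometric(de_genes, background, sets)
        ora.to_csv(outdir / f"ora_{label}.tsv", sep="\t")
        ora_enriched += int((ora["pvalue"] < 0.05).sum())
        gsea = enrichment.gsea_permutation(
            mrna_fpkm,
            design,
            sets,
            a,
            b,
            n_perm=config.gsea_n_perm,
            seed=config.seed,
            min_size=config.gsea_min_size,
            max_size=config.gsea_max_size,
            nes_min=th["nes_min"],
            p_max=th["gsea_p_max"],
            q_max=th["gsea_q_max"],
        )
        gsea.to_csv(outdir / f"gsea_{label}.tsv", sep="\t")
        gsea_tested += len(gsea)
        gsea_significant += int(gsea["significant"].sum())
    done(
        "enrichment",
        t0,
        ora_enriched=ora_enriched,
        gsea_tested=gsea_tested,
        gsea_significant=gsea_significant,
    )

    # -- targets
    t0 = stage("targets")
    lnc_models = [t for t in transcripts if t.biotype == "lncRNA"]
    lnc_fpkm = expression.compute_fpkm(lnc_cm)
    anti = antisense_pairs(lnc_models, genes)
    cis = cis_pairs(lnc_models, genes, int(th["cis_window_bp"]))
    trans = trans_pairs(lnc_fpkm, mrna_fpkm, r_min=th["trans_r_min"])
    all_pairs = pairs_to_frame([*anti, *cis, *trans])
    all_pairs.to_csv(outdir / "targets.tsv", sep="\t", index=False)
    done(
        "targets",
        t0,
        antisense=len(anti),
        cis=len(cis),
        trans=len(trans),
    )

    # -- ceRNA network
    t0 = stage("cerna")
    target_fa = synthetic.read_fasta(outdir / "transcripts.fa")
    mirna_fa = synthetic.read_fasta(outdir / "mirna.fa")
    lnc_seqs = {t.transcript_id: target_fa[t.transcript_id] for t in lnc_models}
    mrna_seqs = {
        t.transcript_id: target_fa[t.transcript_id]
        for t in transcripts
        if t.biotype == "coding"
    }
    cand = pd.concat(
        [
            cerna.seed_match(mirna_fa, mrna_seqs, target_kind="mRNA"),
            cerna.seed_match(mirna_fa, lnc_seqs, target_kind="lncRNA"),
        ],
        ignore_index=True,
    )
    cand.to_csv(outdir / "cerna_candidates.tsv", sep="\t", index=False)

    def _de_union(kind: str) -> set[str]:
        out: set[str] = set()
        for table in de_tables[kind].values():
            out |= set(table.query("status != 'ns'").index)
        return out

    mir_fpkm = expression.compute_fpkm(mir_cm)
    filtered, pairs, network = cerna.cerna_analysis(
        cand,
        mir_fpkm,
        lnc_fpkm,
        mrna_fpkm,
        de_mirna_ids=_de_union("mirna"),
        de_lncrna_ids=_de_union("lncrna"),
        de_mrna_ids=_de_union("mrna"),
        scc_max=th["scc_max"],
        pcc_min=th["pcc_min"],
        sponge_p_max=th["sponge_p_max"],
        universe=config.cerna_universe,
    )
    filtered.to_csv(outdir / "cerna_filtered.tsv", sep="\t", index=False)
    pairs.to_csv(outdir / "cerna_pairs.tsv", sep="\t", index=False)
    cerna.write_sif(network, outdir / "network.sif")
    cerna.write_graphml(network, outdir / "network.graphml")
    done(
        "cerna",
        t0,
        candidates=len(cand),
        filtered=len(filtered),
        pairs=len(pairs),
        nodes=network.number_of_nodes(),
        edges=network.number_of_edges(),
    )

    # -- qPCR validation
    t0 = stage("qpcr")
    folds = syn.qpcr_folds or {"IV": 1.0, "V": 2.0, "VI": 0.5}
    calibrator = next(iter(folds))
    plate = synthetic.generate_qpcr(folds, calibrator, seed=config.seed)
    plate.to_csv(outdir / "qpcr_ct.tsv", sep="\t", index=False)
    rq = qpcr.ddct_quantify(plate, calibrator)
    rq.to_csv(outdir / "qpcr_rq.tsv", sep="\t")
    done("qpcr", t0, samples=len(rq))

    report_path = outdir / "report.json"
    with open(report_path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    with open(outdir / "report.txt", "w") as fh:
        fh.write(f"lncnet {__version__} run (seed {config.seed})\n")
        for name, counts in report["stages"].items():
            fh.write(f"[{name}]\n")
            for key, val in counts.items():
                fh.write(f"  {key}: {val}\n")
    logger.info("pipeline complete: %s", report_path)
    return report
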