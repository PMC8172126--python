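# lncnet

Analysis toolkit for staged bulk RNA-seq designs centered on lncRNA
biology: lncRNA identification and positional classification,
FPKM-based differential expression with BH FDR, hypergeometric
over-representation analysis, permutation GSEA, antisense/cis/trans
target prediction, and competing-endogenous-RNA (ceRNA) network
inference. A deterministic synthetic-data generator with a
planted-truth ledger makes every stage testable end to end without any
external downloads.

## Layout

| module               | what it does                                                       |
| -------------------- | ------------------------------------------------------------------ |
| `lncnet.synthetic`   | annotation/counts/sequences/qPCR plates with planted structure     |
| `lncnet.catalog`     | GTF models, novelty filter, consensus lncRNA call, classification  |
| `lncnet.expression`  | FPKM, Welch stand-in DE test, BH FDR, FC/FDR gates                 |
| `lncnet.enrichment`  | hypergeometric ORA; GSEA (signal-to-noise + label permutation)     |
| `lncnet.targets`     | antisense (positional), cis (<100 kb), trans (correlation) targets |
| `lncnet.cerna`       | seed match, SCC/PCC filters, sponge test, network + SIF/GraphML    |
| `lncnet.qpcr`        | 2^-ddCt quantification, read-retention summaries                   |
| `lncnet.pipeline`    | one-config orchestration with a machine-readable run report        |

Key conventions: internal coordinates are 0-based half-open (GTF I/O
converts at the boundary); all published thresholds are applied exactly
as printed (FC >= 2 inclusive; FDR < 0.05, SCC < -0.7, PCC > 0.9,
sponge p < 0.05, cis distance < 100 kb, |NES| > 1 all strict).

The differential test is a documented stand-in (Welch on
log2(FPKM + 1)), not a negative-binomial GLM; it lives behind the
`de_test` interface so an alternative can be slotted in.

## CLI

Everything is reachable through the `lncnet` console script:

```sh
lncnet synth --outdir demo --seed 1                 # synthetic scenario
lncnet catalog --gtf demo/annotation.gtf \
       --calls demo/coding_calls.tsv --out catalog.tsv
lncnet de --counts demo/counts_mrna.tsv --lengths lengths.tsv \
       --design demo/design.tsv --compare IV V --out de.tsv
lncnet ora --de-genes de_ids.txt --background bg.txt \
       --sets sets.gmt --out ora.tsv
lncnet gsea --fpkm fpkm.tsv --design demo/design.tsv \
       --sets sets.gmt --compare IV V --nperm 1000 --seed 1 --out gsea.tsv
lncnet targets --gtf demo/annotation.gtf --mechanism cis --out targets.tsv
lncnet cerna --mirna-fa demo/mirna.fa --targets-fa demo/transcripts.fa \
       --lnc-ids lnc_ids.txt --expr-mirna fpkm_mir.tsv \
       --expr-lncrna fpkm_lnc.tsv --expr-mrna fpkm_mrna.tsv --out cerna_out
lncnet ddct --ct ct.tsv --calibrator IV --out rq.tsv
lncnet readstats --raw 740000000 --clean 730797538 --hq 720475082
```

The full pipeline (synth -> catalog -> DE -> enrichment -> targets ->
ceRNA -> qPCR) runs from one YAML config, or from built-in defaults:

```sh
lncnet run --seed 1 --outdir demo_run
lncnet run --config pipeline.yaml
```

`demo_run/report.json` holds per-stage record counts and is
byte-identical across reruns with the same seed.

## Notes on the permutation floor

With a 3-replicates-per-stage design only C(6,3) = 20 distinct class
label assignments exist, so the GSEA nominal p cannot go below 0.05 and
the conventional p < 0.05 gate is unreachable; `lncnet` enumerates the
assignments exhaustively and logs a warning. Use wider designs (e.g.
5v5) when permutation significance matters.
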