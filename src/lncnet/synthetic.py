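"""Deterministic synthetic data with planted, recoverable structure.

Generates a GTF annotation whose lncRNAs are placed so the positional
classifier must assign each planted class, negative-binomial count
matrices with planted stage effects and latent-factor ceRNA coupling,
screened FASTA sequences carrying exact seed sites for planted
miRNA-target pairs, and qPCR plates with known fold changes. A
:class:`SyntheticTruth` ledger records everything planted so recovery
can be asserted downstream.

Geometry is laid out in fixed-width blocks (one host gene per block),
spaced widely enough that no unplanned cis/bidirectional relations can
arise. All outputs are pure functions of (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .catalog import PLANTABLE_CLASSES
from .expression import CountMatrix
from .models import GenomicInterval, TranscriptModel, genes_from_transcripts

# block geometry (bp)
_BLOCK = 240_000
_GENE_OFFSET = 120_000
_GENE_EXON = 400
_GENE_INTRON = 3000
_GENE_N_EXONS = 3
_GENE_SPAN = _GENE_N_EXONS * _GENE_EXON + (_GENE_N_EXONS - 1) * _GENE_INTRON

_TARGET_SEQ_LEN = 500
_MIRNA_LEN = 21


class SizingError(ValueError):
    """A chromosome is too short for the requested feature layout."""


@dataclass(frozen=True)
class PlantedEffect:
    """A differential-expression effect between two stages.

    The log2 effect is applied to the second stage of the pair.
    """

    transcript_id: str
    stage_a: str
    stage_b: str
    log2_effect: float

    @property
    def comparison(self) -> str:
        return f"{self.stage_a}_vs_{self.stage_b}"


@dataclass(frozen=True)
class PlantedTriplet:
    """A ceRNA triplet with latent-factor coupling strength beta.

    Per sample, a latent z ~ N(0,1) enters the miRNA log2 mean with
    coefficient -beta and the lncRNA/mRNA log2 means with +beta.
    """

    lncrna_id: str
    mirna_id: str
    mrna_id: str
    beta: float


@dataclass
class SyntheticConfig:
    seed: int = 0
    n_chrom: int = 3
    chrom_length_bp: int = 3_000_000
    n_coding_genes: int = 30
    n_lncrna_per_class: int = 3
    n_mirna: int = 8
    design: list[tuple[str, int]] = field(
        default_factory=lambda: [("IV", 3), ("V", 3), ("VI", 3)]
    )
    baseline_mean: float = 200.0
    #: miRNA libraries run deeper; a higher baseline keeps strongly
    #: down-regulated miRNAs away from the zero-count floor
    mirna_baseline_mean: Optional[float] = None
    dispersion: float = 0.1
    planted_de: list[PlantedEffect] = field(default_factory=list)
    planted_triplets: list[PlantedTriplet] = field(default_factory=list)
    cis_window_bp: int = 100_000
    qpcr_folds: dict[str, float] = field(default_factory=dict)

    def validate(self) -> None:
        if self.n_chrom < 1 or self.n_coding_genes < 1 or self.n_mirna < 0:
            raise ValueError("counts must be >= 1 (n_mirna >= 0)")
        if self.n_lncrna_per_class < 0:
            raise ValueError("n_lncrna_per_class must be >= 0")
        if self.n_lncrna_per_class > self.n_coding_genes:
            raise ValueError(
                "n_lncrna_per_class cannot exceed n_coding_genes "
                "(one host gene per same-class lncRNA)"
            )
        if self.dispersion < 0:
            raise ValueError("dispersion must be >= 0")
        labels = [s for s, _ in self.design]
        if len(labels) != len(set(labels)):
            raise ValueError("stage labels must be unique")
        if any(n < 1 for _, n in self.design):
            raise ValueError("each stage needs >= 1 replicate")
        ids = set(self.transcript_ids()) | set(self.mirna_ids())
        for eff in self.planted_de:
            if eff.transcript_id not in ids:
                raise ValueError(f"planted DE id not generated: {eff.transcript_id}")
            if {eff.stage_a, eff.stage_b} - set(labels):
                raise ValueError(f"planted DE references unknown stage: {eff}")
        for t in self.planted_triplets:
            for tid in (t.lncrna_id, t.mrna_id):
                if tid not in ids:
                    raise ValueError(f"planted triplet id not generated: {tid}")
            if t.mirna_id not in set(self.mirna_ids()):
                raise ValueError(f"planted triplet miRNA not generated: {t.mirna_id}")

    # deterministic id scheme, known before generation
    def gene_ids(self) -> list[str]:
        return [f"gene{i:04d}" for i in range(1, self.n_coding_genes + 1)]

    def mrna_ids(self) -> list[str]:
        return [f"mrna{i:04d}" for i in range(1, self.n_coding_genes + 1)]

    def lncrna_ids(self, positional_class: str) -> list[str]:
        return [
            f"lnc_{positional_class}_{i:03d}"
            for i in range(1, self.n_lncrna_per_class + 1)
        ]

    def all_lncrna_ids(self) -> list[str]:
        return [i for c in PLANTABLE_CLASSES for i in self.lncrna_ids(c)]

    def mirna_ids(self) -> list[str]:
        return [f"mir{i:04d}" for i in range(1, self.n_mirna + 1)]

    def transcript_ids(self) -> list[str]:
        return self.mrna_ids() + self.all_lncrna_ids()

    def sample_ids(self) -> list[str]:
        return [
            f"{stage}_{r}" for stage, n in self.design for r in range(1, n + 1)
        ]

    def design_frame(self) -> pd.DataFrame:
        rows = [
            {"sample_id": f"{stage}_{r}", "stage": stage, "replicate": r}
            for stage, n in self.design
            for r in range(1, n + 1)
        ]
        return pd.DataFrame(rows)


@dataclass
class SyntheticTruth:
    """Ledger of everything planted, keyed by generated ids."""

    class_of: dict[str, str] = field(default_factory=dict)
    target_pairs: list[tuple[str, str, str]] = field(default_factory=list)
    de_ids: dict[str, set[str]] = field(default_factory=dict)
    triplets: list[PlantedTriplet] = field(default_factory=list)


@dataclass
class SyntheticAnnotation:
    transcripts: list[TranscriptModel]
    chrom_lengths: dict[str, int]
    mirna_ids: list[str]

    @property
    def coding(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "coding"]

    @property
    def lncrnas(self) -> list[TranscriptModel]:
        return [t for t in self.transcripts if t.biotype == "lncRNA"]

    def genes(self):
        return genes_from_transcripts(self.coding)

    def lengths(self) -> pd.Series:
        s = pd.Series(
            {t.transcript_id: t.length for t in self.transcripts}, dtype=float
        )
        for m in self.mirna_ids:
            s[m] = float(_MIRNA_LEN)
        return s


def _rng(config: SyntheticConfig, stream: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, stream])


# -- annotation -------------------------------------------------------------

def _gene_model(gene_id, tid, chrom, base, strand) -> TranscriptModel:
    exons = [
        GenomicInterval(
            chrom,
            base + i * (_GENE_EXON + _GENE_INTRON),
            base + i * (_GENE_EXON + _GENE_INTRON) + _GENE_EXON,
            strand,
        )
        for i in range(_GENE_N_EXONS)
    ]
    return TranscriptModel(tid, gene_id, exons, biotype="coding")


def _flip(strand: str) -> str:
    return "-" if strand == "+" else "+"


def _place_lncrna(
    cls: str,
    lnc_id: str,
    host: TranscriptModel,
    cis_window_bp: int,
) -> TranscriptModel:
    """Exon geometry forcing the classifier to assign ``cls``.

    Offsets carry enough margin that each rule is satisfied strictly:
    e.g. the bidirectional TSS gap is half the 1 kb window and the cis
    distance is half the cis window.
    """
    chrom, b, strand = host.chrom, host.start, host.strand

    def t(exons, s):
        return TranscriptModel(
            lnc_id,
            lnc_id,
            [GenomicInterval(chrom, a, z, s) for a, z in exons],
            biotype="lncRNA",
        )

    if cls == "intronic":
        # wholly inside intron 1 (b+400 .. b+3400)
        return t([(b + 1000, b + 1120), (b + 1320, b + 1440)], _flip(strand))
    if cls == "antisense":
        # first exon overlaps gene exon 2 by 200 bp, opposite strand
        return t([(b + 3600, b + 3800), (b + 4000, b + 4200)], _flip(strand))
    if cls == "sense_overlapping":
        # overlaps gene exon 1, extends 600 bp upstream of the gene
        return t([(b - 600, b + 200), (b + 600, b + 800)], strand)
    if cls == "bidirectional":
        if strand == "+":
            end = b - 499  # lncRNA TSS 500 bp upstream, divergent
            return t([(end - 700, end - 500), (end - 200, end)], "-")
        start = host.end - 1 + 500
        return t([(start, start + 200), (start + 500, start + 700)], "+")
    if cls == "intergenic":
        # placed at half the cis window downstream: intergenic AND a
        # planted cis pair with the host gene
        start = host.end + cis_window_bp // 2
        return t([(start, start + 150), (start + 350, start + 500)], strand)
    raise ValueError(f"unknown positional class: {cls}")


def generate_annotation(
    config: SyntheticConfig,
) -> tuple[SyntheticAnnotation, SyntheticTruth]:
    """Deterministic annotation plus the planted-truth ledger."""
    config.validate()
    rng = _rng(config, 0)

    n_genes = config.n_coding_genes
    blocks_per_chrom = -(-n_genes // config.n_chrom)  # ceil
    needed = blocks_per_chrom * _BLOCK
    chrom_names = [f"chr{i}" for i in range(1, config.n_chrom + 1)]
    for name in chrom_names:
        if config.chrom_length_bp < needed:
            raise SizingError(
                f"chromosome {name} too short: need {needed} bp for "
                f"{blocks_per_chrom} gene blocks, have {config.chrom_length_bp}"
            )
    if config.cis_window_bp // 2 + _TARGET_SEQ_LEN + _GENE_SPAN >= _BLOCK - _GENE_OFFSET:
        raise SizingError(
            "cis_window_bp too large for the block layout "
            f"(max ~{2 * (_BLOCK - _GENE_OFFSET - _GENE_SPAN - _TARGET_SEQ_LEN)})"
        )

    strands = rng.choice(["+", "-"], size=n_genes)
    transcripts: list[TranscriptModel] = []
    hosts: list[TranscriptModel] = []
    for i, (gid, tid) in enumerate(zip(config.gene_ids(), config.mrna_ids())):
        chrom = chrom_names[i % config.n_chrom]
        base = (i // config.n_chrom) * _BLOCK + _GENE_OFFSET
        host = _gene_model(gid, tid, chrom, base, strands[i])
        hosts.append(host)
        transcripts.append(host)

    truth = SyntheticTruth()
    for ci, cls in enumerate(PLANTABLE_CLASSES):
        for j, lnc_id in enumerate(config.lncrna_ids(cls)):
            host = hosts[(ci * config.n_lncrna_per_class + j) % n_genes]
            lnc = _place_lncrna(cls, lnc_id, host, config.cis_window_bp)
            transcripts.append(lnc)
            truth.class_of[lnc_id] = cls
            if cls == "antisense":
                truth.target_pairs.append((lnc_id, host.gene_id, "antisense"))
            elif cls in ("bidirectional", "intergenic"):
                truth.target_pairs.append((lnc_id, host.gene_id, "cis"))

    for eff in config.planted_de:
        truth.de_ids.setdefault(eff.comparison, set()).add(eff.transcript_id)
    truth.triplets = list(config.planted_triplets)

    annotation = SyntheticAnnotation(
        transcripts=transcripts,
        chrom_lengths={name: config.chrom_length_bp for name in chrom_names},
        mirna_ids=config.mirna_ids(),
    )
    return annotation, truth


# -- counts -----------------------------------------------------------------

def _sample_nb(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB(mu, phi) with Var = mu + phi mu^2; phi = 0 degrades to Poisson."""
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(r, p)


def generate_counts(
    annotation: SyntheticAnnotation,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> tuple[CountMatrix, CountMatrix, CountMatrix]:
    """NB count matrices for mRNAs, lncRNAs and miRNAs.

    log2 means start at log2(baseline_mean), add the planted stage
    effects, and add the latent ceRNA coupling (+beta z for lncRNA and
    mRNA, -beta z for the miRNA of each triplet).
    """
    rng = _rng(config, 1)
    design = config.design_frame()
    samples = design["sample_id"].tolist()
    stage_of = dict(zip(design["sample_id"], design["stage"]))

    mrna_ids = [t.transcript_id for t in annotation.coding]
    lnc_ids = [t.transcript_id for t in annotation.lncrnas]
    mir_ids = annotation.mirna_ids
    index = {tid: i for i, tid in enumerate(mrna_ids + lnc_ids + mir_ids)}
    n_rows, n_cols = len(index), len(samples)

    log2_mean = np.full((n_rows, n_cols), np.log2(config.baseline_mean))
    mir_base = config.mirna_baseline_mean
    if mir_base is not None:
        log2_mean[len(mrna_ids) + len(lnc_ids):, :] = np.log2(mir_base)

    for eff in config.planted_de:
        row = index[eff.transcript_id]
        for j, s in enumerate(samples):
            if stage_of[s] == eff.stage_b:
                log2_mean[row, j] += eff.log2_effect

    # latent factors drawn in a fixed order -> deterministic
    for trip in truth.triplets:
        z = rng.standard_normal(n_cols)
        log2_mean[index[trip.lncrna_id]] += trip.beta * z
        log2_mean[index[trip.mrna_id]] += trip.beta * z
        log2_mean[index[trip.mirna_id]] -= trip.beta * z

    counts = _sample_nb(rng, 2.0**log2_mean, config.dispersion)
    frame = pd.DataFrame(counts, index=list(index), columns=samples)
    lengths = annotation.lengths()
    # whole-library totals shared by all three slices, so one biotype's
    # planted effects do not masquerade as shifts in the others
    library = frame.sum(axis=0)

    def _cm(ids: Sequence[str]) -> CountMatrix:
        return CountMatrix(frame.loc[list(ids)], lengths.loc[list(ids)], library)

    return _cm(mrna_ids), _cm(lnc_ids), _cm(mir_ids)


# -- sequences --------------------------------------------------------------

_BASES = np.array(list("ACGT"))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_BASES, size=length))


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


def _screened_seq(
    rng: np.random.Generator, length: int, forbidden: Iterable[str]
) -> str:
    """Random sequence free of every forbidden motif (decoy screening)."""
    forb = list(forbidden)
    for _ in range(1000):
        s = _random_seq(rng, length)
        if not any(f in s for f in forb):
            return s
    raise RuntimeError("could not screen a decoy sequence; too many motifs")


def generate_sequences(
    annotation: SyntheticAnnotation,
    truth: SyntheticTruth,
    config: SyntheticConfig,
) -> tuple[dict[str, str], dict[str, str]]:
    """(target sequences, miRNA sequences) with planted 8mer sites.

    Each planted triplet's lncRNA and mRNA carry one exact 8mer site for
    the triplet's miRNA (reverse complement of positions 2-8 plus an A
    opposite position 1); every other sequence is screened to contain no
    seed-core match for any planted miRNA, so the matcher's recovery is
    exact by construction.
    """
    rng = _rng(config, 2)

    # Seeds must be mutually compatible: besides distinct 6mer cores, no
    # planted 8mer site string may contain another miRNA's core, or that
    # core could never be screened out of planted targets.
    mirnas: dict[str, str] = {}
    cores: set[str] = set()
    site_windows: set[str] = set()
    for mid in annotation.mirna_ids:
        for _ in range(1000):
            seq = _random_seq(rng, _MIRNA_LEN)
            site8 = _revcomp(seq[1:8]) + "A"
            core = site8[1:7]  # == revcomp(seq[1:7]), shared by all site types
            windows = {site8[i : i + 6] for i in range(3)}
            if core in site_windows or (windows - {core}) & cores:
                continue
            if core not in cores:
                cores.add(core)
                site_windows |= windows
                mirnas[mid] = seq
                break
        else:  # pragma: no cover
            raise RuntimeError("could not draw mutually compatible miRNA seeds")

    planted_sites: dict[str, list[str]] = {}
    for trip in truth.triplets:
        site8 = _revcomp(mirnas[trip.mirna_id][1:8]) + "A"
        planted_sites.setdefault(trip.lncrna_id, []).append(site8)
        planted_sites.setdefault(trip.mrna_id, []).append(site8)

    all_cores = {_revcomp(seq[1:7]) for seq in mirnas.values()}
    targets: dict[str, str] = {}
    for t in annotation.transcripts:
        tid = t.transcript_id
        sites = planted_sites.get(tid, [])
        if not sites:
            targets[tid] = _screened_seq(rng, _TARGET_SEQ_LEN, all_cores)
            continue
        own_cores = {s[1:7] for s in sites}  # core is inside the 8mer site
        other = all_cores - own_cores
        for _ in range(1000):
            s = _screened_seq(rng, _TARGET_SEQ_LEN, all_cores)
            pos = _TARGET_SEQ_LEN // 4
            for site in sites:
                s = s[:pos] + site + s[pos + len(site):]
                pos += 2 * len(site)
            if not any(f in s for f in other):
                targets[tid] = s
                break
        else:  # pragma: no cover
            raise RuntimeError(f"could not plant sites into {tid}")

    # report miRNAs in the RNA alphabet, as sequenced
    mirnas_rna = {k: v.replace("T", "U") for k, v in mirnas.items()}
    return targets, mirnas_rna


# -- qPCR -------------------------------------------------------------------

def generate_qpcr(
    folds: Mapping[str, float],
    calibrator: str,
    n_replicates: int = 3,
    sigma: float = 0.0,
    seed: int = 0,
    ct_target_base: float = 24.0,
    ct_reference_base: float = 18.0,
) -> pd.DataFrame:
    """Ct plate with known relative quantities.

    ct_target = base - log2(fold) (+ noise), ct_reference = base
    (+ noise), so :func:`lncnet.qpcr.ddct_quantify` against the
    calibrator recovers fold/fold_calibrator exactly at sigma = 0.
    """
    if calibrator not in folds:
        raise ValueError(f"calibrator {calibrator!r} missing from folds")
    if any(f <= 0 for f in folds.values()):
        raise ValueError("folds must be positive")
    rng = np.random.default_rng([seed, 3])
    rows = []
    for sample in folds:  # insertion order: deterministic
        for rep in range(1, n_replicates + 1):
            rows.append(
                {
                    "sample_id": sample,
                    "group": sample,
                    "replicate": rep,
                    "ct_target": ct_target_base
                    - float(np.log2(folds[sample]))
                    + sigma * rng.standard_normal(),
                    "ct_reference": ct_reference_base
                    + sigma * rng.standard_normal(),
                }
            )
    return pd.DataFrame(rows)


# -- auxiliary tables -------------------------------------------------------

def generate_coding_calls(annotation: SyntheticAnnotation) -> pd.DataFrame:
    """Coding-potential verdicts consistent with the planted biotypes."""
    rows = []
    for t in annotation.transcripts:
        nc = t.biotype == "lncRNA"
        rows.append(
            {
                "transcript_id": t.transcript_id,
                "cnci_noncoding": int(nc),
                "cpc_noncoding": int(nc),
                "swissprot_hit": int(not nc),
            }
        )
    return pd.DataFrame(rows)


def generate_gene_sets(
    truth: SyntheticTruth,
    annotation: SyntheticAnnotation,
    config: SyntheticConfig,
    n_decoy_sets: int = 5,
    set_size: int = 8,
) -> dict[str, tuple[str, list[str]]]:
    """GMT-style sets: one per planted comparison plus random decoys."""
    rng = _rng(config, 4)
    mrna_ids = [t.transcript_id for t in annotation.coding]
    sets: dict[str, tuple[str, list[str]]] = {}
    for comparison in sorted(truth.de_ids):
        planted = sorted(i for i in truth.de_ids[comparison] if i in set(mrna_ids))
        if not planted:
            continue
        pool = [i for i in mrna_ids if i not in planted]
        pad = list(rng.choice(pool, size=max(0, set_size - len(planted)), replace=False))
        sets[f"planted_{comparison}"] = (
            f"planted effect set for {comparison}",
            planted + pad,
        )
    for d in range(1, n_decoy_sets + 1):
        members = list(rng.choice(mrna_ids, size=min(set_size, len(mrna_ids)), replace=False))
        sets[f"decoy_{d:02d}"] = (f"random decoy set {d}", members)
    return sets


# -- ready-made scenarios ---------------------------------------------------

def default_scenario(seed: int = 0) -> SyntheticConfig:
    """Pipeline demo: 3 stages x 3 replicates, planted DE and 2 ceRNA
    pairs whose members are also DE (so they survive the network gates).

    Choices that matter at this (triplicate, 3v3) design:

    * ceRNA members follow monotone stage trajectories (+3/+6 log2 for
      lncRNA/mRNA, mirrored for miRNAs) so Spearman/Pearson thresholds
      are met by the stage structure itself; the latent coupling beta is
      kept small because it inflates within-group variance and would
      defeat the members' own DE detection.
    * each ceRNA pair shares two planted miRNAs: with a single shared
      miRNA the sponge test's best attainable p equals 1/M, which cannot
      clear the strict p < 0.05 gate for small miRNA universes.
    * a wide coding background dilutes the library-size distortion the
      (necessarily large) planted effects exert on FPKM values of
      everything else; extra planted mRNAs occupy the leading BH ranks
      so marginal members are not alone at the FDR boundary.
    * miRNAs get a deeper baseline so the -6 log2 trajectory stays away
      from the zero-count floor.
    """
    cfg = SyntheticConfig(
        seed=seed,
        n_chrom=8,
        chrom_length_bp=15_000_000,
        n_coding_genes=400,
        n_lncrna_per_class=4,
        n_mirna=20,
        dispersion=0.02,
        mirna_baseline_mean=3200.0,
    )
    effects = []
    for tid in ("mrna0001", "mrna0002", "lnc_intergenic_001", "lnc_intergenic_002"):
        effects += [
            PlantedEffect(tid, "IV", "V", 3.0),
            PlantedEffect(tid, "V", "VI", 6.0),
        ]
    for tid in ("mir0001", "mir0002", "mir0003", "mir0004"):
        effects += [
            PlantedEffect(tid, "IV", "V", -3.0),
            PlantedEffect(tid, "V", "VI", -6.0),
        ]
    for i in range(3, 11):
        sign = 1.0 if i % 2 else -1.0
        effects.append(PlantedEffect(f"mrna{i:04d}", "IV", "V", 4.0 * sign))
        effects.append(PlantedEffect(f"mrna{i + 10:04d}", "V", "VI", 4.0 * sign))
    effects += [
        PlantedEffect("lnc_antisense_001", "V", "VI", 4.0),
        PlantedEffect("lnc_bidirectional_001", "IV", "V", 4.0),
    ]
    cfg.planted_de = effects
    cfg.planted_triplets = [
        PlantedTriplet("lnc_intergenic_001", "mir0001", "mrna0001", 0.15),
        PlantedTriplet("lnc_intergenic_001", "mir0002", "mrna0001", 0.15),
        PlantedTriplet("lnc_intergenic_002", "mir0003", "mrna0002", 0.15),
        PlantedTriplet("lnc_intergenic_002", "mir0004", "mrna0002", 0.15),
    ]
    cfg.qpcr_folds = {"IV": 1.0, "V": 8.0, "VI": 0.5}
    return cfg


def triplet_recovery_scenario(
    seed: int = 0,
    beta: float = 1.5,
    n_samples: int = 30,
    n_decoys: int = 50,
    n_mirna: int = 30,
) -> SyntheticConfig:
    """Correlation-threshold recovery: 2 planted triplets among decoys.

    Uses a wide single-comparison design (default 30 samples) because
    SCC/PCC thresholds at n = 9 are noise-dominated.
    """
    half = n_samples // 2
    n_genes = max(2 + n_decoys // 2, 5)
    per_class = max(1, -(-(2 + n_decoys // 2) // len(PLANTABLE_CLASSES)))
    cfg = SyntheticConfig(
        seed=seed,
        n_coding_genes=n_genes,
        n_lncrna_per_class=min(per_class, n_genes),
        n_mirna=n_mirna,
        design=[("IV", half), ("V", n_samples - half)],
        dispersion=0.05,
    )
    lnc_ids = cfg.all_lncrna_ids()
    cfg.planted_triplets = [
        PlantedTriplet(lnc_ids[0], "mir0001", "mrna0001", beta),
        PlantedTriplet(lnc_ids[1], "mir0002", "mrna0002", beta),
    ]
    return cfg


# -- file output ------------------------------------------------------------

def write_fasta(seqs: Mapping[str, str], path: str | Path) -> None:
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in seqs.items()
    ]
    seqio_write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    from Bio.SeqIO import parse

    return {rec.id: str(rec.seq) for rec in parse(str(path), "fasta")}


def write_truth(truth: SyntheticTruth, outdir: str | Path) -> None:
    outdir = Path(outdir)
    pd.DataFrame(
        [{"transcript_id": k, "class": v} for k, v in sorted(truth.class_of.items())]
    ).to_csv(outdir / "truth_classes.tsv", sep="\t", index=False)
    pd.DataFrame(
        truth.target_pairs, columns=["lncrna_id", "gene_id", "mechanism"]
    ).to_csv(outdir / "truth_targets.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {"comparison": c, "transcript_id": t}
            for c in sorted(truth.de_ids)
            for t in sorted(truth.de_ids[c])
        ]
    ).to_csv(outdir / "truth_de.tsv", sep="\t", index=False)
    pd.DataFrame(
        [
            {
                "lncrna_id": t.lncrna_id,
                "mirna_id": t.mirna_id,
                "mrna_id": t.mrna_id,
                "beta": t.beta,
            }
            for t in truth.triplets
        ]
    ).to_csv(outdir / "truth_triplets.tsv", sep="\t", index=False)
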