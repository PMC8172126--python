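import logging
from math import comb

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lncnet import synthetic
from lncnet.enrichment import (
    GeneSetCollection,
    gsea_es,
    gsea_permutation,
    ora_hypergeometric,
    read_gmt,
    snr_rank,
    write_gmt,
)
from lncnet.expression import compute_fpkm


def _sets(**kwargs):
    return GeneSetCollection({k: (k, v) for k, v in kwargs.items()})


class TestOra:
    def test_worked_example(self):
        # N=20 background, K=5 in set, n=5 DE, k=3 -> 1126/15504
        background = [f"g{i}" for i in range(20)]
        sets = _sets(s1=background[:5])
        de = background[:3] + background[10:12]
        res = ora_hypergeometric(de, background, sets)
        assert res.loc["s1", "k"] == 3
        assert res.loc["s1", "pvalue"] == pytest.approx(1126 / 15504, abs=1e-12)

    def test_k_zero_p_one(self):
        background = [f"g{i}" for i in range(20)]
        res = ora_hypergeometric(
            background[10:12], background, _sets(s1=background[:5])
        )
        assert res.loc["s1", "pvalue"] == 1.0

    def test_set_equals_background_p_one(self):
        background = [f"g{i}" for i in range(8)]
        res = ora_hypergeometric(background[:3], background, _sets(s1=background))
        assert res.loc["s1", "pvalue"] == pytest.approx(1.0, abs=1e-12)

    def test_de_outside_background_raises(self):
        with pytest.raises(ValueError, match="ghost"):
            ora_hypergeometric(["ghost"], ["a", "b"], _sets(s1=["a"]))

    def test_gmt_round_trip(self, tmp_path):
        sets = _sets(s1=["a", "b"], s2=["c", "d", "e"])
        path = tmp_path / "x.gmt"
        write_gmt(sets, path)
        back = read_gmt(path)
        assert back.sets == sets.sets


class TestSnrRank:
    def test_sigma_floor_example(self, design_3v3):
        # log2(FPKM+1) values 2,2,2 vs 1,1,1 -> (2-1)/(0.4+0.2) = 1.6667
        fpkm = pd.DataFrame(
            [[3, 3, 3, 1, 1, 1]], columns=design_3v3["sample_id"], index=["t"]
        )
        ranked = snr_rank(fpkm, design_3v3, "IV", "V")
        assert ranked.loc["t"] == pytest.approx(1 / 0.6, abs=1e-9)

    def test_equal_means_zero_metric(self, design_3v3):
        fpkm = pd.DataFrame(
            [[4, 5, 6, 6, 5, 4]], columns=design_3v3["sample_id"], index=["t"]
        )
        assert snr_rank(fpkm, design_3v3, "IV", "V").loc["t"] == pytest.approx(0.0)

    def test_label_swap_antisymmetry(self, design_3v3, rng):
        fpkm = pd.DataFrame(
            rng.uniform(0, 50, size=(30, 6)),
            columns=design_3v3["sample_id"],
            index=[f"t{i}" for i in range(30)],
        )
        fwd = snr_rank(fpkm, design_3v3, "IV", "V")
        rev = snr_rank(fpkm, design_3v3, "V", "IV")
        assert np.allclose(fwd.sort_index(), -rev.sort_index())
        assert list(fwd.index) == list(rev.index[::-1])


def ks_statistic_oracle(hit_mask):
    """Signed KS statistic between hit and miss rank CDFs (brute force)."""
    hit = np.asarray(hit_mask, dtype=bool)
    f_hit = np.cumsum(hit) / hit.sum()
    f_miss = np.cumsum(~hit) / (~hit).sum()
    dev = f_hit - f_miss
    return dev[np.argmax(np.abs(dev))]


class TestGseaEs:
    def _ranking(self, n=20):
        return pd.Series(
            np.linspace(3, -3, n), index=[f"g{i}" for i in range(n)]
        )

    def test_singleton_top_gene_es_one(self):
        ranking = self._ranking()
        es, leading = gsea_es(ranking, {"g0"})
        assert es == pytest.approx(1.0)
        assert leading == ["g0"]

    def test_weight_zero_equals_ks_oracle(self, rng):
        for _ in range(100):
            genes = [f"g{i}" for i in range(50)]
            ranking = pd.Series(np.sort(rng.normal(size=50))[::-1], index=genes)
            members = list(rng.choice(genes, size=rng.integers(3, 20), replace=False))
            es, _ = gsea_es(ranking, members, weight=0.0)
            hit = np.isin(genes, members)
            ks = ks_statistic_oracle(hit)
            assert abs(es) == pytest.approx(abs(ks), abs=1e-12)
            f_hit = np.cumsum(hit) / hit.sum()
            dev = f_hit - np.cumsum(~hit) / (~hit).sum()
            top_two = np.sort(np.abs(dev))[-2:]
            if top_two[1] - top_two[0] > 1e-9:  # extremum sign determined
                assert es == pytest.approx(ks, abs=1e-12)

    def test_reversal_negates_es_with_symmetric_metric(self):
        ranking = self._ranking(30)
        members = {"g2", "g3", "g7"}
        es_fwd, _ = gsea_es(ranking, members, weight=0.0)
        reversed_ranking = ranking.iloc[::-1]
        es_rev, _ = gsea_es(reversed_ranking, members, weight=0.0)
        assert es_fwd == pytest.approx(-es_rev, abs=1e-12)

    def test_empty_intersection_raises(self):
        with pytest.raises(ValueError, match="intersect"):
            gsea_es(self._ranking(), {"missing"})

    @settings(max_examples=30, deadline=None)
    @given(st.integers(min_value=0, max_value=10_000))
    def test_es_bounds(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        genes = [f"g{i}" for i in range(n)]
        ranking = pd.Series(np.sort(rng.normal(size=n))[::-1], index=genes)
        members = list(
            rng.choice(genes, size=int(rng.integers(1, n + 1)), replace=False)
        )
        es, _ = gsea_es(ranking, members)
        assert -1.0 <= es <= 1.0


class TestGseaPermutation:
    def _fpkm_design(self, seed=0, n_genes=60):
        rng = np.random.default_rng(seed)
        design = pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(6)],
                "stage": ["IV"] * 3 + ["V"] * 3,
                "replicate": [1, 2, 3, 1, 2, 3],
            }
        )
        fpkm = pd.DataFrame(
            rng.uniform(0, 100, size=(n_genes, 6)),
            columns=design["sample_id"],
            index=[f"g{i}" for i in range(n_genes)],
        )
        return fpkm, design

    def test_3v3_exhaustive_is_20_assignments(self, caplog):
        fpkm, design = self._fpkm_design()
        sets = _sets(s1=[f"g{i}" for i in range(10)])
        with caplog.at_level(logging.WARNING, logger="lncnet.enrichment"):
            res = gsea_permutation(fpkm, design, sets, "IV", "V", n_perm=1000,
                                   min_size=2)
        assert res.attrs["n_perm"] == comb(6, 3) == 20
        assert res.attrs["exhaustive"]
        assert "floor" in caplog.text
        # p granularity: multiples of 1/#same-sign assignments, >= 1/20
        assert res.loc["s1", "nominal_p"] >= 1 / 20

    def test_too_few_permutations_raises(self):
        fpkm, _ = self._fpkm_design()
        design = pd.DataFrame(
            {
                "sample_id": ["a", "b"],
                "stage": ["IV", "V"],
                "replicate": [1, 1],
            }
        )
        with pytest.raises(ValueError, match="gene-set permutation"):
            gsea_permutation(
                fpkm[["s0", "s1"]].rename(columns={"s0": "a", "s1": "b"}),
                design,
                _sets(s1=["g1", "g2"]),
                "IV",
                "V",
                min_size=1,
            )

    def test_planted_set_recovered_at_standard_gates(self):
        # 5v5 so the exhaustive floor (1/252) can clear p < 0.05; high
        # dispersion so label permutations decorrelate the set members
        significant = 0
        for seed in range(10):
            cfg = synthetic.SyntheticConfig(
                seed=seed,
                n_coding_genes=100,
                n_lncrna_per_class=0,
                n_mirna=0,
                design=[("IV", 5), ("V", 5)],
                dispersion=1.0,
                n_chrom=4,
                chrom_length_bp=20_000_000,
            )
            ids = [f"mrna{i:04d}" for i in range(1, 9)]
            cfg.planted_de = [
                synthetic.PlantedEffect(t, "IV", "V", -4.0) for t in ids
            ]
            ann, truth = synthetic.generate_annotation(cfg)
            m, _, _ = synthetic.generate_counts(ann, truth, cfg)
            sets = GeneSetCollection(
                synthetic.generate_gene_sets(truth, ann, cfg)
            )
            res = gsea_permutation(
                compute_fpkm(m),
                cfg.design_frame(),
                sets,
                "IV",
                "V",
                n_perm=300,
                seed=seed,
                min_size=2,
            )
            significant += bool(res.loc["planted_IV_vs_V", "significant"])
        assert significant >= 8

    def test_nes_exactly_one_not_significant(self, design_3v3):
        # strict gate semantics on a synthetic result row
        fpkm, design = self._fpkm_design(3)
        sets = _sets(s1=[f"g{i}" for i in range(8)])
        res = gsea_permutation(fpkm, design, sets, "IV", "V", min_size=2)
        row = res.loc["s1"]
        if abs(row["nes"]) <= 1.0:
            assert not row["significant"]
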