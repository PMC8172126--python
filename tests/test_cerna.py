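from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
import pytest

from lncnet import synthetic
from lncnet.cerna import (
    build_network,
    pcc_filter,
    scc_filter,
    seed_match,
    seed_sites,
    sponge_pairs,
    sponge_test,
    write_graphml,
    write_sif,
)
from lncnet.expression import compute_fpkm


class TestSeedMatch:
    MIRNA = "UGGAAUGUAAAGAAGUAUGUA"

    def test_site_motifs(self):
        sites = seed_sites(self.MIRNA)
        # reverse complement of positions 2-8 (GGAAUGU) plus A1
        assert sites["8mer"] == "ACATTCCA"
        assert sites["7mer-m8"] == "ACATTCC"
        assert sites["7mer-A1"] == "CATTCCA"

    def test_8mer_hit(self):
        target = {"t": "GGGGG" + "ACAUUCCA" + "GGGGG"}
        res = seed_match({"mir": self.MIRNA}, target)
        assert res.iloc[0]["site_type"] == "8mer"

    def test_full_revcomp_contains_7mer_m8(self):
        comp = str.maketrans("ACGU", "UGCA")
        target = {"t": self.MIRNA.translate(comp)[::-1]}
        res = seed_match({"mir": self.MIRNA}, target)
        assert len(res) == 1
        assert res.iloc[0]["site_type"] in {"8mer", "7mer-m8"}

    def test_strongest_site_kept(self):
        target = {"t": "CATTCCA" + "GGGG" + "ACATTCCA"}  # 7mer-A1 and 8mer
        res = seed_match({"mir": self.MIRNA}, target)
        assert len(res) == 1
        assert res.iloc[0]["site_type"] == "8mer"

    def test_no_hit_on_clean_sequence(self):
        res = seed_match({"mir": self.MIRNA}, {"t": "G" * 50})
        assert res.empty

    def test_non_iupac_raises(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            seed_match({"mir": self.MIRNA}, {"t": "ACGT1234"})

    def test_short_mirna_raises(self):
        with pytest.raises(ValueError, match="8 nt"):
            seed_sites("ACGUACG")

    def test_generated_decoys_have_no_sites(self):
        cfg = synthetic.triplet_recovery_scenario(seed=4, n_decoys=10, n_mirna=10)
        ann, truth = synthetic.generate_annotation(cfg)
        targets, mirnas = synthetic.generate_sequences(ann, truth, cfg)
        res = seed_match(mirnas, targets)
        planted = {
            (t.mirna_id, x) for t in truth.triplets for x in (t.lncrna_id, t.mrna_id)
        }
        found = set(zip(res["mirna_id"], res["target_id"]))
        assert found == planted


def _corr_frames(x, y, ids=("mir", "tgt")):
    cols = [f"s{i}" for i in range(len(x))]
    a = pd.DataFrame([x], index=[ids[0]], columns=cols)
    b = pd.DataFrame([y], index=[ids[1]], columns=cols)
    return a, b


class TestSccFilter:
    def _cand(self):
        return pd.DataFrame(
            [{"mirna_id": "mir", "target_id": "tgt", "target_kind": "mRNA",
              "site_type": "8mer"}]
        )

    def test_monotone_decreasing_kept(self):
        mir, tgt = _corr_frames([1, 2, 3, 4, 5], [50, 40, 30, 20, 10])
        out = scc_filter(self._cand(), mir, tgt)
        assert len(out) == 1
        assert out.iloc[0]["scc"] == pytest.approx(-1.0)

    def test_exact_boundary_dropped(self):
        # rho = -0.7 exactly: d^2 sum of 17 at n=5 gives 1-6*17/120 = 0.15;
        # construct rho == -0.7 via y ranks [2,5,3,1,4] ... use direct check
        mir, tgt = _corr_frames([1, 2, 3, 4, 5], [4, 5, 1, 3, 2])
        from scipy.stats import spearmanr

        rho = spearmanr([1, 2, 3, 4, 5], [4, 5, 1, 3, 2]).statistic
        out = scc_filter(self._cand(), mir, tgt, scc_max=rho)
        assert out.empty  # strict inequality

    def test_matches_brute_force_formula_no_ties(self, rng):
        # rho = 1 - 6 sum d^2 / (n (n^2-1)) on tie-free data
        from scipy.stats import rankdata

        x = rng.permutation(20).astype(float)
        y = rng.permutation(20).astype(float)
        d = rankdata(x) - rankdata(y)
        rho_formula = 1 - 6 * (d**2).sum() / (20 * (400 - 1))
        mir, tgt = _corr_frames(x, y)
        out = scc_filter(self._cand(), mir, tgt, scc_max=2.0)
        assert out.iloc[0]["scc"] == pytest.approx(rho_formula, abs=1e-12)

    def test_constant_series_dropped(self, caplog):
        mir, tgt = _corr_frames([1, 1, 1, 1], [4, 3, 2, 1])
        with caplog.at_level("WARNING"):
            out = scc_filter(self._cand(), mir, tgt)
        assert out.empty
        assert "constant" in caplog.text


class TestPccFilter:
    def _pairs(self):
        return pd.DataFrame([{"lncrna_id": "lnc", "mrna_id": "m"}])

    def test_above_threshold_kept(self):
        lnc, m = _corr_frames([1, 2, 3, 4, 6], [1.1, 2, 3.2, 4, 5.9], ("lnc", "m"))
        out = pcc_filter(self._pairs(), lnc, m)
        assert len(out) == 1 and out.iloc[0]["pcc"] > 0.9

    def test_exact_boundary_dropped(self):
        lnc, m = _corr_frames([1, 2, 3], [1, 2, 3], ("lnc", "m"))
        out = pcc_filter(self._pairs(), lnc, m, pcc_min=1.0)
        assert out.empty  # r == 1.0 is not > 1.0

    def test_anticorrelated_dropped(self):
        lnc, m = _corr_frames([1, 2, 3, 4], [8, 6, 4, 2], ("lnc", "m"))
        assert pcc_filter(self._pairs(), lnc, m).empty


def sponge_by_enumeration(K_ids, n_ids, universe, k):
    hits = total = 0
    n = len(n_ids)
    for draw in combinations(sorted(universe), n):
        total += 1
        hits += len(set(draw) & set(K_ids)) >= k
    return hits / total


class TestSpongeTest:
    def test_worked_example(self):
        # M=10, K=4, n=5, k=3 -> 66/252
        uni = [f"m{i}" for i in range(10)]
        res = sponge_test(uni[:4], uni[1:6], uni)
        assert (res.k, res.K, res.n, res.M) == (3, 4, 5, 10)
        assert res.pvalue == pytest.approx(66 / 252, abs=1e-12)
        assert res.pvalue == pytest.approx(
            sponge_by_enumeration(uni[:4], uni[1:6], uni, 3), abs=1e-12
        )

    def test_disjoint_sets_p_one(self):
        uni = [f"m{i}" for i in range(8)]
        res = sponge_test(uni[:3], uni[4:6], uni)
        assert res.k == 0 and res.pvalue == 1.0

    def test_degenerate_full_overlap(self):
        uni = [f"m{i}" for i in range(5)]
        res = sponge_test(uni, uni, uni)
        assert res.k == 5 and res.pvalue == pytest.approx(1.0, abs=1e-12)

    def test_empty_universe_raises(self):
        with pytest.raises(ValueError, match="universe"):
            sponge_test([], [], [])

    def test_not_subset_raises(self):
        with pytest.raises(ValueError, match="subset"):
            sponge_test(["x"], [], ["a", "b"])

    def test_monotone_in_k(self):
        uni = [f"m{i}" for i in range(12)]
        ps = []
        for k in range(5):
            lnc = uni[:5]
            mrna = uni[5 - k: 10 - k]  # shift to control overlap
            res = sponge_test(lnc, mrna, uni)
            ps.append((res.k, res.pvalue))
        ps.sort()
        values = [p for _, p in ps]
        assert all(a >= b - 1e-15 for a, b in zip(values, values[1:]))


class TestNetwork:
    def _minimal_tables(self):
        candidates = pd.DataFrame(
            [
                {"mirna_id": "mir1", "target_id": "lnc1", "target_kind": "lncRNA",
                 "site_type": "8mer", "scc": -0.9},
                {"mirna_id": "mir1", "target_id": "m1", "target_kind": "mRNA",
                 "site_type": "8mer", "scc": -0.8},
            ]
        )
        sponge = pd.DataFrame(
            [
                {"lncrna_id": "lnc1", "mrna_id": "m1", "shared_k": 1, "K": 1,
                 "n": 1, "M": 30, "pvalue": 0.03, "shared_mirnas": "mir1",
                 "pcc": 0.95}
            ]
        )
        return sponge, candidates

    def test_minimal_triplet_three_nodes_three_edges(self):
        sponge, candidates = self._minimal_tables()
        g = build_network(sponge, candidates)
        assert g.number_of_nodes() == 3
        assert g.number_of_edges() == 3
        assert g.nodes["mir1"]["kind"] == "miRNA"

    def test_removing_shared_mirna_removes_edge(self):
        sponge, candidates = self._minimal_tables()
        g = build_network(sponge, candidates[candidates["mirna_id"] != "mir1"])
        assert not g.has_edge("lnc1", "m1")
        assert g.number_of_nodes() == 0  # no isolates

    def test_every_pair_edge_certified_by_shared_mirna(self):
        sponge, candidates = self._minimal_tables()
        g = build_network(sponge, candidates)
        for u, v, data in g.edges(data=True):
            if data["interaction"] != "lncRNA-mRNA":
                continue
            shared = set(g.neighbors(u)) & set(g.neighbors(v))
            assert any(g.nodes[m]["kind"] == "miRNA" for m in shared)

    def test_exports(self, tmp_path):
        sponge, candidates = self._minimal_tables()
        g = build_network(sponge, candidates)
        sif = tmp_path / "n.sif"
        gml = tmp_path / "n.graphml"
        write_sif(g, sif)
        write_graphml(g, gml)
        lines = sif.read_text().strip().split("\n")
        assert len(lines) == 3
        assert all(len(l.split("\t")) == 3 for l in lines)
        import networkx as nx

        back = nx.read_graphml(gml)
        assert back.number_of_edges() == 3


class TestSpongePairs:
    def test_universe_default_is_candidate_mirnas(self):
        candidates = pd.DataFrame(
            [
                {"mirna_id": "mir1", "target_id": "lnc1", "target_kind": "lncRNA",
                 "site_type": "8mer"},
                {"mirna_id": "mir1", "target_id": "m1", "target_kind": "mRNA",
                 "site_type": "8mer"},
            ]
        )
        # M = 1 -> p = 1, never below 0.05
        assert sponge_pairs(candidates).empty
        out = sponge_pairs(candidates, universe=[f"x{i}" for i in range(29)] + ["mir1"])
        assert len(out) == 1
        assert out.iloc[0]["pvalue"] == pytest.approx(1 / 30, abs=1e-12)
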