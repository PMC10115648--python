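import numpy as np
import pandas as pd
import pytest

from nlpipe import (
    DataModelError,
    clump,
    heidi,
    pgs_score,
    read_ma,
    simulate_genotypes,
    simulate_smr_datasets,
    smr,
    twas_predict,
    write_ma,
    SimConfig,
)


def _ss(rows):
    return pd.DataFrame(rows, columns=["SNP", "A1", "A2", "freq", "b", "se", "p", "n", "bp"])


class TestClump:
    def _ld(self, snps, r):
        mat = np.full((len(snps), len(snps)), r, dtype=float)
        np.fill_diagonal(mat, 1.0)
        return pd.DataFrame(mat, index=snps, columns=snps)

    def test_in_window_correlated_pair_keeps_best(self):
        ss = _ss([("rs1", "A", "G", 0.3, 0.2, 0.02, 1e-10, 5000, 1_000_000),
                  ("rs2", "A", "G", 0.4, 0.1, 0.02, 1e-8, 5000, 1_100_000)])
        kept = clump(ss, self._ld(["rs1", "rs2"], np.sqrt(0.5)))
        assert kept == ["rs1"]

    def test_outside_window_both_kept(self):
        ss = _ss([("rs1", "A", "G", 0.3, 0.2, 0.02, 1e-10, 5000, 1_000_000),
                  ("rs2", "A", "G", 0.4, 0.1, 0.02, 1e-8, 5000, 1_300_000)])
        kept = clump(ss, self._ld(["rs1", "rs2"], np.sqrt(0.5)))
        assert kept == ["rs1", "rs2"]

    def test_row_order_invariance(self):
        rows = [("rs1", "A", "G", 0.3, 0.2, 0.02, 1e-10, 5000, 1_000_000),
                ("rs2", "A", "G", 0.4, 0.1, 0.02, 1e-8, 5000, 1_100_000),
                ("rs3", "A", "G", 0.4, 0.1, 0.02, 1e-9, 5000, 4_000_000)]
        ld = self._ld(["rs1", "rs2", "rs3"], 0.0)
        ld.loc["rs1", "rs2"] = ld.loc["rs2", "rs1"] = 0.9
        assert clump(_ss(rows), ld) == clump(_ss(rows[::-1]), ld)

    def test_simulated_blocks_one_index_each(self):
        cfg = SimConfig(seed=21, n_samples=4000, n_snps=12, ld_block_size=4,
                        n_causal_snps=3, snp_h2=0.4, n_gwas=6000)
        dosages, ss, _ = simulate_genotypes(cfg)
        ss = ss.copy()
        ss["bp"] = np.arange(12) * 1000  # all within one window
        ld = pd.DataFrame(np.corrcoef(dosages.to_numpy().T),
                          index=ss["SNP"].to_numpy(), columns=ss["SNP"].to_numpy())
        kept = clump(ss, ld, p_threshold=1e-4)
        blocks = {int(s[2:]) // 4 for s in kept}
        assert len(kept) == len(blocks)  # at most one index SNP per LD block


class TestPgs:
    def _dosages(self):
        return pd.DataFrame({"rs1": [0.0, 1.0, 2.0]}, index=["i1", "i2", "i3"])

    def test_raw_weighted_sum(self):
        ss = _ss([("rs1", "A", "G", 0.5, 0.5, 0.1, 1e-9, 1000, 1)])
        score = pgs_score(self._dosages(), ss, standardize=False)
        np.testing.assert_allclose(score.to_numpy(), [0.0, 0.5, 1.0])

    def test_allele_flip_invariance(self):
        ss = _ss([("rs1", "A", "G", 0.5, 0.5, 0.1, 1e-9, 1000, 1)])
        flipped = _ss([("rs1", "G", "A", 0.5, -0.5, 0.1, 1e-9, 1000, 1)])
        d = self._dosages()
        a1 = pd.Series({"rs1": "A"})
        a2 = pd.Series({"rs1": "G"})
        s1 = pgs_score(d, ss, dosage_a1=a1, dosage_a2=a2, standardize=False)
        s2 = pgs_score(d, flipped, dosage_a1=a1, dosage_a2=a2, standardize=False)
        # flipping the effect allele and negating b shifts by a constant only
        diff = (s1 - s2).to_numpy()
        np.testing.assert_allclose(diff - diff.mean(), 0.0, atol=1e-12)
        z1 = pgs_score(d, ss, dosage_a1=a1, dosage_a2=a2)
        z2 = pgs_score(d, flipped, dosage_a1=a1, dosage_a2=a2)
        np.testing.assert_allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-12)

    def test_palindromic_snp_excluded(self):
        ss = _ss([("rs1", "A", "T", 0.5, 0.5, 0.1, 1e-9, 1000, 1)])
        with pytest.raises(DataModelError, match="harmonization"):
            pgs_score(self._dosages(), ss)

    def test_simulated_pgs_predicts_lipid(self):
        cfg = SimConfig(seed=31, n_samples=600, n_snps=40, n_causal_snps=5,
                        snp_h2=0.3, n_gwas=10_000)
        dosages, ss, effects = simulate_genotypes(cfg)
        rng = np.random.default_rng(32)
        causal = effects["index"].to_numpy()
        y = dosages.to_numpy()[:, causal] @ effects["beta"].to_numpy() \
            + rng.normal(0, np.sqrt(1 - cfg.snp_h2), 600)
        sig = ss[ss["p"] < 5e-4]
        score = pgs_score(dosages, sig)
        r2 = np.corrcoef(score, y)[0, 1] ** 2
        assert 0.1 <= r2 <= 0.4


class TestSmr:
    def _pair(self, b_zx=0.2, se_zx=0.02, b_zy=0.1, se_zy=0.02):
        sx = _ss([("rs1", "A", "G", 0.4, b_zx, se_zx, 1e-20, 10_000, 1)])
        sy = _ss([("rs1", "A", "G", 0.4, b_zy, se_zy, 1e-6, 10_000, 1)])
        return sx, sy

    def test_ratio_estimate(self):
        sx, sy = self._pair()
        res = smr("rs1", sx, sy)
        assert abs(res.b_xy - 0.5) < 1e-12

    def test_delta_method_se(self):
        sx, sy = self._pair()
        res = smr("rs1", sx, sy)
        expected = np.sqrt(0.5**2 * (0.02**2 / 0.1**2 + 0.02**2 / 0.2**2))
        assert abs(res.se_xy - expected) < 1e-12
        assert abs(res.se_xy - 0.1118) < 1e-4

    def test_zero_outcome_effect(self):
        sx, sy = self._pair(b_zy=0.0)
        res = smr("rs1", sx, sy)
        assert res.b_xy == 0.0 and res.p_smr > 0.9

    def test_sign_antisymmetry(self):
        sx, sy = self._pair()
        sy_neg = sy.copy()
        sy_neg["b"] = -sy_neg["b"]
        assert smr("rs1", sx, sy_neg).b_xy == -smr("rs1", sx, sy).b_xy

    def test_zero_instrument_effect_errors(self):
        sx, sy = self._pair(b_zx=0.0)
        with pytest.raises(DataModelError):
            smr("rs1", sx, sy)


class TestHeidi:
    def test_too_few_eligible_snps(self):
        sx, sy = TestSmr()._pair()
        ld = pd.DataFrame([[1.0]], index=["rs1"], columns=["rs1"])
        with pytest.raises(DataModelError, match="eligible"):
            heidi("rs1", ["rs1"], sx, sy, ld)

    def test_single_causal_null_not_rejected(self):
        # single-causal simulations: heterogeneity should rarely be declared
        rejections = 0
        for i in range(6):
            ssx, ssy, ld, inst = simulate_smr_datasets(seed=4000 + i, n_gwas=8000)
            p, n_used = heidi(inst, list(ssx["SNP"]), ssx, ssy, ld)
            assert n_used >= 3
            rejections += p < 0.05
        assert rejections <= 1

    def test_two_causal_heterogeneity_rejected(self):
        rejections = 0
        for i in range(6):
            ssx, ssy, ld, inst = simulate_smr_datasets(seed=5000 + i, n_gwas=8000,
                                                       two_causal=True)
            p, _ = heidi(inst, list(ssx["SNP"]), ssx, ssy, ld)
            rejections += p < 0.05
        assert rejections >= 5


class TestTwas:
    def test_weighted_dosage_sum(self):
        dosages = pd.DataFrame({"rs1": [2.0], "rs2": [1.0]}, index=["i1"])
        weights = pd.DataFrame({"SNP": ["rs1", "rs2"], "A1": ["A", "A"],
                                "A2": ["G", "G"], "weight": [0.2, -0.1],
                                "gene": ["FADS1", "FADS1"]})
        pred = twas_predict(dosages, weights)
        assert abs(pred.loc["i1", "FADS1"] - 0.3) < 1e-12

    def test_zero_weights_zero_prediction(self):
        dosages = pd.DataFrame({"rs1": [0.0, 1.0, 2.0]}, index=["a", "b", "c"])
        weights = pd.DataFrame({"SNP": ["rs1"], "A1": ["A"], "A2": ["G"],
                                "weight": [0.0], "gene": ["g"]})
        assert (twas_predict(dosages, weights)["g"] == 0.0).all()

    def test_predicted_expression_tracks_truth(self):
        cfg = SimConfig(seed=41, n_samples=600, n_snps=30, n_causal_snps=4,
                        snp_h2=0.2, n_gwas=20_000)
        dosages, ss, effects = simulate_genotypes(cfg)
        rng = np.random.default_rng(42)
        causal = effects["index"].to_numpy()
        expr = dosages.to_numpy()[:, causal] @ effects["beta"].to_numpy() \
            + rng.normal(0, np.sqrt(1 - cfg.snp_h2), 600)
        # weights: the oracle GWAS effects at nominally significant SNPs
        sig = ss[ss["p"] < 1e-3]
        weights = pd.DataFrame({"SNP": sig["SNP"], "A1": sig["A1"], "A2": sig["A2"],
                                "weight": sig["b"], "gene": "g"})
        pred = twas_predict(dosages, weights)["g"]
        assert np.corrcoef(pred, expr)[0, 1] > 0.3


def test_ma_roundtrip(tmp_path):
    cfg = SimConfig(seed=51, n_samples=50, n_snps=8)
    _, ss, _ = simulate_genotypes(cfg)
    write_ma(ss, tmp_path / "x.ma")
    back = read_ma(tmp_path / "x.ma")
    np.testing.assert_allclose(back["b"].to_numpy(), ss["b"].to_numpy(), rtol=1e-12)
    assert list(back["SNP"]) == list(ss["SNP"])
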