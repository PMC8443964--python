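"""The simulator must deliver the statistical structure the pipeline assumes:
controllable LD, exact marginal allele frequencies, correlated phenotypes,
and textbook univariate regression summary statistics."""

import numpy as np
import pandas as pd
import pytest

from pleiocca import (
    ParameterError,
    SimulationConfig,
    compute_univariate_gwas,
    ld_r2,
    simulate_panel,
    simulate_phenotypes,
    write_study,
)
from pleiocca.errors import ConsistencyError
from pleiocca.sumstats_io import read_sumstats
from pleiocca.synthetic_data import GroundTruth, draw_ground_truth, simulate_all


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"maf_range": (0.0, 0.5)},
            {"maf_range": (0.1, 0.6)},
            {"rho": 1.0},
            {"pheno_corr": 1.5},
            {"block_size": 0},
            {"n_snps": 0},
            {"n_snps": 10, "n_pleiotropic": 6, "n_private_1": 6, "n_private_2": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ParameterError):
            SimulationConfig(**kwargs).validate()


class TestPanel:
    def test_same_seed_identical(self):
        cfg = SimulationConfig(n_ref=200, n_snps=50, n_pleiotropic=5,
                               n_private_1=5, n_private_2=5, seed=5)
        a, b = simulate_panel(cfg), simulate_panel(cfg)
        assert np.array_equal(a.dosage, b.dosage)
        assert list(a.snp_ids) == list(b.snp_ids)

    def test_independent_snps_have_null_ld(self, null_panel):
        x = null_panel.dosage.astype(float)
        r = np.corrcoef(x, rowvar=False)
        off = r[np.triu_indices_from(r, 1)]
        assert np.mean(off**2) < 3.0 / null_panel.n_samples

    def test_ar_blocks_produce_strong_ld(self):
        # matched MAFs isolate the AR parameter from thresholding attenuation
        cfg = SimulationConfig(
            n_ref=1000, n_snps=100, rho=0.99, block_size=2,
            maf_range=(0.3, 0.5), seed=3,
        )
        panel = simulate_panel(cfg)
        pair_r2 = [
            ld_r2(panel, panel.snp_ids[i], panel.snp_ids[i + 1])
            for i in range(0, 100, 2)
        ]
        assert np.mean(pair_r2) > 0.5

    def test_maf_fidelity(self):
        cfg = SimulationConfig(n_ref=2000, n_snps=200, rho=0.3, seed=9)
        seeds = np.random.SeedSequence(cfg.seed).spawn(1)
        rng = np.random.default_rng(seeds[0])
        from pleiocca.synthetic_data import _draw_mafs, _snp_metadata

        _snp_metadata(cfg, rng)
        target = _draw_mafs(cfg, rng)
        panel = simulate_panel(cfg)
        f = panel.dosage.mean(axis=0) / 2.0
        tol = 4.0 * np.sqrt(target * (1 - target) / (2 * cfg.n_ref))
        assert np.all(np.abs(f - target) <= tol)


class TestPhenotypes:
    def _null_truth(self, cfg):
        ids = [f"rs{100000 + i}" for i in range(cfg.n_snps)]
        return GroundTruth(snp_ids=ids, causal_1=[], causal_2=[],
                           effects=np.zeros((cfg.n_snps, 2)))

    def test_null_uncorrelated(self):
        cfg = SimulationConfig(n_snps=20, pheno_corr=0.0, n_pleiotropic=0,
                               n_private_1=0, n_private_2=0, seed=1)
        x = simulate_panel(cfg).dosage[:, : cfg.n_snps]
        y1, y2 = simulate_phenotypes(
            np.repeat(x, 5, axis=0), cfg, self._null_truth(cfg),
            np.random.default_rng(0))
        n = len(y1)
        assert abs(np.corrcoef(y1, y2)[0, 1]) < 4.0 / np.sqrt(n)

    def test_residual_correlation_recovered(self):
        cfg = SimulationConfig(n_snps=10, pheno_corr=0.8, n_pleiotropic=0,
                               n_private_1=0, n_private_2=0, seed=2)
        geno = np.random.default_rng(1).integers(0, 3, size=(5000, 10))
        y1, y2 = simulate_phenotypes(geno, cfg, self._null_truth(cfg),
                                     np.random.default_rng(3))
        assert abs(np.corrcoef(y1, y2)[0, 1] - 0.8) < 0.05

    def test_single_causal_effect_recovered(self):
        cfg = SimulationConfig(n_snps=10, effect_size=0.3, pheno_corr=0.0,
                               n_pleiotropic=0, n_private_1=0, n_private_2=0, seed=4)
        ids = [f"rs{100000 + i}" for i in range(10)]
        effects = np.zeros((10, 2))
        effects[3, 0] = 0.3
        truth = GroundTruth(snp_ids=ids, causal_1=[ids[3]], causal_2=[],
                            effects=effects)
        geno = np.random.default_rng(5).integers(0, 3, size=(4000, 10)).astype(float)
        y1, _ = simulate_phenotypes(geno, cfg, truth, np.random.default_rng(6))
        xs = (geno[:, 3] - geno[:, 3].mean()) / geno[:, 3].std()
        slope = np.polyfit(xs, y1, 1)[0]
        se = np.sqrt((1 - np.corrcoef(xs, y1)[0, 1] ** 2) / (len(y1) - 2))
        # phenotype is re-standardized, so the true slope is 0.3 / sd(y_raw)
        expected = 0.3 / np.sqrt(0.3**2 + 1.0)
        assert abs(slope - expected) < 3 * se

    def test_unknown_causal_snp_rejected(self):
        cfg = SimulationConfig(n_snps=5, seed=0)
        truth = GroundTruth(snp_ids=["a", "b", "c", "d", "e"],
                            causal_1=["zzz"], causal_2=[], effects=np.zeros((5, 2)))
        with pytest.raises(ConsistencyError):
            simulate_phenotypes(np.zeros((10, 5)), cfg, truth,
                                np.random.default_rng(0))


class TestUnivariateGwas:
    def test_beta_equals_correlation_for_standardized_inputs(self, rng):
        x = rng.standard_normal((500, 4))
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        y = rng.standard_normal(500)
        ys = (y - y.mean()) / y.std()
        res = compute_univariate_gwas(xs, ys)
        expect = np.array([np.corrcoef(xs[:, j], ys)[0, 1] for j in range(4)])
        assert np.allclose(res["BETA"], expect, atol=1e-10)

    def test_null_betas_centered(self, rng):
        # 500 independent null SNPs stand in for 500 replicates
        x = rng.integers(0, 3, size=(800, 500)).astype(float)
        y = rng.standard_normal(800)
        res = compute_univariate_gwas(x, y)
        b = res["BETA"].to_numpy()
        assert abs(b.mean()) < 4 * b.std() / np.sqrt(500)

    def test_se_matches_asymptotic_scale(self, rng):
        x = rng.standard_normal((1000, 50))
        xs = (x - x.mean(axis=0)) / x.std(axis=0)
        y = rng.standard_normal(1000)
        ys = (y - y.mean()) / y.std()
        res = compute_univariate_gwas(xs, ys)
        assert np.all(np.abs(res["SE"] - 1 / np.sqrt(1000)) < 0.1 / np.sqrt(1000))

    def test_monomorphic_flagged(self):
        x = np.ones((50, 2))
        x[:, 1] = np.arange(50) % 3
        res = compute_univariate_gwas(x, np.random.default_rng(0).standard_normal(50))
        assert not res["OK"][0] and np.isnan(res["SE"][0])
        assert res["OK"][1]


class TestWriteStudy:
    def test_round_trip(self, tmp_path, small_sim, small_cfg):
        path = tmp_path / "s.tsv"
        frame = small_sim["studies"][0]
        write_study(frame, path)
        back = read_sumstats(path, label="t", study_n=small_cfg.n_study_1)
        assert list(back.table["SNP"]) == list(frame["SNP"])
        assert np.allclose(back.table["BETA"], frame["BETA"], atol=1e-6)
        assert len(path.read_text().splitlines()) == len(frame) + 1

    def test_empty_results(self, tmp_path):
        cols = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "FREQ", "N"]
        empty = pd.DataFrame(columns=cols)
        path = tmp_path / "empty.tsv"
        write_study(empty, path)
        back = read_sumstats(path, label="t")
        assert len(back) == 0


class TestGroundTruth:
    def test_counts_and_overlap(self):
        cfg = SimulationConfig(n_snps=100, n_pleiotropic=4, n_private_1=3,
                               n_private_2=2, seed=0)
        ids = [f"rs{100000 + i}" for i in range(100)]
        truth = draw_ground_truth(cfg, ids, np.random.default_rng(0))
        assert len(truth.pleiotropic_snps) == 4
        assert len(truth.causal_1) == 7 and len(truth.causal_2) == 6
        assert set(truth.pleiotropic_snps) == set(truth.causal_1) & set(truth.causal_2)

    def test_bundle_deterministic(self, small_cfg, tmp_path):
        from pleiocca import simulate_bundle

        b1 = simulate_bundle(small_cfg, tmp_path / "a")
        b2 = simulate_bundle(small_cfg, tmp_path / "b")
        for key in ("study_1", "study_2", "panel_dosage"):
            t1 = open(b1["paths"][key]).read()
            t2 = open(b2["paths"][key]).read()
            assert t1 == t2
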