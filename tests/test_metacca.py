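"""Summary-statistics CCA: covariance assembly, canonical correlations
(against a dense-grid maximizer oracle), Bartlett significance, and the
SNP- and gene-level scans."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from pleiocca import (
    AnalysisConfig,
    ConsistencyError,
    DomainError,
    PhenoCorr,
    StandardizedBetaMatrix,
    assemble_full_cov,
    build_sigma_xy,
    canonical_corr,
    cca_pvalue,
    estimate_sigma_yy,
    gene_level_scan,
    genotype_corr,
    shrink_to_pd,
    univariate_snp_scan,
)
from pleiocca.sumstats_io import GeneRecord, HarmonizedPair, annotate_snps
from pleiocca.validation import as_study_summary


def _pair(rows):
    t = pd.DataFrame(rows, columns=["SNP", "CHR", "POS", "A1", "A2",
                                    "BETA_1", "SE_1", "N_1",
                                    "BETA_2", "SE_2", "N_2"])
    n1 = int(t["N_1"].max()) if len(t) else 0
    n2 = int(t["N_2"].max()) if len(t) else 0
    return HarmonizedPair(table=t, n_1=n1, n_2=n2, labels=("t1", "t2"))


def grid_cca_r1(xx, xy, yy, n_grid=200_000):
    """Independent maximizer oracle for p = 2 traits.

    Sweeps the trait weight b over a dense angular grid; for each b the
    optimal genotype weight has the closed form of a multiple regression,
    giving r(b) = sqrt((XYb)' XX^-1 (XYb) / (b' YY b)).
    """
    theta = np.linspace(0.0, np.pi, n_grid, endpoint=False)
    b = np.stack([np.cos(theta), np.sin(theta)])
    v = np.atleast_2d(xy) @ b
    w = np.linalg.solve(xx, v)
    num = (v * w).sum(axis=0)
    den = (b * (yy @ b)).sum(axis=0)
    return float(np.sqrt(np.max(num / den)))


class TestBuildSigmaXy:
    def test_standardizes_each_study(self):
        pair = _pair([("rs1", 1, 100, "A", "G", 0.1, 0.02, 100, -0.2, 0.04, 100)])
        s = build_sigma_xy(pair)
        assert np.allclose(s.values, [[0.5, -0.5]])

    def test_empty_pair_rejected(self):
        pair = _pair([])
        with pytest.raises(ConsistencyError):
            build_sigma_xy(pair)

    def test_per_snp_n_preferred_over_study_n(self):
        pair = _pair([("rs1", 1, 100, "A", "G", 0.1, 0.02, 400, 0.1, 0.02, 400),
                      ("rs2", 1, 200, "A", "G", 0.1, 0.02, 100, 0.1, 0.02, 100)])
        s = build_sigma_xy(pair)
        assert s.values[0, 0] == pytest.approx(0.1 / (20 * 0.02))
        assert s.values[1, 0] == pytest.approx(0.1 / (10 * 0.02))


class TestEstimateSigmaYy:
    def _matrix(self, values):
        g = len(values)
        return StandardizedBetaMatrix(
            values=np.asarray(values), snp_ids=[f"rs{i}" for i in range(g)],
            pheno_labels=("a", "b"))

    def test_identical_columns(self):
        col = [0.1, -0.2, 0.3, 0.05]
        yy = estimate_sigma_yy(self._matrix(np.column_stack([col, col])))
        assert yy.matrix[0, 1] == pytest.approx(1.0, abs=0.011)  # shrunk to PD
        assert np.linalg.eigvalsh(yy.matrix)[0] > 0

    def test_negated_column(self):
        col = np.array([0.1, -0.2, 0.3, 0.05])
        yy = estimate_sigma_yy(self._matrix(np.column_stack([col, -col])))
        assert yy.matrix[0, 1] == pytest.approx(-1.0, abs=0.011)

    def test_independent_columns_near_zero(self, rng):
        vals = rng.standard_normal((10_000, 2))
        yy = estimate_sigma_yy(self._matrix(vals))
        assert abs(yy.matrix[0, 1]) < 0.04

    def test_too_few_snps(self):
        with pytest.raises(DomainError):
            estimate_sigma_yy(self._matrix([[0.1, 0.2], [0.3, 0.4]]))


class TestAssembleFullCov:
    def test_block_structure_and_symmetry(self):
        xy = np.array([[0.0, 0.0]])
        yy = np.array([[1.0, 0.3], [0.3, 1.0]])
        full, lam = assemble_full_cov(np.eye(1), xy, yy)
        assert np.array_equal(full, full.T)
        assert np.allclose(full[:1, 1:], xy) and np.allclose(full[1:, 1:], yy)
        assert lam == 0.0

    def test_output_positive_definite(self, rng):
        for _ in range(5):
            g, p = 4, 2
            xy = rng.uniform(-0.9, 0.9, (g, p))  # often breaks PD-ness
            xx = np.eye(g)
            yy = np.eye(p)
            full, lam = assemble_full_cov(xx, xy, yy)
            assert np.linalg.eigvalsh(full)[0] >= 1e-8

    def test_dimension_mismatch(self):
        with pytest.raises(ConsistencyError):
            assemble_full_cov(np.eye(2), np.zeros((1, 2)), np.eye(2))


class TestCanonicalCorr:
    def test_zero_cross_covariance(self):
        r = canonical_corr(np.eye(3), np.zeros((3, 2)), np.eye(2))
        assert np.allclose(r, 0.0)

    def test_scalar_case(self):
        r = canonical_corr(np.array([[1.0]]), np.array([[0.3]]), np.array([[1.0]]))
        assert r[0] == pytest.approx(0.3)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_grid_oracle(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.standard_normal((40, 3))
        xx = np.corrcoef(a, rowvar=False)
        b = rng.standard_normal((40, 2))
        yy = np.corrcoef(b, rowvar=False)
        xy = rng.uniform(-0.2, 0.2, (3, 2))
        r = canonical_corr(xx, xy, yy)
        assert r[0] == pytest.approx(grid_cca_r1(xx, xy, yy), abs=1e-8)
        assert np.all((r >= 0) & (r <= 1)) and r[0] >= r[-1]

    def test_non_pd_rejected(self):
        xx = np.array([[1.0, 1.0], [1.0, 1.0]])
        with pytest.raises(DomainError):
            canonical_corr(xx, np.zeros((2, 2)), np.eye(2))


class TestCcaPvalue:
    def test_null_gives_p_one(self):
        stat, df, p = cca_pvalue([0.0, 0.0], n=1000, g=2, p=2)
        assert stat == pytest.approx(0.0) and p == pytest.approx(1.0)
        assert df == 4

    def test_monotone_in_r(self):
        ps = [cca_pvalue([r], n=500, g=1, p=2)[2] for r in (0.05, 0.1, 0.2, 0.4)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_scalar_limit_matches_pearson_test(self):
        n, r = 10_000, 0.05
        _, _, p_cca = cca_pvalue([r], n=n, g=1, p=1)
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p_pearson = 2 * stats.t.sf(t, n - 2)
        assert max(p_cca, p_pearson) / min(p_cca, p_pearson) < 1.05

    def test_small_n_rejected(self):
        with pytest.raises(DomainError):
            cca_pvalue([0.1], n=4, g=2, p=2)


class TestUnivariateScan:
    def _scan(self, values, panel, yy=None, n=5000):
        s = StandardizedBetaMatrix(
            values=np.asarray(values),
            snp_ids=list(panel.snp_ids[: len(values)]),
            pheno_labels=("a", "b"))
        yy = PhenoCorr(matrix=np.eye(2), n_snps_used=0) if yy is None else yy
        cfg = AnalysisConfig(n_effective=n)
        return univariate_snp_scan(s, panel, yy, cfg)

    def test_null_snp(self, null_panel):
        out = self._scan([[0.0, 0.0]], null_panel)
        assert out["R"].iloc[0] == 0.0 and out["PVAL"].iloc[0] == pytest.approx(1.0)

    def test_identity_yy_closed_form(self, null_panel, rng):
        vals = rng.uniform(-0.1, 0.1, (50, 2))
        out = self._scan(vals, null_panel)
        # output is genomic-sorted; map back by SNP ID
        expect = {s: np.hypot(a, b)
                  for s, (a, b) in zip(null_panel.snp_ids, vals)}
        got = dict(zip(out["SNP"], out["R"]))
        assert all(got[s] == pytest.approx(expect[s], abs=1e-8) for s in expect)

    def test_pleiotropic_snp_tops_scan(self, small_sim, small_cfg, small_panel):
        from pleiocca import build_sigma_xy, estimate_sigma_yy, harmonize

        s1 = as_study_summary(small_sim["studies"][0], "t1", small_cfg.n_study_1)
        s2 = as_study_summary(small_sim["studies"][1], "t2", small_cfg.n_study_2)
        pair = harmonize(s1, s2)
        s = build_sigma_xy(pair)
        yy = estimate_sigma_yy(s)
        cfg = AnalysisConfig(n_effective=min(pair.n_1, pair.n_2))
        out = univariate_snp_scan(s, small_panel, yy, cfg)
        top = out.nsmallest(1, "PVAL")["SNP"].iloc[0]
        causal = set(small_sim["truth"].causal_1) | set(small_sim["truth"].causal_2)
        assert top in causal


class TestGeneScan:
    def _inputs(self, small_sim, small_cfg):
        from pleiocca import build_sigma_xy, estimate_sigma_yy, harmonize
        from pleiocca.sumstats_io import read_gene_ranges

        s1 = as_study_summary(small_sim["studies"][0], "t1", small_cfg.n_study_1)
        s2 = as_study_summary(small_sim["studies"][1], "t2", small_cfg.n_study_2)
        pair = harmonize(s1, s2)
        genes = [GeneRecord(r.GENE, int(r.CHR), int(r.START), int(r.END))
                 for _, r in small_sim["gene_ranges"].iterrows()]
        ann = annotate_snps(pair, genes)
        s = build_sigma_xy(pair)
        yy = estimate_sigma_yy(s)
        return s, yy, ann, pair

    def test_single_snp_gene_matches_univariate(self, small_sim, small_cfg, small_panel):
        s, yy, ann, pair = self._inputs(small_sim, small_cfg)
        snp = s.snp_ids[0]
        one = {"G1": [snp]}
        ann.gene_snps = one
        ann.gene_records = {"G1": GeneRecord("G1", 1, 1, 10**9)}
        cfg = AnalysisConfig(n_effective=min(pair.n_1, pair.n_2))
        gene_out = gene_level_scan(s, small_panel, yy, ann, cfg)
        snp_out = univariate_snp_scan(s, small_panel, yy, cfg)
        row = snp_out[snp_out["SNP"] == snp].iloc[0]
        assert gene_out["R1"].iloc[0] == pytest.approx(row["R"], abs=1e-12)

    def test_zero_beta_gene_is_null(self, null_panel):
        snps = list(null_panel.snp_ids[:3])
        s = StandardizedBetaMatrix(values=np.zeros((3, 2)), snp_ids=snps,
                                   pheno_labels=("a", "b"))
        from pleiocca.sumstats_io import SnpAnnotation

        ann = SnpAnnotation(gene_snps={"G": snps},
                            gene_records={"G": GeneRecord("G", 1, 1, 10**9)},
                            annotated_snps=snps, unannotated_snps=[])
        yy = PhenoCorr(matrix=np.eye(2), n_snps_used=0)
        out = gene_level_scan(s, null_panel, yy, ann, AnalysisConfig(n_effective=1000))
        assert out["R1"].iloc[0] == 0.0 and out["PVAL"].iloc[0] == pytest.approx(1.0)

    def test_max_gene_snps_cap_keeps_highest_maf(self, small_panel):
        snps = list(small_panel.snp_ids[:10])
        s = StandardizedBetaMatrix(values=np.zeros((10, 2)), snp_ids=snps,
                                   pheno_labels=("a", "b"))
        from pleiocca.sumstats_io import SnpAnnotation

        ann = SnpAnnotation(gene_snps={"G": snps},
                            gene_records={"G": GeneRecord("G", 1, 1, 10**9)},
                            annotated_snps=snps, unannotated_snps=[])
        yy = PhenoCorr(matrix=np.eye(2), n_snps_used=0)
        cfg = AnalysisConfig(n_effective=1000, max_gene_snps=4)
        out = gene_level_scan(s, small_panel, yy, ann, cfg)
        assert out["NSNPS"].iloc[0] == 4

    def test_scale_invariance_of_results(self, small_sim, small_cfg, small_panel):
        # rescaling one study's beta and SE by a constant must change nothing
        from pleiocca import build_sigma_xy, harmonize

        s1 = as_study_summary(small_sim["studies"][0], "t1", small_cfg.n_study_1)
        s2 = as_study_summary(small_sim["studies"][1], "t2", small_cfg.n_study_2)
        pair = harmonize(s1, s2)
        scaled = pair.table.copy()
        scaled["BETA_1"] *= 7.3
        scaled["SE_1"] *= 7.3
        pair2 = HarmonizedPair(table=scaled, n_1=pair.n_1, n_2=pair.n_2,
                               labels=pair.labels)
        assert np.allclose(build_sigma_xy(pair).values,
                           build_sigma_xy(pair2).values, atol=1e-12)
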