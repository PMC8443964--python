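"""Simulation experiments that validate the method end to end.

Each function runs one self-contained experiment on synthetic data with
known ground truth and returns the measured quantity: agreement of
summary-statistic CCA with individual-level CCA, type-I error calibration
of the SNP scan and the Monte-Carlo gene test, and the power to rank a
truly pleiotropic gene first.  The test suite and the reproduction script
both drive these functions; sizes are arguments so either can scale them.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .gene_test import run_gene_tests
from .ld_ops import genotype_corr, shrink_to_pd, window_prune
from .metacca import (
    AnalysisConfig,
    build_sigma_xy,
    canonical_corr,
    estimate_sigma_yy,
    gene_level_scan,
    univariate_snp_scan,
)
from .sumstats_io import (
    GeneRecord,
    StudySummary,
    annotate_snps,
    harmonize,
    standardize_beta,
)
from .synthetic_data import (
    GroundTruth,
    SimulationConfig,
    compute_univariate_gwas,
    draw_ground_truth,
    simulate_all,
    simulate_panel,
    simulate_phenotypes,
)

__all__ = [
    "as_study_summary",
    "oracle_equivalence_diff",
    "snp_scan_null_rate",
    "gene_test_null_rate",
    "causal_gene_rank_experiment",
]


def as_study_summary(frame: pd.DataFrame, label: str, study_n: int) -> StudySummary:
    """Wrap a simulated summary-statistics frame without file round-trip."""
    t = frame.dropna(subset=["BETA", "SE"]).reset_index(drop=True)
    return StudySummary(label=label, table=t, study_n=study_n)


def _gene_records(gene_ranges: pd.DataFrame) -> list[GeneRecord]:
    return [GeneRecord(r.GENE, int(r.CHR), int(r.START), int(r.END))
            for _, r in gene_ranges.iterrows()]


def oracle_equivalence_diff(
    g: int, seed: int, n: int = 2000, effect_size: float = 0.1,
    rho: float = 0.5, pheno_corr: float = 0.3,
) -> float:
    """|r1 from summary statistics - r1 from individual-level CCA|.

    One gene of ``g`` SNPs; the reference panel IS the study cohort and
    both phenotypes are observed on it, so the summary-statistic CCA should
    reproduce the individual-level canonical correlation.  The
    individual-level value comes from scikit-learn's iterative CCA — an
    implementation independent of the covariance-assembly route.
    """
    from sklearn.cross_decomposition import CCA

    cfg = SimulationConfig(
        n_ref=n, n_study_1=n, n_study_2=n, n_snps=g, block_size=g, rho=rho,
        maf_range=(0.1, 0.5), n_pleiotropic=min(2, g), n_private_1=0,
        n_private_2=0, effect_size=effect_size, pheno_corr=pheno_corr,
        seed=seed,
    )
    sub = np.random.SeedSequence(seed).spawn(3)
    panel = simulate_panel(cfg, np.random.default_rng(sub[0]))
    truth = draw_ground_truth(cfg, panel.snp_ids, np.random.default_rng(sub[1]))
    y1, y2 = simulate_phenotypes(panel.dosage, cfg, truth,
                                 np.random.default_rng(sub[2]))

    # summary route: GWAS of both traits in the same cohort, panel = cohort
    g1 = compute_univariate_gwas(panel.dosage, y1)
    g2 = compute_univariate_gwas(panel.dosage, y2)
    b = np.column_stack([
        standardize_beta(g1["BETA"], g1["SE"], n),
        standardize_beta(g2["BETA"], g2["SE"], n),
    ])
    xx, _ = shrink_to_pd(genotype_corr(panel, list(panel.snp_ids)).matrix)
    yy = np.corrcoef(y1, y2)
    r1_summary = canonical_corr(xx, b, yy)[0]

    # individual route: iterative CCA on the raw matrices
    x = panel.dosage.astype(float)
    xs = (x - x.mean(axis=0)) / x.std(axis=0)
    ym = np.column_stack([y1, y2])
    cca = CCA(n_components=1, max_iter=5000, tol=1e-10).fit(xs, ym)
    u, v = cca.transform(xs, ym)
    r1_individual = abs(float(np.corrcoef(u[:, 0], v[:, 0])[0, 1]))
    return abs(float(r1_summary) - r1_individual)


def _null_cfg(seed: int, n_snps: int, n_study: int, n_ref: int) -> SimulationConfig:
    return SimulationConfig(
        n_ref=n_ref, n_study_1=n_study, n_study_2=n_study, n_snps=n_snps,
        n_pleiotropic=0, n_private_1=0, n_private_2=0, seed=seed,
    )


def _scan_pipeline(sim: dict, cfg: SimulationConfig):
    """Shared harmonize -> prune -> standardize -> trait-correlation steps."""
    s1 = as_study_summary(sim["studies"][0], "t1", cfg.n_study_1)
    s2 = as_study_summary(sim["studies"][1], "t2", cfg.n_study_2)
    pair = harmonize(s1, s2)
    panel = sim["panel"]
    panel_set = set(panel.snp_ids)
    in_panel = [x for x in pair.snp_ids if x in panel_set]
    pruned = window_prune(panel, in_panel)
    sub = pair.table[pair.table["SNP"].isin(set(pruned))].reset_index(drop=True)
    from .sumstats_io import HarmonizedPair

    pruned_pair = HarmonizedPair(table=sub, n_1=pair.n_1, n_2=pair.n_2,
                                 labels=pair.labels)
    s = build_sigma_xy(pruned_pair)
    yy = estimate_sigma_yy(s)
    return s1, s2, pair, pruned_pair, s, yy


def snp_scan_null_rate(
    seeds, n_snps: int = 2000, n_study: int = 5000, n_ref: int = 1000,
    alpha: float = 0.05,
) -> tuple[float, int]:
    """Fraction of null SNPs with CCA p < alpha, pooled over seeds.

    With no causal SNPs and disjoint cohorts the scan's p-values should be
    uniform, so the fraction should match alpha to binomial accuracy.
    """
    hits = total = 0
    for seed in seeds:
        cfg = _null_cfg(seed, n_snps, n_study, n_ref)
        sim = simulate_all(cfg)
        _, _, _, _, s, yy = _scan_pipeline(sim, cfg)
        acfg = AnalysisConfig(n_effective=n_study, alpha=alpha)
        out = univariate_snp_scan(s, sim["panel"], yy, acfg)
        hits += int((out["PVAL"] < alpha).sum())
        total += len(out)
    return hits / total, total


def gene_test_null_rate(
    seed: int, n_genes: int = 200, block_size: int = 10, n_study: int = 5000,
    n_ref: int = 1000, alpha: float = 0.01, n_sims: int = 2000,
    max_sims: int = 20_000,
) -> tuple[float, int]:
    """Fraction of null genes flagged by the Monte-Carlo gene test."""
    cfg = SimulationConfig(
        n_ref=n_ref, n_study_1=n_study, n_study_2=n_study,
        n_snps=n_genes * block_size, block_size=block_size,
        n_pleiotropic=0, n_private_1=0, n_private_2=0, seed=seed,
    )
    sim = simulate_all(cfg)
    s1 = as_study_summary(sim["studies"][0], "t1", cfg.n_study_1)
    s2 = as_study_summary(sim["studies"][1], "t2", cfg.n_study_2)
    pair = harmonize(s1, s2)
    ann = annotate_snps(pair, _gene_records(sim["gene_ranges"]))
    table = run_gene_tests(s1, ann, sim["panel"], alpha=alpha,
                           n_sims=n_sims, seed=seed, max_sims=max_sims)
    return float(table["SIG"].mean()), len(table)


def causal_gene_rank_experiment(
    n_reps: int = 100, base_seed: int = 0, n_null_genes: int = 20,
    snps_per_gene: int = 3, effect_size: float = 0.15, n_study: int = 5000,
    n_ref: int = 1000,
) -> float:
    """Fraction of replicates in which the pleiotropic gene ranks first.

    One gene carries ``snps_per_gene`` SNPs causal for both traits; the
    remaining genes are null.  The gene-level scan should place the causal
    gene at the smallest p-value in nearly every replicate.
    """
    n_snps = (n_null_genes + 1) * snps_per_gene
    wins = 0
    rep_seeds = np.random.SeedSequence(base_seed).generate_state(n_reps) % (2**31)
    for rep_seed in rep_seeds:
        cfg = SimulationConfig(
            n_ref=n_ref, n_study_1=n_study, n_study_2=n_study, n_snps=n_snps,
            block_size=snps_per_gene, n_pleiotropic=snps_per_gene,
            n_private_1=0, n_private_2=0, effect_size=effect_size,
            seed=int(rep_seed),
        )
        ids = [f"rs{100000 + i}" for i in range(n_snps)]
        effects = np.zeros((n_snps, 2))
        effects[:snps_per_gene, :] = effect_size  # causal gene = first block
        truth = GroundTruth(snp_ids=ids, causal_1=ids[:snps_per_gene],
                            causal_2=ids[:snps_per_gene], effects=effects,
                            pleiotropic_snps=ids[:snps_per_gene])
        sim = simulate_all(cfg, truth=truth)
        _, _, pair, _, s, yy = _scan_pipeline(sim, cfg)
        ann = annotate_snps(pair, _gene_records(sim["gene_ranges"]))
        acfg = AnalysisConfig(n_effective=n_study)
        table = gene_level_scan(s, sim["panel"], yy, ann, acfg)
        causal = table[table["GENE"] == "GENE0001"]["PVAL"]
        others = table[table["GENE"] != "GENE0001"]["PVAL"]
        if len(causal) and float(causal.iloc[0]) < float(others.min()):
            wins += 1
    return wins / n_reps
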