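"""Canonical correlation analysis of GWAS summary statistics.

The individual-level CCA of a genotype block X (n x g) against a phenotype
block Y (n x p) needs only the joint covariance of (X, Y).  With
standardized variables that covariance splits into three blocks, each
recoverable without individual data:

* ``Sigma_XY`` — the g x p matrix of standardized effects
  ``beta_std = beta / (sqrt(n) * se)``, one column per trait;
* ``Sigma_XX`` — the genotypic correlation of the g SNPs, estimated from a
  reference panel;
* ``Sigma_YY`` — the trait-trait correlation, estimated as the Pearson
  correlation between the traits' beta_std vectors across many SNPs.

Plugging the assembled joint covariance into the CCA eigenproblem yields
the canonical correlation(s) r between the SNP set and the trait set.
Significance uses Bartlett's chi-square approximation to Wilks' lambda,
which reduces to the classical correlation test at g = p = 1; the effective
N is conservatively the smallest study sample size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg, stats

from .errors import ConsistencyError, DomainError
from .ld_ops import LdBlock, ReferencePanel, genotype_corr, shrink_to_pd
from .sumstats_io import HarmonizedPair, SnpAnnotation, standardize_beta

logger = logging.getLogger(__name__)

__all__ = [
    "StandardizedBetaMatrix",
    "PhenoCorr",
    "AnalysisConfig",
    "CcaResult",
    "build_sigma_xy",
    "estimate_sigma_yy",
    "assemble_full_cov",
    "canonical_corr",
    "cca_pvalue",
    "univariate_snp_scan",
    "gene_level_scan",
]

_P_FLOOR = 1e-300  # keep reported p-values in (0, 1]


@dataclass
class StandardizedBetaMatrix:
    """g x p matrix of standardized effects (rows SNPs, columns traits)."""

    values: np.ndarray
    snp_ids: list
    pheno_labels: tuple
    _index: dict = field(init=False, repr=False)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if not np.isfinite(self.values).all():
            raise ConsistencyError("standardized beta matrix contains non-finite values")
        if len(self.snp_ids) != self.values.shape[0]:
            raise ConsistencyError("row count does not match SNP IDs")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ConsistencyError("duplicate SNP IDs")
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def rows(self, snp_ids) -> np.ndarray:
        return self.values[[self._index[s] for s in snp_ids]]


@dataclass
class PhenoCorr:
    """Trait-trait correlation matrix estimated from beta_std columns."""

    matrix: np.ndarray
    n_snps_used: int
    lam: float = 0.0


@dataclass
class AnalysisConfig:
    """Scan-level settings.

    ``n_effective``: effective sample size; defaults to the smallest study
    sample size.  ``alpha``: family-wise error target for Bonferroni
    flagging.  ``max_gene_snps``: cap on SNPs analyzed jointly per gene
    (the highest-reference-MAF SNPs are kept when exceeded).
    """

    n_effective: int | None = None
    alpha: float = 0.01
    max_gene_snps: int = 50
    shrink_step: float = 0.01
    shrink_eps: float = 1e-8
    seed: int = 0

    def validate(self) -> None:
        if self.n_effective is not None and self.n_effective < 3:
            raise DomainError("n_effective must be >= 3")
        if not (0 < self.alpha < 1):
            raise DomainError("alpha must lie in (0, 1)")
        if self.max_gene_snps < 1:
            raise DomainError("max_gene_snps must be >= 1")


@dataclass
class CcaResult:
    """Canonical correlation(s) and test for one SNP set or gene."""

    unit: str
    g: int
    p: int
    corrs: np.ndarray
    statistic: float
    df: int
    pvalue: float
    lam: float = 0.0


def build_sigma_xy(pair: HarmonizedPair, n_per_study=None) -> StandardizedBetaMatrix:
    """Standardized-effect matrix from a harmonized study pair.

    Column k is ``standardize_beta`` of study k's (beta, se) with study k's
    sample size; per-SNP n is used when present, else the study-level n.
    """
    if len(pair) == 0:
        raise ConsistencyError("empty harmonized pair")
    t = pair.table
    if n_per_study is None:
        n_per_study = (pair.n_1, pair.n_2)
    cols = []
    for k, n_default in zip((1, 2), n_per_study):
        n = t[f"N_{k}"].fillna(n_default).to_numpy(dtype=float)
        cols.append(standardize_beta(t[f"BETA_{k}"], t[f"SE_{k}"], n))
    return StandardizedBetaMatrix(
        values=np.column_stack(cols),
        snp_ids=list(t["SNP"]),
        pheno_labels=pair.labels,
    )


def estimate_sigma_yy(
    s: StandardizedBetaMatrix, shrink_step: float = 0.01, shrink_eps: float = 1e-8
) -> PhenoCorr:
    """Trait correlation from beta_std columns across all (pruned) SNPs.

    Entry (j, k) is the Pearson correlation of columns j and k over the g
    SNPs; the matrix is then shrunk to positive definiteness if needed.
    """
    g, p = s.values.shape
    if g < 3:
        raise DomainError("need at least 3 SNPs to estimate trait correlation")
    m = np.corrcoef(s.values, rowvar=False)
    m = np.atleast_2d(m)
    np.fill_diagonal(m, 1.0)
    shrunk, lam = shrink_to_pd(m, step=shrink_step, eps=shrink_eps)
    return PhenoCorr(matrix=shrunk, n_snps_used=g, lam=lam)


def assemble_full_cov(
    xx: LdBlock | np.ndarray,
    xy: np.ndarray,
    yy: PhenoCorr | np.ndarray,
    shrink_step: float = 0.01,
    shrink_eps: float = 1e-8,
) -> tuple[np.ndarray, float]:
    """Joint (g+p) x (g+p) covariance [[XX, XY], [XY', YY]], shrunk PD.

    Returns the matrix and the shrinkage lam applied to the whole block
    matrix (0 if it was already positive definite).
    """
    xx_m = xx.matrix if isinstance(xx, LdBlock) else np.asarray(xx, dtype=float)
    yy_m = yy.matrix if isinstance(yy, PhenoCorr) else np.asarray(yy, dtype=float)
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    g, p = xy.shape
    if xx_m.shape != (g, g) or yy_m.shape != (p, p):
        raise ConsistencyError("block dimensions are not conformable")
    full = np.block([[xx_m, xy], [xy.T, yy_m]])
    full = (full + full.T) / 2.0
    if np.linalg.eigvalsh(full)[0] >= shrink_eps:
        return full, 0.0
    return shrink_to_pd(full, step=shrink_step, eps=shrink_eps)


def canonical_corr(xx, xy, yy) -> np.ndarray:
    """Canonical correlations of a genotype block against a trait block.

    Computes the singular values of ``L_xx^-1 XY L_yy^-T`` (the whitened
    cross-covariance), which equal the square roots of the eigenvalues of
    ``XX^-1 XY YY^-1 XY'``.  Values are clipped to [0, 1].  Both ``xx`` and
    ``yy`` must be positive definite (shrink first if not).
    """
    xx_m = xx.matrix if isinstance(xx, LdBlock) else np.atleast_2d(np.asarray(xx, dtype=float))
    yy_m = yy.matrix if isinstance(yy, PhenoCorr) else np.atleast_2d(np.asarray(yy, dtype=float))
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    if xy.shape != (xx_m.shape[0], yy_m.shape[0]):
        raise ConsistencyError("XY block not conformable with XX/YY")
    try:
        lx = linalg.cholesky(xx_m, lower=True)
        ly = linalg.cholesky(yy_m, lower=True)
    except linalg.LinAlgError as exc:
        raise DomainError("XX and YY must be positive definite; shrink first") from exc
    m = linalg.solve_triangular(lx, xy, lower=True)
    m = linalg.solve_triangular(ly, m.T, lower=True).T
    r = linalg.svdvals(m)
    return np.clip(r, 0.0, 1.0)


def cca_pvalue(r, n: int, g: int, p: int) -> tuple[float, int, float]:
    """Bartlett chi-square test on Wilks' lambda for canonical correlations.

    ``Lambda = prod(1 - r_i^2)``; the statistic
    ``-(N - 1 - (g + p + 1)/2) * ln(Lambda)`` is referred to a chi-square
    with g*p degrees of freedom.  Requires ``N > g + p + 1``.
    """
    r = np.atleast_1d(np.asarray(r, dtype=float))
    if n <= g + p + 1:
        raise DomainError(f"N={n} too small for g={g}, p={p} (need N > g+p+1)")
    lam_wilks = float(np.prod(np.clip(1.0 - r**2, 1e-16, 1.0)))
    statistic = -(n - 1 - (g + p + 1) / 2.0) * np.log(lam_wilks)
    df = g * p
    pvalue = max(float(stats.chi2.sf(statistic, df)), _P_FLOOR)
    return statistic, df, pvalue


def _neglog10_sf_chi2(statistic, df):
    return -stats.chi2.logsf(statistic, df) / np.log(10.0)


def univariate_snp_scan(
    s: StandardizedBetaMatrix,
    panel: ReferencePanel,
    yy: PhenoCorr,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Per-SNP (g=1) canonical correlation against all traits.

    For a single SNP Sigma_XX = [1], so ``r^2 = b' YY^-1 b`` with b the
    SNP's beta_std row.  Returns a genomic-order table with columns
    ``SNP CHR POS R PVAL NEGLOG10P SIG``; SIG applies the Bonferroni
    threshold alpha / (number of SNPs scanned).
    """
    cfg.validate()
    if cfg.n_effective is None:
        raise DomainError("cfg.n_effective must be set for a scan")
    idx = panel.indices(s.snp_ids)  # raises LookupError if any row missing
    b = s.values
    p = b.shape[1]
    yy_inv_b = np.linalg.solve(yy.matrix, b.T).T
    r2 = np.clip(np.einsum("ij,ij->i", b, yy_inv_b), 0.0, 1.0)
    r = np.sqrt(r2)
    n = cfg.n_effective
    if n <= 1 + p + 1:
        raise DomainError("n_effective too small")
    mult = n - 1 - (1 + p + 1) / 2.0
    statistic = -mult * np.log(np.clip(1.0 - r2, 1e-16, 1.0))
    pval = np.maximum(stats.chi2.sf(statistic, p), _P_FLOOR)
    neglog = _neglog10_sf_chi2(statistic, p)
    thresh = cfg.alpha / len(r)
    out = pd.DataFrame(
        {
            "SNP": s.snp_ids,
            "CHR": panel.chrom[idx],
            "POS": panel.pos[idx],
            "R": r,
            "PVAL": pval,
            "NEGLOG10P": neglog,
            "SIG": pval < thresh,
        }
    )
    out = out.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
    out.attrs["bonferroni_threshold"] = thresh
    out.attrs["n_tests"] = len(r)
    return out


def gene_level_scan(
    s: StandardizedBetaMatrix,
    panel: ReferencePanel,
    yy: PhenoCorr,
    annotation: SnpAnnotation,
    cfg: AnalysisConfig,
) -> pd.DataFrame:
    """Per-gene multivariate-SNP canonical correlation against all traits.

    Each gene's (pruned) SNP set supplies the rows of Sigma_XY; Sigma_XX is
    the reference-panel correlation of those SNPs, shrunk to positive
    definiteness (lam recorded).  Genes exceeding ``cfg.max_gene_snps``
    SNPs keep the highest-reference-MAF subset.  Output columns:
    ``GENE CHR START END NSNPS R1 PVAL LAMBDA SIG``.
    """
    cfg.validate()
    if cfg.n_effective is None:
        raise DomainError("cfg.n_effective must be set for a scan")
    have = set(s.snp_ids)
    maf_of = dict(zip(panel.snp_ids, panel.maf))
    pos_of = dict(zip(panel.snp_ids, panel.pos))
    rows = []
    skipped = []
    for gene, snps in annotation.gene_snps.items():
        snps = [x for x in snps if x in have]
        if not snps:
            skipped.append(gene)
            continue
        if len(snps) > cfg.max_gene_snps:
            # deterministic cap: highest reference MAF, ties to lower position
            snps = sorted(snps, key=lambda x: (-maf_of[x], pos_of[x]))[: cfg.max_gene_snps]
            snps = sorted(snps, key=lambda x: pos_of[x])
        block = genotype_corr(panel, snps)
        xx, lam = shrink_to_pd(block.matrix, step=cfg.shrink_step, eps=cfg.shrink_eps)
        r = canonical_corr(xx, s.rows(snps), yy.matrix)
        g, p = len(snps), yy.matrix.shape[0]
        statistic, df, pvalue = cca_pvalue(r, cfg.n_effective, g, p)
        rec = annotation.gene_records[gene]
        rows.append(
            {
                "GENE": gene,
                "CHR": rec.chrom,
                "START": rec.start,
                "END": rec.end,
                "NSNPS": g,
                "R1": float(r[0]),
                "PVAL": pvalue,
                "LAMBDA": lam,
            }
        )
    if skipped:
        logger.info("gene scan: %d gene(s) skipped with no scanned SNPs", len(skipped))
    out = pd.DataFrame(rows)
    if len(out):
        thresh = cfg.alpha / len(out)
        out["SIG"] = out["PVAL"] < thresh
        out = out.sort_values(["CHR", "START"], kind="mergesort").reset_index(drop=True)
        out.attrs["bonferroni_threshold"] = thresh
        out.attrs["n_tests"] = len(out)
    out.attrs["skipped_genes"] = skipped
    return out
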