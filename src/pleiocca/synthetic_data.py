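"""Synthetic GWAS inputs with known ground truth.

Generates everything the pleiotropy pipeline consumes: an LD-blocked
reference genotype panel, two disjoint study cohorts drawn from the same
population, a pair of phenotypes with shared (pleiotropic) and private
causal SNPs, per-SNP univariate regression summary statistics for each
cohort, and a gene-range annotation tiling the simulated SNPs.

LD model
--------
Haplotypes are generated from a latent Gaussian that follows a first-order
autoregressive process within each block of ``block_size`` consecutive SNPs
(correlation ``rho`` between adjacent SNPs) and is independent across
blocks.  Each latent value is thresholded at the normal quantile of the
SNP's target allele frequency, so the marginal allele frequency is exact in
expectation while the AR parameter controls the strength of LD.  Dosages
are the sum of two independent haplotypes.

Phenotype model
---------------
``y_k = sum_j effect * x_std_j + e_k`` over phenotype k's causal SNPs, with
``(e_1, e_2)`` bivariate normal with unit variances and correlation
``pheno_corr``; each phenotype is then standardized.  Pleiotropic SNPs
enter both phenotypes with the same effect sign.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConsistencyError, ParameterError
from .ld_ops import ReferencePanel

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_phenotypes",
    "compute_univariate_gwas",
    "write_study",
    "simulate_all",
    "simulate_bundle",
]

# unambiguous (non-palindromic) allele pairs only, so harmonization keeps all
_ALLELE_PAIRS = [("A", "G"), ("A", "C"), ("T", "G"), ("T", "C"),
                 ("G", "A"), ("C", "A"), ("G", "T"), ("C", "T")]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated two-trait GWAS experiment."""

    n_ref: int = 1000
    n_study_1: int = 5000
    n_study_2: int = 5000
    n_snps: int = 2000
    block_size: int = 10
    rho: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_pleiotropic: int = 20
    n_private_1: int = 20
    n_private_2: int = 20
    effect_size: float = 0.15
    pheno_corr: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ParameterError("maf_range bounds must satisfy 0 < lo <= hi <= 0.5")
        if not (-1.0 < self.rho < 1.0):
            raise ParameterError("rho must lie in (-1, 1)")
        if not (-1.0 <= self.pheno_corr <= 1.0):
            raise ParameterError("pheno_corr must lie in [-1, 1]")
        if self.block_size < 1:
            raise ParameterError("block_size must be >= 1")
        if self.n_snps < 1:
            raise ParameterError("n_snps must be >= 1")
        for name in ("n_ref", "n_study_1", "n_study_2",
                     "n_pleiotropic", "n_private_1", "n_private_2"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        n_causal = self.n_pleiotropic + self.n_private_1 + self.n_private_2
        if n_causal > self.n_snps:
            raise ParameterError("causal SNP counts exceed n_snps")


@dataclass
class GroundTruth:
    """Which simulated SNPs are causal, for which phenotype, at what effect."""

    snp_ids: list
    causal_1: list
    causal_2: list
    effects: np.ndarray  # (n_snps, 2) true effects on standardized genotype
    pleiotropic_snps: list = field(default_factory=list)
    pleiotropic_genes: list = field(default_factory=list)

    def validate(self) -> None:
        known = set(self.snp_ids)
        for s in list(self.causal_1) + list(self.causal_2):
            if s not in known:
                raise ConsistencyError(f"causal SNP {s!r} not in simulated panel")


def _snp_metadata(cfg: SimulationConfig, rng: np.random.Generator):
    ids = np.array([f"rs{100000 + i}" for i in range(cfg.n_snps)], dtype=object)
    chrom = np.ones(cfg.n_snps, dtype=int)
    pos = np.arange(1, cfg.n_snps + 1) * 1000
    alleles = np.array(
        [_ALLELE_PAIRS[k] for k in rng.integers(0, len(_ALLELE_PAIRS), cfg.n_snps)],
        dtype=object,
    )
    return ids, chrom, pos, alleles


def _draw_mafs(cfg: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    lo, hi = cfg.maf_range
    return rng.uniform(lo, hi, size=cfg.n_snps)


def _simulate_genotypes(
    n: int, cfg: SimulationConfig, mafs: np.ndarray, rng: np.random.Generator
) -> np.ndarray:
    """Dosage matrix from two latent-AR(1) thresholded haplotypes per person."""
    thresholds = stats.norm.ppf(mafs)
    dosage = np.zeros((n, cfg.n_snps), dtype=np.int8)
    for _ in range(2):  # two haplotypes
        z = np.empty((n, cfg.n_snps))
        innov = rng.standard_normal((n, cfg.n_snps))
        scale = np.sqrt(1.0 - cfg.rho**2)
        for j in range(cfg.n_snps):
            if j % cfg.block_size == 0:  # new LD block: fresh AR chain
                z[:, j] = innov[:, j]
            else:
                z[:, j] = cfg.rho * z[:, j - 1] + scale * innov[:, j]
        dosage += (z < thresholds).astype(np.int8)
    # polymorphism guard: flip one allele at any monomorphic SNP (vanishingly
    # rare at the default sizes, but keeps downstream invariants exact)
    freq = dosage.mean(axis=0) / 2.0
    for j in np.flatnonzero((freq <= 0.0) | (freq >= 1.0)):
        dosage[0, j] = 1
    return dosage


def simulate_panel(cfg: SimulationConfig, rng: np.random.Generator | None = None) -> ReferencePanel:
    """Simulate a reference panel of ``cfg.n_ref`` individuals.

    Deterministic given ``cfg.seed``; SNPs are partitioned into blocks of
    ``cfg.block_size`` with latent AR(1) correlation ``cfg.rho`` within a
    block and independence across blocks.
    """
    cfg.validate()
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(1)[0])
    ids, chrom, pos, alleles = _snp_metadata(cfg, rng)
    mafs = _draw_mafs(cfg, rng)
    dosage = _simulate_genotypes(cfg.n_ref, cfg, mafs, rng)
    return ReferencePanel(snp_ids=ids, chrom=chrom, pos=pos, dosage=dosage, alleles=alleles)


def draw_ground_truth(cfg: SimulationConfig, snp_ids, rng: np.random.Generator) -> GroundTruth:
    """Place pleiotropic and private causal SNPs uniformly at random."""
    n_causal = cfg.n_pleiotropic + cfg.n_private_1 + cfg.n_private_2
    picked = rng.choice(cfg.n_snps, size=n_causal, replace=False)
    pleio = picked[: cfg.n_pleiotropic]
    priv1 = picked[cfg.n_pleiotropic : cfg.n_pleiotropic + cfg.n_private_1]
    priv2 = picked[cfg.n_pleiotropic + cfg.n_private_1 :]
    effects = np.zeros((cfg.n_snps, 2))
    effects[pleio, 0] = cfg.effect_size
    effects[pleio, 1] = cfg.effect_size
    effects[priv1, 0] = cfg.effect_size
    effects[priv2, 1] = cfg.effect_size
    snp_ids = list(snp_ids)
    truth = GroundTruth(
        snp_ids=snp_ids,
        causal_1=[snp_ids[i] for i in sorted(np.concatenate([pleio, priv1]))],
        causal_2=[snp_ids[i] for i in sorted(np.concatenate([pleio, priv2]))],
        effects=effects,
        pleiotropic_snps=[snp_ids[i] for i in sorted(pleio)],
    )
    truth.validate()
    return truth


def simulate_phenotypes(
    genotypes: np.ndarray,
    cfg: SimulationConfig,
    truth: GroundTruth,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Two standardized phenotype vectors with correlated residuals."""
    n, m = genotypes.shape
    if m != len(truth.snp_ids):
        raise ConsistencyError("genotype column count does not match ground truth")
    truth.validate()
    x = np.asarray(genotypes, dtype=float)
    xs = (x - x.mean(axis=0)) / np.where(x.std(axis=0) == 0, 1.0, x.std(axis=0))
    pc = cfg.pheno_corr
    e = rng.standard_normal((n, 2))
    noise = np.column_stack([e[:, 0], pc * e[:, 0] + np.sqrt(1.0 - pc**2) * e[:, 1]])
    ys = []
    for k in range(2):
        y = xs @ truth.effects[:, k] + noise[:, k]
        ys.append((y - y.mean()) / y.std())
    return ys[0], ys[1]


def compute_univariate_gwas(genotypes: np.ndarray, phenotype: np.ndarray) -> pd.DataFrame:
    """Per-SNP simple linear regression of phenotype on dosage.

    Returns a frame with columns ``BETA SE FREQ N`` (one row per SNP in
    column order).  Monomorphic SNPs get ``NaN`` beta/SE and are flagged in
    the boolean ``OK`` column; writers emit them as ``NA`` so readers drop
    them downstream.
    """
    x = np.asarray(genotypes, dtype=float)
    y = np.asarray(phenotype, dtype=float)
    n = x.shape[0]
    if n < 3:
        raise ParameterError("need at least 3 individuals for regression")
    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sxx = (xc**2).sum(axis=0)
    syy = float((yc**2).sum())
    ok = sxx > 0
    with np.errstate(divide="ignore", invalid="ignore"):
        sxy = xc.T @ yc
        beta = np.where(ok, sxy / np.where(ok, sxx, 1.0), np.nan)
        ss_res = np.maximum(syy - beta * sxy, 0.0)
        se = np.sqrt(ss_res / (n - 2) / np.where(ok, sxx, 1.0))
    se[~ok] = np.nan
    return pd.DataFrame(
        {
            "BETA": beta,
            "SE": se,
            "FREQ": x.mean(axis=0) / 2.0,
            "N": n,
            "OK": ok,
        }
    )


def write_study(results: pd.DataFrame, path) -> None:
    """Write summary statistics in the pipeline's tab-separated dialect.

    ``results`` must carry columns ``SNP CHR POS A1 A2 BETA SE FREQ N``;
    missing values are written as ``NA``.
    """
    cols = ["SNP", "CHR", "POS", "A1", "A2", "BETA", "SE", "FREQ", "N"]
    missing = [c for c in cols if c not in results.columns]
    if missing:
        raise ParameterError(f"results missing column(s): {', '.join(missing)}")
    results[cols].to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.10g")


def _study_frame(panel_meta: pd.DataFrame, gwas: pd.DataFrame) -> pd.DataFrame:
    out = panel_meta.copy()
    for c in ("BETA", "SE", "FREQ", "N"):
        out[c] = gwas[c].to_numpy()
    return out


def make_gene_ranges(cfg: SimulationConfig, pos: np.ndarray, chrom: np.ndarray) -> pd.DataFrame:
    """One gene per LD block, tiling all simulated SNP positions."""
    rows = []
    for b in range(0, cfg.n_snps, cfg.block_size):
        sl = slice(b, min(b + cfg.block_size, cfg.n_snps))
        rows.append(
            {
                "CHR": int(chrom[sl][0]),
                "START": int(pos[sl].min()) - 1,
                "END": int(pos[sl].max()) + 1,
                "GENE": f"GENE{b // cfg.block_size + 1:04d}",
            }
        )
    return pd.DataFrame(rows)


def simulate_all(
    cfg: SimulationConfig,
    truth: GroundTruth | None = None,
    panel_from_study_1: bool = False,
    return_individual: bool = False,
) -> dict:
    """Simulate panel, two disjoint study cohorts and their GWAS, in memory.

    The panel and both cohorts share the same per-SNP MAFs and LD structure
    but are disjoint individuals; study k's summary statistics regress
    phenotype k on that cohort's dosages.  Pass a ``truth`` to control
    causal-SNP placement, otherwise one is drawn at random.

    ``panel_from_study_1`` substitutes study 1's genotype matrix for the
    reference panel, which makes the reference LD exact for that cohort —
    the regime in which summary-statistic CCA should agree with
    individual-level CCA.  ``return_individual`` additionally returns each
    cohort's genotype matrix and phenotype vectors.
    """
    cfg.validate()
    seeds = np.random.SeedSequence(cfg.seed).spawn(6)
    rng_panel = np.random.default_rng(seeds[0])

    ids, chrom, pos, alleles = _snp_metadata(cfg, rng_panel)
    mafs = _draw_mafs(cfg, rng_panel)
    if truth is None:
        truth = draw_ground_truth(cfg, ids, np.random.default_rng(seeds[1]))
    else:
        if list(truth.snp_ids) != list(ids):
            raise ConsistencyError("supplied truth does not match simulated SNP IDs")
        truth.validate()

    meta = pd.DataFrame(
        {"SNP": ids, "CHR": chrom, "POS": pos, "A1": alleles[:, 0], "A2": alleles[:, 1]}
    )
    out: dict = {"meta": meta, "truth": truth, "mafs": mafs, "studies": []}

    genos = []
    for k, (n_study, seed_geno, seed_pheno) in enumerate(
        [(cfg.n_study_1, seeds[2], seeds[3]), (cfg.n_study_2, seeds[4], seeds[5])]
    ):
        geno = _simulate_genotypes(n_study, cfg, mafs, np.random.default_rng(seed_geno))
        y_pair = simulate_phenotypes(geno, cfg, truth, np.random.default_rng(seed_pheno))
        gwas = compute_univariate_gwas(geno, y_pair[k])
        out["studies"].append(_study_frame(meta, gwas))
        genos.append(geno)
        if return_individual:
            out[f"genotypes_{k + 1}"] = geno
            out[f"phenotypes_{k + 1}"] = y_pair

    panel_dosage = (
        genos[0] if panel_from_study_1
        else _simulate_genotypes(cfg.n_ref, cfg, mafs, rng_panel)
    )
    out["panel"] = ReferencePanel(
        snp_ids=ids, chrom=chrom, pos=pos, dosage=panel_dosage, alleles=alleles
    )
    out["gene_ranges"] = make_gene_ranges(cfg, pos, chrom)

    pleio_pos = {int(pos[list(ids).index(s)]) for s in truth.pleiotropic_snps}
    truth.pleiotropic_genes = sorted(
        r.GENE for _, r in out["gene_ranges"].iterrows()
        if any(r.START <= p <= r.END for p in pleio_pos)
    )
    return out


def simulate_bundle(cfg: SimulationConfig, outdir, flip_fraction: float = 0.1) -> dict:
    """Simulate and write a complete, self-consistent input bundle.

    Writes two study summary files, the reference panel (dosages + SNP map),
    a gene-range annotation (one gene per LD block), and a ground-truth
    table.  A ``flip_fraction`` of SNPs in study 2 are written with A1/A2
    swapped and beta negated, exercising allele harmonization downstream.
    Returns a dict of output paths plus the ground truth.
    """
    from pathlib import Path

    cfg.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sim = simulate_all(cfg)
    panel, truth = sim["panel"], sim["truth"]

    paths = {
        "panel_dosage": outdir / "panel.dosage.tsv",
        "panel_map": outdir / "panel.map.tsv",
        "study_1": outdir / "study1.sumstats.tsv",
        "study_2": outdir / "study2.sumstats.tsv",
        "gene_ranges": outdir / "genes.glist.txt",
        "truth": outdir / "truth.tsv",
    }
    panel.write(paths["panel_dosage"], paths["panel_map"])

    for k, frame in enumerate(sim["studies"]):
        frame = frame.copy()
        if k == 1 and flip_fraction > 0:
            flip_rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 17)))
            flip = flip_rng.random(cfg.n_snps) < flip_fraction
            frame.loc[flip, ["A1", "A2"]] = frame.loc[flip, ["A2", "A1"]].to_numpy()
            frame.loc[flip, "BETA"] = -frame.loc[flip, "BETA"]
            frame.loc[flip, "FREQ"] = 1.0 - frame.loc[flip, "FREQ"]
        write_study(frame, paths[f"study_{k + 1}"])

    with open(paths["gene_ranges"], "w") as fh:
        for _, r in sim["gene_ranges"].iterrows():
            fh.write(f"{r.CHR} {r.START} {r.END} {r.GENE}\n")

    pd.DataFrame(
        {
            "SNP": sim["meta"]["SNP"],
            "EFFECT_1": truth.effects[:, 0],
            "EFFECT_2": truth.effects[:, 1],
        }
    ).to_csv(paths["truth"], sep="\t", index=False)

    return {"paths": {k: str(v) for k, v in paths.items()}, "truth": truth,
            "config": asdict(cfg)}
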