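# Methods

## Summary-statistics CCA

The joint covariance of standardized genotypes X (g SNPs) and phenotypes Y
(p traits) is assembled block-wise:

    Σ = [ Σ̂_XX  Σ_XY ]
        [ Σ_XYᵀ  Σ̂_YY ]

- `Σ_XY[j,k] = β_jk / (√n_k · SE_jk)`. For standardized variables the OLS
  identities give `β/SE = t ≈ r√n`, so `β_std ≈ r`, the genotype–phenotype
  correlation; this also makes the pipeline invariant to rescaling any
  study's β and SE by a common constant (units cancel).
- `Σ̂_XX` is the Pearson correlation of reference-panel dosages for the
  SNP set under test. Dosage (allelic) correlation is used rather than
  haplotype correlation, matching how PLINK-style pruning and most
  summary-statistics methods define LD.
- `Σ̂_YY` is estimated once, genome-wide, as the correlation of the two
  β_std columns across all pruned, annotated SNPs — not per gene — so a
  single consistent trait-correlation estimate enters every unit's test.
  With disjoint study cohorts its null value is ≈ 0 even when the traits
  themselves are correlated, because the sampling noise of the two β
  vectors is independent; shared causal signal is what moves it away from
  zero. Requires at least 3 SNPs.

Canonical correlations are computed as singular values of
`L_XX⁻¹ Σ_XY L_YY⁻ᵀ` (Cholesky whitening), clipped to [0, 1]. Clipping
matters only when sampling noise pushes an eigenvalue marginally outside
the unit interval.

### Positive definiteness

Estimated correlation blocks can be singular (perfect LD, duplicated
columns, g close to or above the panel size). `shrink_to_pd` applies
`(1 − λ)M + λI` with the smallest λ on the grid {0, 0.01, 0.02, …} whose
minimum eigenvalue is ≥ 1e-8. The grid step (0.01) and floor (1e-8) are
configurable; λ = 1 (the identity) always succeeds, so shrinkage cannot
fail, and the λ actually used is recorded per gene and in the run
manifest. The grid search is preferred over a single eigenvalue-based
jump because it reproduces the iterative-shrinkage behaviour of existing
summary-CCA implementations and keeps λ interpretable.

### Significance

The literature on summary-statistics CCA reports p-values for r without
fixing a distributional recipe. This implementation uses Bartlett's χ²
approximation on Wilks' Λ (statistic `−(N − 1 − (g+p+1)/2)·lnΛ`, g·p
degrees of freedom) because (i) it needs only N, g and p, all available
from summary data, and (ii) it reduces to the classical Pearson
correlation test at g = p = 1, which the test suite verifies to within 5%
at N = 10⁴. The effective N is the smallest study sample size — the
conservative choice when cohorts differ. The function is isolated so an
F-approximation (Rao) variant could be swapped in without touching the
scans. Reported p-values are floored at 1e-300 to stay in (0, 1].

Only the leading canonical correlation is tested per unit; no sequential
dimension testing is attempted.

### Gene-level scan

Gene SNP sets come from positional annotation (1-based inclusive
containment, configurable symmetric flank, default 0 kb; SNPs in
overlapping genes count for each) intersected with the post-pruning SNP
set. Genes with more than `max_gene_snps` (default 50) SNPs keep the
highest-reference-MAF subset (ties broken toward the lower position) —
a deterministic cap that keeps Σ̂_XX well-conditioned relative to the
panel size. The Bonferroni family is the set of genes actually tested.

## Harmonization

Studies are intersected by SNP ID; study 2 effects are re-signed onto
study 1's effect allele, unreconcilable allele pairs are dropped, and
strand-ambiguous (A/T, C/G) SNPs are always removed — the conservative
standard when strand information is unavailable. Duplicate SNP IDs keep
the first file occurrence. Per-SNP sample sizes are used when present,
else the study-level n. All drop counts are reported; nothing is dropped
silently.

One genome-scale detail is deliberately surfaced rather than hard-coded:
with α = 0.01 over 440,440 SNP tests the Bonferroni quotient is
2.27 × 10⁻⁸ (0.01/440440), not 2.77 × 10⁻⁸ as sometimes quoted; the
pipeline always computes the quotient from the actual test count and
records it at full precision in the run manifest.

## LD pruning

Windowed pruning (defaults: 50-SNP windows, 5-SNP step, r² > 0.2) removes
the smaller-MAF SNP of each violating pair, with MAF taken from the
reference panel and ties broken by removing the larger genomic position.
The kept set is defined as the fixed point of a naive
rescan-from-the-start pruner; the implementation reaches that fixed point
with a backtracking window pointer (windows strictly left of a removal
are provably unaffected, so scanning resumes at the earliest window that
overlaps the removed slot). The equivalence is enforced in the test suite
against an independently written naive oracle. Trailing windows are
truncated rather than re-anchored so the window grid does not shift as
SNPs are removed. Chromosomes are pruned independently.

## Gene-based Monte-Carlo test

Per gene, T = Σ (β/SE)² over the gene's annotated SNPs — the pre-pruning
set, since the multivariate-normal null models LD directly (this differs
intentionally from the CCA gene scan, which uses pruned sets). The null
draws z ~ MVN(0, R) with R the shrunk LD correlation matrix and compares
Σz²ᵢ with T; the empirical p is (exceedances + 1)/(n_sims + 1), so p is
never 0 and the floor is 1/(n_sims + 1). Simulation starts at 10⁴ draws
and escalates tenfold whenever p < 10α, capped at 10⁶ (both
configurable); draws are chunked (2 × 10⁵ per batch) to bound memory.
Under identity LD the test is exactly the χ²(k) tail, and under perfect
LD it collapses to k·χ²(1); both limits are verified in the tests. The
plain all-SNP statistic with 0 kb flank is implemented; top-percentage
variants are out of scope.

## Synthetic data: what it does and does not emulate

Genotypes: per block of `block_size` SNPs, a latent Gaussian AR(1) process
(adjacent correlation `rho`) is thresholded at each SNP's normal MAF
quantile; dosage is the sum of two independent haplotypes. This yields
exact marginal allele frequencies and controllable within-block LD with
independence across blocks — no coalescent machinery, and also none of
real data's long-range LD, MAF–LD coupling, population structure,
imputation error or genomic inflation. Thresholding attenuates the latent
correlation, most strongly between SNPs of dissimilar MAF, so the realized
r² is bounded above by the MAF-compatibility of each pair; tests that
probe the AR construction therefore use matched MAF ranges.

Phenotypes: `y_k = Σ effect · x_std + e_k` over phenotype k's causal SNPs,
with bivariate-normal residuals (correlation `pheno_corr`) and final
standardization. Summary statistics are per-SNP simple OLS computed in two
disjoint cohorts, matching the two-independent-meta-analyses setting; the
reference panel is a third disjoint sample by default, with an option to
reuse the study-1 genotypes for oracle-equivalence experiments. Defaults —
cohorts of 5,000, panel of 1,000, 2,000 SNPs in blocks of 10, rho 0.5,
MAF uniform on (0.05, 0.5), per-SNP effect 0.15, residual correlation
0.2 — are desk-scale stand-ins for a biobank GWAS: large enough that a
0.15 effect is unambiguous (z ≈ 10) while a full calibration run stays
under a minute. Study 2's written file flips the allele frame of 10% of
SNPs (with β re-signed) so harmonization is exercised on every synthetic
bundle. All randomness flows from one seed through `numpy` SeedSequence
spawning.

Passing tests on these data show the estimator and its calibration are
correct under the stated model; they do not certify behaviour under
population stratification, allele-frequency mismatch between studies and
panel, or imputation artefacts.

## Validation experiments (what the numbers mean)

- **Oracle equivalence**: with the panel equal to the study cohort and
  both traits observed on it, the summary route should reproduce
  individual-level CCA. The individual-level value comes from
  scikit-learn's iterative (NIPALS) CCA — an independent implementation —
  and agreement is required within 0.02 at n = 2000 for genes of 2–10
  SNPs. Residual discrepancy is the β_std ≈ r approximation, O(r³).
- **Calibration**: with zero causal SNPs, the SNP scan's p < 0.05 rate
  over 3 × 2000 SNPs and the gene test's α = 0.01 flag rate over 200
  genes must sit within 3 binomial standard errors of nominal.
- **Power**: a gene with 3 shared causal SNPs (effect 0.15, n = 5000)
  must attain a strictly smaller p than all 20 null genes in ≥ 95% of 100
  replicates.
- **Pruning**: the windowed pruner must equal the naive fixed-point
  oracle exactly on a 200-SNP AR chromosome, and the kept set must
  contain no window pair with r² > 0.2.

`scripts/acceptance.py` reruns all of these from scratch at the sizes
above and writes the measured values; the test suite asserts them at the
stated tolerances.

## Known limitations

- The trait-correlation estimate Σ̂_YY degrades when few SNPs survive
  pruning (it needs many approximately independent SNPs); with g in the
  single digits it is dominated by causal signal.
- N is a single scalar; per-SNP sample-size variation enters only through
  the standardization of each β, not the test's degrees of freedom.
- Multi-allelic variants, build liftover, missing dosages and haplotype-
  level LD are unsupported by design.
- The CCA p-value is asymptotic; for very small N relative to g the
  Monte-Carlo gene test is the more trustworthy of the two gene-level
  procedures.
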