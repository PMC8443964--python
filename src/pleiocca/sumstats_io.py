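"""Reading, harmonizing, annotating and standardizing GWAS summary statistics.

Two univariate GWAS (one per trait) enter the pipeline as per-SNP tables of
effect size, standard error and sample size.  This module validates them,
intersects them on shared SNPs with effect alleles aligned to a common
frame, standardizes effects to the correlation scale
(``beta_std = beta / (sqrt(n) * se)``), and assigns SNPs to genes by
positional containment.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DomainError, FormatError, NoSharedSnpsError

logger = logging.getLogger(__name__)

__all__ = [
    "StudySummary",
    "HarmonizedPair",
    "GeneRecord",
    "read_sumstats",
    "read_gene_ranges",
    "harmonize",
    "standardize_beta",
    "annotate_snps",
]

_VALID_ALLELES = {"A", "C", "G", "T"}
_PALINDROMIC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

DEFAULT_COLUMNS = {
    "snp": "SNP", "chrom": "CHR", "pos": "POS", "a1": "A1", "a2": "A2",
    "beta": "BETA", "se": "SE", "freq": "FREQ", "n": "N",
}


@dataclass
class StudySummary:
    """One study's validated per-SNP effect table.

    ``table`` columns: ``SNP CHR POS A1 A2 BETA SE FREQ N`` with A1 the
    effect allele; ``study_n`` is the study-level sample size used when a
    per-SNP ``N`` is absent.  ``report`` counts rows dropped per reason.
    """

    label: str
    table: pd.DataFrame
    study_n: int | None = None
    report: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class HarmonizedPair:
    """Shared SNPs of two studies with effects on a common allele frame.

    ``table`` columns: ``SNP CHR POS A1 A2 BETA_1 SE_1 N_1 BETA_2 SE_2 N_2``
    sorted by (chromosome, position).
    """

    table: pd.DataFrame
    n_1: int
    n_2: int
    labels: tuple[str, str]
    report: dict = field(default_factory=dict)

    @property
    def snp_ids(self) -> list:
        return list(self.table["SNP"])

    def __len__(self) -> int:
        return len(self.table)


@dataclass(frozen=True)
class GeneRecord:
    """A gene's symbol and 1-based inclusive genomic interval."""

    gene: str
    chrom: int
    start: int
    end: int

    def __post_init__(self):
        if self.start > self.end:
            raise FormatError(f"gene {self.gene}: start > end")


def read_sumstats(
    path,
    column_map: dict | None = None,
    label: str = "study",
    study_n: int | None = None,
) -> StudySummary:
    """Read a tab-separated summary-statistics file into a validated table.

    ``column_map`` maps the canonical field names (snp, chrom, pos, a1, a2,
    beta, se, freq, n) to the file's header names; defaults to the dialect
    written by :func:`pleiocca.synthetic_data.write_study`.  Rows with
    non-numeric beta/SE, SE <= 0, or alleles outside {A,C,G,T} are dropped
    and counted; of duplicated SNP IDs only the first occurrence is kept.
    A missing mandatory column raises :class:`FormatError` naming it.
    """
    cmap = dict(DEFAULT_COLUMNS)
    if column_map:
        cmap.update(column_map)
    raw = pd.read_csv(path, sep="\t", dtype=str, na_values=["NA"], keep_default_na=True)
    mandatory = ["snp", "chrom", "pos", "a1", "a2", "beta", "se"]
    for key in mandatory:
        if cmap[key] not in raw.columns:
            raise FormatError(f"{path}: missing mandatory column {cmap[key]!r}")

    df = pd.DataFrame({
        "SNP": raw[cmap["snp"]],
        "CHR": pd.to_numeric(raw[cmap["chrom"]], errors="coerce"),
        "POS": pd.to_numeric(raw[cmap["pos"]], errors="coerce"),
        "A1": raw[cmap["a1"]].str.upper(),
        "A2": raw[cmap["a2"]].str.upper(),
        "BETA": pd.to_numeric(raw[cmap["beta"]], errors="coerce"),
        "SE": pd.to_numeric(raw[cmap["se"]], errors="coerce"),
        "FREQ": pd.to_numeric(raw[cmap["freq"]], errors="coerce")
        if cmap["freq"] in raw.columns else np.nan,
        "N": pd.to_numeric(raw[cmap["n"]], errors="coerce")
        if cmap["n"] in raw.columns else np.nan,
    })

    report: dict[str, int] = {"rows_read": len(df)}
    bad_numeric = df["BETA"].isna() | df["SE"].isna() | df["POS"].isna() | df["CHR"].isna()
    report["dropped_non_numeric"] = int(bad_numeric.sum())
    df = df[~bad_numeric]
    bad_se = df["SE"] <= 0
    report["dropped_nonpositive_se"] = int(bad_se.sum())
    df = df[~bad_se]
    bad_allele = ~(df["A1"].isin(_VALID_ALLELES) & df["A2"].isin(_VALID_ALLELES))
    report["dropped_invalid_allele"] = int(bad_allele.sum())
    df = df[~bad_allele]
    dup = df["SNP"].duplicated(keep="first")
    if dup.any():
        logger.warning("%s: %d duplicate SNP ID(s) dropped (kept first)", label, dup.sum())
    report["dropped_duplicate_id"] = int(dup.sum())
    df = df[~dup]
    report["rows_kept"] = len(df)

    df = df.astype({"CHR": int, "POS": int}).reset_index(drop=True)
    if study_n is None and df["N"].notna().any():
        study_n = int(df["N"].max())
    return StudySummary(label=label, table=df, study_n=study_n, report=report)


def read_gene_ranges(path) -> list[GeneRecord]:
    """Read a whitespace-separated ``CHR START END GENE`` gene-range file
    (glist-hg19 dialect, 1-based inclusive coordinates)."""
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 4:
                raise FormatError(f"{path}: expected 4 fields, got {len(parts)}")
            chrom, start, end, gene = parts
            genes.append(GeneRecord(gene=gene, chrom=int(chrom), start=int(start), end=int(end)))
    return genes


def harmonize(a: StudySummary, b: StudySummary) -> HarmonizedPair:
    """Intersect two studies on SNP ID and align study b to study a's alleles.

    Where b's effect allele equals a's other allele, b's beta sign is
    flipped and its alleles swapped.  SNPs whose alleles cannot be
    reconciled, and strand-ambiguous (A/T, C/G) SNPs, are dropped and
    counted.  Output is sorted by chromosome then position.
    """
    if len(a) == 0 or len(b) == 0:
        raise NoSharedSnpsError("cannot harmonize an empty study")
    ta = a.table.set_index("SNP")
    tb = b.table.set_index("SNP")
    shared = ta.index.intersection(tb.index)
    if len(shared) == 0:
        raise NoSharedSnpsError(f"no shared SNPs between {a.label} and {b.label}")
    ta, tb = ta.loc[shared], tb.loc[shared]

    report = {"shared": len(shared)}
    palindromic = np.array(
        [(x, y) in _PALINDROMIC for x, y in zip(ta["A1"], ta["A2"])]
    ) | np.array([(x, y) in _PALINDROMIC for x, y in zip(tb["A1"], tb["A2"])])
    same = (ta["A1"].to_numpy() == tb["A1"].to_numpy()) & (
        ta["A2"].to_numpy() == tb["A2"].to_numpy()
    )
    flipped = (ta["A1"].to_numpy() == tb["A2"].to_numpy()) & (
        ta["A2"].to_numpy() == tb["A1"].to_numpy()
    )
    report["dropped_ambiguous"] = int(palindromic.sum())
    keep = ~palindromic & (same | flipped)
    report["dropped_mismatched_alleles"] = int((~palindromic & ~(same | flipped)).sum())
    report["kept"] = int(keep.sum())
    if keep.sum() == 0:
        raise NoSharedSnpsError("no SNPs with reconcilable alleles remain")

    sign = np.where(flipped, -1.0, 1.0)
    n_a = ta["N"].fillna(a.study_n if a.study_n else np.nan)
    n_b = tb["N"].fillna(b.study_n if b.study_n else np.nan)
    out = pd.DataFrame(
        {
            "SNP": shared,
            "CHR": ta["CHR"].to_numpy(),
            "POS": ta["POS"].to_numpy(),
            "A1": ta["A1"].to_numpy(),
            "A2": ta["A2"].to_numpy(),
            "BETA_1": ta["BETA"].to_numpy(),
            "SE_1": ta["SE"].to_numpy(),
            "N_1": n_a.to_numpy(),
            "BETA_2": tb["BETA"].to_numpy() * sign,
            "SE_2": tb["SE"].to_numpy(),
            "N_2": n_b.to_numpy(),
        }
    )[keep]
    out = out.sort_values(["CHR", "POS"], kind="mergesort").reset_index(drop=True)
    return HarmonizedPair(
        table=out,
        n_1=a.study_n or int(np.nanmax(out["N_1"])),
        n_2=b.study_n or int(np.nanmax(out["N_2"])),
        labels=(a.label, b.label),
        report=report,
    )


def standardize_beta(beta, se, n):
    """Standardize GWAS effects to the correlation scale.

    ``beta_std = beta / (sqrt(n) * se)``: dividing the per-allele effect by
    sqrt(n) times its standard error removes trait and genotype units,
    leaving approximately the genotype-phenotype Pearson correlation.
    Vectorized; warns if any |result| exceeds 1.
    """
    beta = np.asarray(beta, dtype=float)
    se = np.asarray(se, dtype=float)
    n = np.asarray(n, dtype=float)
    if np.any(se <= 0):
        raise DomainError("standard errors must be positive")
    if np.any(n < 1):
        raise DomainError("sample sizes must be >= 1")
    out = beta / (np.sqrt(n) * se)
    if np.any(np.abs(out) > 1.0):
        warnings.warn("standardized beta magnitude exceeds 1; check n and SE units",
                      stacklevel=2)
    return out


@dataclass
class SnpAnnotation:
    """SNP-to-gene assignment by positional containment."""

    gene_snps: dict  # gene symbol -> ordered list of SNP IDs
    gene_records: dict  # gene symbol -> GeneRecord
    annotated_snps: list  # SNPs inside at least one gene, genomic order
    unannotated_snps: list


def annotate_snps(
    pair: HarmonizedPair, genes: list[GeneRecord], flank: int = 0
) -> SnpAnnotation:
    """Assign each SNP to every gene whose (flanked) interval contains it.

    SNPs falling in no gene are reported as unannotated and excluded from
    gene-level analyses; SNPs inside overlapping genes join each gene's set.
    """
    t = pair.table
    gene_snps: dict[str, list] = {}
    records: dict[str, GeneRecord] = {}
    covered = np.zeros(len(t), dtype=bool)
    by_chrom = {c: g.sort_values("POS") for c, g in t.groupby("CHR")}
    pos_of = {c: g["POS"].to_numpy() for c, g in by_chrom.items()}
    for rec in genes:
        if rec.chrom not in by_chrom:
            continue
        pos = pos_of[rec.chrom]
        lo = np.searchsorted(pos, rec.start - flank, side="left")
        hi = np.searchsorted(pos, rec.end + flank, side="right")
        if hi > lo:
            idx = by_chrom[rec.chrom].index[lo:hi]
            gene_snps[rec.gene] = list(t.loc[idx, "SNP"])
            records[rec.gene] = rec
            covered[t.index.get_indexer(idx)] = True
    annotated = list(t.loc[covered, "SNP"])
    unannotated = list(t.loc[~covered, "SNP"])
    return SnpAnnotation(
        gene_snps=gene_snps,
        gene_records=records,
        annotated_snps=annotated,
        unannotated_snps=unannotated,
    )
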