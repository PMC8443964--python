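"""Linkage-disequilibrium operations on a reference genotype panel.

The reference panel is a samples x SNPs dosage matrix (0/1/2 copies of the
effect allele).  It supplies three things to the rest of the pipeline:

* pairwise LD (squared Pearson correlation of dosages, the PLINK ``r2``),
* windowed LD pruning (window 50 SNPs / step 5 / r2 > 0.2 by default),
* per-SNP-set genotypic correlation blocks, shrunk to positive definiteness
  when needed so they can enter a canonical correlation analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    DegenerateMatrixError,
    DomainError,
    FormatError,
    OrderingError,
)

__all__ = [
    "ReferencePanel",
    "LdBlock",
    "ld_r2",
    "window_prune",
    "genotype_corr",
    "shrink_to_pd",
]


@dataclass
class ReferencePanel:
    """Dosage matrix plus SNP metadata, ordered by (chromosome, position).

    Parameters
    ----------
    snp_ids : array of str
        Unique SNP identifiers, one per dosage column.
    chrom, pos : integer arrays
        Genomic coordinates (1-based positions).
    dosage : (n_samples, n_snps) array
        Effect-allele dosages in {0, 1, 2}.
    alleles : (n_snps, 2) array of str, optional
        Effect allele (A1) and other allele (A2) per SNP.
    """

    snp_ids: np.ndarray
    chrom: np.ndarray
    pos: np.ndarray
    dosage: np.ndarray
    alleles: np.ndarray | None = None
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.chrom = np.asarray(self.chrom, dtype=int)
        self.pos = np.asarray(self.pos, dtype=int)
        self.dosage = np.asarray(self.dosage)
        if self.dosage.ndim != 2 or self.dosage.shape[1] != len(self.snp_ids):
            raise FormatError("dosage matrix shape does not match SNP count")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise FormatError("duplicate SNP IDs in reference panel")
        freqs = self.dosage.mean(axis=0) / 2.0
        mono = (freqs <= 0.0) | (freqs >= 1.0)
        if mono.any():
            warnings.warn(
                f"dropping {int(mono.sum())} monomorphic SNP(s) from panel",
                stacklevel=2,
            )
            keep = ~mono
            self.snp_ids = self.snp_ids[keep]
            self.chrom = self.chrom[keep]
            self.pos = self.pos[keep]
            self.dosage = self.dosage[:, keep]
            if self.alleles is not None:
                self.alleles = self.alleles[keep]
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    @property
    def n_samples(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosage.shape[1]

    @property
    def maf(self) -> np.ndarray:
        """Minor allele frequency per SNP, computed from the dosages."""
        f = self.dosage.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    def indices(self, snp_ids) -> np.ndarray:
        try:
            return np.array([self._index[s] for s in snp_ids], dtype=int)
        except KeyError as exc:
            raise LookupError(f"SNP {exc.args[0]!r} not in reference panel") from exc

    def write(self, dosage_path, map_path) -> None:
        """Write the dosage matrix (SNP header row, one sample per line) and
        the companion SNP map (``SNP CHR POS A1 A2``)."""
        df = pd.DataFrame(self.dosage, columns=list(self.snp_ids))
        df.to_csv(dosage_path, sep="\t", index=False)
        alleles = (
            self.alleles
            if self.alleles is not None
            else np.full((self.n_snps, 2), "N", dtype=object)
        )
        pd.DataFrame(
            {
                "SNP": self.snp_ids,
                "CHR": self.chrom,
                "POS": self.pos,
                "A1": alleles[:, 0],
                "A2": alleles[:, 1],
            }
        ).to_csv(map_path, sep="\t", index=False)

    @classmethod
    def read(cls, dosage_path, map_path) -> "ReferencePanel":
        dose = pd.read_csv(dosage_path, sep="\t")
        snp_map = pd.read_csv(map_path, sep="\t")
        required = {"SNP", "CHR", "POS", "A1", "A2"}
        if not required.issubset(snp_map.columns):
            missing = sorted(required - set(snp_map.columns))
            raise FormatError(f"SNP map missing column(s): {', '.join(missing)}")
        if list(dose.columns) != list(snp_map["SNP"]):
            raise FormatError("dosage header does not match SNP map order")
        mat = dose.to_numpy()
        if not np.isin(mat, (0, 1, 2)).all():
            raise FormatError("dosages must be 0/1/2 with no missing values")
        return cls(
            snp_ids=snp_map["SNP"].to_numpy(dtype=object),
            chrom=snp_map["CHR"].to_numpy(),
            pos=snp_map["POS"].to_numpy(),
            dosage=mat.astype(np.int8),
            alleles=snp_map[["A1", "A2"]].to_numpy(dtype=object),
        )


@dataclass
class LdBlock:
    """Genotypic correlation matrix for an ordered SNP set.

    ``lam`` records the convex shrinkage toward the identity that was applied
    to reach positive definiteness (0 when none was needed).
    """

    snp_ids: list
    matrix: np.ndarray
    lam: float = 0.0


def _corr_columns(x: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix of the columns of ``x``."""
    xc = x - x.mean(axis=0)
    sd = xc.std(axis=0)
    if np.any(sd == 0):
        raise DomainError("monomorphic SNP: correlation undefined")
    xc = xc / sd
    r = (xc.T @ xc) / x.shape[0]
    np.fill_diagonal(r, 1.0)
    return np.clip((r + r.T) / 2.0, -1.0, 1.0)


def ld_r2(panel: ReferencePanel, snp_i: str, snp_j: str) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    idx = panel.indices([snp_i, snp_j])
    x = panel.dosage[:, idx].astype(float)
    r = _corr_columns(x)[0, 1]
    return float(min(r * r, 1.0))


def window_prune(
    panel: ReferencePanel,
    snps_in_order,
    window: int = 50,
    step: int = 5,
    r2_max: float = 0.2,
) -> list:
    """Windowed LD pruning: remove the lower-MAF SNP of every high-LD pair.

    Slides a ``window``-SNP window in ``step``-SNP increments along each
    chromosome (trailing windows truncated); within a window, the first pair
    with r2 > ``r2_max`` loses its smaller-MAF member (ties broken by removing
    the larger genomic position), and scanning resumes at the earliest window
    that could contain the removed slot.  The process repeats until no window
    over the kept set contains a violating pair, i.e. the result is the fixed
    point of the naive rescan-from-the-start pruner.  Chromosomes are
    processed independently; output preserves genomic order.
    """
    if not (window >= step >= 1):
        raise DomainError("require window >= step >= 1")
    snps_in_order = list(snps_in_order)
    idx = panel.indices(snps_in_order)
    key = list(zip(panel.chrom[idx], panel.pos[idx]))
    if key != sorted(key):
        raise OrderingError("SNPs must be sorted by chromosome then position")

    maf = panel.maf[idx]
    pos = panel.pos[idx]
    dosage = panel.dosage[:, idx].astype(float)
    chrom = panel.chrom[idx]

    kept: list[int] = []
    for c in pd.unique(chrom):
        local = np.flatnonzero(chrom == c)
        kept_local = _prune_chromosome(
            dosage[:, local], maf[local], pos[local], window, step, r2_max
        )
        kept.extend(local[i] for i in kept_local)
    return [snps_in_order[i] for i in sorted(kept)]


def _first_violation(r2: np.ndarray, r2_max: float):
    """Row-major first upper-triangle entry exceeding the threshold."""
    mask = np.triu(r2 > r2_max, k=1)
    if not mask.any():
        return None
    flat = int(np.argmax(mask))
    return divmod(flat, r2.shape[1])


def _prune_chromosome(dosage, maf, pos, window, step, r2_max):
    """Prune one chromosome to its windowed-LD fixed point.

    Equivalent to: repeatedly scan all windows from the start, remove the
    smaller-MAF SNP of the first violating pair found, and restart, until a
    full scan is clean.  Implemented with a backtracking window pointer:
    windows strictly left of a removal are untouched by it, so scanning only
    needs to resume at the earliest window overlapping the removed slot.
    """
    n = dosage.shape[1]
    alive = np.ones(n, dtype=bool)
    xc = dosage - dosage.mean(axis=0)
    norm = np.sqrt((xc**2).sum(axis=0))
    xn = xc / np.where(norm == 0, 1.0, norm)

    w = 0  # window-grid pointer: window w covers live[w*step : w*step+window]
    while True:
        live = np.flatnonzero(alive)
        if w * step >= max(len(live) - 1, 0):
            break
        win = live[w * step : w * step + window]
        r = xn[:, win].T @ xn[:, win]
        hit = _first_violation(r * r, r2_max)
        if hit is None:
            w += 1
            continue
        a, b = win[hit[0]], win[hit[1]]
        if maf[a] < maf[b]:
            drop = a
        elif maf[b] < maf[a]:
            drop = b
        else:  # MAF tie: remove the larger genomic position
            drop = a if pos[a] > pos[b] else b
        r_idx = int(np.searchsorted(live, drop))
        alive[drop] = False
        # earliest grid start whose window reaches the removed slot
        w = max(0, -(-(max(0, r_idx - window + 1)) // step))
    return list(np.flatnonzero(alive))


def genotype_corr(panel: ReferencePanel, snp_ids) -> LdBlock:
    """Pearson correlation matrix of the requested dosage columns (no shrinkage)."""
    snp_ids = list(snp_ids)
    if len(snp_ids) < 1:
        raise DomainError("need at least one SNP")
    idx = panel.indices(snp_ids)
    if len(idx) == 1:
        return LdBlock(snp_ids, np.ones((1, 1)))
    r = _corr_columns(panel.dosage[:, idx].astype(float))
    return LdBlock(snp_ids, r)


def shrink_to_pd(
    matrix: np.ndarray, step: float = 0.01, eps: float = 1e-8
) -> tuple[np.ndarray, float]:
    """Shrink a symmetric matrix toward the identity until positive definite.

    Returns ``(1 - lam) * M + lam * I`` with the smallest ``lam`` on the grid
    {0, step, 2*step, ...} whose minimum eigenvalue is >= ``eps``.  For a
    correlation matrix the unit diagonal is preserved by construction.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise DomainError("matrix must be square")
    if not np.allclose(m, m.T, atol=1e-10):
        raise DomainError("matrix must be symmetric")
    m = (m + m.T) / 2.0
    eye = np.eye(m.shape[0])
    lam = 0.0
    while lam <= 1.0 + 1e-12:
        shrunk = (1.0 - lam) * m + lam * eye
        if np.linalg.eigvalsh(shrunk)[0] >= eps:
            return shrunk, round(lam, 10)
        lam += step
    raise DegenerateMatrixError(
        "matrix cannot be made positive definite with lam <= 1"
    )
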