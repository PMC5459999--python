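"""Core in-memory containers shared across the pipeline.

Genotypes use the EIGENSTRAT code convention: per SNP and individual, the
number of copies of the reference allele (0, 1, 2) with 9 for missing.
Pseudo-haploid individuals (single sampled read represented as a
homozygote) only ever carry 0, 2 or 9 and contribute one allele, not two,
to population allele counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = 9
VALID_CODES = frozenset({0, 1, 2, 9})

SNP_COLUMNS = ["snp_id", "chrom", "gpos", "ppos", "ref", "alt"]
IND_COLUMNS = ["sample_id", "sex", "population"]


@dataclass
class GenotypeDataset:
    """Sample-by-SNP genotype matrix with SNP map and individual metadata.

    Parameters
    ----------
    geno : ndarray of shape (n_snps, n_individuals)
        Genotype codes in {0, 1, 2, 9} (rows follow the SNP table order,
        matching the on-disk EIGENSTRAT layout).
    snp : DataFrame with columns ``snp_id, chrom, gpos, ppos, ref, alt``
        Genetic positions in Morgans; physical positions 1-based.
    ind : DataFrame with columns ``sample_id, sex, population``
        An optional boolean ``pseudo_haploid`` column marks individuals
        whose calls are single sampled reads; absent means all-diploid.
    """

    geno: np.ndarray
    snp: pd.DataFrame
    ind: pd.DataFrame

    def __post_init__(self) -> None:
        self.geno = np.asarray(self.geno)
        if self.geno.ndim != 2:
            raise ValueError("geno must be a 2-D (n_snps, n_ind) array")
        if self.geno.shape[0] != len(self.snp):
            raise ValueError(
                f"geno has {self.geno.shape[0]} rows but snp table has "
                f"{len(self.snp)} entries"
            )
        if self.geno.shape[1] != len(self.ind):
            raise ValueError(
                f"geno has {self.geno.shape[1]} columns but ind table has "
                f"{len(self.ind)} entries"
            )
        bad = set(np.unique(self.geno)) - VALID_CODES
        if bad:
            raise ValueError(f"invalid genotype codes: {sorted(bad)}")
        if "pseudo_haploid" not in self.ind.columns:
            self.ind = self.ind.assign(pseudo_haploid=False)
        ph = self.ind["pseudo_haploid"].to_numpy(bool)
        if ph.any() and np.any(self.geno[:, ph] == 1):
            raise ValueError("pseudo-haploid individuals cannot be heterozygous")

    @property
    def n_snps(self) -> int:
        return self.geno.shape[0]

    @property
    def n_ind(self) -> int:
        return self.geno.shape[1]

    @property
    def populations(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.ind["population"]:
            seen.setdefault(p, None)
        return list(seen)

    def pop_indices(self, population: str) -> np.ndarray:
        idx = np.flatnonzero((self.ind["population"] == population).to_numpy())
        if idx.size == 0:
            raise KeyError(f"population {population!r} not in dataset")
        return idx

    def subset_individuals(self, mask: np.ndarray) -> "GenotypeDataset":
        return GenotypeDataset(
            self.geno[:, mask], self.snp.copy(), self.ind.loc[mask].reset_index(drop=True)
        )


@dataclass
class PileupSite:
    """The read stack observed at one target site.

    All per-read arrays are parallel.  ``dist5p``/``dist3p`` are 0-based
    distances of the site from the read's 5' and 3' end.
    """

    snp_id: str
    ref: str
    alt: str
    base: np.ndarray          # dtype '<U1'
    baseq: np.ndarray         # int
    mapq: np.ndarray          # int
    strand: np.ndarray        # '+' or '-'
    dist5p: np.ndarray        # int, >= 0
    dist3p: np.ndarray        # int, >= 0
    maf: float | None = None  # population minor-allele frequency, if known

    def __post_init__(self) -> None:
        n = len(self.base)
        for name in ("baseq", "mapq", "strand", "dist5p", "dist3p"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"pileup field {name} length mismatch")

    @property
    def depth(self) -> int:
        return len(self.base)


@dataclass
class HaplogroupCountTable:
    """Population-by-haplogroup matrix of non-negative integer counts."""

    populations: list[str]
    haplogroups: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.populations), len(self.haplogroups)):
            raise ValueError("count matrix shape does not match labels")
        if np.any(self.counts < 0) or not np.issubdtype(self.counts.dtype, np.integer):
            raise ValueError("counts must be non-negative integers")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.populations, columns=self.haplogroups)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "HaplogroupCountTable":
        return cls(list(df.index), list(df.columns), df.to_numpy())

    def row(self, population: str) -> np.ndarray:
        return self.counts[self.populations.index(population)]


@dataclass
class DistanceMatrix:
    """Symmetric non-negative distance matrix with a zero diagonal.

    The triangle inequality is *not* assumed (pairwise Phi_ST can
    violate it).
    """

    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(self.values, self.values.T, atol=1e-12, equal_nan=True):
            raise ValueError("distance matrix is not symmetric")
        if np.any(np.nan_to_num(self.values) < -1e-12):
            raise ValueError("distances must be non-negative")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)
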