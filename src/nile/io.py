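"""Readers and writers for the on-disk formats the pipeline consumes.

Formats: EIGENSTRAT genotype trios (``.geno``/``.snp``/``.ind``), aligned
FASTA, pileup TSV (one row per read), sample-metadata CSV and
population-by-haplogroup count CSV.  Parsers reject malformed input
rather than coercing; every writer's output is re-readable by its reader.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .containers import (
    GenotypeDataset,
    HaplogroupCountTable,
    PileupSite,
    VALID_CODES,
)

logger = logging.getLogger(__name__)

_ALLOWED_ALLELES = set("ACGT0")
_ALLOWED_SEQ_CHARS = set("ACGTN-")

METADATA_COLUMNS = [
    "sample_id",
    "tissue",
    "period",
    "mt_coverage",
    "mt_contamination",
    "damage_5p",
    "sex",
    "x_snps_covered_twice",
]


class ParseError(ValueError):
    """Raised when an input file violates its format contract."""


# ---------------------------------------------------------------------------
# EIGENSTRAT


def read_eigenstrat(prefix: str | Path) -> GenotypeDataset:
    """Read a ``<prefix>.geno`` / ``.snp`` / ``.ind`` trio.

    Genetic positions are Morgans, physical positions 1-based, and
    physical positions must be strictly increasing within a chromosome.
    """
    prefix = Path(prefix)
    snp = _read_snp(prefix.with_suffix(".snp"))
    ind = _read_ind(prefix.with_suffix(".ind"))
    geno = _read_geno(prefix.with_suffix(".geno"), n_ind=len(ind), n_snps=len(snp))
    return GenotypeDataset(geno=geno, snp=snp, ind=ind)


def _read_snp(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) not in (4, 6):
                raise ParseError(
                    f"{path}:{lineno}: expected 4 or 6 columns "
                    f"(snp_id chrom gpos ppos [ref alt]), got {len(fields)}"
                )
            snp_id, chrom, gpos, ppos = fields[:4]
            ref, alt = (fields[4], fields[5]) if len(fields) == 6 else ("0", "0")
            if ref not in _ALLOWED_ALLELES or alt not in _ALLOWED_ALLELES:
                raise ParseError(f"{path}:{lineno}: invalid alleles {ref!r}/{alt!r}")
            rows.append((snp_id, chrom, float(gpos), int(ppos), ref, alt))
    snp = pd.DataFrame(rows, columns=["snp_id", "chrom", "gpos", "ppos", "ref", "alt"])
    if (snp["ppos"] < 0).any() or (snp["gpos"] < 0).any():
        raise ParseError(f"{path}: negative positions")
    for chrom, grp in snp.groupby("chrom", sort=False):
        if not np.all(np.diff(grp["ppos"].to_numpy()) > 0):
            raise ParseError(
                f"{path}: physical positions not strictly increasing on chromosome {chrom}"
            )
    return snp


def _read_ind(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            fields = line.split()
            if not fields:
                continue
            if len(fields) != 3:
                raise ParseError(
                    f"{path}:{lineno}: expected 3 columns (id, sex, population), "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    return pd.DataFrame(rows, columns=["sample_id", "sex", "population"])


def _read_geno(path: Path, n_ind: int, n_snps: int) -> np.ndarray:
    geno = np.empty((n_snps, n_ind), dtype=np.int8)
    with open(path) as fh:
        row = 0
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if len(line) != n_ind:
                raise ParseError(
                    f"{path}:{lineno}: line has {len(line)} genotypes, "
                    f"expected {n_ind} (one per individual)"
                )
            codes = np.frombuffer(line.encode(), dtype=np.uint8) - ord("0")
            bad = set(np.unique(codes)) - VALID_CODES
            if bad:
                raise ParseError(f"{path}:{lineno}: unknown genotype code(s) {sorted(bad)}")
            if row >= n_snps:
                raise ParseError(f"{path}: more genotype lines than SNPs ({n_snps})")
            geno[row] = codes
            row += 1
    if row != n_snps:
        raise ParseError(f"{path}: {row} genotype lines for {n_snps} SNPs")
    return geno


def write_eigenstrat(dataset: GenotypeDataset, prefix: str | Path) -> None:
    """Write ``dataset`` as an EIGENSTRAT trio; round-trip is lossless."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".snp"), "w") as fh:
        for rec in dataset.snp.itertuples(index=False):
            fh.write(
                f"{rec.snp_id}\t{rec.chrom}\t{rec.gpos:.10g}\t{rec.ppos}\t{rec.ref}\t{rec.alt}\n"
            )
    with open(prefix.with_suffix(".ind"), "w") as fh:
        for rec in dataset.ind.itertuples(index=False):
            fh.write(f"{rec.sample_id}\t{rec.sex}\t{rec.population}\n")
    with open(prefix.with_suffix(".geno"), "w") as fh:
        for row in dataset.geno:
            fh.write("".join(map(str, row)) + "\n")


# ---------------------------------------------------------------------------
# FASTA alignments


def read_fasta_alignment(path: str | Path) -> dict[str, str]:
    """Read an aligned FASTA file as ``{record id: uppercased sequence}``.

    All sequences must have equal length; characters outside
    ``A C G T N -`` are rejected.
    """
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        bad = set(seq) - _ALLOWED_SEQ_CHARS
        if bad:
            raise ParseError(f"{path}: record {rec.id}: invalid characters {sorted(bad)}")
        seqs[rec.id] = seq
    if not seqs:
        raise ParseError(f"{path}: no FASTA records found")
    lengths = {len(s) for s in seqs.values()}
    if len(lengths) > 1:
        offenders = [k for k, s in seqs.items() if len(s) != len(next(iter(seqs.values())))]
        raise ParseError(
            f"{path}: sequences are not aligned (unequal lengths); "
            f"offending record(s): {offenders}"
        )
    return seqs


def write_fasta_alignment(seqs: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n{seq.upper()}\n")


# ---------------------------------------------------------------------------
# Pileup TSV

PILEUP_COLUMNS = ["snp_id", "ref", "alt", "base", "baseq", "mapq", "strand", "dist5p", "dist3p"]


def write_pileups(sites: list[PileupSite], path: str | Path) -> None:
    """One row per read: site, ref/alt alleles, base, quals, strand, end distances."""
    frames = []
    for s in sites:
        frames.append(
            pd.DataFrame(
                {
                    "snp_id": s.snp_id,
                    "ref": s.ref,
                    "alt": s.alt,
                    "base": s.base,
                    "baseq": s.baseq,
                    "mapq": s.mapq,
                    "strand": s.strand,
                    "dist5p": s.dist5p,
                    "dist3p": s.dist3p,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_pileups(path: str | Path) -> list[PileupSite]:
    df = pd.read_csv(path, sep="\t", dtype={"base": str, "strand": str})
    missing = set(PILEUP_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing pileup columns {sorted(missing)}")
    sites = []
    for snp_id, grp in df.groupby("snp_id", sort=False):
        sites.append(
            PileupSite(
                snp_id=str(snp_id),
                ref=str(grp["ref"].iloc[0]),
                alt=str(grp["alt"].iloc[0]),
                base=grp["base"].to_numpy(str),
                baseq=grp["baseq"].to_numpy(int),
                mapq=grp["mapq"].to_numpy(int),
                strand=grp["strand"].to_numpy(str),
                dist5p=grp["dist5p"].to_numpy(int),
                dist3p=grp["dist3p"].to_numpy(int),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# Sample metadata and haplogroup counts


def read_sample_metadata(path: str | Path) -> pd.DataFrame:
    """Read the per-sample metadata CSV used by the QC filters.

    Numeric fields left empty stay missing (NaN); the QC filters treat
    missing values as failures with an explicit reason, never as zero.
    """
    df = pd.read_csv(path)
    missing = set(METADATA_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    for col in ("mt_contamination", "damage_5p"):
        vals = df[col].dropna()
        if ((vals < 0) | (vals > 1)).any():
            raise ParseError(f"{path}: {col} outside [0, 1]")
    if (df["mt_coverage"].dropna() < 0).any():
        raise ParseError(f"{path}: negative mt_coverage")
    return df


def read_haplogroup_counts(path: str | Path) -> HaplogroupCountTable:
    """Population-by-haplogroup CSV (first column = population labels)."""
    df = pd.read_csv(path, index_col=0)
    try:
        counts = df.to_numpy(dtype=np.int64)
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: non-integer haplogroup counts") from exc
    if (counts < 0).any():
        raise ParseError(f"{path}: negative haplogroup counts")
    return HaplogroupCountTable(list(df.index.astype(str)), list(df.columns), counts)


def write_haplogroup_counts(table: HaplogroupCountTable, path: str | Path) -> None:
    table.to_frame().to_csv(path)
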