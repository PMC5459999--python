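"""Read-level computations for ancient samples.

Pseudo-haploid genotype calling (one random read per SNP), coverage-ratio
sex determination, terminal-deamination damage profiling, method-of-moments
X-chromosome contamination estimation for male samples, the mtDNA and
nuclear QC filter cascades, and the Y-haplogroup / phenotype-SNP lookups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .containers import MISSING, PileupSite

logger = logging.getLogger(__name__)

#: authenticity threshold on the first-base C->T rate (inclusive)
DAMAGE_THRESHOLD = 0.08
#: minimum number of X SNPs covered at least twice for contamination
MIN_X_SNPS = 150
#: mtDNA QC bounds (both strict)
MT_MIN_COVERAGE = 10.0
MT_MAX_CONTAMINATION = 0.03


@dataclass
class DamageProfile:
    """Per-position terminal substitution rates.

    ``ct_rate[k]`` is the C->T rate at 0-based 5' distance k (NaN where
    no reference-C read covers the position); ``ga_rate`` mirrors G->A
    from the 3' end.  ``*_total`` are the denominators.
    """

    ct_rate: np.ndarray
    ga_rate: np.ndarray
    ct_total: np.ndarray
    ga_total: np.ndarray

    @property
    def first_base_ct(self) -> float:
        return float(self.ct_rate[0])

    def passes_authenticity(self, threshold: float = DAMAGE_THRESHOLD) -> bool:
        """True when the first-base C->T rate reaches the threshold (inclusive)."""
        return bool(self.first_base_ct >= threshold)


@dataclass
class SexCall:
    x_auto_ratio: float
    y_auto_ratio: float
    call: str  # male | female | undetermined


@dataclass
class ContaminationEstimate:
    estimate: float  # clipped to [0, 1]
    raw_estimate: float
    n_sites_used: int
    error_rate_estimate: float


# ---------------------------------------------------------------------------
# genotype calling


def _passing_mask(site: PileupSite, min_mapq: int, min_baseq: int) -> np.ndarray:
    return (site.mapq >= min_mapq) & (site.baseq >= min_baseq)


def call_random_read(
    site: PileupSite,
    min_mapq: int = 30,
    min_baseq: int = 30,
    rng: np.random.Generator | None = None,
) -> int:
    """Pseudo-haploid call: sample one random passing read at the site.

    Only reads whose base is the ref or alt allele are eligible; the
    sampled allele is returned as a pseudo-diploid homozygote code
    (ref -> 2, alt -> 0).  No eligible read yields missing (9) — degraded
    input never produces a guess.
    """
    if rng is None:
        rng = np.random.default_rng()
    ok = _passing_mask(site, min_mapq, min_baseq)
    allelic = ok & ((site.base == site.ref) | (site.base == site.alt))
    idx = np.flatnonzero(allelic)
    if idx.size == 0:
        return MISSING
    chosen = site.base[idx[rng.integers(idx.size)]]
    return 2 if chosen == site.ref else 0


def call_random_reads(
    sites: Sequence[PileupSite],
    min_mapq: int = 30,
    min_baseq: int = 30,
    seed: int = 0,
) -> np.ndarray:
    """Vector of pseudo-haploid codes, one per site, from a single seeded RNG."""
    rng = np.random.default_rng(seed)
    return np.array(
        [call_random_read(s, min_mapq, min_baseq, rng) for s in sites], dtype=np.int8
    )


# ---------------------------------------------------------------------------
# sex determination


def determine_sex(mean_cov_x: float, mean_cov_y: float, mean_cov_autosomal: float) -> SexCall:
    """Coverage-ratio sex call.

    Male: X/autosome <= 0.75 and Y/autosome >= 0.25 (a single X and a Y).
    Female: X/autosome > 0.75 and Y/autosome < 0.25.  Anything else is
    undetermined.
    """
    if mean_cov_autosomal <= 0:
        raise ValueError("autosomal coverage must be positive")
    x = mean_cov_x / mean_cov_autosomal
    y = mean_cov_y / mean_cov_autosomal
    if x <= 0.75 and y >= 0.25:
        call = "male"
    elif x > 0.75 and y < 0.25:
        call = "female"
    else:
        call = "undetermined"
    return SexCall(x_auto_ratio=x, y_auto_ratio=y, call=call)


# ---------------------------------------------------------------------------
# damage profile


def damage_profile(sites: Iterable[PileupSite], K: int = 10) -> DamageProfile:
    """Terminal misincorporation rates over the first ``K`` positions.

    The 5' C->T rate at position k is the fraction of reads covering a
    reference-C site at 5' distance k that read T; G->A is mirrored from
    the 3' end.  Positions with no qualifying read report NaN, not 0.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    ct_hit = np.zeros(K)
    ct_tot = np.zeros(K)
    ga_hit = np.zeros(K)
    ga_tot = np.zeros(K)
    for s in sites:
        if s.ref == "C":
            m = s.dist5p < K
            np.add.at(ct_tot, s.dist5p[m], 1)
            np.add.at(ct_hit, s.dist5p[m & (s.base == "T")], 1)
        if s.ref == "G":
            m = s.dist3p < K
            np.add.at(ga_tot, s.dist3p[m], 1)
            np.add.at(ga_hit, s.dist3p[m & (s.base == "A")], 1)
    with np.errstate(invalid="ignore", divide="ignore"):
        ct = np.where(ct_tot > 0, ct_hit / ct_tot, np.nan)
        ga = np.where(ga_tot > 0, ga_hit / ga_tot, np.nan)
    return DamageProfile(ct_rate=ct, ga_rate=ga, ct_total=ct_tot, ga_total=ga_tot)


# ---------------------------------------------------------------------------
# X contamination (method of moments, male samples)


def estimate_x_contamination(
    polymorphic_sites: Sequence[PileupSite],
    monomorphic_sites: Sequence[PileupSite],
    min_depth: int = 2,
    min_sites: int = MIN_X_SNPS,
) -> ContaminationEstimate:
    """Method-of-moments contamination estimate from male X pileups.

    A male is hemizygous on X, so any second allele at a polymorphic
    site is error or contamination.  With per-site mismatch rate m_i
    (fraction of reads differing from the majority base), error rate
    eps estimated from monomorphic flanking sites, and population
    minor-allele frequency q_i (the probability the contaminant carries
    the other allele): c_hat = sum_i (m_i - eps) / sum_i q_i.

    Refuses (QC rule) when fewer than ``min_sites`` polymorphic sites
    are covered at least ``min_depth`` times, or when any qualifying
    site lacks a population frequency.
    """
    mono_reads = 0
    mono_mismatch = 0
    for s in monomorphic_sites:
        if s.depth == 0:
            continue
        maj = _majority_base(s)
        mono_reads += s.depth
        mono_mismatch += int(np.sum(s.base != maj))
    eps = mono_mismatch / mono_reads if mono_reads else 0.0

    qualifying = [s for s in polymorphic_sites if s.depth >= min_depth]
    if len(qualifying) < min_sites:
        raise ValueError(
            f"only {len(qualifying)} X SNPs covered >= {min_depth} times; "
            f"at least {min_sites} required for a contamination estimate"
        )
    num = 0.0
    den = 0.0
    for s in qualifying:
        if s.maf is None:
            raise ValueError(f"site {s.snp_id}: population minor-allele frequency missing")
        maj = _majority_base(s)
        m_i = float(np.mean(s.base != maj))
        num += m_i - eps
        den += s.maf
    raw = num / den
    est = float(np.clip(raw, 0.0, 1.0))
    if raw != est:
        logger.info("contamination estimate %.4f clipped to %.4f", raw, est)
    return ContaminationEstimate(
        estimate=est,
        raw_estimate=float(raw),
        n_sites_used=len(qualifying),
        error_rate_estimate=float(eps),
    )


def _majority_base(site: PileupSite) -> str:
    bases, counts = np.unique(site.base, return_counts=True)
    return str(bases[np.argmax(counts)])


# ---------------------------------------------------------------------------
# QC filter cascades


def _qc_report(samples: pd.DataFrame, reasons: list[list[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    report = pd.DataFrame(
        {
            "sample_id": samples["sample_id"].to_numpy(),
            "pass": [not r for r in reasons],
            "reasons": [";".join(r) for r in reasons],
        }
    )
    passing = samples.loc[report["pass"].to_numpy()].reset_index(drop=True)
    return passing, report


def qc_filter_mt(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Mitochondrial QC: coverage > 10-fold AND contamination < 3%.

    Both bounds are strict.  Missing metadata excludes the sample with
    reason ``missing_metadata``.  Returns (passing subset, full report).
    """
    reasons: list[list[str]] = []
    for rec in samples.itertuples(index=False):
        r: list[str] = []
        cov, con = rec.mt_coverage, rec.mt_contamination
        if pd.isna(cov) or pd.isna(con):
            r.append("missing_metadata")
        else:
            if not cov > MT_MIN_COVERAGE:
                r.append("low_mt_coverage")
            if not con < MT_MAX_CONTAMINATION:
                r.append("high_mt_contamination")
        reasons.append(r)
    return _qc_report(samples, reasons)


def qc_filter_nuclear(samples: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Nuclear QC: male, damage >= 8% at the first base, >= 150 X SNPs
    covered twice.  Both numeric bounds are inclusive ("at least")."""
    reasons: list[list[str]] = []
    for rec in samples.itertuples(index=False):
        r: list[str] = []
        if pd.isna(rec.damage_5p) or pd.isna(rec.x_snps_covered_twice) or pd.isna(rec.sex):
            r.append("missing_metadata")
        else:
            if rec.sex != "male":
                r.append("not_male")
            if not rec.damage_5p >= DAMAGE_THRESHOLD:
                r.append("low_damage")
            if not rec.x_snps_covered_twice >= MIN_X_SNPS:
                r.append("few_x_snps")
        reasons.append(r)
    return _qc_report(samples, reasons)


# ---------------------------------------------------------------------------
# Y haplogroups and phenotype SNPs


def call_y_haplogroup(
    calls: Mapping[str, tuple[str, int]],
    isogg_table: pd.DataFrame,
    min_mapq: int = 30,
) -> str:
    """Most-derived Y haplogroup supported by the observed alleles.

    ``calls`` maps SNP id to (observed base, mapping quality); only
    calls with mapping quality strictly above ``min_mapq`` are used.
    ``isogg_table`` columns: snp_id, haplogroup, depth, ancestral,
    derived.  The deepest haplogroup with a derived defining SNP whose
    ancestor chain (name-prefix hierarchy) is not contradicted by
    observed ancestral states wins; ties break by number of supporting
    derived SNPs, then lexically.  Returns "unresolved" when no derived
    SNP is observed.
    """
    state: dict[str, dict[str, int]] = {}
    table = isogg_table.set_index("snp_id")
    for snp_id, (base, mapq) in calls.items():
        if mapq <= min_mapq or snp_id not in table.index:
            continue
        row = table.loc[snp_id]
        hg = str(row["haplogroup"])
        s = state.setdefault(hg, {"derived": 0, "ancestral": 0})
        if base == row["derived"]:
            s["derived"] += 1
        elif base == row["ancestral"]:
            s["ancestral"] += 1
    depth_of = dict(zip(isogg_table["haplogroup"].astype(str), isogg_table["depth"]))
    candidates = []
    for hg, s in state.items():
        if s["derived"] == 0:
            continue
        chain_ok = True
        for anc, anc_state in state.items():
            if anc != hg and hg.startswith(anc):
                if anc_state["ancestral"] > 0 and anc_state["derived"] == 0:
                    chain_ok = False
                    break
        if chain_ok:
            candidates.append((depth_of.get(hg, 0), s["derived"], hg))
    if not candidates:
        return "unresolved"
    candidates.sort(key=lambda t: (-t[0], -t[1], t[2]))
    return candidates[0][2]


def phenotype_lookup(
    calls: Mapping[str, tuple[str, int]],
    phenotype_table: pd.DataFrame,
    min_mapq: int = 30,
) -> pd.DataFrame:
    """Per-locus state (derived | ancestral | missing) at phenotype SNPs.

    ``phenotype_table`` columns: locus, snp_id, ancestral, derived.
    Loci without a quality-passing call report ``missing``.
    """
    rows = []
    for rec in phenotype_table.itertuples(index=False):
        obs = calls.get(rec.snp_id)
        if obs is None or obs[1] <= min_mapq:
            st = "missing"
        elif obs[0] == rec.derived:
            st = "derived"
        elif obs[0] == rec.ancestral:
            st = "ancestral"
        else:
            st = "missing"
        rows.append((rec.locus, rec.snp_id, st))
    return pd.DataFrame(rows, columns=["locus", "snp_id", "state"])
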