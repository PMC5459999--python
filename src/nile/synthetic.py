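"""Synthetic-data generators with known ground truth.

Every input class the pipeline consumes can be generated here:

* allele frequencies under a two-source admixture graph with
  Balding–Nichols drift, so f-statistics have closed-form expectations;
* diploid / pseudo-haploid genotype panels with missingness;
* ancestry-mosaic haplotypes from a pulse admixture (exponential-tract
  Markov approximation), the substrate for weighted-LD admixture dating;
* per-site read pileups with terminal C->T deamination, sequencing error
  and contaminant reads;
* haplogroup count tables evolving under multinomial Wright-Fisher
  drift (haploid, i.e. maternal-lineage, effective size for mtDNA);
* sequence pairs evolved under TN93 with gamma rate heterogeneity.

All generators are bit-reproducible given their seed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .containers import GenotypeDataset, MISSING, PileupSite

#: populations produced by the admixture graph, in output order.
#: Topology: ancestral -> {O, C, internal}; internal -> {A, B};
#: X = alpha * B + (1 - alpha) * C.  A is a sister of source B, which is
#: what an f4-ratio needs; extra outgroup-like populations O2, O3, ...
#: branch independently off the ancestral node.
GRAPH_POPULATIONS = ("O", "A", "B", "C", "X")

_BASES = np.array(["A", "C", "G", "T"])


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class AdmixtureGraphSpec:
    """Two-source admixture graph for allele-frequency simulation.

    ``drift`` is either one Wright-Fisher divergence parameter F in
    [0, 1) applied to every branch, or a mapping from branch name
    (``internal``, ``A``, ``B``, ``C``, ``O``, ``O2`` ...) to F.
    ``ancestral_freq`` is ``("beta", a, b)`` or ``("uniform", lo, hi)``
    for the per-SNP ancestral frequency p.
    """

    n_snps: int
    alpha: float
    drift: float | Mapping[str, float] = 0.02
    ancestral_freq: tuple = ("uniform", 0.05, 0.95)
    extra_outgroups: int = 0
    sample_sizes: Mapping[str, int] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for name in self.branch_names():
            F = self.branch_drift(name)
            if not 0.0 <= F < 1.0:
                raise ValueError(f"drift_F for branch {name} must be in [0, 1)")

    def branch_names(self) -> list[str]:
        extras = [f"O{i + 2}" for i in range(self.extra_outgroups)]
        return ["internal", "A", "B", "C", "O", *extras]

    def branch_drift(self, branch: str) -> float:
        if isinstance(self.drift, Mapping):
            return float(self.drift.get(branch, 0.0))
        return float(self.drift)

    def population_names(self) -> list[str]:
        return list(GRAPH_POPULATIONS) + [f"O{i + 2}" for i in range(self.extra_outgroups)]


@dataclass(frozen=True)
class PulseAdmixtureSpec:
    """Single pulse of admixture ``n_generations`` ago.

    Haplotypes are mosaics of source-1/source-2 tracts; tract boundaries
    follow a Poisson process of rate ``n_generations`` per Morgan and
    each tract is source 1 with probability ``alpha`` (exponential-tract
    Markov approximation, adequate for n >= 5 generations).
    """

    n_generations: int
    alpha: float
    map_length: float  # Morgans
    n_haplotypes: int
    n_snps: int
    seed: int = 0
    source_freq_low: float = 0.05
    source_freq_high: float = 0.95
    pool_size: int = 100

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise ValueError("n_generations must be >= 1")
        if self.map_length <= 0:
            raise ValueError("map_length must be positive (Morgans)")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")


@dataclass(frozen=True)
class PileupSimSpec:
    """Read-stack simulation at target sites.

    Terminal deamination: a read base C at 0-based 5' distance k is
    flipped to T with probability ``damage_amplitude * damage_decay**k``
    (G->A mirrored at the 3' end).  Each read is a contaminant with
    probability ``contamination_fraction``, drawing its allele from
    ``contaminant_genotypes`` instead of ``endogenous_genotypes``.
    """

    endogenous_genotypes: np.ndarray  # codes 0/1/2 per site
    contamination_fraction: float = 0.0
    error_rate: float = 0.0
    damage_amplitude: float = 0.0
    damage_decay: float = 0.5
    mean_coverage: float = 5.0
    read_length: int = 60
    seed: int = 0
    ref_alleles: np.ndarray | None = None
    alt_alleles: np.ndarray | None = None
    contaminant_genotypes: np.ndarray | None = None
    maf: np.ndarray | None = None  # per-site population minor-allele frequency
    baseq: int = 40
    mapq: int = 60

    def __post_init__(self) -> None:
        if not 0.0 <= self.contamination_fraction <= 1.0:
            raise ValueError("contamination_fraction must be in [0, 1]")
        if not 0.0 <= self.error_rate <= 0.25:
            raise ValueError("error_rate must be in [0, 0.25]")
        if not 0.0 <= self.damage_amplitude <= 1.0:
            raise ValueError("damage_amplitude must be in [0, 1]")
        if not 0.0 < self.damage_decay < 1.0:
            raise ValueError("damage_decay must be in (0, 1)")
        if self.read_length < 1:
            raise ValueError("read_length must be >= 1")


# ---------------------------------------------------------------------------
# admixture-graph frequencies


def _draw_ancestral(rng: np.random.Generator, dist: tuple, n: int) -> np.ndarray:
    kind, a, b = dist
    if kind == "beta":
        return rng.beta(a, b, size=n)
    if kind == "uniform":
        return rng.uniform(a, b, size=n)
    raise ValueError(f"unknown ancestral frequency distribution {kind!r}")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, F: float) -> np.ndarray:
    """Draw drifted frequencies around p with divergence F.

    F = 0 copies p exactly; frequencies fixed at 0 or 1 stay fixed
    (a Beta with a zero shape parameter is degenerate at the boundary).
    """
    if F == 0.0:
        return p.copy()
    scale = (1.0 - F) / F
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        pi = p[interior]
        out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def generate_graph_frequencies(spec: AdmixtureGraphSpec) -> pd.DataFrame:
    """Population-by-SNP allele-frequency table under the admixture graph.

    Returns a DataFrame indexed by population name (see
    :data:`GRAPH_POPULATIONS`); entries are the frequency of the allele
    counted by the genotype code (the reference allele).
    """
    rng = np.random.default_rng(spec.seed)
    p = _draw_ancestral(rng, spec.ancestral_freq, spec.n_snps)
    internal = _balding_nichols(rng, p, spec.branch_drift("internal"))
    freqs = {
        "O": _balding_nichols(rng, p, spec.branch_drift("O")),
        "A": _balding_nichols(rng, internal, spec.branch_drift("A")),
        "B": _balding_nichols(rng, internal, spec.branch_drift("B")),
        "C": _balding_nichols(rng, p, spec.branch_drift("C")),
    }
    freqs["X"] = spec.alpha * freqs["B"] + (1.0 - spec.alpha) * freqs["C"]
    for i in range(spec.extra_outgroups):
        name = f"O{i + 2}"
        freqs[name] = _balding_nichols(rng, p, spec.branch_drift(name))
    table = pd.DataFrame.from_dict(freqs, orient="index").loc[spec.population_names()]
    table.columns = [f"snp{i}" for i in range(spec.n_snps)]
    return table


def generate_genotypes(
    freq_table: pd.DataFrame,
    sample_sizes: Mapping[str, int],
    missing_rate: float = 0.0,
    pseudo_haploid: Mapping[str, bool] | set | tuple = (),
    seed: int = 0,
) -> GenotypeDataset:
    """Draw a genotype panel from a population-by-SNP frequency table.

    Diploid genotype codes ~ Binomial(2, f); pseudo-haploid populations
    (named in ``pseudo_haploid``) draw a single allele, Bernoulli(f),
    encoded 0/2.  Entries are set to missing (9) at ``missing_rate``.
    """
    f = freq_table.to_numpy(dtype=float)
    if np.any((f < 0) | (f > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_snps = f.shape[1]
    cols, ind_rows = [], []
    for k, pop in enumerate(freq_table.index):
        n = int(sample_sizes.get(pop, 0))
        if n == 0:
            warnings.warn(f"population {pop} has sample size 0; omitted")
            continue
        is_ph = pop in pseudo_haploid
        if is_ph:
            g = 2 * (rng.random((n_snps, n)) < f[k][:, None]).astype(np.int8)
        else:
            g = rng.binomial(2, f[k][:, None], size=(n_snps, n)).astype(np.int8)
        if missing_rate > 0:
            g[rng.random((n_snps, n)) < missing_rate] = MISSING
        cols.append(g)
        ind_rows += [
            (f"{pop}_{i}", "U", pop, is_ph) for i in range(n)
        ]
    if not cols:
        raise ValueError("no populations with positive sample size")
    geno = np.concatenate(cols, axis=1)
    snp = pd.DataFrame(
        {
            "snp_id": freq_table.columns,
            "chrom": "1",
            "gpos": np.arange(n_snps) * 1e-6,
            "ppos": np.arange(1, n_snps + 1) * 1000,
            "ref": "A",
            "alt": "G",
        }
    )
    ind = pd.DataFrame(ind_rows, columns=["sample_id", "sex", "population", "pseudo_haploid"])
    return GenotypeDataset(geno=geno, snp=snp, ind=ind)


def simulate_graph_dataset(spec: AdmixtureGraphSpec, missing_rate: float = 0.0,
                           pseudo_haploid=(), ) -> GenotypeDataset:
    """Convenience wrapper: graph frequencies -> genotype panel."""
    if spec.sample_sizes is None:
        raise ValueError("spec.sample_sizes required to draw genotypes")
    freqs = generate_graph_frequencies(spec)
    return generate_genotypes(
        freqs, spec.sample_sizes, missing_rate=missing_rate,
        pseudo_haploid=pseudo_haploid, seed=spec.seed + 1,
    )


# ---------------------------------------------------------------------------
# pulse-admixture haplotype mosaics


@dataclass
class AdmixedHaplotypes:
    """Output of :func:`generate_admixed_haplotypes`."""

    haplotypes: np.ndarray     # (n_haplotypes, n_snps) 0/1 alleles
    ancestry: np.ndarray       # (n_haplotypes, n_snps) source label 1 or 2
    positions: np.ndarray      # genetic positions, Morgans, strictly increasing
    source_freqs: np.ndarray   # (2, n_snps) true source allele frequencies
    n_breakpoints: np.ndarray  # recombination breakpoints per haplotype


def generate_admixed_haplotypes(spec: PulseAdmixtureSpec) -> AdmixedHaplotypes:
    rng = np.random.default_rng(spec.seed)
    positions = np.sort(rng.uniform(0.0, spec.map_length, spec.n_snps))
    if np.unique(positions).size != spec.n_snps:  # pragma: no cover - measure-zero
        positions = np.sort(rng.uniform(0.0, spec.map_length, spec.n_snps))
    source_freqs = rng.uniform(
        spec.source_freq_low, spec.source_freq_high, size=(2, spec.n_snps)
    )
    # finite source pools: tract alleles are copied from pool members
    pools = (rng.random((2, spec.pool_size, spec.n_snps)) < source_freqs[:, None, :]).astype(
        np.int8
    )
    haps = np.empty((spec.n_haplotypes, spec.n_snps), dtype=np.int8)
    anc = np.empty_like(haps)
    bp_counts = np.empty(spec.n_haplotypes, dtype=np.int64)
    snp_idx = np.arange(spec.n_snps)
    for h in range(spec.n_haplotypes):
        n_bp = rng.poisson(spec.n_generations * spec.map_length)
        bp_counts[h] = n_bp
        bp = np.sort(rng.uniform(0.0, spec.map_length, n_bp))
        seg_source = (rng.random(n_bp + 1) >= spec.alpha).astype(np.int8)  # 0=src1, 1=src2
        seg_member = rng.integers(spec.pool_size, size=n_bp + 1)
        seg_of_snp = np.searchsorted(bp, positions, side="right")
        src = seg_source[seg_of_snp]
        haps[h] = pools[src, seg_member[seg_of_snp], snp_idx]
        anc[h] = src + 1
    return AdmixedHaplotypes(haps, anc, positions, source_freqs, bp_counts)


# ---------------------------------------------------------------------------
# pileups


def _code_to_allele(code: int, ref: str, alt: str, rng: np.random.Generator) -> str:
    if code == 2:
        return ref
    if code == 0:
        return alt
    return ref if rng.random() < 0.5 else alt


def generate_pileups(spec: PileupSimSpec) -> list[PileupSite]:
    """Simulate the read stack at each target site.

    Per site: Poisson(mean_coverage) reads, each contaminant with
    probability c; terminal deamination then sequencing error applied to
    the sampled allele.
    """
    rng = np.random.default_rng(spec.seed)
    geno = np.asarray(spec.endogenous_genotypes)
    n_sites = geno.shape[0]
    ref = spec.ref_alleles if spec.ref_alleles is not None else np.full(n_sites, "C")
    alt = spec.alt_alleles if spec.alt_alleles is not None else np.full(n_sites, "T")
    contam = (
        np.asarray(spec.contaminant_genotypes)
        if spec.contaminant_genotypes is not None
        else np.zeros(n_sites, dtype=int)  # contaminant homozygous alt by default
    )
    sites = []
    for i in range(n_sites):
        depth = rng.poisson(spec.mean_coverage)
        bases = np.empty(depth, dtype="<U1")
        d5 = rng.integers(0, spec.read_length, size=depth)
        d3 = spec.read_length - 1 - d5
        is_contam = rng.random(depth) < spec.contamination_fraction
        for r in range(depth):
            code = contam[i] if is_contam[r] else geno[i]
            base = _code_to_allele(int(code), str(ref[i]), str(alt[i]), rng)
            # post-mortem deamination before sequencing error
            if base == "C" and rng.random() < spec.damage_amplitude * spec.damage_decay ** d5[r]:
                base = "T"
            elif base == "G" and rng.random() < spec.damage_amplitude * spec.damage_decay ** d3[r]:
                base = "A"
            if spec.error_rate > 0 and rng.random() < spec.error_rate:
                base = str(rng.choice(_BASES[_BASES != base]))
            bases[r] = base
        sites.append(
            PileupSite(
                snp_id=f"site{i}",
                ref=str(ref[i]),
                alt=str(alt[i]),
                base=bases,
                baseq=np.full(depth, spec.baseq),
                mapq=np.full(depth, spec.mapq),
                strand=np.where(rng.random(depth) < 0.5, "+", "-"),
                dist5p=d5,
                dist3p=d3,
                maf=None if spec.maf is None else float(spec.maf[i]),
            )
        )
    return sites


# ---------------------------------------------------------------------------
# haplogroup drift series


def generate_drift_series(
    ancestral_counts: np.ndarray,
    Ne: int,
    n_generations: int,
    sample_size: int,
    seed: int = 0,
) -> np.ndarray:
    """Evolve haplogroup frequencies by Wright-Fisher drift, then sample.

    ``Ne`` is the haploid (maternal-lineage) effective number of mtDNA
    lineages resampled multinomially each generation; the returned
    descendant table is a multinomial sample of ``sample_size`` from the
    final frequencies.
    """
    counts = np.asarray(ancestral_counts, dtype=np.int64)
    if counts.sum() <= 0:
        raise ValueError("ancestral counts are all zero")
    if np.any(counts < 0):
        raise ValueError("counts must be non-negative")
    if Ne < 1:
        raise ValueError("Ne must be >= 1")
    rng = np.random.default_rng(seed)
    freq = counts / counts.sum()
    for _ in range(int(n_generations)):
        freq = rng.multinomial(int(Ne), freq) / float(Ne)
    return rng.multinomial(int(sample_size), freq)


# ---------------------------------------------------------------------------
# sample metadata


def generate_sample_metadata(
    n_pre_ptolemaic: int = 44,
    n_ptolemaic: int = 27,
    n_roman: int = 19,
    n_decoys: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-sample metadata table for the mtDNA QC cascade.

    The three period groups (defaults follow the study's 44/27/19 split)
    all satisfy the coverage and contamination thresholds; each decoy
    violates exactly one of them, half sitting exactly on a boundary
    (coverage 10-fold, contamination 3%) to pin down strictness.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for period, n in (("pre_ptolemaic", n_pre_ptolemaic), ("ptolemaic", n_ptolemaic),
                      ("roman", n_roman)):
        for i in range(n):
            rows.append({
                "sample_id": f"{period[:3]}_{i}",
                "tissue": rng.choice(["bone", "tooth", "soft_tissue"]),
                "period": period,
                "mt_coverage": float(rng.uniform(10.5, 250.0)),
                "mt_contamination": float(rng.uniform(0.0, 0.029)),
                "damage_5p": float(rng.uniform(0.05, 0.30)),
                "sex": rng.choice(["male", "female"]),
                "x_snps_covered_twice": int(rng.integers(0, 1000)),
            })
    for i in range(n_decoys):
        kind = i % 4
        cov, con = float(rng.uniform(10.5, 250.0)), float(rng.uniform(0.0, 0.029))
        if kind == 0:
            cov = 10.0                     # boundary: ">10-fold" is strict
        elif kind == 1:
            con = 0.03                     # boundary: "<3%" is strict
        elif kind == 2:
            cov = float(rng.uniform(0.1, 9.9))
        else:
            con = float(rng.uniform(0.031, 0.5))
        rows.append({
            "sample_id": f"decoy_{i}",
            "tissue": "bone",
            "period": "roman",
            "mt_coverage": cov,
            "mt_contamination": con,
            "damage_5p": float(rng.uniform(0.05, 0.30)),
            "sex": "male",
            "x_snps_covered_twice": int(rng.integers(0, 1000)),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# TN93 sequence pairs


def simulate_tn93_pair(
    length: int,
    distance: float,
    gamma_shape: float | None = None,
    base_freqs: tuple[float, float, float, float] = (0.30, 0.25, 0.15, 0.30),
    kappa1: float = 4.0,
    kappa2: float = 8.0,
    seed: int = 0,
) -> tuple[str, str]:
    """Evolve one sequence from another under TN93 at a given distance.

    ``distance`` is the expected number of substitutions per site;
    ``kappa1``/``kappa2`` scale purine (A<->G) and pyrimidine (C<->T)
    transitions relative to transversions.  With ``gamma_shape`` set,
    per-site rates are Gamma(shape, 1/shape) distributed.
    """
    pi = np.asarray(base_freqs, dtype=float)
    pi = pi / pi.sum()
    piA, piC, piG, piT = pi
    # rate matrix, order A C G T
    Q = np.array(
        [
            [0.0, piC, kappa1 * piG, piT],
            [piA, 0.0, piG, kappa2 * piT],
            [kappa1 * piA, piC, 0.0, piT],
            [piA, kappa2 * piC, piG, 0.0],
        ]
    )
    np.fill_diagonal(Q, -Q.sum(axis=1))
    Q /= -(pi * np.diag(Q)).sum()  # mean rate 1 at stationarity
    # reversible -> symmetrize and eigendecompose once
    d = np.sqrt(pi)
    S = (Q * d[:, None]) / d[None, :]
    lam, U = np.linalg.eigh((S + S.T) / 2.0)
    L = U / d[:, None]
    R = U.T * d[None, :]

    rng = np.random.default_rng(seed)
    rates = (
        rng.gamma(gamma_shape, 1.0 / gamma_shape, size=length)
        if gamma_shape is not None
        else np.ones(length)
    )
    t = distance * rates
    E = np.exp(np.outer(t, lam))  # (length, 4)
    seq1 = rng.choice(4, size=length, p=pi)
    P = np.einsum("ia,sa,aj->sij", L, E, R)  # per-site transition matrices
    probs = np.clip(P[np.arange(length), seq1, :], 0.0, None)
    probs /= probs.sum(axis=1, keepdims=True)
    u = rng.random(length)
    seq2 = (probs.cumsum(axis=1) < u[:, None]).sum(axis=1)
    return "".join(_BASES[seq1]), "".join(_BASES[seq2])
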