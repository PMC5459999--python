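"""f-statistics with weighted block jackknife, scans, ancestry proportions
and PCA with projection of ancient samples.

Estimators follow the standard allele-frequency definitions with
small-sample heterozygosity corrections h_X = x(1-x)/(n_X - 1) applied
per SNP (n_X = observed allele count; pseudo-haploid samples contribute
one allele each and can never be heterozygous):

    f2(A,B)   = (a-b)^2 - h_A - h_B
    f3(C;A,B) = (c-a)(c-b) - h_C
    f4(A,B;C,D) = (a-b)(c-d)

SNPs with any involved population unobserved are dropped per statistic
(complete case).  Standard errors come from a weighted block jackknife
over contiguous SNP blocks, weighted by per-block SNP counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .containers import GenotypeDataset, MISSING

logger = logging.getLogger(__name__)


@dataclass
class FStatResult:
    name: str
    pops: tuple[str, ...]
    estimate: float
    se: float
    z: float
    n_blocks: int
    n_snps_used: int
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.se > 0:
            assert abs(self.z - self.estimate / self.se) < 1e-9


@dataclass
class AncestryProportion:
    """Admixture proportion estimate (f4-ratio or constrained LSQ)."""

    method: str  # "f4_ratio" | "lsq"
    sources: tuple[str, ...]
    alpha: float
    se: float
    weights: np.ndarray | None = None
    weight_se: np.ndarray | None = None
    residual_norm: float | None = None
    flags: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# allele frequencies


def allele_frequencies(
    dataset: GenotypeDataset, population: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP (alt-allele frequency, observed allele count).

    Missing codes are excluded; pseudo-haploid samples contribute one
    allele.  SNPs with zero observed alleles report NaN frequency.
    """
    idx = dataset.pop_indices(population)
    G = dataset.geno[:, idx]
    ph = dataset.ind["pseudo_haploid"].to_numpy(bool)[idx]
    obs = G != MISSING
    Gd, obs_d = G[:, ~ph], obs[:, ~ph]
    Gp, obs_p = G[:, ph], obs[:, ph]
    alt = ((2 - Gd) * obs_d).sum(axis=1) + (Gp == 0).sum(axis=1)
    count = 2 * obs_d.sum(axis=1) + obs_p.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = np.where(count > 0, alt / count, np.nan)
    return freq, count


def _het_correction(freq: np.ndarray, count: np.ndarray) -> tuple[np.ndarray, bool]:
    """h = x(1-x)/(n-1); SNPs with n < 2 get h = 0 and raise a flag."""
    undef = count < 2
    n = np.where(undef, 2, count)
    h = freq * (1.0 - freq) / (n - 1.0)
    h = np.where(undef, 0.0, h)
    return h, bool(np.any(undef & (count > 0)))


# ---------------------------------------------------------------------------
# block jackknife


def assign_blocks(dataset: GenotypeDataset, n_blocks: int | None = None,
                  block_cm: float = 5.0) -> np.ndarray:
    """Per-SNP block ids for the jackknife.

    Default: genetic-map windows of ``block_cm`` centimorgans per
    chromosome; if that yields fewer than 20 blocks, contiguous index
    blocks of ~n_snps/50 SNPs are used instead.
    """
    n = dataset.n_snps
    if n_blocks is not None:
        return np.minimum(np.arange(n) * n_blocks // n, n_blocks - 1)
    keys = list(
        zip(dataset.snp["chrom"], (dataset.snp["gpos"].to_numpy() // (block_cm / 100.0)).astype(int))
    )
    uniq = {k: i for i, k in enumerate(dict.fromkeys(keys))}
    ids = np.array([uniq[k] for k in keys])
    if len(uniq) >= 20:
        return ids
    g = min(50, n)
    return np.minimum(np.arange(n) * g // n, g - 1)


def _busing_jackknife(theta: float, theta_del: np.ndarray, m: np.ndarray, n: int) -> float:
    """Weighted delete-m_j jackknife variance (Busing et al. 1999)."""
    g = len(m)
    if g < 2:
        return 0.0
    h = n / m
    theta_J = g * theta - float(np.sum((1.0 - m / n) * theta_del))
    tau = h * theta - (h - 1.0) * theta_del
    var = float(np.mean((tau - theta_J) ** 2 / (h - 1.0)))
    return max(var, 0.0)


def _jackknife_mean(terms: np.ndarray, block_ids: np.ndarray) -> tuple[float, float, int]:
    """Mean of per-SNP terms with weighted block-jackknife SE."""
    n = terms.size
    order = np.argsort(block_ids, kind="stable")
    t, b = terms[order], block_ids[order]
    uniq, start = np.unique(b, return_index=True)
    sums = np.add.reduceat(t, start)
    m = np.diff(np.append(start, n)).astype(float)
    total = float(t.sum())
    theta = total / n
    theta_del = (total - sums) / (n - m)
    var = _busing_jackknife(theta, theta_del, m, n)
    return theta, float(np.sqrt(var)), len(uniq)


def _jackknife_ratio(
    num: np.ndarray, den: np.ndarray, block_ids: np.ndarray
) -> tuple[float, float, int]:
    """Ratio of per-SNP sums with block-jackknife SE of the ratio."""
    n = num.size
    order = np.argsort(block_ids, kind="stable")
    u, v, b = num[order], den[order], block_ids[order]
    uniq, start = np.unique(b, return_index=True)
    su = np.add.reduceat(u, start)
    sv = np.add.reduceat(v, start)
    m = np.diff(np.append(start, n)).astype(float)
    theta = float(u.sum() / v.sum())
    theta_del = (u.sum() - su) / (v.sum() - sv)
    var = _busing_jackknife(theta, theta_del, m, n)
    return theta, float(np.sqrt(var)), len(uniq)


def _result(name, pops, terms, mask, block_ids, flags) -> FStatResult:
    terms = terms[mask]
    if terms.size == 0:
        raise ValueError(f"{name}{pops}: no SNPs with complete data")
    est, se, g = _jackknife_mean(terms, block_ids[mask])
    z = est / se if se > 0 else 0.0
    return FStatResult(
        name=name, pops=tuple(pops), estimate=est, se=se, z=z,
        n_blocks=g, n_snps_used=int(terms.size), flags=flags,
    )


# ---------------------------------------------------------------------------
# f2 / f3 / f4


def f2(dataset: GenotypeDataset, A: str, B: str, n_blocks: int | None = None) -> FStatResult:
    block_ids = assign_blocks(dataset, n_blocks)
    if A == B:
        # identical columns: the statistic is exactly 0 without corrections
        return FStatResult("f2", (A, B), 0.0, 0.0, 0.0, 0, dataset.n_snps,
                           flags=["identical_populations"])
    a, na = allele_frequencies(dataset, A)
    b, nb = allele_frequencies(dataset, B)
    hA, flagA = _het_correction(a, na)
    hB, flagB = _het_correction(b, nb)
    mask = (na > 0) & (nb > 0)
    terms = (a - b) ** 2 - hA - hB
    flags = ["het_correction_skipped"] if (flagA or flagB) else []
    return _result("f2", (A, B), terms, mask, block_ids, flags)


def f3(dataset: GenotypeDataset, C: str, A: str, B: str,
       n_blocks: int | None = None) -> FStatResult:
    block_ids = assign_blocks(dataset, n_blocks)
    c, nc = allele_frequencies(dataset, C)
    a, na = allele_frequencies(dataset, A)
    b, nb = allele_frequencies(dataset, B)
    hC, flagC = _het_correction(c, nc)
    mask = (na > 0) & (nb > 0) & (nc > 0)
    terms = (c - a) * (c - b) - hC
    flags = ["het_correction_skipped"] if flagC else []
    return _result("f3", (C, A, B), terms, mask, block_ids, flags)


def f4(dataset: GenotypeDataset, A: str, B: str, C: str, D: str,
       n_blocks: int | None = None) -> FStatResult:
    block_ids = assign_blocks(dataset, n_blocks)
    a, na = allele_frequencies(dataset, A)
    b, nb = allele_frequencies(dataset, B)
    c, nc = allele_frequencies(dataset, C)
    d, nd = allele_frequencies(dataset, D)
    mask = (na > 0) & (nb > 0) & (nc > 0) & (nd > 0)
    terms = (a - b) * (c - d)
    return _result("f4", (A, B, C, D), terms, mask, block_ids, [])


# ---------------------------------------------------------------------------
# scans


def outgroup_f3_scan(
    dataset: GenotypeDataset, outgroup: str, focal: str, candidates: list[str],
    n_blocks: int | None = None,
) -> list[FStatResult]:
    """f3(outgroup; focal, X) for each candidate X, ranked by shared drift
    (descending estimate, ties broken lexically)."""
    results = []
    for cand in candidates:
        try:
            results.append(f3(dataset, outgroup, focal, cand, n_blocks=n_blocks))
        except (KeyError, ValueError) as exc:
            logger.warning("outgroup f3 scan: candidate %s omitted (%s)", cand, exc)
    results.sort(key=lambda r: (-r.estimate, r.pops[2]))
    return results


def admixture_f3_scan(
    dataset: GenotypeDataset, target: str, fixed_source: str, candidates: list[str],
    n_blocks: int | None = None,
) -> list[FStatResult]:
    """f3(target; fixed_source, X), ranked by Z ascending — the most
    negative Z marks the most likely admixture source."""
    results = []
    for cand in candidates:
        try:
            results.append(f3(dataset, target, fixed_source, cand, n_blocks=n_blocks))
        except (KeyError, ValueError) as exc:
            logger.warning("admixture f3 scan: candidate %s omitted (%s)", cand, exc)
    results.sort(key=lambda r: (r.z, r.pops[2]))
    return results


# ---------------------------------------------------------------------------
# ancestry proportions


def f4_ratio(dataset: GenotypeDataset, A: str, O: str, X: str, B: str, C: str,
             n_blocks: int | None = None) -> AncestryProportion:
    """alpha = f4(A,O;X,C) / f4(A,O;B,C): ancestry fraction of X from the
    B-related source, the remainder from the C-related source.

    SE is the block jackknife of the ratio.  A denominator smaller than
    10 of its own jackknife SEs is flagged "weak_denominator".
    """
    block_ids = assign_blocks(dataset, n_blocks)
    freqs = {p: allele_frequencies(dataset, p) for p in dict.fromkeys([A, O, X, B, C])}
    mask = np.ones(dataset.n_snps, dtype=bool)
    for f_, n_ in freqs.values():
        mask &= n_ > 0
    a, o, x, b, c = (freqs[p][0] for p in (A, O, X, B, C))
    num = ((a - o) * (x - c))[mask]
    den = ((a - o) * (b - c))[mask]
    ids = block_ids[mask]
    alpha, se, _ = _jackknife_ratio(num, den, ids)
    den_est, den_se, _ = _jackknife_mean(den, ids)
    flags = []
    if abs(den_est) < 10 * den_se:
        flags.append("weak_denominator")
    return AncestryProportion(
        method="f4_ratio", sources=(B, C), alpha=alpha, se=se, flags=flags
    )


def lsq_admixture_weights(
    dataset: GenotypeDataset,
    target: str,
    sources: list[str],
    right_populations: list[str],
    base_right: str,
    n_blocks: int | None = None,
) -> AncestryProportion:
    """Sum-to-one weighted least-squares admixture weights.

    Under target = sum_k w_k source_k (in allele-frequency space), the
    shared-drift statistics y_r = f4(target, base; r, base) equal
    sum_k w_k f4(source_k, base; r, base) for every right population r.
    Weights minimise the jackknife-variance-weighted squared residuals
    subject to sum(w) = 1; SEs come from re-solving with each block of
    SNPs deleted.
    """
    rights = [r for r in right_populations if r != base_right]
    if len(rights) < 2:
        raise ValueError("need at least 2 right populations beyond the base")
    K = len(sources)
    block_ids = assign_blocks(dataset, n_blocks)
    pops = list(dict.fromkeys([target, *sources, base_right, *rights]))
    freqs = {p: allele_frequencies(dataset, p) for p in pops}
    mask = np.ones(dataset.n_snps, dtype=bool)
    for f_, n_ in freqs.values():
        mask &= n_ > 0
    if mask.sum() == 0:
        raise ValueError("no SNPs with complete data across all populations")
    b0 = freqs[base_right][0][mask]
    lefts = [target] + list(sources)
    left_f = np.stack([freqs[p][0][mask] for p in lefts])  # (K+1, S)
    right_f = np.stack([freqs[r][0][mask] for r in rights])  # (R, S)
    # per-SNP terms for every (left, right) statistic
    terms = (left_f[:, None, :] - b0) * (right_f[None, :, :] - b0)  # (K+1, R, S)

    ids = block_ids[mask]
    order = np.argsort(ids, kind="stable")
    terms = terms[:, :, order]
    uniq, start = np.unique(ids[order], return_index=True)
    bsums = np.add.reduceat(terms, start, axis=2)  # (K+1, R, G)
    m = np.diff(np.append(start, terms.shape[2])).astype(float)
    n = terms.shape[2]
    tot = bsums.sum(axis=2)  # (K+1, R)

    # jackknife variance of each y_r for the weighting
    w_var = np.empty(len(rights))
    for r in range(len(rights)):
        theta = tot[0, r] / n
        theta_del = (tot[0, r] - bsums[0, r]) / (n - m)
        w_var[r] = _busing_jackknife(theta, theta_del, m, n)
    w_var = np.where(w_var > 0, w_var, np.nanmin(w_var[w_var > 0]) if (w_var > 0).any() else 1.0)
    Wh = 1.0 / np.sqrt(w_var)

    def solve(stats: np.ndarray) -> np.ndarray:
        y = stats[0]
        M = stats[1:].T  # (R, K)
        # collinear sources are unresolvable
        for i in range(K):
            for j in range(i + 1, K):
                mi, mj = M[:, i], M[:, j]
                denom = np.linalg.norm(mi) * np.linalg.norm(mj)
                if denom > 0 and abs(np.dot(mi, mj)) / denom > 1.0 - 1e-10:
                    raise ValueError(
                        f"collinear sources: {sources[i]} and {sources[j]}"
                    )
        w0 = np.full(K, 1.0 / K)
        if K == 1:
            return w0
        N = np.vstack([np.eye(K - 1), -np.ones(K - 1)])  # null space of sum constraint
        Aw = (Wh[:, None] * M) @ N
        bw = Wh * (y - M @ w0)
        v, *_ = np.linalg.lstsq(Aw, bw, rcond=None)
        return w0 + N @ v

    w_full = solve(tot / n)
    G = len(uniq)
    w_del = np.empty((G, K))
    for gidx in range(G):
        w_del[gidx] = solve((tot - bsums[:, :, gidx]) / (n - m[gidx]))
    w_se = np.empty(K)
    for k in range(K):
        w_se[k] = np.sqrt(_busing_jackknife(float(w_full[k]), w_del[:, k], m, n))

    y, M = tot[0] / n, (tot[1:] / n).T
    resid = Wh * (y - M @ w_full)
    resid_norm = float(np.linalg.norm(resid))
    flags = []
    dof = len(rights) - (K - 1)
    if dof >= 1 and resid_norm**2 > chi2.ppf(0.999, dof):
        flags.append("poor_fit")
    return AncestryProportion(
        method="lsq",
        sources=tuple(sources),
        alpha=float(w_full[0]),
        se=float(w_se[0]),
        weights=w_full,
        weight_se=w_se,
        residual_norm=resid_norm,
        flags=flags,
    )


# ---------------------------------------------------------------------------
# PCA with projection


def pca_with_projection(
    dataset: GenotypeDataset,
    reference_populations: list[str],
    projected_samples: list[str] | None = None,
    n_components: int = 2,
) -> pd.DataFrame:
    """PCA on reference individuals; ancient samples projected by least
    squares on their non-missing SNPs.

    SNPs are mean-centred and scaled by sqrt(p(1-p)) with p estimated
    from the reference; monomorphic or all-missing SNPs are dropped.
    Returns a DataFrame with sample_id, population, projected flag and
    PC coordinates.
    """
    ref_mask = dataset.ind["population"].isin(reference_populations).to_numpy()
    if not ref_mask.any():
        raise ValueError("no reference individuals found")
    proj_ids = list(projected_samples or [])
    proj_mask = dataset.ind["sample_id"].isin(proj_ids).to_numpy()
    ref_mask &= ~proj_mask

    G = dataset.geno.astype(float)
    G[G == MISSING] = np.nan
    Gr = G[:, ref_mask]
    with np.errstate(invalid="ignore"):
        p = np.nanmean(Gr, axis=1) / 2.0
    keep = np.isfinite(p) & (p > 0) & (p < 1)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("PCA: dropped %d monomorphic or all-missing SNPs", dropped)
    Gk, pk = G[keep], p[keep]
    scale = np.sqrt(pk * (1.0 - pk))
    M = (Gk - 2.0 * pk[:, None]) / scale[:, None]
    Mr = np.nan_to_num(M[:, ref_mask], nan=0.0)

    U, S, Vt = np.linalg.svd(Mr.T, full_matrices=False)
    rank = int(np.sum(S > S[0] * 1e-10)) if S.size else 0
    if n_components > rank:
        raise ValueError(f"n_components={n_components} exceeds rank {rank}")
    V = Vt[:n_components].T  # (snps, k) loadings
    coords = np.full((dataset.n_ind, n_components), np.nan)
    coords[ref_mask] = U[:, :n_components] * S[:n_components]

    for i in np.flatnonzero(proj_mask):
        obs = np.isfinite(M[:, i])
        if not obs.any():
            continue
        sol, *_ = np.linalg.lstsq(V[obs], M[obs, i], rcond=None)
        coords[i] = sol

    out = dataset.ind[["sample_id", "population"]].copy()
    out["projected"] = proj_mask
    for k in range(n_components):
        out[f"PC{k + 1}"] = coords[:, k]
    return out[ref_mask | proj_mask].reset_index(drop=True)
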