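"""Mitochondrial analyses.

Haplogroup binning and frequency PCA, Tamura-Nei (TN93) distances with
gamma rate-heterogeneity correction, AMOVA-based Phi_ST with permutation
tests, Benjamini-Hochberg correction, Slatkin linearization and classical
(Torgerson) multidimensional scaling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .containers import DistanceMatrix, HaplogroupCountTable

logger = logging.getLogger(__name__)

#: the 20 haplogroup bins; anything else maps to "other".
HAPLOGROUP_BINS = (
    "H", "HV", "I", "J", "K", "L0", "L1", "L2", "L3", "L4",
    "M1", "N", "R", "R0", "T", "T1", "T2", "U", "W", "X",
)
OTHER_BIN = "other"

_BINS_BY_LENGTH = sorted(HAPLOGROUP_BINS, key=len, reverse=True)


def bin_haplogroup(full_label: str) -> str:
    """Map a full haplogroup label onto the 20 analysis bins.

    Longest-prefix match, so "HV1" goes to HV (not H) and "T2b" to T2
    (not T); labels matching no bin (e.g. "M2" — M1 is a bin, M is not)
    go to "other".  Matching is on the uppercased label.
    """
    if not full_label:
        raise ValueError("empty haplogroup label")
    label = full_label.strip().upper()
    for b in _BINS_BY_LENGTH:
        if label.startswith(b):
            return b
    return OTHER_BIN


def count_binned_haplogroups(assignments: pd.DataFrame) -> HaplogroupCountTable:
    """Population-by-bin count table from per-sample haplogroup calls.

    ``assignments`` columns: population, haplogroup.
    """
    binned = assignments.assign(bin=assignments["haplogroup"].map(bin_haplogroup))
    pops = list(dict.fromkeys(binned["population"]))
    bins = list(HAPLOGROUP_BINS) + [OTHER_BIN]
    counts = np.zeros((len(pops), len(bins)), dtype=np.int64)
    tab = binned.groupby(["population", "bin"]).size()
    for (pop, b), c in tab.items():
        counts[pops.index(pop), bins.index(b)] = c
    return HaplogroupCountTable(pops, bins, counts)


# ---------------------------------------------------------------------------
# haplogroup-frequency PCA


def haplogroup_frequency_pca(
    table: HaplogroupCountTable, n_components: int = 2
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of per-population haplogroup frequency vectors.

    Rows are converted to frequencies and column-centred; scores of the
    first components are returned together with explained-variance
    fractions.  Populations with zero total count are excluded.
    """
    totals = table.counts.sum(axis=1)
    keep = totals > 0
    if (~keep).any():
        logger.warning("haplogroup PCA: excluded zero-count populations %s",
                       [p for p, k in zip(table.populations, keep) if not k])
    pops = [p for p, k in zip(table.populations, keep) if k]
    if len(pops) < 3:
        raise ValueError("haplogroup PCA needs at least 3 populations with data")
    freq = table.counts[keep] / totals[keep, None]
    centred = freq - freq.mean(axis=0)
    U, S, Vt = np.linalg.svd(centred, full_matrices=False)
    k = min(n_components, S.size)
    scores = U[:, :k] * S[:k]  # null directions get zero scores
    explained = (S**2 / np.sum(S**2))[:k]
    coords = pd.DataFrame(scores, columns=[f"PC{i + 1}" for i in range(k)])
    coords.insert(0, "population", pops)
    return coords, explained


# ---------------------------------------------------------------------------
# TN93 (+ gamma) distances


def tn93_gamma_distance(seq1: str, seq2: str, gamma_shape: float | None = None) -> float:
    """TN93 substitutions/site between two aligned sequences.

    With ``gamma_shape`` a, rate heterogeneity is corrected by replacing
    each -log(w) term with a (w^(-1/a) - 1).  Base frequencies are
    estimated from the sequence pair; sites with anything other than
    A/C/G/T in either sequence are excluded pairwise.  Saturated pairs
    (a logarithm/power argument <= 0) return NaN.
    """
    if len(seq1) != len(seq2):
        raise ValueError("sequences must have equal length")
    s1 = np.frombuffer(seq1.upper().encode(), dtype="S1")
    s2 = np.frombuffer(seq2.upper().encode(), dtype="S1")
    valid = np.isin(s1, (b"A", b"C", b"G", b"T")) & np.isin(s2, (b"A", b"C", b"G", b"T"))
    s1, s2 = s1[valid], s2[valid]
    L = s1.size
    if L == 0:
        raise ValueError("no comparable sites after pairwise deletion")
    both = np.concatenate([s1, s2])
    piA, piC, piG, piT = (np.mean(both == b) for b in (b"A", b"C", b"G", b"T"))
    gR, gY = piA + piG, piC + piT
    diff = s1 != s2
    P1 = np.mean(diff & np.isin(s1, (b"A", b"G")) & np.isin(s2, (b"A", b"G")))
    P2 = np.mean(diff & np.isin(s1, (b"C", b"T")) & np.isin(s2, (b"C", b"T")))
    Q = np.mean(diff) - P1 - P2
    if P1 + P2 + Q == 0:
        return 0.0
    k1 = 2.0 * piA * piG / gR if gR > 0 else 0.0
    k2 = 2.0 * piC * piT / gY if gY > 0 else 0.0
    k3 = 2.0 * (gR * gY - (piA * piG * gY / gR if gR > 0 else 0.0)
                - (piC * piT * gR / gY if gY > 0 else 0.0))
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gR) if k1 > 0 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gY) if k2 > 0 else 1.0
    w3 = 1.0 - Q / (2.0 * gR * gY)
    if min(w1, w2, w3) <= 0.0:
        logger.warning("TN93 distance saturated (w1=%.4g w2=%.4g w3=%.4g)", w1, w2, w3)
        return float("nan")
    if gamma_shape is None:
        d = -k1 * np.log(w1) - k2 * np.log(w2) - k3 * np.log(w3)
    else:
        a = float(gamma_shape)
        d = a * (k1 * (w1 ** (-1.0 / a) - 1.0)
                 + k2 * (w2 ** (-1.0 / a) - 1.0)
                 + k3 * (w3 ** (-1.0 / a) - 1.0))
    return float(d)


def pairwise_tn93_matrix(
    seqs: dict[str, str], gamma_shape: float | None = None
) -> DistanceMatrix:
    labels = list(seqs)
    n = len(labels)
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            D[i, j] = D[j, i] = tn93_gamma_distance(seqs[labels[i]], seqs[labels[j]],
                                                    gamma_shape)
    return DistanceMatrix(labels, D)


# ---------------------------------------------------------------------------
# Phi_ST (AMOVA on pairwise distances)


@dataclass
class PhiStResult:
    phi_st: float
    p_value: float
    sigma_among: float
    sigma_within: float
    n_permutations: int


def _phi_from_d2(D2: np.ndarray, codes: np.ndarray, n_pops: int) -> float:
    """Phi_ST variance-component ratio from squared distances and integer
    population codes."""
    N = codes.size
    ss_total = D2.sum() / (2.0 * N)
    ss_within = 0.0
    sizes = np.bincount(codes, minlength=n_pops)
    for p in range(n_pops):
        idx = np.flatnonzero(codes == p)
        ss_within += D2[np.ix_(idx, idx)].sum() / (2.0 * sizes[p])
    ss_among = ss_total - ss_within
    df_among = n_pops - 1
    df_within = N - n_pops
    sigma_w = ss_within / df_within
    n0 = (N - np.sum(sizes**2) / N) / df_among
    sigma_a = (ss_among / df_among - sigma_w) / n0
    denom = sigma_a + sigma_w
    return sigma_a / denom if denom != 0 else 0.0


def phi_st(
    distances: DistanceMatrix | np.ndarray,
    populations: list[str] | np.ndarray,
    n_permutations: int = 10_000,
    seed: int = 0,
) -> PhiStResult:
    """AMOVA-based Phi_ST on a matrix of pairwise individual distances.

    Phi_ST = sigma2_among / (sigma2_among + sigma2_within), computed
    from sums of squared distances.  The permutation p-value shuffles
    individual labels and uses the add-one rule
    p = (1 + #{perm >= observed}) / (n_permutations + 1).
    """
    D = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances)
    pops = np.asarray(populations)
    if pops.size != D.shape[0]:
        raise ValueError("one population label per individual required")
    uniq, codes = np.unique(pops, return_inverse=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 populations")
    sizes = np.bincount(codes)
    if sizes.min() < 2:
        small = uniq[np.argmin(sizes)]
        raise ValueError(
            f"population {small!r} has a single individual; "
            "within-population variance is undefined"
        )
    D2 = D**2
    observed = _phi_from_d2(D2, codes, len(uniq))
    rng = np.random.default_rng(seed)
    sigma_a_w = _variance_components(D2, codes, len(uniq))
    ge = 0
    for _ in range(n_permutations):
        perm = rng.permutation(codes)
        if _phi_from_d2(D2, perm, len(uniq)) >= observed:
            ge += 1
    p = (1 + ge) / (n_permutations + 1)
    return PhiStResult(
        phi_st=float(observed), p_value=float(p),
        sigma_among=sigma_a_w[0], sigma_within=sigma_a_w[1],
        n_permutations=n_permutations,
    )


def _variance_components(D2: np.ndarray, codes: np.ndarray, n_pops: int) -> tuple[float, float]:
    N = codes.size
    ss_total = D2.sum() / (2.0 * N)
    sizes = np.bincount(codes, minlength=n_pops)
    ss_within = sum(
        D2[np.ix_(np.flatnonzero(codes == p), np.flatnonzero(codes == p))].sum()
        / (2.0 * sizes[p])
        for p in range(n_pops)
    )
    df_among, df_within = n_pops - 1, N - n_pops
    sigma_w = ss_within / df_within
    n0 = (N - np.sum(sizes**2) / N) / df_among
    sigma_a = ((ss_total - ss_within) / df_among - sigma_w) / n0
    return float(sigma_a), float(sigma_w)


def pairwise_phi_st(
    distances: DistanceMatrix,
    populations: list[str],
    n_permutations: int = 10_000,
    seed: int = 0,
    pool: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Phi_ST and permutation p for every population pair, with
    BH-adjusted p-values.

    ``pool`` optionally maps original group labels onto merged ones
    (e.g. the three ancient period groups onto a single meta-population)
    before the pairwise comparisons.
    """
    pops = np.asarray([pool.get(p, p) if pool else p for p in populations])
    labels = list(dict.fromkeys(pops))
    rows = []
    for i, a in enumerate(labels):
        for b in labels[i + 1:]:
            m = (pops == a) | (pops == b)
            res = phi_st(distances.values[np.ix_(m, m)], pops[m],
                         n_permutations=n_permutations, seed=seed)
            rows.append((a, b, res.phi_st, res.p_value))
    out = pd.DataFrame(rows, columns=["pop1", "pop2", "phi_st", "p"])
    out["p_bh"] = bh_adjust(out["p"].to_numpy())
    return out


# ---------------------------------------------------------------------------
# Slatkin linearization, BH adjustment, classical MDS


def slatkin_linearize(fst: float) -> float:
    """Slatkin's linearized distance FST / (1 - FST).

    Negative FST estimates are clamped to 0 before the transform.
    """
    if fst >= 1.0:
        raise ValueError("FST must be < 1 for linearization")
    if fst < 0.0:
        logger.info("negative FST %.4g clamped to 0 before linearization", fst)
        fst = 0.0
    return fst / (1.0 - fst)


def bh_adjust(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def classical_mds(
    distances: DistanceMatrix | np.ndarray, k: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Classical (Torgerson) MDS.

    Double-centres B = -1/2 J D^2 J and returns the top-k eigenvectors
    scaled by sqrt(eigenvalue), plus all eigenvalues (descending).
    Requesting more axes than there are positive eigenvalues is an
    error; negative eigenvalues merely mean the configuration is not
    perfectly Euclidean and their axes are dropped.
    """
    D = distances.values if isinstance(distances, DistanceMatrix) else np.asarray(distances)
    if not np.allclose(D, D.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")
    n = D.shape[0]
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ (D**2) @ J
    vals, vecs = np.linalg.eigh((B + B.T) / 2.0)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    tol = max(abs(vals[0]), 1.0) * 1e-12
    n_pos = int(np.sum(vals > tol))
    if k > n_pos:
        raise ValueError(f"k={k} exceeds the {n_pos} positive eigenvalues")
    if np.any(vals < -tol):
        logger.warning("MDS: %d negative eigenvalues dropped (non-Euclidean input)",
                       int(np.sum(vals < -tol)))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    return coords, vals
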