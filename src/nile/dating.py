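"""Admixture dating from weighted LD decay, and effective-population-size
rescaling arithmetic.

A single pulse of admixture n generations ago leaves covariance between
SNP pairs that decays as exp(-n*d) with genetic distance d (Morgans).
Weighting each pair's covariance in the admixed target by the product of
reference allele-frequency differences isolates the admixture signal;
fitting A*exp(-n*d) + c to the binned curve dates the pulse.

The rescaling helpers convert a coalescent estimate of female effective
population size times generation time (years * individuals) into a
census-like number of individuals: divide by half the generation time
(equal male and female effective sizes), i.e. by 14.5 for a 29-year
generation, truncating the result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

logger = logging.getLogger(__name__)

DEFAULT_GENERATION_TIME = 29.0
#: ALDER-style defaults, in cM: discard short-range background LD below
#: min_dist; 0.05 cM bins out to 30 cM.
DEFAULT_BIN_WIDTH_CM = 0.05
DEFAULT_MIN_DIST_CM = 0.5
DEFAULT_MAX_DIST_CM = 30.0
MIN_PAIRS_PER_BIN = 100


class NoDecaySignalError(RuntimeError):
    """The binned curve carries no positive decaying component."""


@dataclass
class WeightedLDCurve:
    """Binned weighted-LD curve and (after fitting) its exponential fit."""

    bin_centers_cm: np.ndarray
    weighted_ld: np.ndarray      # NaN where a bin has too few pairs
    pair_counts: np.ndarray
    amplitude: float | None = None
    n_generations: float | None = None
    offset: float | None = None
    fit_rmse: float | None = None

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers_cm) <= 0):
            raise ValueError("bin centers must be strictly increasing")


@dataclass
class NeRescale:
    input_value: float        # female Ne x generation time (years*individuals)
    generation_time: float
    output: int               # individuals


# ---------------------------------------------------------------------------
# weighted LD


def weighted_ld_curve(
    target_genotypes: np.ndarray,
    ref1_freqs: np.ndarray,
    ref2_freqs: np.ndarray,
    genetic_positions: np.ndarray,
    bin_width_cm: float = DEFAULT_BIN_WIDTH_CM,
    min_dist_cm: float = DEFAULT_MIN_DIST_CM,
    max_dist_cm: float = DEFAULT_MAX_DIST_CM,
) -> WeightedLDCurve:
    """Bin SNP-pair covariances weighted by reference frequency contrasts.

    ``target_genotypes`` is (n_individuals, n_snps) without missing data
    (haplotypes coded 0/1 work too); ``genetic_positions`` are Morgans.
    For each SNP pair (i, j) the contribution is
    cov_target(i, j) * w_i * w_j with w = ref1_freqs - ref2_freqs; the
    curve is the per-bin mean.  Bins with fewer than 100 pairs report
    NaN.  Swapping the two references leaves the curve unchanged (the
    weights enter as a product).
    """
    X = np.asarray(target_genotypes, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("need at least 2 target samples")
    pos = np.asarray(genetic_positions, dtype=float)
    w = np.asarray(ref1_freqs, dtype=float) - np.asarray(ref2_freqs, dtype=float)
    if not (X.shape[1] == pos.size == w.size):
        raise ValueError("genotypes, frequencies and map sizes disagree")
    Xc = X - X.mean(axis=0)
    C = (Xc.T @ Xc) / (X.shape[0] - 1)
    P = C * np.outer(w, w)
    dist_cm = np.abs(pos[:, None] - pos[None, :]) * 100.0

    edges = np.arange(min_dist_cm, max_dist_cm + bin_width_cm, bin_width_cm)
    iu = np.triu_indices(pos.size, k=1)
    d = dist_cm[iu]
    v = P[iu]
    keep = (d >= min_dist_cm) & (d < edges[-1])
    which = np.digitize(d[keep], edges) - 1
    n_bins = edges.size - 1
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=v[keep], minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts >= MIN_PAIRS_PER_BIN, sums / np.maximum(counts, 1), np.nan)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return WeightedLDCurve(bin_centers_cm=centers, weighted_ld=means, pair_counts=counts)


def fit_exponential_decay(curve: WeightedLDCurve) -> tuple[float, float, float]:
    """Fit z(d) = A * exp(-n * d) + c to the binned curve (d in Morgans).

    Starting values come from a log-linear regression on the
    offset-corrected positive bins; the refined fit is nonlinear least
    squares.  Returns (A, n, c) and stores them on the curve.  Raises
    :class:`NoDecaySignalError` when no positive decaying amplitude
    exists (e.g. a constant curve).
    """
    ok = np.isfinite(curve.weighted_ld)
    if ok.sum() < 5:
        raise ValueError("need at least 5 non-missing bins")
    d = curve.bin_centers_cm[ok] / 100.0  # Morgans
    z = curve.weighted_ld[ok]
    c0 = float(np.mean(z[-max(3, z.size // 10):]))
    resid = z - c0
    pos = resid > 0
    # the near half of the curve must rise above the long-range offset
    if pos.sum() < 3 or not pos[: max(3, pos.size // 4)].any():
        raise NoDecaySignalError("no positive amplitude after offset correction")
    slope, intercept = np.polyfit(d[pos], np.log(resid[pos]), 1)
    n0 = max(-slope, 1e-3)
    A0 = float(np.exp(intercept))

    def model(x, A, n, c):
        return A * np.exp(-n * x) + c

    try:
        popt, _ = curve_fit(model, d, z, p0=[A0, n0, c0], maxfev=20_000)
    except RuntimeError as exc:  # pragma: no cover - pathological curves
        raise NoDecaySignalError(f"exponential fit failed: {exc}") from exc
    A, n, c = (float(x) for x in popt)
    if A <= 0 or n <= 0:
        raise NoDecaySignalError("fitted amplitude or rate is non-positive")
    curve.amplitude, curve.n_generations, curve.offset = A, n, c
    curve.fit_rmse = float(np.sqrt(np.mean((model(d, A, n, c) - z) ** 2)))
    return A, n, c


# ---------------------------------------------------------------------------
# generation/year conversion and Ne rescaling


def generations_to_years(n_generations: float,
                         generation_time: float = DEFAULT_GENERATION_TIME) -> float:
    if n_generations <= 0 or generation_time <= 0:
        raise ValueError("inputs must be positive")
    return n_generations * generation_time


def years_to_generations(years: float,
                         generation_time: float = DEFAULT_GENERATION_TIME) -> int:
    """Years to generations, rounded to the nearest integer
    (700 years at 29 years/generation -> 24 generations)."""
    if years <= 0 or generation_time <= 0:
        raise ValueError("inputs must be positive")
    return int(round(years / generation_time))


def rescale_ne(ne_female_times_gentime: float,
               generation_time: float = DEFAULT_GENERATION_TIME) -> NeRescale:
    """Rescale female-Ne-times-generation-time to individuals.

    With equal male and female effective sizes the total is twice the
    female size, so the divisor is generation_time / 2 (14.5 for a
    29-year generation); the quotient is rounded to the nearest
    individual (1,625,187 / 14.5 = 112,081.86 -> 112,082).
    """
    if generation_time <= 0:
        raise ValueError("generation_time must be positive")
    if ne_female_times_gentime < 0:
        raise ValueError("input must be non-negative")
    out = int(round(ne_female_times_gentime / (generation_time / 2.0)))
    return NeRescale(
        input_value=float(ne_female_times_gentime),
        generation_time=float(generation_time),
        output=out,
    )
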