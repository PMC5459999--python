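"""f-statistics: brute-force oracle equivalence, algebraic identities,
scans, ancestry proportions and PCA projection."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, strategies as st

from nile.containers import MISSING
from nile import fstats
from nile.synthetic import AdmixtureGraphSpec, simulate_graph_dataset

from conftest import make_dataset, random_dataset


# ---------------------------------------------------------------------------
# naive reference implementation (double loops, no vectorisation)


def naive_freq(dataset, pop):
    """Alt-allele frequency and allele count per SNP, one loop at a time."""
    idx = [i for i, p in enumerate(dataset.ind["population"]) if p == pop]
    ph = list(dataset.ind["pseudo_haploid"])
    freqs, counts = [], []
    for s in range(dataset.n_snps):
        alt = 0.0
        total = 0
        for i in idx:
            g = dataset.geno[s, i]
            if g == MISSING:
                continue
            if ph[i]:
                alt += (2 - g) / 2
                total += 1
            else:
                alt += 2 - g
                total += 2
        freqs.append(alt / total if total else np.nan)
        counts.append(total)
    return np.array(freqs), np.array(counts)


def _h(x, n):
    return x * (1 - x) / (n - 1) if n >= 2 else 0.0


def naive_f2(dataset, A, B):
    a, na = naive_freq(dataset, A)
    b, nb = naive_freq(dataset, B)
    terms = [
        (a[s] - b[s]) ** 2 - _h(a[s], na[s]) - _h(b[s], nb[s])
        for s in range(dataset.n_snps)
        if na[s] > 0 and nb[s] > 0
    ]
    return float(np.mean(terms))


def naive_f3(dataset, C, A, B):
    c, nc = naive_freq(dataset, C)
    a, na = naive_freq(dataset, A)
    b, nb = naive_freq(dataset, B)
    terms = [
        (c[s] - a[s]) * (c[s] - b[s]) - _h(c[s], nc[s])
        for s in range(dataset.n_snps)
        if na[s] > 0 and nb[s] > 0 and nc[s] > 0
    ]
    return float(np.mean(terms))


def naive_f4(dataset, A, B, C, D):
    a, na = naive_freq(dataset, A)
    b, nb = naive_freq(dataset, B)
    c, nc = naive_freq(dataset, C)
    d, nd = naive_freq(dataset, D)
    terms = [
        (a[s] - b[s]) * (c[s] - d[s])
        for s in range(dataset.n_snps)
        if min(na[s], nb[s], nc[s], nd[s]) > 0
    ]
    return float(np.mean(terms))


# ---------------------------------------------------------------------------
# oracle equivalence and identities


@pytest.mark.parametrize("seed", range(8))
def test_fstats_match_bruteforce_oracle(seed):
    ds = random_dataset(seed, n_snps=10, pops={"A": 2, "B": 2, "C": 1, "D": 1},
                        pseudo_haploid_pops={"C"})
    assert fstats.f2(ds, "A", "B").estimate == pytest.approx(naive_f2(ds, "A", "B"), abs=1e-12)
    assert fstats.f3(ds, "C", "A", "B").estimate == pytest.approx(
        naive_f3(ds, "C", "A", "B"), abs=1e-12)
    assert fstats.f4(ds, "A", "B", "C", "D").estimate == pytest.approx(
        naive_f4(ds, "A", "B", "C", "D"), abs=1e-12)


@given(st.integers(0, 500))
def test_f4_antisymmetry_and_exchange(seed):
    ds = random_dataset(seed, n_snps=6, pops={"A": 2, "B": 1, "C": 2, "D": 1})
    abcd = fstats.f4(ds, "A", "B", "C", "D").estimate
    assert fstats.f4(ds, "B", "A", "C", "D").estimate == pytest.approx(-abcd, abs=1e-14)
    assert fstats.f4(ds, "A", "B", "D", "C").estimate == pytest.approx(-abcd, abs=1e-14)
    assert fstats.f4(ds, "C", "D", "A", "B").estimate == pytest.approx(abcd, abs=1e-14)


@given(st.integers(0, 500))
def test_f3_decomposes_into_f2_terms(seed):
    # f3(C;A,B) = [f2(A,C) + f2(B,C) - f2(A,B)] / 2; the heterozygosity
    # corrections cancel exactly, so this holds with complete data
    ds = random_dataset(seed, n_snps=6, pops={"A": 2, "B": 2, "C": 2}, missing_rate=0.0)
    lhs = fstats.f3(ds, "C", "A", "B").estimate
    rhs = (
        fstats.f2(ds, "A", "C").estimate
        + fstats.f2(ds, "B", "C").estimate
        - fstats.f2(ds, "A", "B").estimate
    ) / 2
    assert lhs == pytest.approx(rhs, abs=1e-13)


def test_f2_same_population_is_exactly_zero_and_flagged():
    ds = random_dataset(1, pops={"A": 3, "B": 2})
    r = fstats.f2(ds, "A", "A")
    assert r.estimate == 0.0 and r.se == 0.0
    assert "identical_populations" in r.flags


def test_f4_fixed_frequencies_give_unit_value():
    # a=1, b=0, c=1, d=0 at every SNP: f4 = 1 exactly (no corrections)
    geno = np.column_stack([[0, 0], [2, 2], [0, 0], [2, 2]] * 2).reshape(2, -1)
    geno = np.tile([[0, 2, 0, 2]], (5, 1))
    ds = make_dataset(geno, ["A", "B", "C", "D"])
    assert fstats.f4(ds, "A", "B", "C", "D").estimate == 1.0


def test_f3_forced_value_at_large_sample_size():
    # a=1, b=0, c=0.5 fixed -> f3(C;A,B) -> (0.5-1)(0.5-0) = -0.25 as n grows
    n = 400
    geno = np.tile(
        np.concatenate([np.zeros(n), np.full(n, 2), np.tile([0, 2], n // 2)]),
        (6, 1),
    ).astype(np.int8)
    pops = ["A"] * n + ["B"] * n + ["C"] * n
    ds = make_dataset(geno, pops)
    assert fstats.f3(ds, "C", "A", "B").estimate == pytest.approx(-0.25, abs=1e-3)


def test_het_correction_skipped_flag_for_single_allele_population():
    # a pseudo-haploid singleton contributes one allele: n - 1 = 0
    ds = random_dataset(3, pops={"A": 2, "B": 2, "C": 1}, missing_rate=0.0,
                        pseudo_haploid_pops={"C"})
    r = fstats.f3(ds, "C", "A", "B")
    assert "het_correction_skipped" in r.flags


# ---------------------------------------------------------------------------
# jackknife behaviour


def test_jackknife_constant_blocks_give_zero_se():
    # identical per-SNP terms in every block -> SE exactly 0
    geno = np.tile([[0, 2]], (100, 1))
    ds = make_dataset(geno, ["A", "B"])
    r = fstats.f2(ds, "A", "B", n_blocks=10)
    assert r.se == 0.0 and r.n_blocks == 10


def test_jackknife_se_shrinks_with_snps():
    big = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=20_000, alpha=0.5, drift=0.05, seed=5,
                           sample_sizes={p: 10 for p in "OABCX"}))
    small = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=2_000, alpha=0.5, drift=0.05, seed=5,
                           sample_sizes={p: 10 for p in "OABCX"}))
    assert fstats.f2(big, "A", "C").se < fstats.f2(small, "A", "C").se


# ---------------------------------------------------------------------------
# scans


def test_outgroup_f3_scan_ranks_focal_duplicate_first():
    ds = random_dataset(7, n_snps=40, pops={"O": 3, "F": 3, "X1": 3, "X2": 3},
                        missing_rate=0.0)
    results = fstats.outgroup_f3_scan(ds, "O", "F", ["X1", "F", "X2"])
    assert results[0].pops[2] == "F"  # maximal shared drift with itself


def test_outgroup_f3_scan_prefers_sister_population():
    # A shares the internal branch with B; O2 branches off the root
    ds = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=20_000, alpha=1.0, drift=0.05, seed=9,
                           extra_outgroups=1,
                           sample_sizes={p: 10 for p in ["O", "A", "B", "C", "X", "O2"]}))
    results = fstats.outgroup_f3_scan(ds, "O", "B", ["A", "O2"])
    assert [r.pops[2] for r in results] == ["A", "O2"]


def test_outgroup_f3_scan_empty_candidates():
    ds = random_dataset(7, pops={"O": 2, "F": 2})
    assert fstats.outgroup_f3_scan(ds, "O", "F", []) == []


def test_admixture_f3_negative_for_mixed_target():
    ds = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=30_000, alpha=0.5, drift=0.05, seed=13,
                           sample_sizes={p: 20 for p in "OABCX"}))
    r = fstats.f3(ds, "X", "B", "C")
    assert r.estimate < 0 and r.z < -3


def test_admixture_f3_nonnegative_for_unadmixed_target():
    # target drawn from the same frequencies as source B (alpha = 1)
    ds = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=30_000, alpha=1.0, drift=0.05, seed=17,
                           sample_sizes={p: 20 for p in "OABCX"}))
    r = fstats.f3(ds, "X", "B", "C")
    assert r.estimate > -3 * r.se


def test_admixture_scan_orders_by_z():
    ds = random_dataset(21, n_snps=60, pops={"T": 3, "S": 3, "X1": 3, "X2": 3},
                        missing_rate=0.0)
    results = fstats.admixture_f3_scan(ds, "T", "S", ["X1", "X2"])
    zs = [r.z for r in results]
    assert zs == sorted(zs)


# ---------------------------------------------------------------------------
# ancestry proportions


def _with_copied_population(ds, source, new_name):
    idx = ds.pop_indices(source)
    geno = np.concatenate([ds.geno, ds.geno[:, idx]], axis=1)
    extra = ds.ind.iloc[idx].copy()
    extra["population"] = new_name
    extra["sample_id"] = [f"{new_name}_{i}" for i in range(len(idx))]
    import pandas as pd

    ind = pd.concat([ds.ind, extra], ignore_index=True)
    return make_dataset(geno, list(ind["population"]),
                        pseudo_haploid=list(ind["pseudo_haploid"]))


def test_f4_ratio_boundaries():
    ds = random_dataset(5, n_snps=50, pops={"A": 3, "O": 3, "B": 3, "C": 3},
                        missing_rate=0.0)
    as_b = _with_copied_population(ds, "B", "XB")
    assert fstats.f4_ratio(as_b, "A", "O", "XB", "B", "C").alpha == pytest.approx(1.0, abs=1e-12)
    as_c = _with_copied_population(ds, "C", "XC")
    assert fstats.f4_ratio(as_c, "A", "O", "XC", "B", "C").alpha == pytest.approx(0.0, abs=1e-12)


def test_f4_ratio_weak_denominator_flagged():
    # B and C drawn from the same frequencies -> denominator ~ 0
    ds = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=5_000, alpha=0.5, drift={"internal": 0.0, "A": 0.05,
                                                           "B": 0.0, "C": 0.0, "O": 0.05},
                           seed=3, sample_sizes={p: 10 for p in "OABCX"}))
    r = fstats.f4_ratio(ds, "A", "O", "X", "B", "C")
    assert "weak_denominator" in r.flags


def test_lsq_weights_for_target_equal_to_source():
    ds = random_dataset(11, n_snps=60, pops={"B": 3, "C": 3, "O": 3, "A": 3,
                                             "R1": 3, "R2": 3}, missing_rate=0.0)
    ds2 = _with_copied_population(ds, "B", "T")
    r = fstats.lsq_admixture_weights(ds2, "T", ["B", "C"], ["A", "R1", "R2"], "O")
    assert r.weights == pytest.approx([1.0, 0.0], abs=1e-9)
    assert sum(r.weights) == pytest.approx(1.0)


def test_lsq_collinear_sources_error_names_pair():
    ds = random_dataset(19, n_snps=60, pops={"B": 3, "C": 3, "O": 3, "A": 3,
                                             "R1": 3, "R2": 3}, missing_rate=0.0)
    ds2 = _with_copied_population(ds, "B", "Bcopy")
    with pytest.raises(ValueError, match="B and Bcopy"):
        fstats.lsq_admixture_weights(ds2, "C", ["B", "Bcopy"], ["A", "R1", "R2"], "O")


def test_lsq_poor_fit_flag_for_unrelated_target():
    # single source unrelated to the target: residuals blow up
    ds = simulate_graph_dataset(
        AdmixtureGraphSpec(n_snps=20_000, alpha=0.0, drift=0.1, seed=23,
                           extra_outgroups=2,
                           sample_sizes={p: 15 for p in ["O", "A", "B", "C", "X", "O2", "O3"]}))
    r = fstats.lsq_admixture_weights(ds, "X", ["A"], ["B", "O2", "O3"], "O")
    assert "poor_fit" in r.flags and r.residual_norm > 10


def test_lsq_needs_two_rights_beyond_base():
    ds = random_dataset(2, pops={"B": 2, "C": 2, "O": 2, "A": 2})
    with pytest.raises(ValueError, match="right"):
        fstats.lsq_admixture_weights(ds, "C", ["B"], ["A", "O"], "O")


# ---------------------------------------------------------------------------
# PCA with projection


def test_pca_projection_of_duplicate_individual_matches_reference_twin():
    rng = np.random.default_rng(31)
    geno = rng.integers(0, 3, size=(200, 12)).astype(np.int8)
    geno = np.concatenate([geno, geno[:, :1]], axis=1)  # copy of ind0 as "ANC"
    pops = ["P1"] * 6 + ["P2"] * 6 + ["ANC"]
    ds = make_dataset(geno, pops)
    coords = fstats.pca_with_projection(ds, ["P1", "P2"], ["ind12"], n_components=2)
    ref_row = coords[coords["sample_id"] == "ind0"]
    proj_row = coords[coords["sample_id"] == "ind12"]
    assert proj_row["projected"].item()
    for pc in ("PC1", "PC2"):
        assert proj_row[pc].item() == pytest.approx(ref_row[pc].item(), abs=1e-8)


def test_pca_separates_populations_and_orders_admixed_by_alpha():
    sizes = {p: 25 for p in "OABCX"}
    coords_by_alpha = {}
    for alpha in (0.1, 0.5, 0.9):
        ds = simulate_graph_dataset(
            AdmixtureGraphSpec(n_snps=4_000, alpha=alpha, drift=0.2, seed=41,
                               sample_sizes=sizes))
        proj = [s for s in ds.ind["sample_id"] if s.startswith("X_")]
        coords = fstats.pca_with_projection(ds, ["B", "C"], proj, n_components=2)
        b = coords.loc[coords["population"] == "B", "PC1"].mean()
        c = coords.loc[coords["population"] == "C", "PC1"].mean()
        x = coords.loc[coords["population"] == "X", "PC1"].mean()
        # references separate on PC1; admixed target falls between
        assert abs(b - c) > 2 * coords.loc[coords["population"] == "B", "PC1"].std()
        coords_by_alpha[alpha] = (x - c) / (b - c)
    assert coords_by_alpha[0.1] < coords_by_alpha[0.5] < coords_by_alpha[0.9]


def test_pca_rank_error():
    ds = random_dataset(3, n_snps=30, pops={"P": 3}, missing_rate=0.0)
    with pytest.raises(ValueError, match="rank"):
        fstats.pca_with_projection(ds, ["P"], n_components=5)
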