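"""Shared fixtures and helpers for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from nile.containers import GenotypeDataset

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")


def make_dataset(
    geno: np.ndarray,
    populations: list[str],
    pseudo_haploid: list[bool] | None = None,
    sex: list[str] | None = None,
) -> GenotypeDataset:
    """Build a GenotypeDataset from a (n_snps, n_ind) code matrix."""
    geno = np.asarray(geno, dtype=np.int8)
    n_snps, n_ind = geno.shape
    assert len(populations) == n_ind
    snp = pd.DataFrame(
        {
            "snp_id": [f"rs{i}" for i in range(n_snps)],
            "chrom": "1",
            "gpos": np.arange(n_snps) * 1e-6,
            "ppos": np.arange(1, n_snps + 1) * 100,
            "ref": "A",
            "alt": "G",
        }
    )
    ind = pd.DataFrame(
        {
            "sample_id": [f"ind{i}" for i in range(n_ind)],
            "sex": sex if sex is not None else ["U"] * n_ind,
            "population": populations,
            "pseudo_haploid": pseudo_haploid if pseudo_haploid is not None else [False] * n_ind,
        }
    )
    return GenotypeDataset(geno=geno, snp=snp, ind=ind)


def random_dataset(
    seed: int,
    n_snps: int = 8,
    pops: dict[str, int] | None = None,
    missing_rate: float = 0.1,
    pseudo_haploid_pops: set[str] = frozenset(),
) -> GenotypeDataset:
    """Random small dataset with missingness, for oracle comparisons."""
    pops = pops or {"A": 2, "B": 2, "C": 1, "D": 2}
    rng = np.random.default_rng(seed)
    cols, labels, ph = [], [], []
    for pop, n in pops.items():
        is_ph = pop in pseudo_haploid_pops
        for _ in range(n):
            if is_ph:
                g = 2 * rng.integers(0, 2, size=n_snps)
            else:
                g = rng.integers(0, 3, size=n_snps)
            g[rng.random(n_snps) < missing_rate] = 9
            cols.append(g)
            labels.append(pop)
            ph.append(is_ph)
    return make_dataset(np.column_stack(cols), labels, pseudo_haploid=ph)


@pytest.fixture
def qc_metadata() -> pd.DataFrame:
    """Mixed metadata table exercising both QC cascades."""
    rows = [
        # sample, tissue, period, cov, contam, damage, sex, xsnps
        ("ok1", "bone", "roman", 25.0, 0.01, 0.10, "male", 300),
        ("ok2", "tooth", "ptolemaic", 10.5, 0.029, 0.08, "male", 150),
        ("lowcov", "bone", "roman", 10.0, 0.01, 0.10, "male", 300),
        ("highcont", "bone", "roman", 25.0, 0.03, 0.10, "male", 300),
        ("female", "tooth", "roman", 25.0, 0.01, 0.10, "female", 300),
        ("lowdam", "bone", "roman", 25.0, 0.01, 0.079, "male", 300),
        ("fewx", "bone", "roman", 25.0, 0.01, 0.10, "male", 149),
        ("nometa", "bone", "roman", np.nan, 0.01, np.nan, "male", 300),
    ]
    return pd.DataFrame(
        rows,
        columns=[
            "sample_id", "tissue", "period", "mt_coverage", "mt_contamination",
            "damage_5p", "sex", "x_snps_covered_twice",
        ],
    )
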