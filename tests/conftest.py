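"""Shared fixtures: small simulated cohorts and random-variant helpers."""

from __future__ import annotations

import numpy as np
import pytest

from mutchemo import simdata, varfilter


SMALL_CONFIG = simdata.SimConfig(
    seed=11,
    n_chromosomes=1,
    chrom_length=300_000,
    n_genes=8,
    min_gene_gap=15_000,
    n_lines=3,
    background_snvs_per_line=25.0,
)


@pytest.fixture(scope="session")
def small_cohort() -> simdata.Cohort:
    """A desk-scale cohort: 1 x 300 kb chromosome, 8 genes, 3 lines."""
    return simdata.simulate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_cohort() -> simdata.Cohort:
    """One cohort at the full default study conditions (10-Mb genome)."""
    return simdata.simulate_cohort(simdata.SimConfig(seed=0))


def random_variants(
    rng: np.random.Generator,
    n: int,
    chrom: str = "chr1",
    chrom_length: int = 100_000,
    line_id: str = "line",
) -> list[varfilter.Variant]:
    """Uniform random SNVs of every substitution class, mixed genotypes."""
    out = []
    bases = "ACGT"
    for _ in range(n):
        ref = bases[rng.integers(4)]
        alt = bases[rng.integers(4)]
        while alt == ref:
            alt = bases[rng.integers(4)]
        out.append(
            varfilter.Variant(
                chrom=chrom,
                pos=int(rng.integers(1, chrom_length + 1)),
                ref=ref,
                alt=alt,
                genotype=varfilter.HOM_ALT if rng.random() < 0.8 else varfilter.HET,
                depth=int(rng.integers(1, 60)) if rng.random() < 0.7 else None,
                line_id=line_id,
            )
        )
    return out
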