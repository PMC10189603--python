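"""Shared fixtures: all test data is generated programmatically."""
from __future__ import annotations

import numpy as np
import pytest

from rookery.genotypes import GenotypeTable
from rookery.simulate import (
    ErrorModel,
    RookeryDesign,
    simulate_panel,
    simulate_rookery,
)


@pytest.fixture(scope="session")
def panel135():
    """Default-condition marker panel: 135 loci, mean ~2.61 alleles."""
    return simulate_panel(135, seed=11)


@pytest.fixture(scope="session")
def panel30():
    return simulate_panel(30, seed=12)


@pytest.fixture(scope="session")
def rookery_small():
    """A compact rookery (100 loci, modest clutches) with default errors."""
    design = RookeryDesign(clutch_size_range=(8, 15))
    return simulate_rookery(design, n_loci=100, fst=0.04, seed=42, replicate_fraction=0.0)


@pytest.fixture(scope="session")
def rookery_clean():
    """Error-free rookery: observed genotypes equal truth."""
    design = RookeryDesign(clutch_size_range=(5, 10))
    return simulate_rookery(
        design,
        n_loci=40,
        fst=0.0,
        error=ErrorModel(0.0, 0.0, 0.0, 0.02),
        seed=7,
        view_noise=0.0,
        noise_alleles=False,
    )


def make_table(codes, loci=None, alleles=None, prefix="I"):
    """Small helper to build a GenotypeTable from a raw code array."""
    codes = np.asarray(codes, dtype=np.int16)
    n, m = codes.shape[:2]
    loci = loci or [f"L{j + 1}" for j in range(m)]
    if alleles is None:
        alleles = {l: [chr(65 + a) for a in range(max(int(codes[:, j].max()) + 1, 2))]
                   for j, l in enumerate(loci)}
    inds = [f"{prefix}{i + 1}" for i in range(n)]
    return GenotypeTable(codes, inds, loci, alleles)
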