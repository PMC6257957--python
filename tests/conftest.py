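"""Shared fixtures: small planted-truth datasets and helper constructors.

Everything is generated at test time from seeds; heavyweight products
(balanced maps, pipeline bundles) are session-scoped so multiple tests
share one computation.
"""

from __future__ import annotations

import numpy as np
import pytest

from hicsqueeze import GenomeBinning, make_truth, simulate_map
from hicsqueeze.matrix import BalancedMap, ContactMap, ice_balance
from hicsqueeze.synth import TruthConfig


@pytest.fixture(scope="session")
def truth():
    """Default study-condition truth (2 x 30 Mb, seed 1)."""
    return make_truth(seed=1)


@pytest.fixture(scope="session")
def maps_100kb(truth):
    return {cond: simulate_map(truth, cond, 3_000_000, seed=i, binsize=100_000)
            for i, cond in enumerate(("baseline", "constricted"))}


@pytest.fixture(scope="session")
def balanced_100kb(maps_100kb):
    return {cond: ice_balance(m) for cond, m in maps_100kb.items()}


@pytest.fixture(scope="session")
def small_truth():
    """Smaller single-purpose genome for cheap unit tests."""
    cfg = TruthConfig(chrom_lengths=(("chr1", 12_000_000), ("chr2", 12_000_000)),
                      n_genes=2_000, set_sizes=(40, 80, 30))
    return make_truth(cfg, seed=7)


def bal_from_dense(binning: GenomeBinning, dense: dict[str, np.ndarray]) -> BalancedMap:
    """A BalancedMap with unit biases around a given dense matrix."""
    cmap = ContactMap.from_dense(binning, dense)
    biases = {c: np.ones(binning.n_bins(c)) for c in dense}
    mask = {c: np.zeros(binning.n_bins(c), dtype=bool) for c in dense}
    return BalancedMap(cmap, biases, mask,
                       {c: True for c in dense}, {c: 0 for c in dense})


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
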