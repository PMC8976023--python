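"""Shared fixtures: one simulated, balanced desk-scale dataset per session."""

import warnings

import numpy as np
import pytest

from archcomp import (
    SimParams,
    ice_balance,
    expected_by_distance,
    observed_over_expected,
    simulate_architecture,
    simulate_contact_map,
)
from archcomp.compartments import compartment_eigenvector, gene_density_track

warnings.filterwarnings("ignore", message=".*lacks a full flank.*")


@pytest.fixture(scope="session")
def default_truth():
    """Architecture with the default planted structure (gamma=1.4, tau=1.5)."""
    return simulate_architecture(SimParams(seed=1))


@pytest.fixture(scope="session")
def balanced_map(default_truth):
    m = simulate_contact_map(default_truth, 1, seed=11)
    ice_balance(m)
    return m


@pytest.fixture(scope="session")
def oe_default(balanced_map):
    profile = expected_by_distance(balanced_map)
    return observed_over_expected(balanced_map, profile)


@pytest.fixture(scope="session")
def track_default(default_truth, oe_default):
    density = gene_density_track(default_truth.genes, default_truth.binning)
    return compartment_eigenvector(oe_default, density)


def bins_covered(binning, intervals):
    """Boolean per-bin indicator of interval coverage (test helper)."""
    out = np.zeros(binning.n_bins, dtype=bool)
    for iv in intervals:
        lo, _ = binning.chrom_bin_range(iv.chrom)
        a = lo + iv.start // binning.bin_size
        b = lo + -(-iv.end // binning.bin_size)
        out[a:b] = True
    return out
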