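import numpy as np
import pytest

from omescan import (MarkerMatrix, TraitVector, compute_kinships,
                     simulate_ril_genotypes, simulate_trait)


@pytest.fixture(scope="session")
def small_panel():
    """30-marker, 20-individual RIL-like panel with LD blocks."""
    return simulate_ril_genotypes(n=20, m=30, n_chrom=3, switch_prob=0.2,
                                  seed=42)


@pytest.fixture(scope="session")
def small_kinships(small_panel):
    return compute_kinships(small_panel)


@pytest.fixture(scope="session")
def small_trait(small_panel):
    y, _ = simulate_trait(small_panel, 0.4, 0.3, 0.3, seed=7)
    return y


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def random_marker_matrix(rng, m, n, values=None):
    vals = rng.normal(size=(m, n)) if values is None else values
    return MarkerMatrix(vals, [f"m{i}" for i in range(m)],
                        [f"s{j}" for j in range(n)])


def random_trait(rng, n):
    return TraitVector(rng.normal(size=n), [f"s{j}" for j in range(n)], "t")
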