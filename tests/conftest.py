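import numpy as np
import pytest

from popband import (BandMatrix, SyntheticBarcodeConfig, SyntheticPopGenConfig,
                     simulate_band_matrix, simulate_barcode_alignment)


@pytest.fixture(scope="session")
def study_matrix():
    """Synthetic study-shaped matrix: 4 populations 30/30/30/20, 81 loci."""
    m, truth = simulate_band_matrix(SyntheticPopGenConfig(seed=11))
    return m, truth


@pytest.fixture(scope="session")
def study_alignment():
    """Synthetic two-species alignment: 697 bp core, 32 diagnostic, 17 gap cols."""
    return simulate_barcode_alignment(SyntheticBarcodeConfig(seed=7))


@pytest.fixture
def tiny_matrix():
    """Deterministic 6-sample, 4-locus matrix over two populations."""
    vals = np.array([
        [1, 0, 1, 1],
        [1, 1, 1, 0],
        [0, 0, 1, 1],
        [0, 1, 0, 0],
        [0, 1, 0, 1],
        [1, 1, 0, 0],
    ])
    return BandMatrix(
        tuple(f"s{i}" for i in range(6)),
        ("A", "A", "A", "B", "B", "B"),
        ("l1", "l2", "l3", "l4"),
        vals,
        primer_of_locus={"l1": "p1", "l2": "p1", "l3": "p2", "l4": "p2"},
    )


def random_band_matrix(rng, n=8, L=6, k=2):
    """Helper for randomized oracle tests: k equal-ish populations."""
    vals = rng.integers(0, 2, size=(n, L))
    labels = tuple(f"P{i % k}" for i in range(n))
    return BandMatrix(tuple(f"s{i}" for i in range(n)), labels,
                      tuple(f"l{j}" for j in range(L)), vals)
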