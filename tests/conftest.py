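import numpy as np
import pytest

from spotdecon.io import AnnotatedCounts, cpm_normalize
from spotdecon.reference import build_signature, select_markers
from spotdecon.simulation import synthetic_reference


@pytest.fixture(scope="session")
def reference_counts() -> AnnotatedCounts:
    """Synthetic annotated scRNA reference: 5 types x 40 cells, 200 genes."""
    return synthetic_reference(
        T=5, cells_per_type=40, n_genes=200, markers_per_type=40, seed=13
    )


@pytest.fixture(scope="session")
def reference_cpm(reference_counts):
    return cpm_normalize(reference_counts)


@pytest.fixture(scope="session")
def marker_genes(reference_cpm):
    _, markers = select_markers(reference_cpm)
    return markers


@pytest.fixture(scope="session")
def signature(reference_counts, marker_genes):
    return build_signature(reference_counts, marker_genes)


@pytest.fixture(scope="session")
def signature_full(reference_counts):
    return build_signature(reference_counts)


def random_simplex(rng: np.random.Generator, T: int) -> np.ndarray:
    return rng.dirichlet(np.ones(T))
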