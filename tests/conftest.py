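import numpy as np
import pandas as pd
import pytest

from tomoseq import CountMatrix, TissueDesign, simulate_tissue


@pytest.fixture
def small_matrix() -> CountMatrix:
    """3 genes x 2 sections with one mitochondrial and one spike-in gene."""
    counts = pd.DataFrame(
        [[10, 5], [30, 0], [2, 1]],
        index=["TTN", "MT-ND1", "ERCC-00001"],
        columns=["S1", "S2"],
    )
    return CountMatrix(counts)


@pytest.fixture(scope="session")
def default_sim():
    """One default synthetic tissue (173 sections, 5 domains), reused."""
    return simulate_tissue(TissueDesign(seed=11))


def random_count_matrix(rng: np.random.Generator, n_genes=12, n_sections=8,
                        high=60, n_mito=2, n_spike=2) -> CountMatrix:
    """Small random matrix with mito and spike-in rows, for oracle tests."""
    names = (
        [f"G{i}" for i in range(n_genes - n_mito - n_spike)]
        + [f"MT-{i}" for i in range(n_mito)]
        + [f"ERCC-{i:05d}" for i in range(n_spike)]
    )
    counts = pd.DataFrame(
        rng.integers(0, high, size=(n_genes, n_sections)),
        index=names,
        columns=[f"S{j+1:02d}" for j in range(n_sections)],
    )
    return CountMatrix(counts)
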