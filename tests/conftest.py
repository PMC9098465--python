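import numpy as np
import pytest

from maltpred import (
    SimulationConfig,
    build_similarity,
    preprocess_pipeline,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def small_dataset():
    """80 plots (20 lines x 2 locations x 2 reps), 800 bins, full noise."""
    return simulate_dataset(
        SimulationConfig(n_lines=20, n_bins=800, replicates_per_line=2, seed=1)
    )


@pytest.fixture(scope="session")
def small_standardized(small_dataset):
    Q, report = preprocess_pipeline(small_dataset.spectra)
    return Q, report


@pytest.fixture(scope="session")
def small_kernel(small_standardized):
    return build_similarity(small_standardized[0])


@pytest.fixture(scope="session")
def medium_dataset():
    """600 plots (150 lines x 2 x 2), single trait with target RVCm 0.95."""
    return simulate_dataset(
        SimulationConfig(
            n_lines=150,
            n_bins=800,
            replicates_per_line=2,
            seed=3,
            target_rvc={"Y": 0.95},
            trait_means={"Y": 10.0},
            trait_sds={"Y": 2.0},
        )
    )


@pytest.fixture(scope="session")
def medium_pipeline(medium_dataset):
    Q, _ = preprocess_pipeline(medium_dataset.spectra)
    K = build_similarity(Q)
    y = medium_dataset.phenotypes.set_index("plot_id")["Y"]
    return Q, K, y


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def standardized_matrix(rng, n, m):
    """Random divisor-n standardized matrix wrapped as a StandardizedMatrix."""
    from maltpred import SpectraMatrix, standardize

    X = rng.normal(size=(n, m))
    ppm = np.linspace(1.0, 2.0, m)
    ids = [f"S{i:03d}" for i in range(n)]
    return standardize(SpectraMatrix(ids, ppm, X))
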