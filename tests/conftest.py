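import numpy as np
import pytest

import slamkin as sk


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def steady_course():
    """Steady-state progressive labeling simulation shared across tests.

    300 genes, single replicates at 1/2/4/8 h, 2000 reads per gene: small
    enough to simulate in seconds, deep enough for informative NTR posteriors.
    """
    config = sk.ProgressiveConfig(
        n_genes=300, times=(1.0, 2.0, 4.0, 8.0), replicates=1,
        reads_per_gene=2000.0, dispersion=0.005, seed=42,
    )
    data, truth = sk.simulate_experiment(config)
    return config, data, truth


@pytest.fixture(scope="session")
def tiny_experiment():
    """Hand-built 4-gene, 3-sample experiment for data-model tests."""
    designs = [
        sk.SampleDesign("mock.no4sU.A", condition="mock", is_no4sU=True),
        sk.SampleDesign("mock.2h.A", condition="mock", labeling_time_nominal=2.0,
                        replicate="A"),
        sk.SampleDesign("mock.2h.B", condition="mock", labeling_time_nominal=2.0,
                        replicate="B"),
    ]
    counts = np.array([
        [100.0, 110.0, 90.0],
        [10.0, 12.0, 8.0],
        [1000.0, 900.0, 1100.0],
        [50.0, 55.0, 45.0],
    ])
    nan = np.nan
    ntr = np.array([
        [nan, 0.2, 0.25],
        [nan, 0.8, 0.75],
        [nan, 0.05, 0.06],
        [nan, 0.5, 0.45],
    ])
    data = sk.ExperimentData(
        ["g1", "g2", "g3", "g4"], designs,
        {"count": counts, "ntr": ntr},
    )
    return data
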