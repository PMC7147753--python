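import numpy as np
import pandas as pd
import pytest

from trcascade.dataset import ExpressionDataset
from trcascade.network import RegulatoryNetwork
from trcascade.synthetic import PlantedDesign, generate_planted


def make_dataset(values, samples=None, times=None, reps=None, genes=None):
    """Small ExpressionDataset helper for hand-written matrices."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    genes = genes or [f"G{i}" for i in range(n_genes)]
    if samples is None:
        samples = [f"T{t}" for t in range(n_samples)]
    if times is None:
        times = list(range(n_samples))
    if reps is None:
        reps = [0] * n_samples
    t_sorted = sorted(set(times))
    design = pd.DataFrame(
        {
            "time": [float(t) for t in times],
            "time_index": [t_sorted.index(t) for t in times],
            "replicate": reps,
        },
        index=pd.Index(samples, name="sample"),
    )
    vdf = pd.DataFrame(values, index=pd.Index(genes, name="gene"), columns=samples)
    return ExpressionDataset(vdf, design)


@pytest.fixture
def small_dataset():
    """3 genes x 4 time points, single replicate."""
    return make_dataset(
        [[0, 100, 0, 0], [5, 5, 5, 5], [1, 9, 2, 0]],
        genes=["PEAKY", "FLAT", "NOISY"],
    )


@pytest.fixture
def toy_network():
    return RegulatoryNetwork.from_edge_list(
        [("A", "B"), ("B", "C"), ("A", "A"), ("C", "D")]
    )


@pytest.fixture(scope="session")
def noiseless_fixture():
    return generate_planted(PlantedDesign(noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_fixture():
    return generate_planted(PlantedDesign(seed=11))
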