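import numpy as np
import pytest

from epitarget import SynthSpec, generate_dataset, smiles_to_graph


@pytest.fixture(scope="session")
def small_dataset():
    """300 molecules, 5 planted motifs, noise-free labels."""
    records, registry = generate_dataset(
        SynthSpec(n_molecules=300, label_noise=0.0, seed=7)
    )
    return records, registry


@pytest.fixture(scope="session")
def small_graphs(small_dataset):
    records, _ = small_dataset
    return [smiles_to_graph(r.smiles) for r in records]


@pytest.fixture(scope="session")
def small_labels(small_dataset):
    records, _ = small_dataset
    return {
        t: np.array([1 if r.labels[t] == "active" else 0 for r in records])
        for t in ("T1", "T2")
    }


@pytest.fixture(scope="session")
def planted_study():
    """The full-scale study conditions: 1000 molecules, 5 targets, 10% noise."""
    records, registry = generate_dataset(
        SynthSpec(n_molecules=1000, label_noise=0.1, seed=0)
    )
    graphs = {r.compound_id: smiles_to_graph(r.smiles) for r in records}
    return records, registry, graphs
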