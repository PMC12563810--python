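import numpy as np
import pytest

from lofdti.chem_io import pad_batch, smiles_to_graph
from lofdti.model import ModelConfig
from lofdti.synthetic_data import SyntheticSpec, generate_dataset


@pytest.fixture(scope="session")
def fast_config() -> ModelConfig:
    """Small, fast training profile used throughout the suite."""
    return ModelConfig(
        drug_dim=32, protein_dim=32, hidden_dim=32, kmer_dim=32,
        n_heads=2, n_gin_layers=2, n_residual_blocks=1,
        max_epochs=2, learning_rate=1e-3, batch_size=32, seed=0,
    )


@pytest.fixture(scope="session")
def tiny_records():
    spec = SyntheticSpec(n_pairs=60, seed=5, protein_length=(30, 40))
    return generate_dataset(spec)


@pytest.fixture(scope="session")
def trained_synth_model():
    """Scaled-down model trained on the noiseless generator (n=2000).

    Shared by the criterion-9 acceptance test and the end-to-end
    attribution sanity check; this is the long fixture of the suite.
    """
    from lofdti.chem_io import SplitSpec, split_dataset
    from lofdti.model import compute_metrics, prepare_records, train

    spec = SyntheticSpec(n_pairs=2000, seed=11, protein_length=(40, 60),
                         noise_rate=0.0)
    records = generate_dataset(spec)
    tr, va, te = split_dataset(records, SplitSpec(seed=11))
    config = ModelConfig(drug_dim=64, protein_dim=64, hidden_dim=64,
                         kmer_dim=64, n_heads=2, max_epochs=15,
                         learning_rate=1e-3, batch_size=64, seed=0)
    model, _ = train(tr, va, config)
    te_data = prepare_records(te)
    metrics = compute_metrics(model.predict_proba(te_data), te_data.labels)
    return {"model": model, "spec": spec, "records": records,
            "test_records": te, "test_metrics": metrics}


@pytest.fixture
def benzene_batch():
    graph = smiles_to_graph("c1ccccc1")
    return pad_batch([graph], max_nodes=6)


def rng(seed: int = 0) -> np.random.Generator:
    return np.random.default_rng(seed)
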