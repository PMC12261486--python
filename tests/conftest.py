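import dataclasses

import pytest

from admeseq.chem_data import (
    EndpointSpec,
    aggregate_endpoints,
    fit_and_apply_normalization,
)
from admeseq.seq_mtl import validation_split
from admeseq.synthetic_data import SyntheticConfig, generate_labels, generate_molecules


@pytest.fixture
def toy_specs():
    return [
        EndpointSpec(name="e1", category="A", task_type="classification"),
        EndpointSpec(name="e2", category="D", task_type="regression"),
    ]


def build_synth_dataset(n_molecules, seed, normalize=True, **overrides):
    """Aggregate-and-normalize a synthetic dataset at the given size."""
    cfg = dataclasses.replace(
        SyntheticConfig(seed=seed), n_molecules=n_molecules, **overrides
    )
    molecules = generate_molecules(cfg)
    data = generate_labels(molecules, cfg)
    dataset = aggregate_endpoints(data.endpoint_tables, data.specs)
    if normalize:
        train_idx, _ = validation_split(dataset.keys, seed)
        train_keys = {dataset.keys[i] for i in train_idx}
        dataset = fit_and_apply_normalization(dataset, train_keys)
    return dataset, data


@pytest.fixture(scope="session")
def synth_small():
    """300-molecule synthetic dataset shared by the training tests."""
    dataset, data = build_synth_dataset(300, seed=11)
    return dataset, data
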