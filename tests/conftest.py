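"""Shared fixtures: synthetic datasets and trained models, built once.

The heavier fixtures (the cluster split of the nitro dataset and the
model trained on it) are session-scoped so the learning, scrambling,
interpretation and acceptance tests all reuse the same artifacts.
"""

from __future__ import annotations

import numpy as np
import pytest

from fpgnn.data import cluster_split
from fpgnn.network import ModelConfig
from fpgnn.synth import SynthSpec, TaskSpec, generate
from fpgnn.training import TrainConfig, train_model

# one learnable single-task dataset: label = nitro substructure, no noise
NITRO_TASKS = (TaskSpec("nitro", "[N+](=O)[O-]", "[N+](=O)[O-]"),)


@pytest.fixture(scope="session")
def nitro_records():
    return generate(SynthSpec(n_molecules=800, tasks=NITRO_TASKS, noise_rate=0.0,
                              missing_rate=0.0, task_correlation=0.0, seed=11))


@pytest.fixture(scope="session")
def nitro_split(nitro_records):
    return cluster_split(nitro_records, k=6, n_valid=100, n_test=200, seed=11)


@pytest.fixture(scope="session")
def tiny_model_cfg():
    return ModelConfig(n_tasks=1, fpn_hidden=(64, 32), gnn_hidden=16, gnn_heads=2,
                       gnn_layers=2, fusion_hidden=32, seed=0)


@pytest.fixture(scope="session")
def tiny_train_cfg():
    return TrainConfig(epochs=30, batch_size=64, learning_rate=3e-3, patience=30, seed=0)


@pytest.fixture(scope="session")
def trained_nitro(nitro_split, tiny_model_cfg, tiny_train_cfg):
    """(state, history) of the tiny model trained on the nitro task."""
    return train_model(nitro_split, tiny_model_cfg, tiny_train_cfg)


@pytest.fixture(scope="session")
def multitask_state():
    """An initialized (untrained) 5-task model for structural tests."""
    from fpgnn.network import init_model

    cfg = ModelConfig(n_tasks=5, fpn_hidden=(32, 16), gnn_hidden=8, gnn_heads=2,
                      gnn_layers=2, fusion_hidden=16, seed=7)
    return init_model(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
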