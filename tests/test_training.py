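"""Masked multi-task loss, training loop behavior, hyperparameter search."""

import numpy as np
import pytest

from fpgnn.autodiff import Tensor
from fpgnn.data import DatasetSplit, cluster_split
from fpgnn.network import GraphBatch, ModelConfig, forward, init_model
from fpgnn.synth import SynthSpec, TaskSpec, generate
from fpgnn.training import (TrainConfig, featurize_records, hyperparameter_search,
                            multitask_bce_loss, train_model, y_scramble)


# --- loss definition --------------------------------------------------------------


def test_loss_half_prediction_is_log_two():
    loss = multitask_bce_loss(np.array([[0.5]]), np.array([[1.0]]), np.array([[True]]))
    assert loss == pytest.approx(-np.log(0.5), abs=1e-12)


def test_loss_zero_when_prediction_equals_label():
    pred = np.array([[1.0, 0.0], [0.0, 1.0]])
    label = pred.copy()
    loss = multitask_bce_loss(pred, label, np.ones_like(pred, bool))
    assert loss == pytest.approx(0.0, abs=1e-5)  # clamping epsilon only


def test_loss_is_mean_of_per_task_losses(rng):
    pred = rng.uniform(0.05, 0.95, size=(12, 3))
    label = (rng.random((12, 3)) < 0.5).astype(float)
    mask = rng.random((12, 3)) < 0.8
    mask[0, :] = True  # keep every task populated
    total = multitask_bce_loss(pred, label, mask)
    per_task = [multitask_bce_loss(pred[:, [j]], label[:, [j]], mask[:, [j]])
                for j in range(3)]
    assert total == pytest.approx(float(np.mean(per_task)), abs=1e-12)


def test_loss_ignores_fully_masked_rows(rng):
    pred = rng.uniform(0.1, 0.9, size=(6, 2))
    label = (rng.random((6, 2)) < 0.5).astype(float)
    mask = np.ones((6, 2), bool)
    base = multitask_bce_loss(pred, label, mask)
    pred2 = np.vstack([pred, rng.uniform(0.1, 0.9, size=(3, 2))])
    label2 = np.vstack([label, np.ones((3, 2))])
    mask2 = np.vstack([mask, np.zeros((3, 2), bool)])
    assert multitask_bce_loss(pred2, label2, mask2) == pytest.approx(base, abs=1e-12)


def test_loss_excludes_empty_tasks_from_average(rng):
    pred = rng.uniform(0.1, 0.9, size=(5, 2))
    label = (rng.random((5, 2)) < 0.5).astype(float)
    mask = np.ones((5, 2), bool)
    mask[:, 1] = False
    expected = multitask_bce_loss(pred[:, [0]], label[:, [0]], mask[:, [0]])
    assert multitask_bce_loss(pred, label, mask) == pytest.approx(expected, abs=1e-12)


def test_loss_all_masked_is_an_error():
    with pytest.raises(ValueError, match="masked"):
        multitask_bce_loss(np.array([[0.5]]), np.array([[1.0]]), np.array([[False]]))


def test_loss_gradient_matches_finite_differences():
    """Autodiff gradient of the whole model's loss on a 2-molecule,
    2-task toy agrees with central differences to 1e-4 relative."""
    cfg = ModelConfig(n_tasks=2, fpn_hidden=(6,), gnn_hidden=4, gnn_heads=2,
                      gnn_layers=2, fusion_hidden=5, seed=3)
    state = init_model(cfg)
    rng = np.random.default_rng(0)
    for p in state.params.values():  # move off the zero init of head/biases
        p.data += rng.normal(scale=0.1, size=p.data.shape)
    fset = featurize_records(generate(SynthSpec(
        n_molecules=2, tasks=(TaskSpec("nitro", "[N+](=O)[O-]", "[N+](=O)[O-]"),
                              TaskSpec("chloro", "Cl", "Cl")), seed=4)))
    batch = GraphBatch.from_graphs(fset.graphs)

    def loss_value() -> float:
        probs = forward(fset.fps, batch, state)
        return float(multitask_bce_loss(probs, fset.y, fset.mask).data)

    probs = forward(fset.fps, batch, state)
    loss = multitask_bce_loss(probs, fset.y, fset.mask)
    loss.backward()
    eps = 1e-6
    for name in ("fpn/W0", "gnn/L0/H0/W", "gnn/L1/H1/a_src", "readout/u",
                 "fusion/W0", "head/W", "head/b"):
        p = state.params[name]
        flat = p.data.reshape(-1)
        idxs = np.linspace(0, flat.size - 1, num=min(5, flat.size)).astype(int)
        for i in idxs:
            orig = flat[i]
            flat[i] = orig + eps
            up = loss_value()
            flat[i] = orig - eps
            down = loss_value()
            flat[i] = orig
            num = (up - down) / (2 * eps)
            got = p.grad.reshape(-1)[i]
            assert got == pytest.approx(num, rel=1e-4, abs=1e-8), name


# --- training loop -----------------------------------------------------------------


@pytest.fixture(scope="module")
def small_split():
    records = generate(SynthSpec(
        n_molecules=120, tasks=(TaskSpec("nitro", "[N+](=O)[O-]", "[N+](=O)[O-]"),),
        seed=9, task_correlation=0.0))
    return cluster_split(records, k=3, n_valid=25, n_test=25, seed=9)


def _small_cfg(seed=0):
    return ModelConfig(n_tasks=1, fpn_hidden=(16, 8), gnn_hidden=4, gnn_heads=1,
                       gnn_layers=1, fusion_hidden=8, seed=seed)


def test_training_is_deterministic(small_split):
    tcfg = TrainConfig(epochs=3, batch_size=16, learning_rate=3e-3, patience=3, seed=5)
    _, h1 = train_model(small_split, _small_cfg(), tcfg)
    _, h2 = train_model(small_split, _small_cfg(), tcfg)
    assert h1.epochs == h2.epochs
    assert h1.best_epoch == h2.best_epoch


def test_best_epoch_has_maximum_validation_auc(small_split):
    tcfg = TrainConfig(epochs=4, batch_size=16, learning_rate=3e-3, patience=4, seed=1)
    _, hist = train_model(small_split, _small_cfg(), tcfg)
    aucs = [e["val_auc_avg"] for e in hist.epochs]
    assert hist.best_val_auc == max(aucs)


def test_patience_zero_stops_on_first_plateau(small_split):
    tcfg = TrainConfig(epochs=20, batch_size=16, learning_rate=3e-3, patience=0, seed=2)
    _, hist = train_model(small_split, _small_cfg(), tcfg)
    aucs = [e["val_auc_avg"] for e in hist.epochs]
    # every intermediate epoch must have improved on the running best
    for i in range(1, len(aucs) - 1):
        assert aucs[i] > max(aucs[:i])
    if len(aucs) < 20:  # stopped early: the last epoch did not improve
        assert aucs[-1] <= max(aucs[:-1])


def test_train_config_validation():
    with pytest.raises(ValueError):
        TrainConfig(epochs=0)
    with pytest.raises(ValueError):
        TrainConfig(patience=-1)


def test_y_scramble_round_count_validation(small_split):
    tcfg = TrainConfig(epochs=1, batch_size=16, seed=0)
    with pytest.raises(ValueError):
        y_scramble(small_split, _small_cfg(), tcfg, rounds=0)


def test_hyperparameter_search_ranks_by_validation_auc(small_split):
    tcfg = TrainConfig(epochs=2, batch_size=16, learning_rate=3e-3, patience=2, seed=0)
    space = {"fusion_hidden": [4, 8], "learning_rate": [1e-3]}
    best, board = hyperparameter_search(small_split, space, budget=2, seed=0,
                                        mcfg=_small_cfg(), tcfg=tcfg)
    assert len(board) == 2
    assert board[0]["val_auc"] >= board[1]["val_auc"]
    assert best.fusion_hidden == board[0]["params"]["fusion_hidden"]
    best2, board2 = hyperparameter_search(small_split, space, budget=2, seed=0,
                                          mcfg=_small_cfg(), tcfg=tcfg)
    assert [e["params"] for e in board] == [e["params"] for e in board2]


def test_hyperparameter_search_degenerate_budget(small_split):
    tcfg = TrainConfig(epochs=1, batch_size=16, seed=0)
    best, board = hyperparameter_search(small_split, {"fusion_hidden": [8]}, budget=1,
                                        seed=0, mcfg=_small_cfg(), tcfg=tcfg)
    assert len(board) == 1 and best.fusion_hidden == 8
    with pytest.raises(ValueError):
        hyperparameter_search(small_split, {}, budget=1, seed=0,
                              mcfg=_small_cfg(), tcfg=tcfg)
    with pytest.raises(ValueError):
        hyperparameter_search(small_split, {"bogus_knob": [1]}, budget=1, seed=0,
                              mcfg=_small_cfg(), tcfg=tcfg)
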