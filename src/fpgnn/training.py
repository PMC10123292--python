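"""Optimization of the network under the masked multi-task BCE loss.

The loss is binary cross-entropy computed per task over the entries
whose label is present, averaged within each task over its masked-in
molecules of the batch, then averaged (unweighted) over the tasks that
have at least one masked-in entry. Molecules missing a task's label
thus contribute nothing to that task — the only reading consistent with
per-subtask loss averaging when assay coverage is partial.

Also here: mini-batch Adam training with AUC-driven model selection and
early stopping, grid/random hyperparameter search, and Y-scrambling
(retraining on per-task permuted labels to rule out chance
correlation).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, fields, replace

import numpy as np
import pandas as pd

from .autodiff import Adam, Tensor
from .data import DatasetSplit, MoleculeRecord, labels_matrix
from .featurize import FeaturizationError, mixed_fingerprint, mol_to_graph
from .metrics import auc
from .network import GraphBatch, ModelConfig, ModelState, forward, init_model

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig", "TrainHistory", "FeaturizedSet", "YScrambleResult",
    "multitask_bce_loss", "featurize_records", "train_model",
    "hyperparameter_search", "y_scramble",
]

_EPS = 1e-7  # probability clamp; the BCE log is undefined at exactly 0/1


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 30
    batch_size: int = 32
    learning_rate: float = 1e-3
    lr_decay: float = 1.0          # multiplicative per-epoch factor
    patience: int = 10             # epochs without validation improvement
    seed: int = 0
    y_scramble_rounds: int = 5

    def __post_init__(self):
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.patience < 0:
            raise ValueError("patience must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class TrainHistory:
    epochs: list[dict] = field(default_factory=list)  # per-epoch records
    best_epoch: int = -1

    def append(self, epoch: int, train_loss: float, val_auc_per_task: list[float],
               val_auc_avg: float) -> None:
        self.epochs.append({
            "epoch": epoch, "train_loss": train_loss,
            "val_auc_per_task": val_auc_per_task, "val_auc_avg": val_auc_avg,
        })

    @property
    def best_val_auc(self) -> float:
        return self.epochs[self.best_epoch]["val_auc_avg"]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.epochs)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def multitask_bce_loss(pred, label, mask):
    """Masked multi-task binary cross-entropy.

    Per task: mean of -[y*log(p) + (1-y)*log(1-p)] over masked-in
    entries; the total is the unweighted mean over tasks with at least
    one masked-in entry. Accepts an autodiff Tensor (returns a Tensor)
    or plain arrays (returns a float). Predictions are clamped to
    [1e-7, 1 - 1e-7] before the log.
    """
    is_tensor = isinstance(pred, Tensor)
    p_t = pred if is_tensor else Tensor(np.atleast_2d(np.asarray(pred, dtype=float)))
    y = np.atleast_2d(np.asarray(label, dtype=float))
    m = np.atleast_2d(np.asarray(mask, dtype=bool)).astype(float)
    if p_t.data.shape != y.shape or y.shape != m.shape:
        raise ValueError("pred, label and mask must have equal shapes")
    counts = m.sum(axis=0)
    included = counts > 0
    if not included.any():
        raise ValueError("all labels masked out: loss undefined")
    # weight w_j folds the per-task mean and the task average together
    w = np.where(included, 1.0, 0.0) / np.where(included, counts, 1.0) / included.sum()
    p = p_t.clip(_EPS, 1.0 - _EPS)
    ll = Tensor(y) * p.log() + Tensor(1.0 - y) * (1.0 - p).log()
    loss = -((ll * Tensor(m)) * Tensor(w)).sum()
    return loss if is_tensor else float(loss.data)


@dataclass
class FeaturizedSet:
    """Pre-featurized records: fingerprints, graphs, labels, masks."""

    records: list[MoleculeRecord]
    fps: np.ndarray
    graphs: list
    y: np.ndarray
    mask: np.ndarray

    def __len__(self) -> int:
        return len(self.records)


def featurize_records(records: list[MoleculeRecord]) -> FeaturizedSet:
    """Featurize once; molecules that fail are dropped with a logged count."""
    kept, fps, graphs = [], [], []
    n_failed = 0
    for r in records:
        try:
            g = mol_to_graph(r.smiles_canonical)
            f = mixed_fingerprint(r.smiles_canonical).concatenated
        except FeaturizationError:
            n_failed += 1
            continue
        kept.append(r)
        graphs.append(g)
        fps.append(f)
    if n_failed:
        logger.warning("dropped %d molecules that failed featurization", n_failed)
    if not kept:
        raise ValueError("no featurizable molecules")
    y, m = labels_matrix(kept)
    return FeaturizedSet(kept, np.vstack(fps), graphs, y, m)


def _mean_val_auc(probs: np.ndarray, y: np.ndarray, m: np.ndarray) -> tuple[list[float], float]:
    per_task = []
    for j in range(y.shape[1]):
        try:
            per_task.append(auc(probs[:, j], y[:, j], m[:, j]))
        except ValueError:
            per_task.append(float("nan"))
    vals = [v for v in per_task if not np.isnan(v)]
    if not vals:
        raise ValueError("validation AUC undefined for every task")
    return per_task, float(np.mean(vals))


def _fit(train_set: FeaturizedSet, valid_set: FeaturizedSet,
         mcfg: ModelConfig, tcfg: TrainConfig,
         select_best: bool = True) -> tuple[ModelState, TrainHistory]:
    state = init_model(mcfg)
    opt = Adam(state.parameters(), lr=tcfg.learning_rate)
    rng = np.random.default_rng(tcfg.seed)
    valid_batch = GraphBatch.from_graphs(valid_set.graphs)

    history = TrainHistory()
    best_state = state.copy()
    best_auc = -np.inf
    since_best = 0
    n = len(train_set)
    for epoch in range(tcfg.epochs):
        order = rng.permutation(n)
        losses = []
        for lo in range(0, n, tcfg.batch_size):
            idx = order[lo:lo + tcfg.batch_size]
            if not train_set.mask[idx].any():
                continue  # a batch with no labels carries no gradient signal
            batch = GraphBatch.from_graphs([train_set.graphs[i] for i in idx])
            probs = forward(train_set.fps[idx], batch, state, training=True, rng=rng)
            loss = multitask_bce_loss(probs, train_set.y[idx], train_set.mask[idx])
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"loss diverged (non-finite) at epoch {epoch}, batch offset {lo}")
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))
        opt.lr *= tcfg.lr_decay

        val_probs = forward(valid_set.fps, valid_batch, state).data
        per_task, avg = _mean_val_auc(val_probs, valid_set.y, valid_set.mask)
        history.append(epoch, float(np.mean(losses)) if losses else float("nan"),
                       per_task, avg)
        if avg > best_auc:
            best_auc = avg
            if select_best:
                best_state = state.copy()
            history.best_epoch = epoch
            since_best = 0
        else:
            since_best += 1
            if select_best and since_best > tcfg.patience:
                break
    if not select_best:  # keep the fully trained model
        best_state = state
        history.best_epoch = len(history.epochs) - 1
    best_state.metadata.update(epoch=history.best_epoch, best_val_auc=best_auc)
    return best_state, history


def train_model(split: DatasetSplit, mcfg: ModelConfig,
                tcfg: TrainConfig) -> tuple[ModelState, TrainHistory]:
    """Train on the split's training set, select the epoch with the best
    averaged validation AUC, and return that model state."""
    if not split.train or not split.validation:
        raise ValueError("split must have nonempty train and validation sets")
    return _fit(featurize_records(split.train), featurize_records(split.validation),
                mcfg, tcfg)


def _expand_space(space: dict[str, list]) -> list[dict]:
    keys = list(space)
    return [dict(zip(keys, combo)) for combo in itertools.product(*(space[k] for k in keys))]


def hyperparameter_search(split: DatasetSplit, space: dict[str, list], budget: int,
                          seed: int, mcfg: ModelConfig, tcfg: TrainConfig,
                          ) -> tuple[ModelConfig, list[dict]]:
    """Evaluate up to `budget` configurations, ranked by validation AUC.

    `space` maps ModelConfig / TrainConfig field names to candidate
    values; the full grid is enumerated and subsampled without
    replacement when it exceeds the budget.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not space:
        raise ValueError("empty hyperparameter space")
    mcfg_fields = {f.name for f in fields(ModelConfig)}
    tcfg_fields = {f.name for f in fields(TrainConfig)}
    unknown = set(space) - mcfg_fields - tcfg_fields
    if unknown:
        raise ValueError(f"unknown hyperparameters: {sorted(unknown)}")

    grid = _expand_space(space)
    rng = np.random.default_rng(seed)
    if len(grid) > budget:
        grid = [grid[i] for i in rng.choice(len(grid), size=budget, replace=False)]

    train_set = featurize_records(split.train)
    valid_set = featurize_records(split.validation)
    leaderboard = []
    for combo in grid:
        m_over = {k: v for k, v in combo.items() if k in mcfg_fields}
        t_over = {k: v for k, v in combo.items() if k in tcfg_fields}
        m = replace(mcfg, **m_over)
        t = replace(tcfg, **t_over)
        _, history = _fit(train_set, valid_set, m, t)
        leaderboard.append({"params": combo, "val_auc": history.best_val_auc,
                            "model_config": m, "train_config": t})
    leaderboard.sort(key=lambda e: -e["val_auc"])
    return leaderboard[0]["model_config"], leaderboard


def _test_auc(state: ModelState, test_set: FeaturizedSet) -> list[float]:
    probs = forward(test_set.fps, GraphBatch.from_graphs(test_set.graphs), state).data
    out = []
    for j in range(test_set.y.shape[1]):
        try:
            out.append(auc(probs[:, j], test_set.y[:, j], test_set.mask[:, j]))
        except ValueError:
            out.append(float("nan"))
    return out


def _scramble_labels(fset: FeaturizedSet, rng: np.random.Generator) -> FeaturizedSet:
    """Permute labels within each task among masked-in entries only,
    preserving per-task class balance and the mask pattern."""
    y = fset.y.copy()
    for j in range(y.shape[1]):
        idx = np.flatnonzero(fset.mask[:, j])
        y[idx, j] = y[rng.permutation(idx), j]
    return FeaturizedSet(fset.records, fset.fps, fset.graphs, y, fset.mask)


@dataclass
class YScrambleResult:
    reference_auc: list[float]          # per-task test AUC, true labels
    rounds_auc: list[list[float] | None]  # per round (None if the round failed)

    @property
    def reference_mean(self) -> float:
        return float(np.nanmean(self.reference_auc))

    def round_means(self) -> list[float]:
        return [float(np.nanmean(r)) for r in self.rounds_auc if r is not None]


def y_scramble(split: DatasetSplit, mcfg: ModelConfig, tcfg: TrainConfig,
               rounds: int | None = None) -> YScrambleResult:
    """Retrain on label-scrambled training data to expose chance correlation.

    Each round permutes the labels within every task (masks fixed),
    retrains from scratch with a fresh seed, and records the per-task
    test AUC, alongside the unscrambled reference. Validation labels
    are permuted together with the training labels: epoch selection is
    part of the fitting pipeline, and selecting scrambled models
    against true validation labels would leak the true response into
    the supposedly null run.
    """
    rounds = tcfg.y_scramble_rounds if rounds is None else rounds
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    train_set = featurize_records(split.train)
    valid_set = featurize_records(split.validation)
    test_set = featurize_records(split.test)

    ref_state, _ = _fit(train_set, valid_set, mcfg, tcfg)
    result = YScrambleResult(reference_auc=_test_auc(ref_state, test_set), rounds_auc=[])

    for r in range(rounds):
        round_seed = int((tcfg.seed + 1000003 * (r + 1)) % 2**31)
        rng = np.random.default_rng(round_seed)
        scrambled = _scramble_labels(train_set, rng)
        scrambled_valid = _scramble_labels(valid_set, rng)
        try:
            # the fully trained model is evaluated: epoch selection is a
            # max-statistic that would resurrect chance alignment
            state, _ = _fit(scrambled, scrambled_valid,
                            replace(mcfg, seed=round_seed),
                            replace(tcfg, seed=round_seed),
                            select_best=False)
            result.rounds_auc.append(_test_auc(state, test_set))
        except (RuntimeError, ValueError) as exc:  # a failed round is recorded, not fatal
            logger.error("y-scramble round %d failed: %s", r, exc)
            result.rounds_auc.append(None)
    return result
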