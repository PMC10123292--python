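"""High-level modelling interface: build a model from data, fit, inspect.

`FPGNN` wraps a dataset split plus the architecture and optimization
configs; `fit()` trains the network and returns `FPGNNResults`, which
carries the selected parameters, the training history, evaluation
metrics, prediction, applicability-domain and interpretation methods,
and a `summary()` table.

    >>> model = FPGNN.from_dataframe(df, task_columns=["t1", "t2"])
    >>> res = model.fit()
    >>> print(res.summary())
    >>> res.predict("c1ccccc1[N+](=O)[O-]")
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .data import DatasetSplit, MoleculeRecord, cluster_split, labels_matrix, read_dataset
from .domain import ADModel, classify_ad, fit_ad
from .interpret import AttentionMap, BitImportance, attention_map, bit_importance
from .metrics import MetricsReport, evaluate_multitask
from .network import (GraphBatch, ModelConfig, ModelState, PredictionResult, forward,
                      load_model, predict as _predict, save_model)
from .training import (TrainConfig, TrainHistory, YScrambleResult, featurize_records,
                       train_model, y_scramble)

__all__ = ["FPGNN", "FPGNNResults"]


class FPGNN:
    """A multi-task molecular inhibition classifier over a dataset split."""

    def __init__(self, split: DatasetSplit, task_names: list[str] | None = None,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.split = split
        n_tasks = len(split.train[0].labels)
        self.task_names = task_names or [f"task_{j}" for j in range(n_tasks)]
        if len(self.task_names) != n_tasks:
            raise ValueError("task_names length does not match the label vectors")
        self.model_config = model_config or ModelConfig(n_tasks=n_tasks)
        if self.model_config.n_tasks != n_tasks:
            raise ValueError(
                f"model_config.n_tasks={self.model_config.n_tasks} but data has {n_tasks}")
        self.train_config = train_config or TrainConfig()

    @classmethod
    def from_records(cls, records: list[MoleculeRecord], task_names: list[str] | None = None,
                     k: int = 6, n_valid: int | None = None, n_test: int | None = None,
                     seed: int = 0, **kwargs) -> "FPGNN":
        """Cluster-split a flat record list (defaults: k=6 clusters,
        15% validation, 15% test) and build the model over it."""
        n = len(records)
        n_valid = n_valid if n_valid is not None else max(1, int(0.15 * n))
        n_test = n_test if n_test is not None else max(1, int(0.15 * n))
        split = cluster_split(records, k=min(k, n), n_valid=n_valid, n_test=n_test, seed=seed)
        return cls(split, task_names=task_names, **kwargs)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, task_columns: list[str],
                       smiles_column: str = "smiles", **kwargs) -> "FPGNN":
        import io

        buf = io.StringIO()
        df.to_csv(buf, index=False)
        buf.seek(0)
        records = read_dataset(buf, task_columns, smiles_column=smiles_column)
        return cls.from_records(records, task_names=list(task_columns), **kwargs)

    def fit(self, **train_overrides) -> "FPGNNResults":
        tcfg = replace(self.train_config, **train_overrides) if train_overrides \
            else self.train_config
        state, history = train_model(self.split, self.model_config, tcfg)
        return FPGNNResults(self, state, history)

    def y_scramble(self, rounds: int | None = None) -> YScrambleResult:
        return y_scramble(self.split, self.model_config, self.train_config, rounds)


class FPGNNResults:
    """Fitted model: selected parameters, history, and diagnostics."""

    def __init__(self, model: FPGNN | None, state: ModelState,
                 history: TrainHistory | None = None):
        self.model = model
        self.state = state
        self.history = history
        self._ad: ADModel | None = None

    @property
    def task_names(self) -> list[str]:
        if self.model is not None:
            return self.model.task_names
        return [f"task_{j}" for j in range(self.state.config.n_tasks)]

    # -- prediction ------------------------------------------------------------
    def predict(self, smiles, check_domain: bool = False):
        """Per-task probabilities and 0.5-threshold calls for SMILES input.

        With `check_domain=True` each result also carries an `in_domain`
        attribute from the fitted applicability domain."""
        results = _predict(smiles, self.state)
        if check_domain:
            from .featurize import fingerprint_matrix

            singles = [results] if isinstance(results, PredictionResult) else results
            fps = fingerprint_matrix([r.molecule_id for r in singles])
            for r, a in zip(singles, classify_ad(fps, self.applicability_domain())):
                r.in_domain = a.inside
                r.nn_distance = a.distance
        return results

    def evaluate(self, records: list[MoleculeRecord] | None = None) -> MetricsReport:
        """Metrics report on given records (default: the test set)."""
        if records is None:
            if self.model is None:
                raise ValueError("no attached dataset; pass records explicitly")
            records = self.model.split.test
        fset = featurize_records(records)
        probs = forward(fset.fps, GraphBatch.from_graphs(fset.graphs), self.state).data
        return evaluate_multitask(probs, fset.y, fset.mask, task_names=self.task_names)

    # -- applicability domain -----------------------------------------------------
    def applicability_domain(self, k: int = 3, z: float = 0.2) -> ADModel:
        """Fit (and cache) the k-NN Euclidean distance domain on the
        training fingerprints; defaults are the published optimum."""
        if self._ad is None or self._ad.k != k or self._ad.z != z:
            if self.model is None:
                raise ValueError("no attached dataset; fit the AD explicitly via fit_ad")
            train_fps = featurize_records(self.model.split.train).fps
            self._ad = fit_ad(train_fps, k=k, z=z)
        return self._ad

    # -- interpretation -------------------------------------------------------------
    def attention_map(self, smiles: str, layer: int = -1) -> AttentionMap:
        return attention_map(smiles, self.state, layer=layer)

    def bit_importance(self, task: int = 0, top_n: int = 10,
                       dataset: list[MoleculeRecord] | None = None,
                       method: str = "occlusion") -> list[BitImportance]:
        if dataset is None:
            if self.model is None:
                raise ValueError("no attached dataset; pass one explicitly")
            dataset = self.model.split.test
        return bit_importance(self.state, dataset, task=task, top_n=top_n, method=method)

    # -- persistence ------------------------------------------------------------------
    def save(self, path) -> None:
        save_model(self.state, path)

    @classmethod
    def load(cls, path, model: FPGNN | None = None) -> "FPGNNResults":
        expected = model.model_config if model is not None else None
        return cls(model, load_model(path, expected_config=expected))

    # -- reporting ---------------------------------------------------------------------
    def summary(self) -> str:
        cfg = self.state.config
        lines = [
            "Multi-task fingerprint + graph-attention classifier",
            "=" * 60,
            f"tasks:            {len(self.task_names)} ({', '.join(self.task_names)})",
            f"parameters:       {self.state.n_parameters():,}",
            f"fingerprint dim:  {cfg.fp_dim}   FPN hidden: {cfg.fpn_hidden}",
            f"GNN:              {cfg.gnn_layers} layers x {cfg.gnn_heads} heads x "
            f"{cfg.gnn_hidden} units",
            f"fusion hidden:    {cfg.fusion_hidden}   dropout: {cfg.dropout}",
        ]
        if self.history is not None and self.history.epochs:
            lines += [
                f"epochs run:       {len(self.history.epochs)} "
                f"(best epoch {self.history.best_epoch})",
                f"best val AUC:     {self.history.best_val_auc:.4f}",
            ]
        if self.model is not None and self.model.split.test:
            report = self.evaluate()
            lines += ["", "Test-set metrics (threshold 0.5):", str(report)]
        return "\n".join(lines)

    def __repr__(self) -> str:
        return (f"<FPGNNResults: T={self.state.config.n_tasks}, "
                f"{self.state.n_parameters():,} parameters>")
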