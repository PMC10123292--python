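"""The hybrid fingerprint + graph-attention network.

Four blocks, all sharing weights across tasks except the last linear
map:

* **FPN branch** — a feed-forward network over the mixed
  [MACCS | PubChem | ErG] fingerprint.
* **GNN branch** — message passing over bonds with attention-weighted
  neighbour aggregation (graph-attention layers with additive scoring
  over source, destination and bond features), followed by an
  attention-weighted readout over all atoms of a molecule.
* **Fusion** — fully connected layers over the concatenated branch
  embeddings.
* **Multi-task head** — one sigmoid output per task; each column of the
  head weight matrix belongs to exactly one task, so all representation
  parameters are shared while predictions stay task-specific.

Self-loops (with zero bond features) are added to every atom so that a
neighbourhood is never empty; attention coefficients therefore sum to
one over each atom's bonded neighbours plus itself, and a single-atom
molecule reduces to a readout of its own transformed features.
"""

from __future__ import annotations

import io
import json
from dataclasses import asdict, dataclass, field

import numpy as np

from . import autodiff as ad
from .autodiff import Parameter, Tensor, concat, gather, segment_softmax, segment_sum
from .featurize import (ATOM_FEATURE_DIM, BOND_FEATURE_DIM, FP_LENGTH, FeaturizationError,
                        MixedFingerprint, MolGraph, mixed_fingerprint, mol_to_graph,
                        schema_hash)

__all__ = [
    "ModelConfig", "ModelState", "GraphBatch", "PredictionResult", "ShapeError",
    "init_model", "fpn_forward", "gnn_forward", "fuse_and_predict",
    "forward", "predict", "save_model", "load_model", "THRESHOLD",
]

THRESHOLD = 0.5  # probability cut-off for a positive call (>= counts as positive)


class ShapeError(ValueError):
    pass


@dataclass(frozen=True)
class ModelConfig:
    """Architecture hyperparameters; parameter shapes follow from these."""

    n_tasks: int
    fp_dim: int = FP_LENGTH
    atom_dim: int = ATOM_FEATURE_DIM
    bond_dim: int = BOND_FEATURE_DIM
    fpn_hidden: tuple[int, ...] = (256, 64)
    gnn_hidden: int = 48        # per attention head
    gnn_layers: int = 2
    gnn_heads: int = 2
    readout_hidden: int = 32
    fusion_hidden: int = 64
    dropout: float = 0.1
    seed: int = 0

    def __post_init__(self):
        if self.n_tasks < 1:
            raise ValueError("n_tasks must be >= 1")
        sizes = (self.fp_dim, self.atom_dim, self.bond_dim, self.gnn_hidden,
                 self.gnn_layers, self.gnn_heads, self.readout_hidden,
                 self.fusion_hidden, *self.fpn_hidden)
        if any(s < 1 for s in sizes):
            raise ValueError("all sizes must be >= 1")
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError("dropout must lie in [0, 1)")

    @property
    def gnn_out_dim(self) -> int:
        return self.gnn_heads * self.gnn_hidden


@dataclass
class ModelState:
    """All learnable parameters plus the config that shaped them."""

    config: ModelConfig
    params: dict[str, Parameter]
    metadata: dict = field(default_factory=dict)

    def parameters(self) -> list[Parameter]:
        return list(self.params.values())

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.params.values())

    def copy(self) -> "ModelState":
        return ModelState(
            config=self.config,
            params={k: Parameter(p.data.copy()) for k, p in self.params.items()},
            metadata=dict(self.metadata),
        )


@dataclass
class PredictionResult:
    molecule_id: str
    probabilities: np.ndarray  # (T,), each in [0, 1]
    calls: np.ndarray          # (T,), 1 iff probability >= THRESHOLD


def _glorot(rng: np.random.Generator, n_in: int, n_out: int) -> np.ndarray:
    bound = np.sqrt(6.0 / (n_in + n_out))
    return rng.uniform(-bound, bound, size=(n_in, n_out))


def init_model(config: ModelConfig) -> ModelState:
    """Seeded initialization; the output head starts at zero so an
    untrained model predicts probability 0.5 for every task."""
    rng = np.random.default_rng(config.seed)
    p: dict[str, Parameter] = {}

    sizes = (config.fp_dim,) + tuple(config.fpn_hidden)
    for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
        p[f"fpn/W{i}"] = Parameter(_glorot(rng, a, b))
        p[f"fpn/b{i}"] = Parameter(np.zeros((1, b)))

    d_in = config.atom_dim
    for layer in range(config.gnn_layers):
        for h in range(config.gnn_heads):
            pre = f"gnn/L{layer}/H{h}"
            p[f"{pre}/W"] = Parameter(_glorot(rng, d_in, config.gnn_hidden))
            p[f"{pre}/We"] = Parameter(_glorot(rng, config.bond_dim, config.gnn_hidden))
            p[f"{pre}/a_src"] = Parameter(_glorot(rng, 1, config.gnn_hidden))
            p[f"{pre}/a_dst"] = Parameter(_glorot(rng, 1, config.gnn_hidden))
            p[f"{pre}/a_edge"] = Parameter(_glorot(rng, 1, config.gnn_hidden))
            p[f"{pre}/b"] = Parameter(np.zeros((1, config.gnn_hidden)))
        d_in = config.gnn_out_dim

    p["readout/W"] = Parameter(_glorot(rng, config.gnn_out_dim, config.readout_hidden))
    p["readout/b"] = Parameter(np.zeros((1, config.readout_hidden)))
    p["readout/u"] = Parameter(_glorot(rng, 1, config.readout_hidden))

    fused_in = config.fpn_hidden[-1] + config.gnn_out_dim
    p["fusion/W0"] = Parameter(_glorot(rng, fused_in, config.fusion_hidden))
    p["fusion/b0"] = Parameter(np.zeros((1, config.fusion_hidden)))
    p["head/W"] = Parameter(np.zeros((config.fusion_hidden, config.n_tasks)))
    p["head/b"] = Parameter(np.zeros((1, config.n_tasks)))

    return ModelState(config=config, params=p,
                      metadata={"epoch": 0, "best_val_auc": None, "schema": schema_hash()})


# --- graph batching -------------------------------------------------------------
@dataclass
class GraphBatch:
    """Several molecular graphs packed into flat arrays.

    Directed edges list every bond twice plus one self-loop per atom
    (self-loop bond features are zero). `edge_bond` maps each directed
    edge to its source bond index within its molecule (-1 for
    self-loops), which lets interpretation map attention back to bonds.
    """

    atom_features: np.ndarray
    edge_src: np.ndarray
    edge_dst: np.ndarray
    edge_features: np.ndarray
    edge_bond: np.ndarray
    graph_id: np.ndarray
    n_mols: int
    atom_offsets: np.ndarray

    @classmethod
    def from_graphs(cls, graphs: list[MolGraph]) -> "GraphBatch":
        if not graphs:
            raise ValueError("empty graph batch")
        xs, srcs, dsts, efs, ebonds, gids = [], [], [], [], [], []
        offset = 0
        offsets = []
        for g_idx, g in enumerate(graphs):
            if g.n_atoms == 0:
                raise ValueError("empty graph in batch")
            offsets.append(offset)
            xs.append(g.atom_features)
            for b_idx, (i, j) in enumerate(g.adjacency):
                for s, d in ((i, j), (j, i)):
                    srcs.append(offset + s)
                    dsts.append(offset + d)
                    efs.append(g.bond_features[b_idx])
                    ebonds.append(b_idx)
            for i in range(g.n_atoms):  # self-loops keep neighbourhoods nonempty
                srcs.append(offset + i)
                dsts.append(offset + i)
                efs.append(np.zeros(BOND_FEATURE_DIM))
                ebonds.append(-1)
            gids.extend([g_idx] * g.n_atoms)
            offset += g.n_atoms
        return cls(
            atom_features=np.vstack(xs),
            edge_src=np.array(srcs, dtype=np.intp),
            edge_dst=np.array(dsts, dtype=np.intp),
            edge_features=np.vstack(efs),
            edge_bond=np.array(ebonds, dtype=np.intp),
            graph_id=np.array(gids, dtype=np.intp),
            n_mols=len(graphs),
            atom_offsets=np.array(offsets, dtype=np.intp),
        )


# --- forward passes ----------------------------------------------------------------
def fpn_forward(fp, state: ModelState, training: bool = False,
                rng: np.random.Generator | None = None) -> Tensor:
    """Fingerprint branch: MLP embedding of the mixed fingerprint(s)."""
    if isinstance(fp, MixedFingerprint):
        fp = fp.concatenated[None, :]
    x = np.atleast_2d(np.asarray(fp, dtype=np.float64))
    cfg = state.config
    if x.shape[1] != cfg.fp_dim:
        raise ShapeError(f"fingerprint length {x.shape[1]} != model schema {cfg.fp_dim}")
    h = Tensor(x)
    n_layers = len(cfg.fpn_hidden)
    for i in range(n_layers):
        h = h @ state.params[f"fpn/W{i}"] + state.params[f"fpn/b{i}"]
        h = h.relu()
        if training and cfg.dropout > 0 and i < n_layers - 1:
            h = h.dropout(cfg.dropout, rng)
    return h


def gnn_forward(graph, state: ModelState, training: bool = False,
                rng: np.random.Generator | None = None,
                capture: dict | None = None) -> Tensor:
    """Graph branch: attention message passing + attention readout.

    When `capture` is a dict it is filled with the raw attention
    coefficients: ``capture["layers"][layer][head]`` holds (src, dst,
    alpha) over directed edges, ``capture["readout"]`` the per-atom
    readout weights.
    """
    if isinstance(graph, MolGraph):
        graph = GraphBatch.from_graphs([graph])
    cfg = state.config
    if graph.atom_features.shape[1] != cfg.atom_dim:
        raise ShapeError(
            f"atom feature length {graph.atom_features.shape[1]} != model schema {cfg.atom_dim}")
    n_atoms = graph.atom_features.shape[0]
    src, dst = graph.edge_src, graph.edge_dst
    e_feats = Tensor(graph.edge_features)
    h = Tensor(graph.atom_features)
    if capture is not None:
        capture["layers"] = []
        capture["edge_src"] = src
        capture["edge_dst"] = dst
        capture["edge_bond"] = graph.edge_bond

    for layer in range(cfg.gnn_layers):
        head_outputs = []
        layer_capture = []
        for head in range(cfg.gnn_heads):
            pre = f"gnn/L{layer}/H{head}"
            hw = h @ state.params[f"{pre}/W"]                       # (N, d)
            he = e_feats @ state.params[f"{pre}/We"]                # (E, d)
            h_src, h_dst = gather(hw, src), gather(hw, dst)
            logits = ((h_src * state.params[f"{pre}/a_src"]).sum(axis=1)
                      + (h_dst * state.params[f"{pre}/a_dst"]).sum(axis=1)
                      + (he * state.params[f"{pre}/a_edge"]).sum(axis=1)).leaky_relu(0.2)
            alpha = segment_softmax(logits, dst, n_atoms)           # (E,)
            msg = (h_src + he) * alpha.reshape(-1, 1)
            agg = segment_sum(msg, dst, n_atoms)                    # (N, d)
            head_outputs.append((agg + state.params[f"{pre}/b"]).elu())
            if capture is not None:
                layer_capture.append(alpha.data.copy())
        h = head_outputs[0] if len(head_outputs) == 1 else concat(head_outputs, axis=1)
        if training and cfg.dropout > 0:
            h = h.dropout(cfg.dropout, rng)
        if capture is not None:
            capture["layers"].append(layer_capture)

    scores = ((h @ state.params["readout/W"] + state.params["readout/b"]).tanh()
              * state.params["readout/u"]).sum(axis=1)
    atom_alpha = segment_softmax(scores, graph.graph_id, graph.n_mols)
    emb = segment_sum(h * atom_alpha.reshape(-1, 1), graph.graph_id, graph.n_mols)
    if capture is not None:
        capture["readout"] = atom_alpha.data.copy()
        capture["graph_id"] = graph.graph_id
    return emb


def fuse_and_predict(fpn_emb: Tensor, gnn_emb: Tensor, state: ModelState,
                     training: bool = False,
                     rng: np.random.Generator | None = None) -> Tensor:
    """Fusion layers over both embeddings, then T sigmoid outputs."""
    cfg = state.config
    if fpn_emb.shape[1] != cfg.fpn_hidden[-1]:
        raise ShapeError(f"FPN embedding {fpn_emb.shape[1]} != config {cfg.fpn_hidden[-1]}")
    if gnn_emb.shape[1] != cfg.gnn_out_dim:
        raise ShapeError(f"GNN embedding {gnn_emb.shape[1]} != config {cfg.gnn_out_dim}")
    z = concat([fpn_emb, gnn_emb], axis=1)
    z = (z @ state.params["fusion/W0"] + state.params["fusion/b0"]).relu()
    if training and cfg.dropout > 0:
        z = z.dropout(cfg.dropout, rng)
    logits = z @ state.params["head/W"] + state.params["head/b"]
    return logits.sigmoid()


def forward(fps: np.ndarray, batch: GraphBatch, state: ModelState,
            training: bool = False, rng: np.random.Generator | None = None) -> Tensor:
    """Whole-model forward pass over pre-featurized inputs."""
    return fuse_and_predict(
        fpn_forward(fps, state, training, rng),
        gnn_forward(batch, state, training, rng),
        state, training, rng,
    )


def predict(smiles, state: ModelState) -> PredictionResult | list[PredictionResult]:
    """Evaluation-mode prediction for one SMILES or a list of SMILES."""
    single = isinstance(smiles, str)
    smiles_list = [smiles] if single else list(smiles)
    graphs, fps = [], []
    for s in smiles_list:
        try:
            graphs.append(mol_to_graph(s))
            fps.append(mixed_fingerprint(s).concatenated)
        except FeaturizationError as exc:
            raise FeaturizationError(s, f"prediction failed ({exc})") from exc
    probs = forward(np.vstack(fps), GraphBatch.from_graphs(graphs), state).data
    results = [
        PredictionResult(molecule_id=s, probabilities=p.copy(),
                         calls=(p >= THRESHOLD).astype(int))
        for s, p in zip(smiles_list, probs)
    ]
    return results[0] if single else results


# --- checkpointing ---------------------------------------------------------------
def save_model(state: ModelState, path) -> None:
    """Write a checkpoint: parameter tensors + JSON config + schema hash."""
    arrays = {f"param:{k}": p.data for k, p in state.params.items()}
    header = json.dumps({
        "config": asdict(state.config),
        "metadata": state.metadata,
        "schema": schema_hash(),
    })
    buf = io.BytesIO()
    np.savez(buf, __header__=np.frombuffer(header.encode(), dtype=np.uint8), **arrays)
    with open(path, "wb") as fh:
        fh.write(buf.getvalue())


def load_model(path, expected_config: ModelConfig | None = None) -> ModelState:
    """Load a checkpoint; fails loudly on schema or config mismatch."""
    with np.load(path) as npz:
        if "__header__" not in npz:
            raise ValueError(f"{path} is not a model checkpoint")
        header = json.loads(bytes(npz["__header__"]).decode())
        cfg_dict = dict(header["config"])
        cfg_dict["fpn_hidden"] = tuple(cfg_dict["fpn_hidden"])
        config = ModelConfig(**cfg_dict)
        if header["schema"] != schema_hash():
            raise ValueError(
                f"feature schema mismatch: checkpoint {header['schema']}, "
                f"current {schema_hash()}")
        if expected_config is not None and config != expected_config:
            if config.n_tasks != expected_config.n_tasks:
                raise ValueError(
                    f"task count mismatch: expected T={expected_config.n_tasks}, "
                    f"checkpoint has T={config.n_tasks}")
            raise ValueError("checkpoint config does not match the expected config")
        params = {k[len("param:"):]: Parameter(npz[k].copy())
                  for k in npz.files if k.startswith("param:")}
    reference = init_model(config)
    if set(params) != set(reference.params):
        raise ValueError("checkpoint parameter names do not match the config")
    for k, p in params.items():
        if p.data.shape != reference.params[k].data.shape:
            raise ValueError(
                f"parameter {k} has shape {p.data.shape}, "
                f"config implies {reference.params[k].data.shape}")
    return ModelState(config=config, params=params, metadata=header["metadata"])
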