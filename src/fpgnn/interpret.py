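"""Model interpretation: bond-level attention maps and fingerprint-bit importances.

The graph branch's attention coefficients are captured during a forward
pass and mapped onto bonds (the symmetric bond score is the mean of the
two directed coefficients); per-atom aggregates are the sums of
incident bond scores, min–max normalised per molecule for rendering
only. The fingerprint branch is attributed by occlusion: the importance
of a bit is the mean absolute change in a task's predicted probability
when that bit is zeroed across a dataset (a gradient×input variant is
also available). A bit that is zero in every molecule necessarily has
occlusion importance zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from rdkit import Chem
from rdkit.Chem.Draw import rdMolDraw2D

from .autodiff import Tensor
from .data import MoleculeRecord
from .featurize import bit_family, bit_meaning, mol_to_graph
from .network import GraphBatch, ModelState, fpn_forward, fuse_and_predict, gnn_forward
from .training import featurize_records

logger = logging.getLogger(__name__)

__all__ = ["AttentionMap", "BitImportance", "attention_map", "bit_importance",
           "render_molecule_attention"]


@dataclass
class AttentionMap:
    smiles: str
    layer: int
    heads: int
    bond_pairs: list[tuple[int, int]]   # undirected atom-index pairs
    bond_scores: np.ndarray             # (n_bonds,) >= 0
    atom_scores_raw: np.ndarray         # (n_atoms,) sums of incident bond scores
    atom_scores: np.ndarray             # (n_atoms,) min-max normalised to [0, 1]
    directed_alpha: np.ndarray          # per directed edge (incl. self-loops), head-aggregated
    edge_src: np.ndarray
    edge_dst: np.ndarray


@dataclass
class BitImportance:
    bit: int           # global index in the concatenated fingerprint
    family: str        # MACCS | PubChem | ErG
    local_bit: int     # index within the family block
    importance: float  # >= 0
    meaning: str


def attention_map(smiles: str, state: ModelState, layer: int = -1,
                  aggregation: str = "mean") -> AttentionMap:
    """Capture the graph-attention coefficients of one molecule.

    `layer` selects the message-passing layer (negative indices count
    from the end); `aggregation` combines heads ("mean" or "max").
    """
    graph = mol_to_graph(smiles)
    capture: dict = {}
    gnn_forward(graph, state, capture=capture)
    n_layers = state.config.gnn_layers
    if not -n_layers <= layer < n_layers:
        raise IndexError(f"layer {layer} out of range for {n_layers} GNN layers")
    layer %= n_layers
    head_alphas = np.stack(capture["layers"][layer])  # (heads, E)
    if aggregation == "mean":
        alpha = head_alphas.mean(axis=0)
    elif aggregation == "max":
        alpha = head_alphas.max(axis=0)
    else:
        raise ValueError(f"unknown aggregation {aggregation!r}")

    edge_bond = capture["edge_bond"]
    n_bonds = len(graph.adjacency)
    bond_scores = np.zeros(n_bonds)
    for b in range(n_bonds):
        sel = edge_bond == b
        bond_scores[b] = alpha[sel].mean()  # mean of the two directions

    atom_raw = np.zeros(graph.n_atoms)
    for b, (i, j) in enumerate(graph.adjacency):
        atom_raw[i] += bond_scores[b]
        atom_raw[j] += bond_scores[b]
    spread = atom_raw.max() - atom_raw.min()
    atom_norm = (atom_raw - atom_raw.min()) / spread if spread > 0 else np.zeros_like(atom_raw)

    return AttentionMap(
        smiles=smiles, layer=layer, heads=state.config.gnn_heads,
        bond_pairs=list(graph.adjacency), bond_scores=bond_scores,
        atom_scores_raw=atom_raw, atom_scores=atom_norm,
        directed_alpha=alpha, edge_src=capture["edge_src"], edge_dst=capture["edge_dst"],
    )


def _dataset_probs(fps: np.ndarray, gnn_emb: Tensor, state: ModelState) -> np.ndarray:
    return fuse_and_predict(fpn_forward(fps, state), gnn_emb, state).data


def bit_importance(state: ModelState, dataset: list[MoleculeRecord], task: int,
                   top_n: int = 10, method: str = "occlusion") -> list[BitImportance]:
    """Ranked importances of mixed-fingerprint bits for one task.

    Occlusion: importance of bit b is the dataset mean of
    |p_task(x) - p_task(x with bit b zeroed)|; the graph-branch
    embedding is held fixed. "gradient" scores mean |dp/dx_b * x_b|
    instead. Ranked descending; the top `top_n` are returned.
    """
    if not dataset:
        raise ValueError("dataset must be nonempty")
    if not 0 <= task < state.config.n_tasks:
        raise IndexError(f"task {task} out of range for T={state.config.n_tasks}")
    fset = featurize_records(dataset)
    n_bits = fset.fps.shape[1]
    if top_n > n_bits:
        logger.warning("top_n=%d exceeds %d bits; clipping", top_n, n_bits)
        top_n = n_bits
    gnn_emb = Tensor(gnn_forward(GraphBatch.from_graphs(fset.graphs), state).data)

    scores = np.zeros(n_bits)
    if method == "occlusion":
        base = _dataset_probs(fset.fps, gnn_emb, state)[:, task]
        for b in np.flatnonzero((fset.fps != 0).any(axis=0)):
            occluded = fset.fps.copy()
            occluded[:, b] = 0.0
            probs = _dataset_probs(occluded, gnn_emb, state)[:, task]
            scores[b] = np.abs(probs - base).mean()
    elif method == "gradient":
        x = Tensor(fset.fps, requires_grad=True)
        onehot = np.zeros((state.config.n_tasks, 1))
        onehot[task, 0] = 1.0
        out = fuse_and_predict(_fpn_tensor(x, state), gnn_emb, state)
        (out @ Tensor(onehot)).sum().backward()
        scores = np.abs(x.grad * fset.fps).mean(axis=0)
    else:
        raise ValueError(f"unknown attribution method {method!r}")

    order = np.argsort(-scores, kind="stable")[:top_n]
    out = []
    for b in order:
        family, local = bit_family(int(b))
        out.append(BitImportance(bit=int(b), family=family, local_bit=local,
                                 importance=float(scores[b]), meaning=bit_meaning(int(b))))
    return out


def _fpn_tensor(x: Tensor, state: ModelState) -> Tensor:
    """FPN forward that keeps the input tensor in the autodiff graph."""
    cfg = state.config
    h = x
    for i in range(len(cfg.fpn_hidden)):
        h = (h @ state.params[f"fpn/W{i}"] + state.params[f"fpn/b{i}"]).relu()
    return h


def render_molecule_attention(amap: AttentionMap, smiles: str, path,
                              size: tuple[int, int] = (400, 400)) -> None:
    """Write a 2-D depiction (SVG) with bonds/atoms shaded by attention.

    Shading is monotone in the aggregate score: the highest-scoring
    bond is darkest. The map must come from the same molecule.
    """
    mol = Chem.MolFromSmiles(smiles)
    ref = Chem.MolFromSmiles(amap.smiles)
    if mol is None or ref is None or Chem.MolToSmiles(mol) != Chem.MolToSmiles(ref):
        raise ValueError("attention map does not belong to this molecule")
    if mol.GetNumAtoms() != len(amap.atom_scores):
        raise ValueError("atom count mismatch between molecule and attention map")

    bmax = amap.bond_scores.max() if len(amap.bond_scores) else 1.0
    bond_colors, bond_ids = {}, []
    for b, (i, j) in enumerate(amap.bond_pairs):
        bond = mol.GetBondBetweenAtoms(int(i), int(j))
        if bond is None:
            raise ValueError("attention map bond not present in molecule")
        s = float(amap.bond_scores[b] / bmax) if bmax > 0 else 0.0
        bond_ids.append(bond.GetIdx())
        bond_colors[bond.GetIdx()] = (1.0, 1.0 - 0.85 * s, 1.0 - 0.85 * s)
    atom_colors = {a: (1.0, 1.0 - 0.85 * float(s), 1.0 - 0.85 * float(s))
                   for a, s in enumerate(amap.atom_scores)}

    drawer = rdMolDraw2D.MolDraw2DSVG(*size)
    rdMolDraw2D.PrepareAndDrawMolecule(
        drawer, mol,
        highlightAtoms=list(atom_colors), highlightAtomColors=atom_colors,
        highlightBonds=bond_ids, highlightBondColors=bond_colors)
    drawer.FinishDrawing()
    with open(path, "w") as fh:
        fh.write(drawer.GetDrawingText())
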