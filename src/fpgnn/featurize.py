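"""Molecule featurization: molecular graphs and mixed fingerprints.

Two representations feed the two network branches:

* :class:`MolGraph` — heavy-atom graph with per-atom descriptors
  (element one-hot, degree, formal charge, aromaticity, hydrogen count,
  hybridisation) and per-bond descriptors (bond order, conjugation,
  ring membership). Hydrogens are implicit, encoded as an atom feature.
* :class:`MixedFingerprint` — the fixed concatenation
  ``[MACCS(166) | PubChem(881) | ErG(315)]``: two substructure key sets
  and a pharmacophore extended-reduced-graph descriptor.

Featurization is pure and canonicalization-invariant; the schema is
versioned by :func:`schema_hash` so cached features and checkpoints can
detect mismatches.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem
from rdkit.Chem import MACCSkeys, rdReducedGraphs

from .pubchem_fp import PUBCHEM_FP_LENGTH, pubchem_bit_meaning, pubchem_fingerprint

__all__ = [
    "FeaturizationError", "MolGraph", "MixedFingerprint",
    "mol_to_graph", "mixed_fingerprint", "fingerprint_matrix",
    "ATOM_FEATURE_DIM", "BOND_FEATURE_DIM",
    "MACCS_LENGTH", "ERG_LENGTH", "FP_LENGTH",
    "bit_family", "bit_meaning", "schema_hash",
]


class FeaturizationError(ValueError):
    """Raised when a SMILES cannot be turned into model inputs."""

    def __init__(self, smiles: str, reason: str = "cannot parse SMILES"):
        self.smiles = smiles
        super().__init__(f"{reason}: {smiles!r}")


# --- feature schema (versioned; changing it is a config change) ---------------
_ELEMENTS = ["B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"]  # + other
_HYBRIDIZATIONS = [
    Chem.HybridizationType.SP,
    Chem.HybridizationType.SP2,
    Chem.HybridizationType.SP3,
    Chem.HybridizationType.SP3D,
    Chem.HybridizationType.SP3D2,
]  # + other
_MAX_DEGREE = 5
_CHARGES = [-1, 0, 1]  # + other
_MAX_NUM_H = 4

ATOM_FEATURE_DIM = (len(_ELEMENTS) + 1) + (_MAX_DEGREE + 2) + (len(_CHARGES) + 1) \
    + 1 + (_MAX_NUM_H + 2) + (len(_HYBRIDIZATIONS) + 1)
BOND_FEATURE_DIM = 4 + 1 + 1  # bond-type one-hot, conjugation, ring membership

MACCS_LENGTH = 166
ERG_LENGTH = 315
FP_LENGTH = MACCS_LENGTH + PUBCHEM_FP_LENGTH + ERG_LENGTH

_ERG_PROPERTIES = ["Donor", "Acceptor", "Positive", "Negative", "Hydrophobic", "Aromatic"]
_ERG_MAX_PATH = 15


def schema_hash() -> str:
    """Stable digest of the feature schema; stored in checkpoints and caches."""
    desc = repr((_ELEMENTS, [str(h) for h in _HYBRIDIZATIONS], _MAX_DEGREE, _CHARGES,
                 _MAX_NUM_H, MACCS_LENGTH, PUBCHEM_FP_LENGTH, ERG_LENGTH))
    return hashlib.sha256(desc.encode()).hexdigest()[:16]


def _one_hot(value, choices: list) -> list[float]:
    vec = [0.0] * (len(choices) + 1)
    vec[choices.index(value) if value in choices else len(choices)] = 1.0
    return vec


def _atom_features(atom: Chem.Atom) -> list[float]:
    return (
        _one_hot(atom.GetSymbol(), _ELEMENTS)
        + _one_hot(min(atom.GetDegree(), _MAX_DEGREE), list(range(_MAX_DEGREE + 1)))
        + _one_hot(atom.GetFormalCharge(), _CHARGES)
        + [1.0 if atom.GetIsAromatic() else 0.0]
        + _one_hot(min(atom.GetTotalNumHs(), _MAX_NUM_H), list(range(_MAX_NUM_H + 1)))
        + _one_hot(atom.GetHybridization(), _HYBRIDIZATIONS)
    )


def _bond_features(bond: Chem.Bond) -> list[float]:
    bt = bond.GetBondType()
    return [
        1.0 if bt == Chem.BondType.SINGLE else 0.0,
        1.0 if bt == Chem.BondType.DOUBLE else 0.0,
        1.0 if bt == Chem.BondType.TRIPLE else 0.0,
        1.0 if bt == Chem.BondType.AROMATIC else 0.0,
        1.0 if bond.GetIsConjugated() else 0.0,
        1.0 if bond.IsInRing() else 0.0,
    ]


@dataclass
class MolGraph:
    """Heavy-atom graph of one molecule."""

    atom_features: np.ndarray          # (n_atoms, ATOM_FEATURE_DIM)
    bond_features: np.ndarray          # (n_bonds, BOND_FEATURE_DIM)
    adjacency: list[tuple[int, int]]   # undirected atom-index pairs, one per bond
    n_atoms: int = field(init=False)
    n_bonds: int = field(init=False)

    def __post_init__(self):
        self.n_atoms = int(self.atom_features.shape[0])
        self.n_bonds = int(self.bond_features.shape[0])
        for i, j in self.adjacency:
            if i == j or not (0 <= i < self.n_atoms and 0 <= j < self.n_atoms):
                raise ValueError(f"bond ({i},{j}) references invalid atom indices")


@dataclass
class MixedFingerprint:
    """Concatenated [MACCS | PubChem | ErG] descriptor of one molecule."""

    maccs: np.ndarray     # (166,) in {0,1}
    pubchem: np.ndarray   # (881,) in {0,1}
    erg: np.ndarray       # (315,) nonnegative reals

    @property
    def concatenated(self) -> np.ndarray:
        return np.concatenate([
            self.maccs.astype(np.float64),
            self.pubchem.astype(np.float64),
            self.erg.astype(np.float64),
        ])


def _parse(smiles: str) -> Chem.Mol:
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise FeaturizationError(smiles)
    return mol


def mol_to_graph(smiles: str) -> MolGraph:
    """Build the heavy-atom :class:`MolGraph` for one SMILES."""
    mol = _parse(smiles)
    if mol.GetNumAtoms() == 0:
        raise FeaturizationError(smiles, "molecule has no heavy atoms")
    atom_feats = np.array([_atom_features(a) for a in mol.GetAtoms()], dtype=np.float64)
    if mol.GetNumBonds():
        bond_feats = np.array([_bond_features(b) for b in mol.GetBonds()], dtype=np.float64)
    else:
        bond_feats = np.zeros((0, BOND_FEATURE_DIM))
    adjacency = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx()) for b in mol.GetBonds()]
    return MolGraph(atom_feats, bond_feats, adjacency)


def mixed_fingerprint(smiles: str) -> MixedFingerprint:
    """Compute the mixed [MACCS | PubChem | ErG] fingerprint for one SMILES."""
    mol = _parse(smiles)
    # RDKit MACCS has 167 positions with bit 0 unused; keys 1..166 are kept.
    maccs_full = np.array(MACCSkeys.GenMACCSKeys(mol), dtype=np.uint8)
    maccs = maccs_full[1:]
    pubchem = pubchem_fingerprint(mol)
    erg = np.asarray(rdReducedGraphs.GetErGFingerprint(mol), dtype=np.float64)
    return MixedFingerprint(maccs=maccs, pubchem=pubchem, erg=erg)


def fingerprint_matrix(smiles_list: list[str]) -> np.ndarray:
    """Stack concatenated fingerprints into an (n, FP_LENGTH) float matrix."""
    return np.vstack([mixed_fingerprint(s).concatenated for s in smiles_list])


# --- bit-index bookkeeping ------------------------------------------------------
def bit_family(global_index: int) -> tuple[str, int]:
    """Map a global fingerprint index to (family, family-local index)."""
    if not 0 <= global_index < FP_LENGTH:
        raise IndexError(f"bit index {global_index} out of range [0, {FP_LENGTH})")
    if global_index < MACCS_LENGTH:
        return "MACCS", global_index
    if global_index < MACCS_LENGTH + PUBCHEM_FP_LENGTH:
        return "PubChem", global_index - MACCS_LENGTH
    return "ErG", global_index - MACCS_LENGTH - PUBCHEM_FP_LENGTH


def erg_bit_meaning(local_index: int) -> str:
    """(property, property, distance) triple encoded by an ErG position.

    Positions enumerate unordered property pairs in lexicographic rank
    order over (Donor, Acceptor, Positive, Negative, Hydrophobic,
    Aromatic), each spanning topological distances 1..15.
    """
    if not 0 <= local_index < ERG_LENGTH:
        raise IndexError(f"ErG bit index {local_index} out of range [0, {ERG_LENGTH})")
    pair_rank, dist0 = divmod(local_index, _ERG_MAX_PATH)
    pairs = [(i, j) for i in range(len(_ERG_PROPERTIES)) for j in range(i, len(_ERG_PROPERTIES))]
    i, j = pairs[pair_rank]
    return f"('{_ERG_PROPERTIES[i]}', '{_ERG_PROPERTIES[j]}', {dist0 + 1})"


def _maccs_bit_meaning(local_index: int) -> str:
    smarts = MACCSkeys.smartsPatts.get(local_index + 1, ("?", 0))[0]
    return f"MACCS key {local_index + 1} ({smarts})"


def bit_meaning(global_index: int) -> str:
    """Human-readable meaning of a global mixed-fingerprint bit."""
    family, local = bit_family(global_index)
    if family == "MACCS":
        return _maccs_bit_meaning(local)
    if family == "PubChem":
        return pubchem_bit_meaning(local)
    return erg_bit_meaning(local)
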