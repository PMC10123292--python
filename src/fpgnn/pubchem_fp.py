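"""An 881-slot substructure-key fingerprint in the public PubChem/CACTVS layout.

The fingerprint is organised in the same sections as the public 881-key
description: hierarchic element counts, ring counts, simple bonded atom
pairs, atom nearest-neighbour environments, and SMARTS substructure
patterns. Every populated slot carries a human-readable meaning (CACTVS
style notation, e.g. ``>= 2 P`` or ``C(~C)(~O)~O``); slots whose public
definition is not reproduced here are reserved and always zero, so the
vector length and section boundaries stay fixed at the published 881.

This table is the package's ground truth: tests assert against these
definitions, not against any external dialect.
"""

from __future__ import annotations

from collections import Counter

import numpy as np
from rdkit import Chem

PUBCHEM_FP_LENGTH = 881

# Section boundaries (inclusive start, exclusive end) of the public layout.
SECTIONS = {
    "element_counts": (0, 115),
    "ring_counts": (115, 263),
    "atom_pairs": (263, 327),
    "neighbourhoods": (327, 460),
    "smarts": (460, 881),
}

# --- section 1: hierarchic element counts -----------------------------------
# (symbol, minimum count); H counts include implicit hydrogens.
_ELEMENT_COUNT_KEYS: list[tuple[str, int]] = (
    [("H", t) for t in (4, 8, 16, 32)]
    + [("Li", t) for t in (1, 2)]
    + [("B", t) for t in (1, 2, 4)]
    + [("C", t) for t in (2, 4, 8, 16, 32)]
    + [("N", t) for t in (1, 2, 4, 8)]
    + [("O", t) for t in (1, 2, 4, 8, 16)]
    + [("F", t) for t in (1, 2, 4)]
    + [("Na", t) for t in (1, 2)]
    + [("Si", t) for t in (1, 2)]
    + [("P", t) for t in (1, 2, 4)]
    + [("S", t) for t in (1, 2, 4, 8)]
    + [("Cl", t) for t in (1, 2, 4, 8)]
    + [("K", t) for t in (1, 2)]
    + [("Br", t) for t in (1, 2, 4)]
    + [("I", t) for t in (1, 2, 4)]
    + [(sym, 1) for sym in (
        "He", "Be", "Ne", "Al", "Ar", "Ca", "Sc", "Ti", "V", "Cr", "Mn", "Fe",
        "Co", "Ni", "Cu", "Zn", "Ga", "Ge", "As", "Se", "Kr", "Rb", "Sr", "Y",
        "Zr", "Nb", "Mo", "Tc", "Ru", "Rh", "Pd", "Ag", "Cd", "In", "Sn", "Sb",
        "Te", "Xe", "Cs", "Ba", "La", "Ce", "Pr", "Nd", "Sm", "Eu", "Gd", "Tb",
        "Dy", "Ho", "Er", "Tm", "Yb", "Lu", "Hf", "Ta", "W", "Re", "Os", "Ir",
        "Pt", "Au", "Hg", "Tl", "Pb", "Bi",
    )]
)
assert len(_ELEMENT_COUNT_KEYS) == 115

# --- section 2: ring counts ---------------------------------------------------
# (ring size, minimum count, qualifier); qualifier in
# {any, carbon_only, nitrogen, heteroatom, saturated, unsaturated, aromatic}.
_RING_KEYS: list[tuple[int, int, str]] = []
for _size, _max_count in ((3, 2), (4, 2), (5, 5), (6, 5), (7, 2), (8, 2), (9, 1), (10, 1)):
    for _c in range(1, _max_count + 1):
        _RING_KEYS.append((_size, _c, "any"))
for _size in range(3, 11):
    for _q in ("carbon_only", "nitrogen", "heteroatom", "saturated", "unsaturated", "aromatic"):
        _RING_KEYS.append((_size, 1, _q))
# global aromatic / hetero-aromatic ring counts
_GLOBAL_RING_KEYS = (
    [("aromatic", t) for t in (1, 2, 3, 4)]
    + [("hetero_aromatic", t) for t in (1, 2, 3, 4)]
)
assert len(_RING_KEYS) + len(_GLOBAL_RING_KEYS) <= 148

# --- section 3: simple bonded atom pairs --------------------------------------
_ATOM_PAIRS: list[tuple[str, str]] = [
    ("C", "C"), ("C", "N"), ("C", "O"), ("C", "S"), ("C", "P"), ("C", "F"),
    ("C", "Cl"), ("C", "Br"), ("C", "I"), ("C", "Si"), ("C", "B"), ("N", "N"),
    ("N", "O"), ("N", "S"), ("N", "P"), ("N", "Cl"), ("O", "O"), ("O", "P"),
    ("O", "S"), ("O", "Si"), ("S", "S"), ("P", "P"), ("B", "O"), ("B", "N"),
    ("Si", "Si"), ("S", "Cl"), ("N", "Br"), ("O", "Cl"), ("S", "F"), ("P", "S"),
    ("P", "F"), ("P", "Cl"),
]

# --- sections 4-7: SMARTS-defined keys ----------------------------------------
# (meaning in CACTVS-style notation, SMARTS). Nearest-neighbour environments
# first, then the substructure patterns.
_SMARTS_KEYS: list[tuple[str, str]] = [
    # atom neighbourhoods
    ("C(~C)(~C)", "[#6](~[#6])~[#6]"),
    ("C(~C)(~C)(~C)", "[#6](~[#6])(~[#6])~[#6]"),
    ("C(~C)(~C)(~C)(~C)", "[#6](~[#6])(~[#6])(~[#6])~[#6]"),
    ("C(~C)(~N)", "[#6](~[#6])~[#7]"),
    ("C(~C)(~O)", "[#6](~[#6])~[#8]"),
    ("C(~C)(~O)~O", "[#6](~[#6])(~[#8])~[#8]"),
    ("C(~C)(~H)(~O)(~O)", "[#6;H1](~[#6])(~[#8])~[#8]"),
    ("C(~O)(~O)", "[#6](~[#8])~[#8]"),
    ("C(~N)(~N)", "[#6](~[#7])~[#7]"),
    ("C(~N)(~O)", "[#6](~[#7])~[#8]"),
    ("C(~C)(~S)", "[#6](~[#6])~[#16]"),
    ("C(~C)(~F)", "[#6](~[#6])~[#9]"),
    ("C(~C)(~Cl)", "[#6](~[#6])~[#17]"),
    ("C(~F)(~F)", "[#6](~[#9])~[#9]"),
    ("C(~F)(~F)(~F)", "[#6](~[#9])(~[#9])~[#9]"),
    ("N(~C)(~C)", "[#7](~[#6])~[#6]"),
    ("N(~C)(~C)(~C)", "[#7](~[#6])(~[#6])~[#6]"),
    ("N(~C)(~O)", "[#7](~[#6])~[#8]"),
    ("N(~O)(~O)", "[#7](~[#8])~[#8]"),
    ("O(~C)(~C)", "[#8](~[#6])~[#6]"),
    ("O(~C)(~P)", "[#8](~[#6])~[#15]"),
    ("S(~C)(~C)", "[#16](~[#6])~[#6]"),
    ("S(~O)(~O)", "[#16](~[#8])~[#8]"),
    ("P(~O)(~O)", "[#15](~[#8])~[#8]"),
    ("P(~O)(~O)(~O)", "[#15](~[#8])(~[#8])~[#8]"),
    ("Si(~C)(~C)", "[#14](~[#6])~[#6]"),
    # bond-order specific fragments
    ("C=C", "C=C"),
    ("C#C", "C#C"),
    ("C=O", "[#6]=[#8]"),
    ("C=N", "[#6]=[#7]"),
    ("C#N", "C#N"),
    ("N=O", "[#7]=[#8]"),
    ("N=N", "[#7]=[#7]"),
    ("S=O", "[#16]=[#8]"),
    ("P=O", "[#15]=[#8]"),
    # functional groups
    ("O=C-O (carboxyl/ester)", "O=C[OX2,OX1-]"),
    ("O=C-OH (carboxylic acid)", "O=C[OX2H1]"),
    ("O=C-N (amide)", "O=C[NX3]"),
    ("O=C-C (ketone/aldehyde context)", "O=C[#6]"),
    ("nitro", "[NX3](=O)=O|[NX3+](=O)[O-]"),
    ("nitrile", "[NX1]#[CX2]"),
    ("sulfonamide", "S(=O)(=O)[NX3]"),
    ("sulfonyl", "S(=O)(=O)"),
    ("sulfoxide", "[#16X3]=[OX1]"),
    ("thiol", "[SX2H]"),
    ("thioether", "[SX2]([#6])[#6]"),
    ("hydroxyl", "[OX2H]"),
    ("ether", "[OX2]([#6])[#6]"),
    ("primary amine", "[NX3;H2][#6]"),
    ("secondary amine", "[NX3;H1]([#6])[#6]"),
    ("tertiary amine", "[NX3]([#6])([#6])[#6]"),
    ("guanidine", "[NX3][CX3](=[NX2])[NX3]"),
    ("amidine", "[CX3](=[NX2])[NX3]"),
    ("urea", "[NX3][CX3](=[OX1])[NX3]"),
    ("carbamate", "[NX3][CX3](=[OX1])[OX2]"),
    ("phosphate/phosphonate", "[PX4](=O)([OX2,OX1-])[OX2,OX1-]"),
    ("halogen on carbon", "[#6][F,Cl,Br,I]"),
    ("halogen on aromatic carbon", "c[F,Cl,Br,I]"),
    ("trihalomethyl", "[CX4]([F,Cl,Br,I])([F,Cl,Br,I])[F,Cl,Br,I]"),
    # aromatic systems
    ("benzene ring", "c1ccccc1"),
    ("pyridine ring", "c1ccncc1"),
    ("pyrimidine ring", "c1cncnc1"),
    ("pyrrole ring", "c1cc[nH]c1"),
    ("furan ring", "c1ccoc1"),
    ("thiophene ring", "c1ccsc1"),
    ("imidazole ring", "c1c[nH]cn1"),
    ("phenol", "c[OX2H]"),
    ("aniline", "c[NX3;H2,H1;!$(NC=O)]"),
    ("aromatic nitro", "c[NX3](=O)=O|c[NX3+](=O)[O-]"),
    ("benzyl", "cC"),
    ("biphenyl", "c1ccc(cc1)-c1ccccc1"),
    ("fused bicyclic aromatic", "c1ccc2ccccc2c1"),
    # chains
    ("CCCC chain", "CCCC"),
    ("CCCCCC chain", "CCCCCC"),
    ("CCCCCCCC chain", "CCCCCCCC"),
    ("C-O-C-C", "COCC"),
    ("N-C-C-O", "NCCO"),
    ("O-C-C-O", "OCCO"),
    ("aromatic ether", "c[OX2][#6]"),
    ("aromatic carbonyl", "cC=O"),
    ("vinyl on aromatic", "cC=C"),
]

_COMPILED: list | None = None


def _rd(smarts: str) -> list:
    # "|" joins alternative SMARTS for one key ("," is reserved by SMARTS itself)
    pats = [Chem.MolFromSmarts(s) for s in smarts.split("|")]
    if any(p is None for p in pats):
        raise ValueError(f"bad SMARTS in key table: {smarts}")
    return pats


def _compiled() -> list:
    global _COMPILED
    if _COMPILED is None:
        _COMPILED = [(meaning, _rd(s)) for meaning, s in _SMARTS_KEYS]
    return _COMPILED


def _ring_matches(ring_atoms: list, mol: Chem.Mol, qualifier: str) -> bool:
    atoms = [mol.GetAtomWithIdx(i) for i in ring_atoms]
    if qualifier == "any":
        return True
    if qualifier == "carbon_only":
        return all(a.GetAtomicNum() == 6 for a in atoms)
    if qualifier == "nitrogen":
        return any(a.GetAtomicNum() == 7 for a in atoms)
    if qualifier == "heteroatom":
        return any(a.GetAtomicNum() not in (6, 1) for a in atoms)
    if qualifier == "aromatic":
        return all(a.GetIsAromatic() for a in atoms)
    ring_set = set(ring_atoms)
    bonds = [b for b in mol.GetBonds()
             if b.GetBeginAtomIdx() in ring_set and b.GetEndAtomIdx() in ring_set]
    if qualifier == "saturated":
        return all(b.GetBondType() == Chem.BondType.SINGLE for b in bonds)
    if qualifier == "unsaturated":
        return (not all(a.GetIsAromatic() for a in atoms)
                and any(b.GetBondType() != Chem.BondType.SINGLE for b in bonds))
    raise ValueError(qualifier)


def pubchem_fingerprint(mol: Chem.Mol) -> np.ndarray:
    """Compute the 881-slot substructure-key vector for an RDKit molecule."""
    bits = np.zeros(PUBCHEM_FP_LENGTH, dtype=np.uint8)

    # element counts (implicit H included)
    counts: Counter = Counter()
    for atom in mol.GetAtoms():
        counts[atom.GetSymbol()] += 1
        counts["H"] += atom.GetTotalNumHs()
    for i, (sym, thresh) in enumerate(_ELEMENT_COUNT_KEYS):
        if counts.get(sym, 0) >= thresh:
            bits[i] = 1

    # ring counts from the SSSR
    ring_info = mol.GetRingInfo()
    rings = [list(r) for r in ring_info.AtomRings()]
    base = SECTIONS["ring_counts"][0]
    for j, (size, min_count, qualifier) in enumerate(_RING_KEYS):
        n = sum(1 for r in rings if len(r) == size and _ring_matches(r, mol, qualifier))
        if n >= min_count:
            bits[base + j] = 1
    goff = base + len(_RING_KEYS)
    n_arom = sum(1 for r in rings
                 if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r))
    n_het_arom = sum(1 for r in rings
                     if all(mol.GetAtomWithIdx(i).GetIsAromatic() for i in r)
                     and any(mol.GetAtomWithIdx(i).GetAtomicNum() != 6 for i in r))
    for j, (kind, thresh) in enumerate(_GLOBAL_RING_KEYS):
        n = n_arom if kind == "aromatic" else n_het_arom
        if n >= thresh:
            bits[goff + j] = 1

    # bonded atom pairs
    pairs = {tuple(sorted((b.GetBeginAtom().GetSymbol(), b.GetEndAtom().GetSymbol())))
             for b in mol.GetBonds()}
    base = SECTIONS["atom_pairs"][0]
    for j, pair in enumerate(_ATOM_PAIRS):
        if tuple(sorted(pair)) in pairs:
            bits[base + j] = 1

    # SMARTS keys (neighbourhoods + substructures share one table)
    base = SECTIONS["neighbourhoods"][0]
    for j, (_, pats) in enumerate(_compiled()):
        if any(mol.HasSubstructMatch(p) for p in pats):
            bits[base + j] = 1

    return bits


def pubchem_bit_meaning(i: int) -> str:
    """Human-readable meaning of a family-local bit index (0..880)."""
    if not 0 <= i < PUBCHEM_FP_LENGTH:
        raise IndexError(f"PubChem bit index {i} out of range [0, {PUBCHEM_FP_LENGTH})")
    if i < len(_ELEMENT_COUNT_KEYS):
        sym, t = _ELEMENT_COUNT_KEYS[i]
        return f">= {t} {sym}"
    lo, hi = SECTIONS["ring_counts"]
    if lo <= i < hi:
        j = i - lo
        if j < len(_RING_KEYS):
            size, c, q = _RING_KEYS[j]
            return f">= {c} {q.replace('_', '-')} ring(s) of size {size}"
        j -= len(_RING_KEYS)
        if j < len(_GLOBAL_RING_KEYS):
            kind, t = _GLOBAL_RING_KEYS[j]
            return f">= {t} {kind.replace('_', '-')} ring(s)"
        return "reserved"
    lo, hi = SECTIONS["atom_pairs"]
    if lo <= i < hi:
        j = i - lo
        if j < len(_ATOM_PAIRS):
            a, b = _ATOM_PAIRS[j]
            return f"{a}-{b} bond"
        return "reserved"
    j = i - SECTIONS["neighbourhoods"][0]
    if j < len(_SMARTS_KEYS):
        return _SMARTS_KEYS[j][0]
    return "reserved"
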