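"""Synthetic multi-task molecule datasets with known structure–label rules.

Molecules are assembled from a scaffold × substituent grammar (aromatic
and aliphatic rings and chains decorated with halogen, nitro, carboxyl,
amine, nitrile and sulfonamide fragments), so every SMILES is valid and
every label is determined by a SMARTS substructure match, optionally
XOR-ed with seeded noise and masked out at a missing-label rate. Tasks
can be correlated through a shared latent inclusion decision, emulating
panels of related assays where one trunk of structural signal drives
several endpoints.

A separate out-of-domain probe family (fluorinated organophosphorus /
organosilicon chemistry, absent from the base grammar) provides
structurally distant molecules for applicability-domain experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from rdkit import Chem

from .data import MoleculeRecord

__all__ = ["TaskSpec", "SynthSpec", "generate", "generate_od_probe", "DEFAULT_TASKS",
           "OD_FAMILIES"]


@dataclass(frozen=True)
class TaskSpec:
    """One synthetic task: its label-defining SMARTS and the grammar
    fragment whose inclusion plants that substructure."""

    name: str
    smarts: str
    fragment: str


# Five correlated substructure tasks, one per common pharmacophore-ish
# fragment — stand-ins for a panel of related inhibition assays.
DEFAULT_TASKS = (
    TaskSpec("nitro", "[N+](=O)[O-]", "[N+](=O)[O-]"),
    TaskSpec("sulfonamide", "S(=O)(=O)N", "S(=O)(=O)N"),
    TaskSpec("carboxyl", "C(=O)O", "C(=O)O"),
    TaskSpec("chloro", "Cl", "Cl"),
    TaskSpec("nitrile", "C#N", "C#N"),
)

# scaffold templates, grouped by number of substituent slots
_TEMPLATES: dict[int, list[str]] = {
    1: [
        "c1ccc({0})cc1",
        "c1ccnc({0})c1",
        "c1cc({0})oc1",
        "c1cc({0})sc1",
        "C1CCC({0})CC1",
        "CCCC{0}",
        "CC(C){0}",
    ],
    2: [
        "c1ccc({0})cc1{1}",
        "c1cc({0})ccc1{1}",
        "c1ccnc({0})c1{1}",
        "C1CCC({0})CC1{1}",
        "CC({0})CCC{1}",
        "CCC({0})C{1}",
    ],
    3: [
        "c1cc({0})cc({1})c1{2}",
        "c1c({0})ccc({1})c1{2}",
        "CC({0})CC({1})C{2}",
    ],
    4: [
        "c1c({0})cc({1})c({2})c1{3}",
        "CC({0})C({1})CC({2})C{3}",
    ],
    5: [
        "c1c({0})c({1})c({2})c({3})c1{4}",
    ],
}
_MAX_SLOTS = max(_TEMPLATES)

# neutral fillers: chosen not to match any DEFAULT_TASKS SMARTS and to
# contain no fluorine (keeping the base grammar disjoint from OD probes)
_NEUTRAL = ["", "", "C", "CC", "CCC", "C(C)C", "O", "OC", "OCC", "N", "NC", "N(C)C", "C=C", "CO"]

# out-of-domain probe families; every template carries F and/or P/Si,
# which the base grammar never emits
OD_FAMILIES: dict[str, list[str]] = {
    "fluorous": [
        "FC(F)(F)C(F)(F)C({0})(F)F",
        "FC(F)(F)C(F)(F)C(F)(F)C(F)(F){0}",
        "OP(=O)(OC(F)(F)F)C({0})(F)F",
        "O=P(O)(OCC(F)(F)F)OC{0}",
        "C[Si](C)(OC(F)(F)F)C{0}",
        "C[Si](C)(C{0})CC(F)(F)F",
        "c1c(F)c(F)c({0})c(F)c1F",
        "c1c(F)c(F)nc({0})c1F",
        "Fc1ccc({0})c(F)c1C(F)(F)F",
    ],
}


@dataclass(frozen=True)
class SynthSpec:
    """Generation conditions for one synthetic dataset."""

    n_molecules: int = 500
    tasks: tuple[TaskSpec, ...] = DEFAULT_TASKS
    noise_rate: float = 0.0          # P(label flip), per task per molecule
    missing_rate: float | tuple = 0.0  # P(label masked out); scalar or per task
    class_balance: float = 0.5       # target positive fraction per task
    task_correlation: float = 0.3    # P(task copies the shared latent decision)
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.noise_rate < 0.5:
            raise ValueError("noise_rate must lie in [0, 0.5)")
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if not self.tasks:
            raise ValueError("at least one task is required")

    def missing_rates(self) -> np.ndarray:
        m = np.broadcast_to(np.asarray(self.missing_rate, dtype=float),
                            (len(self.tasks),))
        if ((m < 0) | (m >= 1)).any():
            raise ValueError("missing rates must lie in [0, 1)")
        return m


def _compiled_tasks(tasks) -> list:
    pats = []
    for t in tasks:
        p = Chem.MolFromSmarts(t.smarts)
        if p is None:
            raise ValueError(f"task {t.name}: bad SMARTS {t.smarts!r}")
        pats.append(p)
    return pats


def _labels_for(mol: Chem.Mol, patterns, spec: SynthSpec,
                rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    miss = spec.missing_rates()
    labels = np.zeros(len(patterns))
    mask = np.ones(len(patterns), dtype=bool)
    for j, pat in enumerate(patterns):
        match = mol.HasSubstructMatch(pat)
        flip = rng.random() < spec.noise_rate
        labels[j] = float(match ^ flip)
        mask[j] = rng.random() >= miss[j]
    return labels, mask


def _assemble(templates_by_slots: dict[int, list[str]], fragments: list[str],
              rng: np.random.Generator) -> str | None:
    n_frag = len(fragments)
    eligible = [s for s in templates_by_slots if s >= n_frag]
    if not eligible:
        raise ValueError(f"no template with {n_frag} slots")
    slots = int(rng.choice(eligible))
    template = templates_by_slots[slots][rng.integers(len(templates_by_slots[slots]))]
    fill = list(fragments) + [_NEUTRAL[rng.integers(len(_NEUTRAL))]
                              for _ in range(slots - n_frag)]
    rng.shuffle(fill)
    smiles = template.format(*fill).replace("()", "")  # empty slots vanish
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def generate(spec: SynthSpec) -> list[MoleculeRecord]:
    """Generate `spec.n_molecules` records with SMARTS-determined labels.

    Canonical SMILES are unique within the dataset. Per molecule, a
    shared latent Bernoulli(class_balance) decision is copied by each
    task with probability `task_correlation` (otherwise the task draws
    its own), and the corresponding defining fragments are planted in a
    randomly chosen scaffold. Deterministic given `spec.seed`.
    """
    rng = np.random.default_rng(spec.seed)
    patterns = _compiled_tasks(spec.tasks)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    max_attempts = 200 * spec.n_molecules
    while len(records) < spec.n_molecules:
        attempts += 1
        if attempts > max_attempts:
            raise RuntimeError(
                f"grammar exhausted after {attempts} attempts "
                f"({len(records)}/{spec.n_molecules} unique molecules); "
                "the requested size or balance target is infeasible")
        latent = rng.random() < spec.class_balance
        include = []
        for _ in spec.tasks:
            if rng.random() < spec.task_correlation:
                include.append(latent)
            else:
                include.append(rng.random() < spec.class_balance)
        fragments = list(dict.fromkeys(  # dedupe, preserving order
            t.fragment for t, inc in zip(spec.tasks, include) if inc))
        if len(fragments) > _MAX_SLOTS:
            fragments = fragments[:_MAX_SLOTS]
        # retry assembly under the same label plan, so duplicates and
        # parse failures do not bias the class balance
        canonical = None
        for _ in range(30):
            candidate = _assemble(_TEMPLATES, fragments, rng)
            if candidate is not None and candidate not in seen:
                canonical = candidate
                break
        if canonical is None:
            continue
        seen.add(canonical)
        mol = Chem.MolFromSmiles(canonical)
        labels, mask = _labels_for(mol, patterns, spec, rng)
        records.append(MoleculeRecord(
            id=f"synth-{len(records)}", smiles_raw=canonical,
            smiles_canonical=canonical, labels=labels, mask=mask))
    return records


def generate_od_probe(spec: SynthSpec, shift: str = "fluorous") -> list[MoleculeRecord]:
    """Generate molecules from a fragment family disjoint from the base
    grammar, guaranteed structurally distant in fingerprint space.

    Labels follow the same SMARTS rules (and noise/mask rates) as
    `generate`, with task fragments planted into the alien scaffolds.
    """
    if shift not in OD_FAMILIES:
        raise ValueError(f"unknown OD family {shift!r}; available: {sorted(OD_FAMILIES)}")
    templates = OD_FAMILIES[shift]
    if not templates:
        raise ValueError(f"OD family {shift!r} is empty")
    rng = np.random.default_rng(spec.seed + 7919)
    patterns = _compiled_tasks(spec.tasks)
    records: list[MoleculeRecord] = []
    seen: set[str] = set()
    attempts = 0
    while len(records) < spec.n_molecules:
        attempts += 1
        if attempts > 200 * spec.n_molecules:
            raise RuntimeError("OD probe grammar exhausted; request fewer molecules")
        include_any = rng.random() < spec.class_balance
        if include_any:
            frag = spec.tasks[rng.integers(len(spec.tasks))].fragment
            fragments = [frag]
        else:
            fragments = [_NEUTRAL[rng.integers(len(_NEUTRAL))]]
        canonical = _assemble({1: templates}, fragments, rng)
        if canonical is None or canonical in seen:
            continue
        seen.add(canonical)
        mol = Chem.MolFromSmiles(canonical)
        labels, mask = _labels_for(mol, patterns, spec, rng)
        records.append(MoleculeRecord(
            id=f"od-{len(records)}", smiles_raw=canonical,
            smiles_canonical=canonical, labels=labels, mask=mask))
    return records
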