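"""Reading, cleaning, splitting and profiling multi-task molecule datasets.

A dataset is a list of :class:`MoleculeRecord`: one molecule with a
binary label and presence mask per task (labels may be missing per task
per molecule, as is typical when several assay datasets are merged).
Cleaning follows standard QSAR curation: inorganics out, largest
organic fragment kept for salts/mixtures, canonical SMILES
deduplication with conservative label merging. Splitting is
structure-based: k-means clustering of mixed-fingerprint vectors with
validation/test drawn proportionally from every cluster, which limits
train/test structural leakage compared to a random split.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from rdkit import Chem
from rdkit.Chem import Crippen, Descriptors
from rdkit.Chem.Scaffolds import MurckoScaffold
from sklearn.cluster import KMeans

from .featurize import fingerprint_matrix

logger = logging.getLogger(__name__)

__all__ = [
    "MoleculeRecord", "DatasetSplit", "DatasetProfile",
    "ConfigurationError", "EmptyDatasetError",
    "read_dataset", "write_dataset", "clean_dataset", "cluster_split",
    "elbow_curve", "profile_dataset", "labels_matrix", "write_split",
]


class ConfigurationError(ValueError):
    pass


class EmptyDatasetError(ValueError):
    pass


@dataclass
class MoleculeRecord:
    """One molecule with per-task binary labels and presence mask."""

    id: str
    smiles_raw: str
    smiles_canonical: str
    labels: np.ndarray  # (T,) values in {0,1}; meaningful only where mask is True
    mask: np.ndarray    # (T,) bool

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.labels.shape != self.mask.shape:
            raise ValueError("labels and mask must have equal length")


@dataclass
class DatasetSplit:
    train: list[MoleculeRecord]
    validation: list[MoleculeRecord]
    test: list[MoleculeRecord]
    split_meta: dict = field(default_factory=dict)


@dataclass
class DatasetProfile:
    mw_values: list[float]
    logp_values: list[float]
    scaffold_fraction: float
    task_counts: list[dict]  # per task: {"positive": _, "negative": _, "missing": _}


def labels_matrix(records: list[MoleculeRecord]) -> tuple[np.ndarray, np.ndarray]:
    """Stack labels and masks into (n, T) arrays."""
    y = np.vstack([r.labels for r in records])
    m = np.vstack([r.mask for r in records])
    return y, m


def _canonical(smiles: str) -> str | None:
    mol = Chem.MolFromSmiles(smiles)
    return None if mol is None else Chem.MolToSmiles(mol)


def read_dataset(path, task_names: list[str], smiles_column: str = "smiles") -> list[MoleculeRecord]:
    """Read a CSV with one SMILES column and one binary label column per task.

    Empty label cells become masked-out entries. Rows whose SMILES does
    not parse are dropped with a logged count. Row order is preserved.
    """
    df = pd.read_csv(path)
    if smiles_column not in df.columns:
        raise ConfigurationError(f"CSV {path} has no {smiles_column!r} column")
    for t in task_names:
        if t not in df.columns:
            raise ConfigurationError(f"CSV {path} has no column for task {t!r}")
    records: list[MoleculeRecord] = []
    n_bad = 0
    for idx, row in df.iterrows():
        smiles = str(row[smiles_column])
        canonical = _canonical(smiles)
        if canonical is None:
            n_bad += 1
            continue
        labels = np.zeros(len(task_names))
        mask = np.zeros(len(task_names), dtype=bool)
        for j, t in enumerate(task_names):
            cell = row[t]
            if pd.isna(cell) or (isinstance(cell, str) and not cell.strip()):
                continue
            labels[j] = float(cell)
            mask[j] = True
        rec_id = str(row["id"]) if "id" in df.columns else str(idx)
        records.append(MoleculeRecord(rec_id, smiles, canonical, labels, mask))
    if n_bad:
        logger.warning("dropped %d rows with unparsable SMILES from %s", n_bad, path)
    if not records:
        raise EmptyDatasetError(f"no parsable molecules in {path}")
    return records


def write_dataset(records: list[MoleculeRecord], path, task_names: list[str]) -> None:
    """Write records to the CSV dialect :func:`read_dataset` reads."""
    rows = []
    for r in records:
        row = {"id": r.id, "smiles": r.smiles_canonical}
        for j, t in enumerate(task_names):
            row[t] = int(r.labels[j]) if r.mask[j] else ""
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def _largest_organic_fragment(mol: Chem.Mol) -> Chem.Mol | None:
    frags = Chem.GetMolFrags(mol, asMols=True, sanitizeFrags=False)
    organic = [f for f in frags if any(a.GetAtomicNum() == 6 for a in f.GetAtoms())]
    if not organic:
        return None
    return max(organic, key=lambda f: f.GetNumHeavyAtoms())


def clean_dataset(records: list[MoleculeRecord]) -> tuple[list[MoleculeRecord], dict]:
    """Curate records: inorganics, salts/mixtures, canonicalization, dedup.

    Steps, in order: (1) drop molecules without a carbon atom; (2) for
    multi-fragment SMILES keep the largest carbon-containing fragment
    (largest by heavy-atom count); (3) re-canonicalize; (4) deduplicate
    by canonical SMILES — duplicate label vectors are merged and a task
    on which duplicates disagree is marked missing.

    Returns the cleaned records and a dict of per-step removal counts.
    """
    counts = {"inorganic": 0, "no_organic_fragment": 0, "duplicate": 0, "label_conflicts": 0}
    staged: list[MoleculeRecord] = []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles_canonical)
        if mol is None or not any(a.GetAtomicNum() == 6 for a in mol.GetAtoms()):
            counts["inorganic"] += 1
            continue
        if len(Chem.GetMolFrags(mol)) > 1:
            mol = _largest_organic_fragment(mol)
            if mol is None:
                counts["no_organic_fragment"] += 1
                continue
            Chem.SanitizeMol(mol)
        canonical = Chem.MolToSmiles(mol)
        staged.append(MoleculeRecord(r.id, r.smiles_raw, canonical,
                                     r.labels.copy(), r.mask.copy()))

    by_canonical: dict[str, MoleculeRecord] = {}
    order: list[str] = []
    for r in staged:
        if r.smiles_canonical not in by_canonical:
            by_canonical[r.smiles_canonical] = r
            order.append(r.smiles_canonical)
            continue
        counts["duplicate"] += 1
        kept = by_canonical[r.smiles_canonical]
        for j in range(len(kept.labels)):
            if r.mask[j] and not kept.mask[j]:
                kept.labels[j] = r.labels[j]
                kept.mask[j] = True
            elif r.mask[j] and kept.mask[j] and r.labels[j] != kept.labels[j]:
                kept.mask[j] = False  # conservative: conflicting duplicates
                kept.labels[j] = 0.0
                counts["label_conflicts"] += 1
    return [by_canonical[s] for s in order], counts


def _proportional_quota(sizes: np.ndarray, total: int) -> np.ndarray:
    """Largest-remainder apportionment of `total` over clusters."""
    if total == 0:
        return np.zeros_like(sizes)
    exact = sizes * total / sizes.sum()
    quota = np.floor(exact).astype(int)
    remainder = exact - quota
    short = total - quota.sum()
    for idx in np.argsort(-remainder)[:short]:
        quota[idx] += 1
    return np.minimum(quota, sizes)


def cluster_split(records: list[MoleculeRecord], k: int, n_valid: int, n_test: int,
                  seed: int, n_restarts: int = 10,
                  fps: np.ndarray | None = None) -> DatasetSplit:
    """Structure-based split: k-means on mixed fingerprints, stratified draw.

    Validation and test molecules are sampled proportionally from every
    cluster with a seeded generator; the remainder trains the model.
    """
    n = len(records)
    if k < 1 or k > n:
        raise ValueError(f"k={k} must be in [1, {n}]")
    if n_valid + n_test >= n:
        raise ValueError("n_valid + n_test must be smaller than the dataset")
    if fps is None:
        fps = fingerprint_matrix([r.smiles_canonical for r in records])
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    assignment = km.fit_predict(fps)
    wss = float(km.inertia_)

    rng = np.random.default_rng(seed)
    sizes = np.bincount(assignment, minlength=k)
    holdout_quota = _proportional_quota(sizes, n_valid + n_test)
    holdout: list[int] = []
    for c in range(k):
        members = np.flatnonzero(assignment == c)
        picked = rng.choice(members, size=holdout_quota[c], replace=False)
        holdout.extend(int(i) for i in picked)
    holdout_arr = np.array(sorted(holdout), dtype=int)
    rng.shuffle(holdout_arr)
    valid_idx = set(holdout_arr[:n_valid].tolist())
    test_idx = set(holdout_arr[n_valid:n_valid + n_test].tolist())

    split = DatasetSplit(
        train=[r for i, r in enumerate(records) if i not in valid_idx and i not in test_idx],
        validation=[records[i] for i in sorted(valid_idx)],
        test=[records[i] for i in sorted(test_idx)],
        split_meta={
            "seed": seed, "k": k, "wss": wss,
            "cluster_sizes": sizes.tolist(),
            "assignments": assignment.tolist(),
        },
    )
    return split


def elbow_curve(records: list[MoleculeRecord], k_max: int, seed: int,
                n_restarts: int = 10, fps: np.ndarray | None = None) -> list[tuple[int, float]]:
    """Within-cluster sum of squares for k = 1..k_max (elbow diagnostics)."""
    if k_max < 2:
        raise ValueError("k_max must be >= 2")
    if fps is None:
        fps = fingerprint_matrix([r.smiles_canonical for r in records])
    curve = []
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed).fit(fps)
        curve.append((k, float(km.inertia_)))
    return curve


def murcko_scaffold(smiles: str) -> str:
    """Bemis–Murcko scaffold SMILES; acyclic molecules share the empty scaffold."""
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"cannot parse {smiles!r}")
    return Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol))


def profile_dataset(records: list[MoleculeRecord]) -> DatasetProfile:
    """Chemical-space profile: MW, LogP, scaffold diversity, label counts."""
    if not records:
        raise EmptyDatasetError("cannot profile an empty dataset")
    mws, logps, scaffolds = [], [], set()
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles_canonical)
        mws.append(float(Descriptors.MolWt(mol)))
        logps.append(float(Crippen.MolLogP(mol)))
        scaffolds.add(Chem.MolToSmiles(MurckoScaffold.GetScaffoldForMol(mol)))
    y, m = labels_matrix(records)
    task_counts = []
    for j in range(y.shape[1]):
        task_counts.append({
            "positive": int(((y[:, j] == 1) & m[:, j]).sum()),
            "negative": int(((y[:, j] == 0) & m[:, j]).sum()),
            "missing": int((~m[:, j]).sum()),
        })
    return DatasetProfile(
        mw_values=mws,
        logp_values=logps,
        scaffold_fraction=len(scaffolds) / len(records),
        task_counts=task_counts,
    )


def write_split(split: DatasetSplit, out_dir, task_names: list[str]) -> None:
    """Write the split as three CSVs plus a JSON sidecar of its metadata."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name, part in (("train", split.train), ("validation", split.validation),
                       ("test", split.test)):
        write_dataset(part, out / f"{name}.csv", task_names)
    with open(out / "split_meta.json", "w") as fh:
        json.dump(split.split_meta, fh, indent=2)
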