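"""Euclidean-distance applicability domain (AD) for the QSAR model.

The threshold is ``D_T = d_ave + Z * theta`` where, over the training
set, each compound's average Euclidean distance to its k nearest other
training compounds is computed (in mixed-fingerprint space, unscaled);
``d_ave`` is the mean and ``theta`` the population standard deviation
of those per-compound averages, and Z is a significance multiplier. A
query is outside the domain (OD) when its distance to its single
nearest training compound exceeds D_T, otherwise inside (ID). Note the
deliberate asymmetry — k-NN averaging on the training side, single
nearest neighbour on the query side — which follows the method as
published.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist

from .data import DatasetSplit
from .metrics import MetricsReport, evaluate_multitask
from .network import GraphBatch, ModelState, forward
from .training import featurize_records

__all__ = ["ADModel", "ADAssignment", "fit_ad", "classify_ad", "ad_grid",
           "DEFAULT_K_GRID", "DEFAULT_Z_GRID"]

# default grid mirrors the published protocol, whose optimum was k=3, Z=0.2
DEFAULT_K_GRID = (1, 2, 3, 4, 5)
DEFAULT_Z_GRID = (0.2, 0.4, 0.6, 0.8, 1.0)


@dataclass
class ADModel:
    train_fps: np.ndarray
    k: int
    z: float
    d_ave: float
    theta: float
    d_t: float  # = d_ave + z * theta


@dataclass
class ADAssignment:
    distance: float  # to the single nearest training compound
    inside: bool     # OD iff distance > D_T

    @property
    def flag(self) -> str:
        return "ID" if self.inside else "OD"


def fit_ad(train_fps: np.ndarray, k: int, z: float) -> ADModel:
    """Estimate the distance threshold from the training fingerprints."""
    train_fps = np.asarray(train_fps, dtype=float)
    n = train_fps.shape[0]
    if k < 1 or k >= n:
        raise ValueError(f"k={k} must satisfy 1 <= k < n_train={n}")
    d = cdist(train_fps, train_fps)
    np.fill_diagonal(d, np.inf)  # self excluded
    # stable sort keeps tie-breaking by training index deterministic
    knn = np.sort(d, axis=1, kind="stable")[:, :k]
    per_compound = knn.mean(axis=1)
    d_ave = float(per_compound.mean())
    theta = float(per_compound.std())  # population std (divisor n)
    return ADModel(train_fps=train_fps, k=k, z=float(z),
                   d_ave=d_ave, theta=theta, d_t=d_ave + z * theta)


def classify_ad(query_fps: np.ndarray, ad: ADModel) -> list[ADAssignment]:
    """Flag each query ID/OD by its nearest-neighbour distance to training."""
    query_fps = np.atleast_2d(np.asarray(query_fps, dtype=float))
    if query_fps.shape[1] != ad.train_fps.shape[1]:
        raise ValueError(
            f"fingerprint length {query_fps.shape[1]} != training {ad.train_fps.shape[1]}")
    nearest = cdist(query_fps, ad.train_fps).min(axis=1)
    return [ADAssignment(distance=float(dist), inside=bool(dist <= ad.d_t))
            for dist in nearest]


def ad_grid(split: DatasetSplit, state: ModelState,
            k_values=DEFAULT_K_GRID, z_values=DEFAULT_Z_GRID,
            task_names: list[str] | None = None) -> list[dict]:
    """Sweep (k, Z): fit the AD on training fingerprints, split the test
    set into ID/OD, and evaluate the model separately on each subset.

    Returns one row per (k, Z) with the OD count and the two metric
    reports (None when a subset is empty). At fixed k the OD count is
    nonincreasing in Z since D_T grows with Z.
    """
    k_values, z_values = list(k_values), list(z_values)
    if not k_values or not z_values:
        raise ValueError("k_values and z_values must be nonempty")
    train_set = featurize_records(split.train)
    test_set = featurize_records(split.test)
    probs = forward(test_set.fps, GraphBatch.from_graphs(test_set.graphs), state).data

    rows = []
    for k in k_values:
        for z in z_values:
            ad = fit_ad(train_set.fps, k, z)
            inside = np.array([a.inside for a in classify_ad(test_set.fps, ad)])
            row = {"k": k, "z": z, "d_t": ad.d_t,
                   "n_id": int(inside.sum()), "n_od": int((~inside).sum()),
                   "metrics_id": None, "metrics_od": None}
            for key, sel in (("metrics_id", inside), ("metrics_od", ~inside)):
                if sel.any():
                    row[key] = _subset_metrics(probs, test_set, sel, task_names)
            rows.append(row)
    return rows


def _subset_metrics(probs, test_set, sel, task_names) -> MetricsReport:
    return evaluate_multitask(probs[sel], test_set.y[sel], test_set.mask[sel],
                              task_names=task_names)
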