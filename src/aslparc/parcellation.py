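"""k-means parcellation of ROI voxels from connectivity profiles.

Each ROI voxel is described by its connectivity profile — its column of the
group extrinsic matrix (length m - n) or its row of the group intrinsic
matrix (length n, self-correlation retained) — and hard-clustered with
k-means (squared Euclidean on raw correlation profiles, k-means++
initialization, multiple restarts).  Labels are canonicalized by descending
cluster size.  Two parcellations are compared after Hungarian label
alignment; the consensus keeps voxels where the aligned extrinsic and
intrinsic solutions agree and marks conflicts -1 (unassigned).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment
from sklearn.cluster import KMeans

from .connectivity import ConnectivityMatrix

DEFAULT_SEED = 20210113
UNASSIGNED = -1


@dataclass
class Parcellation:
    """Integer labels 1..k over ROI voxels (registry order); -1 only in
    consensus outputs."""

    labels: np.ndarray
    k: int
    source: str                    # "extrinsic" | "intrinsic" | "consensus"
    seed: int | None = None
    inertia: float | None = None
    n_init: int | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)
        valid = (self.labels >= 1) & (self.labels <= self.k)
        if self.source == "consensus":
            valid |= self.labels == UNASSIGNED
        if not valid.all():
            raise ValueError("labels out of range")

    @property
    def n(self) -> int:
        return len(self.labels)


def features_from_matrix(mat: ConnectivityMatrix) -> np.ndarray:
    """n x d feature matrix, one row per ROI voxel in registry order."""
    if mat.level != "group":
        raise ValueError("parcellation features require a group-level matrix")
    if mat.kind == "extrinsic":
        return mat.values.T.copy()       # ROI voxels are the columns
    return mat.values.copy()             # intrinsic: rows are ROI voxels


def _canonicalize(labels0: np.ndarray, k: int) -> np.ndarray:
    """Renumber clusters 1..k by descending size (ties: original order)."""
    sizes = np.bincount(labels0, minlength=k)
    order = np.argsort(-sizes, kind="stable")
    remap = np.empty(k, dtype=int)
    remap[order] = np.arange(1, k + 1)
    return remap[labels0]


def kmeans_parcellate(features: np.ndarray, k: int, seed: int = DEFAULT_SEED,
                      n_init: int = 50, source: str = "extrinsic") -> Parcellation:
    """Lloyd k-means with k-means++ init and ``n_init`` restarts; the best
    inertia is kept.  Deterministic given (seed, n_init)."""
    features = np.asarray(features, dtype=float)
    n = features.shape[0]
    if not 2 <= k <= n:
        raise ValueError(f"k must satisfy 2 <= k <= n={n}, got {k}")
    if not np.isfinite(features).all():
        raise ValueError("features must be finite")
    km = KMeans(n_clusters=k, init="k-means++", n_init=n_init, max_iter=300,
                algorithm="lloyd", random_state=int(seed) % (2 ** 31))
    labels0 = km.fit_predict(features)
    return Parcellation(labels=_canonicalize(labels0, k), k=k, source=source,
                        seed=seed, inertia=float(km.inertia_), n_init=n_init)


def _contingency(a: np.ndarray, b: np.ndarray, ka: int, kb: int) -> np.ndarray:
    """ka x kb overlap counts for labels in 1..ka / 1..kb (-1 ignored)."""
    keep = (a >= 1) & (b >= 1)
    return np.histogram2d(a[keep], b[keep],
                          bins=[np.arange(0.5, ka + 1), np.arange(0.5, kb + 1)])[0]


def align_labels(a: Parcellation, b: Parcellation) -> Parcellation:
    """Relabel ``b`` to maximize overlap with ``a`` (Hungarian assignment
    on the contingency table, padded square).  Labels of ``b`` beyond the
    matched min(k_a, k_b) get fresh labels above k_a."""
    if a.n != b.n:
        raise ValueError("parcellations differ in length")
    cont = _contingency(a.labels, b.labels, a.k, b.k)
    size = max(a.k, b.k)
    padded = np.zeros((size, size))
    padded[: a.k, : b.k] = cont
    rows, cols = linear_sum_assignment(-padded)
    mapping = np.full(b.k + 1, UNASSIGNED, dtype=int)
    next_free = a.k + 1
    for i, j in sorted(zip(rows, cols), key=lambda rc: rc[1]):
        if j >= b.k:
            continue
        if i < a.k:
            mapping[j + 1] = i + 1
        else:
            mapping[j + 1] = next_free
            next_free += 1
    new_labels = np.where(b.labels == UNASSIGNED, UNASSIGNED, mapping[b.labels])
    k_out = max(a.k, b.k, next_free - 1)
    return Parcellation(labels=new_labels, k=k_out, source=b.source,
                        seed=b.seed, inertia=b.inertia, n_init=b.n_init)


def consensus(extrinsic: Parcellation, intrinsic: Parcellation) -> Parcellation:
    """Post-alignment agreement of the two routes; conflicts become -1."""
    if extrinsic.k != intrinsic.k:
        raise ValueError("consensus requires equal k")
    if extrinsic.n != intrinsic.n:
        raise ValueError("parcellations differ in length")
    aligned = align_labels(extrinsic, intrinsic)
    agree = extrinsic.labels == aligned.labels
    labels = np.where(agree, extrinsic.labels, UNASSIGNED)
    return Parcellation(labels=labels, k=extrinsic.k, source="consensus",
                        seed=extrinsic.seed)


def unassigned_fraction(p: Parcellation) -> float:
    return float(np.mean(p.labels == UNASSIGNED))
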