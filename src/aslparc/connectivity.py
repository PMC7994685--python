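"""Voxelwise Pearson connectivity matrices over masked dM time series.

Two kinds, mirroring the two parcellation routes:

* extrinsic — (m - n) x n matrix of correlations between every non-ROI
  gray-matter voxel and every ROI voxel;
* intrinsic — n x n matrix among ROI voxels (symmetric, unit diagonal).

Subject matrices are averaged element-wise into a group matrix (plain mean
of r by default; Fisher-z averaging behind a flag).  Zero-variance voxel
series yield r = 0 with a logged warning rather than NaN, so matrix shape
and registries are stable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .io import MaskSet
from .preprocess import DeltaMSeries

logger = logging.getLogger(__name__)

ATANH_CLIP = 1.0 - 1e-7


@dataclass
class ConnectivityMatrix:
    values: np.ndarray
    kind: str                      # "extrinsic" | "intrinsic"
    row_registry: np.ndarray       # (rows, 3) voxel coords
    col_registry: np.ndarray       # (cols, 3) voxel coords
    level: str = "subject"         # "subject" | "group"
    n_subjects_averaged: int = 1
    is_fisher_z: bool = False
    zero_variance_rows: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_registry), len(self.col_registry)):
            raise ValueError("matrix shape does not match registries")
        if self.kind not in ("extrinsic", "intrinsic"):
            raise ValueError(f"unknown kind {self.kind!r}")


def voxel_timeseries(dm: DeltaMSeries, index: np.ndarray) -> np.ndarray:
    """Voxel x time matrix in registry order."""
    if len(index) == 0:
        raise ValueError("empty voxel registry")
    return dm.data[tuple(np.asarray(index).T)]


def _standardize_rows(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Demean rows and scale to unit norm; zero-variance rows become zero."""
    Xc = X - X.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Xc, axis=1, keepdims=True)
    # constant series leave rounding residue after demeaning; treat as flat
    tol = 1e-10 * np.maximum(1.0, np.abs(X).max(axis=1))
    flat = norms[:, 0] <= tol
    if flat.any():
        logger.warning("%d zero-variance voxel series set to r=0", int(flat.sum()))
        norms[flat] = 1.0
        Xc[flat] = 0.0
    return Xc / norms, np.flatnonzero(flat)


def _pearson(A: np.ndarray, B: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    a, fa = _standardize_rows(A)
    b, fb = _standardize_rows(B)
    r = np.clip(a @ b.T, -1.0, 1.0)
    return r, fa, fb


def correlate_extrinsic(dm: DeltaMSeries, masks: MaskSet,
                        chunk_cols: int | None = None) -> ConnectivityMatrix:
    """(m - n) x n Pearson matrix: rows non-ROI gray matter, columns ROI.

    ``chunk_cols`` bounds peak memory by computing blocks of ROI columns at
    a time (the result is identical).
    """
    if dm.n_frames < 3:
        raise ValueError("need at least 3 dM frames to correlate")
    rows_ts = voxel_timeseries(dm, masks.gm_minus_roi_index)
    cols_ts = voxel_timeseries(dm, masks.roi_index)
    if chunk_cols is None:
        r, frow, _ = _pearson(rows_ts, cols_ts)
    else:
        a, frow = _standardize_rows(rows_ts)
        parts = []
        for start in range(0, len(cols_ts), chunk_cols):
            b, _ = _standardize_rows(cols_ts[start:start + chunk_cols])
            parts.append(np.clip(a @ b.T, -1.0, 1.0))
        r = np.concatenate(parts, axis=1)
    return ConnectivityMatrix(values=r, kind="extrinsic",
                              row_registry=masks.gm_minus_roi_index,
                              col_registry=masks.roi_index,
                              zero_variance_rows=frow)


def correlate_intrinsic(dm: DeltaMSeries, masks: MaskSet) -> ConnectivityMatrix:
    """n x n Pearson matrix among ROI voxels: symmetric, unit diagonal."""
    if dm.n_frames < 3:
        raise ValueError("need at least 3 dM frames to correlate")
    ts = voxel_timeseries(dm, masks.roi_index)
    r, flat, _ = _pearson(ts, ts)
    r = 0.5 * (r + r.T)
    np.fill_diagonal(r, 1.0)
    return ConnectivityMatrix(values=r, kind="intrinsic",
                              row_registry=masks.roi_index,
                              col_registry=masks.roi_index,
                              zero_variance_rows=flat)


def group_average(mats: list[ConnectivityMatrix],
                  fisher_z: bool = False) -> ConnectivityMatrix:
    """Element-wise mean across subjects (plain r, or mean atanh(r) in z
    units when ``fisher_z``)."""
    if not mats:
        raise ValueError("no matrices to average")
    ref = mats[0]
    for m in mats[1:]:
        if (m.kind != ref.kind or m.values.shape != ref.values.shape
                or not np.array_equal(m.row_registry, ref.row_registry)
                or not np.array_equal(m.col_registry, ref.col_registry)):
            raise ValueError("matrices differ in kind, shape or registries")
    stack = np.stack([m.values for m in mats])
    if fisher_z:
        stack = np.arctanh(np.clip(stack, -ATANH_CLIP, ATANH_CLIP))
    mean = stack.mean(axis=0)
    if ref.kind == "intrinsic" and not fisher_z:
        np.fill_diagonal(mean, 1.0)
    return ConnectivityMatrix(values=mean, kind=ref.kind,
                              row_registry=ref.row_registry,
                              col_registry=ref.col_registry,
                              level="group", n_subjects_averaged=len(mats),
                              is_fisher_z=fisher_z)


def save_matrix(mat: ConnectivityMatrix, path) -> None:
    """Persist as .npy plus a JSON sidecar manifest."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), mat.values)
    manifest = {
        "kind": mat.kind, "level": mat.level,
        "n_subjects_averaged": mat.n_subjects_averaged,
        "is_fisher_z": mat.is_fisher_z,
        "row_registry": mat.row_registry.tolist(),
        "col_registry": mat.col_registry.tolist(),
    }
    path.with_suffix(".json").write_text(json.dumps(manifest))


def load_matrix(path) -> ConnectivityMatrix:
    path = Path(path)
    values = np.load(path.with_suffix(".npy"))
    man = json.loads(path.with_suffix(".json").read_text())
    return ConnectivityMatrix(values=values, kind=man["kind"],
                              row_registry=np.asarray(man["row_registry"]),
                              col_registry=np.asarray(man["col_registry"]),
                              level=man["level"],
                              n_subjects_averaged=man["n_subjects_averaged"],
                              is_fisher_z=man["is_fisher_z"])
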