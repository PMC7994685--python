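"""NIfTI input/output and the shared image-grid / mask containers.

Every pipeline stage operates on a single common voxel grid (the working
grid; 4 mm isotropic in the reference analysis).  No resampling happens
inside the pipeline: series and masks must arrive pre-aligned.  Voxel
registries are deterministic — lexicographic by (i, j, k), 0-based — so
matrix rows/columns mean the same voxel in every run.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

logger = logging.getLogger(__name__)

PARITIES = ("control_first", "label_first")


class GridMismatchError(ValueError):
    """Image shapes/affines do not agree with the working grid."""


class FormatError(ValueError):
    """File content violates a structural precondition (e.g. not 4D)."""


@dataclass(frozen=True)
class ImageGrid:
    """A 3D voxel grid: shape, voxel size (mm) and voxel-to-world affine."""

    shape: tuple[int, int, int]
    voxel_size: tuple[float, float, float]
    affine: np.ndarray

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        vox = tuple(float(v) for v in self.voxel_size)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive ints, got {self.shape}")
        if len(vox) != 3 or any(v <= 0 for v in vox):
            raise ValueError(f"voxel_size must be 3 positive lengths, got {self.voxel_size}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4) or abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be an invertible 4x4 matrix")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size", vox)
        object.__setattr__(self, "affine", affine)

    @classmethod
    def isotropic(cls, shape, voxel_mm: float = 4.0) -> "ImageGrid":
        aff = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
        return cls(tuple(shape), (voxel_mm,) * 3, aff)

    def matches(self, other: "ImageGrid", atol: float = 1e-4) -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size, other.voxel_size, atol=atol)
            and np.allclose(self.affine, other.affine, atol=atol)
        )


@dataclass
class RawAslSeries:
    """4D interleaved control/label pCASL frames.

    ``parity`` states which frame comes first and is always declared by the
    caller, never inferred from the data.  ``tr`` is the per-frame repetition
    time in seconds (one member of a control-label pair); the effective
    perfusion sampling interval after surround subtraction is ``2 * tr``.
    """

    data: np.ndarray
    grid: ImageGrid
    tr: float
    parity: str

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise FormatError(f"series must be 4D, got {self.data.ndim}D")
        if self.data.shape[:3] != self.grid.shape:
            raise GridMismatchError(
                f"series spatial shape {self.data.shape[:3]} != grid {self.grid.shape}"
            )
        if self.n_frames < 3:
            raise ValueError(f"need >= 3 frames, got {self.n_frames}")
        if self.parity not in PARITIES:
            raise ValueError(f"parity must be one of {PARITIES}, got {self.parity!r}")
        if self.tr <= 0:
            raise ValueError("tr must be positive")
        _check_finite(self.data, "series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]


def _check_finite(arr: np.ndarray, what: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = tuple(int(i) for i in np.argwhere(bad)[0])
        raise ValueError(f"{what} contains non-finite value at index {idx}")


def _index_of(mask: np.ndarray) -> np.ndarray:
    """Deterministic voxel registry: (N,3) int array, lexicographic (i,j,k)."""
    return np.argwhere(mask)  # C-order argwhere is lexicographic


@dataclass
class MaskSet:
    """Target-ROI / gray-matter / nuisance masks sharing one grid.

    Invariants: roi ⊆ gm, roi ∩ nuisance = ∅, n >= 2 ROI voxels and
    m − n >= 2 non-ROI gray-matter voxels.
    """

    roi: np.ndarray
    gm: np.ndarray
    nuisance: np.ndarray
    grid: ImageGrid
    roi_index: np.ndarray = field(init=False)
    gm_index: np.ndarray = field(init=False)
    gm_minus_roi_index: np.ndarray = field(init=False)
    nuisance_index: np.ndarray = field(init=False)

    def __post_init__(self):
        for name in ("roi", "gm", "nuisance"):
            arr = np.asarray(getattr(self, name))
            if arr.shape != self.grid.shape:
                raise GridMismatchError(
                    f"{name} mask shape {arr.shape} != grid shape {self.grid.shape}"
                )
            setattr(self, name, arr.astype(bool))
        dropped = int(np.count_nonzero(self.roi & ~self.gm))
        if dropped:
            logger.info("dropping %d ROI voxels outside gray matter", dropped)
            self.roi = self.roi & self.gm
        overlap = int(np.count_nonzero(self.roi & self.nuisance))
        if overlap:
            logger.warning("removing %d ROI voxels from nuisance mask", overlap)
            self.nuisance = self.nuisance & ~self.roi
        if np.count_nonzero(self.roi) == 0:
            raise ValueError("ROI is empty after intersection with gray matter")
        if np.count_nonzero(self.roi) < 2:
            raise ValueError("ROI must contain at least 2 voxels")
        if np.count_nonzero(self.gm & ~self.roi) < 2:
            raise ValueError("need at least 2 gray-matter voxels outside the ROI")
        self.roi_index = _index_of(self.roi)
        self.gm_index = _index_of(self.gm)
        self.gm_minus_roi_index = _index_of(self.gm & ~self.roi)
        self.nuisance_index = _index_of(self.nuisance)

    @property
    def n_roi(self) -> int:
        return len(self.roi_index)

    @property
    def n_gm(self) -> int:
        return len(self.gm_index)


def _grid_from_img(img) -> ImageGrid:
    zooms = img.header.get_zooms()[:3]
    return ImageGrid(tuple(img.shape[:3]), tuple(float(z) for z in zooms),
                     np.asarray(img.affine, dtype=float))


def read_series(path, parity: str, tr: float | None = None) -> RawAslSeries:
    """Load a 4D NIfTI as a raw interleaved series.

    ``tr`` defaults to the header's 4th zoom when present and positive.
    """
    img = nib.load(str(path))
    if img.ndim != 4:
        raise FormatError(f"{path}: expected a 4D image, got {img.ndim}D")
    data = np.asarray(img.get_fdata(), dtype=float)
    _check_finite(data, f"{path}")
    if tr is None:
        zooms = img.header.get_zooms()
        tr = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 1.0
    return RawAslSeries(data=data, grid=_grid_from_img(img), tr=tr, parity=parity)


def read_mask(path, grid: ImageGrid) -> np.ndarray:
    """Load a 3D mask, binarize at >0.5, check grid compatibility."""
    img = nib.load(str(path))
    if img.ndim != 3:
        raise FormatError(f"{path}: expected a 3D mask, got {img.ndim}D")
    g = _grid_from_img(img)
    if g.shape != grid.shape:
        raise GridMismatchError(f"{path}: mask shape {g.shape} != grid shape {grid.shape}")
    return np.asarray(img.get_fdata()) > 0.5


def read_masks(roi_path, gm_path, nuisance_path, grid: ImageGrid) -> MaskSet:
    roi = read_mask(roi_path, grid)
    gm = read_mask(gm_path, grid)
    nuisance = read_mask(nuisance_path, grid)
    return MaskSet(roi=roi, gm=gm, nuisance=nuisance, grid=grid)


def _nifti_header(grid: ImageGrid, tr: float | None = None):
    hdr = nib.Nifti1Header()
    if tr is not None:
        hdr.set_zooms(tuple(grid.voxel_size) + (tr,))
    return hdr


def write_series(series: RawAslSeries, path) -> None:
    """Write a 4D series as float32 NIfTI-1, preserving the grid affine."""
    _check_finite(series.data, "series")
    img = nib.Nifti1Image(series.data.astype(np.float32), series.grid.affine)
    img.header.set_zooms(tuple(series.grid.voxel_size) + (series.tr,))
    nib.save(img, str(path))


def write_map(arr: np.ndarray, grid: ImageGrid, path) -> None:
    """Write a 3D map; integer arrays (label maps) stored int16, else float32."""
    arr = np.asarray(arr)
    if arr.shape != grid.shape:
        raise GridMismatchError(f"map shape {arr.shape} != grid shape {grid.shape}")
    _check_finite(arr.astype(float), "map")
    dtype = np.int16 if np.issubdtype(arr.dtype, np.integer) else np.float32
    img = nib.Nifti1Image(arr.astype(dtype), grid.affine)
    img.header.set_zooms(tuple(grid.voxel_size))
    nib.save(img, str(path))


def labels_to_volume(labels: np.ndarray, index: np.ndarray, grid: ImageGrid,
                     background: int = 0) -> np.ndarray:
    """Scatter per-voxel labels (registry order) into a 3D int volume."""
    vol = np.full(grid.shape, background, dtype=np.int16)
    vol[tuple(index.T)] = labels
    return vol
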