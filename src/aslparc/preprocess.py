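"""Raw interleaved series -> denoised perfusion-weighted (dM) series.

Three stages, applied in fixed order: surround subtraction, isotropic
Gaussian smoothing (FWHM in mm), and CompCor-style nuisance regression
(components extracted from a combined WM/CSF ROI and regressed out of every
voxel).  No temporal band-pass is applied by default: paired control-label
subtraction already cancels slow instrument drift (any temporally linear
additive term cancels exactly), which is one of the modality's selling
points.  An optional band-pass is available behind a flag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy import signal as sps

from .io import ImageGrid, MaskSet, RawAslSeries, _check_finite

__all__ = [
    "DeltaMSeries", "NuisanceBasis", "PreprocessParams",
    "surround_subtract", "smooth", "extract_nuisance_basis",
    "regress_nuisance", "bandpass", "preprocess_subject",
]

FWHM_TO_SIGMA = 1.0 / np.sqrt(8.0 * np.log(2.0))   # sigma = fwhm / 2.3548


@dataclass
class DeltaMSeries:
    """Perfusion-weighted series: one volume per usable label frame.

    ``dt_s`` is the effective sampling interval (2 x frame TR).
    ``provenance`` is the ordered list of applied steps with parameters.
    """

    data: np.ndarray
    grid: ImageGrid
    dt_s: float
    provenance: list = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("dM series must be 4D")
        _check_finite(self.data, "dM series")

    @property
    def n_frames(self) -> int:
        return self.data.shape[3]

    def _with(self, data, step: dict) -> "DeltaMSeries":
        return DeltaMSeries(data=data, grid=self.grid, dt_s=self.dt_s,
                            provenance=self.provenance + [step])


@dataclass
class NuisanceBasis:
    """r nuisance time courses: zero-mean, unit-norm rows, ordered by
    explained variance (PCA: singular value; ICA: back-projected variance)."""

    components: np.ndarray
    method: str
    r: int

    def __post_init__(self):
        self.components = np.atleast_2d(np.asarray(self.components, dtype=float))
        if self.r < 1 or self.components.shape[0] != self.r:
            raise ValueError("need r >= 1 component rows")


def surround_subtract(raw: RawAslSeries) -> DeltaMSeries:
    """dM(tau) = (c(tau-1) + c(tau+1)) / 2 - l(tau) for each interior label.

    Each labeled frame is subtracted from the mean of its flanking control
    frames; labels lacking both neighbors are dropped.  Sign convention:
    dM >= 0 in perfused tissue (label < control).  Cancels any temporally
    linear additive signal exactly.
    """
    t = raw.n_frames
    first_label = 1 if raw.parity == "control_first" else 0
    label_idx = np.arange(first_label, t, 2)
    label_idx = label_idx[(label_idx - 1 >= 0) & (label_idx + 1 <= t - 1)]
    if len(label_idx) == 0:
        raise ValueError("no label frame has both control neighbors")
    ctrl = raw.data
    dm = 0.5 * (ctrl[..., label_idx - 1] + ctrl[..., label_idx + 1]) - ctrl[..., label_idx]
    step = {"step": "surround_subtract", "parity": raw.parity,
            "n_labels": int(len(label_idx)), "tr_s": raw.tr}
    return DeltaMSeries(data=dm, grid=raw.grid, dt_s=2.0 * raw.tr, provenance=[step])


def smooth(dm: DeltaMSeries, fwhm_mm: float = 5.0) -> DeltaMSeries:
    """Convolve each volume with an isotropic Gaussian of the given FWHM.

    sigma_mm = fwhm / sqrt(8 ln 2); per-axis sigma in voxels divides by the
    voxel size.  Edge mode is nearest-neighbour replication so constant
    volumes stay constant and the spatial mean is preserved.  fwhm 0 is the
    identity.
    """
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be >= 0")
    step = {"step": "smooth", "fwhm_mm": float(fwhm_mm)}
    if fwhm_mm == 0:
        return dm._with(dm.data.copy(), step)
    sigma_vox = [fwhm_mm * FWHM_TO_SIGMA / v for v in dm.grid.voxel_size]
    out = ndimage.gaussian_filter(dm.data, sigma=sigma_vox + [0.0], mode="nearest")
    return dm._with(out, step)


def extract_nuisance_basis(dm: DeltaMSeries, masks: MaskSet, r: int = 5,
                           method: str = "pca", seed: int = 0) -> NuisanceBasis:
    """CompCor basis from the WM/CSF nuisance ROI.

    The voxel x time matrix is row-demeaned; ``pca`` keeps the top-r right
    singular vectors (ordered by singular value), ``ica`` runs a fixed-seed
    FastICA and orders the r sources by the variance their back-projection
    explains.  Rows are standardized to zero mean and unit norm.
    """
    if len(masks.nuisance_index) == 0:
        raise ValueError("nuisance ROI is empty")
    if r < 1:
        raise ValueError("r must be >= 1")
    if r >= dm.n_frames:
        raise ValueError(f"r={r} must be < number of dM frames {dm.n_frames}")
    X = dm.data[tuple(masks.nuisance_index.T)]          # voxels x time
    X = X - X.mean(axis=1, keepdims=True)
    if method == "pca":
        _, s, vt = np.linalg.svd(X, full_matrices=False)
        comps = vt[:r]
    elif method == "ica":
        from sklearn.decomposition import FastICA
        ica = FastICA(n_components=r, random_state=seed, max_iter=1000, tol=1e-4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            sources = ica.fit_transform(X.T)            # time x r
        # order by back-projected variance: ||col of mixing||^2 * var(source)
        ev = (ica.mixing_ ** 2).sum(axis=0) * sources.var(axis=0)
        comps = sources.T[np.argsort(ev)[::-1]]
    else:
        raise ValueError(f"unknown method {method!r}")
    comps = comps - comps.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(comps, axis=1, keepdims=True)
    if (norms == 0).any():
        raise ValueError("degenerate (all-zero) nuisance component")
    return NuisanceBasis(components=comps / norms, method=method, r=r)


def regress_nuisance(dm: DeltaMSeries, basis: NuisanceBasis) -> DeltaMSeries:
    """OLS-residualize every voxel series on [intercept + components].

    The result is orthogonal to every component; applying the operation
    twice equals applying it once (projection).
    """
    t = dm.n_frames
    if basis.components.shape[1] != t:
        raise ValueError("basis length does not match dM series")
    design = np.column_stack([np.ones(t), basis.components.T])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("rank-deficient nuisance design matrix")
    Y = dm.data.reshape(-1, t).T                        # time x voxels
    beta, *_ = np.linalg.lstsq(design, Y, rcond=None)
    resid = Y - design @ beta
    out = resid.T.reshape(dm.data.shape)
    step = {"step": "compcor", "r": basis.r, "method": basis.method}
    return dm._with(out, step)


def bandpass(dm: DeltaMSeries, lo_hz: float, hi_hz: float, order: int = 4) -> DeltaMSeries:
    """Optional zero-phase Butterworth band-pass over time (off by default
    in the pipeline; paired subtraction already removes drift)."""
    nyq = 0.5 / dm.dt_s
    lo, hi = max(lo_hz / nyq, 1e-6), min(hi_hz / nyq, 1 - 1e-6)
    sos = sps.butter(order, [lo, hi], btype="bandpass", output="sos")
    out = sps.sosfiltfilt(sos, dm.data, axis=-1)
    return dm._with(np.ascontiguousarray(out),
                    {"step": "bandpass", "lo_hz": lo_hz, "hi_hz": hi_hz})


@dataclass
class PreprocessParams:
    fwhm_mm: float = 5.0
    compcor_r: int = 5
    compcor_method: str = "pca"
    band_hz: tuple[float, float] | None = None
    seed: int = 0


def preprocess_subject(raw: RawAslSeries, masks: MaskSet,
                       params: PreprocessParams | None = None) -> DeltaMSeries:
    """Fixed-order pipeline: subtract -> smooth -> CompCor [-> band-pass]."""
    params = params or PreprocessParams()
    dm = surround_subtract(raw)
    dm = smooth(dm, params.fwhm_mm)
    if params.compcor_r > 0:
        basis = extract_nuisance_basis(dm, masks, r=params.compcor_r,
                                       method=params.compcor_method, seed=params.seed)
        dm = regress_nuisance(dm, basis)
    if params.band_hz is not None:
        dm = bandpass(dm, *params.band_hz)
    return dm
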