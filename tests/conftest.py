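import numpy as np
import pytest

from aslparc.connectivity import correlate_extrinsic, correlate_intrinsic
from aslparc.io import ImageGrid, MaskSet, RawAslSeries
from aslparc.preprocess import preprocess_subject
from aslparc.simulate import SimConfig, make_masks, simulate_subject


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=1)


@pytest.fixture(scope="session")
def default_masks(default_cfg):
    masks, truth = make_masks(default_cfg)
    return masks, truth


@pytest.fixture(scope="session")
def small_cfg():
    """Short-scan cohort for fast unit tests."""
    return SimConfig(n_subjects=3, n_sessions=1, n_frames=80, seed=3)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    """(cfg, masks, truth, dms): preprocessed dM series of 3 short subjects."""
    masks, truth = make_masks(small_cfg)
    dms = [preprocess_subject(simulate_subject(small_cfg, s, 0, masks, truth), masks)
           for s in range(small_cfg.n_subjects)]
    return small_cfg, masks, truth, dms


@pytest.fixture(scope="session")
def small_matrices(small_cohort):
    cfg, masks, truth, dms = small_cohort
    ext = [correlate_extrinsic(dm, masks) for dm in dms]
    intr = [correlate_intrinsic(dm, masks) for dm in dms]
    return ext, intr


@pytest.fixture(scope="session")
def tiny_grid():
    return ImageGrid.isotropic((6, 5, 4), 4.0)


@pytest.fixture(scope="session")
def tiny_masks(tiny_grid):
    """Hand-built minimal MaskSet on a 6x5x4 grid."""
    roi = np.zeros(tiny_grid.shape, bool)
    roi[1:3, 1:3, 1:3] = True
    gm = np.zeros(tiny_grid.shape, bool)
    gm[0:5, 0:4, 0:4] = True
    nuis = np.zeros(tiny_grid.shape, bool)
    nuis[5, :, :] = True
    return MaskSet(roi=roi, gm=gm, nuisance=nuis, grid=tiny_grid)


def series_from_frames(frames, grid=None, tr=3.9, parity="control_first"):
    """Build a RawAslSeries whose every voxel shows the given 1D frame values."""
    frames = np.asarray(frames, float)
    if grid is None:
        grid = ImageGrid.isotropic((2, 2, 2), 4.0)
    data = np.broadcast_to(frames, grid.shape + frames.shape).copy()
    return RawAslSeries(data=data, grid=grid, tr=tr, parity=parity)
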