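"""Synthetic multi-subject pCASL cohorts with planted parcellation structure.

The generator emulates the acquisition the pipeline is built for: a ~20 min
resting pCASL scan (300 interleaved control/label frames at TR = 3.9 s) on a
4 mm isotropic grid, with a block-shaped target ROI partitioned into
``k_true`` sub-blocks.  Each sub-block shares a band-limited (0.01-0.10 Hz)
latent network signal with one dedicated non-ROI gray-matter target blob, so
connectivity-based parcellation has a known ground truth to recover.  On top
of the perfusion signal the raw frames carry slow polynomial scanner drift,
a global physiological nuisance series present throughout brain tissue, and
i.i.d. thermal noise.

Signal model (per voxel v, frame t):

    control  c(v,t) = M0(v) + d_s(t) + g(t)·1[v in gm ∪ nuisance] + eps
    label    l(v,t) = c(v,t) − dM(v,t)

with dM(v,t) = P(v)·(1 + A·a_j·S_j(t)) for ROI voxels of planted cluster j
and for the paired target blob, P(v) for other perfused tissue, 0 outside;
S_j are independent unit-variance band-limited series, A the fractional
network amplitude and a_j an optional per-cluster scale.

All randomness is drawn from streams keyed by (seed, subject, session), so
any subject/session is reproducible independently of generation order.
Session 2 redraws everything stochastic (signals, drift, nuisance, noise)
but reuses the planted labels, geometry and per-subject amplitude traits.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import signal as sps

from .io import ImageGrid, MaskSet, RawAslSeries, write_map, write_series

__all__ = [
    "SimConfig", "GroundTruth", "ConfigurationError",
    "make_masks", "simulate_subject", "simulate_cohort", "Cohort",
]


class ConfigurationError(ValueError):
    """Simulation geometry or parameters are infeasible."""


@dataclass
class SimConfig:
    """Study-condition parameters for the synthetic cohort.

    Defaults mirror the reference acquisition: n=20 subjects, two sessions,
    300 frames at TR=3.9 s on a 20x20x10 grid of 4 mm voxels, ROI of
    8x8x4=256 voxels split into ``k_true`` planted clusters.
    """

    grid_shape: tuple[int, int, int] = (20, 20, 10)
    voxel_mm: float = 4.0
    n_subjects: int = 20
    n_sessions: int = 2
    n_frames: int = 300
    tr_s: float = 3.9
    parity: str = "control_first"
    k_true: int = 2
    n_targets: int | None = None          # defaults to k_true
    network_band_hz: tuple[float, float] = (0.01, 0.10)
    perfusion_baseline: float = 60.0      # mean dM amplitude, a.u.
    network_amplitude: float = 0.15       # fractional dM modulation
    drift_coeffs: tuple[float, float] = (20.0, 10.0)  # linear, quadratic sd (a.u.)
    nuisance_amplitude: float = 20.0      # global physiological series sd (a.u.)
    noise_sd: float = 15.0                # thermal noise sd (a.u.)
    subject_variability: float = 0.1      # sd of per-subject amplitude jitter
    m0_brain: float = 1000.0              # static tissue signal, a.u.
    m0_background: float = 100.0
    wm_perfusion_fraction: float = 0.3    # nuisance-ROI perfusion vs GM baseline
    # per-cluster angular spread (deg) of the internal rostral-caudal
    # connectivity gradient (cycled over clusters; 0 = homogeneous blocks)
    intra_gradient_deg: tuple[float, ...] = (60.0, 40.0)
    cluster_amplitude_scale: tuple[float, ...] | None = None
    cluster_lag_frames: tuple[int, ...] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.n_targets is None:
            self.n_targets = self.k_true
        if self.k_true < 1:
            raise ConfigurationError("k_true must be >= 1")
        if self.n_targets != self.k_true:
            raise ConfigurationError("n_targets must equal k_true")
        if not 0 <= self.network_amplitude < 1:
            raise ConfigurationError("network_amplitude must be in [0, 1)")
        if self.n_frames < 6 or self.n_frames % 2:
            raise ConfigurationError("n_frames must be even and >= 6")
        for attr in ("cluster_amplitude_scale", "cluster_lag_frames"):
            v = getattr(self, attr)
            if v is not None and len(v) != self.k_true:
                raise ConfigurationError(f"{attr} must have k_true entries")

    @property
    def grid(self) -> ImageGrid:
        return ImageGrid.isotropic(self.grid_shape, self.voxel_mm)


@dataclass
class GroundTruth:
    """Planted structure: per-ROI-voxel labels plus the latent series drawn
    for each (subject, session) during simulation."""

    labels_true: np.ndarray                       # (n_roi,), values 1..k_true
    target_labels: np.ndarray                     # 3D int volume, target blobs
    gradient_angle: np.ndarray | None = None      # (n_roi,) radians, intra-cluster
    network_signals: dict = field(default_factory=dict)   # (sub, ses) -> (k, t)
    sub_signals: dict = field(default_factory=dict)       # (sub, ses) -> (k, t)
    nuisance_signals: dict = field(default_factory=dict)  # (sub, ses) -> (t,)
    drifts: dict = field(default_factory=dict)            # (sub, ses) -> (t,)


# ----------------------------------------------------------------- geometry

_ROI_SHAPE = (8, 8, 4)
_TARGET_SHAPE = (3, 3, 3)


def _box(vol, origin, shape, value=True):
    sl = tuple(slice(o, o + s) for o, s in zip(origin, shape))
    vol[sl] = value
    return sl


def make_masks(cfg: SimConfig) -> tuple[MaskSet, GroundTruth]:
    """Build the ROI / gray-matter / nuisance geometry and planted labels.

    Layout on the default 20x20x10 grid: a WM/CSF nuisance slab in the two
    bottom slices, a gray-matter box above it, the ROI block centred in the
    box, and one 3x3x3 target blob per planted cluster placed in gray matter
    outside the ROI (south band, then north band).
    """
    nx, ny, nz = cfg.grid_shape
    if nx < 20 or ny < 20 or nz < 10:
        raise ConfigurationError(
            f"grid {cfg.grid_shape} too small to host ROI, targets and nuisance slab"
        )
    if cfg.k_true > 6:
        raise ConfigurationError("at most 6 planted clusters are supported")

    gm = np.zeros(cfg.grid_shape, dtype=bool)
    _box(gm, (2, 2, 3), (16, 16, 6))

    nuisance = np.zeros(cfg.grid_shape, dtype=bool)
    _box(nuisance, (2, 2, 0), (16, 16, 2))

    roi = np.zeros(cfg.grid_shape, dtype=bool)
    roi_origin = (6, 6, 4)
    _box(roi, roi_origin, _ROI_SHAPE)

    # planted labels: split ROI along x (medial-lateral analogue), then
    # subdivide each half along y (rostral-caudal analogue) for k_true > 2
    label_vol = np.zeros(cfg.grid_shape, dtype=np.int16)
    ox, oy, oz = roi_origin
    sx, sy, sz = _ROI_SHAPE
    if cfg.k_true == 1:
        label_vol[roi] = 1
    else:
        n_right = cfg.k_true // 2
        n_left = cfg.k_true - n_right
        next_label = 1
        for half, n_bands in (((ox, ox + sx // 2), n_left),
                              ((ox + sx // 2, ox + sx), n_right)):
            y_edges = np.linspace(oy, oy + sy, n_bands + 1).astype(int)
            for b in range(n_bands):
                label_vol[half[0]:half[1], y_edges[b]:y_edges[b + 1], oz:oz + sz] = next_label
                next_label += 1

    # target blobs in gm \ roi: south band (y=3) then north band (y=14)
    slots = [(3, 3, 4), (13, 3, 4), (8, 3, 4), (3, 14, 4), (13, 14, 4), (8, 14, 4)]
    target_vol = np.zeros(cfg.grid_shape, dtype=np.int16)
    for j in range(cfg.k_true):
        sl = tuple(slice(o, o + s) for o, s in zip(slots[j], _TARGET_SHAPE))
        if roi[sl].any() or not gm[sl].all():
            raise ConfigurationError("target blob placement infeasible")
        target_vol[sl] = j + 1

    masks = MaskSet(roi=roi, gm=gm, nuisance=nuisance, grid=cfg.grid)
    labels_true = label_vol[tuple(masks.roi_index.T)].astype(int)
    assert (labels_true >= 1).all()
    angle = _gradient_angles(labels_true, masks, cfg)
    return masks, GroundTruth(labels_true=labels_true, target_labels=target_vol,
                              gradient_angle=angle)


def _gradient_angles(labels_true: np.ndarray, masks: MaskSet,
                     cfg: SimConfig) -> np.ndarray:
    """Intra-cluster mixing angle per ROI voxel (radians).

    Real cortical areas are not internally homogeneous: connectivity drifts
    smoothly along secondary axes.  Each planted cluster therefore carries a
    linear gradient along y (the rostral-caudal analogue): a voxel's latent
    series is cos(a)*S_j + sin(a)*S'_j with a running from -spread/2 to
    +spread/2 across the cluster's y extent (S'_j a weak cluster-specific
    secondary signal).  Cluster boundaries stay sharp, so the primary
    partition remains unambiguous ground truth.
    """
    y = masks.roi_index[:, 1].astype(float)
    angle = np.zeros(masks.n_roi)
    spreads = cfg.intra_gradient_deg
    for j in np.unique(labels_true):
        sel = labels_true == j
        spread = np.deg2rad(spreads[(j - 1) % len(spreads)])
        yj = y[sel]
        span = yj.max() - yj.min()
        frac = (yj - yj.min()) / span - 0.5 if span > 0 else np.zeros(sel.sum())
        angle[sel] = spread * frac
    return angle


# ------------------------------------------------------------------ signals

def _rng(cfg: SimConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def band_limited_signals(rng, n_signals: int, n_frames: int, tr_s: float,
                         band_hz: tuple[float, float]) -> np.ndarray:
    """Unit-variance zero-mean Gaussian series band-limited to ``band_hz``.

    White Gaussian noise filtered forward-backward with a 4th-order
    Butterworth band-pass at the frame rate, then standardized.
    """
    fs = 1.0 / tr_s
    nyq = fs / 2.0
    lo = max(band_hz[0] / nyq, 1e-6)
    hi = min(band_hz[1] / nyq, 1 - 1e-6)
    sos = sps.butter(4, [lo, hi], btype="bandpass", output="sos")
    white = rng.standard_normal((n_signals, n_frames))
    out = sps.sosfiltfilt(sos, white, axis=1, padlen=min(n_frames - 1, 27))
    out = out - out.mean(axis=1, keepdims=True)
    sd = out.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return out / sd


def simulate_subject(cfg: SimConfig, subject_id: int, session_id: int = 0,
                     masks: MaskSet | None = None,
                     truth: GroundTruth | None = None) -> RawAslSeries:
    """Simulate one raw interleaved series for (subject, session).

    If ``truth`` is given, the latent series drawn here are recorded in it.
    Deterministic for a given (cfg.seed, subject_id, session_id).
    """
    if masks is None or truth is None:
        masks, truth_local = make_masks(cfg)
        if truth is None:
            truth = truth_local
    t = cfg.n_frames
    k = cfg.k_true

    trait_rng = _rng(cfg, 0, subject_id)          # subject traits: shared by sessions
    amp_jitter = 1.0 + cfg.subject_variability * trait_rng.standard_normal()
    baseline_s = cfg.perfusion_baseline * max(amp_jitter, 0.1)

    rng = _rng(cfg, 1, subject_id, session_id)    # session stream
    S = band_limited_signals(rng, k, t, cfg.tr_s, cfg.network_band_hz)
    S2 = band_limited_signals(rng, k, t, cfg.tr_s, cfg.network_band_hz)
    if cfg.cluster_lag_frames is not None:
        for j, lag in enumerate(cfg.cluster_lag_frames):
            S[j] = np.roll(S[j], int(lag))
    g = cfg.nuisance_amplitude * rng.standard_normal(t)
    u = np.linspace(-0.5, 0.5, t)
    c1 = rng.normal(0.0, cfg.drift_coeffs[0])
    c2 = rng.normal(0.0, cfg.drift_coeffs[1])
    drift = c1 * u + c2 * u ** 2

    truth.network_signals[(subject_id, session_id)] = S
    truth.sub_signals[(subject_id, session_id)] = S2
    truth.nuisance_signals[(subject_id, session_id)] = g
    truth.drifts[(subject_id, session_id)] = drift

    brain = masks.gm | masks.nuisance
    m0 = np.where(brain, cfg.m0_brain, cfg.m0_background)

    # perfusion map and per-voxel network assignment
    perf = np.zeros(cfg.grid_shape)
    perf[masks.gm] = baseline_s
    perf[masks.nuisance] = cfg.wm_perfusion_fraction * baseline_s
    net_idx = np.zeros(cfg.grid_shape, dtype=int)          # 0 = no network
    net_idx[tuple(masks.roi_index.T)] = truth.labels_true
    tgt = truth.target_labels > 0
    net_idx[tgt] = truth.target_labels[tgt]
    scales = np.ones(k + 1)
    if cfg.cluster_amplitude_scale is not None:
        scales[1:] = np.asarray(cfg.cluster_amplitude_scale, dtype=float)

    # dM(v, t) = perf(v) * (1 + A * scale_j * U_v(t)); target blobs carry the
    # pure cluster signal, ROI voxels the angular mixture of their cluster's
    # main and secondary signals (internal rostral-caudal gradient)
    mod = np.zeros((k + 1, t))
    for j in range(1, k + 1):
        mod[j] = cfg.network_amplitude * scales[j] * S[j - 1]
    dm_true = perf[..., None] * (1.0 + mod[net_idx])
    roi_ijk = tuple(masks.roi_index.T)
    ang = (truth.gradient_angle if truth.gradient_angle is not None
           else np.zeros(masks.n_roi))
    own = truth.labels_true - 1
    U = np.cos(ang)[:, None] * S[own] + np.sin(ang)[:, None] * S2[own]
    roi_scale = scales[truth.labels_true]
    dm_true[roi_ijk] = perf[roi_ijk][:, None] * (
        1.0 + cfg.network_amplitude * roi_scale[:, None] * U)

    data = np.empty(cfg.grid_shape + (t,))
    data[:] = m0[..., None] + drift[None, None, None, :]
    data += g[None, None, None, :] * brain[..., None]
    label_idx = np.arange(1 if cfg.parity == "control_first" else 0, t, 2)
    data[..., label_idx] -= dm_true[..., label_idx]
    if cfg.noise_sd > 0:
        data += cfg.noise_sd * rng.standard_normal(data.shape)

    return RawAslSeries(data=data, grid=cfg.grid, tr=cfg.tr_s, parity=cfg.parity)


@dataclass
class Cohort:
    """Lazy handle on a simulated cohort: masks + truth, series on demand."""

    cfg: SimConfig
    masks: MaskSet
    truth: GroundTruth

    def series(self, subject_id: int, session_id: int = 0) -> RawAslSeries:
        return simulate_subject(self.cfg, subject_id, session_id,
                                masks=self.masks, truth=self.truth)

    def iter_series(self, session_id: int = 0):
        for s in range(self.cfg.n_subjects):
            yield s, self.series(s, session_id)


def simulate_cohort(cfg: SimConfig, outdir=None) -> Cohort:
    """Build the cohort handle; optionally write the full NIfTI fixture set.

    Layout under ``outdir``: ``sub-XX_ses-Y_asl.nii.gz``,
    ``masks/{roi,gm,nuisance}.nii.gz``, ``truth/labels.nii.gz`` and a
    ``manifest.txt`` recording the configuration and seed.
    """
    masks, truth = make_masks(cfg)
    cohort = Cohort(cfg=cfg, masks=masks, truth=truth)
    if outdir is not None:
        outdir = Path(outdir)
        (outdir / "masks").mkdir(parents=True, exist_ok=True)
        (outdir / "truth").mkdir(parents=True, exist_ok=True)
        for name in ("roi", "gm", "nuisance"):
            write_map(getattr(masks, name).astype(np.int16), cfg.grid,
                      outdir / "masks" / f"{name}.nii.gz")
        from .io import labels_to_volume
        write_map(labels_to_volume(truth.labels_true, masks.roi_index, cfg.grid),
                  cfg.grid, outdir / "truth" / "labels.nii.gz")
        for ses in range(cfg.n_sessions):
            for sub in range(cfg.n_subjects):
                series = cohort.series(sub, ses)
                write_series(series, outdir / f"sub-{sub:02d}_ses-{ses + 1}_asl.nii.gz")
        with open(outdir / "manifest.txt", "w") as fh:
            for key, val in vars(cfg).items():
                fh.write(f"{key} = {val!r}\n")
    return cohort


def null_config(cfg: SimConfig) -> SimConfig:
    """Copy of ``cfg`` with the planted network signal switched off."""
    return replace(cfg, network_amplitude=0.0)
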