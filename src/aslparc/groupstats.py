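"""Cluster-wise whole-brain connectivity maps with sign-flip permutation
inference, plus two diagnostics (lag profile, variance contrast).

Per subject and cluster, each gray-matter voxel gets the mean Fisher-z
correlation with the cluster's ROI voxels (z first, then mean).  A
one-sample test on those subject maps uses the sign-flip permutation null:
each subject's whole map is randomly negated, the one-sample t is
recomputed, and p = (1 + #{perm >= obs}) / (n_perm + 1); when
2^n_subjects <= n_perm the flips are enumerated exactly (identity
included), giving exact p-values.

``contrast_clusters`` tests paired differences between two clusters' maps.
The "unique connectivity" masks threshold the group statistic at
z >= z_crit after converting t through the normal quantile of its CDF.
Because a whole gray-matter map is tested at once, the default inference
additionally controls the family-wise error over voxels with the
max-statistic permutation distribution (the standard voxelwise-corrected
rule for permutation inference on images), at the alpha implied by z_crit;
``correction="none"`` gives the plain voxelwise threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .connectivity import ATANH_CLIP, _pearson, voxel_timeseries
from .io import MaskSet
from .parcellation import Parcellation
from .preprocess import DeltaMSeries

__all__ = [
    "cluster_mean_connectivity", "seed_guard_selection",
    "permutation_one_sample", "PermutationResult",
    "contrast_clusters", "ContrastResult", "lag_profile", "LagResult",
    "variance_contrast",
]


def cluster_mean_connectivity(dm: DeltaMSeries, masks: MaskSet,
                              parc: Parcellation, cluster_id: int
                              ) -> tuple[np.ndarray, np.ndarray]:
    """Per-gray-matter-voxel mean Fisher-z connectivity to one cluster.

    Returns ``(zmap, in_cluster)``: a length-m vector over the gm registry
    and a boolean flag marking gm voxels that belong to the cluster itself
    (included in the map but typically excluded from display).
    """
    member = parc.labels == cluster_id
    if not member.any():
        raise ValueError(f"cluster {cluster_id} is empty")
    cluster_index = masks.roi_index[member]
    gm_ts = voxel_timeseries(dm, masks.gm_index)
    cl_ts = voxel_timeseries(dm, cluster_index)
    r, _, _ = _pearson(gm_ts, cl_ts)
    z = np.arctanh(np.clip(r, -ATANH_CLIP, ATANH_CLIP))
    zmap = z.mean(axis=1)
    gm_lin = np.ravel_multi_index(tuple(masks.gm_index.T), masks.grid.shape)
    cl_lin = np.ravel_multi_index(tuple(cluster_index.T), masks.grid.shape)
    in_cluster = np.isin(gm_lin, cl_lin)
    return zmap, in_cluster


def seed_guard_selection(masks: MaskSet, guard_vox: int = 2) -> np.ndarray:
    """Boolean selector over the gm registry keeping voxels outside the ROI
    and a guard zone around it.

    Spatial smoothing mixes noise between adjacent voxels, so gray matter
    immediately bordering a cluster genuinely correlates with it in every
    subject; contrasting cluster connectivity there reports kernel leakage,
    not networks.  Excluding the seed vicinity (dilation by the kernel
    support, ~FWHM) is the usual remedy in seed-based connectivity.
    """
    from scipy.ndimage import binary_dilation
    dilated = binary_dilation(masks.roi, iterations=guard_vox) if guard_vox > 0 \
        else masks.roi
    return ~dilated[tuple(masks.gm_index.T)]


def _tstat(maps: np.ndarray) -> np.ndarray:
    """One-sample t per voxel (subjects on axis 0)."""
    s = maps.shape[0]
    mean = maps.mean(axis=0)
    sd = maps.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(s)), 0.0)
    return t


def _sign_flips(n_subjects: int, n_perm: int, seed) -> tuple[np.ndarray, bool]:
    """(flips, exact): all 2^n patterns when feasible, else random draws
    (identity pattern always included first)."""
    if 2 ** n_subjects <= n_perm:
        bits = np.arange(2 ** n_subjects)[:, None] >> np.arange(n_subjects)[None, :]
        return 1.0 - 2.0 * (bits & 1), True
    rng = np.random.default_rng(seed)
    flips = rng.choice([-1.0, 1.0], size=(n_perm, n_subjects))
    flips[0] = 1.0
    return flips, False


def _perm_t(maps: np.ndarray, flips: np.ndarray) -> np.ndarray:
    """t-statistics for every sign-flip row (flips x voxels), using the
    flip-invariance of the per-voxel sum of squares."""
    s, v = maps.shape
    sumsq = (maps ** 2).sum(axis=0)
    mean_f = flips @ maps / s
    var_f = (sumsq[None, :] - s * mean_f ** 2) / (s - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var_f > 0, mean_f / np.sqrt(var_f / s), 0.0)
    return t


@dataclass
class PermutationResult:
    t: np.ndarray                 # observed one-sample t per voxel
    p: np.ndarray                 # one-sided (greater) permutation p
    exact: bool
    n_perm: int
    null_max: np.ndarray          # per-permutation max t over voxels


def permutation_one_sample(maps: np.ndarray, n_perm: int = 5000,
                           seed=None) -> PermutationResult:
    """One-sample sign-flip permutation test, alternative mean > 0.

    ``maps`` is subjects x voxels.  Exact enumeration when
    2^n_subjects <= n_perm; otherwise Monte Carlo with
    p = (1 + #{perm >= obs}) / (n_perm + 1), so the smallest achievable
    p is 1 / (n_perm + 1) and the identity flip is always counted.
    """
    maps = np.atleast_2d(np.asarray(maps, dtype=float))
    s = maps.shape[0]
    if s < 2:
        raise ValueError("need at least 2 subjects")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t_obs = _tstat(maps)
    flips, exact = _sign_flips(s, n_perm, seed)
    t_null = _perm_t(maps, flips)
    ge = (t_null >= t_obs[None, :] - 1e-12).sum(axis=0)
    if exact:
        p = ge / flips.shape[0]
    else:
        # identity row reproduces t_obs; the +1/(n+1) convention counts it once
        p = (1.0 + (ge - 1)) / (n_perm + 1.0)
    return PermutationResult(t=t_obs, p=p, exact=exact, n_perm=flips.shape[0],
                             null_max=t_null.max(axis=1))


def t_to_z(t: np.ndarray, df: int) -> np.ndarray:
    """Map t to the standard-normal quantile of its CDF (sf-based for
    positive-tail precision)."""
    t = np.asarray(t, dtype=float)
    z = np.empty_like(t)
    pos = t >= 0
    z[pos] = stats.norm.isf(stats.t.sf(t[pos], df))
    z[~pos] = stats.norm.ppf(stats.t.cdf(t[~pos], df))
    return z


@dataclass
class ContrastResult:
    z_a: np.ndarray               # group z for A - B
    z_b: np.ndarray               # group z for B - A  (= -z_a)
    mask_a: np.ndarray            # voxels uniquely connected to cluster A
    mask_b: np.ndarray
    fwe_p_a: np.ndarray | None
    fwe_p_b: np.ndarray | None
    z_crit: float
    correction: str


def contrast_clusters(maps_a: np.ndarray, maps_b: np.ndarray,
                      z_crit: float = 2.3, n_perm: int = 5000, seed=None,
                      correction: str = "maxstat") -> ContrastResult:
    """Unique-connectivity masks from paired cluster-map differences.

    Sign-flip permutation on the per-subject differences d = A - B (both
    tails come from the same flips).  A voxel is "unique to A" when its
    z(A-B) >= z_crit — and, under the default max-statistic correction,
    its family-wise-corrected permutation p is below the one-sided alpha
    implied by z_crit.  The two masks are disjoint by construction.
    """
    maps_a = np.atleast_2d(np.asarray(maps_a, dtype=float))
    maps_b = np.atleast_2d(np.asarray(maps_b, dtype=float))
    if maps_a.shape != maps_b.shape:
        raise ValueError("cluster map stacks differ in shape")
    if correction not in ("maxstat", "none"):
        raise ValueError(f"unknown correction {correction!r}")
    d = maps_a - maps_b
    s, v = d.shape
    if s < 2:
        raise ValueError("need at least 2 subjects")
    t_obs = _tstat(d)
    z_a = t_to_z(t_obs, s - 1)
    z_b = -z_a
    mask_a = z_a >= z_crit
    mask_b = z_b >= z_crit
    fwe_a = fwe_b = None
    if correction == "maxstat":
        flips, exact = _sign_flips(s, n_perm, seed)
        t_null = _perm_t(d, flips)
        max_pos = t_null.max(axis=1)       # null max over voxels, A side
        max_neg = (-t_null).max(axis=1)    # B side (same flips)
        n_eff = flips.shape[0]
        ge_a = (max_pos[:, None] >= t_obs[None, :] - 1e-12).sum(axis=0)
        ge_b = (max_neg[:, None] >= -t_obs[None, :] - 1e-12).sum(axis=0)
        if exact:
            fwe_a, fwe_b = ge_a / n_eff, ge_b / n_eff
        else:
            fwe_a = (1.0 + ge_a - 1) / (n_perm + 1.0)
            fwe_b = (1.0 + ge_b - 1) / (n_perm + 1.0)
        alpha = float(stats.norm.sf(z_crit))
        mask_a &= fwe_a <= alpha
        mask_b &= fwe_b <= alpha
    return ContrastResult(z_a=z_a, z_b=z_b, mask_a=mask_a, mask_b=mask_b,
                          fwe_p_a=fwe_a, fwe_p_b=fwe_b, z_crit=z_crit,
                          correction=correction)


@dataclass
class LagResult:
    lags: np.ndarray
    xcorr: np.ndarray
    best_lag: int
    best_r: float
    time_shifted: bool            # best lag non-zero with > 0.1 gain over lag 0


def lag_profile(series_a: np.ndarray, series_b: np.ndarray,
                max_lag: int) -> LagResult:
    """Normalized cross-correlation of two mean cluster series by lag.

    r(lag) is the Pearson correlation between a(t) and b(t + lag) on the
    overlapping samples.  A "time-shifted relationship" is flagged when the
    best lag is non-zero and improves on lag 0 by more than 0.1.
    """
    a = np.asarray(series_a, dtype=float).ravel()
    b = np.asarray(series_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("series differ in length")
    if len(a) <= 2 * max_lag or max_lag < 0:
        raise ValueError("series too short for requested max_lag")
    lags = np.arange(-max_lag, max_lag + 1)
    xcorr = np.empty(len(lags))
    for i, lag in enumerate(lags):
        if lag >= 0:
            x, y = a[: len(a) - lag], b[lag:]
        else:
            x, y = a[-lag:], b[: len(b) + lag]
        xcorr[i] = np.corrcoef(x, y)[0, 1] if x.std() > 0 and y.std() > 0 else 0.0
    best = int(np.argmax(xcorr))
    best_lag = int(lags[best])
    r0 = float(xcorr[max_lag])
    shifted = best_lag != 0 and xcorr[best] - r0 > 0.1
    return LagResult(lags=lags, xcorr=xcorr, best_lag=best_lag,
                     best_r=float(xcorr[best]), time_shifted=shifted)


def variance_contrast(dms: list[DeltaMSeries], masks: MaskSet,
                      parc: Parcellation, cluster_ids=(1, 2)
                      ) -> tuple[np.ndarray, np.ndarray, float]:
    """Per-subject mean temporal dM variance in two clusters, compared with
    a paired Wilcoxon signed-rank test.  Returns (var_a, var_b, p)."""
    ca, cb = cluster_ids
    idx_a = masks.roi_index[parc.labels == ca]
    idx_b = masks.roi_index[parc.labels == cb]
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValueError("empty cluster in variance contrast")
    var_a, var_b = [], []
    for dm in dms:
        va = voxel_timeseries(dm, idx_a).var(axis=1, ddof=1).mean()
        vb = voxel_timeseries(dm, idx_b).var(axis=1, ddof=1).mean()
        var_a.append(va)
        var_b.append(vb)
    var_a, var_b = np.asarray(var_a), np.asarray(var_b)
    if len(dms) < 6:
        warnings.warn("variance contrast with < 6 subjects is underpowered")
    diffs = var_a - var_b
    if np.allclose(diffs, 0.0):
        return var_a, var_b, 1.0
    p = float(stats.wilcoxon(var_a, var_b, zero_method="wilcox").pvalue)
    return var_a, var_b, p
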