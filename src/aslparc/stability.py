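"""Split-half stability (variation of information) and between-session
reproducibility of parcellations.

The cohort is randomly bifurcated into two half-groups many times; each half
is averaged and clustered independently at every k, and the two half
parcellations are compared with the variation of information (VI), an
information-theoretic metric on partitions:

    VI(A, B) = H(A) + H(B) - 2 I(A; B)      [bits]

Mean VI per k typically grows logarithmically with k; an OLS fit of
mean VI on ln(k) summarizes that growth.  Between-session reproducibility
is the percentage of ROI voxels keeping the same (alignment-matched)
cluster across two sessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import ConnectivityMatrix, group_average
from .parcellation import (DEFAULT_SEED, Parcellation, align_labels,
                           features_from_matrix, kmeans_parcellate)

__all__ = [
    "variation_of_information", "SplitPlan", "VIResult", "split_half_vi",
    "fit_log_growth", "session_agreement",
]


def variation_of_information(a, b) -> float:
    """VI between two labelings of the same items, in bits.

    Computed from the joint contingency table with p(i,j) = n_ij / n and
    the convention 0 * log 0 = 0.  VI is a true metric on partitions.
    """
    a = np.asarray(a).ravel()
    b = np.asarray(b).ravel()
    if a.shape != b.shape:
        raise ValueError("labelings differ in length")
    if a.size == 0:
        raise ValueError("empty labelings")
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    joint = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb)
    p = joint / a.size
    pa = p.sum(axis=1)
    pb = p.sum(axis=0)
    def entropy(q):
        q = q[q > 0]
        return float(-(q * np.log2(q)).sum())
    h_joint = entropy(p.ravel())
    vi = 2.0 * h_joint - entropy(pa) - entropy(pb)   # H(A|B) + H(B|A)
    return 0.0 if vi < 1e-12 else vi                 # snap rounding residue


@dataclass
class SplitPlan:
    """Seeded plan of random cohort bifurcations (half/half, sizes within 1)."""

    repetitions: int = 100
    seed: int = 0
    splits: list = field(default_factory=list)   # list of (ids_a, ids_b)

    def generate(self, subject_ids) -> "SplitPlan":
        ids = np.asarray(list(subject_ids))
        if len(ids) < 2:
            raise ValueError("need at least 2 subjects to bifurcate")
        rng = np.random.default_rng(self.seed)
        half = (len(ids) + 1) // 2
        self.splits = []
        for _ in range(self.repetitions):
            perm = rng.permutation(ids)
            self.splits.append((np.sort(perm[:half]), np.sort(perm[half:])))
        return self


@dataclass
class VIResult:
    per_k: dict                   # k -> list of VI values (bits)
    mean_vi: dict                 # k -> mean bits
    sd_vi: dict                   # k -> sd bits
    fit: tuple                    # (a, b, r_squared) of mean_vi = a + b ln k


def split_half_vi(subject_mats: list[ConnectivityMatrix], k_list=(2, 3, 4, 6, 8),
                  plan: SplitPlan | None = None, kmeans_seed: int = DEFAULT_SEED,
                  n_init: int = 50) -> VIResult:
    """Mean split-half VI per k over the plan's random bifurcations.

    Each half-cohort is re-averaged from the subject-level matrices and
    re-clustered; both halves of a repetition share that repetition's
    k-means seed so that identical half-group matrices always give VI = 0
    and VI reflects data variation only.
    """
    k_list = list(k_list)
    if not k_list:
        raise ValueError("empty k list")
    if plan is None:
        plan = SplitPlan(repetitions=100, seed=0)
    if not plan.splits:
        plan.generate(range(len(subject_mats)))
    per_k: dict[int, list[float]] = {k: [] for k in k_list}
    for rep, (ids_a, ids_b) in enumerate(plan.splits):
        halves = []
        for h, ids in enumerate((ids_a, ids_b)):
            mean = group_average([subject_mats[i] for i in ids])
            feats = features_from_matrix(mean)
            halves.append((feats, h))
        for k in k_list:
            parcs = [
                kmeans_parcellate(feats, k, seed=kmeans_seed + 1000 * rep,
                                  n_init=n_init, source=subject_mats[0].kind)
                for feats, h in halves
            ]
            per_k[k].append(variation_of_information(parcs[0].labels, parcs[1].labels))
    mean_vi = {k: float(np.mean(v)) for k, v in per_k.items()}
    sd_vi = {k: float(np.std(v, ddof=1)) if len(v) > 1 else 0.0 for k, v in per_k.items()}
    fit = fit_log_growth(mean_vi) if len(mean_vi) >= 3 else (np.nan, np.nan, np.nan)
    return VIResult(per_k=per_k, mean_vi=mean_vi, sd_vi=sd_vi, fit=fit)


def fit_log_growth(mean_vi: dict) -> tuple[float, float, float]:
    """OLS fit mean_vi = a + b ln(k); returns (a, b, r_squared).

    A zero-variance target is fit perfectly by the constant, so its
    r_squared is defined as 1.
    """
    ks = sorted(mean_vi)
    if len(ks) < 3:
        raise ValueError("need at least 3 distinct k")
    x = np.log(np.asarray(ks, dtype=float))
    y = np.asarray([mean_vi[k] for k in ks], dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 if ss_tot == 0 else 1.0 - float((resid ** 2).sum()) / ss_tot
    return float(beta[0]), float(beta[1]), r2


def session_agreement(p1: Parcellation, p2: Parcellation) -> float:
    """Percent of ROI voxels assigned to the same cluster across sessions,
    after aligning p2's labels to p1.  Unassigned (-1) voxels count as
    disagreement."""
    if p1.n != p2.n:
        raise ValueError("parcellations differ in length")
    if p1.k != p2.k:
        raise ValueError("parcellations differ in k")
    aligned = align_labels(p1, p2)
    agree = (p1.labels == aligned.labels) & (p1.labels >= 1) & (aligned.labels >= 1)
    return 100.0 * float(np.mean(agree))
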