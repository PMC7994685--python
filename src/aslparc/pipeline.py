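"""End-to-end orchestration: cohort -> dM -> matrices -> parcellations ->
stability / reproducibility / contrast maps.

Two entry layers: in-memory helpers over a synthetic :class:`Cohort`
(`cohort_matrices`, `parcellate_cohort`, ...) used by the analyses and the
test-bench, and the file-driven :func:`run_all` behind the CLI, which reads
NIfTI inputs listed in a :class:`PipelineConfig` and writes the full output
tree (label maps, VI table, agreement report, contrast maps, run log).
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as nio
from .connectivity import (ConnectivityMatrix, correlate_extrinsic,
                           correlate_intrinsic, group_average, save_matrix)
from .groupstats import cluster_mean_connectivity, contrast_clusters
from .parcellation import (DEFAULT_SEED, Parcellation, consensus,
                           features_from_matrix, kmeans_parcellate,
                           unassigned_fraction)
from .preprocess import PreprocessParams, preprocess_subject
from .simulate import Cohort, SimConfig, simulate_cohort
from .stability import SplitPlan, session_agreement, split_half_vi

logger = logging.getLogger(__name__)


# ------------------------------------------------------- in-memory helpers

def cohort_matrices(cohort: Cohort, session_id: int = 0, kind: str = "extrinsic",
                    pp: PreprocessParams | None = None,
                    keep_dm: bool = False):
    """Subject-level connectivity matrices for one session (raw series are
    generated, preprocessed and discarded one at a time).

    Returns ``(mats, dms)``; ``dms`` is empty unless ``keep_dm``.
    """
    pp = pp or PreprocessParams()
    corr = correlate_extrinsic if kind == "extrinsic" else correlate_intrinsic
    mats, dms = [], []
    for sub, raw in cohort.iter_series(session_id):
        dm = preprocess_subject(raw, cohort.masks, pp)
        mats.append(corr(dm, cohort.masks))
        if keep_dm:
            dms.append(dm)
    return mats, dms


def parcellate_group(mats: list[ConnectivityMatrix], k: int,
                     seed: int = DEFAULT_SEED, n_init: int = 50) -> Parcellation:
    """Average subject matrices and k-means the group connectivity profiles."""
    group = group_average(mats)
    feats = features_from_matrix(group)
    return kmeans_parcellate(feats, k, seed=seed, n_init=n_init,
                             source=mats[0].kind)


def adjusted_rand(labels_a, labels_b) -> float:
    from sklearn.metrics import adjusted_rand_score
    return float(adjusted_rand_score(labels_a, labels_b))


# ---------------------------------------------------------- file pipeline

@dataclass
class PipelineConfig:
    """Layered plain-text (YAML) configuration for :func:`run_all`."""

    series: list = field(default_factory=list)            # session-1 paths
    series_session2: list = field(default_factory=list)   # optional follow-up
    roi_mask: str = ""
    gm_mask: str = ""
    nuisance_mask: str = ""
    truth_labels: str = ""                                # optional ground truth
    parity: str = "control_first"
    tr_s: float = 3.9
    fwhm_mm: float = 5.0
    compcor_r: int = 5
    compcor_method: str = "pca"
    band_hz: list | None = None
    kind: str = "both"                                    # extrinsic|intrinsic|both
    k_list: list = field(default_factory=lambda: [2, 3, 4, 6, 8])
    stability_reps: int = 100
    stability_kind: str = "extrinsic"
    n_perm: int = 5000
    z_crit: float = 2.3
    guard_vox: int = 2        # seed-vicinity exclusion around the ROI
    n_init: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def pp_params(self) -> PreprocessParams:
        band = tuple(self.band_hz) if self.band_hz else None
        return PreprocessParams(fwhm_mm=self.fwhm_mm, compcor_r=self.compcor_r,
                                compcor_method=self.compcor_method,
                                band_hz=band, seed=self.seed)


def _load_session(paths, masks, cfg: PipelineConfig, kinds):
    mats = {k: [] for k in kinds}
    dms = []
    for path in paths:
        if not Path(path).exists():
            raise FileNotFoundError(f"series file not found: {path}")
        raw = nio.read_series(path, parity=cfg.parity, tr=cfg.tr_s)
        if not raw.grid.matches(masks.grid, atol=1e-3):
            raise nio.GridMismatchError(f"{path} is not on the mask grid")
        dm = preprocess_subject(raw, masks, cfg.pp_params())
        if "extrinsic" in kinds:
            mats["extrinsic"].append(correlate_extrinsic(dm, masks))
        if "intrinsic" in kinds:
            mats["intrinsic"].append(correlate_intrinsic(dm, masks))
        dms.append(dm)
    return mats, dms


def run_all(cfg: PipelineConfig, outdir) -> dict:
    """Run the full analysis and write the output tree; returns a summary
    dict (also written as ``summary.json``)."""
    outdir = Path(outdir)
    for sub in ("matrices", "parcellations", "maps"):
        (outdir / sub).mkdir(parents=True, exist_ok=True)
    for p in (cfg.roi_mask, cfg.gm_mask, cfg.nuisance_mask):
        if not Path(p).exists():
            raise FileNotFoundError(f"mask file not found: {p}")
    ref = nio.nib.load(str(cfg.roi_mask))
    grid = nio._grid_from_img(ref)
    masks = nio.read_masks(cfg.roi_mask, cfg.gm_mask, cfg.nuisance_mask, grid)

    kinds = ["extrinsic", "intrinsic"] if cfg.kind == "both" else [cfg.kind]
    mats, dms = _load_session(cfg.series, masks, cfg, kinds)
    summary: dict = {"n_subjects": len(cfg.series), "k_list": list(cfg.k_list),
                     "seed": cfg.seed}

    parcs: dict[tuple[str, int], Parcellation] = {}
    for kind in kinds:
        group = group_average(mats[kind])
        save_matrix(group, outdir / "matrices" / f"group_{kind}")
        for k in cfg.k_list:
            p = parcellate_group(mats[kind], k, seed=cfg.seed + DEFAULT_SEED,
                                 n_init=cfg.n_init)
            parcs[(kind, k)] = p
            vol = nio.labels_to_volume(p.labels, masks.roi_index, grid)
            nio.write_map(vol, grid, outdir / "parcellations" / f"{kind}_k{k}.nii.gz")
            summary[f"inertia_{kind}_k{k}"] = p.inertia
    if cfg.kind == "both":
        for k in cfg.k_list:
            cons = consensus(parcs[("extrinsic", k)], parcs[("intrinsic", k)])
            vol = nio.labels_to_volume(cons.labels, masks.roi_index, grid)
            nio.write_map(vol, grid, outdir / "parcellations" / f"consensus_k{k}.nii.gz")
            summary[f"consensus_unassigned_k{k}"] = unassigned_fraction(cons)

    if cfg.truth_labels and Path(cfg.truth_labels).exists():
        truth = np.asarray(nio.nib.load(str(cfg.truth_labels)).get_fdata()).astype(int)
        tl = truth[tuple(masks.roi_index.T)]
        for (kind, k), p in parcs.items():
            summary[f"ari_{kind}_k{k}"] = adjusted_rand(tl, p.labels)

    if cfg.stability_reps > 0 and len(cfg.series) >= 2:
        plan = SplitPlan(repetitions=cfg.stability_reps, seed=cfg.seed)
        vi = split_half_vi(mats[cfg.stability_kind], k_list=cfg.k_list, plan=plan,
                           kmeans_seed=cfg.seed + DEFAULT_SEED, n_init=cfg.n_init)
        with open(outdir / "vi_table.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["k", "mean_vi_bits", "sd_vi_bits"])
            for k in cfg.k_list:
                w.writerow([k, f"{vi.mean_vi[k]:.4f}", f"{vi.sd_vi[k]:.4f}"])
        summary["vi_mean"] = vi.mean_vi
        summary["vi_fit_a"], summary["vi_fit_b"], summary["vi_fit_r2"] = vi.fit

    if cfg.series_session2:
        mats2, _ = _load_session(cfg.series_session2, masks, cfg,
                                 [cfg.stability_kind])
        for k in (2, 3):
            if k not in cfg.k_list:
                continue
            p1 = parcs[(cfg.stability_kind, k)]
            p2 = parcellate_group(mats2[cfg.stability_kind], k,
                                  seed=cfg.seed + DEFAULT_SEED, n_init=cfg.n_init)
            summary[f"session_agreement_k{k}_percent"] = session_agreement(p1, p2)

    if cfg.n_perm > 0 and 2 in cfg.k_list and len(dms) >= 2:
        from .groupstats import seed_guard_selection
        kind = kinds[0]
        p2 = parcs[(kind, 2)]
        maps = {c: [] for c in (1, 2)}
        for dm in dms:
            for c in (1, 2):
                zmap, _ = cluster_mean_connectivity(dm, masks, p2, c)
                maps[c].append(zmap)
        sel = seed_guard_selection(masks, guard_vox=cfg.guard_vox)
        keep_index = masks.gm_index[sel]
        res = contrast_clusters(np.asarray(maps[1])[:, sel],
                                np.asarray(maps[2])[:, sel],
                                z_crit=cfg.z_crit, n_perm=cfg.n_perm,
                                seed=cfg.seed)
        for name, mask, zmap in (("unique_cluster1", res.mask_a, res.z_a),
                                 ("unique_cluster2", res.mask_b, res.z_b)):
            vol = np.zeros(grid.shape, dtype=np.int16)
            vol[tuple(keep_index.T)] = mask.astype(np.int16)
            nio.write_map(vol, grid, outdir / "maps" / f"{name}.nii.gz")
            zvol = np.zeros(grid.shape, dtype=float)
            zvol[tuple(keep_index.T)] = zmap
            nio.write_map(zvol, grid, outdir / "maps" / f"{name}_z.nii.gz")
            summary[f"{name}_voxels"] = int(mask.sum())

    (outdir / "run_log.txt").write_text(
        "\n".join(f"{k} = {v!r}" for k, v in asdict(cfg).items()) + "\n")
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2, default=float))
    return summary


def report(outdir) -> str:
    """Plain-text summary of a run_all output tree."""
    outdir = Path(outdir)
    summary = json.loads((outdir / "summary.json").read_text())
    lines = ["aslparc run report", "==================", ""]
    for key in sorted(summary):
        val = summary[key]
        if isinstance(val, float):
            lines.append(f"{key:40s} {val:.4f}")
        else:
            lines.append(f"{key:40s} {val}")
    text = "\n".join(lines) + "\n"
    (outdir / "report.txt").write_text(text)
    return text


def demo(outdir, n_subjects: int = 6, n_frames: int = 120, k_list=(2, 3),
         reps: int = 5, n_perm: int = 200, n_init: int = 10, seed: int = 0) -> dict:
    """Simulate a small cohort to disk and run the full pipeline on it."""
    outdir = Path(outdir)
    cfg_sim = SimConfig(n_subjects=n_subjects, n_sessions=2, n_frames=n_frames,
                        seed=seed)
    data_dir = outdir / "data"
    simulate_cohort(cfg_sim, outdir=data_dir)
    series1 = [str(data_dir / f"sub-{s:02d}_ses-1_asl.nii.gz") for s in range(n_subjects)]
    series2 = [str(data_dir / f"sub-{s:02d}_ses-2_asl.nii.gz") for s in range(n_subjects)]
    cfg = PipelineConfig(series=series1, series_session2=series2,
                         roi_mask=str(data_dir / "masks/roi.nii.gz"),
                         gm_mask=str(data_dir / "masks/gm.nii.gz"),
                         nuisance_mask=str(data_dir / "masks/nuisance.nii.gz"),
                         truth_labels=str(data_dir / "truth/labels.nii.gz"),
                         tr_s=cfg_sim.tr_s, k_list=list(k_list),
                         stability_reps=reps, n_perm=n_perm, n_init=n_init,
                         seed=seed)
    summary = run_all(cfg, outdir / "results")
    report(outdir / "results")
    return summary
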