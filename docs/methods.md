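# Methods

This note documents the models, defaults and numerical choices behind
`aslparc`, and what the synthetic test-bench does and does not demonstrate.

## Perfusion signal chain

A pCASL acquisition interleaves control and label frames (parity is always
declared by the caller — `control_first` or `label_first` — never inferred).
Surround subtraction forms, for every labeled frame with both neighbours,

    ΔM(τ) = (c(τ−1) + c(τ+1)) / 2 − l(τ),

so an even-length series of t frames yields t/2 − 1 ΔM volumes at sampling
interval 2·TR (7.8 s at the default TR of 3.9 s).  The stencil is a second
difference on any signal common to control and label frames: temporally
linear terms cancel exactly (this is why no drift correction or high-pass
filter is applied by default; an optional 0.01–0.10 Hz band-pass exists
behind a flag), while broadband physiological fluctuations survive with
gain up to 2 and are left to CompCor.  Sign convention: ΔM ≥ 0 in perfused
tissue.

Smoothing is an isotropic Gaussian per volume, σ = FWHM/√(8 ln 2) (5 mm
default → 0.531 voxels at 4 mm), edge mode nearest-neighbour so constant
volumes are preserved and the spatial mean is conserved.

CompCor extracts r = 5 nuisance time courses from the combined WM/CSF ROI
of the ΔM series (voxel series demeaned first).  Default extraction is PCA
(top right singular vectors, ordered by singular value); ICA (FastICA,
fixed seed) is available, with "top r" defined as the components whose
back-projection explains the most variance, since ICA has no intrinsic
order.  Components are standardized to zero mean and unit norm and
regressed out of every voxel by OLS with an intercept; the operation is a
projection (idempotent, residuals orthogonal to the basis).  Smoothing
precedes CompCor in the fixed pipeline order subtract → smooth → CompCor.

## Connectivity and parcellation

Subject-level matrices are plain Pearson correlations of ΔM voxel series,
extrinsic `[(m−n) × n]` or intrinsic `[n × n]` (symmetrized, unit
diagonal).  Voxel registries are lexicographic in (i, j, k) and shared by
every stage.  Zero-variance series (detected with a relative tolerance of
1e−10) correlate 0 rather than NaN so matrix shapes stay stable; they are
reported.  Group matrices are element-wise means of r across subjects —
the literal averaging convention — with Fisher-z averaging behind a flag;
subject-level cluster maps for inference are always Fisher-z.

Each ROI voxel's feature vector is its column of the group extrinsic
matrix or its row of the group intrinsic matrix (self-correlation
retained, profiles not standardized).  Hard clustering is Lloyd k-means
with k-means++ initialization, squared Euclidean distance on the raw
profiles, 50 restarts, 300 iterations, fixed default seed 20210113;
clusters are renumbered by descending size.  Two parcellations are
compared after Hungarian alignment of their contingency table (padded
square, surplus labels of the finer solution mapped to fresh labels).
Consensus keeps post-alignment agreements and marks conflicts −1; the
ROI-voxel label maps written to NIfTI use 1..k with 0 background and −1
unassigned.

## Stability and reproducibility

Split-half stability bifurcates the cohort at random (⌈n/2⌉/⌊n/2⌋, 100
repetitions by default), re-averages each half from the stored
subject-level matrices, re-clusters, and computes the variation of
information in bits from the joint contingency table (0·log 0 = 0; values
below 1e−12 are snapped to 0 so identical partitions report exactly 0).
Both halves of a repetition share that repetition's k-means seed, so
identical half-group matrices give VI = 0 and VI measures data variation,
not restart luck.  Mean VI per k is fit by OLS on ln k; a zero-variance
target is defined to have r² = 1 (perfectly fit by a constant).
Between-session reproducibility aligns the follow-up parcellation to the
original and reports the percentage of matching ROI voxels; −1 voxels
count as disagreement.

## Group inference

Per subject and cluster, every gray-matter voxel receives the mean over
cluster voxels of atanh(r) (r clipped at |r| ≤ 1 − 1e−7); z first, then
mean.  The one-sample test against zero uses the sign-flip permutation
null: whole subject maps are negated, the per-voxel one-sample t
recomputed (using the flip-invariance of Σx² for speed), and
p = (1 + #{perm ≥ obs})/(n_perm + 1) with the identity flip always counted,
so the smallest achievable p is 1/(n_perm+1).  When 2^n ≤ n_perm all flips
are enumerated and p is exact.

Cluster uniqueness is a paired contrast: sign flips of the per-subject
difference maps, both tails from the same flips, t mapped to z through the
normal quantile of the t CDF.  Two design choices depart from the bare
voxelwise threshold and are deliberate:

* **Family-wise correction.**  A whole gray-matter map is tested at once;
  at z ≥ 2.3 (one-sided p ≈ 0.011) a few hundred voxels would produce
  false "unique connectivity" in essentially every null dataset.  The
  default inference therefore also requires the max-statistic
  family-wise-corrected permutation p (the standard voxelwise-corrected
  rule for permutation inference on images) to fall below the alpha
  implied by z_crit; `correction="none"` restores the plain rule.
* **Seed-vicinity guard.**  Spatial smoothing mixes noise between
  neighbouring voxels, so gray matter bordering a cluster genuinely
  correlates with it in every subject; contrasts there report kernel
  leakage, not networks (empirically, all null suprathreshold voxels lie
  within one voxel of the ROI).  The pipeline evaluates contrasts on gray
  matter outside a 2-voxel dilation of the ROI (`guard_vox`), the usual
  seed-vicinity exclusion of seed-based connectivity.

Two diagnostics accompany the maps: a lag profile (normalized
cross-correlation of two cluster-mean series at integer lags; a
"time-shifted relationship" is flagged when a non-zero lag beats lag 0 by
more than 0.1) and a variance contrast (per-subject mean temporal ΔM
variance per cluster, paired Wilcoxon signed-rank; all-zero differences
return p = 1, fewer than 6 subjects warn).

## Synthetic cohorts

The generator emulates the acquisition the pipeline targets — n = 20
subjects (8-subject follow-up cohorts for reproducibility runs), two
sessions, 300 frames at TR 3.9 s, a 20×20×10 grid of 4 mm voxels — with an
8×8×4 ROI (256 voxels) split into k_true planted clusters (halves along x;
additional bands along y for k_true > 2), one 3×3×3 gray-matter target
blob per cluster, a gray-matter box and a disjoint WM/CSF slab.

Signal model per voxel and frame:

    control  c = M0 + d_s(t) + g(t)·1[brain] + ε
    label    l = c − ΔM_true,
    ΔM_true  = P(v) · (1 + A · a_j · U_v(t))

with M0 = 1000 (brain) / 100 (background) a.u.; P(v) the perfusion map
(baseline 60 a.u. in gray matter, jittered ±10% per subject; 0.3× in the
WM/CSF slab; 0 outside); A = 0.15 the fractional network amplitude; a_j an
optional per-cluster scale (used to plant variance differences); d_s a
random linear+quadratic drift (scales 20/10 a.u.); g white physiological
noise (sd 20 a.u., white at the frame rate so that it survives surround
subtraction and CompCor has something to remove); ε i.i.d. thermal noise
(sd 15 a.u.).  The latent series U_v mixes the cluster's main network
signal with a weak cluster-specific secondary signal,
U_v = cos(a_v)·S_j + sin(a_v)·S′_j, the angle a_v running linearly along y
across the cluster (spreads 60°/40° by default): cortical areas are not
internally homogeneous, and without this continuous secondary gradient the
block symmetry makes particular k values artificially stable in split-half
analyses.  Target blobs carry the pure S_j.  All S are unit-variance white
noise band-passed to 0.01–0.10 Hz (4th-order Butterworth,
forward-backward) at the frame rate; after decimation to the ΔM rate the
above-Nyquist part of the band folds back inside it, so >95% of spectral
power remains in-band at the ΔM sampling rate.  Randomness comes from
streams keyed by (seed, subject, session); session 2 redraws everything
stochastic but reuses geometry, labels and subject traits.  Latent network
time courses are drawn per subject and session (within-subject correlation
is what connectivity measures; independent sessions must not share time
courses), and the draws are recorded in the ground-truth object.

With these defaults the planted k = 2 partition is recovered at ARI = 1.0
— deliberately comfortable signal-to-noise, since the tests verify the
pipeline, not the detection limit.  What the synthetic bench does *not*
emulate: motion, ASL kinetics (T1 decay, arterial transit times),
background suppression, venous BOLD weighting, registration error, or
anatomically realistic geometry.  Passing tests therefore demonstrate
correctness of the analysis chain under a known generative model, not
expected effect sizes on real scans.

## Problem sizes in the test-bench

The verification suite runs: the full default cohort for recovery and for
split-half VI (20 bifurcations); ten 8-subject two-session cohorts for
reproducibility; 2000 exact-enumeration null simulations (n = 12) for
permutation calibration; twenty 6-subject null cohorts for recovery
safety; and forty 12-subject null cohorts (150 frames) for contrast
emptiness.  These sizes keep the whole suite at a few minutes on one CPU
while leaving the Monte-Carlo margins comfortable.

## Known limitations

* The ICA ordering heuristic (back-projected variance) is one of several
  defensible definitions of "top" components.
* Consensus is defined by post-alignment agreement; other consensus rules
  (e.g., co-association clustering) exist.
* The contrast's family-wise correction is voxelwise max-statistic;
  cluster-extent or TFCE-style enhancement is out of scope.
* No automatic choice of k: the VI analysis characterizes stability but
  does not select a solution.
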