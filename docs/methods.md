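# Methods

## The NH statistic

For a run with preprocessed series x_i(t) on the N voxels of a network
mask, NH(i) is the average Pearson correlation of voxel i with the other
N−1 voxels. The production implementation uses the algebraic identity
Σ_j corr(i,j) = z_i·(Σ_j z_j)/t on population-z-scored series, which is
O(N·t) and equal to the brute-force pairwise average to machine
precision; the brute-force path is retained as a test oracle. Raw
correlations are averaged directly (no Fisher-z transform before
averaging), matching the statistic's definition; zero-variance voxel
series contribute and receive correlations of 0 (logged, never NaN).
Per-run NH maps are z-scored within the mask before group analysis
(standardisation on by default; raw maps always available) so that group
contrasts compare spatial NH structure rather than global correlation
level.

## Synthetic cohort generator

The generator emulates the data structure of a two-arm longitudinal
treatment study, not any real brain:

* grid 20×24×20 voxels at 3 mm isotropic (desk-scale but large enough
  for smoothness estimation); 240 volumes at TR = 2 s; ~20
  subjects/group (controls scanned at baseline only, mirroring the
  single control scan of such designs);
* the network is a union of four spheres occupying ~10% of the grid;
  every in-network voxel is loading·g(t) + local AR(1) + AR(1) noise,
  with g a shared unit-variance signal, plus a linear drift and a weak
  white-matter/CSF nuisance contribution; out-of-network voxels carry no
  shared signal. AR(1) with coefficient 0.3 is the simplest temporally
  autocorrelated BOLD-like noise; expected in-cluster NH is monotone in
  the loading (verified by simulation);
* two planted ~30-voxel clusters: a deficit (patient loading 0.3 vs
  control 0.9) restored to 0.9 at week 8 in the DPP arm only, and a
  stable excess (patient 1.0 vs control 0.6) that carries the clinical
  coupling;
* motion is a bounded random walk (translations clipped at 1 mm,
  rotations — stored in radians — at 0.01 rad) with single-frame
  displacement spikes of 0.3–0.6 mm at probability 0.02/frame, so
  scrubbing has work to do but no subject trips the 2 mm / 2° exclusion
  unless a large spike is injected deliberately;
* clinical scores: patient PANSS subscales are drawn at realistic
  baseline levels with totals forced above the inclusion threshold of
  75. The reduction ratio is planted as
  RR = clamp(intercept + slope·z(baseline region NH) + noise, 0, 1);
  because the slope applies to the z-scored region NH, the planted
  population correlation is slope/√(slope²+noise_sd²) independent of the
  realized NH scale — the defaults (0.1, 0.55, 0.0484) plant r = 0.9.
  Week-8 subscale scores are back-computed from per-subscale RRs that
  scatter around the planted value and are rescaled so the total RR
  equals the planted value exactly; the stored rr_* columns are then
  re-derived from the stored scores, keeping the table internally
  consistent. Cognitive battery scores are independent Gaussians (they
  are only consumed by the correlation analysis).

Random streams are keyed as (seed, purpose, subject, timepoint, block),
with in-network and out-of-network voxels on separate substreams, so the
`scope="network"` fast path is bit-identical to the network part of the
full-grid run — this is what makes the 25-seed Monte-Carlo suites cheap.

What the generator does **not** model: hemodynamic response,
physiological noise, EPI distortion, spatial autocorrelation of the
noise (voxel noise is spatially white; smoothness enters the GRF
calibration suite through explicitly smoothed null fields), motion
artefacts in the voxel data itself, and site/scanner effects. Passing
tests therefore demonstrate the correctness and calibration of the
analysis chain under a known generative model, not performance on real
fMRI.

## Preprocessing

Fixed order: drop 10 initial volumes → motion QC (exclude any subject
exceeding 2 mm translation or 2° rotation on any axis) → linear detrend
→ band-pass → nuisance regression → scrub. Choices the statistic's
definition leaves open:

* **FD**: Power-style — sum of absolute frame differentials of the six
  parameters with rotations converted to arc length on a 50 mm sphere
  (the dominant convention in this pipeline family). fd[0] = 0.
* **Band-pass** 0.01–0.08 Hz as a frequency-domain response that is 1 in
  band with raised-cosine transitions of width 10% of each cutoff: fully
  reproducible, no filter-order or ripple choices. DC is removed.
* **Nuisance regression**: Friston-24 expansion (parameters, squares,
  lags, lagged squares; lag row 0 filled with 0 — any constant is
  absorbed by the intercept) plus WM and CSF series, no global signal.
  Rank-deficient designs fall back to the pseudoinverse; residuals are
  orthogonal to every confound column to < 1e−8 on full-rank designs.
* **Scrubbing** censors frames with FD > 0.2 mm *after* filtering
  (censor-after-filter); no adjacent-frame augmentation. Runs left with
  fewer than 20 frames are flagged unusable and refused downstream.

## Network mask by group ICA

Baseline runs of all groups are temporally concatenated with two-stage
PCA reduction (30 per-subject, 20 group dimensions by default) and
unmixed by spatial FastICA; maps are z-scored over the grid. The network
component is selected by the spatial correlation of |map| with a
template indicator (in the synthetic study: the true network; on real
data any prior network atlas), sign-aligned, and thresholded at z ≥ 1.96
on the positive side. Masks under 30 voxels are rejected. Selection
reliability and mask Dice ≥ 0.7 against ground truth are part of the
test suite.

## Group inference

All inference is OLS GLM per mask voxel with mean-centred age and
mean-FD covariates. Within-subject (time) effects and the arm×time
interaction are realised on within-subject difference maps — a paired
design that sidesteps the unstated parameterisation of a full
repeated-measures ANCOVA; for a two-level factor the interaction F is
exactly T². Once-scanned controls enter baseline contrasts only, and
patient-vs-control contrasts run per arm (pooled available).

Cluster correction follows stationary GRF theory: residual smoothness by
the Kiebel/Worsley estimator (per-axis FWHM from the variance of spatial
derivatives of voxel-normalised residuals, floored at half a voxel),
resel counts R₀..R₃ from the mask geometry by the standard
voxel/edge/face/cube counting scheme, Euler-characteristic densities for
a Gaussian field at the z-equivalent of the voxel threshold, and the
expected-cluster-count approximation P(n ≥ k) = exp(−β k^{2/3}) for the
cluster-level p. Clusters are 26-connected. Two-sided inference runs one
pass per tail at voxel p < 0.001 and multiplies the corrected cluster p
by 2, so the combined procedure controls FWE at the nominal cluster
p — empirically ≤ 0.08 (measured ~0.01, i.e. conservative, as GRF at
moderate smoothness is known to be) over 200 smoothed-noise null
simulations, and the GRF critical cluster size agrees with a
subject-relabelling permutation null within a factor of 2. The
stationarity assumption is a logged caveat: smoothness is estimated
globally, and no non-stationarity correction is applied.

## SVM / SVR evaluation

Classification and regression run leave-one-out over subjects with RBF
kernels and a powers-of-two (C, γ) grid. The grid search is **nested**
inside each training fold by default (features are standardised with
training-fold statistics; no information from the held-out subject
reaches model selection); a `pooled` mode that selects hyperparameters
once on all data — the likelier historical protocol, with its documented
optimism risk — is selectable and labelled. Metrics come from the pooled
fold predictions; the grid surface is stored for parameter-selection
plots.

Two LOO artefacts matter for null behaviour and are deliberately part of
the package's conventions:

* Under a permuted-label null with balanced groups, pooled LOO accuracy
  is biased *below* chance (the held-out subject is always the
  training-fold minority, and with uninformative features the classifier
  degenerates toward majority vote). The null check is therefore
  one-sided: the null must not produce systematically high accuracy.
* Under a null coupling, LOO-SVR predictions shrink toward the
  training-fold mean, which is mechanically anti-correlated with the
  held-out target. A *negative* predicted-vs-actual correlation is
  therefore never evidence of prediction: `SVRReport.significant`
  requires r > 0 **and** p below the Bonferroni threshold (0.05/16 by
  default — 4 regions × 4 PANSS domains). Constant predictions (all
  targets inside the ε tube) are reported as r = 0.

The soft-margin linear SVM (½‖w‖² + CΣξ under the margin constraints,
equivalently hinge loss + ℓ2 penalty) is additionally implemented
directly as a small dual QP (SLSQP, box constraints, equality Σαy = 0;
bias from on-margin support vectors with a primal line-search fallback)
and verified against an independent primal-QP oracle and KKT conditions;
it serves as the correctness reference for the libsvm-backed production
path.

## Pipeline

The file-based pipeline (library API or the thin `nethom` CLI) runs
simulate → preprocess → mask → nh → infer → ml → report against one
config whose fields name every study constant (10 dropped volumes,
0.01–0.08 Hz, FD 0.2 mm, 2 mm/2°, voxel p 0.001, cluster p 0.05,
α/16). Every artefact is SHA-256-checksummed into a run manifest;
re-running skips stages whose recorded inputs and outputs verify, and a
corrupted intermediate invalidates its producing stage, which repairs it
deterministically (outputs are byte-identical across fresh runs, NIfTI
included). Reports mirror the conventional result layout: a per-contrast
cluster table (with explicit "No cluster" rows), a classifier table, an
SVR summary and, for synthetic runs, Dice overlap of every detection
with the planted ground truth.

## Problem sizes

The test suite and acceptance script run the full study conditions
(default grid, 240 volumes, 19–20 subjects per group) for single-seed
checks; Monte-Carlo suites use 25 seeds for planted-cluster and
SVR-coupling recovery, 100–200 simulations for FWE calibration and null
rates, and desk-scale grids (12–14 voxels per axis, 60–120 volumes) for
ICA and pipeline orchestration tests. These sizes were chosen as the
smallest at which each property is stably expressed.

## Known limitations

* No spatial preprocessing (slice timing, realignment estimation,
  normalisation): cohorts live on a common grid by construction.
* Stationary GRF only; the conservatism observed on smooth synthetic
  nulls need not transfer to strongly non-stationary real smoothness.
* The generator's planted effects are large by design (power ≈ 1 at
  n = 20/group); the suite validates correctness and calibration, not
  sensitivity at realistic effect sizes.
* Group ICA selection needs a template; with no prior template the
  synthetic truth is used, which real-data use must replace with an
  atlas.
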