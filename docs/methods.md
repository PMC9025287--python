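# Methods

## Overview

`habitatpipe` implements a perfusion-habitat analysis of three-phase
dynamic contrast-enhanced (DCE) breast MRI. The chain is:

1. **Preprocessing** — every study (pre-contrast, early and delayed
   post-contrast T1-weighted volumes plus a binary tumour ROI) is
   resampled to 1 mm isotropic resolution; validation-cohort
   intensities are harmonised to the development cohort by quantile
   (histogram) matching.
2. **Perfusion maps** — per voxel, wash-in `Ein = I_early − I_pre`,
   washout `Eout = I_early − I_delayed`, and washout ratio
   `RWO = Eout / I_early` if `I_delayed < I_early`, else 0 ("no
   washout"). `Ein − Eout ≡ I_delayed − I_pre` is checked as an
   algebraic invariant.
3. **Habitat discovery** — the (Ein, Eout, RWO) perfusion feature
   vectors (PFVs) of all development-cohort tumour voxels are pooled,
   each feature quantised onto a uniform 256-bin grid spanning its
   pooled range, and k-means (Euclidean, k-means++ restarts, Lloyd
   iterations, relative inertia tolerance 1e-6, ≤300 iterations) is
   run at the cohort level for k = 2…32. The habitat count is chosen
   from the Calinski-Harabasz and silhouette curves averaged over the
   restarts; the chosen centres are frozen and propagated verbatim to
   the validation cohort, whose voxels are labelled by nearest centre.
4. **Heterogeneity features** — the habitat label map is summarised by
   58 features: 4 histogram (entropy, uniformity, skewness, kurtosis),
   24 GLCM and 16 GLSZM texture features computed with the labels as
   gray levels (bin size one), and 14 mesh-based 3D shape features of
   the ROI; the per-habitat volume proportions are appended. Two
   whole-tumour comparator panels apply the same texture machinery to
   32-bin discretisations of the three phase images and of the three
   perfusion maps (24 GLCM features per image, 72 per panel).
5. **Habitat risk score (HRS)** — features are z-scored with
   development-cohort statistics and fed to an L1-penalised Cox
   proportional-hazards fit. The HRS of patient *i* is the relative
   hazard at time zero, `HRS_i = h0(0) · exp(Σ_j β_j x_ij)`, with
   `h0(0)` the Breslow baseline-hazard increment at the earliest
   development event time. Patients are stratified at the development
   median score (`score ≥ cutoff` → high risk), the high/low groups are
   compared with a single-covariate Cox fit (hazard ratio, Wald CI),
   discrimination is measured by Harrell's C, and models are compared
   with a paired t-test over bootstrap replicates of the per-replicate
   C-index difference.

Five risk models are built on the development cohort and applied frozen
(coefficients, z-score statistics, cutoffs) to the validation cohort:
whole-tumour radiomics on the DCE phases, whole-tumour radiomics on the
perfusion maps, HRS-only, clinical (the clinicopathological/radiological
covariates), and combined (clinical + HRS).

## Synthetic cohorts

Patient DCE-MRI with linked outcomes cannot be redistributed, so the
`cohort` module generates data carrying exactly the statistical
structure the analysis assumes. Two modes exist:

* **pfv mode** (`sample_pfvs`) draws bare PFV triplets from an
  isotropic Gaussian mixture at the five reference habitat centres
  — (825, −667, 0.021), (2420, 864, 0.361), (2206, −14, 0.075),
  (1154, 362, 0.338), (1302, 915, 0.717) in intensity units — with
  mixing proportions (0.419, 0.068, 0.256, 0.235, 0.022). Values are
  deliberately unclipped: this mode exists to give clustering tests
  exact centre control.
* **image mode** (`generate_cohort`) renders full volumes. A spherical
  tumour (radius 6–14 mm, drawn in physical mm so anisotropic spacing
  yields anisotropic voxel footprints) is placed in a breast-sized
  field of view; habitat labels are assigned inside the tumour by
  thresholding a rank-uniformised smoothed Gaussian field at the
  cumulative target proportions (correlation length 4 voxels: patches
  must span several 3 mm slices, ~1 cm, to survive 1 mm resampling,
  matching the large contiguous subregions visible in real habitat
  maps), which
  gives spatially contiguous patches with near-exact proportions; the
  analysis ROI is the tumour mask eroded by one voxel, mirroring the
  clinical practice of excluding rim voxels to avoid partial-volume
  effects; the phases are rendered by inverting the perfusion-map definitions
  (`I_early = I_pre + Ein[h]`, `I_delayed = I_early · (1 − RWO[h])`)
  plus i.i.d. Gaussian phase noise, with low-enhancement textured
  background tissue. The reference centre triplets are not exactly
  self-consistent as voxelwise kinetics (the centroid of a ratio is not
  the ratio of centroids), so image mode is parametrised by (Ein, RWO)
  per habitat, with Eout emerging from the rendered phases.

Key generator parameters (all in `CohortSpec`, defaults in brackets):

| parameter | default | rationale |
|---|---|---|
| n_patients | 308 dev / 147 val | reference cohort sizes |
| voxel_spacing | (0.85, 0.85, 3.0) / (0.80, 0.80, 3.0) mm | clinical in-plane × 3 mm slices; differs across cohorts to exercise resampling |
| PFV noise SD | (50, 50, 0.025) | ~2.5% of each feature's dynamic range; keeps the tightest inter-centre separation (habitats 4 vs 5, ~570 units) at ≥10σ, so the habitats are distinct subpopulations rather than a continuum — the premise of the habitat model |
| image_noise_sd | 30 | per-phase additive noise, ~7% of baseline |
| scanner_transform | a·x^γ + b, (1.35, 0.93, 150) for validation | strictly monotone inter-scanner intensity distortion; rank order inside the ROI is preserved, so habitat structure survives harmonisation |
| baseline_hazard | 0.0013 /month | ≈11% event rate by 108 months of administrative censoring, matching a screening-era breast-cancer DFS profile |
| survival coefficients | +0.6 on label-histogram entropy, −0.8 on IDMN, −0.4 on surface-to-volume ratio (z-scored), plus clinical contributions (N stage +0.199, LVI +0.624, ER− +0.398, PR− +0.325, Ki-67≥20% +0.623) | heterogeneity-driven hazard with a realistic clinical component; planted on features stable across acquisition grids — zone-size statistics change non-monotonically under 1 mm resampling, so a hazard planted on them would be unrecoverable from images by construction |

Survival times are exponential given the linear predictor
(`T = −log U / (h_base · e^LP)`) with administrative censoring; clinical
covariates are drawn at development-cohort marginal frequencies.

What image mode does **not** emulate: breast anatomy, B0/B1 bias
fields, motion, partial-volume mixing at habitat boundaries beyond
interpolation, pharmacokinetic (Tofts-type) enhancement dynamics, and
correlated clinical covariates. Passing tests therefore demonstrate
correctness of the pipeline's statistical machinery under the planted
model, not clinical performance on real patients.

## Numerical and design choices

* **Quantisation** — uniform 256-bin grids per feature, min/max from
  the development pool only; values map to bin centres; the pooled
  maximum falls in the last (right-closed) bin; out-of-range validation
  values clip to the edge bins. Clustering operates on raw bin centres
  (not bin indices) so centres stay in intensity units; per-feature
  standardisation is available behind a `standardize` flag but off by
  default, which matches centres quoted in raw units.
* **Histogram matching** — 256 evenly spaced quantiles estimated from
  tumour-ROI voxels only (the tumour intensities are what feed
  clustering; background air would otherwise dominate) but applied to
  the whole volume; linear interpolation between quantiles; values
  outside the source range clamp to the reference extremes. Matching is
  idempotent up to quantisation.
* **Resampling** — cubic B-spline for intensities, nearest neighbour
  for masks; the output grid is sized so its last sample stays inside
  the input extent (no extrapolation); spline overshoot is clipped at
  zero because negative MR magnitudes are non-physical.
* **k selection** — per k, scores are averaged over repeated restarts
  (restart r seeded `seed + r`; the retained model is the best-inertia
  restart). The CH candidate is the last k, at or before the curve's
  maximum, whose single-step gain exceeds 10% of the largest gain — a
  noise-tolerant reading of "the last point before the curve's
  sustained decrease" — and must agree with the silhouette top-2;
  otherwise the silhouette winner is taken when it is among the CH
  top-2, else the CH candidate stands with a warning. Guards: CH increasing through the
  whole range returns the largest k with a warning; best silhouette
  below 0.25 signals no substantial structure and returns the smallest
  k with a warning; ties break to smaller k.
* **Silhouette subsampling** — the silhouette is O(n²) and cohort pools
  reach millions of voxels, so it is evaluated on a seeded subsample of
  2048 voxels per restart (configurable).
* **Tie-breaking** — nearest-centre assignment resolves distance ties
  to the lowest canonical label (centres sorted lexicographically by
  wash-in, then washout); score-equals-cutoff stratifies as high risk.
  Both conventions are arbitrary but fixed for bit-reproducibility.
* **Texture conventions** — GLCM: distance 1, the 13 unique 3D
  directions, symmetric matrices, features computed per direction then
  averaged; gray levels are the label values present in each
  direction's pairs; degenerate single-level maps score Correlation 1,
  IMC1 0, MCC 1. GLSZM: 26-connected zones. Histogram skewness and
  kurtosis are the standardised third/fourth moments (Pearson, no −3).
  Shape: marching-cubes mesh on a lightly Gaussian-smoothed mask
  (σ = 1 voxel) — meshing the raw binary mask overestimates curved
  surface area by the staircase effect — with a voxel-based fallback,
  flagged by a warning, for masks below two voxels. The four histogram
  features and the whole-tumour panel composition are configurable;
  defaults are recorded in output metadata.
* **Cox-LASSO** — glmnet-style coordinate descent on the Breslow
  partial likelihood (IRLS with diagonal Hessian weights; covariance
  updates; active-set sweeps). Breslow rather than Efron tie handling
  keeps closed-form updates; synthetic survival times are continuous so
  ties are measure-zero. The penalty grid has 50 log-spaced points from
  the smallest all-zero penalty down 3 decades; folds are stratified by
  event status; the CV criterion is the Verweij–van Houwelingen
  partial-likelihood deviance; inside CV the per-λ fits use a relaxed
  tolerance (1e-5) since the deviance curve is smooth in λ, and the
  final whole-development refit uses 1e-8. Penalty selection is 10-fold
  CV for λ plus a final refit; no outer CV loop is run, because
  generalisation is measured by the held-out validation cohort rather
  than by resampling the development cohort. For saturated designs
  (p ≥ n) the penalty floor rises to 0.01·λ_max and the path freezes
  once the active set reaches 90% of the event count: beyond that point
  the partial-likelihood optimum is unbounded and smaller penalties
  cannot win the cross-validation.
* **h0(0)** — the Breslow increment at the earliest development event
  time. It is a patient-independent positive constant, so ranking,
  median split, hazard ratios and C-indices are invariant to the
  choice; it only fixes the absolute scale of the printed scores.
* **C-index SE and model comparison** — the SE is the binomial
  approximation `sqrt(C(1−C)/N_pairs)` over usable pairs; model
  comparison bootstraps patients (default 200 replicates) and applies a
  two-sided paired t-test to per-replicate C differences. Both are
  deliberately simple, documented stand-ins for the many variants in
  circulation.

## Problem sizes

The bundled analysis scripts and test suite run at desk scale: habitat
recovery uses 100k pooled voxels with 20 restarts per k; the analysis
chain simulates 60 + 30 patients on 48×48×16 grids with k swept to 12
and 10 restarts; the end-to-end smoke test uses 20 patients. These
sizes were chosen so the statistical behaviour of every stage is
measurable (proportion recovery tolerance scales as n^−1/2) while a
full run stays in the minutes range on one CPU; all of them are
configuration values, and the defaults in `PipelineConfig` mirror the
reference cohort sizes.

## Known limitations

* Habitat discovery assumes compact, roughly isotropic clusters in raw
  intensity units; k-means cannot represent skewed or curved kinetic
  families, and the raw-unit metric means the wash-in/washout axes
  dominate distances over the bounded washout ratio.
* The CH-elbow + silhouette rule is a heuristic; on data without
  genuine cluster structure both criteria are noise (handled by the
  weak-structure guard, but the returned k is then arbitrary).
* Harrell's C with the binomial SE underestimates uncertainty under
  heavy censoring; the bootstrap comparison inherits the usual
  optimism of resampling the same patients for both models.
* Cross-series co-registration is out of scope: synthetic studies are
  aligned by construction, and the pipeline assumes aligned inputs.
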