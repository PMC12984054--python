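# Methods

This note records the modelling choices behind the package: what the phantom
generator emulates, the fixed numerical conventions of each pipeline stage,
the parameters that matter, and what desk-scale results do and do not show.

## The phantom cohort

Each phantom patient is a 64³ voxel chest patch at 1 mm isotropic spacing:

- **Parenchyma**: i.i.d. N(−800, 30²) HU, so the marginal lung-density
  histogram is exactly normal (tested by Kolmogorov–Smirnov).
- **Chest wall**: a 4 mm slab at +40 ± 10 HU on one volume face; the lung
  mask is its complement. Its only role is to exercise the ring-exclusion
  rule.
- **Tumor**: a solid ellipsoid whose longest axis realizes the lung-window
  diameter (clipped to ≤ 20 mm; secondary axes 0.75–1.0 of the first). The
  mediastinal-window size is modelled as the solid core: Mwts = 11.6 + 3.9
  z_size mm with Lwts ≈ Mwts + 2.7 mm, matching the reference cohort's
  means/SDs and their ordering.
- **Subregions**: the tumor is split into three parallel *bands* along a
  random axis, ordered by decreasing HU — (60, 15, corr 1), (10, 25, corr 2),
  (−80, 40, corr 3) as (mean HU, SD HU, texture correlation length in
  voxels) — with smoothly perturbed boundaries. Bands rather than nested
  shells: on ≤ 20 mm tumors, shells are 2–3 voxels thick, so the 5³ feature
  windows straddle boundaries almost everywhere and voxel clustering sees a
  gradient rather than plateaus; bands minimize internal boundary area and
  never place the brightest and darkest plateau in contact. Texture is
  Gaussian noise smoothed at the per-subregion correlation length and
  rescaled to unit variance (one knob for GLCM-visible texture).
- **Peritumoral signal**: the ≤ 5 mm shell outside the tumor receives added
  correlated noise (correlation length 1.5 voxels) with amplitude
  14 + 7·z_peri HU.
- **Label model**: P(STAS) = expit(−0.7 + 0.3·z_size + 1.5·z_rim +
  1.2·z_peri) on three independent standard-normal latents; z_rim maps to
  the dark-band volume fraction (0.35 + 0.12·z_rim, clipped to [0.10,
  0.62]). Latents are standardized by construction so effect sizes are
  comparable across units. The intercept puts prevalence near the reference
  cohort's 37.8%; the effect ordering (imaging signals ≫ clinical size) was
  fixed a priori to mirror the reference study's reported model ordering and
  sized by a power analysis so that the ordering is decidable at cohort
  sizes of ~100 patients. Clinical covariates without planted effects (sex,
  smoking, tumor markers, CT signs, lobe) are Bernoulli/categorical draws at
  the reference training-cohort marginal frequencies.

Scalar randomness (latents, label, clinical, geometry parameters) and image
randomness are separate per-patient streams, so cohorts can be generated
without rendering for label-model studies with bit-identical clinical
tables.

**What the phantoms are not**: anatomically realistic lungs. There are no
airways, vessels, pleural surfaces, scanner or reconstruction-kernel
effects, or segmentation error. Passing tests therefore demonstrate that the
pipeline's *mechanics* are correct and that its statistics behave as
designed under known ground truth — not that the models would reach any
particular performance on patient CTs.

## Preprocessing

Intensities are resampled to 1 mm isotropic with B-spline interpolation
(masks: nearest-neighbour), then lung-windowed: x ↦ clip((HU + 1250)/1500,
0, 1). Windowing after resampling avoids interpolating a clipped signal.
Radiomic and voxel features are computed on the windowed image; out-of-field
voxels created by resampling are filled with −1024 HU (air). Voxel indices
are 0-based; world coordinates follow the NIfTI affine; distances are mm.

## Peritumoral rings

Rings are built from a Euclidean distance transform with the voxel spacing
as sampling, so "3 mm" means 3 mm even at anisotropic spacing; distance is
measured to the tumor voxel-centre set. The ring is dilation minus tumor,
intersected with the lung mask (automatic stand-in for the study's manual
chest-wall correction; for real data a HU < −300 connected-component
heuristic is provided). Rings are strictly exterior — intratumoral cavities
are not part of any ring. An empty post-exclusion ring is an error naming
the case.

## Habitat clustering

Each tumor voxel gets 19 first-order statistics of its 5×5×5 window: mean,
median, min, max, range, variance, SD, skewness, kurtosis (Pearson,
non-excess), energy, RMS, entropy and uniformity (32 fixed bins on [0, 1]),
MAD, robust MAD (P10–P90 band), and percentiles 10/25/75/90. Windows are
clipped at the volume border and **masked to the tumor**: extratumoral
voxels never enter a window, because the tumor/parenchyma edge contrast
(~0.5 in windowed units) would otherwise dominate the ~0.03–0.06 windowed
separation between subregions and voxel clustering would segment
distance-to-boundary instead of texture. Fixed entropy bins remove
per-window bin instability.

Per sample, features are Z-scored and clustered with K-means (k-means++, 10
restarts, fixed seed). The cluster count is selected once, cohort-wide, as
the argmax of the per-sample **mean** CH index over k = 2..8 (per-sample k
is not allowed; pooling voxels across patients is not done). Cross-patient
correspondence is imposed by relabeling clusters in increasing order of mean
windowed intensity — label 1 is always the darkest habitat. Whether the
source study Z-scored voxel features or averaged vs pooled CH is
undocumented; both choices here are flagged as such.

## Radiomic features

88 features per region on the original (windowed) image: 14 shape, 18
first-order, 24 GLCM, 16 GLRLM, 16 GLSZM, following IBSI reference
formulas. Conventions fixed here: fixed-bin-count 32 discretization over the
region's intensity range; GLCM symmetric, distance 1, feature values
averaged over the 13 unique 3-D directions; GLRLM likewise per-direction
averaged; GLSZM zones are 26-connected. Shape features come from the
marching-cubes mesh of the mask after Gaussian pre-smoothing (σ = 0.8
voxels), which suppresses the ~10% staircase inflation of surface area on
digital spheres at the cost of a few percent volume bias on small regions;
single-slice or sub-8-voxel regions fall back to voxel-face surface
estimates with a warning. Regions under 2 voxels yield all-missing vectors
that feed the imputation stage.

A published filter-bank feature count of ~1834 per region implies wavelet
and LoG image filters whose settings are not described; this package
implements the 88 original-image features and documents the difference
rather than guessing a filter bank.

KNN imputation: missing cells take the mean of the 5 nearest training rows
by Euclidean distance on Z-scored complete columns; the neighbour pool is
the training split only, for every split.

## Selection cascade

Order: ICC → Z-score → Mann–Whitney → Pearson pruning → mRMR → LASSO.
All statistics are fitted on training rows only; survivor sets are nested by
construction and the report enforces it.

- ICC(2,1), two-way random, absolute agreement; a feature must exceed 0.75
  in every supplied rating study (inter- and intra-observer).
- Z-scores use the population-SD convention; zero-SD training columns are
  dropped, never divided.
- Mann–Whitney is two-sided with scipy's exact/normal switching; constant
  features get p = 1.
- Pearson pruning is greedy in descending |r| over pairs with |r| > 0.9;
  the member with the larger U-test p is dropped (tie: lexicographically
  later name).
- mRMR uses the MID (difference) criterion with plug-in mutual information
  after equal-frequency 4-bin discretization; m = 30 by default.
- LASSO-logistic: 100 log-spaced λ from the KKT bound λ_max down 3 decades;
  λ* minimizes mean 10-fold stratified CV binomial deviance (min-deviance
  rather than 1-SE); if λ* zeroes every coefficient the largest λ with
  nonempty support is used, logged.

## Models and fusion

Five families per region — logistic regression, KNN, random forest,
LightGBM, MLP — each tuned by stratified 5-fold CV on the training split
over small fixed grids (e.g. RF depth {6, ∞}; LightGBM 100/300 trees, depth
{3, ∞}; MLP (32,) or (64, 32); chosen for reproducibility over
exhaustiveness). The winning family per region has the highest
validation-split AUC; this is the only step that reads validation labels
and it is logged as such. The test split never influences any choice.

The Combined model stacks Habitat + Peri3mm + Clinical: base estimators are
refitted per fold at their chosen hyperparameters, out-of-fold
probabilities on the training split form the meta design, and the
meta-learner is a logistic combiner with **non-negative** base weights
(L-BFGS-B with box constraints, light L2) over a **forward-selected** base
subset: starting from the best single base, a base is admitted only when it
raises the cross-validated AUC of the combiner over the OOF rows by more
than 0.005 (a noise-level guard). Non-negativity and selection are the
classical stabilizers for stacked ensembles at small n: an unconstrained
fit on a few dozen noisy collinear OOF columns routinely flips signs or
dilutes the stack below its own best member. When no other base helps, the
stack reduces to a monotone transform of its best base. Simple-average
fusion remains available by combining base probabilities directly.

The clinical model uses the multivariable-significant predictors from the
univariable → multivariable (p < 0.05) Wald screen; at desk-scale cohorts
where no variable reaches significance the pipeline falls back to the
single best univariable predictor, logged. Binary operating points use the
training-split Youden threshold, frozen for validation/test.

## Evaluation

AUC is the tie-corrected Mann–Whitney statistic; variance and the paired
test use DeLong structural components with normal CIs (the CI method is a
choice; the source names only "DeLong"). Hosmer–Lemeshow uses 10 deciles of
risk (bin count unstated in the source), χ² with bins−2 df. Decision curves
use NB = TP/n − (FP/n)·p_t/(1−p_t) on a 0–0.99 grid. Odds ratios are ad/bc
with Wald CIs, Haldane 0.5 correction on zero cells. No multiple-testing
correction is applied anywhere (the reference analysis applies none).
Comparisons against published 2-dp values use half-up rounding.

## Study problem sizes

Chosen so the full suite runs in minutes on one CPU, and stated here as the
package's own design: k-recovery uses 20 replicates of 40-patient default
cohorts; the model-ordering study uses 20 replicates of 100-patient cohorts
(7:3 train/validation) plus 60 external-test phantoms on 48³ grids with the
3 mm ring and k fixed at the recovered optimum 3; coefficient-recovery uses
15 scalar-only cohorts of 1000. The 48³ grid changes only the field of
view, not tumor sizes or any planted effect.

## Known limitations

- Habitat composition is recovered only partially at the planted texture
  contrasts: per-sample Z-scoring plus per-sample K-means absorb part of a
  composition shift, so recovered subregion volume fractions are attenuated
  estimates of the planted fractions (the signal survives multivariably
  across the habitat feature block).
- The 19 voxel statistics and several discretization/aggregation settings
  are field-standard conventions fixed here, not validated choices from the
  source study; sensitivity to them is untested.
- Phantom realism limits (above) mean desk-scale AUCs say nothing about
  clinical performance; only orderings and mechanics are meaningful.
- Shape features on very small regions (habitat fragments of a few voxels)
  are dominated by mesh fallback behaviour and carry little information.
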