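# Methods

This note documents the models, algorithms and design choices behind
`lvatlas`: what each stage assumes, which parameters matter, what the
synthetic cohorts do and do not emulate, and the numerical conventions that
make every run reproducible.

## 1. Shape representation and synthetic geometry

A case is a flat vector `[x1, y1, z1, …, xN, yN, zN]` (mm) of homologous LV
surface points: endocardium and epicardium at end-diastole (ED) and
end-systole (ES). The default sampling is 785 points per surface (28 rings
× 28 meridians plus an apical pole), i.e. 3140 points and 9420 coordinates
per case. Homology means identical grid indices across cases, so
coordinate-wise statistics are meaningful.

The synthetic LV is a truncated prolate spheroid:

| parameter | default | unit | rationale |
|---|---|---|---|
| endo semi-axes at ED (a,b,c) | (22, 22, 63) | mm | EDV ≈ 126 mL, mid-range for the 54–77-year band |
| wall thickness at ED | 7 | mm | LV mass ≈ 123 g (LVMI ≈ 65 g/m² at BSA 1.9 m²) |
| radial thickening fraction | 0.25 | – | with shortening 0.28 gives EF = 59.5% |
| long-axis shortening fraction | 0.28 | – | ″ |
| basal truncation fraction | 0.92 | – | basal plane at 0.92·c; keeps enclosed volume within ~1.5% of the full-spheroid closed form, which anchors the volumetry tests |

The ES endocardium is the anisotropic contraction of the ED spheroid
(transverse axes ×(1−0.25), long axis ×(1−0.28)); the ES wall offset is
solved by root finding so myocardial (shell) volume is conserved, giving
systolic wall thickening of ~7→10.5 mm. Because ES is a linear image of ED
on the same parametric grid, the mesh-integrated EF equals the scaling
determinant exactly, independent of grid resolution.

The truncation plane is higher (more apical) than a real LV base; this is a
stand-in choice that trades basal realism for analytically checkable
volumes. Real LV bases, papillary detail, fibre orientation and regional
wall-motion abnormalities are all absent.

## 2. Synthetic cohorts

`generate_cohort` draws, in a documented stream order (demographics → risk
assignment → covariates → remodeling traits → background modes →
coordinate noise → rigid misalignment), all from one master seed:

- **Risk assignment** is independent Bernoulli per factor at the configured
  prevalence. Covariates are then sampled *conditionally on assignment* so
  that the guideline classifier reproduces the configured prevalence in
  expectation (e.g. assigned hypertensives are either medicated or receive
  SBP/DBP above the case's threshold, which is 130/80 mm Hg for diabetics
  and 140/90 mm Hg otherwise; diabetes is resolved first because it lowers
  those thresholds). Assignment is independent of age and sex by
  construction, which is what makes the null-calibration runs clean.
- **Shapes** = base LV + per-factor remodeling displacement + background
  modes + i.i.d. coordinate jitter, then optional core-lab bias and a
  random rigid misalignment (rotation SD 5°, translation SD 5 mm) that the
  Procrustes stage must remove.

**Displacement scale convention.** Effect sizes, trait SDs and
background-mode SDs are root-mean-square *per-point* displacements in mm: a
"1 mm effect" moves surface points by 1 mm RMS (the displacement vector is
`effect × √N_points × unit direction`). This keeps effects on the physical
scale of wall remodeling and puts the generator in the regime of real
atlases, where population variance is low-rank and far above measurement
noise.

- **Remodeling directions** are named parametric deformations, each a unit
  vector in shape space: concentric wall thickening (hypertension), cavity
  dilation (obesity), reduced systolic excursion (diabetes), and two fixed
  blends (hypercholesterolaemia, smoking). They are geometrically derived,
  mutually correlated (as comorbid remodeling is), and overridable per
  factor — including by an explicitly orthogonal random direction to model
  a cohort in which a factor remodels the heart differently.
- **Remodeling traits**: every case has a latent level along each effect
  direction, `N(0, 0.5 mm)`; carrying the factor shifts the mean by the
  effect size. Population overlap along the remodeling direction — not
  measurement noise — is what limits discrimination, so the ideal
  separability is `d′ = effect/0.5`. Default effect sizes (0.37–0.65 mm)
  were calibrated once by simulation to target internal AUCs in the
  0.70–0.85 range typical of large-cohort shape–risk discrimination (the
  README's worked example shows the resulting values).
- **Background modes**: 10 orthonormal modes, the first being global heart
  size (SD 2.0 mm RMS/point, the dominant mode in real atlases), the rest
  random directions with decaying SDs (1.2 → 0.25 mm). The size mode
  overlaps the remodeling directions (bigger hearts have thicker walls),
  adding realistic confounding.
- **Coordinate noise**: 0.05 mm SD per coordinate by default. Shapes of
  this kind come from smooth model surfaces fitted to contours, so
  per-point jitter is far below voxel size; with this default, ~99.9% of
  cohort variance lies in a few dozen modes and the atlas cutoff retains
  K ≈ 15–35 components. (At 0.5 mm jitter the cutoff retains ≈ n−1
  components; the package still runs there — the parameter-recovery
  validation uses exactly that setting — but leave-one-out evaluation in
  a K ≈ n regime is intrinsically unstable and does not correspond to real
  atlas data.)
- **Core-lab bias** (`apply_corelab_bias`) deterministically re-contours
  every case: endocardial points scale about the cavity centroid by
  `cavity_scale^(1/3)` (cavity volume scales by exactly `cavity_scale`);
  the epicardium is rebuilt as new endo + `wall_thickness_scale` × the
  homologous wall offset, with optional apically weighted thinning. The
  operation follows local endo→epi directions, so it commutes with rigid
  motion. The "cohort A" preset (wall ×1.384, cavity ×0.78) yields ~30%
  more mass and ~22% smaller volumes than the reference convention.

## 3. Risk-factor definitions

Guideline thresholds, applied to complete cases (missing covariates raise):
hypertension = antihypertensive medication OR adjusted SBP ≥ 140 / DBP ≥ 90
(130/80 if diabetic), with +15/+10 mm Hg added to treated participants'
measured pressures before comparison (the medication OR-clause already
classifies them; the adjustment matters for any continuous use of BP);
diabetes = HbA1c > 48 mmol/mol (equivalently > 6.5%) OR insulin OR known
diagnosis; hypercholesterolaemia = LDL-C ≥ 190 mg/dL OR (LDL-C ≥ 100 mg/dL
AND age ≥ 65 AND lipid-lowering medication); obesity = BMI > 30 kg/m²
(strict); smoking = current or previous. "Above" thresholds are strict
`>`, "≥" thresholds inclusive, following the wording of the definitions.
The no-risk group is the absence of all five; per-factor analyses compare
carriers of that factor (regardless of others) against the no-risk group,
excluding everyone else.

## 4. Atlas construction and projection

Generalised Procrustes alignment: rotation + translation only (optimal
per-shape rotation by SVD with determinant correction — reflections are
forbidden because anatomical chirality must be preserved; scale retained).
Convergence at relative mean-change < 1e-10, max 100 iterations, first pass
aligned to shape 0; after convergence each shape is re-aligned once to the
final mean, so every aligned training shape is the optimal rigid fit to the
returned mean — this is what makes one-shot external projection reproduce
training scores to ~1e-12.

PCA by economy SVD of the centred matrix, variances with divisor n−1,
component signs fixed so the largest-magnitude loading is positive
(deterministic output). K = smallest count reaching the 99.9% cumulative
variance cutoff. Projection of an arbitrary homologous shape: one-shot
rigid alignment to the atlas mean, subtraction, dot products with the
components; the out-of-subspace residual is discarded (its norm is kept in
`last_projection_residual_` for auditing).

## 5. Discrimination and evaluation

Predictors `[age, sex, shape scores]` are centred and scaled **block-wise**:
age and sex each to unit variance, the entire score block by one pooled SD.
The scores are mutually commensurate (mm along orthonormal modes); scaling
each score column individually would inflate near-noise components by an
order of magnitude relative to signal components and destroy the anatomical
meaning of the coefficient direction — a failure the direction-recovery
validation (section 6) is designed to catch.

PLSR uses the standard univariate-response NIPALS decomposition (identical
to SIMPLS for a single response). The component count minimises
cross-validated squared error of the 0/1 response over a 1–30 grid
(stratified five-fold, seeded, ties to the smaller count); the per-fold
coefficient path for all grid points comes from a single maximal fit, using
the triangular structure of NIPALS loadings.

Internal performance is leave-one-out: each case scored by a model fitted
to all others, with the component count fixed beforehand. LOO scores are
**intercept-free** (the per-fold label-mean intercept is omitted): the fold
intercept is perfectly anti-correlated with the held-out label and, if
kept, deterministically depresses the null AUC — the classic leave-one-out
pessimism artifact. Omitting a per-fold constant is rank-preserving for
any fixed model. Null calibration was verified by simulation (mean
zero-effect LOO AUC ≈ 0.50).

External evaluation trains on all internal cases, projects the external
cohort's shapes through the internal atlas, combines them with external
age/sex, standardises with the *internal* training parameters, and applies
the frozen coefficients.

AUC is the Mann–Whitney rank statistic (ties half-credit; verified exactly
against pair enumeration). CIs are stratified percentile bootstrap (2000
replicates, seeded; stratified resampling keeps every replicate two-class).
The internal-vs-external comparison is a z test with per-curve DeLong
variances — the standard unpaired-ROC procedure — with a Welch t test on
bootstrap replicates available behind a flag as the alternative reading of
the procedure. Operating points maximise Youden J (ties to the lower
threshold). The no-risk cohort comparison matches cases 1:1 exactly on
(age, sex) — with only those two variables in the propensity score, nearest
matching reduces to exact cell matching, paired in input order. Cohort
tables use Wilcoxon rank-sum for continuous and Pearson χ² for categorical
variables; significance at p < 0.05 throughout.

Shape-effect contours reconstruct `mean ± magnitude × direction`, where the
direction is the shape block of the raw-unit coefficients mapped through
the atlas components and normalised (so the displacement norm equals
`magnitude` exactly). Age/sex coefficients are excluded from the contour:
the contour is meant to display the shape effect, and the covariates have
no shape-space image.

## 6. Validation experiments and problem sizes

`lvatlas.calibration` packages the standard validation runs; the test suite
and `scripts/acceptance.py` drive them at these sizes:

- **Null calibration**: five balanced single-factor cohort pairs
  (prevalence 0.5, zero effects, n = 500/cohort) — the maximum-precision
  design for a fixed n, since the no-risk group is undiluted by other
  factors. LOO AUCs should sit in [0.45, 0.55]; note the intrinsic
  per-run SD is ~0.03, so occasional excursions to ±0.06 are expected
  statistical behaviour, not leakage. The DeLong comparison's type-I rate
  is checked on 200 replicate null pairs (150/150 per curve).
- **Parameter recovery**: effect 2 mm, n = 800, coordinate noise 0.5 mm;
  the recovered effect direction should align with the generative one
  (cosine > 0.8; additional CV-chosen components drift the coefficient
  towards the whitened discriminant, so the cosine sits closer to the
  bound than a single-component fit would). The effect-size sweep
  (0, 0.5, 1, 2 mm; n = 300; five seeds) should be monotone in mean
  internal AUC, rising from chance to near-perfect separation.
- **Twin-cohort generalisability**: n = 800/cohort, effect 1.5 mm, cohort A
  carrying the core-lab bias. With shared remodeling directions, internal
  and external AUCs agree within 0.05 for every factor — the central
  result: constant contouring bias shifts all projected scores equally and
  cancels in rank-based discrimination. With the obesity direction made
  orthogonal in cohort B, obesity loses external performance in both
  directions (an AUC drop well above 0.05 at p < 0.05) while every other
  factor stays within the 0.05 band — "only obesity" is asserted through
  that band rather than through the other factors' p-values, which, being
  calibrated null tests, reject at their nominal rate across repeated
  runs.

These sizes were chosen so the full validation completes in a few minutes
on one CPU while keeping every check's statistical resolution well inside
its tolerance.

## 7. Known limitations

- The geometry is a smooth axisymmetric stand-in; passing tests say nothing
  about segmentation error, basal-slice selection, or regional remodeling
  patterns in real images.
- Risk factors are assigned independently; real comorbidity correlation
  (which raises the no-risk fraction and couples group compositions) is not
  modelled.
- Effects are additive mean shifts in fixed directions; nonlinear or
  heterogeneous remodeling (e.g. the documented complexity of
  obesity–shape relationships) only enters through the orthogonal-direction
  scenario.
- Leave-one-out AUC in a K ≈ n score regime (high coordinate noise) is
  intrinsically unstable; conclusions there should rest on the full-data
  model, not LOO.
- The unpaired DeLong comparison treats internal and external AUCs as
  independent; both use the same trained model, so the test is
  approximate — consistent with its use here as a flagging rule.
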