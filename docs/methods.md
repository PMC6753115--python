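# Methods

## The model

The package studies whether a nonlocal patch-based grading score can
order a clinical continuum — cognitively healthy controls (CH), subjective
cognitive decline (SCD), early and late mild cognitive impairment (eMCI,
lMCI), and Alzheimer's dementia (AD) — better than plain structure
volumes, using a fully synthetic cohort in which the ground truth is
known.

### Patch grading

Given a subject image in template space and a library of training scans
labeled CN (group tag 1) or AD (tag 2), each subject voxel *x* is
described by its cubic intensity patch `P(x)` (default 7×7×7 voxels,
`patch_radius=3`). Every template patch within the search window
(default ±`search_radius` voxels per axis around the same template-space
location, across all templates) is a candidate *j* with distance

    d_j = Σ (P(x) − Q_j)²          (sum of squared differences)

and weight

    w_j = exp(−d_j / h²),   h² = min_j d_j .

When `min_j d_j = 0` (exact match) the weights degenerate to uniform mass
on the zero-distance candidates; this limit makes the subject-in-library
case exact and the whole rule invariant to rescaling all intensities by a
common constant, since only the ratios `d_j / min d` enter.

Two quantities are fused per voxel:

* **label** — structure code with the maximal summed weight (patch-based
  segmentation; ties break to the lowest code);
* **grading** — `Σ w_j g_j / Σ w_j` with `g_j` the candidate template's
  group tag, a value in [1, 2] where higher means more AD-like.

A structure's **region grading score** is the unweighted mean grading over
the voxels fused to that structure. Averaging over the fused segmentation
(rather than a fixed prior mask) keeps segmentation and grading
self-consistent; both behaviors are available.

**Candidate preselection.** Candidates whose patch mean or variance ratio
against the subject patch falls outside `[t, 1/t]` (default `t = 0.5`) are
skipped; a voxel where nothing survives falls back to the exhaustive set
(counted, never empty). In this implementation preselection is a candidate
*filter*, not a speed-up — the vectorized engine computes distance fields
for whole voxel blocks at once — and at structure boundaries it can drop
cross-tissue candidates and flip a few percent of fused labels relative to
the exhaustive set. It is on by default for fidelity to standard
patch-based segmentation practice, and the exhaustive path is the
reference.

**Engine.** For each (template, window-offset) pair the SSD of all target
voxels is computed in one pass as a box filter of the squared shifted
difference image, in float64, two streaming passes (min-distance, then
weight accumulation). A deliberately naive per-candidate loop
(`brute_force_grade`) is kept as the reference oracle; the two agree to
~1e-15 relative.

### The phantom

Real T1 anatomy is replaced by the simplest geometry with an analytically
checkable volume: a large "brain" ellipsoid of uniform tissue (intensity
80) on background 10, containing mirror-symmetric ellipsoid pairs for the
hippocampus (HPC, core 110, rim 95) and entorhinal cortex (EC), each with
a rim shell (outer 25% of the radius). A severity scalar `s ∈ [0, 1]`
drives:

* volume: radii shrink so the ellipsoid volume is `1 − 0.3·s` of baseline
  (`volume_loss_max = 0.3`);
* intensity: rim *and* core fade linearly toward tissue by up to 30%
  (`intensity_shift_max = 0.3`). The core fade matters: without it the
  interior patches of CN and AD templates are identical and region grading
  dilutes toward the 1.5 midpoint.

Subject realizations add per-subject shape jitter (centers ±1 voxel SD,
radii ±3%), additive Gaussian noise (SD = 3% of tissue intensity; a
simplification of scanner noise, which is Rician at low SNR), a smooth
multiplicative polynomial bias field (peak-to-trough 20%, order 2, mean 1
over the brain), and a small rigid pose (≤3 voxels translation, ≤3°
rotation). Template-library scans are emitted aligned and bias-free with
noise only, the way a curated training library of preprocessed scans
would be; CN templates draw severity from U[0, 0.1] and AD from
U[0.8, 1].

The default cohort reproduces the emulated study's final sample:
CH 29, SCD 66, eMCI 22, lMCI 8, AD 12 (137 total). Group severities are
CH 0.05, SCD 0.15, eMCI 0.40, lMCI 0.60, AD 0.85 with a per-subject SD of
0.05. No quantitative atrophy difference between SCD and CH is
established, so the SCD value is a free parameter set barely above CH;
the 0.10 gap (two within-group SDs) is chosen once so the designed
CH-to-AD ordering is resolvable at the default sample sizes. A
consequence worth noting: at the full 137-subject size this small offset
*is* statistically detectable, so SCD-vs-CH contrasts in this synthetic
study measure the generator's dial, not a claim about real SCD anatomy.
Covariates (age, sex, education, MoCA, CDR,
Logical Memory, GAI, GDS, RAVLT) are drawn per group from truncated
normals matching the study sample's moments, truncated to each group's
classification ranges so that every generated record classifies back to
its group; truncation locations are mean-matched so the realized group
means hit their targets.

What the phantom does **not** emulate: realistic neuroanatomical shape
and texture, partial-volume mixtures, multi-tissue contrast, Rician
noise, scanner/site effects, or any true age/sex effect on anatomy (the
normative covariate slopes are therefore near zero — the adjustment
machinery is exercised, not stressed). Passing tests show the pipeline
recovers the structure it was given under this corruption model, not that
it would perform equivalently on clinical MRI.

### Preprocessing

1. **Denoising** — nonlocal means (scikit-image), bandwidth 0.8× a noise
   SD estimated from the median absolute deviation of discrete-Laplacian
   residuals (stencil variance gain 42).
2. **Bias correction** — polynomial fit (order 2) to log-intensity over an
   eroded foreground mask, with an iterated 2.5-MAD residual trim so
   structures and boundary ramps do not bend the field; the field is
   normalized to mean 1 over the mask and divided out. This is a stand-in
   sharing the classic correctors' contract, not a re-implementation of
   them. On a bias-free phantom the recovered field is 1 to 1e-6; a known
   order-2 field is recovered to ≪5% relative RMSE.
3. **Registration** — SimpleITK rigid (Euler) transform maximizing
   normalized correlation, multiresolution shrink factors [4, 2, 1] with
   smoothing sigmas [3, 1, 0] and a regular-step gradient descent
   (learning rate 1.0, relaxation 0.5; settings selected by a grid search
   over known poses). Cohort runs stop at half resolution (levels = 2,
   ~0.3 s, ~0.7-voxel accuracy — inside what the patch search window
   absorbs); the recovery test uses the full pyramid with a 400-iteration
   budget, reaching <0.3 voxel mean displacement. Output is resampled
   onto the template grid (trilinear; labels nearest-neighbor).
4. **Intensity normalization** — least-squares linear map `a·I + b` onto
   the template, fitted over the whole grid with one robust trim pass.
   The whole-grid fit is deliberate: within the brain mask alone,
   inter-subject anatomical mismatch acts as an errors-in-variables
   problem and attenuates the slope catastrophically, while the
   head-versus-background contrast anchors it.
5. **Brain extraction** — the fusion engine with brain/non-brain labels,
   run only over the library's mask-disagreement band (the interior and
   exterior consensus is taken as-is), in axial slabs to keep working
   boxes small, against a balanced 4-template subset. Dice against truth
   ≥0.99 on clean phantoms.

Normalization runs before extraction (library intensities are assumed
template-normalized); the order is recorded in each result's log.

### Normative Z-scores and QC

Raw measures are structure volumes from the fused label field (voxel
count × voxel volume) and the four region grading scores. A normative
model is fitted by OLS on CN subjects only — age + sex for grading
scores; age + sex + estimated intracranial volume (= brain-mask volume)
for volumes — and applied as `Z = (raw − predicted) / residual SD`, with
the degrees-of-freedom-corrected residual SD. Grading Z-scores are
sign-flipped so negative = more AD-like for every measure. The normative
sample is generated at CH severity and pushed through the *same*
corruption and preprocessing chain as the cohort; calibrating against
clean scans instead leaves the healthy cohort group 1–2.5 SD off zero,
because preprocessing shifts raw gradings systematically.

Segmentation QC counts voxels carried by exactly one of the
estimated/reference label fields and excludes the region at ≥100
discrepant voxels. In the pipeline the rule gates the volume (atrophy)
arm only — mirroring a design where segmentation QC governs the
morphometry while the grading arm has its own pipeline — and composites
average the surviving regions. With ~800-voxel structures the 100-voxel
rule is strict; typical runs exclude an appreciable fraction of HPC
volumes while EC survives, and the exclusion rate is reported per run.

### Statistics

Classical one-way ANOVA with Tukey-Kramer post-hoc pairs (scipy) for the
main outcomes; Benjamini-Hochberg FDR across the region battery for the
SCD-vs-CH scan; Cohen's d with the (n−1)-weighted pooled SD; Pearson
chi-square (uncorrected) for sex tables; and OLS interaction models
`biomarker ~ complaint + symptom + complaint×symptom` for the
anxiety/depression (GAI/GDS) moderation question. Welch-type corrections
are not applied (plain one-way ANOVA is the emulated design); adjusted
p-values are reported untruncated.

## Problem sizes

The method defaults are `patch_radius=3` (7×7×7) and `search_radius=5`;
the analysis runs use `search_radius=1` with an 8+8 template library, a
40-subject normative sample and half-resolution registration — the
working point where a full 137-subject study runs in minutes on one core.
Registered subjects sit well under a voxel from template space, so the
±1-voxel window already spans the residual misalignment plus the
phantom's shape jitter; widening it mainly adds redundant candidates at
these problem sizes. Test-suite checks run the same engine at reduced
sizes (toy 16³ grids for oracle comparisons; 32³ phantoms for the
50-seed null-cohort control; a 44-subject gradient cohort), and the
statistics calibration uses 500 simulations per error-rate estimate.

## Numerical choices and degenerate inputs

* Engine arithmetic is float64 end-to-end; the box-sum SSD is exact
  enough that the oracle comparison passes at 1e-10 relative.
* Argmax ties in label fusion resolve to the lowest code; patch windows
  at volume borders use replicate padding.
* Exact-match limit: `min d = 0` → uniform weights on zero-distance
  candidates (no division by zero, exact tag recovery).
* Flat or nonpositive subject patches make the preselection ratios
  undecidable; such candidates are kept.
* An all-background volume fails brain extraction loudly (no intensity
  contrast across the mask); a constant volume is rejected by intensity
  normalization (zero variance); empty masks and rank-deficient normative
  designs raise with the offending covariates named.
* Per-subject pipeline failures are recorded in the scores table and the
  run continues; a structure with no fused voxels yields an undefined
  (NaN) score and a warning.

## Known limitations

* The phantom's geometry is far simpler than neuroanatomy; absolute
  grading values and effect sizes are not comparable to clinical studies,
  only orderings and calibration properties are meaningful.
* The bias-correction and brain-extraction stages are contract-level
  stand-ins for N3-class and BEaST-class algorithms.
* Registration is rigid only; the phantom generates no affine scale
  component.
* The normative adjustment has near-null covariate slopes by
  construction (no age/sex effect in the generator).
* The QC rule's absolute 100-voxel threshold interacts with structure
  size; at desk scale it is a strict filter and its exclusion rate is a
  reported output rather than a tuned quantity.
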