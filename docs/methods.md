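# Methods

`radiotme` implements a radio-genomics analysis linking semi-quantitative
breast DCE-MRI radiomic phenotypes to the cellular composition of the tumor
microenvironment, exercised end-to-end on synthetic cohorts with planted,
recoverable ground truth. This note documents the models, the numerical
conventions, the synthetic data design, and the known limits of what the
test suite demonstrates.

## Imaging model and kinetic features

A lesion study is one pre-contrast and three post-contrast T1-weighted
volumes on a shared grid with a binary tumor mask. Each in-mask voxel
carries a 4-point enhancement curve

E_t = (S_t − S_0) / max(S_0, ε),  E_0 = 0,

with ε = 1 intensity unit guarding non-positive baselines (logged once per
lesion). The four semi-quantitative kinetic parameters are

* **PE** (peak enhancement) = max_t E_t over the post-contrast phases
  (unitless);
* **TTP** (time to peak) = time of the earliest maximizing phase minus the
  pre-contrast time (minutes). Ties break toward the earliest phase; a
  flat curve takes the first post-contrast phase with WIS = 0;
* **WIS** (wash-in slope) = PE / TTP (min⁻¹);
* **WOS** (wash-out slope) = (E_last − E_peak)/(t_last − t_peak), defined
  as 0 when the peak is the last phase (min⁻¹, ≤ 0 on washout curves).

Enhancement is baseline-relative because it is the standard unit-free
normalization in semi-quantitative DCE analysis; parameters are computed
per voxel and then aggregated (a tumor-mean-curve variant can be derived
from the same maps but is not the default).

The **88 kinetic features** come in three groups:

1. *Aggregate (10)*: mean and SD over the mask of WIS/WOS/PE/TTP, the
   maximum voxel PE (MPE), and the **hot spot** — the highest mean PE over
   a 3×3×3 (26-connected) neighborhood intersected with the mask. The
   neighborhood size is a fixed convention of this implementation.
2. *Heterogeneity (21)*: the mask is partitioned into **quick /
   intermediate / slow** arrivals at peak. With three post-contrast phases
   TTP takes exactly three values, so the partition is exact and needs no
   clustering (a k-means-on-TTP fallback would slot in for longer series).
   Per sub-cluster: mean and SD of WIS, WOS, PE (empty sub-clusters
   contribute zeros) plus the three proportions, which always form a
   simplex.
3. *Textural kinetic (57)*: for each of the WIS, WOS and PE parameter
   maps, in-mask values are quantized to 11 equal-width bins (min–max),
   a symmetric 3D co-occurrence matrix is pooled over the 13 unique
   distance-1 offsets and normalized, and 13 classic co-occurrence
   descriptors (ASM, contrast, correlation, variance, IDM, sum
   average/variance/entropy, entropy, difference variance/entropy,
   IMC1/IMC2) plus AVD (Σ p(i,j)·|i−j|) and 5 histogram statistics
   (mean, SD, skewness, kurtosis, quantized-histogram entropy) are
   emitted. Computing texture on the three kinetic parameter maps is the
   choice made here because a 3-level TTP label map alone cannot support
   a 57-descriptor catalog.

Degenerate conventions: a constant map quantizes to a single level and the
co-occurrence descriptors take their closed forms (ASM = 1, contrast = 0,
IDM = 1, AVD = 0, entropy = 0); correlation is defined as 0 when the
marginal variance vanishes. No feature is ever NaN.

## Static radiomic features

The **111 static features** split 14 shape / 22 first-order / 24 GLCM /
16 GLRLM / 16 GLSZM / 14 GLDM / 5 NGTDM. The split is a frozen, documented
catalog (`radiotme.catalog`); the binding constraint is the total of 111.
Intensity families are computed on the first post-contrast volume (highest
lesion conspicuity), preprocessed by min–max rescaling of in-mask values
to 8 bits and fixed-bin-width quantization with binWidth = 25
(level = ⌊rescaled/25⌋ + 1, at most ⌈256/25⌉ = 11 levels).

* *Shape (14)*: voxel and mesh volume, mesh surface area, surface/volume,
  sphericity, compactness, maximum 3D diameter, the three PCA axis
  lengths (4√λ), elongation and flatness (√(λ₂/λ₁), √(λ₃/λ₁)), equivalent
  sphere diameter, and bounding-box extent — all in physical mm units.
  The surface mesh is extracted by marching cubes from a σ = 0.8-voxel
  Gaussian-smoothed indicator to suppress the staircase bias of meshing a
  binary volume (a digital ball of radius 10 then measures sphericity
  ≈ 0.99 instead of ≈ 0.91); masks too small to survive smoothing fall
  back to the binary indicator.
* *First-order (22)*: 18 statistics of the reference-phase in-mask
  intensities (entropy and uniformity on the quantized histogram, the
  rest on raw values) plus the tumor mean intensity of each of the four
  phases as separate features.
* *Texture matrices*: GLCM uses the 13 distance-1 offsets, counted
  symmetrically, matrices pooled over offsets and normalized once; GLRLM
  pools runs over the same 13 directions (the run-percentage denominator
  is voxels × 13); GLSZM zones and GLDM dependencies (α = 0) use
  26-connectivity; NGTDM neighborhood tone is the mean level of in-mask
  26-neighbors, with isolated voxels contributing zero difference. All
  matrix families are verified against exhaustive-enumeration oracles on
  random ≤ 6³ ROIs.

## Synthetic cohorts

The generator is first-class, tested code: it defines the study
conditions under which every downstream stage is validated.

* **Phantom curves are piecewise linear in time**, not pharmacokinetic
  ODEs: a linear rise from 0 at the pre-contrast time to the archetype's
  peak enhancement at its peak phase, then a linear washout. This makes
  PE/TTP/WIS/WOS analytically known, giving 1e-9-level closed-form test
  oracles. Default acquisition times are (0, 1, 2, 3) minutes — contrast
  timing is a free parameter of the phantom.
* Three TTP archetypes (quick/intermediate/slow; defaults: peak
  enhancement 1.2/1.0/0.9 at phase 1/2/3, washout −0.25/−0.15/0 min⁻¹)
  are assigned per voxel i.i.d. from the configured simplex. Lesion masks
  are axis-aligned random-semi-axis ellipsoids (≥ 30 voxels enforced).
  Baseline signal is 100 intensity units; Gaussian noise (default SD 2,
  i.e. 2% of baseline) is added to every voxel of every phase.
* **Institution profiles** emulate two acquisition protocols: "A"
  (axial-like, 10×32×32 grid at 2.0×0.7×0.7 mm, identity intensity map)
  and "B" (sagittal-like, 10×24×24 at 2.2×0.9×0.9 mm, fixed affine shift
  S → 1.12·S + 18). The affine shift deflates relative enhancement by
  ≈ 14%, which is what makes a model trained on A degrade on B — the
  batch effect the PCA diagnostic and external-test comparison probe.
* **Expression**: 2,000 genes (desk-scale stand-in for a full
  transcriptome), 5 synthetic markers per population whose
  log2(1 + count) is base + 1.0 × true abundance + N(0, 0.25²);
  background genes are abundance-independent. Counts are 2^loc − 1, so
  the abundance score (mean log2(1 + count)) recovers the construction
  exactly at zero noise.
* **Planted couplings**: `planted_assoc` ties the lesion enhancement
  amplitude latent (amp = 1 + 0.15·z, clipped positive) to a population's
  abundance through a Gaussian copula at a target Pearson r; the realized
  correlation is recorded in the ground truth rather than assumed.
  `planted_effect` instead shifts the amplitude latent by d within-group
  SDs for samples above the abundance median, making a Cohen's-d group
  effect exact — this is the ground truth for the classification-sanity
  checks, where a copula inversion would only be approximate.

What the phantom does **not** emulate: pharmacokinetics (no Tofts-type
exchange), realistic breast anatomy or lesion morphology, spatially
correlated noise, motion, partial-volume effects, or real marker-gene
biology. Passing tests therefore demonstrate correctness of the
computational pipeline and its statistical behavior under known signal,
not clinical performance on real cohorts.

## Abundance scoring and stratification

Scores follow the MCP-counter idea: score(sample, population) = mean
log2(1 + count) over the population's marker genes present in the matrix
(absent markers dropped with a warning; a population with no matching
marker is an error). Scores are comparable across samples within a
population only. The shipped marker table is synthetic and
user-replaceable; published marker lists are not redistributed here.

High/low stratification uses the per-population median over the dataset
being labelled, with score ≥ median → "high". An external cohort is
stratified by its own medians (the alternative — reusing training
medians — is a one-line change; the dataset-local rule is the default
because the stratification is defined "across the entire data set" being
analyzed).

## Association scan

For each (feature, population) pair: simple linear regression of abundance
on the feature; the two-sided slope t-test p-value (identical to the
Pearson test for simple regression — asserted to 1e-9 in the suite);
Benjamini–Hochberg adjustment jointly over all pairs (199 × 10 = 1990 on
the full catalog) by default, per-population by flag. Zero-variance
features are annotated as degenerate with NaN statistics, never silently
dropped, so the output always has exactly 199 × 10 rows. The Welch
(unequal-variance) two-sided t-test is used for the high-vs-low
two-feature comparisons (tumor volume and mean PE against each
population's labels, 10 p-values BH-adjusted per feature).

## Classification

Per population, on the training cohort: recursive feature elimination
driven by random-forest importance (100 trees), eliminating down through
candidate subset sizes {2, 3, 4, 6, 8, 10, 12, 16, 20} with re-ranking at
each step; each candidate subset is scored by 5-fold stratified CV
repeated 5 times (accuracy), ties toward fewer features; fully
deterministic given the seed. The classifier is a binary logistic
gradient-boosted tree ensemble (100 rounds, depth 3, learning rate 0.1 —
stated defaults, all overridable; no hyperparameter search by design).

Evaluation: leave-one-out cross-validation pools all n held-out scores
into a single ROC (per-fold ROC is undefined for one sample). Each
held-out score is centered by its fold's mean predicted probability on
the training set: leaving a sample out shifts the training class prior
opposite to the held-out label, which biases the pooled AUC of
permuted-label data below 0.5, and per-fold centering removes that
artifact without affecting real signal (AUC is invariant to a common
monotone transform, and the centering only corrects the fold-specific
offset). External
cohorts are scored by the unchanged trained model. By default feature
selection runs once on the full training set and LOOCV runs on the
selected features — matching a single reported feature count per model —
and the evaluation record names this mode; a strict mode nesting
selection inside every fold is available (`nested_selection=True`).
AUC is rank-based with midrank tie handling (verified against the
Mann–Whitney pair-count identity).

The PCA batch diagnostic z-scores the pooled feature table (zero-SD
columns left centered), projects on the top two principal components, and
reports the silhouette coefficient of the cohort labels: ≈ 0 when no
batch structure exists, > 0.5 under a strong planted shift.

## Problem sizes used in validation

The shipped checks use desk-scale problem sizes chosen to make the
statistical assertions well-powered: planted-correlation recovery at
n = 500 lesions (tolerance ±0.1 on r); null p-value uniformity over 1,000
independent pairs at n = 100 (KS < 0.05); classification sanity with 5
informative + 95 noise features at n = 60 and planted d = 2 (LOOCV AUC
≥ 0.85); a 200-permutation null at n = 60 (mean AUC within 0.5 ± 0.05);
texture oracles on 100 random ≤ 6³ ROIs; batch comparisons with 60
training and 40 external lesions. Default synthetic grids (10×32×32,
≈ 500–2,000 in-mask voxels) keep a full 199-feature extraction at ~40 ms
per lesion.

## Known limitations

* The per-family feature-count split (111 = 14+22+24+16+16+14+5 and
  88 = 10+21+57) is a frozen reconstruction; only the totals are
  externally constrained.
* The copula planting realizes the target correlation only up to
  amplitude clipping and extraction noise; the realized value is recorded
  and checked, not assumed.
* MCP-counter-style scores are arbitrary-unit; no cross-population
  comparison or deconvolution is attempted.
* The batch-effect comparison is qualitative by design: the external AUC
  under a profile shift is asserted to be lower than the matched-profile
  AUC on identical ground truth, not to match any particular value.
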