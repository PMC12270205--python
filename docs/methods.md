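# Methods

## Scientific setting

Brain age is a scalar, in years, predicted from a structural T1-weighted
MRI volume by a regression model trained on cognitively unimpaired (CU)
individuals. The brain-age gap (BAG = BA − CA) summarizes how much older
a brain looks than its owner's chronological age; after bias correction
it is a sensitive marker of neurodegenerative burden. This package
implements a desk-scale version of that analysis for cohorts defined by
two cerebrospinal-fluid biomarker axes: AD status from the
p-tau181/Aβ42 ratio (positive at ratio ≥ 0.021, with the boundary ratio
counted positive — the threshold convention is configurable) and
Lewy-body status from the α-synuclein seed amplification assay
(positive / negative; intermediate readouts are excluded). The question
of interest is whether the co-pathology group (AD+LB+) shows faster
brain aging and steeper regional atrophy and cognitive decline than
either pathology alone.

Real multi-cohort MRI is controlled-access, so the package ships a
first-class synthetic-data generator whose planted effect sizes default
to the effect table a full-scale analysis of this design reports. Every
downstream stage is exercised and validated against that known ground
truth.

## Synthetic cohorts (`synth`)

**Demographics.** CU baseline ages are uniform over 23–100 years
(configurable); the four impaired subgroups draw ages from normal
distributions with means 72.0–74.3 and SDs 7.0–8.2 years, sex fractions
28–42% female, and MCI/dementia mixtures matching the reference
baseline table. Visit schedules are annual with 1–6 visits per subject
(ADNI-like), first visit at t = 0.

**Biomarkers.** Aβ42 is uniform on [500, 1700]; the p-tau181/Aβ42 ratio
is drawn uniformly below 0.98×threshold for AD− subjects and between
1× and 4× threshold for AD+, so labels reclassify exactly under the
0.021 rule. A configurable fraction (default 5%) of extra impaired
subjects carries intermediate SAA readouts to exercise the exclusion
path; their latent group is recorded but their table label is
`excluded`.

**Effective age.** Each subject's generative brain age at follow-up
time t is CA0 + t + offset(group) + slope(group)·t. Offsets default to
the cross-sectional corrected-BAG group means (0, 2.08, 2.40, 4.64,
6.93 years for CU and the four subgroups); slopes to (0, 0.03, 0.14,
0.29, 0.54) yr/yr. CU has offset and slope 0 by construction, so its
effective age is exactly chronological when noise is off.

**Volumes.** A rendered scan is a two-shell head phantom (cortical
shell intensity 1.0 around tissue 0.8, zero background) with a central
ellipsoidal cavity (0.05) standing in for the ventricles. The cavity
radius is parameterized so cavity *volume* grows linearly with
effective age, which makes the voxel-count feature (the brute-force
oracle `cavity_volume`) linear in age and the signal learnable by
global-average-pooled convolutional features. Default grid 32³ with
voxel noise SD 0.05; noise is applied only when an RNG is passed, so
noise-free rendering is bit-deterministic. The generator emulates
morphological aging only — no MRI physics, bias fields, scanner
effects, or realistic anatomy — so passing tests demonstrate pipeline
correctness, not clinical performance on real scans.

**Longitudinal outcomes.** Regional composites (ICV-normalized, with a
nominal ICV of 1,500 cm³) and cognitive scores follow
baseline + group-contrast + (slope + group-slope)·t (+ quadratic terms
where configured) + per-subject random intercept/slope + residual.
Group contrasts default to the reported mixed-model coefficients (e.g.
MTL atrophy-slope contrasts −1.45e−4 and −2.14e−4 per year for AD+LB−
and AD+LB+ vs AD−LB−); reference-group slopes, random-effect SDs, and
residual SDs are not reported at full scale and are fixed once at
plausible ADNI-like magnitudes, documented in `default_outcomes`.

## Quality control (`qc`)

Three detectors run *separately within each subgroup stratum* (minimum
stratum size 10; smaller strata are skipped with a warning), and the
union of flags is marked for manual review:

1. **Intensity screening** (raw volumes): robust z-scores (median/MAD,
   normal-consistent) of each scan's global mean and SD, threshold 3.0;
   plus a cohort-standardized voxel-extremes criterion (threshold 6.0)
   that catches scans whose voxels fall far outside the stratum's
   intensity range. Zero-MAD strata fall back to flagging any exact
   deviation from the median (so identical volumes flag nothing).
2. **PCA + Mahalanobis** (normalized volumes): flattened volumes are
   projected onto components retaining 95% of variance, capped at 10
   components — with the dimension approaching the sample count, sample
   Mahalanobis distances become nearly constant and the detector loses
   power. Squared distances are cut at the χ² 0.999 quantile with k
   degrees of freedom; near-zero component variances are diagonally
   loaded with a warning.
3. **Isolation Forest** on the same PCA scores, flagging the
   ⌈contamination·n⌉ most isolable scans (default 2%), deterministic
   given the seed.

An external pre-screening hook records externally supplied pass/fail
labels (e.g. from an automated surface-QC tool) without re-running it.

## Cohort handling (`cohort`)

One scan per subject is kept (earliest date, ties broken by scan id).
The train/validation/test split stratifies on 5-year age bins with
exact global targets train = round(0.8N), validation = ⌊0.1N⌋, test =
remainder — the rounding convention that reproduces (3,484, 435, 436)
at N = 4,355 — allocated to bins by floor + largest remainder, with
overflowing bin quotas spilled to bins with room (logged). Within-bin
assignment shuffles records keyed by a stable sort, so the split is
invariant to input row order for a fixed seed. `balance_check` reports
the age ANOVA and sex chi-square across splits.

## Brain-age network (`net`)

The regressor is a 3D DenseNet: a 5×5×5 stem convolution (stride 2 —
the standard downsampling stem; stride never affects parameter counts),
four dense blocks of (3, 6, 12, 8) layers separated by transitions
(norm → ReLU → 1×1×1 conv with compression 0.5 → 2× average pooling),
then an optional 3×3×3 convolution, global average pooling, and a
fully connected scalar head. Each dense layer is norm → ReLU → 1×1×1
bottleneck scaling the *current* in-channel dimension by factor s →
norm → ReLU → 3×3×3 convolution emitting k (growth-rate) channels,
concatenated onto the block's running features. Convolutions followed
by a normalization carry no bias by default (toggleable); the stem and
final convolutions do. Normalization layers are batch-norm with affine
pairs (2 parameters per channel).

`count_parameters` mirrors this construction in closed form and is
property-tested to equal the instantiated count for arbitrary
configurations. The full-scale reference configuration was resolved by
enumerating (stem width, growth rate, bottleneck scale, compression,
final width, bias toggles) with the closed-form counter and freezing
the candidate whose total is exactly 251,098,737 under the default bias
conventions: stem width 448, growth rate 156, bottleneck scale 1,
compression 0.5, final width 156.

**Training protocol.** Five cycles of 15 epochs (defaults), Adam, MAE
loss in years, batch size 8, initial learning rate 5e−6, early stopping
with patience 6 on an epoch-global no-improvement counter (reset only
on improvement, not at cycle boundaries), learning rate × 0.7 at any
cycle boundary whose completed cycle produced no new best validation
loss, checkpoint on every improvement, all randomness seeded (default
42). The scalar head's bias is initialized to the training-set mean age
(toggleable): under an MAE objective the gradient magnitude is
independent of the error, so without this the optimizer spends most of
its budget recovering the age scale.

Because no deep-learning framework ships in this stack, the layers,
backward passes, and Adam are implemented directly in numpy (`nn`),
with convolutions evaluated as one GEMM per kernel offset. Parameter
gradients and input gradients are verified against central finite
differences.

**Scaled-down study size.** The end-to-end echo trains a tiny
configuration (stem 8, growth 4, blocks (1,1,1,1), final width 16) on
200 synthetic 32³ volumes for up to 4×8 epochs at learning rate 5e−3 —
a problem size chosen so the whole echo, including ten seeded
evaluation cohorts, runs comfortably on one CPU. It reaches a
validation MAE of roughly 1.5–3 years on the phantom task; this shows
the pipeline learns the planted morphology, nothing more.

## BAG statistics (`bag`)

The bias model BA = a·CA + b is ordinary least squares on CU
*validation* data only; corrected BAG = (BA − b)/a − CA, with the same
(a, b) applied to every other dataset. On the fitting set this has
exactly zero mean and zero OLS slope against CA (asserted to 1e−8), and
it is invariant to affine rescaling of BA when the bias model is
refitted. A near-zero fitted slope (|a| < 1e−8) is rejected with a
diagnostic, since the correction divides by a.

Group comparisons residualize corrected BAG on CA (the nuisance
covariate) by OLS before a one-way ANOVA; Welch pairwise t-tests are
Holm–Šídák step-down adjusted. An ANCOVA formulation (group factor +
CA term) is available behind a flag and agrees with residualization on
F up to the usual equivalence. Sex contrasts run male-vs-female within
each subgroup (Holm–Šídák across subgroups) plus per-sex ANOVAs across
subgroups; cells with fewer than two observations are skipped and
logged. Accuracy metrics are MAE on bias-corrected predictions,
Spearman's r, and R² (variance in BA explained by CA in a simple linear
model), with the corrected-BAG mean reported ± its standard error.

## Saliency (`saliency`)

Voxel importance is the gradient of the scalar brain-age output with
respect to the input volume (first-order Taylor sensitivity), computed
per scan in evaluation mode — the head is a single scalar, so the
gradient target is that output; a documented hook covers hypothetical
multi-output heads by selecting the maximal activation. Maps take
absolute values by default (importance is sign-free; signed maps behind
a flag), then Gaussian smoothing with σ = 2 voxels and reflective
boundaries (σ = 0 is the identity; reflective smoothing preserves the
map's total sum to numerical tolerance). Group maps are voxelwise
means; difference maps are signed A − B. Region summaries average the
map within integer atlas labels (background 0 excluded); at desk scale
the generator's own four-region phantom atlas stands in for a
volumetric parcellation atlas, and real-data mode accepts any integer
label volume.

A note on validating gradients: central finite differences with
ε = 1e−3 are only a valid oracle where no ReLU kink lies inside the
±ε interval; the ε = 1e−3 check therefore runs on a fixed seeded
network/input pair verified kink-free, while a second check at
ε = 1e−5, where crossings are negligible, holds across seeds. The
analytic gradient itself is exact (error → 0 as ε → 0).

## Longitudinal models (`trajectories`)

Regional volumes are divided by each subject's ICV; composites are sums
of constituent normalized volumes (mean available behind a flag):
MTL = hippocampus + entorhinal + amygdala + parahippocampal;
basal ganglia = caudate + putamen + accumbens + pallidum;
occipital = lateral occipital + cuneus + pericalcarine + lingual;
middle temporal = middle temporal; all bilateral. A missing constituent
marks the composite missing for that scan.

Baseline contrasts use an OLS GLM with treatment-coded groups
(reference AD−LB−) and covariates baseline age, sex, cognitive state
({MCI, dementia}; CU subjects are excluded from impaired-cohort
models), and education; continuous covariates are centered; constant
covariates are dropped; rank-deficient designs fail naming the aliased
columns. All pairwise group contrasts are Benjamini–Hochberg adjusted.

Longitudinal models are linear mixed models with per-subject random
intercept and slope (time in years since each subject's baseline),
fixed effects group, time, group×time (+ time², group×time² in the
quadratic model), and the same covariates. Estimation is maximum
likelihood, not REML, so BIC is comparable across fixed-effect
structures; BIC = −2·llf + k·ln(n) with n = number of observations and
k = fixed effects + random-effect (co)variances + residual variance
(statsmodels' mixed-model results do not expose a BIC directly).
Random-effect covariance is unstructured by default with a diagonal
fallback on non-convergence, flagged in the output. Model order is the
lower BIC, ties to linear. Pairwise contrasts on baseline, slope, and
(when quadratic) acceleration terms use normal-approximation tests on
fixed-effect linear combinations, BH-adjusted within each term family;
inestimable contrasts are marked, not dropped.

## Numerical and design choices

- Float64 everywhere except large network instantiations and training
  (float32), where memory bandwidth dominates.
- All stochastic components take explicit seeds or RNGs; fixed seeds
  reproduce cohorts, volumes, QC flags, splits, and loss curves
  bit-for-bit on a fixed platform.
- The AD−LB+ baseline BAG offset is not directly reported against
  AD−LB−; the generator default (0.94 yr) is derived from the printed
  AD+LB+ vs AD−LB+ contrast (3.53 − 2.59) and is a modeling
  convenience, not an empirical claim.
- The planted yearly BAG slopes are interpreted as absolute group
  slopes (0.03, 0.14, 0.29, 0.54) vs CU; recovery checks therefore
  target the implied reference-group slope 0.03 and contrasts (0.11,
  0.26, 0.51) vs AD−LB−.
- Simulation sizes in the test suite (200 null replicates for type-I
  calibration, 100 replicates for CI coverage and BIC selection
  consistency, 200 volumes for the training echo) were chosen as the
  smallest sizes at which the Monte-Carlo bands are meaningful.

## Known limitations

- The phantom encodes age in a single dominant morphological feature;
  real brain aging is distributed and subtle, so model-capacity
  conclusions do not transfer.
- Mixed-model contrast p-values use the normal approximation
  (appropriate at the simulated subject counts; small-sample df
  corrections are not implemented).
- Real-data mode expects preprocessed, affinely registered NIfTI input;
  no registration, segmentation, or surface reconstruction is provided
  or wrapped.
- Only the linear bias-correction family is implemented; quadratic or
  age-level corrections are out of scope.
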