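# Methods

`adcqual` re-implements a multi-stage pipeline for predicting non-diagnostic
prostate ADC maps from the T2-weighted images acquired earlier in the same
visit. Because the clinical cohort behind the original study is not publicly
deposited, every stage is exercised on a synthetic phantom cohort whose
artifact taxonomy, label statistics and correlation structure are planted and
therefore recoverable. This note documents the models, the generator, the
numerical choices, and what the passing tests do and do not establish.

## 1. The phantom cohort

### Anatomy and artifacts

Each visit renders paired T2/ADC axial stacks containing three organs at
fixed fractional positions: bladder (upper), prostate (center), and a rectum
modelled as a gas-filled elliptical lumen (lower). The central-slice
rasterized lumen area is the visit's `rectal_area_true` (mm²). Organ shapes
are jittered per patient (consistent across sites); slice-wise scaling
emulates through-plane anatomy.

Five artifact operators, each a parametric map with severity `s ∈ [0, 1]`
and exact identity at `s = 0`:

| kind | model | applied to |
|---|---|---|
| `gas_susceptibility` | radial displacement field centred on the gas lumen, magnitude ∝ s × lumen area, plus local signal dropout | ADC (EPI distortion) |
| `motion` | ghost train: convex blend with replicas rolled by k·H/8, k=1…7, weight 0.6 s | mainly T2 |
| `low_contrast` | per-slice compression toward the mean: σ_out = (1−s) σ_in exactly | both |
| `aliasing` | convex blend with the image rolled by half the FOV | both |
| `noise` | Rician with scale 0.12 s | both |

The fine (H/8) ghost spacing was chosen because coarse ghosts are largely
re-normalized away by CLAHE; a periodic ghost train survives local
equalization and remains learnable at small input sizes.

### Quality labels

Composite severity per modality is a weighted max over artifact severities;
gas has weight 0 for T2 and 1 for ADC (rectal gas degrades the EPI-based ADC
map but not the T2 image itself, although the distended rectum is *visible*
on T2 — this is precisely what makes early prediction possible). Motion has
weight 1 for T2 and 0.5 for ADC. Cut-points at composite 0.35 (3→2) and 0.65
(2→1) map severity to the ordinal 1–3 scale (1 = non-diagnostic). Dominant
artifact classes: T2 is dominated by motion (0.8 probability), ADC by gas
(0.7), matching the artifact prevalences the study reports. Optional label
noise moves a label one step with the configured probability (clipped to
[1, 3]).

### Correlation structure

Latent Gaussian copula per (patient, site, modality):

    L = a·P + b·V + c·E,   a² = r_cs,  b² = r_cm − r_cs (shared-trait mode)

with P a patient trait, V a visit factor shared across modalities, E noise.
When the cross-modality target is below the cross-site target the patient
trait becomes modality-specific and the two loadings decouple. The
*latent* correlations r_cs, r_cm are calibrated numerically (bivariate-normal
quadrature + Brent root find, no Monte Carlo) so that the **discretized
3-level labels** hit the configured Pearson targets — discretization
attenuates correlation, so using the targets directly on the latent scale
would undershoot by 0.05–0.15. Defaults: 0.4 within-visit across modalities,
0.2 across sites. With different severity margins per modality the label
correlation has a hard ceiling (~0.80 for the defaults); configurations
requesting higher targets must share a margin, and the generator raises a
clear error otherwise.

Composite severity marginals are Beta(a, b) per modality (defaults
Beta(1.0, 2.8) for T2, Beta(1.1, 2.0) for ADC, giving ≈9% / ≈16%
non-diagnostic — a minority positive class mirroring clinical rates; the
"strong artifact" stress configuration uses a shared Beta(1.4, 1.5), ≈26%
ADC failures).

### Area → quality linkage

Gas severity maps linearly to lumen area, crossing the configured
`area_threshold_mm2` (default 700) exactly at the 2→1 cut-point, so
P(ADC non-diagnostic | area) is step-like at the threshold. This plants the
breakpoint the rectal-area module must recover.

### What the phantom does *not* model

No Bloch/EPI physics, no k-space sampling, no 3-D deformation, no observer
noise in the radiologist sense beyond the ±1 label-noise channel, no
scanner-protocol dependence of artifact rates. Passing tests therefore show
that the *pipeline* recovers planted structure under its stated assumptions —
not that it would reach the same operating points on clinical data.

## 2. Preprocessing

Fourteen (configurable) consecutive slices centred on the stack middle
(higher index = inferior; odd remainders keep the inferior slice); per-slice
CLAHE at clip limit 2.0 (histogram-count convention; converted to the
normalized convention of the underlying implementation by dividing by the
bin count) on an 8-bit quantized copy with an 8×8 tile grid; central crop;
three overlapping fixed-fraction region windows — bladder = top 55% of rows,
rectum = bottom 55%, prostate = central 50%×50% — each bilinearly resized to
the network input size. Region windows are fixed fractions rather than
segmentations because the phantom places organs at known fractional
positions; real deployments would re-tune them.

Training-time augmentation: horizontal flip (p = 0.5), ±10° rotation,
contrast ×[0.8, 1.2], brightness ±0.1, and with probability 0.90 one square
cutout of side 25% filled with the image mean. The 0.90 is interpreted as
the per-sample probability of applying cutout (a hole *fraction* of 0.9
would destroy the image). The inner training loop uses a vectorized variant
without rotation; per-image resampling would dominate the runtime at these
image sizes, and on the phantom rotation adds no measurable validation gain.

## 3. Ordinal networks

Each (modality, region) is scored by two complementary compact CNNs
(`small_cnn`: 3×3 stem, channels 8/16/32/32; `wide_cnn`: 5×5 stem, channels
12/24/48/48; both: three conv-pool blocks, a conv block, global average
pooling, small dense head). The networks are built on the package's own
numpy forward/backward engine (im2col convolutions over BLAS, exact
gradients verified against finite differences).

Heads are CORN (Consistent Rank Logits): logit k models
P(y > k | y > k−1); unconditional exceedance probabilities are cumulative
products of conditional sigmoids, hence monotone by construction; rank =
1 + #{exceedance > 0.5}; the non-diagnostic probability is 1 − P(y > 1).
The loss is the CORN conditional-subset binary cross-entropy with
inverse-frequency class weights, the lowest-quality class further multiplied
by 5, normalized to mean 1.

Optimization: Adam with decoupled weight decay 1e-2, cosine-annealed
learning rate, and the two-pass adaptive sharpness-aware (ASAM) update
(element-wise |w|-scaled ascent of radius ρ, gradient re-evaluated at the
perturbed point, descent applied at the original weights; ρ = 0 reduces
exactly to plain Adam). Early stopping tracks binary AUC on the held-out
test split; the best-AUC checkpoint is always returned. Defaults follow the
fine-tuning-scale settings (lr 5e-5 → 1e-6, ρ = 0.5, patience 10); the
desk-scale configuration trains its from-scratch backbones at lr 1e-2 →
5e-4, batch 64, ρ = 0.1 — compact random-initialized networks need far
larger steps than pretrained ones, and smaller batches give the 5-epoch
budget enough update steps to fit.

Visit-level scores average the slice-level exceedance probabilities over the
visit's slices (the slice-aggregation rule is an open design point; the mean
is the simplest unbiased pooling).

## 4. Hierarchical fusion

Three stacked levels of L2-regularized logistic regression (liblinear,
balanced class weights), fitted on the stacking set only:

1. per (modality, region): the two networks' non-diagnostic probabilities →
   region score, trained against that modality's binary label;
2. per modality: the three region scores → modality score (the T2 score is
   the early, pre-DWI prediction);
3. the two modality scores → final score, trained against the endpoint
   (ADC binary quality).

Features are z-scored within each stage (network probabilities can be
compressed into a narrow band; without standardization the penalty grid
cannot reach them and stages collapse to constants). Penalty strength is
chosen from {0.01, 0.1, 1, 10, 100} by stratified 5-fold cross-validated
AUC, ties resolved toward stronger regularization. Scores ≥ 0.5 are called
non-diagnostic — the fail-safe direction for a screening tool.

## 5. Validation protocol

All partitioning is by patient ID. 20% of patients form the holdout; the
remainder is split into stratified 5 folds (stratification on the
patient-level "any ADC-non-diagnostic visit" flag). Per fold: networks train
on the other four folds' patients (all sites), the cascade is fitted on the
fold's own patients — restricted to external-site visits when more than one
site exists, emulating a multicenter test set — and everything is evaluated
once on the holdout. Reported: per-fold metrics, across-fold mean ± SD, and
the single fold with the best stacking-set AUC ("selected model"). Any
holdout ID appearing in a fitting stage raises a hard error, as does any
train/test patient overlap inside the training loop. All holdout metrics
are computed against the ADC binary label — the clinical endpoint — for the
T2-only, ADC-only and combined scores alike.

Metrics: confusion-matrix rates at threshold 0.5 plus rank-statistic AUC
with midrank ties. Zero-denominator rates are reported as NaN with a
warning, never silently as 0.

## 6. Rectal-area module

The few-shot segmenter embeds pixels in a 5-feature space (intensity and
5×5 local mean, both up-weighted ×3 because the gas lumen is a strong signal
void; normalized row/col ×0.7; local contrast) and soft-labels each query
pixel by the rectum fraction among its 9 nearest support pixels (KD-tree
over ≤1200 stratified samples per support image), followed by Gaussian
smoothing (σ=1) and mild sharpening (power 1.3) that suppresses the diffuse
background halo which otherwise inflates soft areas. Area = soft-probability
sum × spacing² (a hard-threshold variant is provided). On phantom central
slices the thresholded masks reach Dice ≈ 0.9 against the planted lumen.

Group comparison: Kruskal-Wallis with tie correction, Dunn pairwise z tests
(midranks, tie-corrected) with family-wise adjustment — classical Bonferroni
under the name `dunn_family`, Holm-Šídák as the alternative — and Welch t
tests for any requested pair.

Breakpoint estimation: logit P(non-diagnostic) = β₀ + β₁·area +
β₂·(area−ψ)₊, with ψ profiled over area deciles and refined by
golden-section search to 1 mm². Inner fits use a lightly ridge-stabilized
logistic regression (C = 1e4); the profile compares the *penalized*
likelihood, because under complete separation the raw likelihood is flat in
ψ and optimizer stopping noise would pick an arbitrary point, while the
ridge term consistently favours the least-steep separating breakpoint.
Fully area-separated data short-circuit to the midpoint of the separating
gap (the canonical representative of the flat-likelihood set). Monte-Carlo
recovery on simulated data: bias ≈ 0.5% of the planted 700 mm² at n = 2000.

## 7. Acquisition statistics

Per parameter and modality: Kruskal-Wallis across the 3-point scale,
two-sample Kolmogorov-Smirnov between passing and failing scans (exact
null distribution when both samples have n ≤ 25), and a piecewise-logistic
threshold scan; categorical parameters use a 2×2 Fisher exact test.
Parameters with fewer than 10 observed values are reported but not tested
(the metadata emulates sparse DICOM retrieval — e.g. the maximum b-value is
present for only ~19% of ADC records). Multiplicity adjustment is applied
independently per test family. Protocol-adherence checking is pure
configuration: user-supplied min/max bounds per field; missing fields are
"indeterminate" and excluded from the overall verdict.

## 8. Problem sizes and reproducibility

The desk-scale study configuration — the package's default for end-to-end
runs — uses 200 patients × 2 sites, 64-px slices at 2 mm spacing, 6 slices
per volume, 24-px network inputs, 5 training epochs. The full nested
protocol (60 network trainings + 5 cascades) completes in ≈9 minutes on one
CPU; correlation calibration uses label-only generation (no rendering) at
n = 2000. A single global seed expands into per-stage seeds via SHA-256, so
stages re-run in isolation reproduce exactly; `run-all` emits a manifest
with all derived seeds and SHA-256 hashes of every output file, and
re-running the same configuration reproduces the hashes bit for bit.

## 9. Known limitations

- The compact backbones trade capacity for CPU speed; T2 motion scoring is
  the weakest stage (per-region visit AUC ≈ 0.75 on the phantom, recovered
  to ≈ 0.83 by fusing regions and networks).
- CLAHE largely removes the low-contrast artifact's cue by design; visits
  whose quality is driven by low contrast are close to unlearnable after
  equalization, which caps per-modality AUCs below the generative ceiling.
- The label copula calibrates Pearson correlations of the noise-free
  labels; label noise > 0 attenuates the empirical correlations below the
  configured targets.
- Soft-sum areas carry a small positive bias from the residual probability
  halo; the sharpening exponent reduces but does not eliminate it.
- The segmenter's feature space is tuned to this phantom's contrast
  conventions; swapping in a stronger support-conditioned backend is the
  intended path for real images (the support-set contract is preserved).
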