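# Methods

`nashmri` re-implements, as a tested pipeline on synthetic cohorts, an
analysis that separates non-alcoholic steatohepatitis (NASH) from simple
steatosis on multi-sequence liver MRI: unsupervised deep-clustering (UDC)
texture signatures fed to a Random Forest, conventional relative liver
enhancement (RLE) and dual-echo fat fraction (FF), and the diagnostic
statistics that compare them against SAF histology labels.

## Reference standard

Each subject carries four SAF components: steatosis grade S (0–3),
lobular inflammation activity (0–2), hepatocyte ballooning activity
(0–2), and fibrosis stage F (0–4). The NASH rule is S ≥ 1 together with
inflammation ≥ 1 and ballooning ≥ 1, at any fibrosis stage; everything
else is simple steatosis.

## Synthetic cohort generator

No patient data are distributed, so a seeded generator defines the study
conditions. Design goal: every downstream formula must invert the
generator analytically, so correctness is testable to machine precision.

**Histology.** Grades are drawn from class-conditional categorical
tables whose defaults approximate the grade frequencies of a published
46-patient NAFLD derivation cohort (61% NASH). Rejection sampling (cap
10,000 draws) guarantees the intended class under the SAF rule.

**Signal model.** All images are 64×64 single axial slices (the texture
analysis operates on whole 2D slices; 3D is out of scope). Inside a
randomized convex-ish liver blob:

- Chemical shift: in-phase = W + L, opposed-phase = W − L with
  L/(W+L) = FF/100. FF is drawn uniformly from a per-grade bin with
  equally spaced midpoints — [0.5,12), [12,24), [24,36), [36,48) percent
  for S = 0..3 — so expected FF is linear in grade. Signal FF is capped
  below 50%, where the dual-echo formula saturates; histologic percent of
  steatotic hepatocytes and signal FF are different quantities, so the
  bins are the package's own calibration.
- Enhancement: t1_hbp = t1_pre_noiseless × (1 + RLE) with
  RLE = 1.8 − 0.132·F − 0.144·inflammation. The two slopes are the
  published multivariate regression coefficients of fibrosis and
  inflammation on RLE; the baseline reproduces group means near the
  published 1.6/1.0 split. Baseline T1 signal is 285 intensity units.
- Texture: zero-mean random fields whose second-order statistics depend
  on the grades — granularity (Gaussian smoothing scale 0.5 + 0.9·grade)
  tracks inflammation, sparse bright blobs track ballooning, anisotropic
  horizontal streaks track fibrosis, and chemical-shift granularity
  tracks steatosis. Texture multiplies the shared base of each ratio
  (pre/HBP share one field; in-/opposed-phase share one field), so it
  carries class information in the spatial statistics while leaving
  per-ROI RLE and FF exactly invertible. Relative amplitudes default to
  0.10/0.10/0.08/0.08 of the base signal.
- Noise: additive Gaussian (SD 5 intensity units ≈ 2% of baseline),
  truncated at zero.

A `null_effects` variant removes every class-informative image effect
(flat textures, grade-independent RLE and FF) and is the negative
control: labels still exist, images carry no class signal.

**What the generator does not emulate:** anatomy (Couinaud segments are
emulated by nine disjoint ROI sites), B0/B1 inhomogeneity, iron,
motion/partial-volume artifacts, scanner differences, or any coupling
between texture and mean signal beyond the model above. Passing tests
therefore demonstrate correctness of the pipeline's computations and its
ability to recover planted effects — not clinical performance on real
livers.

## Segmentation

A small encoder–decoder network (two resolution levels, 6/12 channels,
one skip concatenation, sigmoid pixel head) is trained with binary
cross-entropy on the hepatobiliary-phase image, full-batch Adam, 40
epochs, seeded — written in numpy with hand-derived gradients and checked
by finite differences. An analytic fallback (Otsu threshold on HBP,
largest connected component, hole filling) decouples the rest of the
pipeline from network training. Metrics: Dice 2|P∩T|/(|P|+|T|), recall,
precision; an empty prediction is flagged and scored precision 1.

## ROI quantification

Nine disjoint circular ROIs (radius ≥ 3 px at 64×64, emulating "≥ 1 cm"
per segment) are placed inside the mask, centers drawn with probability
proportional to squared distance-to-boundary (the analogue of avoiding
vessels and edges). Per ROI:

    RLE = (PostSI − PreSI) / PreSI
    FF  = (SIin − SIopp) / (2·SIin) × 100

and the per-subject summary is the arithmetic mean across ROIs (ratio
first, then mean). The printed form of the FF formula is typographically
ambiguous; the standard dual-echo reading above is used. A second
emulated reader repeats placement with a different stream for the
inter-reader ICC. Clinical scores (FIB-4, NAFLD fibrosis score, ALBI,
APRI) are implemented from their printed formulas; NFS converts albumin
from g/L to g/dL internally.

## UDC texture signatures

Patches of 16×16 pixels are sampled uniformly (with replacement) over
all window positions having ≥ 90% of pixels inside the mask, pooled
across subjects; 2,000 patches per sequence at desk scale (a
`paper_scale` preset raises this to 50,000 behind an explicit --force
guard). Images are z-normalized per subject and sequence using in-mask
statistics first, so signatures encode texture rather than the mean
level already captured by RLE/FF.

The deep clustering network is a convolutional autoencoder with k
latent centroids:

- Encoder: three 3×3 convolution + ReLU + 2×2 average-pooling stages
  (8/16/24 channels). The latent code is the concatenation of the
  spatially pooled rectified-response energies of the three stages
  (48 dimensions) — a translation-invariant, multi-scale texture
  descriptor. The first convolution initialises as a zero-DC oriented
  derivative / band-pass filterbank and remains trainable.
- Decoder: a linear map to a 24×2×2 tensor followed by three nearest-
  neighbour upsampling + convolution stages back to the patch.
- Training: Adam (lr 3e-3, batch 128), 10 reconstruction-only epochs;
  then k-means (10 restarts, seeded) initialises k = 10 centroids on the
  standardized latents (per-dimension mean/SD frozen into the model);
  then 5 joint epochs minimising reconstruction + 0.1 × squared distance
  of each standardized latent to its assigned centroid, alternating
  gradient steps with hard reassignment and centroid re-estimation
  (empty clusters keep their previous centroid).

Design note: an earlier variant with strided convolutions and a
trainable linear bottleneck produced phase-dominated latents whose
k-means partition ignored texture scale — on three visually distinct
texture families it reached an adjusted Rand index of only ~0.2, while
the pooled energies separate the same families perfectly. Hence the
energy latent; the reconstruction objective then shapes the filters
without being able to collapse the discriminative directions.

A subject's signature is the k-bin histogram of cluster assignments over
a sliding window (stride = patch_size/2 = 8, same mask-fraction rule),
normalized to sum 1. Unenhanced-T1 and HBP signatures concatenate to a
20-component vector; the in-/opposed-phase pair pools into one model and
one additional 10-component vector. Assignment is hard nearest-centroid
with ties to the lowest index.

## Prediction and statistics

Random Forests (500 trees, seeded per fold) run in stratified 5-fold CV
for NASH classification (out-of-fold class probabilities) and plain
5-fold CV regression per SAF component. Low/high dichotomizations:
steatosis {0,1} vs {2,3}, fibrosis < 3 vs ≥ 3, inflammation and
ballooning {0,1} vs {2} (the latter two cuts are this package's choice,
symmetrical with the printed steatosis rule); strata are compared by
pooled t-test on out-of-fold predictions.

The statistics layer: empirical ROC over all observed thresholds plus a
sentinel (positive = score ≥ threshold), AUC by trapezoid (verified
identical to the Mann–Whitney pair statistic), Youden-maximal cutoff
with numerical ties broken to the lower threshold, confusion metrics at
that cutoff, AUC confidence interval from the DeLong variance; paired
DeLong test from placement values; ICC(A,1) (two-way, absolute
agreement, single measure) from ANOVA mean squares; Pearson chi-square
without continuity correction; pooled-variance Student's t (zero pooled
variance: p = 1 for equal means, 0 otherwise); OLS univariate and
backward-elimination multiple regression (drop the largest-p predictor
while p > 0.05), reporting unstandardized B, standardized beta, p and
95% CI.

Orientation: NASH is the positive class; RLE falls with disease, so its
ROC uses the negated value (the reported cutoff is mapped back to the
RLE scale); FF rises and is used directly.

## Numerical and degenerate-input choices

- All randomness flows through `numpy.random.Generator` objects seeded
  from explicit config fields; identical configs reproduce cohorts,
  models and reports bit-for-bit.
- ROI placement fails loudly, naming the violated constraint, after a
  bounded number of draws.
- `rle`/`ff` reject non-positive denominators; chi-square rejects empty
  margins; ICC rejects zero between-subject variance; regression rejects
  singular designs naming the columns.
- Desk-scale problem sizes (64×64 images, n≈60 subjects, 2,000 patches,
  10+5 training epochs) are the package defaults; they are large enough
  for every planted effect to be recovered and small enough for a
  single-CPU run.

## Known limitations

- Backward elimination with three null predictors at a stay threshold of
  0.05 retains a spurious predictor in roughly 14% of replicates (the
  familywise null-retention rate); exact recovery of the single
  generating predictor therefore plateaus near 85% per replicate. This
  is a property of stepwise selection at that alpha, not of the
  implementation (verified by simulation with iid predictors).
- The texture parameterization by histology grade is this package's
  modelling assumption; the source analysis does not specify one.
- Single-sequence texture information in the T1 pair is shared (HBP is
  the enhanced pre image by construction), so concatenation mainly
  averages histogram noise rather than adding independent information.
- The CSI signature carries only steatosis-related texture by design,
  mirroring the weaker reported performance of chemical-shift-based
  texture features.
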