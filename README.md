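# nashmri

Distinguishing non-alcoholic steatohepatitis (NASH) from simple
steatosis on multi-sequence liver MRI, against SAF histology as the
reference standard. The package is aimed at imaging researchers who want
a fully reproducible, testable re-implementation of this analysis on
synthetic cohorts: every stage — liver segmentation, ROI-based signal
quantification, unsupervised deep-clustering texture signatures,
Random-Forest prediction, and the diagnostic statistics — runs from a
single seed on one CPU.

## The analysis

A subject's histology carries the four SAF components (steatosis S 0–3,
lobular inflammation 0–2, ballooning 0–2, fibrosis F 0–4); NASH is
defined as S ≥ 1 with inflammation ≥ 1 and ballooning ≥ 1, any F. Two
independent imaging readouts compete to recover that label:

**Conventional quantification.** Nine circular ROIs inside the liver
mask measure per-sequence signal intensity, giving per subject

    RLE = (PostSI − PreSI) / PreSI                 (hepatobiliary enhancement)
    FF  = (SIin − SIopp) / (2·SIin) × 100          (dual-echo fat fraction, %)

averaged across ROIs. RLE falls with fibrosis and inflammation; FF rises
with steatosis.

**UDC texture signatures.** 2D patches sampled inside the liver mask
train a deep clustering network — a convolutional autoencoder (three
convolution stages, three upsampling stages) whose latent texture
descriptors are partitioned into k = 10 clusters by a joint
reconstruction + clustering objective. A sliding window assigns every
liver window to a cluster; the subject's signature is the normalized
k-bin histogram. Signatures from unenhanced T1 and hepatobiliary-phase
T1 concatenate to a 20-component feature vector (the in-/opposed-phase
pair gives an additional 10-component vector), which a Random Forest
classifies in stratified 5-fold cross-validation.

The statistics layer supplies empirical ROC analysis with the
Youden-optimal cutoff (sensitivity, specificity, PPV, NPV, accuracy,
AUC with DeLong-variance CI), the paired DeLong test between correlated
AUCs, two-way mixed absolute-agreement ICC for inter-reader agreement,
χ² and pooled t group tests, and univariate plus backward-elimination
multiple linear regression of RLE/FF on the SAF components.

Because no patient data are deposited, a seeded synthetic cohort
generator (a first-class, tested module) emulates the study conditions:
class-conditional SAF grades, a water/lipid chemical-shift model that
the FF formula inverts exactly, multiplicative hepatobiliary enhancement
that the RLE formula inverts exactly, and zero-mean texture fields whose
spatial statistics depend on the histology grades. See
`docs/methods.md` for the model and its assumptions.

## Worked example

```sh
nashmri run --seed 1 --out run1/
```

or equivalently `run_pipeline(PipelineConfig(seed=1), outdir="run1")`.
This simulates a 46-subject cohort (61% NASH), segments it (Otsu
fallback on the HBP image by default), quantifies RLE/FF with two
emulated readers, trains one DCN per sequence on 2,000 patches each,
and writes `report.json` / `report.md`. The run above prints:

```
| features | AUROC | accuracy | sensitivity | specificity | PPV | NPV |
|---|---|---|---|---|---|---|
| udc_t1 | 0.948 | 0.957 | 0.968 | 0.933 | 0.968 | 0.933 |
| udc_csi | 0.677 | 0.674 | 0.613 | 0.800 | 0.864 | 0.500 |
| rle | 0.972 | 0.913 | 0.903 | 0.933 | 0.966 | 0.824 |
| ff | 0.604 | 0.587 | 0.419 | 0.933 | 0.929 | 0.438 |
| combined | 0.978 | 0.935 | 0.935 | 0.933 | 0.967 | 0.875 |

- RLE: simple steatosis 1.673 ± 0.108, NASH 1.296 ± 0.173 (p = 1.04e-09)
- FF (%): simple steatosis 24.01 ± 7.64, NASH 29.41 ± 12.41 (p = 1.30e-01)
- Inter-reader ICC(A,1): RLE 1.000, FF 1.000
- RLE retained: ['inflammation', 'fibrosis']
- FF retained: ['steatosis_grade']
```

Reading this: the 20-component T1 UDC signature and mean RLE both
separate NASH from simple steatosis cleanly (out-of-fold AUROC 0.948 and
0.972), the chemical-shift-based readouts are weaker (AUROC 0.68/0.60),
RLE is lower in NASH (1.30 vs 1.67, enhancement lost with
fibrosis/inflammation), and backward elimination keeps exactly the
components that drive each readout in the generator (RLE depends on
fibrosis and inflammation; FF on steatosis grade).

Each stage is also exposed as a subcommand (`simulate`, `segment`,
`quantify`, `udc-train`, `udc-signature`, `predict`, `stats`, `report`)
operating on plain NIfTI/CSV/JSON files, so any stage can be rerun in
isolation. The `paper_scale` preset (50,000 patches) requires `--force`.

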