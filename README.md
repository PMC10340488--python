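# leukoseg

Segmentation of white-blood-cell (leukocyte) nuclei in stained blood-smear
micrographs, for use as a "hard attention" preprocessing step in leukemia
image analysis — plus the evaluation metrics and a logit-space
cluster-separability statistic for downstream classifiers.

## What it does

Romanowsky-type stains turn leukocyte nuclei purple while red cells and the
background stay pink/yellow. `leukoseg` exploits this with an **ensemble of
two segmenters**:

1. **Handcrafted color-space pipeline.** Gray-world color constancy rescales
   each channel by `gray_mean / channel_mean`, homogenizing stain and
   illumination. The CMYK Magenta channel `M` and HSV Saturation channel `S`
   are then combined by their Hadamard product `M ⊙ S`, which is high only
   for purple, saturated pixels — the nuclei. Bilateral smoothing, global
   Otsu thresholding, morphological closing, hole filling, and an area
   filter produce the final mask.

2. **U-Net segmenter.** A five-level encoder–decoder (channels 32 → 512,
   strided-convolution downsampling 1,2,2,2,2, instance normalization,
   dropout, Mish activation `x·tanh(ln(1+eˣ))`), trained with the Unified
   Focal Loss

   `L = λ·L_focal + (1−λ)·L_focalTversky`,

   a mixture of a distribution-based focal term `δ(1−p)^{1−γ}·BCE` and a
   region-based focal Tversky term `Σ_c (1−mTI_c)^γ` with
   `mTI = TP/(TP + δ·FN + (1−δ)·FP)`. Training runs on the package's own
   NumPy reverse-mode autodiff engine, with Adam, plateau LR reduction,
   10-fold cross-validation, and on-the-fly augmentation.

The two masks are fused by **pixelwise logical AND** followed by an area
opening: a pixel is nucleus only if both methods agree, which can only
reduce false positives.

Quality is measured with the six standard pixel metrics (accuracy,
precision, recall, specificity, DSC, IoU; `DSC = 2·IoU/(1+IoU)`). For
3-class classifiers built on top of the segmentation, the
`cluster` module projects test-set logits (L1, L2, L3) onto two principal
components and computes the **Dist/SD ratio**
`3 · Σ pairwise centroid distances / sqrt(Σ_c SD_c²)` — larger means
tighter, better-separated classes.

A synthetic smear generator (pink background, disk-shaped red cells,
irregular purple nucleus blobs with exact ground truth) and a Gaussian
logit-cloud generator make everything testable without any dataset
download.

## Worked example

```python
import leukoseg as L

image, gt = L.make_smear(L.SmearParams(seed=7))      # synthetic smear + GT
mask, segmented = L.segment_handcrafted(image)       # handcrafted pipeline
print(L.evaluate(mask, gt).iou)                      # 0.9749687108886108

ratio = L.analyze_logits(L.make_logits(L.LogitSimParams(seed=0))).ratio
print(round(ratio, 2))                               # 32.52
```

The first number is the pixel IoU of the handcrafted mask against the
generator's exact ground truth; ≥ 0.9 is typical for the default palette.
The second is the Dist/SD ratio of three well-separated Gaussian logit
clouds (centroid separation 6σ); overlapping clouds score far lower.

From the shell:

```bash
leukoseg make-fixtures fixtures --n 10          # paired images/ + masks/
leukoseg run fixtures/images out --masks-dir fixtures/masks
leukoseg train-unet fixtures/images fixtures/masks model.npz --epochs 100
leukoseg cluster-report logits.csv summary.json
```

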