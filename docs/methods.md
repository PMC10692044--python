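# Methods

This note documents the models, conventions and numerical choices behind
`crlmvol`, in the order data flows through the package.

## Synthetic CT phantoms

Real contrast-enhanced abdominal CT of patients with liver metastases is
not redistributable, so all development and testing runs on a generative
phantom that keeps the *statistical* structure of the segmentation problem
while simplifying the anatomy to shapes with known volumes.

A phantom is a rank-3 Hounsfield grid with per-axis spacing in mm:

| parameter | default | meaning |
|---|---|---|
| `grid_shape` | (48, 48, 32) voxels | axial slices along z |
| `spacing_mm` | (2.0, 2.0, 2.5) | anisotropic, CT-like |
| `liver_hu_mean/sd` | 110 ± 10 HU | enhancing parenchyma (portal venous phase) |
| `lesion_hu_mean/sd` | 65 ± 10 HU | hypodense metastases |
| `background_hu_mean/sd` | 20 ± 15 HU | soft-tissue surround |
| `n_lesions_range` | [1, 4] | per scan |
| `lesion_radius_range_mm` | [4, 10] | spheres |
| `noise_sd_hu` | 10 | additive acquisition noise |
| `blur_sigma_mm` | 1.0 | partial-volume smoothing |

The liver is an axis-aligned ellipsoid with semi-axes drawn uniformly from
30–40% of the field of view and a jittered centre; lesions are spheres
whose centres are drawn inside the liver ellipsoid *eroded by the lesion
radius*, so every lesion fits entirely inside the organ.  Lesions may
overlap and merge ("confluent" disease is the common presentation in the
population of interest); a flag disables overlap for applications that
need isolated lesions.  A lesion that cannot be placed (radius too large
for the liver) exhausts a bounded retry budget and raises a generation
error rather than silently shrinking.

The image is assembled as tissue-mean + tissue-texture noise, smoothed by
a Gaussian of `blur_sigma_mm` (partial volume), plus white acquisition
noise.  The HU defaults put roughly 2.5–3 combined standard deviations
between lesion and liver intensities — clearly learnable, deliberately not
trivially separable.  Everything is deterministic given `(seed, scan_id)`:
the per-scan generator is seeded with `SeedSequence([seed, crc32(scan_id)])`.

Ground-truth TTV is defined as *the volumetry module's output on the
generated tumor mask*, so generator and measurement can never disagree by
construction.

**What the phantom does not emulate:** vasculature, non-ellipsoidal organ
shape, contrast-phase timing, respiratory motion, scanner-dependent noise
spectra, and lesion texture heterogeneity.  Passing the end-to-end bars on
phantoms therefore demonstrates that the pipeline's machinery (training,
volume-of-interest restriction, volumetry, agreement statistics) works; it
does not certify performance on clinical CT.

### Simulated observers

Independent readers are simulated by boundary jitter: the mask is
re-thresholded at `signed_distance + field > 0`, where the signed
Euclidean distance (mm, positive inside) is perturbed by a smooth,
zero-mean, unit-variance Gaussian random field scaled to `magnitude` mm.
Magnitude 0 is an exact identity; empty and full masks are returned
unchanged (no boundary to move).  The default magnitude of **1.5 mm**
was calibrated once so that pairwise per-case DSC between two simulated
readers of the default phantoms falls around 0.90 (observed median 0.905,
range 0.87–0.95 over six scans × two readers), matching the agreement
typically reported between expert abdominal radiologists.

### Cohort splits

`split_cohort` assigns *patients*, not scans, to train/validation/test, so
no patient's imaging can appear on both sides of the train/test boundary.
Patient counts per partition follow the largest-remainder rule applied to
the requested fractions (ties broken in partition order), which is
deterministic, order-independent, and as close to the requested fractions
as whole patients allow.  Fractions are accepted if they sum to 1 within
5×10⁻³ (published cohort fractions are rounded to three decimals and sum
to 0.999) and renormalised internally.

## Preprocessing

Two steps, in fixed order. (1) HU values are clipped to [−100, 400], the
soft-tissue window containing the liver. (2) The clipped volume is mapped
through its own empirical CDF over 256 equal-width bins of the window
("histogram equalization"), giving values in [0, 1] that use the range
evenly.  Equalization is computed per *volume*, not per slice — slice-wise
equalization would give the same tissue different intensities on different
slices of one scan.  The exact parameters used are recorded in a
provenance dict that travels with the normalized volume and into model
checkpoints; the cascade refuses to run a model on data normalized with
different parameters.  A constant-valued volume (degenerate histogram)
maps to 0.5 everywhere with a warning.

## Segmentation cascade

Two 2-D U-Nets applied to axial slices and restacked to 3-D.

**Architecture.**  Encoder–decoder with skip connections; each block is
two 3×3 conv + ReLU layers; 2×2 max-pooling down, nearest-neighbour ×2 up
followed by a 3×3 conv halving the channels; final 1×1 conv + sigmoid.
Depth *d* and base filter count *f* give channel widths *f, 2f, …, 2^d f*;
the parameter count is the closed form in `unet.n_params`.  Implemented
directly on numpy (im2col convolutions as flat GEMMs, hand-written
backprop, Adam), in float32, fully seeded.  Inputs whose in-plane size is
not divisible by 2^d are rejected with the required padding named —
nothing is resized silently.

**Stage defaults.**  Liver: depth 3, 4 base filters, 6 epochs at learning
rate 3×10⁻³ — the organ is large and high-contrast and saturates quickly.
Tumor: depth 3, 8 base filters, 12 epochs at 1×10⁻³ — small structures
under heavy class imbalance need the wider net and the gentler rate.
Batch size 16, probability threshold 0.5 (configurable).

**Loss.**  Soft-Dice (batch-level, smoothing 1.0) plus voxelwise binary
cross-entropy, equal weights.  The Dice term carries the signal for rare
foreground; the BCE term stabilises the background.  Because tumor voxels
are < 1% of the volume, lesion-bearing slices are repeated 4× in the
tumor stage's training set so most batches contain foreground — without
this the batch Dice gradient is starved and training stalls.

**Early stopping.**  After each epoch the mean per-scan DSC on the
validation partition is computed; training stops when it fails to improve
for `early_stop_patience` consecutive epochs, and the weights of the best
validation epoch are restored.

**Volume-of-interest restriction.**  The tumor stage sees only the liver:
at training time the ground-truth liver mask, at inference the predicted
one, in both cases dilated by a 5 mm margin (so a slightly under-segmented
liver border cannot clip peripheral lesions) with everything outside set
to 0.  At inference the masked volume is cropped to the dilated mask's
bounding box (offset and original shape recorded for an exact map-back)
and zero-padded up to the next multiple of 2^depth.  The liver prediction
itself is post-processed by keeping the largest 3-D connected component
and filling internal holes, which removes spurious islands before they
can widen the VOI.  The final tumor mask is intersected with the liver
mask, so `tumor ⊆ liver` holds for every output.  An empty liver
prediction is an explicit error ("no liver volume of interest"), not an
empty result.

## Evaluation metrics

Voxel confusion counts (TP, FP, FN, TN) between aligned masks, from which
DSC, IoU, precision and recall follow.  Conventions, fixed for
reproducibility:

* **global vs per-case** — global metrics pool counts over all scans
  before taking ratios; per-case DSC is computed per scan and summarised
  as median, IQR and mean.  The two are not interchangeable and both are
  always reported.
* **empty-vs-empty** — a scan where both masks are empty scores per-case
  DSC 1.0 and contributes nothing to pooled numerators; if exactly one
  mask is empty the DSC is 0.
* **IQR** — 25th–75th percentile with linear interpolation (type-7).
* **display rounding** — half-up to 2 decimals, kept separate from the
  full-precision values in JSON output.

## Volumetry

TTV = voxel volume (product of the three spacings, mm³) × number of
segmented voxels / 1000, in cm³.  Per-lesion volumes come from 3-D
connected components, default 26-connectivity (faces + edges + corners),
which merges confluent lesions the way contiguous tumor tissue is
outlined in practice; 6- and 18-connectivity are available.  No minimum
lesion size is applied by default; an optional voxel-count floor exists
for noise suppression.  Component volumes sum to the TTV exactly under
any connectivity.

## Agreement

ICC form: two-way model, single measurement, absolute agreement —
ICC(A,1) — because each scan contributes one volume per rater and a
systematic offset between raters must count against agreement.  The 95%
CI uses the McGraw–Wong F-distribution method with Satterthwaite degrees
of freedom.  The consistency form ICC(C,1) is provided for comparison
(an offset column leaves it at 1.0 while lowering the absolute form).
Categories: poor < 0.40 ≤ fair < 0.60 ≤ good < 0.75 ≤ excellent ≤ 1.0;
the boundary values belong to the upper category.  Degenerate inputs are
errors, not NaNs: incomplete tables, fewer than 3 subjects or 2 raters,
and zero between-subject variance.

## Problem sizes and acceptance bars

Development-scale runs use 48×48×32 phantoms and a 40-patient cohort
split 25/5/10 — sizes chosen once so a full train-and-evaluate cycle
takes minutes on a single CPU core while leaving the tumor stage a
non-trivial learning problem.  On that setup the package holds itself to:
median per-case liver DSC ≥ 0.85, median per-case tumor DSC ≥ 0.6, and
reference-vs-automatic TTV ICC ≥ 0.90 ("excellent") on the held-out
partition with fixed seeds.  These are desk-scale bars for synthetic
data, not claims about clinical cohorts.

## Known limitations

* The numpy U-Net is CPU-bound and deliberately small; it is not a
  state-of-the-art segmentation architecture and makes no attempt at
  augmentation, normalisation layers, or 3-D context.
* Phantom realism is limited (see above); in particular lesion detection
  difficulty is governed almost entirely by intensity contrast.
* Histogram equalization discards calibrated HU values; models trained on
  equalized data cannot be applied to raw-HU inputs (the provenance check
  enforces this).
* The ICC assumes the volume pairs are exchangeable across scans;
  heteroscedasticity (error growing with tumor burden) is not modelled —
  no variance-stabilising transform is applied.
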