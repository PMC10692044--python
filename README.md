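# crlmvol

Automatic liver/tumor segmentation and total tumor volume (TTV) assessment
for contrast-enhanced abdominal CT, at desk scale.

Volumetric follow-up of liver metastases asks for three things that manual,
diameter-based response criteria do not provide: a segmentation of *every*
lesion, the total tumor volume those segmentations imply, and a statistical
statement of how well automatic volumes agree with a radiologist's
reference. `crlmvol` implements that pipeline end to end:

* **phantoms** — synthetic portal-venous CT volumes (ellipsoidal liver of
  elevated density, hypodense spherical lesions, partial-volume blur,
  acquisition noise) with exact ground truth, simulated second observers,
  and patient-level cohort splits;
* **preprocess** — Hounsfield clipping to [−100, 400] HU followed by
  per-volume histogram equalization onto [0, 1];
* **cascade** — a two-stage 2-D U-Net scheme: a liver model segments the
  organ, its output (dilated by a safety margin) restricts the volume of
  interest in which a tumor model runs; `tumor ⊆ liver` holds by
  construction.  The networks are compact numpy implementations (im2col
  convolutions, manual backprop, Adam) that train on a CPU in minutes;
* **metrics** — evaluation in the liver-tumor benchmark style: voxel
  confusion counts, pooled ("global") and per-case Dice, IoU, precision,
  recall;
* **volumetry** — TTV as voxel volume × segmented voxel count (cm³), with
  per-lesion volumes from 3-D connected components;
* **agreement** — two-way mixed-effects, single-measurement, absolute
  agreement intraclass correlation ICC(A,1) with the F-based 95% CI, and
  pairwise observer DSC matrices.

## The statistics in brief

With voxel counts TP/FP/FN pooled over scans,

    DSC = 2·TP / (2·TP + FP + FN)        IoU = TP / (TP + FP + FN)
    precision = TP / (TP + FP)           recall = TP / (TP + FN)

and DSC = 2·IoU/(1+IoU) identically.  The *global* DSC pools counts first;
the *per-case* DSC is computed per scan and summarised as median (IQR).
TTV is `voxel_volume(mm³) × n_voxels / 1000` in cm³.  Agreement between
reference and automatic TTV uses, with mean squares MSR (scans), MSC
(raters), MSE from the two-way ANOVA of the n×k volume table,

    ICC(A,1) = (MSR − MSE) / (MSR + (k−1)·MSE + (k/n)·(MSC − MSE))

categorised poor (< 0.40), fair (0.40–0.59), good (0.60–0.74), excellent
(0.75–1.0).

## Worked example

Train the default cascade on a 40-patient phantom cohort (25 train /
5 validation / 10 test, split at the patient level) and evaluate the
held-out scans — about 7 minutes on one CPU core:

```python
from crlmvol import CascadeModel, PhantomSpec, RatingsTable, icc_absolute_agreement
from crlmvol.phantoms import generate_cohort

manifest, data = generate_cohort(PhantomSpec(seed=20), n_patients=40,
                                 fractions=(0.625, 0.125, 0.25))
results = CascadeModel(manifest, data).fit()
ev = results.evaluate("test")
print(results.summary(ev))

ttv = ev["ttv"]
table = RatingsTable(subjects=list(ttv["scan_id"]),
                     raters=["reference", "automatic"],
                     values=ttv[["reference_ttv_cm3", "automatic_ttv_cm3"]].to_numpy())
print(icc_absolute_agreement(table).summary())
```

Output of this exact run:

```
Cascaded liver/tumor segmentation — fit summary
================================================
liver stage : depth=3, base_filters=4, params=33653, best epoch=5, val DSC=0.976
tumor stage : depth=3, base_filters=8, params=134121, best epoch=4, val DSC=0.740
preprocess  : clip [-100.0, 400.0] HU, 256 bins; VOI margin 5.0 mm
------------------------------------------------
test scans  : 10
liver  global DSC 0.977, per-case median 0.977 (IQR 0.975-0.977)
tumor  global DSC 0.844, per-case median 0.855 (IQR 0.834-0.870), IoU 0.730, precision 0.842, recall 0.846
ICC(A,1) = 0.922 (95% CI 0.716–0.980), excellent agreement; n=10 subjects, k=2 raters
```

Read: on held-out phantoms the liver model recovers the organ almost
perfectly (median per-case DSC 0.98), the tumor model recovers the lesions
with median per-case DSC 0.86, and the automatic tumor volumes agree with
the ground-truth volumes at ICC 0.92 — "excellent" by the conventional
categories.  The same pipeline is available from the shell:

```bash
crlmvol demo --seed 20 --out demo_out     # writes metrics.json, ttv.csv, icc.json
crlmvol phantom --n-patients 20 --seed 42 --out cohort/
crlmvol ttv --mask tumor.nii.gz --connectivity 26 --out ttv.json
crlmvol icc --table volumes.csv --out icc.json
```

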