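# Methods

## The detection model

`pdacdetect` frames tumor detection as segmentation-for-detection. Four
stages share one residual 3D U-Net definition and differ only in input
channels, working resolution and field of view:

| stage | input | resolution | inference |
|---|---|---|---|
| coarse pancreas | CT (1 ch) | low (2× spacing) | sliding window |
| fine pancreas | CT crop (1 ch) | high | sliding window |
| ducts | CT crop (1 ch) | high | sliding window, 3-class softmax |
| tumor | CT + pancreas + CBD + PD (4 ch) | high | one full-crop pass |

The duct stage supports two modes: a single multi-label softmax model
(background / common bile duct / pancreatic duct, the default) or two
single-label sigmoid models. Predicted duct masks pass an anatomical
plausibility filter: connected components (26-connectivity) that do not
intersect the pancreas mask dilated by `attach_radius` voxels (default 2)
are discarded. The filter is a subset operation, idempotent, and monotone
in the attach radius; it is applied to both ducts by default.

Each stage is trained three times on independently re-drawn ("bootstrapped")
per-patient splits. At inference the three tumor probability maps are
averaged voxel-wise **before** the case score is taken as the maximum
voxel of the ensemble map; a case is called positive at score ≥ 0.61
(inclusive). Intermediate pancreas/duct binarization uses 0.5; the 0.61
operating point applies only to the tumor call. Multi-scan patients are
aggregated by the max rule (`mean` available by configuration).

Full-scale defaults mirror standard abdominal-CT practice: intensities
clipped to the (−87, 199) HU window and scaled to [0, 1]; low resolution
(1.37, 1.37, 2.0) mm and high resolution (0.68, 0.68, 1.0) mm; pancreas
crops of 256 × 256 × 192 voxels; pancreas patches 128 × 128 × 64 and duct
patches 128 × 128 × 128, both at stride 32³; depth-4 U-Nets with
(32, 64, 128, 256) filters. All geometry lives in `StageBundle` so the
phantom-scale configuration (below) is geometry-similar rather than a
separate code path.

## Network and optimization

No deep-learning framework is used: the network is a numpy implementation
with analytic backward passes (convolution as per-offset BLAS
contractions, instance normalization, pre-activation two-convolution
residual units, average-pool downsampling, nearest-neighbour upsampling,
skip concatenation, 1³ head). Initialization is He-normal and fully
determined by an integer seed; gradient correctness is verified against
central finite differences in the test suite. The head is a sigmoid for
single-channel tasks and a channel softmax for the multi-label duct task.

Training minimizes soft-Dice (smoothing 1.0) plus cross-entropy with Adam
(default lr 3 × 10⁻³ at phantom scale), on foreground-biased sampled
patches (foreground fraction 0.7); the tumor stage trains on whole crops.
Checkpoints are selected by best validation Dice. Augmentation follows
stage-specific suites: rotations (±15°) and elastic deformations for the
pancreas/duct stages; additionally flips, duct erosion/dilation (radius 1,
duct channels only — never the CT channel), Gaussian noise (σ 0.02 in
normalized units) and additive Poisson-distributed noise for the tumor
stage. Loss/metric logs are emitted per step.

"Threefold bootstrapping" is implemented as three independently re-drawn
70/15 train/validation splits over the non-test patients (test = 15%,
fixed across folds, assigned per patient so multi-scan patients never
straddle buckets). A rotated-cross-validation reading of the same phrase
is possible; the re-drawn reading matches the word "bootstrapping" and is
what the splitter does.

## The phantom

The generator emulates the statistical structure the cascade exploits, not
anatomy: a curved tapering tube of pancreatic tissue (80 HU) spanning the
volume laterally in soft-tissue background (40 HU), a thin pancreatic duct
(10 HU, radius 2 mm) along its axis, a common bile duct (radius 2.4 mm)
descending into the head (the low-x quarter), and i.i.d. Gaussian
acquisition noise (σ 10 HU) on the CT only. Tissue means were chosen once
to sit inside the (−87, 199) HU window with realistic ordering
(duct fluid < background < parenchyma).

A tumor case plants a sphere (default radius 6 mm, jittered ±35% across a
cohort) on the duct axis in the head, with attenuation class hypo / iso /
hyper offsetting its mean by −30 / 0 / +30 HU; cohort class proportions
default to 77 : 14 : 8. The obstructing tumor multiplies duct radii
upstream of itself by `duct_dilation_factor` (default 1.8) — tail-ward for
the pancreatic duct, liver-ward for the bile duct — effaces the duct
segment it engulfs, and suppresses the duct head-ward of the obstruction.
Labels use precedence tumor > pancreatic duct > bile duct > pancreas, with
the bile duct terminating at the pancreatic duct's surface so each duct
remains a single connected component. Everything derives bit-exactly from
one integer seed (per-case seeds spawn from the cohort seed).

What the phantom does **not** model: surrounding organs and vasculature,
contrast phases, partial-volume and beam-hardening effects, anatomical
shape variability, pancreatitis, stents. Passing phantom experiments
therefore demonstrates that the cascade, its training loop and its metrics
are correct and that duct morphology alone is a learnable signal — not
clinical-grade performance on real CT.

The iso-attenuating configuration is the scientifically load-bearing one:
the tumor itself is invisible by intensity (mean contrast ≈ 0 against
parenchyma; a simple intensity threshold inside the pancreas cannot
separate cases from controls), while the duct channels carry the
dilation/interruption signature. One honest caveat: the ducts are
hypodense fluid structures and therefore visible in the CT channel too —
exactly as they are to a radiologist — so at this phantom's noise level a
CT-only tumor model can also learn the duct-dilation sign from intensity
and the ablation margin between the two arms can be small or zero. The
ablation criterion is therefore "with-ducts ≥ CT-only and with-ducts
strong", not "CT-only fails".

## Phantom-scale experiment sizes

Desk-scale runs use 48³ phantoms at 1 mm spacing with a geometry-similar
bundle: low resolution 2 mm, crop 32 × 32 × 24, pancreas patches
16 × 16 × 8 and duct patches 16³ at stride 8³, depth-2 U-Nets with (8, 16)
filters, 150 training steps per stage and fold. The detection experiment
trains 40 / validates 10 / tests 20 phantoms over 3 folds (~7 min on one
CPU); the ablation trains tumor models on 24 iso-attenuating cases and
tests on 16 (~3 min per arm pair). These sizes are the package's chosen
study conditions; all of them are parameters.

## Numerical choices and conventions

- 0-based voxel indices, half-open boxes `[start, start+size)`, axis order
  (x, y, z); volumes are reoriented to canonical orientation on load.
- Resampled shape is `round(shape · spacing / target)` (half-up, min 1);
  intensities resample linearly, labels nearest-neighbour (never creating
  new label values); no anti-alias pre-smoothing on downsampling.
- Crop padding fills with the window minimum (0 after normalization);
  out-of-bounds voxels are dropped on paste-back.
- Sliding-window tiling clamps the final start per axis so the last patch
  is flush with the boundary; overlapping predictions merge by unweighted
  arithmetic mean (the only rule under which a constant predictor is a
  fixed point of tiling).
- Largest-component ties break toward the component containing the
  lexicographically smallest voxel.
- Dice of two empty masks is defined as 1.0 (a control case with no
  predicted and no true tumor is perfect agreement) but control cases are
  excluded from "mean Dice", which averages tumor cases only.
- `f1_paper` is the arithmetic mean of precision and recall — a
  non-standard convention retained for comparability; the harmonic F1 is
  reported separately as `f1_harmonic`.
- AUROC is computed by the Mann–Whitney rank formula (ties half-weighted);
  the threshold-sweep ROC table integrates to the same value to 1e-9 and
  both are cross-checked against scikit-learn in the tests.
- Localization is a separate criterion from classification: a detected
  tumor case is "localized" when the predicted tumor mask (binarized at
  the operating threshold) shares ≥ 1 voxel with the ground truth, and the
  localization rate is reported over detected tumor cases.

## Known limitations

- The numpy network is CPU-bound; full-scale (256 × 256 × 192, depth-4)
  training is out of reach here — the full-scale configuration is provided
  as an architecture contract, exercised at reduced spatial extent.
- Per-fold decision thresholds are not calibrated; the shared 0.61
  operating point is used for every fold and the ensemble.
- Whether duct filtering should use predicted or annotated pancreas at
  inference is configurable; the default is predicted.
- Phantom realism limits are listed above; no claim is made about
  performance on clinical CT.
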