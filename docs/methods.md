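# Methods

## Problem and pipeline

Anomalous aortic origin of a coronary artery (AAOCA) is a congenital variant
in which a coronary arises from the wrong aortic sinus or an abnormal ostium
position. Its clinical significance depends on the proximal course:
inter-arterial and sub-pulmonic courses are high anatomical risk, while
pre-pulmonic, retro-aortic and high take-off courses are low risk.
`coroscreen` implements an automated screening pipeline for contrast-enhanced
coronary CT angiography (CCTA):

1. **Localization.** The aortic root is found as the centroid of the
   aorta/LV contact set, shifted 10 mm toward patient right and 10 mm
   superior, and an 8 × 8 × 6 cm³ axis-aligned box is cropped around it.
2. **Preprocessing.** The crop is spline-resampled to fixed grid dimensions,
   clipped to [−1024, 1024] HU, discretized into 256 levels, and min-max
   scaled to [0, 1].
3. **Classification.** A 3D squeeze-and-excitation (SE) residual network
   produces a probability for each of three binary tasks: anomaly detection
   (normal vs AAOCA), origin (right vs left anomalous vessel, AAOCA only),
   and anatomical risk (low vs high, AAOCA only). Origin and risk networks
   are fine-tuned from the anomaly backbone. Five identically split,
   differently initialized trainings are averaged into an ensemble.
4. **Evaluation and interpretability.** Metrics (ROC AUC, sensitivity,
   specificity, F1, PPV, AUPR, accuracy) with percentile-bootstrap
   intervals, cutoff sweeps over 0.1–0.9, sex-stratified reports,
   Grad-CAM++ volumetric saliency, and t-SNE maps of last-layer embeddings.

Because clinical CCTA is restricted data, the package ships a synthetic
phantom generator that realizes the anomaly taxonomy with closed-form
geometry, so every stage has an exact oracle and the pipeline can be
exercised end to end on any machine.

## The phantom generator

Anatomy is built from analytic primitives in a canonical patient frame
(+x right, +y anterior, +z superior; mm): an elliptical soft-tissue body and
two lungs; an LV cavity ellipsoid (semi-axes 18 × 16 × 21 mm) with a 6 mm
myocardial shell; an aortic root sphere (r = 15 mm) merged with a vertical
ascending aorta cylinder (r = 13 mm); a pulmonary artery cylinder (r = 8 mm)
anterior-left of the aorta; and two coronary arteries rasterized as
cubic-spline tubes (default radius 2 mm). The root sphere interpenetrates
the LV by a few millimetres, giving a realistic aorto-ventricular contact
patch for the localizer.

Each case draws one of three classes — normal, R-AAOCA (anomalous right
coronary) or L-AAOCA (anomalous left coronary) — and, for anomalous cases,
one of five courses. The anomalous vessel's ostium and proximal control
points realize the course geometry (e.g. the inter-arterial course threads
the corridor between the aortic and pulmonary surfaces before turning
toward its territory); the other vessel is drawn normally. The risk label
derives mechanically from the course (inter-arterial, sub-pulmonic → high;
pre-pulmonic, retro-aortic, high take-off → low), with no per-case override.

Voxels take their tissue's mean HU (air −1000, lung −800, soft tissue 40,
myocardium 80, contrast blood pool 400, PA blood 150, coronary 350 —
typical CCTA ranges, all inside the clip window) plus i.i.d. Gaussian noise
with σ = 20 HU, a typical CCTA noise magnitude. The default grid is
128 × 128 × 96 at 1.25 mm isotropic, which makes the default crop box
exactly 64 × 64 × 48 voxels. Optional pseudo-phases warp phase 0 by a
smooth random displacement field with bounded maximum norm
(`simulate_phases`), emulating multi-phase reconstructions.

**What the phantoms do not model:** partial-volume blur at tissue
boundaries, beam hardening and other physics artifacts at acquisition time,
anatomical variability of the great vessels (the geometry is fixed up to
the coronary course), coronary plaque or stenosis, and intramural segments.
Consequently, passing phantom tests demonstrates that the pipeline's
machinery is correct and that the architecture can learn course geometry
from volumetric contrast patterns — it says nothing about clinical
performance, which depends on variability the phantoms deliberately lack.

## Localization details

"Intersected" is operationalized as the dilated-contact set: the aorta
voxels whose 1-voxel dilation touches the LV plus the symmetric LV-side
set, growing the dilation radius up to 3 voxels; a literal voxel overlap,
when present, takes precedence. Masks still disjoint after maximal dilation
raise a "no aorto-ventricular contact" error. "Right" is taken as patient
+x and "upward" as superior (+z) — the anatomical intent is to include more
ascending aorta — and the offset vector is configurable since image-right
conventions differ. Crop voxel ranges are half-open, 0-based, rounded
outward by at most one voxel per face; out-of-field voxels are padded with
−1024 HU, which is neutral after clipping.

`naive_segment` is a phantom-only stand-in for a segmentation model: it
thresholds the contrast blood pool, splits it at the aorto-mitral neck by
erosion + watershed, and assigns the superior component to the aorta. It
exists because cropping needs only rough masks; it is not a general CT
segmenter.

## Preprocessing details

The published "256 levels (0 to 256)" is internally inconsistent (257
values); it is resolved as integer levels 0..255 with the upper clip edge
mapped to 255, the standard 8-bit convention (configurable). Spline order
defaults to cubic. Min-max scaling is per-volume, after discretization;
constant volumes map to all zeros by contract. Resampling preserves the
physical field of view: output spacing is `shape × spacing / target_dims`.

## Augmentation details

The artifact models are minimal physically motivated emulations, with all
magnitudes configurable: motion as a convex ghost sum of rigidly shifted
copies (first ghost unshifted), and the step-and-shoot artifact as a rigid
in-plane translation of all slices above a random table position. The
transform order is fixed (contrast → blur → noise → motion → step) so
intensity statistics stay interpretable; out-of-field voxels created by
shifts are filled with 0, the post-normalization air value. Every transform
maps [0, 1] tensors to [0, 1] tensors of the same shape, and zero
magnitude or probability is an exact identity, so switching augmentation
off recovers the deterministic pipeline bitwise.

## Network and training

The classifier family is a strided convolutional stem, `n_stages` stages of
SE-residual blocks (width doubles and resolution halves at stage
transitions), global average pooling and a single-logit sigmoid head. The
publication-scale preset is 4 stages with the (3, 8, 36, 3) bottleneck
pattern of the SE-ResNet-152 family adapted to 3D; counting main-path
convolutions plus the head gives a realized depth of 152, reported by
`layer_count` so the preset is auditable. A 2-stage basic-block `tiny`
preset (base width 8, SE reduction 4) is the default for CPU-scale
experiments.

The deep-learning core is a compact NumPy implementation with explicit
forward/backward passes (im2col convolution over BLAS, batch
normalization, SE gates, residual blocks); it is validated against
finite-difference gradients in both batch-statistics and running-statistics
modes. Training uses binary cross entropy, Kaiming initialization, a
cosine-annealed learning rate starting at 0.001, early stopping on
validation loss (default patience 20; checkpoint = lowest validation loss,
ties broken by higher validation accuracy — the selection rule made
concrete), and a patient-wise 90:10 split shared by all ensemble members.
The default optimizer is RMSprop (momentum-free adaptive); batch size 8 and
optional weight decay are exposed in `TrainConfig`. Multi-phase inference
aggregates by the mean over phases (configurable to max), chosen for
symmetry with member averaging.

## Evaluation details

One canonical ROC AUC is used everywhere: the Mann-Whitney pair statistic
with ties counting ½, identical to the area under the empirical ROC curve.
AUPR is step-integrated average precision. A probability exactly at the
cutoff counts as positive (the tie direction must be fixed for
reproducibility). Bootstrap intervals resample at case level — respecting
the patient-wise independence used for splitting — with percentile 2.5/97.5
bounds; single-class resamples are redrawn with bounded retries. The
"tolerance" mode returns a pointwise percentile band of resampled ROC
curves for plot shading. Metrics with empty denominators are reported as
NaN, never 0, so degenerate groups cannot silently inflate summaries.

## Saliency and embeddings

Grad-CAM++ follows the second/third-order positive-gradient weighting with
the piecewise-linear closed form; the exponential score factor cancels
under the final per-volume min-max normalization. Zero-gradient inputs
return an all-zero map with a logged warning. Maps are computed at any
stage and trilinearly upsampled to the input grid. Embeddings are the
global-average-pooled features entering the head; t-SNE uses perplexity 30
with PCA pre-reduction to 50 dimensions when the feature width exceeds 50,
and requires an explicit member choice since members' feature spaces
differ.

## Problem sizes used in tests and the acceptance script

The shipped study conditions are desk-scale by design: phantoms at the
default 1.25 mm grid, crops of 64 × 64 × 48 voxels resampled to
32 × 32 × 24 network inputs, the `tiny` network, 15 training epochs, and
3-member ensembles on cohorts of 240 cases (180 train / 60 held out). The
overfit sanity check uses 8 noise-free phantoms at 24 × 24 × 16. Bootstrap
calibration uses 500 synthetic replicates of a binormal score model with
400 resamples each. The publication-scale settings (215 × 215 × 85 inputs,
300 epochs, 5 members, 10,000 bootstrap iterations) remain the configured
defaults of `PreprocessConfig`, `TrainConfig` and the evaluation API.

## Known limitations

* Phantom realism is not validated against clinical images; thresholds met
  on phantoms are repository-defined study conditions, not clinical claims.
* The NumPy training core is single-threaded beyond BLAS and intended for
  compact volumes; publication-scale inputs are supported by the
  architecture code but not practical to train here.
* `naive_segment` assumes phantom-like HU statistics and a single connected
  contrast pool.
* The exact artifact parameterizations used in clinical training pipelines
  are generally unpublished; the augmentations here claim functional
  analogy, not equivalence.
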