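# Methods

## Overview

`neuromae` implements, at desk scale, a self-supervised pretraining strategy
for multi-contrast 3D brain MRI and the downstream analysis chain built on
it: cross-contrast masked reconstruction with a hybrid loss, fine-tuning of
the pretrained encoder into a two-class parkinsonian-syndrome discriminator
(PD-like vs PPS-like), occlusion-sensitivity saliency with voxelwise group
statistics (GLM, TFCE, max-statistic permutation FWER), and the evaluation
layer (confusion metrics with bootstrap CIs, rank AUC, DeLong test).
Clinical multi-contrast data of this kind is not publicly distributable, so
the package ships a procedural phantom generator that preserves the
structural roles the analysis needs; everything downstream treats phantoms
and real NIFTI volumes identically.

## Pretext task and hybrid loss

Each subject is a 3-channel volume (T1, T2, FLAIR order) normalised per
channel to [0, 1]. A corruption hides `n_blocks` axis-aligned cubes of edge
`block_edge` voxels (paper-scale default 84 blocks of 16³ on the
128×128×64 grid), drawn uniformly over all placements fully inside the
grid, independently per channel — so recovery of a hidden region can use
both in-channel context and the other contrasts at the same location.
Blocks may overlap; consequently the expected masked fraction of the
whole grid is below the disjoint bound `n_blocks·edge³/V` (0.3281 at paper
scale; the exact expectation under this placement law is 0.2662, and the
within-brain fraction is higher, of order 0.4, because brain voxels sit in
the well-covered interior). The mask generator reports both the whole-grid
and within-brain fractions.

Each training step draws **two** independent corruptions of the same batch
and reconstructs both. With reconstructions `r1, r2` of original `x`:

* `L_recon = ½(‖r1 − x‖₁ + ‖r2 − x‖₁)` — mean absolute error over all
  voxels and channels (not only masked voxels, following the stated
  definition of the reconstruction loss);
* `L_contrast = ‖r1 − r2‖₁` — the discrepancy between the paired
  reconstructions under different masks. The source describes this term
  only as a paired-reconstruction discrepancy; we use the mean absolute
  difference because it shares the scale of `L_recon` and keeps the product
  form below bounded. An embedding-space alternative would need negative
  pairs the task does not define.
* `L_total = L_recon · (1 + L_contrast)` — exactly; the multiplicative
  coupling means consistency errors amplify the reconstruction gradient
  rather than adding an independently-scaled term.

## Backbone

The encoder is a strided convolutional pyramid honouring the stage-shape
contract of the hierarchical attention encoder it stands in for: stage *i*
has spatial shape `(X/2^i, Y/2^i, Z/2^i)` with `C` feature maps at stages
0–1 and `2^(i−1)·C` beyond, for *i* = 0 … `n_downsamples`. At paper scale
`C = 24` with 5 downsamples on 128×128×64; the test profile uses `C = 8`
with 4 downsamples on 32×32×16 (a 16-voxel z-extent cannot be divided by
2⁵). `depths`/`num_heads` are carried as configuration metadata for
attention variants and do not alter the convolutional profile. The decoder
upsamples (nearest-neighbour ×2) with skip concatenation at every
resolution and ends in a 1×1×1 convolution with sigmoid, so reconstructions
lie strictly in (0, 1). The whole model runs on a small numpy reverse-mode
autodiff core written for this package (im2col/GEMM 3D convolution,
float32, single-threaded and bit-reproducible per seed).

## Training schedules

Pretraining uses Adam at a fixed learning rate with held-out volumes
excluded from every update; reconstruction SSIM/PSNR on the held-out set is
evaluated every `eval_interval` epochs (default 5) and the best-SSIM
weights are kept. Fine-tuning uses cross-entropy with AdamW and cosine
learning-rate decay to a 1e-9 floor, monitors validation accuracy every
epoch and keeps the earliest best-accuracy weights.

The protocol-scale schedules (pretraining lr 1e-4, 500 epochs; fine-tuning
1e-5 → 1e-9 over 200 epochs) remain the configuration defaults. The
desk-scale fixture runs use larger rates (3e-3) and far fewer epochs
(pretraining 20 on 8 volumes; fine-tuning 30 on 80 subjects): with tens of
gradient steps rather than ~10⁵, the total parameter displacement at 1e-5
would be O(1e-3) and no schedule could express a training signal. This is
step-count arithmetic, not tuning: the number of update steps times the
learning rate must be commensurate with the weight scale.

The classification head is global average pooling of the deepest encoder
stage, a parameter-free layer normalisation of the pooled feature vector,
then FC(128) → ReLU → FC(2). The normalisation makes the head invariant to
the overall activation scale of the encoder — pretraining is free to move
that scale by orders of magnitude, and without it a pretrained encoder
starts fine-tuning deep in the saturated regime. Class A (PD-like) is the
positive class everywhere: sensitivity counts PD-like detection.

## Phantom cohorts

A subject is built from a six-tissue label map: an ellipsoidal grey-matter
shell and white-matter core, a CSF ventricle, a brainstem-like midline
column, and a cerebellum-like posterior-inferior mass, with seeded jitter
of centres and radii providing anatomical variation. The two classes differ
by a localised morphological effect applied before rendering: class B
(PPS-like) dilates the ventricle into surrounding tissue and erodes the
midline core; class A (PD-like) thins the posterior mass. The number of
morphological steps is `2·effect_size`, with fractional steps flipping a
seeded random subset of the next boundary layer so the effect is monotone
and continuous in `effect_size`; the changed voxels are recorded per
subject as a ground-truth lesion mask. `effect_size = 0` produces
exchangeable classes by construction.

Rendering assigns each channel a tissue-mean intensity from a fixed lookup
table whose tissue *rank order differs across channels* (CSF darkest on
T1/FLAIR, brightest on T2, etc.), so no channel is a monotone function of
another and cross-channel context is genuinely informative for recovery —
the property the pretext task exploits. Gaussian noise (default sd 0.05) is
added inside the brain, a smooth multiplicative bias field (default
amplitude 0.1, Gaussian-filtered white noise at a quarter of the grid
scale) emulates coil inhomogeneity, and channels are min–max normalised
over brain voxels; background stays exactly 0.

Cohorts are split 8:1:1 (largest-remainder apportionment, stratified by
class, seeded); per-subject seeds derive from the master seed and subject
index, so cohorts are reproducible and extendable.

**What the phantoms do not emulate:** acquisition physics (no k-space, no
sequence simulation), real anatomical variability, registration error,
motion, pathology heterogeneity, or site effects. Passing tests show the
*pipeline* recovers implanted, localised, class-consistent structure under
controlled noise — they say nothing about discriminating real parkinsonian
syndromes.

## Preprocessing

Adaptive resampling mirrors the clinical protocol: volumetric T1
acquisitions to 1 mm isotropic, planar acquisitions to 0.8×0.8 mm in-plane
with slice spacing untouched. Interpolation is trilinear with a
voxel-centre convention (physical position of index *i* is `(i+0.5)·sp`).
Skull stripping and cross-contrast registration are out of scope and
accepted as precomputed inputs (a brain-mask NIFTI and co-registered
channels). Intensity normalisation is min–max over brain voxels — taken as
voxels non-zero in any channel when no explicit mask is supplied, which
makes repeated normalisation a no-op on multi-channel data; normalisation
precedes the resize to the network grid, matching the stated processing
order, and resized normalised volumes are clipped back to [0, 1].

## Saliency and group statistics

Occlusion sensitivity hides a cubic patch (all channels) at every position
of a stride lattice and records the drop in the predicted probability of
the subject's true class; per-voxel contributions are averaged over
covering patches. Defaults are patch 16, stride 8 (half-edge stride giving
2× overlap averaging) at paper grid scale and the scaled analogue 8/4 on
the 32×32×16 fixture grid; the fill value 0 equals the background value.
These parameters are not specified by the source and are documented
assumptions, chosen to mirror the pretraining block size.

Maps from correctly classified subjects are smoothed (Gaussian, FWHM 4
voxels at fixture scale; σ = FWHM/2.3548, reflective padding), contrasted
with a voxelwise two-sample pooled-variance t statistic (A − B; zero
pooled variance yields t = 0 with a flag), enhanced with TFCE
(E = 0.5, H = 2, 26-connectivity, 100 integration steps of height
`Δh = max/n_steps`; negative values enhanced on the negated map and
recombined with sign), and corrected by the max-statistic permutation test:
`p(v) = (1 + #{perm max ≥ |TFCE(v)|}) / (n_perm + 1)`, significance at
p < 0.05. Group sizes allowing fewer than 20 distinct relabelings trigger a
warning stating the attainable minimum p.

Two protocol details matter when validating FWER control under an
effect-free null. First, the correct-classification filter is *not*
applied: with exchangeable classes it would condition group membership on
the model's output, making the model's own decision boundary a real
between-group map difference and thereby testing a different hypothesis.
Second, null maps are computed against one *fixed* target class rather
than each subject's own (arbitrary) label: with two classes the P(A) and
P(B) occlusion deltas are exact negatives, so per-label maps would differ
between arbitrary groups by sign alone. Both filters belong to the
observed-effect analysis, where the classes genuinely differ.

Registration to a standard space is replaced by the phantoms' shared grid;
for real data the module accepts pre-registered maps.

## Evaluation statistics

Confusion metrics come from test-set tallies with zero-denominator metrics
reported as undefined (never silently 0). AUC is the Mann–Whitney rank
statistic with midranks for ties (equal to the trapezoidal area under the
empirical ROC). Confidence intervals are stratified nonparametric bootstrap
percentile intervals (resampling within each true class; default 2000
resamples; resamples with undefined metrics are skipped and counted). The
CI construction is a documented choice — the source reports CIs without a
method. DeLong's test uses placement-value covariance estimates; degenerate
variance returns z = 0, p = 1 by convention, and the reported AUCs are
computed with the same rank formula as `roc_auc` so the two agree exactly.

## Numerical choices and degenerate inputs

* float32 network arithmetic, float64 statistics; all randomness flows
  through `numpy.random.SeedSequence` keyed by explicit integer seeds.
* SSIM uses Gaussian weighting (σ 1.5, truncate 3.5), population
  covariance, and crops the filter-boundary margin before averaging —
  matching the conventional definition and the scikit-image reference to
  within 1e-5.
* PSNR of identical volumes is reported as +infinity (sentinel 100 dB
  inside training histories).
* Validation-accuracy ties during fine-tuning resolve to the earliest
  epoch; best-SSIM ties during pretraining keep the earlier checkpoint.
* A constant non-zero channel normalises to 0 with a warning rather than
  failing.
* TFCE's threshold step is tied to each map's maximum; the documented
  monotonicity property therefore applies to maps sharing a peak value
  (equal integration grids).

## Fixture scale and what it shows

The standard fixture is 32×32×16 voxels, C = 8, 4 masking blocks of edge 8,
8 pretraining volumes (20 epochs), 40 subjects/class downstream (30
epochs), saliency on 15/class evaluation cohorts with 199 permutations.
These sizes keep a full pipeline run in CPU-minutes while leaving every
contract (shape formula, loss identities, FWER control, parameter
recovery) exercised end to end. Paper-scale settings (128×128×64, C = 24,
84×16³ blocks, schedules above) remain available through configuration but
are not what the tests run.

## Known limitations

* The convolutional backbone honours the representation-shape contract but
  not the attention mechanism of the original encoder; transfer-learning
  magnitudes at this scale are not comparable to GPU-scale results.
* The phantom effect is geometric and strong relative to clinical effect
  sizes; parameter-recovery thresholds (AUC ≥ 0.9 at large effect) are
  claims about the pipeline, not about clinical attainability.
* Bootstrap CIs are percentile intervals; no continuity or acceleration
  correction.
* The masked fraction of the original protocol ("approximately 40 % of
  content") is not reproducible from 84·16³ against the whole grid
  (≤ 32.8 %); it is consistent with a within-brain accounting, and both
  fractions are reported.
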