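# Methods

This note records the models, conventions and numerical choices behind
`bodycomp`, in the spirit of a package reference manual: what each stage
assumes, which knobs matter, and what the synthetic experiments do and do
not demonstrate.

## Data model and preprocessing

A case is a pair of co-registered fat- and water-sequence volumes with
shared geometry, indexed `(slice, row, col)` with spacing `(dz, dy, dx)` in
mm. MR intensities are uncalibrated, so normalization is per-channel
Z-scoring over the *whole volume* (not per slice); a constant channel maps
to zeros. Resampling is in-plane only — images by third-order spline, masks
by nearest neighbour — because the segmentation model is 2D and slice
thickness (3–10 mm) is an order of magnitude above in-plane resolution
(0.3–1.0 mm); interpolating across such anisotropy would create artifacts.
The output grid size is `round_half_up(extent / target_spacing)`. Crop/pad
to the network's in-plane size is centred, pads masks with background, and
retains an invertible transform so predictions map back to native geometry.
Normalization precedes resampling; the order is exposed in the calling code
and makes no practical difference for these smooth transforms.

## Segmentation network

The backbone is a dual-channel 2D U-Net: 6 encoder blocks (two 3×3
same-padded convolutions, each followed by LeakyReLU with slope 0.01, then
2×2 max pooling), a two-convolution bottleneck at (480, 480) filters, and 6
decoder blocks (2×2 stride-2 transposed convolution, concatenation with the
matching encoder feature map, two convolutions). Encoder filter pairs are
(32,32), (64,64), (128,128), (256,256), (480,480), (480,480); the decoder
mirrors them; a 1×1 convolution forms the head. A 512×512 input reaches an
8×8 bottleneck. No normalization layers are used. The thigh head has 5
channels (4 labels + background). For the abdomen, 7 foreground labels
cannot share 7 softmax channels with a background class, so the head uses
8 channels (7 + background). For strict replication of the published
channel count, a 7-channel head can be configured (`out_channels=7`) with
`predict_volume(..., class_ids=[1..7])`, treating every channel as a
foreground label with no background class.

The engine is plain numpy in float32: convolutions and their backward
passes are lowered to GEMMs via `sliding_window_view` (the input gradient
of a same-padded correlation is a correlation with the flipped,
channel-transposed kernel, so no scatter-add is required). Finite-difference
tests pin every layer's gradients. Inference applies softmax then argmax
per slice, ties broken toward the lower class id.

A `tiny` preset (4 levels, filters capped at 64, nominal 128×128 input) is
provided for desk-scale experiments; the network is fully convolutional, so
any input divisible by `2^levels` is accepted.

## Training

Loss is the unweighted sum of soft Dice loss and cross-entropy. Dice is
pooled over batch and space, averaged over foreground classes only, with
smoothing ε = 1e−5 in numerator and denominator. Optimization is SGD with
Nesterov momentum μ = 0.99 from He-initialized weights, with the poly
schedule `lr = lr₀ (1 − epoch/epochs)^p`, lr₀ = 0.01. The decay exponent
p = 0.9 follows the usual convention for the poly policy and is
configurable. Reference-scale values are 200 epochs × 250 minibatches of
batch 10; desk-scale runs shrink these through the same config (the
scaled-down recovery experiment uses 25 epochs × 24 minibatches of batch 4
on 64×64 phantoms, which trains in a few minutes on one CPU core).
Minibatches draw slices uniformly with replacement, so the minibatch count
per epoch is independent of cohort size. With deep supervision, auxiliary
1×1 heads at the 1/2 and 1/4 decoder resolutions receive nearest-downsampled
targets; per-resolution weights halve coarse-ward and are normalized to sum
to 1. No early stopping or weight decay; the final checkpoint is the
last-epoch state (configurable). Augmentation (rotation ±30°, scale 0.7–1.4,
additive Gaussian noise variance 0–0.1, blur σ 0.5–1.0, gamma 0.7–1.5,
mirroring) fires independently per transform with probability 0.5; geometric
transforms warp image (spline) and mask (nearest) through one shared affine,
and a fired mirror flips all configured axes so that firing twice is the
identity.

## Evaluation metrics

Per compartment and case (3D voxel sets): DSC = 2TP/(2TP+FP+FN),
Jaccard = TP/(TP+FP+FN), TPF = TP/(TP+FN), OSR = FP/(TP+FN), and relative
area difference |(TP+FP) − (TP+FN)|/(TP+FN) × 100. The area difference is
reported as an absolute value (the signed variant is available); a
compartment empty in both masks scores DSC/Jaccard 1.0 and leaves
TPF/OSR/area difference missing, so compartment-free cases do not drag
cohort averages. Derived compartments (SAT, VAT) are unions of label ids
computed on the counts, which is identical to relabel-then-count. Cohort
tables weight cases equally (mean ± SD).

## Quantification

Volumes are voxel counts × `dz·dy·dx` in mm³ (reported in mL), with no
morphological post-processing. Circumference is measured per slice as the
perimeter of the iso-0.5 contour around the largest connected component,
after Gaussian smoothing of the binary blob with σ = 1 px: the raw
marching-squares polyline overestimates arc length on binary data by ~5%
(staircase bias), while the smoothed contour tracks discs to well under 1%,
at the cost of rounding sharp corners by about the smoothing radius (a
10×10 px square measures ≈ 36.6 rather than 40). The per-case value is the
mean over slices containing the compartment; a single-slice mode exists.

IMAT is quantified inside one muscle compartment per region — the core
muscle for the abdomen, the thigh muscle for the thigh — by 1-D 2-means on
raw (pre-normalization) fat-channel intensities: k-means++ seeding from a
seeded generator, convergence when the Frobenius norm of the centre change
is below 1e−4 of the centre norm or after 300 iterations, higher-mean
cluster labelled IMAT. An exact alternative — enumerating threshold cuts of
the sorted sample, which contains the global 2-means optimum in 1-D — is
provided as `threshold_search_1d` and doubles as the test oracle. Constant
intensities are flagged degenerate (IMAT = 0). IMAT percentage is the voxel
count ratio × 100; it is mapped onto a 3-level fatty-infiltration scale
(none / streaks / severe) with default cut points (5%, 25%) — the grading
standard defines stages qualitatively, so the numeric cuts are explicitly
configuration, not a published mapping.

## Agreement statistics

ICC is the single-measure two-way random-effects absolute-agreement form,
ICC(2,1) = (MS_R − MS_E) / (MS_R + (k−1)MS_E + k/n(MS_C − MS_E)) with k = 2
raters, computed from the ANOVA mean squares; it is invariant to a common
affine rescaling of both raters and strictly penalized by a constant bias
in one rater (the average-measure variant is behind a flag). Bland–Altman
limits are bias ± 1.96·SD of the paired differences. The trend test is OLS
of the measured value on the ordinal grade treated as continuous, with the
two-sided t-test on the slope; the group comparison is an independent
t-test, Welch by default (pooled selectable). All tests are two-sided at
α = 0.05.

## Synthetic phantoms: what they emulate, and what they do not

The generator produces anisotropic dual-channel volumes (default 8 slices
of 64×64 at (10, 1, 1) mm) with procedural geometry: the abdominal slice
nests skin → sSAT → dSAT → core-muscle wall → visceral cavity (IPAT
anteriorly, RPAT posteriorly, vertebral body and paired psoas embedded);
the thigh slice nests a SAT ring, muscle, a central femur and 2–3 small
vessel discs. Contrast defaults make adipose bright (≈800) and muscle dark
(≈100) in the fat channel, reversed in the water channel, with vessel
bright only in water; the fat/muscle modes sit ≥ 5 noise SDs apart at the
default noise SD of 40, guaranteeing K-means separability. IMAT is planted
as seeded speckle clusters of 1–3 voxels inside the host muscle until the
requested fraction is met to within one voxel; the planted mask is returned
exactly. Geometry and noise use independent seeded streams, so noise level
never alters the truth. Cohorts draw per-case IMAT fractions from a Beta
distribution around the configured mean (SD 0.04) and attach a lognormal
BMI-like covariate loosely tied to the realized subcutaneous-fat ring, so
the stratified split has a real stratifier.

These phantoms exercise every label, merge rule and pipeline stage, but
they are *not* anatomically or physically realistic: no Dixon reconstruction
physics, bias fields, chemical shift, partial-volume mixing, or realistic
IMAT streak morphology. Passing the desk-scale training-recovery experiment
(held-out mean foreground DSC > 0.8 for the tiny preset) shows the
architecture, loss, schedule and inference plumbing learn and generalize on
separable geometry; it says nothing about performance on clinical images.

In the synthetic agreement experiment the "reference rater" is the
ground-truth profile plus additive Gaussian noise with SD equal to 0.5% of
the cohort-mean volume — the scale of semi-automated re-tracing variability,
consistent with near-unity volume ICCs for tool-assisted readers. The IMAT
trend experiment plants fractions at 2%, 12% and 35% (8 phantoms each),
grades them with the (5%, 25%) cuts, and regresses recovered IMAT% on
grade.

## Splitting and orchestration

The cohort split is 8:1:1 train/validation/test, stratified on the BMI-like
covariate by rank-based quantile binning into 4 strata; within each stratum
cases are shuffled (seeded) and apportioned by largest-remainder rounding,
then single cases move between splits — always from the stratum where the
source split is most over-represented — until global sizes equal the
largest-remainder allocation of the whole cohort, keeping every stratum
within one case of proportionality. The pipeline derives per-stage seeds
from one master seed by fixed offsets; two runs with the same config are
byte-identical in every numeric artifact on a single CPU thread.

## Known limitations

- The numpy engine is single-threaded BLAS; the full 512×512 preset is
  practical for inference and contracts, not for full-scale training.
- Phantom realism as above; external validity requires real cohorts.
- DICOM support covers plain single-series axial stacks (no multi-frame,
  no orientation handling beyond slice ordering).
- The circumference convention (smoothed iso-contour, mean over slices) is
  one of several defensible definitions; it is documented and tested against
  analytic shapes rather than claimed to match any manual protocol.
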