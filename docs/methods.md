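# Methods

`hydroparc` implements a consciousness-evaluation stack for hydrocephalus
neuroimaging: inpainting of abnormal brain regions guided by the brain's
left-right symmetry, atlas parcellation mediated by the inpainted image,
functional-connectivity (FC) small-world analysis, and sparse regression
of behavioural consciousness scores (CRS-R) on FC features.  Because
clinical scans of this population cannot be redistributed, every stage is
exercised on synthetic phantoms generated by the package itself; this
note records the models, the defaults, and what the synthetic evidence
does and does not establish.

## Symmetry-guided inpainting

**Model.** The generator is a partial-convolution U-Net.  A partial
convolution computes, at each output location, the kernel response over
the *valid* pixels of its window, renormalized by `window_size / n_valid`,
and emits an updated validity mask (a location becomes valid as soon as
any input pixel in its window was valid).  Stacked layers therefore fill
an erased hole from its rim inward; a hole whose deepest pixel is k steps
from valid tissue fills after k 3x3 layers.  The network input is the
erased image with its mask *and the mirrored copies of both*: for
unilateral abnormalities the intact contralateral hemisphere appears in
the mirrored channel exactly where tissue is missing, so the network can
copy rather than hallucinate.

**Losses.** Training minimizes, per pass,

    L_inpainting = L_valid + 6 L_erase + 0.05 L_perceptual
                 + 120 (L_style_out + L_style_comp) + 0.1 L_tv

with pixel-count-normalized L1 terms over valid and erased pixels, a
perceptual L1 and two Gram-matrix style terms from a feature extractor,
and a total-variation penalty over a 1-pixel dilation of the hole on the
composited image `M*I_gt + (1-M)*I_out`.  Both the raw and the mirrored
pass are scored, a flip-consistency L1 ties the two outputs together in
the raw frame, and the generator additionally minimizes
`0.1 * (-log D(fake))` against an encoder discriminator trained with
binary cross-entropy on `[I_out, I_outflip]` versus `[I_gt, I_gtflip]`.
Generator and discriminator alternate one Adam step per batch.

Numerical choices: discriminator probabilities are clamped to
`[1e-7, 1 - 1e-7]` before logarithms; erased input pixels are exactly 0;
the flipped-pass output is re-flipped to the raw frame before the
consistency term (comparing in a common frame is the only reading that
makes it a symmetry constraint).  The TV term is an absolute smoothing
prior: it is not zero at perfect reconstruction unless the penalized
region is flat — all *error* terms are.

**Feature extractor.** The perceptual/style terms use a fixed-seed
random-weight convolutional stack (two stride-2 layers, 8 and 16
channels).  A fixed random deep feature is a valid perceptual metric and
requires no downloaded weights; the extractor is pluggable, so a
pretrained network can be substituted where available.

**Networks run on a small numpy reverse-mode autodiff engine**
(`hydroparc.nn`) with im2col-based convolutions; training is
deterministic for a fixed seed in single-threaded execution.

## Inpainting-mediated parcellation

The label-transfer chain is: erase the (manually identified) abnormal
region; inpaint it to get a pseudo-normal image I_N for the original
image I_T; compute a brain mask on I_N (threshold + largest component +
closing — an interface any skull-stripper can stand behind); warp the
mask onto I_T through the nonrigid registration I_N -> I_T and strip
both; register atlas -> I_N^S and I_N^S -> I_T^S; compose the two
displacement fields functionally (`composed(x) = phi1(x + phi2(x)) +
phi2(x)`, interpolated, not added); warp the atlas labels with
nearest-neighbour interpolation; and finally carry the labels onto the
functional grid with a rigid registration.  An ablation flag registers
the atlas directly onto I_T instead.

The built-in nonrigid registration is a 3-level demons-style gradient
descent on intensity MSE (iterations 60/60/40 coarse-to-fine, step 1.5,
fluid smoothing sigma 1.0, elastic smoothing sigma 1.5, all in voxels).
The erased region is excluded from the similarity force of the
I_N -> I_T and I_N^S -> I_T^S steps: there the two images differ by
construction (synthetic fill vs abnormality), so the field is
extrapolated from the trustworthy surroundings by the elastic smoothing.
Registration that fails to improve on identity returns the identity
field with a warning.  Displacement fields live on the fixed grid in
voxel units with pull-back sampling (`warped(x) = moving(x + u(x))`);
world affines are honoured only at I/O boundaries.

## Connectivity and small-world analysis

Region time courses are spatial means of the BOLD series over each
label; FC is the Pearson correlation matrix (symmetric, unit diagonal);
scans are binarized at ten thresholds and each graph's clustering
coefficient C (triangle-based, degree<2 nodes contribute 0) and
characteristic path length L (BFS, averaged over reachable pairs — the
convention of the standard toolboxes) are normalized by the means of ten
degree-preserving rewired references: lambda = L/L_rand, gamma = C/C_rand,
sigma = gamma/lambda.  The ten default thresholds are the even grid
0.05..0.50 — the analysis convention fixes their *count*, not their
values, so they are configurable.  Strict `>` binarization excludes
negative correlations by construction.  Graphs too small to rewire fall
back to density-matched uniform random references with a warning.
Group contrasts use a paired t-test within a group (same patients before
and after drainage) and a Welch t-test between the favorable and
unfavorable outcome groups.

## Score regression

The regression model is `min_w ||y - Xw||^2 + k ||w||_1` on features
standardized within each training fold; the solver is coordinate descent
(scikit-learn) with the penalty mapped as `alpha = k/(2n)`.  Evaluation
is nested leave-one-out cross-validation at the *patient* level: both
scans of the held-out patient are predicted by a model that never saw
them, with the penalty chosen by an inner leave-one-patient-out grid
search (default 30 log-spaced values over `[1e-3, 1] * k_max`, where
`k_max = 2 max|Z^T y_c|` provably zeroes the solution).  Discriminative
features are those with `|w|` above the mean `|w|` over all p
coefficients (the printed rule; a flag switches to nonzero-only means),
reported with region-pair names and raw two-sided marginal correlation
p-values, uncorrected, as in the source analyses.

## Synthetic data: what it emulates, and what it does not

Phantoms are 2-D (the inpainting operates on 2-D slices), exactly
mirror-symmetric about the vertical midline by construction, with
Voronoi-style bilateral region pairs sharing intensities, smooth
symmetric texture, intensities in [0, 1].  Lesions are elliptical
intensity shifts with an optional compact radial deformation.  Erase
masks are unions of random rectangles/ellipses/strokes with controlled
coverage, optionally confined to one hemisphere.  BOLD is a per-region
latent Gaussian process with a planted region covariance plus voxel
noise; cohorts plant a sparse linear feature-score relation and a
before/after small-worldness shift with opposite signs in the favorable
(mean -shift) and unfavorable (+shift) outcome groups, split 17:11 as in
the study population.

Real data differ in ways the phantoms deliberately ignore: anatomy is
only approximately symmetric and the midsagittal plane must be found
before flipping (the generators sidestep this; real-data users must
rigidly align the midline first); MR intensity physics, partial-volume
effects and scanner noise are absent; BOLD autocorrelation and
physiological confounds are not modelled; and the planted linear
score model is a best-case for LASSO.  Passing tests therefore establish
the *mechanisms* — the flip prior helps inpainting, inpainting mediation
helps registration, the statistics are computed correctly — not clinical
performance.

## Problem sizes

Experiments default to desk scale so the whole suite reruns routinely on
one CPU: the flip-guidance ablation trains on 80 phantoms of 48x48 for 6
epochs per configuration, over 3 training seeds, scoring 20 held-out
phantoms (typical contrast: +3 to +4 dB PSNR, +0.03 SSIM); the
parcellation-benefit experiment uses 10 hydrocephalus-like subjects with
cavities of radius 0.20-0.28 of the image size (severe ventricular
expansion) against a 12-region atlas; the end-to-end pipeline demo uses
12 patients, 8 regions and 180 timepoints.  Region counts below the
90-region atlas convention keep region sizes realistic at 48x48; all
structural conventions (90 labels, 4005 features, 10 thresholds, 10
random references) are preserved wherever the convention itself is the
point.

## Known limitations

2-D only; single-atlas label transfer (no multi-atlas fusion); the
built-in registration is MSE-driven and assumes comparable intensity
distributions (histogram matching of the atlas is applied by default);
the discriminator is small and the adversarial term correspondingly
gentle; LASSO solutions at very small penalties on near-noiseless folds
converge slowly (their validation error disqualifies them in the grid
search); and the favorable/unfavorable *classification* task is out of
scope — only the regression and group-contrast analyses are implemented.
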