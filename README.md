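# hydroparc

Consciousness evaluation for post-traumatic hydrocephalus from structural
and functional MRI: **symmetry-guided inpainting** of abnormal brain
regions, **inpainting-mediated atlas parcellation**, **small-world
analysis** of functional-connectivity (FC) networks, and **sparse (LASSO)
regression** of CRS-R consciousness scores on FC features.

Severe hydrocephalus deforms and erodes the brain so badly that
registering a healthy atlas template directly onto the patient image —
the standard route to whole-brain parcellation — fails around the
abnormality, and everything downstream (BOLD extraction, FC networks,
score prediction) inherits the damage.  The package's core idea: healthy
anatomy is approximately left-right mirror symmetric, while hydrocephalic
abnormalities are typically unilateral.  A partial-convolution GAN that
sees the erased image *and its mirror* can restore the abnormal region
from the intact contralateral hemisphere, and registration through this
pseudo-normal image succeeds where direct registration fails.

The package is aimed at methods researchers in neuroimage analysis.  The
clinical cohort it models cannot be redistributed, so first-class
synthetic generators (`hydroparc.synthetic_data`) emulate every input —
symmetric phantoms with unilateral lesions, BOLD with planted region
covariance, cohorts with a planted sparse FC-score relation — and every
claim the test suite makes is a mechanism demonstrated on them.

## The models

**Inpainting.** Partial convolutions renormalize each window by
`window_size / n_valid` over the validity mask and update the mask, so
stacked layers fill erased holes rim-inward.  The generator (a
partial-convolution U-Net) takes `[I_erased, M]` and the mirrored
`[I_erased_flip, M_flip]`, and trains with

    L_inpainting = L_valid + 6 L_erase + 0.05 L_perceptual
                 + 120 (L_style_out + L_style_comp) + 0.1 L_tv
    L_total = L_inpainting(raw) + L_inpainting(flipped) + L_flip
    generator objective:  L_total + 0.1 L_G,   L_G = -log D([I_out, I_outflip])

against a discriminator trained with binary cross-entropy.  `L_flip` is
the L1 gap between the raw-pass and mirrored-pass outputs.

**Parcellation.**  With `I_T` the patient image and `I_N` its inpainted
pseudo-normal, the label chain composes deformation fields
`phi(atlas -> I_N^S)` and `phi(I_N^S -> I_T^S)` (functional composition,
nearest-neighbour label warping) and finishes with a rigid step onto the
fMRI grid.

**Networks.**  FC is the 90x90 Pearson matrix of region-mean BOLD; ten
threshold cutoffs give binary graphs summarized by
`lambda = L/L_random`, `gamma = C/C_random`, `sigma = gamma/lambda`
against ten degree-preserving random references; `sigma > 1` is
small-world.  Per patient, `delta_sigma = sigma_after - sigma_before`
contrasts the favorable and unfavorable drainage-outcome groups.

**Regression.**  `min_w ||y - Xw||^2 + k||w||_1` on the 4005-entry upper
triangle of the FC matrix, evaluated by nested leave-one-patient-out
cross-validation (inner loop grid-searches k), reported as CC / MSE /
R^2, with discriminative features selected by `|w| > mean|w|`.

## Worked example

`examples/` holds one short script per capability.  For instance,
`python examples/03_parcellation_benefit.py` trains a small inpainting
model, builds ten hydrocephalus-like subjects (atlas anatomy under a
smooth warp plus a large unilateral CSF-dark cavity), and transfers
labels both ways:

```
mean label Dice per phantom
  with inpainting mediation: [0.789 0.87  0.859 0.855 0.874 0.878 0.853 0.812 0.861 0.798]
  direct registration:       [0.718 0.823 0.819 0.789 0.838 0.847 0.776 0.724 0.817 0.793]
inpainting route wins on 10/10 phantoms (mean 0.845 vs 0.794)
```

Dice is overlap with the planted ground-truth labels; the mediated route
wins because the atlas is aligned to a pseudo-normal image the cavity
cannot corrupt.  Similarly, `examples/04_connectivity_smallworld.py`
prints the per-threshold `(L, C, lambda, gamma, sigma)` table for a
planted-covariance scan and the Welch contrast of `delta_sigma` between
outcome groups, and `examples/05_score_regression.py` reports
out-of-sample `CC = 0.99, R^2 = 0.98` on a 28-patient synthetic cohort
with 10% score noise and shows the planted features recovered by the
`|w| > mean|w|` rule.

A thin CLI wraps the same library calls
(`hydroparc simulate|inpaint-train|inpaint-apply|inpaint-eval|parcellate|fc|smallworld|regress|run`).

## Layout

```
src/hydroparc/
  synthetic_data.py   phantoms, erase masks, BOLD, cohorts, atlas bundle
  nn.py               numpy reverse-mode autodiff (conv, pooling, Adam)
  inpainting.py       partial conv, flip-guided GAN, losses, training, PSNR/SSIM
  parcellation.py     deformation fields, demons + rigid registration, label chain
  connectivity.py     ROI series, FC matrices, thresholding, feature vectors
  smallworld.py       C, L, random references, lambda/gamma/sigma, group tests
  regression.py       LASSO objective and solver wrap, nested LOOCV, feature selection
  experiments.py      flip-ablation and parcellation-benefit protocols
  pipeline.py         end-to-end synthetic study with deterministic reports
  io.py, cli.py       NIfTI/PNG/CSV I/O and the thin command-line interface
```

`docs/methods.md` documents the models, defaults, numerical choices and
the limits of the synthetic evidence.
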