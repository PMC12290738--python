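# Methods

`longidiff` imputes a missing 3D structural MRI visit in a longitudinal
trajectory by conditional denoising diffusion, with forward-fill and
autoencoder comparators and a volumetric evaluation suite, all validated on
synthetic phantom cohorts.  This note records the model, the defaults, and
the numerical and design choices a maintainer would want to know.

## Model

A subject's record is an ordered list of (image, existence) pairs at a fixed
nominal 6-month spacing.  For a missing visit r with observed neighbours,
the target x_0 = x_r is generated conditionally on C = x_{r-1} (condition
kind "P") or C = (x_{r-1}, x_{r+1}) (kind "PF").

The forward process is the standard fixed-variance Gaussian chain

    q(x_t | x_{t-1}) = N(sqrt(1 - beta_t) x_{t-1}, beta_t I),
    q(x_t | x_0)     = N(sqrt(abar_t) x_0, (1 - abar_t) I),

with abar_t the running product of alpha_t = 1 - beta_t.  The reverse
transition uses the conjugate posterior mean evaluated at the estimated
clean image x0_hat = (x_t - sqrt(1-abar_t) eps_theta) / sqrt(abar_t):

    mean = sqrt(abar_{t-1}) beta_t / (1-abar_t) * x0_hat
         + sqrt(alpha_t) (1-abar_{t-1}) / (1-abar_t) * x_t,
    var  = (1-abar_{t-1}) / (1-abar_t) * beta_t,

with the convention abar_0 := 1, so the t=1 transition has zero variance and
is deterministic.  Training minimizes the plain noise-prediction objective
||eps - eps_theta(sqrt(abar_t) x_0 + sqrt(1-abar_t) eps, t, C)||^2 with t
uniform on [1, T]; conditions are never diffused — noise is applied to the
target only, and the clean condition units are concatenated along the
channel axis with the noisy target.

### 3D handling: local-continuous units

Full 3D networks are out of reach at this scale, so volumes of shape
(L, H, W) are cut along the slice axis into K near-equal segments (earlier
segments take the extra slices when K does not divide L).  A *unit* stacks
one clip of 2J+1 consecutive slices from every segment into a
K(2J+1)-channel 2D image.  Training draws clip centers uniformly from the
segment interior (skipping J boundary slices); generation takes clips in
order so that every slice is produced exactly once, then reassembles.  When
K(2J+1) does not divide L, the trailing clip of a segment is completed by
replicating the segment's last slice; replicated slots are recorded in the
layout's pad plan and dropped at reassembly, preserving the
every-slice-exactly-once property.

### Network

eps_theta is a UNet-like 2D encoder-decoder: residual blocks (group
normalization, SiLU, 3x3 convolutions, shortcut connection), stride-2
convolution downsampling and nearest-neighbour + convolution upsampling,
single-head self-attention at the coarsest level, and a sinusoidal timestep
embedding passed through two fully-connected layers and added per-channel in
every residual block.  The same backbone without the noisy-target channels
and with a constant t = 0 embedding is the autoencoder baseline, trained
under an l2 reconstruction loss until its running-mean loss plateaus
(window 500 steps, < 0.1% relative improvement twice in a row, hard cap on
steps).

Because no GPU deep-learning stack is part of the package's dependency set,
the network and its training loop are implemented on a small reverse-mode
automatic-differentiation engine over numpy (convolution via im2col, and
hand-derived backward passes for group normalization and attention).  Every
primitive's gradient is verified against central finite differences in the
test suite, as is the composed network.

### Output parameterization (a deliberate deviation from the vanilla recipe)

Two parameterizations of the network output are supported
(`DenoiserSpec.predict_type`):

* `"eps"` — the network predicts the injected noise directly (the textbook
  choice; default for the raw API).
* `"x0"` — the network output parameterizes the clean-image estimate g, and
  the noise prediction is formed algebraically,
  eps_theta = (x_t - sqrt(abar_t) g) / sqrt(1 - abar_t).  This is an exact
  reparameterization of the same eps_theta and leaves the training objective
  and the sampler untouched.

With `"x0"`, `DenoiserSpec.residual_blocks` can additionally declare input
channel blocks whose mean is added to the network output, so the clean-image
estimate becomes (adjacent-visit mean) + learned correction.  This is a
temporal-smoothness prior — the longitudinal analogue of residual frame
prediction in video generation.  The pipeline presets enable both.  The
reason is conditioning of the optimization problem at small scale: the
eps-parameterized x0 estimate carries a 1/sqrt(abar_t) error amplification
that a briefly trained CPU-scale network cannot overcome (empirically its
mid-chain x0 estimates stay worse than predicting the cohort mean), whereas
the residual x0 form starts at the adjacent-visit mean and refines it, and
ancestral sampling remains genuine (per-step Gaussian transitions with the
closed-form posterior variance).

### Sampling

Imputation runs ancestral sampling per generation unit from pure standard
normal noise down to t=1, conditioning each step on the matching condition
unit(s), then reassembles.  The running x0 estimate is clipped to [0, 1]
(the range of min-max-normalized images) before forming the posterior mean —
the standard guard that keeps imperfect noise predictions from driving the
chain out of distribution.  All stochastic operations take an explicit
seeded generator; a run is reproducible bitwise from (config, seed), and
checkpoints carry model, optimizer and generator state so a resumed training
run equals an uninterrupted one.

## Defaults and why

| parameter | default | rationale |
| --- | --- | --- |
| schedule | linear beta, 1e-4 to 0.02, T = 1000 | reference DDPM choice; abar_T < 1e-4 so the terminal marginal is standard normal |
| short chains | T = 50, beta scaled by 1000/T (2e-3 to 0.4) | keeps abar_T ~ 1e-5; an unscaled beta range at T = 50 leaves abar_T ~ 0.6 and ancestral sampling from N(0,1) is misspecified |
| unit geometry | J = 1 (3-slice clips), K = 5 for 32-slice phantoms | 3-slice clips per the unit design; K chosen so units cover a 32^3 volume in 3 passes |
| optimizer | Adam, lr 1e-4, batch 16 (full scale); lr 3e-4, batch 8 (tiny preset) | full-scale settings follow the study protocol; the tiny preset trades batch for steps on one CPU |
| AE stopping | plateau rule, window 500, 0.1% twice | "train until the loss stops decreasing" made precise |
| SSIM | Gaussian window sigma 1.5, size min(11, dim), K1 = 0.01, K2 = 0.03, data_range 1.0, map averaged over mask voxels | Wang-et-al. convention via scikit-image; the window/data-range convention is fixed here because metrics are only comparable under a fixed convention |
| PSNR | 20 log10(range) - 10 log10(masked MSE); +inf sentinel for identical images | dB definition; identical images are a legitimate oracle case, not an error |
| masking | both images multiplied by the mask before filtering | guarantees invariance to arbitrary content outside the mask, including near the boundary where windows straddle it |

## Synthetic cohort: what it emulates, what it does not

Each subject is an ellipsoidal brain (tissue intensity 0.35) containing
three ellipsoidal regions — two bright shrinking bodies and one dark
ventricle-like body (optionally expanding) — with per-subject jitter of
centers and axes, a subject-fixed smooth texture field (Gaussian-filtered
noise, sigma 3), per-visit additive Gaussian noise inside the brain, and
min-max normalization over brain voxels with exactly-zero background.
Region boundaries are rasterized with a one-voxel linear partial-volume
ramp so sub-voxel shrinkage between visits is visible in intensities.
Volume trajectories are geometric (constant per-visit axis ratio rho,
equivalently exponential volume decay) or linear in volume; ground truth is
stored both analytically (4/3 pi abc) and as label-map voxel counts.

Defaults: 32^3 voxels, 5 visits, rho = 0.95 (~14% volume loss per visit —
deliberately strong so that volumetric metrics are well resolved at 32^3),
noise sd 0.02, texture amplitude 0.05.  The nominal 6-month visit interval
is metadata only; no computation uses it.

Not emulated: MRI physics (bias fields, contrast mechanisms), registration
error, scanner/site effects, anatomically realistic shapes, or
segmentation-pipeline noise.  Passing tests therefore show that the
machinery is correct and that the imputers track simple monotone atrophy
under noise; they do not certify performance on real ADNI-like data.

## Volumetry of imputed images

Real pipelines derive regional volumes from a segmentation of the image.
The package's stand-in is deliberately simple: nearest-class-mean labeling
of brain voxels, with class means calibrated on the observed past visit
(image + true label map).  Imputed, observed and previous volumes are all
extracted with the same segmentation, so a perfect imputation scores error
rate exactly 0 and forward filling scores progression rate exactly 0.
External volume tables (tab-separated) can be imported instead.

Annualized atrophy comparison: rates are signed and anchored at baseline,
rate(t) = (V_0 - V_t) / V_0, so a ventricle-like expanding region has a
negative rate; scenario 2 doubles the 6-month rate (exact under linear
volume decline), scenario 3 substitutes the imputed 12-month volume.

## Scaled study sizes

The end-to-end study (`pipeline.run_phantom_study`, also what
`scripts/acceptance.py` runs) uses 24 subjects, 5 visits, 32^3 phantoms,
the PF missingness pattern, a 20/4 train/test subject split, T = 50, the
tiny network preset (base 16 channels, depth 2), batch 8, learning rate
3e-4, and 1200 training steps.  These sizes were chosen so the whole study
is a single-CPU, few-minute computation; the cross-validated protocol
(10 folds, 8:1 train:validation) is implemented and tested but the scaled
study evaluates a single split.

## Known limitations

* The tiny preset's imputation quality rides substantially on the
  adjacent-visit-mean prior; the learned correction improves masked MSE and
  regional error rates over both naive baselines only modestly at these
  training lengths.  Full-scale presets ("paper-p"/"paper-pf") exist but are
  not exercised by the tests.
* Single-head attention and two resolution levels only in the tiny preset;
  the full-scale architecture depth/attention placement is configurable but
  not validated against any reference.
* The numpy training loop is single-threaded and roughly two orders of
  magnitude slower than a GPU implementation; it is meant for correctness
  and desk-scale experiments, not production training.
* NIfTI affines carry voxel spacing only (diagonal); orientation metadata
  beyond spacing is not modelled.
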