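# longidiff

Conditional diffusion-model imputation of missing visits in longitudinal
structural MRI.

## The problem

Longitudinal neuroimaging studies (for example of Alzheimer's disease
progression) collect a T1-weighted MRI from each participant at fixed
intervals, but visits are missed — dropout, scanner artefacts, illness.
Missing whole-image visits shrink samples, bias atrophy estimates and break
downstream pipelines that expect complete trajectories.  `longidiff`
imputes the *entire 3D image* at a missing visit, conditioned on the
adjacent observed visit(s), so that any image-derived phenotype (regional
volumes, atrophy rates) can be computed afterwards with standard tools.

## The model

A denoising diffusion probabilistic model (DDPM) with a fixed variance
schedule β₁…β_T corrupts the missing-visit image x₀ through
q(x_t | x_{t-1}) = N(√(1-β_t) x_{t-1}, β_t I), so that
q(x_t | x₀) = N(√ᾱ_t x₀, (1-ᾱ_t) I) with ᾱ_t = ∏_{s≤t}(1-β_s).  A
noise-prediction network ε_θ(x_t, t, C) is trained on

    L(θ) = E ‖ε − ε_θ(√ᾱ_t x₀ + √(1-ᾱ_t) ε, t, C)‖²,

where the condition C is the past visit (model "P") or the past and
following visits (model "PF"), concatenated channel-wise with the noisy
target and never diffused.  Imputation runs ancestral sampling from pure
noise through the closed-form posterior
p_θ(x_{t-1} | x_t, C) = N(μ̃_θ(x_t, t, C), β̃_t I).

To keep 2D convolutions while generating coherent 3D volumes, each
(L, H, W) volume is split into K segments along the slice axis and
processed as *local-continuous units*: stacks of one (2J+1)-slice clip per
segment, shape K(2J+1)×H×W.  Training samples clips at random; generation
takes them in order and reassembles the volume exactly.

Comparators: forward filling (`naive-p`), adjacent-visit averaging
(`naive-pf`), and autoencoders with the same backbone trained under an ℓ2
loss (`ae-p`, `ae-pf`).  Evaluation: SSIM and PSNR within a brain mask,
per-region volume error rate |v̂−v|/v, progression rate |v_i−v_{i-1}|/v_{i-1},
and an annualized atrophy-rate comparison (complete data vs doubled
6-month rate vs imputed visit).  A synthetic phantom cohort with known
regional atrophy makes the whole pipeline testable end to end; see
`docs/methods.md` for modelling details and limitations.

The network and its training loop run on a small numpy reverse-mode
autodiff engine bundled with the package (`longidiff.autodiff`,
`longidiff.nn`); no GPU framework is required.

## Worked example

`examples/impute_and_evaluate.py` trains the tiny PF diffusion imputer for
300 steps on five 16³ phantom subjects and evaluates a held-out subject
(about a minute on one CPU):

```
training loss: 0.0148 -> 0.0075 -> 0.0097
diff-pf   ssim=0.9876 psnr=28.99 dB mse=0.00126 region error rate=0.1163
naive-pf  ssim=0.9865 psnr=28.24 dB mse=0.00150 region error rate=0.1472
naive-p   ssim=0.9752 psnr=25.57 dB mse=0.00278 region error rate=0.1778
```

Reading the numbers: forward filling (`naive-p`) copies the past visit, so
its error against the truly observed image is the atrophy that happened in
between (masked MSE 2.8e-3, ~18% regional volume error on these
fast-shrinking phantoms).  The diffusion imputer conditioned on both
neighbours tracks that atrophy (MSE 1.3e-3, ~12% volume error), beating
both forward filling and adjacent-visit averaging.  Other capabilities each
have a short script in `examples/`: diffusion arithmetic, unit slicing,
phantom cohorts, atrophy scenarios.

A thin CLI wraps the pipeline for shell use:

```sh
longidiff generate-data --out cohort --seed 1 --pattern PF
longidiff train --data cohort --out ckpt --imputer diff-pf --seed 1
longidiff impute --data cohort --checkpoint ckpt/checkpoint_005000.npz \
    --imputer diff-pf --out imputed --seed 1
longidiff evaluate --data cohort --imputed imputed --out report
```

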