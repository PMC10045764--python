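# dwiguide

Guided residual-CNN denoising of high b-value diffusion-weighted MRI (DWI),
with a multi-NEX rectal phantom simulator and quantitative evaluation.

## The problem

High b-value DWI is the workhorse contrast for detecting rectal tumors and
assessing treatment response, but diffusion weighting destroys SNR: clinical
protocols average 16 repeated excitations (NEX = 16), which multiplies scan
time and increases sensitivity to gas-related motion in the rectum.
`dwiguide` implements the alternative: acquire only 1–4 excitations and
denoise with a convolutional network that uses the high-SNR low b-value
image as an anatomical guide.

The network f_θ is a fully convolutional conv/batch-norm/ReLU stack trained
by **residual learning** — it predicts the noise, which is subtracted from
its input:

    denoised = noisy − f_θ(noisy, guide)

Training minimizes a joint L1–L2 loss against the NEX = 16 reference,

    L = Σₙ ½‖dₙ − rₙ‖₂² + λ Σₙ ‖dₙ − rₙ‖₁ ,   λ = 4 by default,

which trades off the over-smoothing of pure L2 against the residual noise of
pure L1.  Quality is scored with PSNR = 10·log₁₀(d_max/MSE), a global
(windowless) SSIM = I·C·S, their ROI-restricted variants, and pixel-wise
apparent diffusion coefficient (ADC) maps from the two-point inversion
ADC = −ln(s_high/s_low)/Δb.

Patient data are replaced by a seeded phantom generator that emulates
mono-exponential b-value decay, per-excitation Rician magnitude noise,
prefix-averaged NEX ∈ {1, 2, 4} series and the NEX = 16 reference, on a
rectum-like annulus with two distinct wall layers.  See
[docs/methods.md](docs/methods.md) for the full model description.

## Worked example

```python
from dwiguide import (GuidedDenoiser, LossConfig, NetConfig, PhantomSpec,
                      TrainConfig, make_dataset, prepare_dataset)

spec = PhantomSpec(n_slices=2, seed=1)            # 140 x 140, sigma = 0.06
pairs = make_dataset(spec, n_subjects=15, seed=1)
dataset = prepare_dataset(pairs[:10], n_val=2)    # 8 train + 2 validation
model = GuidedDenoiser(
    dataset,
    net_config=NetConfig(depth=8, width=32, seed=1),
    loss_config=LossConfig("joint", 4.0),
    train_config=TrainConfig(epochs=9, patch_stride=40, seed=1),
)
res = model.fit()
print(res.summary())

import pandas as pd
reports = res.evaluate(pairs[10:])                # 5 held-out subjects
table = pd.concat(r.table for r in reports)
print(table.groupby(["image", "nex"])[["psnr_global", "ssim_global"]].mean())
```

which prints (abridged):

```
Guided DWI Denoiser Results
============================================
architecture      depth 8, width 32, kernel 3x3
conv weights      56,160
total parameters  56,577
loss              joint (lambda = 4)
schedule          9 epochs, batch 32, Adam lr 0.001
training subjects 8  validation subjects 2
--------------------------------------------
epoch   1  train loss 3153.86687
epoch   2  train loss 1062.18136
epoch   3  train loss  812.65388   val loss  791.34381
...
epoch   9  train loss  514.76567   val loss  515.95599

              psnr_global  ssim_global
image    nex
denoised 1      26.771838     0.963546
         2      28.405958     0.975776
         4      29.436348     0.981384
noisy    1      21.023320     0.880735
         2      23.939150     0.940574
         4      27.316096     0.973532
```

Read: a single-excitation acquisition (16× faster than the NEX = 16
reference) is denoised from 21.0 dB / 0.881 SSIM to 26.8 dB / 0.964 —
better than the raw two-excitation acquisition — and the denoised NEX = 4
series beats every raw input.  ROI-mean ADC in the rectal wall is preserved
to within a few percent of the simulation ground truth.

The same workflow is available from the shell:

```
dwiguide simulate --subjects 15 --seed 1 --out data/
dwiguide train    --data data/ --loss joint --lambda 4 --seed 1 --out run/
dwiguide denoise  --checkpoint run/checkpoint.npz --noisy data/sub-000_b800_nex1.nii \
                  --guide data/sub-000_b50_guide.nii --out denoised.nii
dwiguide evaluate --data data/ --checkpoint run/checkpoint.npz --out report.csv
dwiguide sweep-lambda --data data/ --lambdas 2,4,5,6,10 --out sweep/
```

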