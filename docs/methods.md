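# Methods

## Problem and model

High b-value diffusion-weighted MRI (DWI) trades SNR for diffusion contrast:
at b = 800 s/mm² the rectal-wall signal is a third or less of its low-b
value, and clinical protocols compensate by averaging many excitations
(NEX, typically 16), at a proportional cost in scan time.  `dwiguide`
implements supervised residual denoising of few-excitation high-b images: a
fully convolutional network receives two channels — the noisy high-b image
and the high-SNR low-b image as an anatomical guide — and predicts the
*noise* component, which is subtracted from the input:

    denoised = noisy − f_θ(noisy, guide)

The network is a plain conv/batch-norm/ReLU stack with 3×3 kernels and zero
"same" padding throughout: layer 1 is conv+ReLU on the 2-channel input,
hidden layers are conv+BN+ReLU at constant width, and the last layer is a
linear conv producing the 1-channel residual.  The full-scale preset is
depth 64 / width 64 (2,287,296 convolution weights); the desk-scale default
used everywhere in this package is depth 8 / width 32, which trains in
minutes on one CPU core while preserving the architecture pattern.  Because
the network is fully convolutional, it is trained on 60 × 60 patches and
applied to full 140 × 140 slices.

Training minimizes the joint L1–L2 objective on denoised-vs-reference patch
pairs,

    L = Σ ½‖d − r‖₂² + λ Σ ‖d − r‖₁ ,

where the reference r is the NEX=16 average.  The L2 term removes noise
aggressively but over-smooths; the L1 term preserves edges but leaves
residual noise; λ = 4 is the default trade-off.  Per batch the sums are
divided by the batch size, so λ has the same meaning at any batch size (the
convention is recorded in checkpoints).  `l1_only` and `l2_only` modes drop
the other term for the three-way loss comparison, and `lambda_sweep` trains
one network per λ over a shared seed/data schedule (the conventional sweep
grid is {2, 4, 5, 6, 10}).

Optimization is Adam (lr 1e-3, batch 32) for 18 epochs by default, with the
validation loss evaluated every 3rd epoch.  The optimizer, batch size and
learning rate are this package's choices; the contract is the loss, not the
optimizer.  Data order, augmentation, and weight initialization
(Kaiming fan-in, seeded) are all driven by explicit seeds; single-threaded
runs are bit-reproducible.

## Phantom simulator

Patient data are replaced by a 2-D multi-slice phantom with the statistical
structure the denoiser relies on:

- **Geometry.** A pelvis-like ellipse (S0 0.75, ADC 1.4e-3 mm²/s) containing
  a rectum-like structure: lumen disk (S0 0.15, ADC 2.5e-3), inner wall ring
  (S0 1.0, ADC 1.0e-3) and outer wall ring (S0 0.8, ADC 1.3e-3), radii
  8/14/20 px on the default 140 × 140 matrix.  Two wall layers with distinct
  S0 make wall delineation after denoising measurable.  The rectum group is
  jittered by up to ±4 px per subject and tapers mildly across slices.
- **Signal.** Mono-exponential decay S(b) = S0·exp(−b·ADC) at b = 50
  (guide) and b = 800 s/mm² (noisy/reference).  b = 0 images are not
  generated; the two-point ADC estimator only uses Δb between the acquired
  b-values.
- **Noise.** Each excitation observes |S + g₁ + i·g₂| with g₁, g₂ i.i.d.
  N(0, σ²) — Rician magnitude noise, the physically standard model for
  magnitude MRI (a pure-Gaussian option exists for analytic tests).  The
  default σ = 0.06 puts the per-excitation wall SNR at ≈ 5.5–7.5, i.e. a
  visibly noisy single excitation.
- **Averaging.** One stack of 16 high-b excitations is drawn per subject;
  the NEX = 1/2/4 noisy volumes are prefix averages of that stack and the
  reference is the full average, so comparisons across NEX isolate
  averaging, as when all images come from a single acquisition.  The guide
  is the average of 4 low-b excitations.
- **Slice geometry** (5 mm thickness, 1 mm gap) is metadata only; the
  simulation and the network are 2-D slice-wise.

What the phantom does **not** emulate: EPI k-space acquisition, partial
Fourier, coil sensitivities, susceptibility distortion, gas-induced
geometric warps (an optional demo hook exists but is off by default), tumor
heterogeneity, or inter-scanner variability.  Passing tests therefore show
that the method behaves correctly under its stated noise model, not that it
generalizes to clinical data.

## Evaluation conventions

- **PSNR** is computed as printed in the source convention this package
  follows: 10·log₁₀(d_max / MSE) with d_max the peak of the image under
  test — *not* d_max².  On unit-normalized images the two coincide.  A
  standards-conformant d_max² variant is available behind a flag and used
  nowhere in defaults.
- **SSIM** is the single global product of luminance, contrast and structure
  terms over the whole image (or mask), with ε = 1e-12 stabilizing each
  denominator — no local windows, no C1/C2/C3 constants.  The windowed
  scikit-image SSIM is available behind a flag for cross-checks.
- Both metrics are computed per slice and aggregated as mean ± std; the ROI
  variants restrict all sums (including d_max) to the rectal mask dilated by
  3 px.
- **ADC** uses the two-point inversion ADC = −ln(s_high/s_low)/Δb in
  mm²/s (reported in 10⁻³ mm²/s).  Pixels where either signal is below
  1e-6 of max(s_low) are excluded via a validity mask; negative values are
  retained and flagged, never clamped.

## Numerical choices

- float32 network compute (float64 supported for gradient checks);
  convolutions are evaluated as one batched GEMM per kernel tap
  (shift-and-matmul), which is what makes CPU training practical.
- Batch-norm: ε 1e-5, running-statistic momentum 0.9; inference uses running
  statistics and is deterministic.
- Hidden conv layers carry no bias (redundant under batch norm); the first
  and last layers do.
- Patch stride defaults to 20 (overlapping); the last row/column of the
  patch grid is clamped to the image border so any stride ≤ size covers the
  full slice.  Augmentation samples uniformly from the 8 dihedral ops per
  patch per batch.
- Training-time normalization divides noisy and reference by the reference's
  global max and the guide by its own max; at inference (no reference) each
  volume is divided by its own max and the scale is returned for unit
  restoration.
- Degenerate inputs fail loudly: all-zero volumes cannot be normalized,
  non-finite training losses abort with a diagnostic, identical images yield
  an infinite-PSNR signal rather than an exception.

## Desk-scale study conditions

The end-to-end checks and `scripts/acceptance.py` run one fixed desk-scale
study: 15 simulated subjects (10 training, of which 2 validation; 5 held
out), 2 slices each at 140 × 140, depth-8/width-32 network, mixed-NEX
{1, 2, 4} patch pool (60 × 60, stride 40), joint loss at λ = 4, 9 epochs of
Adam at lr 1e-3 (≈ 120 optimizer steps).  This trains in a few minutes per
network on one CPU core.  Typical results: denoised NEX=1 gains 4–6 dB
PSNR and 0.05–0.08 global SSIM over the noisy NEX=1 input, with larger
gains at NEX=2/4; rectal-wall ROI-mean ADC is recovered to well within one
percent of the simulation truth.

## ADC bias structure (a caveat worth knowing)

Magnitude averaging reduces the *variance* of the signal estimate, not the
Rician *mean bias*: the expected magnitude of an N-average has the same
offset above the true signal for every N.  Meanwhile the log in the
two-point estimator contributes a downward Jensen term proportional to the
variance, i.e. ∝ 1/N.  At moderate wall SNR these two terms nearly cancel at
NEX = 1, so the ROI-mean ADC of a single excitation is almost unbiased,
while the NEX = 16 reference (and any denoiser trained toward it) carries
the small (≈ 1–2%) asymptotic magnitude-floor bias.  What improves
monotonically with NEX is the per-pixel ADC RMSE (precision), and that is
the property the test suite asserts.  ROI-mean ADC quantification and its
comparison against ground truth are therefore done on the rectal-wall mask
with measurement and truth over the same pixels.

## Known limitations

- The desk-scale network and cohort are far smaller than a clinical-scale
  configuration; reported gains are phantom-specific.
- The global (windowless) SSIM saturates quickly on high-NEX inputs and is
  less discriminative than the windowed standard.
- No registration between series is performed (phantom series are inherently
  aligned).
- The CNN engine is single-threaded numpy; it is intentionally minimal
  (same-padding 3×3-style convs, BN, ReLU, Adam) and not a general deep
  learning framework.
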