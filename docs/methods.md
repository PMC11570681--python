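# Methods

## Problem setting

A 2-D Cartesian MRI acquisition samples k-space line by line along the
phase-encode axis; skipping lines accelerates the scan by the ratio
R = (total lines)/(acquired lines) but violates the Nyquist criterion and
folds coherent aliasing into the image. The package models the scenario where
a slow FLAIR sequence is undersampled and a fast, fully sampled T2WI of the
same slice is available as an anatomical reference, and a convolutional
network restores the FLAIR image from the two.

## Synthetic data

Clinical raw multi-coil data for this task are not publicly distributable, so
the package ships a phantom generator that is itself first-class, tested code.

**Anatomy.** Each case is an ellipse/annulus composite on an even-sized grid
(default 64×64): an outer subcutaneous-fat ring, a muscle ring, a cortical
gray-matter shell, a white-matter core, two ventricular CSF ellipses, and for
patient cases one elliptical lesion placed wholly inside white matter.
Centers, radii and lesion geometry are jittered per seed. All five normal
tissue classes are present in every case; lesions form a single connected
component.

**Contrast.** Per-sequence tissue means (arbitrary units in [0, 1]) encode the
qualitative clinical ordering: CSF bright on T2WI (0.95) and nulled on the
FLAIR variants (0.10/0.12, strictly below white matter); lesions hyperintense
on T2-FLAIR (0.90) and mildly hypointense on T1-FLAIR (0.35). Noise is
additive Gaussian on the magnitude with per-tissue SD (default 0.03, zero in
air); phase is zero unless a phase map is supplied. At phantom SNR ≳ 10 the
difference between this model and Rician magnitude noise is negligible.

**Coils.** Sensitivities are smooth Gaussian lobes centered outside the FOV at
equispaced angles with mild linear phase ramps, normalized so the
root-sum-of-squares (RSS) across coils is exactly 1 at every pixel. That makes
the RSS combination of fully sampled coil images reproduce the ground-truth
magnitude identically, which in turn makes the zero-fill/full-sampling
identity and the long-skip identity exact test anchors. The default is 4
coils (1 for the training experiments below); the count is configurable.

**What the phantoms do not emulate:** realistic anatomy and texture, 3-D
volumes, B0 inhomogeneity, motion, chemical shift, differing voxel sizes
between sequences (phantom contrasts are perfectly co-registered by
construction). Passing tests therefore demonstrate that the pipeline and the
optimization behave as designed on controlled anatomy — not clinical image
quality.

**Cohort split.** `split_cohort` draws the test subjects first, uniformly per
stratum (healthy/patient), then splits the remainder per stratum with
`n_train = floor(train_fraction · n_remaining)`. The floor rule is the one
convention that maps an 80% split of (55 healthy, 167 patients) to exactly
44 + 133 training and 11 + 34 validation subjects (0.8 · 167 = 133.6).

## Undersampling masks

Masks vary only along phase-encode. A contiguous block of `n_acs` central
(lowest-frequency) lines is always sampled; each remaining line is included
independently with probability

    p = (n_ky/R − n_acs) / (n_ky − n_acs),

so the expected sampled-line count is `n_ky/R` — the acceleration is achieved
*on average* across mask draws. Default `n_acs` is 6.25% of `n_ky` (16 of
256), a common auto-calibration fraction for Cartesian protocols; the ACS
block is centered on the DC line (indices [n_ky/2 − n_acs/2,
n_ky/2 + n_acs/2 − 1] in DC-centered ordering). An `exact=True` mode draws
exactly `round(n_ky/R) − n_acs` outer lines without replacement for
line-count-stable experiments. Because the empirical acceleration
`n_ky/N_sampled` is a convex function of the line count, its mean over seeds
sits slightly above R (Jensen); at `n_ky=256`, `n_acs=16` the offset is about
+0.05 at R=4.5 and +0.02 at R=3.0, well inside the 2% calibration band the
tests enforce.

Fourier transforms are DC-centered and orthonormal, so Parseval's identity
and the round-trip identity hold to machine precision and the zero-filled
reconstruction of fully sampled data equals the ground-truth magnitude.

## Network

Inputs are the real and imaginary parts of complex images (2 channels per
branch). Each branch has a 32-channel residual stem; stem features are
concatenated and processed by a U-net body: residual blocks at 128, 256, 512,
1024 channels with 2×2 max pooling between scales, a 2048-channel bottleneck,
and a decoder of 2×2 stride-2 transposed convolutions with encoder skip
concatenation, halving channels per stage. A residual block is two
(3×3 convolution → batch norm → ReLU) units with an identity shortcut (1×1
projection when the channel count changes); one block per scale. The final
3×3 convolution maps to 2 channels and a long skip adds the undersampled
input, so zeroing that convolution makes the whole generator an exact
identity — this anchors the `reconstruct_case ≡ zero_fill_recon` test. The
single-input variant differs only in dropping the reference stem.

The discriminator is a patch critic: stride-2 4×4 convolutions (default 4
layers from 64 channels, batch norm + LeakyReLU 0.2 between) and a final 3×3
convolution to a 1-channel score map with no terminal squashing, as the
least-squares objectives operate on raw scores. Stems do not share weights;
concatenation happens at full resolution before the first pooling.

Complex coil images are processed sequentially (one forward pass per coil)
and combined by RSS. Before entering the network every complex image is
scaled to unit 99th-percentile magnitude (per case and sequence); the scale
is inverted on the output, keeping LSGAN targets well-ranged regardless of
phantom intensity units. Batch-norm statistics are frozen at evaluation time,
so reconstruction is deterministic.

All layers (convolution via im2col, transposed convolution, batch norm, max
pooling, activations) and the Adam optimizer are implemented in numpy with
hand-written backward passes (`msrecon.nnet`); gradient correctness was
verified against central finite differences during development. This keeps
the package CPU-only, dependency-light and bit-reproducible for a fixed seed.

## Training

Generator objective: `pixel + λ_adv · ½·E[(D(G(x)) − 1)²]` with the pixel term
L1 by default (robust, standard in image restoration) and λ_adv = 0.01 so the
pixel term dominates and the adversarial term sharpens. Discriminator
objective: `½·E[(D(y) − 1)²] + ½·E[D(G(x))²]`. One discriminator step per
generator step; both use Adam with betas (0.9, 0.999) and the step schedule
`lr(e) = lr₀ · 0.5^⌊e/100⌋`, default lr₀ = 1e-4. Training pairs are (masked
FLAIR coil image, full T2WI coil image) → full FLAIR coil image with one
random coil drawn per case per iteration and masks redrawn every epoch
(seeded), which is the data-augmentation reading of the expected-rate mask
scheme. With λ_adv = 0 the loop reduces to supervised regression. NaN losses
abort with a diagnostic; the checkpoint with the best validation PSNR is
retained when a validation set is supplied.

### Desk-scale experiment sizes

The full-scale configuration (~130M parameters) is built and verified
structurally, but training experiments use a reduced instance chosen once as
the CPU-scale counterpart of the original multi-day GPU run:

- generator: stems 8, encoder base 16, 2 scales (~126k parameters, full
  wiring preserved); discriminator: 3 layers, base 16;
- data: 20 single-coil 64×64 phantoms (10 healthy + 10 patient), held-out
  evaluation on 6 fresh phantoms from an independent master seed;
- optimization: 600 iterations (30 epochs × 20 cases) at lr 1e-3 — the higher
  rate compensates for the ~3-orders-shorter schedule; λ_adv = 0.01.

Under these conditions the trained dual-input network exceeds zero-filled
PSNR by well over 2 dB at R = 4.0 on held-out phantoms, and the dual-input
model beats the matched single-input model at R = 4.5 on every tested seed
(mean criterion asserted over 3 seeds). These are directional, desk-scale
statements about the method's mechanics, not clinical effect sizes.

## Regional metrics

`SNR = SI/SD` uses the mean and *within-ROI* sample standard deviation
(ddof = 1): background-based noise estimates are invalid for accelerated
images whose artifact level varies across the FOV.
`CNR = |SI₁ − SI₂| / √(SD₁² + SD₂²)` takes the absolute difference so the
statistic is symmetric in its two tissues. ROIs with fewer than two pixels or
(numerically) zero variance raise a degenerate-ROI error — a constant ROI's
floating-point SD is O(ε) rather than exactly zero, so "constant" is
`SD ≤ 1e-12 · max(|SI|, 1)`. Automatic ROIs take each tissue label eroded by
1 pixel (boundary decontamination); the lesion ROI is kept un-eroded so it
always covers the full pathology, and a disjoint "pathology surrounding" ring
(3-pixel dilation minus the lesion, restricted to tissue) is added. PSNR uses
`10·log₁₀(peak²/MSE)` with `inf` as the identical-image sentinel; SSIM is the
standard Gaussian-weighted form (7×7 window, σ = 1.5, k₁ = 0.01, k₂ = 0.03)
via scikit-image.

## Numerical and design notes

- Even grid sizes are required throughout (centered-FFT convention).
- Max-pool ties resolve to the first maximum in fixed scan order;
  reconstruction and training are deterministic per seed on CPU.
- Masks can be regenerated per case or fixed per acceleration factor via the
  `MaskPolicy.per_epoch` flag; both seed policies are supported because the
  original acquisition protocol is agnostic between them.
- k-space containers (HDF5) carry a mandatory convention flag
  ("dc-centered, orthonormal"); images round-trip through paired
  real/imaginary NIfTI volumes with a JSON sidecar.
- CLI exit codes: 0 success, 2 configuration error, 3 I/O error, 4 numeric
  failure.

## Known limitations

- The phantom family is geometrically simple; networks trained on it do not
  transfer to clinical data, and SNR/CNR magnitudes on phantoms are not
  comparable to in-vivo tables.
- No data-consistency layer: the network may alter sampled k-space lines.
- The numpy backend is single-threaded apart from BLAS matmuls; full-scale
  training is out of its intended scope.
- Coil sensitivities are noiseless and RSS-normalized; parallel-imaging
  reconstructions (SENSE/GRAPPA) are deliberately absent — the only baseline
  is zero-filling.
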