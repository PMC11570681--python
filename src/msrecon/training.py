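"""LSGAN + pixel-loss training of the reconstruction generator.

The generator minimizes ``pixel_loss + lambda_adv * lsgan_g_loss`` and
the discriminator the least-squares objective with real/fake targets
1/0.  Optimization is Adam with the halving-every-100-epochs learning
rate schedule; one discriminator step is taken per generator step.

Training pairs are (masked FLAIR coil image, fully sampled T2WI coil
image) -> fully sampled FLAIR coil image, with a fresh seeded
undersampling mask drawn every epoch, so mask realizations act as data
augmentation consistent with the expected-rate Bernoulli mask scheme.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError, NumericError
from .kspace import apply_mask, fft2c, ifft2c, make_cartesian_mask, rss_combine
from .metrics import psnr as _psnr
from .metrics import ssim as _ssim
from .phantom import PhantomCase
from .recon_net import (
    Discriminator,
    Generator,
    clone_generator,
    normalization_scale,
    reconstruct_case,
)
from .nnet import Adam

__all__ = [
    "TrainConfig",
    "MaskPolicy",
    "LossReport",
    "lsgan_d_loss",
    "lsgan_g_loss",
    "pixel_loss",
    "lr_at_epoch",
    "train",
]


@dataclass(frozen=True)
class TrainConfig:
    """Optimizer schedule and loss weighting.

    Defaults are the full-scale recipe: Adam at 1e-4 with betas
    (0.9, 0.999) and the learning rate halved every 100 epochs.
    ``lambda_adv`` weights the adversarial term against the pixel term;
    with ``lambda_adv = 0`` training reduces to supervised regression.
    """

    initial_lr: float = 1e-4
    betas: tuple[float, float] = (0.9, 0.999)
    lr_decay_every: int = 100
    lr_decay_factor: float = 0.5
    epochs: int = 10
    batch_size: int = 1
    lambda_adv: float = 0.01
    pixel_loss: str = "L1"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_loss.upper() not in ("L1", "L2"):
            raise ValueError("pixel_loss must be 'L1' or 'L2'")
        if self.lambda_adv < 0:
            raise ValueError("lambda_adv must be nonnegative")


@dataclass(frozen=True)
class MaskPolicy:
    """How undersampling masks are drawn during training/evaluation.

    ``per_epoch=True`` regenerates the mask of every case each epoch
    (augmentation); ``False`` fixes one mask per case for the whole run.
    """

    target_r: float = 4.0
    n_acs_fraction: float = 0.0625
    per_epoch: bool = True
    seed: int = 0

    def n_acs(self, n_ky: int) -> int:
        return max(1, round(self.n_acs_fraction * n_ky))

    def mask_for(self, n_ky: int, epoch: int, case_index: int):
        seed = self.seed + 100003 * (epoch if self.per_epoch else 0) + case_index
        return make_cartesian_mask(n_ky, self.target_r, self.n_acs(n_ky), seed=seed)


@dataclass
class LossReport:
    """Per-iteration losses and per-epoch validation quality."""

    pixel: list[float] = field(default_factory=list)
    adversarial: list[float] = field(default_factory=list)
    discriminator: list[float] = field(default_factory=list)
    val_psnr: list[float] = field(default_factory=list)
    val_ssim: list[float] = field(default_factory=list)

    @property
    def n_iterations(self) -> int:
        return len(self.pixel)


def _check_finite(name: str, arr: np.ndarray) -> None:
    if not np.isfinite(arr).all():
        raise NumericError(f"non-finite values in {name}")


def lsgan_d_loss(scores_real: np.ndarray, scores_fake: np.ndarray) -> float:
    """Least-squares discriminator loss with targets 1 (real) and 0 (fake)."""
    scores_real = np.asarray(scores_real, dtype=np.float64)
    scores_fake = np.asarray(scores_fake, dtype=np.float64)
    _check_finite("scores_real", scores_real)
    _check_finite("scores_fake", scores_fake)
    return float(0.5 * np.mean((scores_real - 1.0) ** 2) + 0.5 * np.mean(scores_fake**2))


def lsgan_g_loss(scores_fake: np.ndarray) -> float:
    """Least-squares generator loss pushing fake scores toward 1."""
    scores_fake = np.asarray(scores_fake, dtype=np.float64)
    _check_finite("scores_fake", scores_fake)
    return float(0.5 * np.mean((scores_fake - 1.0) ** 2))


def pixel_loss(recon: np.ndarray, target: np.ndarray, kind: str = "L1") -> float:
    """Mean absolute (L1) or mean squared (L2) error over all channels."""
    recon = np.asarray(recon, dtype=np.float64)
    target = np.asarray(target, dtype=np.float64)
    if recon.shape != target.shape:
        raise DimensionError(f"shape mismatch: {recon.shape} vs {target.shape}")
    diff = recon - target
    kind = kind.upper()
    if kind == "L1":
        return float(np.mean(np.abs(diff)))
    if kind == "L2":
        return float(np.mean(diff**2))
    raise ValueError("kind must be 'L1' or 'L2'")


def _pixel_grad(recon: np.ndarray, target: np.ndarray, kind: str) -> np.ndarray:
    diff = recon - target
    n = diff.size
    if kind.upper() == "L1":
        return np.sign(diff) / n
    return 2.0 * diff / n


def lr_at_epoch(config: TrainConfig, epoch: int) -> float:
    """Closed form of the step schedule: ``lr0 * factor**floor(e/every)``."""
    if epoch < 0:
        raise ValueError("epoch must be nonnegative")
    return config.initial_lr * config.lr_decay_factor ** (epoch // config.lr_decay_every)


def _sample_channels(img: np.ndarray, scale: float) -> np.ndarray:
    return np.stack([img.real, img.imag], axis=0) / scale


def validate(
    generator: Generator,
    cases: list[PhantomCase],
    mask_policy: MaskPolicy,
    sequence: str,
) -> tuple[float, float]:
    """Mean held-out PSNR/SSIM of full reconstructions against ground truth."""
    psnrs, ssims = [], []
    for i, case in enumerate(cases):
        k_full = fft2c(case.coil_images[sequence])
        mask = mask_policy.mask_for(k_full.shape[-2], epoch=0, case_index=i)
        k_masked = apply_mask(k_full, mask)
        ref = case.coil_images["T2WI"] if generator.config.use_reference_branch else None
        recon = reconstruct_case(generator, k_masked, ref, combine=True)
        truth = rss_combine(case.coil_images[sequence])
        peak = float(truth.max())
        psnrs.append(_psnr(truth, recon, peak=peak))
        ssims.append(_ssim(truth, recon, data_range=peak))
    return float(np.mean(psnrs)), float(np.mean(ssims))


def train(
    generator: Generator,
    discriminator: Discriminator | None,
    dataset: list[PhantomCase],
    mask_policy: MaskPolicy,
    config: TrainConfig,
    val_dataset: list[PhantomCase] | None = None,
    sequence: str = "T2_FLAIR",
) -> tuple[Generator, LossReport]:
    """Alternating LSGAN training on phantom cases.

    Every iteration draws one (case, coil) sample: the fully sampled
    FLAIR coil image is the regression target, its freshly masked
    zero-filled version the input, and the matching T2WI coil image the
    reference (dual-input models).  Complex images are split into
    real/imaginary channels and normalized per sample to a unit
    99th-percentile magnitude.  Returns the generator state with the best
    validation PSNR (or the final state when no validation set is given)
    plus the loss trace.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    dual = generator.config.use_reference_branch
    use_gan = config.lambda_adv > 0 and discriminator is not None

    rng = np.random.default_rng(config.seed)
    g_opt = Adam(generator.parameters(), lr=config.initial_lr, betas=config.betas)
    d_opt = (
        Adam(discriminator.parameters(), lr=config.initial_lr, betas=config.betas)
        if use_gan
        else None
    )
    report = LossReport()
    best_psnr = -np.inf
    best_state: Generator | None = None

    for epoch in range(config.epochs):
        lr = lr_at_epoch(config, epoch)
        g_opt.lr = lr
        if d_opt is not None:
            d_opt.lr = lr
        order = rng.permutation(len(dataset))
        for pos in range(0, len(order), config.batch_size):
            idx = order[pos : pos + config.batch_size]
            xs, refs, targets = [], [], []
            for i in idx:
                case = dataset[int(i)]
                coils = case.coil_images[sequence]
                c = int(rng.integers(coils.shape[0]))
                k_full = fft2c(coils[c])
                mask = mask_policy.mask_for(k_full.shape[-2], epoch, int(i))
                zf = ifft2c(apply_mask(k_full, mask))
                scale = normalization_scale(zf)
                xs.append(_sample_channels(zf, scale))
                targets.append(_sample_channels(coils[c], scale))
                if dual:
                    ref = case.coil_images["T2WI"][c]
                    refs.append(_sample_channels(ref, normalization_scale(ref)))
            x = np.stack(xs)
            target = np.stack(targets)
            ref_batch = np.stack(refs) if dual else None

            recon = generator.forward(x, ref_batch, train=True)
            p_loss = pixel_loss(recon, target, config.pixel_loss)
            if not np.isfinite(p_loss):
                raise NumericError(
                    f"pixel loss became non-finite at iteration {report.n_iterations}"
                )
            d_recon = _pixel_grad(recon, target, config.pixel_loss)

            a_loss = 0.0
            d_loss = 0.0
            if use_gan:
                # --- discriminator step (generator output treated as constant)
                discriminator.zero_grad()
                s_real = discriminator.forward(target, train=True)
                d_loss = 0.5 * float(np.mean((s_real - 1.0) ** 2))
                discriminator.backward((s_real - 1.0) / s_real.size)
                s_fake = discriminator.forward(recon, train=True)
                d_loss += 0.5 * float(np.mean(s_fake**2))
                discriminator.backward(s_fake / s_fake.size)
                if not np.isfinite(d_loss):
                    raise NumericError(
                        f"discriminator loss non-finite at iteration {report.n_iterations}"
                    )
                d_opt.step()
                # --- adversarial gradient for the generator
                discriminator.zero_grad()
                s_fake = discriminator.forward(recon, train=True)
                a_loss = lsgan_g_loss(s_fake)
                d_recon = d_recon + config.lambda_adv * discriminator.backward(
                    (s_fake - 1.0) / s_fake.size
                )
                discriminator.zero_grad()

            generator.zero_grad()
            generator.backward(d_recon)
            g_opt.step()

            report.pixel.append(p_loss)
            report.adversarial.append(float(a_loss))
            report.discriminator.append(float(d_loss))

        if val_dataset:
            vp, vs = validate(generator, val_dataset, mask_policy, sequence)
            report.val_psnr.append(vp)
            report.val_ssim.append(vs)
            if vp > best_psnr:
                best_psnr = vp
                best_state = clone_generator(generator)

    return (best_state or generator), report
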