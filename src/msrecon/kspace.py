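"""Centered Fourier transforms, Cartesian undersampling, and zero-filling.

Conventions
-----------
All k-space grids are DC-centered (the zero-frequency line sits at index
``n//2`` on each axis) and transforms are orthonormal (``norm="ortho"``),
so Parseval's identity holds exactly and ``ifft2c(fft2c(x)) == x`` to
floating-point precision.

Undersampling follows the scheme used for 2-D accelerated acquisitions:
a contiguous block of the lowest-frequency phase-encode lines (the ACS
region) is always acquired, and every remaining line is included
independently with the probability that achieves the desired
acceleration factor on average.  Only phase-encode (ky) lines are ever
dropped; the readout (kx) direction stays fully sampled, matching what
is physically achievable for 2-D Cartesian sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DimensionError

CONVENTION = "dc-centered, orthonormal"

#: Acceleration factors of the accelerated-FLAIR study protocol.
ACCELERATION_FACTORS = (3.0, 3.5, 4.0, 4.5)

__all__ = [
    "CONVENTION",
    "ACCELERATION_FACTORS",
    "CartesianMask",
    "fft2c",
    "ifft2c",
    "make_cartesian_mask",
    "effective_acceleration",
    "apply_mask",
    "zero_fill_recon",
]


def _check_even(shape: tuple[int, ...]) -> None:
    h, w = shape[-2], shape[-1]
    if h % 2 or w % 2:
        raise DimensionError(
            f"spatial dimensions must be even for the centered FFT, got {h}x{w}"
        )


def fft2c(image: np.ndarray) -> np.ndarray:
    """Centered, orthonormal 2-D FFT over the trailing two axes.

    Accepts a single complex image ``(H, W)`` or a multi-coil stack
    ``(n_coils, H, W)``; the DC component of the result sits at the grid
    center.
    """
    image = np.asarray(image)
    _check_even(image.shape)
    axes = (-2, -1)
    shifted = np.fft.ifftshift(image, axes=axes)
    k = np.fft.fft2(shifted, axes=axes, norm="ortho")
    return np.fft.fftshift(k, axes=axes)


def ifft2c(kspace: np.ndarray) -> np.ndarray:
    """Exact inverse of :func:`fft2c`."""
    kspace = np.asarray(kspace)
    _check_even(kspace.shape)
    axes = (-2, -1)
    shifted = np.fft.ifftshift(kspace, axes=axes)
    img = np.fft.ifft2(shifted, axes=axes, norm="ortho")
    return np.fft.fftshift(img, axes=axes)


@dataclass(frozen=True)
class CartesianMask:
    """Binary phase-encode sampling pattern with a fully sampled center.

    Attributes
    ----------
    sampled
        Boolean vector of length ``n_ky``; ``True`` marks acquired lines.
    n_acs
        Number of contiguous central auto-calibration lines, always sampled.
    target_r
        Nominal acceleration factor the inclusion probability was set for.
    seed
        Seed of the random line draw (reproducibility handle).
    """

    sampled: np.ndarray
    n_acs: int
    target_r: float
    seed: int = field(default=0)

    def __post_init__(self) -> None:
        sampled = np.asarray(self.sampled, dtype=bool)
        object.__setattr__(self, "sampled", sampled)
        n_ky = sampled.size
        lo, hi = _acs_bounds(n_ky, self.n_acs)
        if not sampled[lo:hi].all():
            raise ValueError("ACS block must be fully sampled")

    @property
    def n_ky(self) -> int:
        return int(self.sampled.size)

    @property
    def n_sampled(self) -> int:
        return int(self.sampled.sum())


def _acs_bounds(n_ky: int, n_acs: int) -> tuple[int, int]:
    """Index range [lo, hi) of the centered ACS block in DC-centered ordering."""
    lo = n_ky // 2 - n_acs // 2
    return lo, lo + n_acs


def make_cartesian_mask(
    n_ky: int,
    target_r: float,
    n_acs: int,
    seed: int,
    exact: bool = False,
) -> CartesianMask:
    """Draw a Cartesian undersampling mask for one acceleration factor.

    The ``n_acs`` lowest-frequency lines (centered on DC) are always
    included.  Each remaining line is included independently with
    probability ``p = (n_ky/target_r - n_acs) / (n_ky - n_acs)`` so that
    the expected number of sampled lines is ``n_ky / target_r``.  With
    ``exact=True`` the non-ACS lines are instead drawn without
    replacement so that exactly ``round(n_ky/target_r)`` lines are
    sampled — useful when a bit-stable line count matters more than the
    expected-rate semantics.
    """
    if n_ky <= 0:
        raise ValueError(f"n_ky must be positive, got {n_ky}")
    if target_r < 1:
        raise ValueError(f"acceleration factor must be >= 1, got {target_r}")
    if not 0 <= n_acs <= n_ky:
        raise ValueError(f"n_acs must lie in [0, {n_ky}], got {n_acs}")
    expected = n_ky / target_r
    if n_acs > n_ky:
        raise ValueError("ACS block larger than grid")
    denom = n_ky - n_acs
    if denom == 0:
        p = 1.0 if expected >= n_ky else None
    else:
        p = (expected - n_acs) / denom
    if p is None or not 0.0 <= p <= 1.0:
        raise ValueError(
            f"target_r={target_r} with n_acs={n_acs} requires inclusion "
            f"probability outside [0, 1]"
        )

    sampled = np.zeros(n_ky, dtype=bool)
    lo, hi = _acs_bounds(n_ky, n_acs)
    sampled[lo:hi] = True
    outside = np.flatnonzero(~sampled)
    rng = np.random.default_rng(seed)
    if exact:
        n_extra = int(round(expected)) - n_acs
        if n_extra < 0:
            raise ValueError("target_r too large for the ACS block")
        chosen = rng.choice(outside, size=n_extra, replace=False)
        sampled[chosen] = True
    else:
        sampled[outside] = rng.random(outside.size) < p
    return CartesianMask(sampled=sampled, n_acs=n_acs, target_r=float(target_r), seed=seed)


def effective_acceleration(mask: CartesianMask) -> float:
    """Actual acceleration: total lines over acquired lines."""
    n = mask.n_sampled
    if n == 0:
        raise ValueError("mask samples no lines; acceleration undefined")
    return mask.n_ky / n


def apply_mask(kspace: np.ndarray, mask: CartesianMask) -> np.ndarray:
    """Zero every unsampled ky line across all coils and kx columns.

    ky is the second-to-last axis (rows of each coil grid).  Sampled
    lines are returned bit-identical; the operation is a projection and
    therefore idempotent.
    """
    kspace = np.asarray(kspace)
    if kspace.shape[-2] != mask.n_ky:
        raise DimensionError(
            f"mask length {mask.n_ky} does not match k-space ky size "
            f"{kspace.shape[-2]}"
        )
    out = kspace.copy()
    out[..., ~mask.sampled, :] = 0
    return out


def rss_combine(coil_images: np.ndarray) -> np.ndarray:
    """Root-sum-of-squares magnitude combination over the leading coil axis."""
    coil_images = np.asarray(coil_images)
    if coil_images.ndim == 2:
        return np.abs(coil_images)
    return np.sqrt((np.abs(coil_images) ** 2).sum(axis=0))


def zero_fill_recon(k_masked: np.ndarray) -> np.ndarray:
    """Naive baseline: inverse transform per coil, then RSS combination.

    Missing k-space lines stay zero, producing the characteristic
    coherent aliasing along the phase-encode direction.  Output is a
    nonnegative real image.
    """
    return rss_combine(ifft2c(np.asarray(k_masked)))
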