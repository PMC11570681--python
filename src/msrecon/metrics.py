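"""Regional image-quality metrics: ROI SNR/CNR and reference-based PSNR/SSIM.

The regional formulas follow radiological practice for accelerated-MRI
reading studies: the noise estimate is the standard deviation *within*
each tissue ROI (not a background ROI), because undersampled images have
spatially nonuniform artifact levels.

    SNR  = SI_tissue / SD_tissue
    CNR  = |SI_1 - SI_2| / sqrt(SD_1^2 + SD_2^2)

The absolute value in the numerator makes CNR symmetric in its two
tissues; standard deviations are sample estimates (ddof=1).  Both
formulas are ratios and hence invariant under global positive rescaling
of the image.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import ndimage
from skimage.metrics import structural_similarity

from .errors import DegenerateRoiError, DimensionError
from .phantom import LABEL_NAMES, LESION, TissueMap

__all__ = [
    "Roi",
    "RoiMetricReport",
    "roi_snr",
    "roi_cnr",
    "psnr",
    "ssim",
    "auto_rois",
    "report_for_image",
]


@dataclass(frozen=True)
class Roi:
    """A named pixel set on an H x W grid."""

    mask: np.ndarray  # boolean H x W
    label: int
    name: str

    def __post_init__(self) -> None:
        mask = np.asarray(self.mask, dtype=bool)
        if mask.ndim != 2:
            raise DimensionError("ROI mask must be 2-D")
        if not mask.any():
            raise ValueError(f"ROI {self.name!r} is empty")
        object.__setattr__(self, "mask", mask)

    @property
    def size(self) -> int:
        return int(self.mask.sum())

    def values(self, image: np.ndarray) -> np.ndarray:
        image = np.asarray(image)
        if image.shape != self.mask.shape:
            raise DimensionError(
                f"image shape {image.shape} does not match ROI grid {self.mask.shape}"
            )
        return image[self.mask]


def _roi_stats(image: np.ndarray, roi: Roi) -> tuple[float, float]:
    vals = roi.values(image)
    if vals.size < 2:
        raise DegenerateRoiError(f"ROI {roi.name!r} has fewer than 2 pixels")
    return float(vals.mean()), float(vals.std(ddof=1))


def _is_constant(si: float, sd: float) -> bool:
    # a constant ROI leaves an O(eps) residual SD from mean round-off
    return sd <= 1e-12 * max(abs(si), 1.0)


def roi_snr(image: np.ndarray, roi: Roi) -> float:
    """Mean over the ROI divided by its sample standard deviation."""
    si, sd = _roi_stats(image, roi)
    if _is_constant(si, sd):
        raise DegenerateRoiError(
            f"ROI {roi.name!r} is constant; within-tissue SNR undefined"
        )
    return si / sd


def roi_cnr(image: np.ndarray, roi1: Roi, roi2: Roi) -> float:
    """Absolute ROI-mean difference over the root of summed ROI variances."""
    si1, sd1 = _roi_stats(image, roi1)
    si2, sd2 = _roi_stats(image, roi2)
    denom = np.hypot(sd1, sd2)
    if _is_constant(si1, sd1) and _is_constant(si2, sd2):
        raise DegenerateRoiError(
            f"ROIs {roi1.name!r} and {roi2.name!r} are both constant; CNR undefined"
        )
    return abs(si1 - si2) / denom


def psnr(reference: np.ndarray, test: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; ``inf`` for identical images."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise DimensionError("reference and test shapes differ")
    if peak <= 0:
        raise ValueError("peak must be positive")
    mse = float(np.mean((reference - test) ** 2))
    if mse == 0:
        return float("inf")
    return 10.0 * np.log10(peak**2 / mse)


def ssim(reference: np.ndarray, test: np.ndarray, data_range: float | None = None) -> float:
    """Mean structural similarity with a 7x7 Gaussian window (sigma 1.5)."""
    reference = np.asarray(reference, dtype=np.float64)
    test = np.asarray(test, dtype=np.float64)
    if reference.shape != test.shape:
        raise DimensionError("reference and test shapes differ")
    if data_range is None:
        lo = min(reference.min(), test.min())
        hi = max(reference.max(), test.max())
        data_range = hi - lo if hi > lo else 1.0
    return float(
        structural_similarity(
            reference,
            test,
            data_range=data_range,
            gaussian_weights=True,
            sigma=1.5,
            win_size=7,
            K1=0.01,
            K2=0.03,
        )
    )


def auto_rois(tissue_map: TissueMap, erode: int = 1, ring_width: int = 3) -> list[Roi]:
    """One ROI per tissue label plus a ring around any lesion.

    Each tissue mask is eroded by ``erode`` pixels to avoid
    partial-volume contamination at class boundaries (labels that vanish
    under erosion are skipped with a warning).  For lesions an extra
    "pathology surrounding" ROI is added: a ring of ``ring_width``
    pixels around — and disjoint from — the lesion, restricted to
    non-background tissue.
    """
    labels = tissue_map.labels
    rois: list[Roi] = []
    for label in tissue_map.present_labels():
        if label == 0:
            continue
        mask = labels == label
        # the lesion ROI is kept whole so it always covers more than half
        # of (here: exactly) the pathology; erosion would shrink small
        # lesions below that coverage requirement
        if erode > 0 and label != LESION:
            mask = ndimage.binary_erosion(mask, iterations=erode)
        if not mask.any():
            warnings.warn(
                f"label {LABEL_NAMES.get(label, label)} vanished after erosion; skipped",
                stacklevel=2,
            )
            continue
        rois.append(Roi(mask=mask, label=label, name=LABEL_NAMES.get(label, str(label))))

    lesion = labels == LESION
    if lesion.any():
        ring = ndimage.binary_dilation(lesion, iterations=ring_width) & ~lesion
        ring &= labels > 0
        if ring.any():
            rois.append(Roi(mask=ring, label=LESION, name="pathology_surrounding"))
    return rois


@dataclass
class RoiMetricReport:
    """Per-ROI intensity statistics and all pairwise CNRs for one image."""

    case_id: str
    sequence: str
    acceleration: float
    roi_stats: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    # roi name -> (SI, SD, SNR)
    cnr: dict[tuple[str, str], float] = field(default_factory=dict)

    def rows(self) -> list[dict]:
        """Tidy rows ready for CSV export."""
        out = []
        for name, (si, sd, snr) in self.roi_stats.items():
            out.append(
                {
                    "case_id": self.case_id,
                    "sequence": self.sequence,
                    "acceleration": self.acceleration,
                    "kind": "snr",
                    "roi": name,
                    "SI": si,
                    "SD": sd,
                    "value": snr,
                }
            )
        for (a, b), v in self.cnr.items():
            out.append(
                {
                    "case_id": self.case_id,
                    "sequence": self.sequence,
                    "acceleration": self.acceleration,
                    "kind": "cnr",
                    "roi": f"{a}/{b}",
                    "SI": "",
                    "SD": "",
                    "value": v,
                }
            )
        return out


def report_for_image(
    image: np.ndarray,
    rois: list[Roi],
    case_id: str = "",
    sequence: str = "",
    acceleration: float = 1.0,
) -> RoiMetricReport:
    """Evaluate SNR for every ROI and CNR for every ROI pair.

    Degenerate ROIs (constant intensity, e.g. on a noiseless phantom)
    are skipped with a warning rather than aborting the whole report.
    """
    report = RoiMetricReport(case_id=case_id, sequence=sequence, acceleration=acceleration)
    usable: list[Roi] = []
    for roi in rois:
        try:
            si, sd = _roi_stats(image, roi)
            report.roi_stats[roi.name] = (si, sd, roi_snr(image, roi))
            usable.append(roi)
        except DegenerateRoiError as exc:
            warnings.warn(str(exc), stacklevel=2)
    for a, b in combinations(usable, 2):
        report.cnr[(a.name, b.name)] = roi_cnr(image, a, b)
    return report
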