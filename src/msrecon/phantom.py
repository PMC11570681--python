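"""Seeded multi-contrast 2-D brain phantoms with coil sensitivities.

The generator produces paired T2WI / T1-FLAIR / T2-FLAIR images over a
shared tissue label map, standing in for clinical multi-sequence brain
acquisitions.  Anatomy is an ellipse/annulus composite: an outer
subcutaneous-fat ring, a muscle ring, a cortical gray-matter shell
around a white-matter core, ventricular CSF, and (for patient cases) a
single elliptical lesion inside the white matter.  The same label grid
drives every contrast, so the three sequences are perfectly
co-registered by construction.

Contrasts are piecewise constant at per-tissue mean intensities with
additive Gaussian noise on the magnitude.  The FLAIR sequences null CSF
(its mean sits well below white matter), while T2WI shows CSF bright —
the property the reference-guided reconstruction exploits.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import ConfigurationError, DimensionError

__all__ = [
    "BACKGROUND",
    "WHITE_MATTER",
    "GRAY_MATTER",
    "CSF",
    "FAT",
    "MUSCLE",
    "LESION",
    "LABEL_NAMES",
    "SEQUENCES",
    "TissueMap",
    "ContrastModel",
    "CoilProfile",
    "PhantomCase",
    "default_contrast_model",
    "generate_tissue_map",
    "render_contrast",
    "make_coil_profile",
    "simulate_coils",
    "make_dataset",
    "split_cohort",
]

BACKGROUND, WHITE_MATTER, GRAY_MATTER, CSF, FAT, MUSCLE, LESION = range(7)

LABEL_NAMES = {
    BACKGROUND: "background",
    WHITE_MATTER: "white_matter",
    GRAY_MATTER: "gray_matter",
    CSF: "csf",
    FAT: "fat",
    MUSCLE: "muscle",
    LESION: "lesion",
}

SEQUENCES = ("T2WI", "T1_FLAIR", "T2_FLAIR")


@dataclass(frozen=True)
class TissueMap:
    """Integer label grid defining the anatomy shared by all contrasts."""

    labels: np.ndarray

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels, dtype=np.int8)
        if labels.ndim != 2:
            raise DimensionError("tissue map must be a 2-D grid")
        object.__setattr__(self, "labels", labels)

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def present_labels(self) -> list[int]:
        return sorted(int(v) for v in np.unique(self.labels))


@dataclass(frozen=True)
class ContrastModel:
    """Per-sequence tissue intensity model.

    ``tissues[sequence][label] = (mean_intensity, noise_sd)`` in
    arbitrary units on [0, 1].  FLAIR sequences must place CSF strictly
    below white matter (fluid attenuation).
    """

    tissues: Mapping[str, Mapping[int, tuple[float, float]]]

    def __post_init__(self) -> None:
        for seq, table in self.tissues.items():
            for label, (mean, sd) in table.items():
                if sd < 0:
                    raise ConfigurationError(
                        f"negative noise_sd for {seq}/{LABEL_NAMES.get(label, label)}"
                    )
        for seq in ("T1_FLAIR", "T2_FLAIR"):
            table = self.tissues.get(seq)
            if table and CSF in table and WHITE_MATTER in table:
                if not table[CSF][0] < table[WHITE_MATTER][0]:
                    raise ConfigurationError(
                        f"{seq}: CSF mean must sit below white matter (fluid attenuation)"
                    )

    def mean(self, sequence: str, label: int) -> float:
        return self.tissues[sequence][label][0]

    def noise_sd(self, sequence: str, label: int) -> float:
        return self.tissues[sequence][label][1]


def default_contrast_model(noise_sd: float = 0.03) -> ContrastModel:
    """Canonical intensity tables for the three sequences.

    Values are chosen to mimic qualitative clinical contrast: T2WI shows
    CSF bright; both FLAIR variants null CSF; lesions are hyperintense on
    T2-FLAIR and mildly hypointense on T1-FLAIR.  Background noise is
    zero so air stays clean.
    """

    def table(means: dict[int, float]) -> dict[int, tuple[float, float]]:
        return {
            label: (mean, 0.0 if label == BACKGROUND else noise_sd)
            for label, mean in means.items()
        }

    return ContrastModel(
        tissues={
            "T2WI": table(
                {
                    BACKGROUND: 0.0,
                    WHITE_MATTER: 0.45,
                    GRAY_MATTER: 0.60,
                    CSF: 0.95,
                    FAT: 0.70,
                    MUSCLE: 0.30,
                    LESION: 0.80,
                }
            ),
            "T1_FLAIR": table(
                {
                    BACKGROUND: 0.0,
                    WHITE_MATTER: 0.70,
                    GRAY_MATTER: 0.55,
                    CSF: 0.10,
                    FAT: 0.85,
                    MUSCLE: 0.40,
                    LESION: 0.35,
                }
            ),
            "T2_FLAIR": table(
                {
                    BACKGROUND: 0.0,
                    WHITE_MATTER: 0.45,
                    GRAY_MATTER: 0.55,
                    CSF: 0.12,
                    FAT: 0.60,
                    MUSCLE: 0.30,
                    LESION: 0.90,
                }
            ),
        }
    )


def _ellipse(h: int, w: int, cy: float, cx: float, ry: float, rx: float) -> np.ndarray:
    yy, xx = np.mgrid[0:h, 0:w]
    return ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0


def generate_tissue_map(
    height: int, width: int, lesion: bool, seed: int
) -> TissueMap:
    """Draw one brain-like label grid; deterministic for a fixed seed.

    Geometry is jittered per seed (center, axes, ventricle placement,
    lesion position/size) so a cohort of phantoms varies while every
    anatomy keeps all five normal tissue classes.
    """
    if height % 2 or width % 2:
        raise DimensionError("height and width must be even")
    if height < 32 or width < 32:
        raise DimensionError("phantom must be at least 32x32")

    rng = np.random.default_rng(seed)
    h, w = height, width
    cy = h / 2 + rng.uniform(-0.02, 0.02) * h
    cx = w / 2 + rng.uniform(-0.02, 0.02) * w
    # Outer radii as fractions of the grid; rings are nested ellipses.
    ry = h * rng.uniform(0.40, 0.44)
    rx = w * rng.uniform(0.34, 0.38)

    labels = np.zeros((h, w), dtype=np.int8)
    fat = _ellipse(h, w, cy, cx, ry, rx)
    muscle = _ellipse(h, w, cy, cx, 0.93 * ry, 0.93 * rx)
    gm = _ellipse(h, w, cy, cx, 0.85 * ry, 0.85 * rx)
    wm = _ellipse(h, w, cy, cx, 0.68 * ry, 0.68 * rx)
    labels[fat] = FAT
    labels[muscle] = MUSCLE
    labels[gm] = GRAY_MATTER
    labels[wm] = WHITE_MATTER

    # Two ventricles: small CSF ellipses flanking the midline inside WM.
    for side in (-1.0, 1.0):
        vcx = cx + side * w * rng.uniform(0.08, 0.12)
        vcy = cy + rng.uniform(-0.04, 0.04) * h
        vent = _ellipse(
            h, w, vcy, vcx, h * rng.uniform(0.07, 0.10), w * rng.uniform(0.035, 0.05)
        )
        labels[vent & wm] = CSF

    if lesion:
        # One elliptical lesion placed in white matter, clear of ventricles.
        for _ in range(64):
            side = rng.choice([-1.0, 1.0])
            lcx = cx + side * w * rng.uniform(0.16, 0.24)
            lcy = cy + rng.uniform(-0.18, 0.18) * h
            les = _ellipse(
                h, w, lcy, lcx, h * rng.uniform(0.035, 0.07), w * rng.uniform(0.035, 0.07)
            )
            if les.any() and (labels[les] == WHITE_MATTER).all():
                labels[les] = LESION
                break
        else:  # pragma: no cover - geometry always admits a WM lesion
            raise RuntimeError("failed to place lesion inside white matter")

    return TissueMap(labels=labels)


def render_contrast(
    tissue_map: TissueMap,
    model: ContrastModel,
    sequence: str,
    seed: int,
    phase: np.ndarray | None = None,
) -> np.ndarray:
    """Render one sequence: class mean plus Gaussian noise on the magnitude.

    Phase is zero unless an explicit phase map is supplied, so the
    default output is a real-valued image stored as complex.
    """
    if sequence not in model.tissues:
        raise ConfigurationError(f"model does not define sequence {sequence!r}")
    table = model.tissues[sequence]
    labels = tissue_map.labels
    missing = [l for l in tissue_map.present_labels() if l not in table]
    if missing:
        names = ", ".join(LABEL_NAMES.get(l, str(l)) for l in missing)
        raise ConfigurationError(f"model for {sequence} missing labels: {names}")

    rng = np.random.default_rng(seed)
    magnitude = np.zeros(labels.shape, dtype=np.float64)
    for label in tissue_map.present_labels():
        mean, sd = table[label]
        mask = labels == label
        values = np.full(int(mask.sum()), mean)
        if sd > 0:
            values = values + rng.normal(0.0, sd, size=values.size)
        magnitude[mask] = values
    if phase is None:
        return magnitude.astype(np.complex128)
    if phase.shape != labels.shape:
        raise DimensionError("phase map shape must match the tissue map")
    return magnitude * np.exp(1j * phase)


@dataclass(frozen=True)
class CoilProfile:
    """Smooth complex coil sensitivities, RSS-normalized to 1 everywhere."""

    sensitivities: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.sensitivities, dtype=np.complex128)
        if s.ndim != 3:
            raise DimensionError("sensitivities must be n_coils x H x W")
        rss = np.sqrt((np.abs(s) ** 2).sum(axis=0))
        if not np.allclose(rss, 1.0, atol=1e-6):
            raise ConfigurationError("coil sensitivities must be RSS-normalized")
        object.__setattr__(self, "sensitivities", s)

    @property
    def n_coils(self) -> int:
        return self.sensitivities.shape[0]


def make_coil_profile(n_coils: int, height: int, width: int, seed: int = 0) -> CoilProfile:
    """Gaussian-lobed sensitivities at equispaced angles, RSS-normalized.

    Each coil is a smooth magnitude bump centered outside the FOV edge at
    angle ``2*pi*c/n_coils`` with a mild linear phase ramp — a standard
    desk-scale surrogate for measured birdcage-array sensitivities.
    """
    if n_coils < 1:
        raise ConfigurationError("need at least one coil")
    if n_coils == 1:
        return CoilProfile(np.ones((1, height, width), dtype=np.complex128))
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0:height, 0:width]
    cy, cx = (height - 1) / 2, (width - 1) / 2
    radius = 0.6 * max(height, width)
    sens = np.empty((n_coils, height, width), dtype=np.complex128)
    for c in range(n_coils):
        ang = 2 * np.pi * c / n_coils + rng.uniform(-0.1, 0.1)
        oy, ox = cy + radius * np.sin(ang), cx + radius * np.cos(ang)
        d2 = (yy - oy) ** 2 + (xx - ox) ** 2
        mag = np.exp(-d2 / (2 * (0.7 * radius) ** 2))
        ramp = 2 * np.pi * (yy * np.sin(ang) + xx * np.cos(ang)) / (4 * max(height, width))
        sens[c] = mag * np.exp(1j * ramp)
    rss = np.sqrt((np.abs(sens) ** 2).sum(axis=0))
    return CoilProfile(sens / rss)


def simulate_coils(image: np.ndarray, profile: CoilProfile) -> np.ndarray:
    """Pixelwise modulation of a coil-combined image by each sensitivity."""
    image = np.asarray(image)
    if image.shape != profile.sensitivities.shape[1:]:
        raise DimensionError(
            f"image shape {image.shape} does not match coil grid "
            f"{profile.sensitivities.shape[1:]}"
        )
    return profile.sensitivities * image[None, :, :]


@dataclass
class PhantomCase:
    """One subject: shared anatomy, three contrasts, per-coil images."""

    case_id: str
    cohort: str  # "healthy" | "patient"
    tissue_map: TissueMap
    images: dict[str, np.ndarray]  # sequence -> coil-combined complex H x W
    coil_images: dict[str, np.ndarray]  # sequence -> complex n_coils x H x W
    coil_profile: CoilProfile
    seed: int
    roi_set: list = field(default_factory=list)

    @property
    def has_lesion(self) -> bool:
        return bool((self.tissue_map.labels == LESION).any())


def make_dataset(
    n_healthy: int,
    n_patients: int,
    size: int,
    seed: int,
    n_coils: int = 4,
    noise_sd: float = 0.03,
    model: ContrastModel | None = None,
) -> list[PhantomCase]:
    """Generate a cohort of paired-contrast phantom cases.

    Per-case seeds are spawned deterministically from the master seed, so
    the same ``(counts, size, seed)`` always reproduces the dataset
    bit-for-bit, and lesion geometry varies across patient cases.
    """
    if n_healthy < 0 or n_patients < 0:
        raise ValueError("cohort counts must be nonnegative")
    if model is None:
        model = default_contrast_model(noise_sd=noise_sd)
    from .metrics import auto_rois  # local import: metrics depends on phantom types

    master = np.random.SeedSequence(seed)
    n_total = n_healthy + n_patients
    case_seeds = master.generate_state(max(n_total, 1) * 4, dtype=np.uint32)
    cases: list[PhantomCase] = []
    for i in range(n_total):
        healthy = i < n_healthy
        cohort = "healthy" if healthy else "patient"
        case_id = f"{'H' if healthy else 'P'}{i if healthy else i - n_healthy:03d}"
        s_geo, s_coil, s_img, _ = (int(v) for v in case_seeds[4 * i : 4 * i + 4])
        tmap = generate_tissue_map(size, size, lesion=not healthy, seed=s_geo)
        profile = make_coil_profile(n_coils, size, size, seed=s_coil)
        images: dict[str, np.ndarray] = {}
        coil_images: dict[str, np.ndarray] = {}
        for j, seq in enumerate(SEQUENCES):
            img = render_contrast(tmap, model, seq, seed=s_img + j)
            images[seq] = img
            coil_images[seq] = simulate_coils(img, profile)
        cases.append(
            PhantomCase(
                case_id=case_id,
                cohort=cohort,
                tissue_map=tmap,
                images=images,
                coil_images=coil_images,
                coil_profile=profile,
                seed=s_geo,
                roi_set=auto_rois(tmap, erode=1),
            )
        )
    return cases


def split_cohort(
    n_healthy: int,
    n_patients: int,
    n_test_healthy: int,
    n_test_patients: int,
    train_fraction: float,
    seed: int,
) -> tuple[list[str], list[str], list[str]]:
    """Stratified test/train/validation partition of subject identifiers.

    Within each stratum the test subjects are drawn first uniformly at
    random; the remainder is split with a floor rule,
    ``n_train = floor(train_fraction * n_remaining)``, the rest going to
    validation.  The floor rule is what reproduces an 80% split of
    (55 healthy, 167 patients) as exactly 44+133 training and 11+34
    validation subjects.
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    if n_test_healthy > n_healthy or n_test_patients > n_patients:
        raise ValueError("cannot draw more test subjects than a stratum contains")
    if min(n_healthy, n_patients, n_test_healthy, n_test_patients) < 0:
        raise ValueError("counts must be nonnegative")

    rng = np.random.default_rng(seed)
    train: list[str] = []
    val: list[str] = []
    test: list[str] = []
    for prefix, n, n_test in (
        ("H", n_healthy, n_test_healthy),
        ("P", n_patients, n_test_patients),
    ):
        ids = [f"{prefix}{i:03d}" for i in range(n)]
        perm = rng.permutation(n)
        test_idx = set(perm[:n_test].tolist())
        remaining = [ids[i] for i in perm[n_test:]]
        n_train = int(np.floor(train_fraction * len(remaining)))
        train.extend(sorted(remaining[:n_train]))
        val.extend(sorted(remaining[n_train:]))
        test.extend(sorted(ids[i] for i in test_idx))
    return train, val, test
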