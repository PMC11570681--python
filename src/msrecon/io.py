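"""On-disk artifacts: NIfTI images, HDF5 k-space containers, YAML configs.

Complex images are written as paired real/imaginary NIfTI volumes with a
JSON sidecar carrying the label legend, cohort and seed.  K-space goes
into an HDF5 container with the sampling mask and mandatory convention
metadata, so a container is self-describing.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import nibabel as nib
import numpy as np
import yaml

from .errors import ConfigurationError
from .kspace import CONVENTION, CartesianMask
from .phantom import LABEL_NAMES, PhantomCase, SEQUENCES

__all__ = [
    "save_case_nifti",
    "load_image_nifti",
    "write_kspace_container",
    "read_kspace_container",
    "save_mask_text",
    "load_mask_text",
    "load_run_config",
    "dump_run_config",
]


def _nifti(data: np.ndarray) -> nib.Nifti1Image:
    # trailing axes ordered (x, y) for nibabel; identity affine (phantom space)
    return nib.Nifti1Image(np.asarray(data, dtype=np.float64).T, np.eye(4))


def save_case_nifti(case: PhantomCase, outdir: str | Path) -> list[Path]:
    """One real+imag NIfTI pair per sequence, labels volume, JSON sidecar."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for seq in SEQUENCES:
        img = case.images[seq]
        path = outdir / f"{case.case_id}_{seq}.nii"
        pair = np.stack([img.real, img.imag], axis=-1)  # H x W x 2
        nib.save(nib.Nifti1Image(pair.transpose(1, 0, 2), np.eye(4)), path)
        written.append(path)
    labels_path = outdir / f"{case.case_id}_labels.nii"
    nib.save(_nifti(case.tissue_map.labels), labels_path)
    written.append(labels_path)
    sidecar = outdir / f"{case.case_id}.json"
    sidecar.write_text(
        json.dumps(
            {
                "case_id": case.case_id,
                "cohort": case.cohort,
                "seed": case.seed,
                "labels": {str(k): v for k, v in LABEL_NAMES.items()},
                "sequences": list(SEQUENCES),
                "complex_layout": "last axis = (real, imag)",
            },
            indent=2,
        )
    )
    written.append(sidecar)
    return written


def load_image_nifti(path: str | Path) -> np.ndarray:
    """Load a real+imag pair (or plain magnitude) NIfTI back to a complex array."""
    data = np.asarray(nib.load(str(path)).dataobj)
    if data.ndim == 3 and data.shape[-1] == 2:
        data = data[..., 0] + 1j * data[..., 1]
        return data.T
    return data.T.astype(np.complex128)


def write_kspace_container(
    path: str | Path,
    kspace: np.ndarray,
    mask: CartesianMask,
    meta: dict,
) -> None:
    """HDF5 container: /kspace (complex), /mask (0/1), /meta attributes."""
    meta = dict(meta)
    meta.setdefault("convention", CONVENTION)
    meta.setdefault("target_r", mask.target_r)
    meta.setdefault("seed", mask.seed)
    meta.setdefault("n_acs", mask.n_acs)
    with h5py.File(path, "w") as f:
        f.create_dataset("kspace", data=np.asarray(kspace, dtype=np.complex128))
        f.create_dataset("mask", data=mask.sampled.astype(np.uint8))
        g = f.create_group("meta")
        for k, v in meta.items():
            g.attrs[k] = v


def read_kspace_container(path: str | Path) -> tuple[np.ndarray, CartesianMask, dict]:
    with h5py.File(path, "r") as f:
        kspace = f["kspace"][...]
        sampled = f["mask"][...].astype(bool)
        meta = dict(f["meta"].attrs)
    if "convention" not in meta:
        raise ConfigurationError(f"{path}: container lacks the mandatory convention flag")
    mask = CartesianMask(
        sampled=sampled,
        n_acs=int(meta.get("n_acs", 0)),
        target_r=float(meta.get("target_r", 1.0)),
        seed=int(meta.get("seed", 0)),
    )
    return kspace, mask, meta


def save_mask_text(path: str | Path, mask: CartesianMask) -> None:
    """Plain-text serialization: one 0/1 per line, header with metadata."""
    lines = [f"# target_r={mask.target_r} n_acs={mask.n_acs} seed={mask.seed}"]
    lines += [str(int(v)) for v in mask.sampled]
    Path(path).write_text("\n".join(lines) + "\n")


def load_mask_text(path: str | Path) -> CartesianMask:
    text = Path(path).read_text().strip().splitlines()
    header = text[0]
    kv = dict(item.split("=") for item in header.lstrip("# ").split())
    sampled = np.array([bool(int(v)) for v in text[1:]])
    return CartesianMask(
        sampled=sampled,
        n_acs=int(kv["n_acs"]),
        target_r=float(kv["target_r"]),
        seed=int(kv["seed"]),
    )


def load_run_config(path: str | Path | None, overrides: dict | None = None) -> dict:
    """Merge a YAML config file with CLI overrides (overrides win)."""
    config: dict = {}
    if path is not None:
        loaded = yaml.safe_load(Path(path).read_text())
        if loaded is not None:
            if not isinstance(loaded, dict):
                raise ConfigurationError(f"{path}: top-level YAML must be a mapping")
            config.update(loaded)
    for k, v in (overrides or {}).items():
        if v is not None:
            config[k] = v
    return config


def dump_run_config(config: dict, outdir: str | Path) -> Path:
    """Write the effective configuration back next to the run's outputs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    path = outdir / "run_config.yaml"
    path.write_text(yaml.safe_dump(config, sort_keys=True))
    return path
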