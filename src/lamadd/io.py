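"""File I/O: NIfTI volumes, design tables, config files, manifests."""

from __future__ import annotations

import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "save_nifti",
    "load_nifti",
    "read_config",
    "write_config",
    "write_manifest",
]

_AFFINE = np.diag([0.8, 0.8, 0.8, 1.0])  # nominal sub-millimeter voxels


def save_nifti(data: np.ndarray, path, dtype=np.float32) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), _AFFINE)
    nib.save(img, str(path))


def load_nifti(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).dataobj, dtype=np.float64)


def read_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a flat mapping")
    return cfg


def write_config(cfg: dict, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)


def write_manifest(out_dir, files: list[str]) -> Path:
    """Write a manifest of sha256 checksums for the named output files."""
    out_dir = Path(out_dir)
    manifest = out_dir / "manifest.txt"
    with open(manifest, "w") as fh:
        for name in sorted(files):
            digest = hashlib.sha256((out_dir / name).read_bytes()).hexdigest()
            fh.write(f"{name}\t{digest}\n")
    return manifest
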