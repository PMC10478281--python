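"""Reading and writing images, fields, and provenance records.

2-D slices travel as single-slice NIfTI (via nibabel) or flat ``.npy``
arrays; deformation fields as 2-channel ``.npy``.  Every CLI run drops a
JSON provenance record (config snapshot, seed, package version) beside its
outputs so any artifact can be regenerated from the record alone.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np

from . import __version__
from .errors import ConfigurationError
from .preprocess import HUImage

__all__ = ["read_image", "write_image", "read_field", "write_field",
           "write_provenance"]

_NIFTI_SUFFIXES = (".nii", ".nii.gz")


def _is_nifti(path: Path) -> bool:
    name = path.name.lower()
    return name.endswith(".nii") or name.endswith(".nii.gz")


def read_image(path) -> HUImage:
    """Load a 2-D HU image from NIfTI (.nii/.nii.gz) or .npy."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such image file: {path}")
    if _is_nifti(path):
        try:
            img = nib.load(str(path))
        except Exception as exc:
            raise IOError(f"cannot read NIfTI file {path}: {exc}") from exc
        data = np.asanyarray(img.dataobj).squeeze()
        if data.ndim != 2:
            raise IOError(f"{path} does not hold a single 2-D slice (shape {data.shape})")
        zooms = img.header.get_zooms()[:2]
        return HUImage(np.asarray(data, dtype=np.float32), (float(zooms[0]), float(zooms[1])))
    if path.suffix == ".npy":
        try:
            data = np.load(path, allow_pickle=False)
        except ValueError as exc:
            raise IOError(f"corrupt array file {path}: {exc}") from exc
        return HUImage(np.asarray(data, dtype=np.float32))
    raise ConfigurationError(
        f"unsupported image format {path.suffix!r}; supported: .nii, .nii.gz, .npy")


def write_image(image: HUImage, path) -> None:
    """Write a 2-D HU image as single-slice NIfTI or .npy."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if _is_nifti(path):
        affine = np.diag([image.spacing[0], image.spacing[1], 1.0, 1.0])
        vol = image.values[:, :, None].astype(np.float32)
        nib.save(nib.Nifti1Image(vol, affine), str(path))
        return
    if path.suffix == ".npy":
        np.save(path, image.values.astype(np.float32))
        return
    raise ConfigurationError(
        f"unsupported image format {path.suffix!r}; supported: .nii, .nii.gz, .npy")


def read_field(path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such field file: {path}")
    f = np.load(path, allow_pickle=False)
    if f.ndim != 3 or f.shape[0] != 2:
        raise IOError(f"{path} does not hold a (2, H, W) displacement field")
    return f.astype(np.float32)


def write_field(field: np.ndarray, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.save(path, np.asarray(field, dtype=np.float32))


def write_provenance(out_dir, record: dict) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    record = dict(record)
    record["package_version"] = __version__
    path = out_dir / "provenance.json"
    path.write_text(json.dumps(record, indent=2, sort_keys=True, default=str))
    return path
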