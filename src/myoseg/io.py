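"""Readers/writers for slice datasets (NIfTI volumes and PNG pairs).

Conventions: in-plane arrays are row-major (row 0 anterior), slices stack on
the third NIfTI axis, label volumes are integer-typed.  PNG pairs live in a
directory as ``slice_###.png`` / ``slice_###_labels.png`` (16-bit labels)
with a JSON sidecar carrying district, severity and seed metadata.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
from PIL import Image

from .phantom import AnnotatedSlice

__all__ = ["write_slices_nifti", "read_slices_nifti", "write_slices_png",
           "read_slices_png", "read_slices", "write_labels"]

_EYE4 = np.eye(4)


def write_slices_nifti(path, slices: list[AnnotatedSlice]) -> None:
    """Write a dataset as <path>.nii.gz + <path>_labels.nii.gz + sidecar JSON."""
    path = Path(path)
    image = np.stack([s.image for s in slices], axis=2)
    labels = np.stack([s.labels for s in slices], axis=2).astype(np.int16)
    nib.save(nib.Nifti1Image(image.astype(np.float32), _EYE4), str(path) + ".nii.gz")
    nib.save(nib.Nifti1Image(labels, _EYE4), str(path) + "_labels.nii.gz")
    meta = [
        {"district": s.district, "severity": s.severity, "provenance": s.provenance}
        for s in slices
    ]
    Path(str(path) + ".json").write_text(json.dumps(meta, indent=1, default=str))


def read_slices_nifti(path, require_labels: bool = True) -> list[AnnotatedSlice]:
    path = Path(path)
    img = np.asarray(nib.load(str(path) + ".nii.gz").dataobj, dtype=float)
    lab_path = Path(str(path) + "_labels.nii.gz")
    if not lab_path.exists():
        if require_labels:
            raise FileNotFoundError(f"label volume {lab_path} missing")
        labels = np.zeros(img.shape, dtype=np.int16)
    else:
        labels = np.asarray(nib.load(str(lab_path)).dataobj).astype(np.int16)
    if labels.shape != img.shape:
        raise ValueError(f"image {img.shape} vs labels {labels.shape} dimension mismatch")
    meta_path = Path(str(path) + ".json")
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    out = []
    for k in range(img.shape[2]):
        m = meta[k] if meta else {"district": "thigh", "severity": 0.0, "provenance": {}}
        out.append(
            AnnotatedSlice(
                image=img[:, :, k], labels=labels[:, :, k],
                district=m["district"], severity=m["severity"],
                provenance=m.get("provenance", {}),
            )
        )
    return out


def write_slices_png(directory, slices: list[AnnotatedSlice]) -> None:
    """Write per-slice PNG pairs (image scaled to 16-bit, labels verbatim)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = []
    for i, s in enumerate(slices):
        img16 = np.clip(np.round(s.image * 65535), 0, 65535).astype(np.uint16)
        Image.fromarray(img16).save(directory / f"slice_{i:03d}.png")
        Image.fromarray(s.labels.astype(np.uint16)).save(
            directory / f"slice_{i:03d}_labels.png"
        )
        meta.append({"district": s.district, "severity": s.severity,
                     "provenance": s.provenance})
    (directory / "dataset.json").write_text(json.dumps(meta, indent=1, default=str))


def read_slices_png(directory, require_labels: bool = True) -> list[AnnotatedSlice]:
    directory = Path(directory)
    meta_path = directory / "dataset.json"
    meta = json.loads(meta_path.read_text()) if meta_path.exists() else None
    out = []
    img_paths = [p for p in sorted(directory.glob("slice_[0-9]*.png"))
                 if not p.stem.endswith("_labels")]
    for i, img_path in enumerate(img_paths):
        lab_path = directory / f"{img_path.stem}_labels.png"
        image = np.asarray(Image.open(img_path), dtype=float) / 65535.0
        if not lab_path.exists():
            if require_labels:
                raise FileNotFoundError(f"label image {lab_path} missing")
            labels = np.zeros(image.shape, dtype=np.int16)
        else:
            labels = np.asarray(Image.open(lab_path)).astype(np.int16)
        m = meta[i] if meta else {"district": "thigh", "severity": 0.0, "provenance": {}}
        out.append(AnnotatedSlice(image=image, labels=labels, district=m["district"],
                                  severity=m["severity"],
                                  provenance=m.get("provenance", {})))
    return out


def read_slices(path, require_labels: bool = True) -> list[AnnotatedSlice]:
    """Dispatch on layout: a directory reads PNG pairs, otherwise NIfTI."""
    if Path(path).is_dir():
        return read_slices_png(path, require_labels)
    return read_slices_nifti(path, require_labels)


def write_labels(path, volume: np.ndarray) -> None:
    """Write an integer label volume as NIfTI."""
    nib.save(nib.Nifti1Image(np.asarray(volume).astype(np.int16), _EYE4), str(path))
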