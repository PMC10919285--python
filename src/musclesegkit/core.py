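"""Core image containers for the segmentation pipeline.

Volumes are 3D scalar images with isotropic-or-not voxel spacing in mm;
label maps are integer volumes on the same grid, 0 = background and
1..C = muscle compartments.  Both are thin wrappers around numpy arrays
plus geometry, with NIfTI (.nii/.nii.gz) round-tripping via nibabel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import nibabel as nib
import numpy as np

__all__ = ["Volume", "LabelMap", "Subject", "load_cohort", "save_cohort"]


def _as_spacing(spacing: float | Sequence[float]) -> tuple[float, float, float]:
    if np.isscalar(spacing):
        s = float(spacing)  # type: ignore[arg-type]
        return (s, s, s)
    sp = tuple(float(v) for v in spacing)  # type: ignore[union-attr]
    if len(sp) != 3:
        raise ValueError(f"spacing must be scalar or length-3, got {sp}")
    return sp  # type: ignore[return-value]


@dataclass
class Volume:
    """3D scalar image with voxel spacing (mm) and world origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"Volume expects a 3D array, got ndim={self.data.ndim}")
        self.spacing = _as_spacing(self.spacing)
        self.origin = tuple(float(v) for v in self.origin)  # type: ignore[assignment]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    def same_grid(self, other: "Volume | LabelMap") -> bool:
        return (
            self.shape == other.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return cls(np.asarray(img.dataobj, dtype=np.float64), spacing, origin)


@dataclass
class LabelMap(Volume):
    """3D integer label image; 0 is background, 1..C are compartments."""

    def __post_init__(self) -> None:
        super().__post_init__()
        if not np.issubdtype(self.data.dtype, np.integer):
            rounded = np.rint(self.data)
            if not np.allclose(self.data, rounded):
                raise ValueError("LabelMap requires integer voxel values")
            self.data = rounded
        self.data = self.data.astype(np.int32)

    def labels(self) -> np.ndarray:
        """Sorted nonzero label values present in the map."""
        vals = np.unique(self.data)
        return vals[vals != 0]

    def mask(self, label_id: int) -> np.ndarray:
        return self.data == int(label_id)

    def volume_mm3(self, label_id: int) -> float:
        return float(np.count_nonzero(self.mask(label_id))) * self.voxel_volume_mm3()

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.int16), affine)

    @classmethod
    def load(cls, path: str | Path) -> "LabelMap":
        img = nib.load(str(path))
        affine = img.affine
        spacing = tuple(np.abs(np.diag(affine)[:3]))
        origin = tuple(affine[:3, 3])
        return cls(np.asarray(img.dataobj).astype(np.int32), spacing, origin)


@dataclass
class Subject:
    """A matched (MR volume, label map) pair.

    ``provenance`` is ``"original"`` for generated/acquired subjects and
    ``"augmented"`` for subjects produced by the augmentation pipeline, in
    which case ``provenance_info`` records the reference id, the shape-space
    coordinate of the target and the registration parameters used.
    """

    id: str
    volume: Volume
    labels: LabelMap
    provenance: str = "original"
    provenance_info: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.provenance not in ("original", "augmented"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not self.volume.same_grid(self.labels):
            raise ValueError(
                f"subject {self.id!r}: volume and labels must share grid "
                f"(shapes {self.volume.shape} vs {self.labels.shape})"
            )

    @property
    def is_augmented(self) -> bool:
        return self.provenance == "augmented"

    def save(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.volume.save(out / f"{self.id}_img.nii.gz")
        self.labels.save(out / f"{self.id}_lab.nii.gz")


def save_cohort(subjects: Iterable[Subject], out_dir: str | Path) -> Path:
    """Write NIfTI pairs plus a JSON manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = []
    for s in subjects:
        s.save(out)
        manifest.append(
            {
                "id": s.id,
                "image": f"{s.id}_img.nii.gz",
                "labels": f"{s.id}_lab.nii.gz",
                "provenance": s.provenance,
                "provenance_info": _jsonable(s.provenance_info),
            }
        )
    path = out / "manifest.json"
    path.write_text(json.dumps(manifest, indent=2))
    return path


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def load_cohort(in_dir: str | Path) -> list[Subject]:
    """Load a cohort previously written by :func:`save_cohort`."""
    root = Path(in_dir)
    manifest = json.loads((root / "manifest.json").read_text())
    subjects = []
    for entry in manifest:
        subjects.append(
            Subject(
                id=entry["id"],
                volume=Volume.load(root / entry["image"]),
                labels=LabelMap.load(root / entry["labels"]),
                provenance=entry.get("provenance", "original"),
                provenance_info=entry.get("provenance_info", {}),
            )
        )
    return subjects
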