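"""Lightweight volume containers and NIfTI-1 I/O.

All volumetric data in this package live on a single MNI-like grid:
RAS+ axis-aligned affine, isotropic voxels (3 mm by default), origin at
the grid centre (a stand-in for the anterior commissure). Files are
written as float32 ``.nii.gz`` through :mod:`nibabel`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

DEFAULT_VOXEL_MM = 3.0
DEFAULT_SHAPE = (40, 48, 40)

__all__ = [
    "BoldRun",
    "ContrastMap",
    "MaskVolume",
    "GroupSample",
    "mni_like_affine",
    "voxel_volume_mm3",
    "affines_close",
    "save_volume",
    "load_volume",
    "load_mask",
]


def mni_like_affine(shape=DEFAULT_SHAPE, voxel_mm: float = DEFAULT_VOXEL_MM) -> np.ndarray:
    """RAS+ affine with isotropic voxels and the origin at the grid centre."""
    shape = tuple(int(s) for s in shape)
    affine = np.diag([voxel_mm, voxel_mm, voxel_mm, 1.0])
    affine[:3, 3] = -voxel_mm * (np.asarray(shape, dtype=float) - 1) / 2.0
    return affine


def voxel_volume_mm3(affine: np.ndarray) -> float:
    """Volume of one voxel, |det| of the 3x3 voxel->mm block."""
    return float(abs(np.linalg.det(np.asarray(affine)[:3, :3])))


def affines_close(a: np.ndarray, b: np.ndarray, atol: float = 1e-4) -> bool:
    return np.allclose(np.asarray(a), np.asarray(b), atol=atol)


def _check_affine_match(a: np.ndarray, b: np.ndarray, what: str) -> None:
    if not affines_close(a, b):
        raise ValueError(
            f"affine mismatch between {what}; resample one image onto the "
            "other's grid before combining them"
        )


@dataclass
class BoldRun:
    """A 4D BOLD time series: ``data[x, y, z, t]``, TR in seconds."""

    data: np.ndarray
    affine: np.ndarray
    tr: float = 2.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValueError("BoldRun.data must be 4D (x, y, z, t)")
        if self.tr <= 0:
            raise ValueError("tr must be positive")

    @property
    def n_scans(self) -> int:
        return self.data.shape[-1]

    @property
    def shape(self):
        return self.data.shape[:3]


@dataclass
class ContrastMap:
    """One subject's 3D contrast-estimate volume (contrast units)."""

    data: np.ndarray
    affine: np.ndarray
    contrast_name: str = ""
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ContrastMap.data must be 3D")


@dataclass
class MaskVolume:
    """A binary analysis mask on the same grid as the maps it is applied to.

    Analysis entry points require a non-empty mask; set operations (mask
    overlap) may legitimately produce an empty one.
    """

    data: np.ndarray
    affine: np.ndarray

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data) > 0
        if self.data.ndim != 3:
            raise ValueError("MaskVolume.data must be 3D")

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())


@dataclass
class GroupSample:
    """Per-subject contrast maps of one group, with a shared analysis mask."""

    maps: list[ContrastMap] = field(default_factory=list)
    mask: MaskVolume | None = None
    group_label: str = ""

    def __post_init__(self) -> None:
        if len(self.maps) < 2:
            raise ValueError("a GroupSample needs at least 2 subjects")
        ref = self.maps[0]
        for m in self.maps[1:]:
            if m.data.shape != ref.data.shape:
                raise ValueError("all maps in a GroupSample must share a grid")
            _check_affine_match(m.affine, ref.affine, "maps in a GroupSample")
        if self.mask is not None:
            if self.mask.data.shape != ref.data.shape:
                raise ValueError("mask grid differs from the maps' grid")
            _check_affine_match(self.mask.affine, ref.affine, "mask and maps")

    @property
    def n_subjects(self) -> int:
        return len(self.maps)

    @property
    def affine(self) -> np.ndarray:
        return self.maps[0].affine

    def stack(self) -> np.ndarray:
        """Subjects-first 4D array ``(n, x, y, z)``."""
        return np.stack([m.data for m in self.maps], axis=0)


def save_volume(data: np.ndarray, affine: np.ndarray, path: str | Path) -> Path:
    """Write a 3D/4D array as float32 NIfTI-1 (boolean arrays as uint8)."""
    arr = np.asarray(data)
    dtype = np.uint8 if arr.dtype == bool else np.float32
    img = nib.Nifti1Image(arr.astype(dtype), np.asarray(affine, dtype=float))
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(path))
    return path


def load_volume(path: str | Path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def load_mask(path: str | Path) -> MaskVolume:
    data, affine = load_volume(path)
    return MaskVolume(data=data > 0, affine=affine)
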