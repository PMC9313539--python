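"""Shared image containers: CT volumes in Hounsfield units and label masks.

Axis convention: arrays are indexed (x, y, z) with z the superior-inferior
axis unless declared otherwise; spacing is millimetres per voxel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["CTVolume", "SegmentationMask"]

HU_MIN = -1024.0
HU_MAX = 3071.0


@dataclass
class CTVolume:
    """A 3D CT image in Hounsfield units.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        HU values; must be finite.
    spacing : tuple of float
        Voxel size along each axis, mm; strictly positive.
    affine : ndarray (4, 4), optional
        Voxel-to-world transform. Defaults to a diagonal scaling by
        ``spacing`` (axis-aligned volume at the origin).
    si_axis : int
        Array axis running superior-inferior (the loading axis for
        compression analyses). Default 2.
    """

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray | None = None
    si_axis: int = 2

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be 3D")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("CTVolume.data must be finite")
        self.spacing = tuple(float(s) for s in self.spacing)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError("spacing must be 3 strictly positive values")
        if self.si_axis not in (0, 1, 2):
            raise ValueError("si_axis must be 0, 1 or 2")
        if self.affine is None:
            self.affine = np.diag([*self.spacing, 1.0])
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_nifti(self, path: str) -> None:
        nib.save(nib.Nifti1Image(self.data.astype(np.float32), self.affine), path)

    @classmethod
    def from_nifti(cls, path: str, si_axis: int = 2) -> "CTVolume":
        img = nib.load(path)
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asanyarray(img.dataobj), spacing, img.affine, si_axis)


@dataclass
class SegmentationMask:
    """Integer label volume co-registered with a :class:`CTVolume`.

    Label 0 is background; each nonzero label is one vertebra, named in
    ``level_map`` (e.g. ``{1: "L1"}``).
    """

    labels: np.ndarray
    level_map: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError("SegmentationMask.labels must be 3D")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("SegmentationMask.labels must be integer")

    def check_compatible(self, ct: CTVolume) -> None:
        if self.labels.shape != ct.data.shape:
            raise ValueError(
                f"mask shape {self.labels.shape} != volume shape {ct.data.shape}"
            )

    def level_label(self, level: str) -> int:
        for lab, name in self.level_map.items():
            if name == level:
                return lab
        raise KeyError(f"level {level!r} not present in mask")

    def binary(self, label: int | None = None) -> np.ndarray:
        if label is None:
            return self.labels > 0
        return self.labels == label

    def to_nifti(self, path: str, affine: np.ndarray | None = None) -> None:
        aff = np.eye(4) if affine is None else affine
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), aff), path)

    @classmethod
    def from_nifti(cls, path: str, level_map: dict[int, str] | None = None) -> "SegmentationMask":
        img = nib.load(path)
        labels = np.asanyarray(img.dataobj).astype(np.int32)
        return cls(labels, level_map or {})
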