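"""Voxel grids: the shared 3-D scalar-field container and its NIfTI I/O.

A :class:`VoxelGrid` holds one scalar quantity on an isotropic grid —
counts, activity (MBq per voxel), cumulated activity (MBq·h per voxel) or
absorbed dose (Gy) — together with the voxel edge length in mm.  Array axes
are (x, y, z) with the z axis taken as the scanner (axial) axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["VoxelGrid", "GridSpec"]


@dataclass
class VoxelGrid:
    """A 3-D scalar field on an isotropic voxel grid.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values.  The physical meaning (counts, MBq, MBq·h, Gy) is
        carried by ``unit``.
    voxel_size_mm : float
        Isotropic voxel edge length in millimetres.
    unit : str
        Free-text unit label, stored in the NIfTI description field.
    """

    data: np.ndarray
    voxel_size_mm: float
    unit: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"VoxelGrid data must be 3-D, got ndim={self.data.ndim}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_ml(self) -> float:
        """Volume of one voxel in ml (1 ml = 1 cm³)."""
        return (self.voxel_size_mm / 10.0) ** 3

    def total(self) -> float:
        return float(self.data.sum())

    def copy_with(self, data: np.ndarray) -> "VoxelGrid":
        return VoxelGrid(data, self.voxel_size_mm, self.unit)

    # ---- NIfTI round trip -------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_size_mm, self.voxel_size_mm, self.voxel_size_mm, 1.0])
        img = nib.Nifti1Image(self.data.astype(np.float64), affine)
        img.header.set_zooms((self.voxel_size_mm,) * 3)
        if self.unit:
            img.header["descrip"] = self.unit.encode()[:79]
        return img

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path) -> "VoxelGrid":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0], rtol=1e-3):
            raise ValueError(f"anisotropic voxels not supported: {zooms}")
        unit = bytes(img.header["descrip"]).split(b"\x00")[0].decode(errors="replace")
        return cls(np.asarray(img.dataobj, dtype=float), float(zooms[0]), unit)


@dataclass
class GridSpec:
    """Requested geometry for synthetic images.

    ``shape=None`` lets generators size the grid automatically so each
    object fits with ``margin_mm`` of padding on every side.
    """

    voxel_size_mm: float = 4.67
    shape: tuple[int, int, int] | None = None
    margin_mm: float = 36.0  # 3 x default PSF FWHM

    def __post_init__(self) -> None:
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be > 0")
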