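"""Minimal 3D scalar volume container with NIfTI-1 round-trip.

All volumes in this package live on an isotropic grid in "template space":
physical coordinates are ``voxel_index * voxel_size`` along the array axes
(i, j, k), so the NIfTI affine is diagonal. Label fields reuse the same
container with an integer dtype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np


@dataclass
class Volume:
    """A 3D scalar field on an isotropic grid.

    Parameters
    ----------
    data:
        3D array of voxel values.
    voxel_size:
        Isotropic voxel edge length in mm.
    """

    data: np.ndarray
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.data.ndim}")
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-to-physical affine (diagonal, mm units)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.voxel_size
        return aff

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.voxel_size)

    def save(self, path: str | Path) -> None:
        img = nib.Nifti1Image(np.asarray(self.data), self.affine)
        img.header.set_zooms((self.voxel_size,) * 3)
        nib.save(img, str(path))

    @classmethod
    def load(cls, path: str | Path) -> "Volume":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise ValueError(f"anisotropic voxels not supported: {zooms}")
        return cls(np.asanyarray(img.dataobj), float(zooms[0]))


def save_transform(path: str | Path, matrix: np.ndarray) -> None:
    """Write a 4x4 homogeneous transform as a plain-text sidecar."""
    matrix = np.asarray(matrix, dtype=float)
    if matrix.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    np.savetxt(str(path), matrix, fmt="%.10g")


def load_transform(path: str | Path) -> np.ndarray:
    matrix = np.loadtxt(str(path))
    if matrix.shape != (4, 4):
        raise ValueError("transform must be 4x4")
    return matrix
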