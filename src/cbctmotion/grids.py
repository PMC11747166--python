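"""Volume and displacement-field containers.

World frame convention used throughout the package:

* axes: x = lateral (left-right), y = anterior-posterior, z = superior-
  inferior; units mm.
* the scanner isocenter sits at the volume center; the gantry rotates in
  the axial x-y plane about the z axis.
* voxel indexing is 0-based and node-centered:
  ``world = origin + index * spacing``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class VolumeGrid:
    """A 3-D scalar field (linear attenuation, mm^-1) on a regular grid."""

    values: np.ndarray            # (nx, ny, nz)
    spacing: np.ndarray           # mm per axis
    origin: np.ndarray            # world position of voxel (0,0,0), mm

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError("VolumeGrid requires a 3-D array")

    @classmethod
    def centered(cls, shape, spacing) -> "VolumeGrid":
        """Empty volume whose center coincides with the isocenter."""
        shape = tuple(int(s) for s in shape)
        spacing = np.asarray(spacing, dtype=np.float64)
        origin = -(np.asarray(shape) - 1) * spacing / 2.0
        return cls(np.zeros(shape), spacing, origin)

    @property
    def shape(self):
        return self.values.shape

    @property
    def extent_mm(self) -> np.ndarray:
        return (np.asarray(self.shape) - 1) * self.spacing

    def voxel_centers(self) -> np.ndarray:
        """World coordinates of all voxel centers, shape (N, 3)."""
        ax = [self.origin[i] + self.spacing[i] * np.arange(self.shape[i])
              for i in range(3)]
        gx, gy, gz = np.meshgrid(*ax, indexing="ij")
        return np.stack([gx, gy, gz], axis=-1).reshape(-1, 3)

    def world_to_voxel(self, pts: np.ndarray) -> np.ndarray:
        return (np.asarray(pts) - self.origin) / self.spacing

    def like(self, values: np.ndarray) -> "VolumeGrid":
        return VolumeGrid(values, self.spacing.copy(), self.origin.copy())

    def save_nifti(self, path):
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.values, dtype=np.float32),
                                 affine), str(path))

    @classmethod
    def load_nifti(cls, path) -> "VolumeGrid":
        img = nib.load(str(path))
        aff = img.affine
        return cls(np.asarray(img.dataobj, dtype=np.float64),
                   np.abs(np.diag(aff)[:3]), aff[:3, 3])


@dataclass
class DisplacementField:
    """Dense 3-D displacement vectors (mm) on a volume grid, pull convention:
    the warped image at x samples the reference at ``x + d(x)``."""

    vectors: np.ndarray           # (nx, ny, nz, 3), mm
    spacing: np.ndarray
    origin: np.ndarray

    def __post_init__(self):
        self.vectors = np.asarray(self.vectors, dtype=np.float64)
        self.spacing = np.asarray(self.spacing, dtype=np.float64)
        self.origin = np.asarray(self.origin, dtype=np.float64)
        if self.vectors.ndim != 4 or self.vectors.shape[-1] != 3:
            raise ValueError("DisplacementField requires (nx,ny,nz,3)")

    @property
    def shape(self):
        return self.vectors.shape[:3]

    def magnitude(self) -> np.ndarray:
        return np.linalg.norm(self.vectors, axis=-1)

    def save_nifti(self, path):
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(np.asarray(self.vectors, dtype=np.float32),
                                 affine), str(path))
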