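"""CT volume container with world-coordinate bookkeeping.

The volume is stored as a float32 array indexed ``[ix, iy, iz]`` so that axis 0
is the patient x direction (positive right), axis 1 is y (positive anterior)
and axis 2 is z (positive superior).  World position of a voxel centre is
``origin + index * spacing`` (mm).  NIfTI I/O goes through nibabel with a
diagonal affine carrying the spacing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np


@dataclass
class CTVolume:
    """3D Hounsfield-unit grid with voxel spacing and origin (mm)."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float32)
        if self.data.ndim != 3:
            raise ValueError("CTVolume.data must be a 3D array")
        if any(s <= 0 for s in self.spacing):
            raise ValueError("voxel_spacing: all spacings must be > 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous index coordinates of world-space points (mm)."""
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        return (pts - np.asarray(self.origin)) / np.asarray(self.spacing)

    def index_to_world(self, idx: np.ndarray) -> np.ndarray:
        idx = np.atleast_2d(np.asarray(idx, dtype=float))
        return np.asarray(self.origin) + idx * np.asarray(self.spacing)

    def contains_world(self, points: np.ndarray) -> np.ndarray:
        """Boolean mask of points lying inside the voxel grid."""
        idx = self.world_to_index(points)
        upper = np.asarray(self.shape) - 1
        return np.all((idx >= 0) & (idx <= upper), axis=1)

    # ---- I/O -------------------------------------------------------------

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.spacing) + [1.0])
        affine[:3, 3] = self.origin
        return nib.Nifti1Image(self.data, affine)

    def save(self, path: str) -> None:
        nib.save(self.to_nifti(), path)

    @classmethod
    def load(cls, path: str) -> "CTVolume":
        img = nib.load(path)
        affine = img.affine
        spacing = tuple(float(s) for s in np.abs(np.diag(affine)[:3]))
        origin = tuple(float(o) for o in affine[:3, 3])
        return cls(np.asanyarray(img.dataobj), spacing, origin)
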