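"""Isotropic voxel volumes emulating CT reconstructions.

A :class:`VoxelVolume` stores an intensity grid with isotropic spacing and a
world-space origin (the position of voxel centre ``(0, 0, 0)`` in mm).  The
grid is axis-aligned with the phantom/world frame; trilinear sampling is the
bridge between image space and surface-based measurement.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import nibabel as nib
from scipy.ndimage import map_coordinates

__all__ = ["VoxelVolume", "OutOfBoundsError"]


class OutOfBoundsError(ValueError):
    """A sample point fell outside the voxel grid."""


@dataclass
class VoxelVolume:
    intensities: np.ndarray  # (nx, ny, nz) float
    spacing: float  # isotropic, mm
    origin: np.ndarray  # (3,) mm, world position of voxel (0,0,0) centre

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.intensities.ndim != 3:
            raise ValueError("intensities must be a 3-D array")
        self.spacing = float(self.spacing)
        if self.spacing <= 0:
            raise ValueError("spacing must be > 0")
        self.origin = np.asarray(self.origin, dtype=float).reshape(3)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape  # type: ignore[return-value]

    def world_to_index(self, points: np.ndarray) -> np.ndarray:
        """Continuous voxel indices of world-space points (mm)."""
        return (np.atleast_2d(points) - self.origin) / self.spacing

    def contains(self, points: np.ndarray) -> np.ndarray:
        idx = self.world_to_index(points)
        hi = np.array(self.shape) - 1
        return np.all((idx >= 0) & (idx <= hi), axis=1)

    def sample(self, points: np.ndarray) -> np.ndarray:
        """Trilinear interpolation at world-space points.

        Raises :class:`OutOfBoundsError` naming the first offending point if
        any sample lies outside the grid.
        """
        points = np.atleast_2d(np.asarray(points, dtype=float))
        inside = self.contains(points)
        if not inside.all():
            bad = points[~inside][0]
            raise OutOfBoundsError(
                f"out of bounds: point ({bad[0]:.3f}, {bad[1]:.3f}, {bad[2]:.3f}) mm "
                "lies outside the volume"
            )
        return map_coordinates(self.intensities, self.world_to_index(points).T, order=1)

    # ------------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([self.spacing] * 3 + [1.0])
        affine[:3, 3] = self.origin
        nib.save(nib.Nifti1Image(self.intensities.astype(np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VoxelVolume":
        img = nib.load(str(path))
        affine = img.affine
        sp = np.abs(np.diag(affine)[:3])
        if not np.allclose(sp, sp[0], rtol=1e-4):
            raise ValueError("only isotropic, axis-aligned volumes are supported")
        return cls(np.asarray(img.get_fdata(), dtype=float), float(sp[0]), affine[:3, 3])

    def to_metaimage(self, path: str | Path) -> None:
        """Write MetaImage (.mhd header + .raw payload)."""
        path = Path(path)
        raw = path.with_suffix(".raw")
        nx, ny, nz = self.shape
        header = "\n".join(
            [
                "ObjectType = Image",
                "NDims = 3",
                "BinaryData = True",
                "BinaryDataByteOrderMSB = False",
                f"DimSize = {nx} {ny} {nz}",
                f"ElementSpacing = {self.spacing} {self.spacing} {self.spacing}",
                f"Offset = {self.origin[0]} {self.origin[1]} {self.origin[2]}",
                "ElementType = MET_FLOAT",
                f"ElementDataFile = {raw.name}",
            ]
        )
        path.with_suffix(".mhd").write_text(header + "\n")
        # MetaImage raw order is x fastest; our array is (x, y, z) C-order -> transpose
        self.intensities.astype(np.float32).transpose(2, 1, 0).tofile(raw)
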