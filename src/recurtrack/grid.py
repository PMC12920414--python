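"""Volume grid: the common coordinate frame for all volumes.

Every mask, atlas and orientation field in the package lives on a
``VolumeGrid`` — an axis-aligned, regularly spaced voxel lattice modeled on a
1 mm isotropic template space (MNI152-like).  World coordinates are in
millimetres; the world coordinate of voxel index ``(i, j, k)`` is
``origin_mm + index * voxel_size_mm`` (the origin is the *center* of voxel
``(0, 0, 0)``).  The mapping is affine and exactly invertible for in-grid
points.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["VolumeGrid"]


@dataclass(frozen=True)
class VolumeGrid:
    """Regular 3-D voxel lattice with a world (mm) coordinate frame.

    Parameters
    ----------
    shape
        Number of voxels per axis; every entry must be >= 1.
    voxel_size_mm
        Voxel edge length per axis in mm; strictly positive.  Default 1 mm
        isotropic, the template-grid convention used throughout.
    origin_mm
        World coordinate of the center of voxel ``(0, 0, 0)``.  The default
        ``None`` centers the grid on the world origin, which puts the
        mid-sagittal plane (world ``x = 0``) midway through the volume.
    """

    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        shape = tuple(int(n) for n in self.shape)
        vox = tuple(float(v) for v in self.voxel_size_mm)
        if any(n < 1 for n in shape):
            raise ValueError(f"all shape entries must be >= 1, got {shape}")
        if any(v <= 0 for v in vox):
            raise ValueError(f"all voxel sizes must be > 0, got {vox}")
        if self.origin_mm is None:
            # center of the grid at world (0,0,0)
            origin = tuple(-(n - 1) / 2.0 * v for n, v in zip(shape, vox))
        else:
            origin = tuple(float(o) for o in self.origin_mm)
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "voxel_size_mm", vox)
        object.__setattr__(self, "origin_mm", origin)

    # -- coordinate transforms -------------------------------------------------

    def index_to_world(self, index: np.ndarray) -> np.ndarray:
        """World coordinates (mm) of voxel center(s) for integer index triples."""
        index = np.asarray(index, dtype=float)
        return np.asarray(self.origin_mm) + index * np.asarray(self.voxel_size_mm)

    def world_to_index(self, world_mm: np.ndarray) -> np.ndarray:
        """Continuous voxel index of world point(s); inverse of index_to_world."""
        world_mm = np.asarray(world_mm, dtype=float)
        return (world_mm - np.asarray(self.origin_mm)) / np.asarray(self.voxel_size_mm)

    def world_to_nearest_index(self, world_mm: np.ndarray) -> np.ndarray:
        """Integer index of the voxel whose center is nearest the world point(s)."""
        return np.rint(self.world_to_index(world_mm)).astype(np.int64)

    def contains_index(self, index: np.ndarray) -> np.ndarray:
        """Boolean: does each integer index triple lie inside the grid."""
        index = np.asarray(index)
        shape = np.asarray(self.shape)
        return np.all((index >= 0) & (index < shape), axis=-1)

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> world-mm affine (for NIfTI I/O)."""
        aff = np.eye(4)
        aff[:3, :3] = np.diag(self.voxel_size_mm)
        aff[:3, 3] = self.origin_mm
        return aff

    @classmethod
    def from_affine(cls, shape, affine: np.ndarray) -> "VolumeGrid":
        """Build a grid from a diagonal (axis-aligned) NIfTI affine."""
        affine = np.asarray(affine, dtype=float)
        off_diag = affine[:3, :3] - np.diag(np.diag(affine[:3, :3]))
        if not np.allclose(off_diag, 0, atol=1e-9):
            raise ValueError("only axis-aligned (diagonal) affines are supported")
        vox = np.diag(affine[:3, :3])
        if np.any(vox <= 0):
            raise ValueError("voxel sizes in the affine must be positive")
        return cls(tuple(int(n) for n in shape[:3]),
                   tuple(vox), tuple(affine[:3, 3]))

    def voxel_center_coords(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Per-axis arrays of world coordinates of voxel centers."""
        return tuple(
            self.origin_mm[a] + np.arange(self.shape[a]) * self.voxel_size_mm[a]
            for a in range(3)
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, VolumeGrid):
            return NotImplemented
        return (
            self.shape == other.shape
            and np.allclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    def __hash__(self) -> int:
        return hash((self.shape, self.voxel_size_mm, self.origin_mm))
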