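"""In-memory volume containers (lesion masks, orientation fields) and NIfTI I/O.

A :class:`LesionMask` is a binarized manual segmentation (VOI) of a
contrast-enhancing lesion on the template grid, tagged with patient id and
timepoint.  An :class:`OrientationField` carries one unit fiber direction and
one anisotropy scalar (FA) per voxel and is the substrate for the internal
streamline tracker — a stand-in for a normative-connectome fiber orientation
dataset.

NIfTI conventions: masks are written as uint8 3-D volumes; orientation fields
as 4-D volumes with 4 components along the last axis — direction x, y, z then
anisotropy — recorded in the header description as ``dirx,diry,dirz,fa``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .errors import EmptyMaskError, GridIncompatibilityError, InvalidDirectionError
from .grid import VolumeGrid

__all__ = ["LesionMask", "OrientationField", "Timepoint"]

#: valid timepoint labels for a lesion mask
Timepoint = ("initial", "recurrent")

ORIENTATION_COMPONENT_ORDER = "dirx,diry,dirz,fa"


@dataclass
class LesionMask:
    """Binary lesion volume on a template grid.

    ``data`` is strictly binary (bool array); ``timepoint`` is one of
    ``"initial"`` / ``"recurrent"``.
    """

    patient_id: str
    timepoint: str
    data: np.ndarray
    grid: VolumeGrid
    allow_empty: bool = False

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise GridIncompatibilityError(
                f"mask shape {data.shape} != grid shape {self.grid.shape}"
            )
        uniq = np.unique(data)
        if not np.all(np.isin(uniq, (0, 1))):
            raise ValueError("lesion mask data must be strictly binary (0/1)")
        self.data = data.astype(bool)
        if self.timepoint not in Timepoint:
            raise ValueError(f"timepoint must be one of {Timepoint}, got {self.timepoint!r}")
        if not self.allow_empty and not self.data.any():
            raise EmptyMaskError(
                f"mask {self.patient_id}/{self.timepoint} has no voxels "
                "(pass allow_empty=True to permit)"
            )

    @property
    def voxel_count(self) -> int:
        return int(self.data.sum())

    def voxel_indices(self) -> np.ndarray:
        """(n, 3) integer indices of lesion voxels."""
        return np.argwhere(self.data)

    def world_coords(self) -> np.ndarray:
        """(n, 3) world coordinates (mm) of lesion voxel centers."""
        return self.grid.index_to_world(self.voxel_indices())

    def to_nifti(self) -> nib.Nifti1Image:
        img = nib.Nifti1Image(self.data.astype(np.uint8), self.grid.affine)
        img.header["descrip"] = f"lesion {self.patient_id} {self.timepoint}".encode()[:79]
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path, patient_id: str, timepoint: str,
             allow_empty: bool = False) -> "LesionMask":
        img = nib.load(str(path))
        grid = VolumeGrid.from_affine(img.shape, img.affine)
        data = np.asarray(img.dataobj) > 0
        return cls(patient_id, timepoint, data, grid, allow_empty=allow_empty)


@dataclass
class OrientationField:
    """Per-voxel unit fiber direction plus anisotropy scalar.

    Directions are sign-ambiguous axes: ``d`` and ``-d`` encode the same
    orientation.  A zero vector means "no orientation" at that voxel.
    Anisotropy lies in [0, 1] (FA convention).
    """

    directions: np.ndarray  # (nx, ny, nz, 3) float
    anisotropy: np.ndarray  # (nx, ny, nz) float in [0, 1]
    grid: VolumeGrid

    def __post_init__(self) -> None:
        directions = np.asarray(self.directions, dtype=np.float32)
        anisotropy = np.asarray(self.anisotropy, dtype=np.float32)
        if directions.shape != self.grid.shape + (3,):
            raise GridIncompatibilityError(
                f"directions shape {directions.shape} != {self.grid.shape + (3,)}"
            )
        if anisotropy.shape != self.grid.shape:
            raise GridIncompatibilityError(
                f"anisotropy shape {anisotropy.shape} != grid shape {self.grid.shape}"
            )
        norms = np.linalg.norm(directions, axis=-1)
        bad = (norms > 1e-6) & (np.abs(norms - 1.0) > 1e-4)
        if bad.any():
            raise InvalidDirectionError(
                f"{int(bad.sum())} voxels carry a non-unit, non-zero direction"
            )
        if anisotropy.min() < 0 or anisotropy.max() > 1:
            raise ValueError("anisotropy values must lie in [0, 1]")
        self.directions = directions
        self.anisotropy = anisotropy

    def to_nifti(self) -> nib.Nifti1Image:
        payload = np.concatenate(
            [self.directions, self.anisotropy[..., None]], axis=-1
        ).astype(np.float32)
        img = nib.Nifti1Image(payload, self.grid.affine)
        img.header["descrip"] = ORIENTATION_COMPONENT_ORDER.encode()
        return img

    def save(self, path: str | Path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path: str | Path) -> "OrientationField":
        img = nib.load(str(path))
        if img.ndim != 4 or img.shape[-1] != 4:
            raise GridIncompatibilityError(
                f"orientation field must be 4-D with 4 components, got shape {img.shape}"
            )
        grid = VolumeGrid.from_affine(img.shape[:3], img.affine)
        payload = np.asarray(img.dataobj, dtype=np.float32)
        return cls(payload[..., :3], payload[..., 3], grid)


def require_same_grid(*objs) -> VolumeGrid:
    """Assert all volume-like objects share one grid; return it."""
    grids = [o.grid for o in objs]
    first = grids[0]
    for g in grids[1:]:
        if g != first:
            raise GridIncompatibilityError("volumes do not share a common grid")
    return first
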