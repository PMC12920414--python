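"""Synthetic cohorts: ellipsoidal lesion pairs and orientation-field phantoms.

The analysis pipeline consumes binary lesion masks (initial / recurrent per
patient) and per-voxel white-matter orientation fields.  Real inputs of this
kind come from manual tumor segmentation and normative diffusion connectomes;
this module fabricates geometrically controlled stand-ins so that every
downstream stage — mapping, tracking, alignment statistics — is testable
end-to-end without external data.

Lesions are ellipsoids by design: all downstream math depends only on voxel
sets, so realistic tumor shapes add nothing.  Voxel membership is by
voxel-center inclusion (matching binarized masks).  Displacements are rounded
to integer multiples of the voxel size and lesion centers snapped to voxel
centers, so the discrete centroid displacement recovers the configured
displacement *exactly* (lattice symmetry about the ellipsoid center).

The default cohort reproduces the study geometry this package targets:
30 patients, of which one shows a *remote* recurrence (recurrent lesion
disconnected beyond the maximum tracking length), crossed with 30 synthetic
orientation fields standing in for normative-connectome subjects.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Sequence

import numpy as np

from .errors import BoundsError, ConfigurationError, DegenerateMaskError, InvalidDirectionError
from .grid import VolumeGrid
from .volumes import LesionMask, OrientationField

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_lesion_pair",
    "generate_orientation_field",
    "generate_remote_pair",
    "generate_cohort",
]

DEFAULT_GRID_SHAPE = (96, 72, 72)


def _ellipsoid_mask(grid: VolumeGrid, center_mm: np.ndarray, radii_mm: np.ndarray) -> np.ndarray:
    """Boolean array of voxels whose centers satisfy the ellipsoid inequality."""
    xs, ys, zs = grid.voxel_center_coords()
    u = (xs - center_mm[0]) / radii_mm[0]
    v = (ys - center_mm[1]) / radii_mm[1]
    w = (zs - center_mm[2]) / radii_mm[2]
    return (u[:, None, None] ** 2 + v[None, :, None] ** 2 + w[None, None, :] ** 2) <= 1.0


def _check_fit(grid: VolumeGrid, center_mm: np.ndarray, radii_mm: np.ndarray, what: str) -> None:
    lo = np.asarray(grid.origin_mm)
    hi = grid.index_to_world(np.asarray(grid.shape) - 1)
    if np.any(center_mm - radii_mm < lo) or np.any(center_mm + radii_mm > hi):
        raise BoundsError(
            f"{what} ellipsoid (center {center_mm.tolist()}, radii {radii_mm.tolist()}) "
            "exceeds grid bounds"
        )


def generate_lesion_pair(
    grid: VolumeGrid,
    center_mm: Sequence[float],
    radii_mm: Sequence[float],
    displacement_mm: Sequence[float],
    growth_factor: float = 1.0,
    patient_id: str = "P00",
) -> tuple[LesionMask, LesionMask]:
    """Generate an (initial, recurrent) ellipsoidal lesion-mask pair.

    The recurrent lesion is the initial ellipsoid translated by
    ``displacement_mm`` with radii scaled by ``growth_factor``.  Both
    ellipsoids must fit inside the grid; masks must be non-empty.
    """
    center = np.asarray(center_mm, dtype=float)
    radii = np.asarray(radii_mm, dtype=float)
    disp = np.asarray(displacement_mm, dtype=float)
    if growth_factor <= 0:
        raise ConfigurationError("growth_factor must be positive")
    if np.any(radii <= 0):
        raise ConfigurationError("radii must be positive")
    center_rec = center + disp
    radii_rec = radii * growth_factor
    _check_fit(grid, center, radii, "initial")
    _check_fit(grid, center_rec, radii_rec, "recurrent")

    data_init = _ellipsoid_mask(grid, center, radii)
    data_rec = _ellipsoid_mask(grid, center_rec, radii_rec)
    for data, label in ((data_init, "initial"), (data_rec, "recurrent")):
        if not data.any():
            raise DegenerateMaskError(
                f"{label} ellipsoid contains no voxel centers (radii below voxel size?)"
            )
    return (
        LesionMask(patient_id, "initial", data_init, grid),
        LesionMask(patient_id, "recurrent", data_rec, grid),
    )


def generate_orientation_field(
    grid: VolumeGrid,
    principal_direction: Sequence[float],
    angular_jitter_deg: float = 0.0,
    fa_value: float = 0.8,
    rng_seed: int | np.random.SeedSequence = 0,
) -> OrientationField:
    """Orientation field with a controlled principal direction and angular jitter.

    Each voxel direction is the principal direction rotated by an angle drawn
    from a folded normal (SD = ``angular_jitter_deg``) about a uniformly random
    axis perpendicular to the principal direction — isotropic dispersion about
    the principal axis.  ``angular_jitter_deg = 0`` yields the principal
    direction at every voxel, exactly.  Anisotropy is ``fa_value`` everywhere.
    """
    p = np.asarray(principal_direction, dtype=float)
    norm = np.linalg.norm(p)
    if norm < 1e-12:
        raise InvalidDirectionError("principal direction must be non-zero")
    if not 0.0 < fa_value <= 1.0:
        raise ConfigurationError("fa_value must lie in (0, 1]")
    if angular_jitter_deg < 0:
        raise ConfigurationError("angular jitter must be non-negative")
    p = p / norm
    n_vox = int(np.prod(grid.shape))

    if angular_jitter_deg == 0.0:
        dirs = np.broadcast_to(p, grid.shape + (3,)).copy()
    else:
        rng = np.random.default_rng(rng_seed)
        theta = np.abs(rng.normal(0.0, np.deg2rad(angular_jitter_deg), size=n_vox))
        phi = rng.uniform(0.0, 2.0 * np.pi, size=n_vox)
        # orthonormal basis of the plane perpendicular to p
        helper = np.array([0.0, 0.0, 1.0]) if abs(p[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
        e1 = np.cross(p, helper)
        e1 /= np.linalg.norm(e1)
        e2 = np.cross(p, e1)
        axis = np.cos(phi)[:, None] * e1 + np.sin(phi)[:, None] * e2
        # rotate p about an axis perpendicular to it: cosθ·p + sinθ·(axis × p)
        dirs = (
            np.cos(theta)[:, None] * p
            + np.sin(theta)[:, None] * np.cross(axis, p)
        ).reshape(grid.shape + (3,))
    fa = np.full(grid.shape, fa_value, dtype=np.float32)
    return OrientationField(dirs, fa, grid)


def generate_remote_pair(
    grid: VolumeGrid,
    gap_mm: float = 40.0,
    radii_mm: Sequence[float] = (6.0, 6.0, 6.0),
    max_length_mm: float = 25.0,
    patient_id: str = "P00",
    axis: int = 0,
) -> tuple[LesionMask, LesionMask]:
    """Lesion pair whose recurrence is disconnected beyond tracking range.

    The two ellipsoids are placed along ``axis`` so that the minimum distance
    between any initial-mask voxel center and any recurrent-mask voxel center
    exceeds ``max_length_mm`` (in fact is at least ``gap_mm`` up to voxel
    discretisation) — guaranteeing zero connecting streamlines by
    construction.
    """
    if gap_mm <= max_length_mm:
        raise ConfigurationError(
            f"gap ({gap_mm} mm) must exceed the maximum tracking length "
            f"({max_length_mm} mm) for the pair to be remote by construction"
        )
    radii = np.asarray(radii_mm, dtype=float)
    # surface-to-surface gap along the separation axis
    half_sep = (gap_mm + 2 * radii[axis]) / 2.0
    center = np.zeros(3)
    offset = np.zeros(3)
    offset[axis] = half_sep
    c_init = center - offset
    c_rec = center + offset
    # snap to voxel centers (ceil the separation so the gap never shrinks)
    vox = np.asarray(grid.voxel_size_mm)
    i_init = np.floor((c_init - np.asarray(grid.origin_mm)) / vox)
    i_rec = np.ceil((c_rec - np.asarray(grid.origin_mm)) / vox)
    c_init = grid.index_to_world(i_init)
    c_rec = grid.index_to_world(i_rec)

    _check_fit(grid, c_init, radii, "initial")
    _check_fit(grid, c_rec, radii, "recurrent")
    initial = LesionMask(patient_id, "initial", _ellipsoid_mask(grid, c_init, radii), grid)
    recurrent = LesionMask(patient_id, "recurrent", _ellipsoid_mask(grid, c_rec, radii), grid)

    d_min = minimum_pair_distance(initial, recurrent)
    if d_min <= max_length_mm:
        raise ConfigurationError(
            f"constructed pair has minimum voxel distance {d_min:.2f} mm "
            f"<= max tracking length {max_length_mm} mm"
        )
    return initial, recurrent


def minimum_pair_distance(a: LesionMask, b: LesionMask) -> float:
    """Exact minimum Euclidean distance between voxel centers of two masks."""
    from scipy.spatial import cKDTree

    tree = cKDTree(a.world_coords())
    d, _ = tree.query(b.world_coords(), k=1)
    return float(d.min())


@dataclass
class SyntheticCohortConfig:
    """Parameters of a synthetic cohort.

    Defaults encode the study geometry: 30 patients (1 remote) crossed with
    30 orientation-field "connectomes"; connected-case displacement magnitude
    kept under 20 mm so centroid separations stay inside the 25 mm maximum
    tracking length with margin.
    """

    n_patients: int = 30
    n_connectomes: int = 30
    n_remote: int = 1
    displacement_mm: tuple[float, float, float] = (8.0, 4.0, 2.0)
    growth_factor: float = 1.2
    radii_mm: tuple[float, float, float] = (8.0, 8.0, 8.0)
    alignment_angle_deg: float = 0.0
    angular_jitter_deg: float = 10.0
    fa_value: float = 0.8
    remote_gap_mm: float = 40.0
    max_length_mm: float = 25.0
    grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    center_spread_mm: float = 6.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1 or self.n_connectomes < 1:
            raise ConfigurationError("need at least one patient and one connectome")
        if not 0 <= self.n_remote <= self.n_patients:
            raise ConfigurationError("n_remote must lie in [0, n_patients]")
        disp = np.linalg.norm(self.displacement_mm)
        if disp >= self.max_length_mm:
            raise ConfigurationError(
                f"connected-case displacement |{self.displacement_mm}| = {disp:.1f} mm "
                f"must stay below the max tracking length {self.max_length_mm} mm"
            )
        if not 0.0 <= self.alignment_angle_deg <= 90.0:
            raise ConfigurationError("alignment_angle_deg must lie in [0, 90]")

    @property
    def grid(self) -> VolumeGrid:
        return VolumeGrid(self.grid_shape, self.voxel_size_mm)


@dataclass
class SyntheticCohort:
    """Generated cohort: lesion pairs keyed by patient, fields by connectome."""

    config: SyntheticCohortConfig
    patients: list[tuple[str, LesionMask, LesionMask]] = dc_field(default_factory=list)
    connectomes: list[tuple[str, OrientationField]] = dc_field(default_factory=list)
    remote_ids: set[str] = dc_field(default_factory=set)


def _rotate_from(direction: np.ndarray, angle_deg: float) -> np.ndarray:
    """Unit vector at a fixed angle from ``direction`` (rotation in a pinned plane)."""
    d = direction / np.linalg.norm(direction)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    perp = np.cross(d, helper)
    perp /= np.linalg.norm(perp)
    th = np.deg2rad(angle_deg)
    return np.cos(th) * d + np.sin(th) * perp


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate the full synthetic cohort described by ``config``.

    Produces exactly ``n_patients`` lesion pairs (the last ``n_remote`` of
    them remote) and ``n_connectomes`` orientation fields whose principal
    direction sits at ``alignment_angle_deg`` to the shared displacement
    vector.  Fully reproducible from ``rng_seed``.
    """
    grid = config.grid
    root = np.random.SeedSequence(config.rng_seed)
    ss_centers, ss_fields = root.spawn(2)
    rng = np.random.default_rng(ss_centers)

    disp = np.rint(np.asarray(config.displacement_mm, dtype=float)
                   / np.asarray(config.voxel_size_mm)) * np.asarray(config.voxel_size_mm)
    radii = np.asarray(config.radii_mm, dtype=float)
    vox = np.asarray(config.voxel_size_mm)

    # feasible integer-offset box for initial-lesion centers
    lo = np.asarray(grid.origin_mm)
    hi = grid.index_to_world(np.asarray(grid.shape) - 1)
    margin_lo = lo + radii * max(1.0, config.growth_factor) + np.maximum(-disp, 0) + vox
    margin_hi = hi - radii * max(1.0, config.growth_factor) - np.maximum(disp, 0) - vox
    if np.any(margin_lo > margin_hi):
        raise BoundsError("grid too small for the configured lesions and displacement")
    spread = np.minimum(config.center_spread_mm, (margin_hi - margin_lo) / 2)
    mid_index = np.asarray(grid.shape) // 2

    cohort = SyntheticCohort(config=config)
    n_connected = config.n_patients - config.n_remote
    pad = max(2, len(str(config.n_patients)))
    for i in range(config.n_patients):
        pid = f"P{i + 1:0{pad}d}"
        if i < n_connected:
            # clamp in index space so centers stay exactly on voxel centers
            offset = np.rint(rng.uniform(-spread, spread) / vox)
            idx_lo = np.ceil((margin_lo - np.asarray(grid.origin_mm)) / vox)
            idx_hi = np.floor((margin_hi - np.asarray(grid.origin_mm)) / vox)
            idx = np.clip(mid_index + offset, idx_lo, idx_hi)
            center = grid.index_to_world(idx)
            initial, recurrent = generate_lesion_pair(
                grid, center, radii, disp, config.growth_factor, patient_id=pid
            )
        else:
            initial, recurrent = generate_remote_pair(
                grid,
                gap_mm=config.remote_gap_mm,
                radii_mm=radii * 0.75,
                max_length_mm=config.max_length_mm,
                patient_id=pid,
            )
            cohort.remote_ids.add(pid)
        cohort.patients.append((pid, initial, recurrent))

    principal = _rotate_from(disp, config.alignment_angle_deg)
    field_seeds = ss_fields.spawn(config.n_connectomes)
    pad_c = max(2, len(str(config.n_connectomes)))
    for j in range(config.n_connectomes):
        cid = f"C{j + 1:0{pad_c}d}"
        field = generate_orientation_field(
            grid,
            principal,
            angular_jitter_deg=config.angular_jitter_deg,
            fa_value=config.fa_value,
            rng_seed=field_seeds[j],
        )
        cohort.connectomes.append((cid, field))
    return cohort
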