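"""Deterministic streamline tracking over a per-voxel orientation field.

A minimal FACT-style tracker: fixed-step integration of the single local
fiber orientation, with the sign of each voxel's (axis-ambiguous) direction
chosen to minimize the turning angle against the incoming direction.
Trajectories grow bidirectionally from random sub-voxel seed points inside
the seed region; a trajectory terminates when it leaves the volume, enters a
voxel below the anisotropy (FA) threshold or without orientation, turns more
sharply than the angle threshold, or reaches the maximum length.  A
streamline is *accepted* iff its total arc length lies within the
[min, max] window and it intersects the endpoint region.

This is not a reimplementation of generalized q-sampling tractography: the
downstream alignment analysis consumes only streamline-level direction
vectors, and externally computed tractograms (TRK/TCK) can be substituted
via :func:`read_tractogram` when fidelity matters.

Default parameters follow the tracking protocol the package reproduces:
FA threshold 0.2, minimum length 1 mm, maximum length 25 mm, target fiber
count 5000.  A "step size 0" in the originating tool is a sentinel for an
adaptive default; here the default step is half the smallest voxel dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .errors import (
    ConfigurationError,
    DegenerateStreamlineError,
    EmptyROIError,
    UndefinedDirectionError,
    UnsupportedFormatError,
)
from .volumes import LesionMask, OrientationField, require_same_grid

__all__ = [
    "TrackingParams",
    "StreamlineSet",
    "track",
    "streamline_length",
    "representative_vector",
    "read_tractogram",
    "write_tractogram",
]


@dataclass
class TrackingParams:
    """Termination and seeding parameters for the deterministic tracker."""

    fa_threshold: float = 0.2
    step_mm: float | None = None          # None -> half the smallest voxel dim
    min_length_mm: float = 1.0
    max_length_mm: float = 25.0
    target_count: int = 5000
    angle_threshold_deg: float = 60.0
    max_seed_attempts: int | None = None  # None -> 100 * target_count
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fa_threshold < 1.0:
            raise ConfigurationError("fa_threshold must lie in (0, 1)")
        if self.min_length_mm >= self.max_length_mm:
            raise ConfigurationError("min_length_mm must be < max_length_mm")
        if self.target_count < 1:
            raise ConfigurationError("target_count must be positive")
        if self.step_mm is not None and self.step_mm <= 0:
            raise ConfigurationError("step_mm must be positive")

    def resolved_step(self, voxel_size_mm) -> float:
        return self.step_mm if self.step_mm is not None else min(voxel_size_mm) / 2.0

    def resolved_attempts(self) -> int:
        return self.max_seed_attempts if self.max_seed_attempts is not None \
            else 100 * self.target_count


@dataclass
class StreamlineSet:
    """Accepted streamlines (world-mm polylines) between a seed and end ROI."""

    streamlines: list[np.ndarray]
    params: TrackingParams | None = None
    seed_roi_id: str = ""
    end_roi_id: str = ""
    n_seed_attempts: int = 0

    def __len__(self) -> int:
        return len(self.streamlines)

    def __iter__(self):
        return iter(self.streamlines)

    def representative_vectors(self) -> np.ndarray:
        """(n, 3) unit direction vectors, one per streamline.

        Streamlines with coincident endpoints (no defined direction) are
        excluded with a logged warning rather than coerced.
        """
        import logging

        vecs = []
        n_skipped = 0
        for s in self.streamlines:
            try:
                vecs.append(representative_vector(s))
            except DegenerateStreamlineError:
                n_skipped += 1
        if n_skipped:
            logging.getLogger(__name__).warning(
                "%d streamline(s) had no defined representative direction; excluded",
                n_skipped,
            )
        return np.asarray(vecs).reshape(-1, 3)


def streamline_length(points: np.ndarray) -> float:
    """Arc length (mm) of a polyline: sum of Euclidean segment lengths."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise DegenerateStreamlineError("a streamline needs at least 2 points")
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def representative_vector(points: np.ndarray) -> np.ndarray:
    """Unit direction of a streamline: normalized endpoint displacement.

    The axis sign is irrelevant downstream (orientations, not polarities):
    reversing the point order negates the vector, which the absolute-value
    similarity metrics treat as equivalent.
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[0] < 2:
        raise DegenerateStreamlineError("a streamline needs at least 2 points")
    d = points[-1] - points[0]
    n = np.linalg.norm(d)
    if n < 1e-9:
        raise UndefinedDirectionError("streamline endpoints coincide")
    return d / n


def _propagate_half(
    pos0: np.ndarray,
    prev_dir: np.ndarray,
    field: OrientationField,
    step: float,
    step_budget: np.ndarray,
    fa_threshold: float,
    cos_angle_min: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Grow one half of each trajectory in a batch.

    ``step_budget`` is the per-trajectory maximum number of steps (the two
    halves of a bidirectional trajectory share one arc-length budget).
    Returns ``(paths, n_points)`` where ``paths`` is (B, max_steps + 1, 3)
    with ``paths[:, 0]`` = the seed points, and ``n_points[b]`` counts the
    valid points of trajectory ``b``.
    """
    grid = field.grid
    B = pos0.shape[0]
    max_steps = int(step_budget.max(initial=0))
    origin = np.asarray(grid.origin_mm)
    vox = np.asarray(grid.voxel_size_mm)
    shape = np.asarray(grid.shape)

    paths = np.zeros((B, max_steps + 1, 3), dtype=np.float64)
    paths[:, 0] = pos0
    n_points = np.ones(B, dtype=np.int64)
    pos = pos0.copy()
    prev = prev_dir.copy()
    active = np.linalg.norm(prev, axis=1) > 1e-9

    for k in range(1, max_steps + 1):
        # trajectories whose shared length budget is spent terminate here
        active &= step_budget >= k
        if not active.any():
            break
        idx = np.rint((pos[active] - origin) / vox).astype(np.int64)
        inside = np.all((idx >= 0) & (idx < shape), axis=1)
        act_ids = np.flatnonzero(active)
        # trajectories leaving the volume terminate
        active[act_ids[~inside]] = False
        act_ids = act_ids[inside]
        if act_ids.size == 0:
            break
        idx = idx[inside]
        d = field.directions[idx[:, 0], idx[:, 1], idx[:, 2]].astype(np.float64)
        fa = field.anisotropy[idx[:, 0], idx[:, 1], idx[:, 2]]
        has_dir = np.linalg.norm(d, axis=1) > 1e-9
        ok = has_dir & (fa >= fa_threshold)
        # sign disambiguation: follow the hemisphere of the incoming direction
        dot = np.einsum("ij,ij->i", d, prev[act_ids])
        d = np.where(dot[:, None] < 0, -d, d)
        ok &= np.abs(dot) >= cos_angle_min
        active[act_ids[~ok]] = False
        act_ids = act_ids[ok]
        if act_ids.size == 0:
            break
        d = d[ok]
        pos[act_ids] += step * d
        prev[act_ids] = d
        paths[act_ids, k] = pos[act_ids]
        n_points[act_ids] = k + 1
    return paths, n_points


def track(
    field: OrientationField,
    seed_mask: LesionMask,
    end_mask: LesionMask,
    params: TrackingParams | None = None,
) -> StreamlineSet:
    """Track streamlines from ``seed_mask``, keeping those reaching ``end_mask``.

    Seeding draws one uniformly distributed point per attempt inside a
    uniformly chosen seed-mask voxel; growth is bidirectional from the seed
    point with the two halves concatenated.  Seeding repeats (in batches)
    until ``target_count`` streamlines are accepted or ``max_seed_attempts``
    is exhausted.  Reproducible from ``params.rng_seed``.
    """
    params = params or TrackingParams()
    grid = require_same_grid(field, seed_mask, end_mask)
    if seed_mask.voxel_count == 0:
        raise EmptyROIError("seed mask is empty")
    if end_mask.voxel_count == 0:
        raise EmptyROIError("end mask is empty")

    step = params.resolved_step(grid.voxel_size_mm)
    max_attempts = params.resolved_attempts()
    max_steps = int(np.floor(params.max_length_mm / step + 1e-9))
    cos_min = float(np.cos(np.deg2rad(params.angle_threshold_deg)))
    rng = np.random.default_rng(params.rng_seed)

    seed_voxels = seed_mask.voxel_indices()
    origin = np.asarray(grid.origin_mm)
    vox = np.asarray(grid.voxel_size_mm)
    shape = np.asarray(grid.shape)
    end_data = end_mask.data

    accepted: list[np.ndarray] = []
    attempts = 0
    batch_size = int(min(max(64, params.target_count), 1024))
    while len(accepted) < params.target_count and attempts < max_attempts:
        B = int(min(batch_size, max_attempts - attempts))
        attempts += B
        vi = seed_voxels[rng.integers(0, len(seed_voxels), size=B)]
        pos0 = grid.index_to_world(vi) + rng.uniform(-0.5, 0.5, size=(B, 3)) * vox
        d0 = field.directions[vi[:, 0], vi[:, 1], vi[:, 2]].astype(np.float64)

        full_budget = np.full(B, max_steps, dtype=np.int64)
        fwd_paths, fwd_n = _propagate_half(
            pos0, d0, field, step, full_budget, params.fa_threshold, cos_min
        )
        # the backward half spends whatever arc-length budget remains
        bwd_budget = full_budget - (fwd_n - 1)
        bwd_paths, bwd_n = _propagate_half(
            pos0, -d0, field, step, bwd_budget, params.fa_threshold, cos_min
        )
        for b in range(B):
            if len(accepted) >= params.target_count:
                break
            # backward half reversed (dropping the duplicated seed point) + forward half
            back = bwd_paths[b, 1:bwd_n[b]][::-1]
            fwd = fwd_paths[b, :fwd_n[b]]
            pts = np.vstack([back, fwd])
            if pts.shape[0] < 2:
                continue
            length = step * (pts.shape[0] - 1)
            if not (params.min_length_mm <= length <= params.max_length_mm):
                continue
            idx = np.rint((pts - origin) / vox).astype(np.int64)
            ok = np.all((idx >= 0) & (idx < shape), axis=1)
            idx = idx[ok]
            if idx.size and end_data[idx[:, 0], idx[:, 1], idx[:, 2]].any():
                accepted.append(pts)

    return StreamlineSet(
        accepted,
        params=params,
        seed_roi_id=f"{seed_mask.patient_id}/{seed_mask.timepoint}",
        end_roi_id=f"{end_mask.patient_id}/{end_mask.timepoint}",
        n_seed_attempts=attempts,
    )


# ---------------------------------------------------------------------------
# tractogram I/O (TRK / TCK via nibabel.streamlines)


def write_tractogram(sset: StreamlineSet, path: str | Path) -> None:
    """Write streamlines to TRK or TCK (world/RAS-mm coordinates)."""
    import nibabel as nib
    from nibabel.streamlines import Tractogram

    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise UnsupportedFormatError(f"unsupported tractogram extension: {path.suffix}")
    tg = Tractogram([np.asarray(s, dtype=np.float32) for s in sset.streamlines],
                    affine_to_rasmm=np.eye(4))
    nib.streamlines.save(tg, str(path))


def read_tractogram(path: str | Path) -> StreamlineSet:
    """Read a TRK or TCK tractogram into world/RAS-mm polylines."""
    import nibabel as nib

    path = Path(path)
    if path.suffix.lower() not in (".trk", ".tck"):
        raise UnsupportedFormatError(f"unsupported tractogram extension: {path.suffix}")
    tf = nib.streamlines.load(str(path))
    streamlines = [np.asarray(s, dtype=np.float64) for s in tf.tractogram.streamlines]
    return StreamlineSet(streamlines)
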