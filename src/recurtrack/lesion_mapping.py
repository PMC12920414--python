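"""Voxel-based lesion mapping.

Group-level lesion frequency maps, per-patient recurrence-specific
subtraction maps, hemispheric standardization (left lesions mirrored to the
right), atlas-region labeling, and distribution-shift statistics
(chi-square over the region x timepoint contingency table, with per-region
Fisher exact post hoc).

Conventions pinned here:

* The mid-sagittal plane is world ``x = 0``; negative x is the left
  hemisphere.  Hemisphere assignment is by the sign of the lesion centroid's
  world x-coordinate.
* Mirroring is performed by voxel-index reflection when the grid is symmetric
  about ``x = 0`` (exact involution); otherwise by world-coordinate
  reflection followed by nearest-voxel assignment.
* The recurrence-specific map is the set difference *recurrent minus
  initial*: the voxels newly involved at recurrence.  (Some descriptions
  phrase this as subtracting in the opposite order and discarding negatives;
  the quantity of interest — voxels specific to recurrence — is the one
  implemented.)
* Contingency counts for the distribution test are voxels pooled across
  patients; voxels are not independent observations, so per-patient region
  proportions are also exposed for alternative analyses.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyMaskError, GridIncompatibilityError, InsufficientDataError
from .grid import VolumeGrid
from .volumes import LesionMask, require_same_grid

__all__ = [
    "FrequencyMap",
    "AtlasVolume",
    "RegionCountTable",
    "DistributionComparison",
    "flip_to_right",
    "aggregate",
    "recurrence_specific",
    "label_regions",
    "compare_region_distributions",
    "fisher_exact_2x2",
    "load_lookup_table",
]


def fisher_exact_2x2(table) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 count table.

    Returns ``(odds_ratio, p_two_sided)``; the post hoc of
    :func:`compare_region_distributions` applies this per region.
    """
    odds, p = stats.fisher_exact(np.asarray(table), alternative="two-sided")
    return float(odds), float(p)


@dataclass
class FrequencyMap:
    """Voxel-wise count of contributing lesion masks (the heatmap payload)."""

    counts: np.ndarray
    n_subjects: int
    timepoint_label: str
    grid: VolumeGrid

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.min() < 0 or counts.max() > self.n_subjects:
            raise ValueError("counts must lie in [0, n_subjects]")
        self.counts = counts.astype(np.int32)

    def to_nifti(self):
        import nibabel as nib

        return nib.Nifti1Image(self.counts.astype(np.int32), self.grid.affine)

    def save(self, path: str | Path) -> None:
        import nibabel as nib

        nib.save(self.to_nifti(), str(path))


@dataclass
class AtlasVolume:
    """Integer label volume (0 = background) plus region-id -> name lookup."""

    labels: np.ndarray
    lookup: dict[int, str]
    grid: VolumeGrid

    def __post_init__(self) -> None:
        labels = np.asarray(self.labels).astype(np.int32)
        if labels.shape != self.grid.shape:
            raise GridIncompatibilityError("atlas labels do not match grid shape")
        present = set(np.unique(labels).tolist()) - {0}
        missing = present - set(self.lookup)
        if missing:
            raise ValueError(f"atlas labels missing from lookup: {sorted(missing)}")
        self.labels = labels

    @classmethod
    def load(cls, label_path: str | Path, lookup_path: str | Path) -> "AtlasVolume":
        import nibabel as nib

        img = nib.load(str(label_path))
        grid = VolumeGrid.from_affine(img.shape, img.affine)
        return cls(np.asarray(img.dataobj), load_lookup_table(lookup_path), grid)


def load_lookup_table(path: str | Path) -> dict[int, str]:
    """Read a two-column tab-separated (region id, region name) lookup."""
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "name"], comment="#")
    return dict(zip(df["id"].astype(int), df["name"].astype(str)))


@dataclass
class RegionCountTable:
    """Per-region lesion voxel counts and proportions for one condition.

    ``proportions`` are relative to all lesion voxels (labeled + unlabeled)
    by default; the unlabeled (background) fraction is reported separately.
    """

    table: pd.DataFrame  # columns: region_id, region_name, voxel_count, proportion
    total_voxels: int
    unlabeled_voxels: int
    condition: str = ""

    def region_counts(self) -> pd.Series:
        return self.table.set_index("region_id")["voxel_count"]

    def save_csv(self, path: str | Path) -> None:
        self.table.to_csv(path, index=False)


@dataclass
class DistributionComparison:
    """Chi-square shift test plus per-region Fisher exact post hoc."""

    chi2_stat: float
    df: int
    p_value: float
    per_region: pd.DataFrame  # region_id, region_name, odds_ratio, fisher_p[, fisher_p_adj]
    adjust: str | None = None

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["per_region"] = self.per_region.to_dict(orient="records")
        return d


# ---------------------------------------------------------------------------
# operations


def _centroid_world(mask: LesionMask) -> np.ndarray:
    coords = mask.world_coords()
    if coords.shape[0] == 0:
        raise EmptyMaskError(f"mask {mask.patient_id}/{mask.timepoint} is empty")
    return coords.mean(axis=0)


def flip_to_right(mask: LesionMask, left_is_negative_x: bool = True) -> LesionMask:
    """Mirror a left-hemisphere lesion about the mid-sagittal plane (x = 0).

    Masks whose centroid already lies in the right hemisphere are returned
    unchanged.  Voxel count is preserved exactly.
    """
    cx = _centroid_world(mask)[0]
    on_left = cx < 0 if left_is_negative_x else cx > 0
    if not on_left:
        return mask

    grid = mask.grid
    n, vx, ox = grid.shape[0], grid.voxel_size_mm[0], grid.origin_mm[0]
    # index reflection about the world x=0 plane: i' = -i - 2*ox/vx
    shift = -2.0 * ox / vx
    if abs(shift - round(shift)) < 1e-9:
        # grid symmetric about x = 0 -> exact index reflection
        idx = mask.voxel_indices()
        new_i = (round(shift) - idx[:, 0]).astype(np.int64)
        if new_i.min() < 0 or new_i.max() >= n:
            raise GridIncompatibilityError("mirrored lesion falls outside the grid")
        data = np.zeros(grid.shape, dtype=bool)
        data[new_i, idx[:, 1], idx[:, 2]] = True
    else:
        # asymmetric grid: reflect world coordinates, assign nearest voxel
        coords = mask.world_coords()
        coords[:, 0] *= -1.0
        idx = grid.world_to_nearest_index(coords)
        if not np.all(grid.contains_index(idx)):
            raise GridIncompatibilityError("mirrored lesion falls outside the grid")
        data = np.zeros(grid.shape, dtype=bool)
        data[idx[:, 0], idx[:, 1], idx[:, 2]] = True
    if int(data.sum()) != mask.voxel_count:
        raise GridIncompatibilityError(
            "mirroring collapsed voxels (grid not symmetric about x = 0)"
        )
    return LesionMask(mask.patient_id, mask.timepoint, data, grid)


def aggregate(masks: list[LesionMask], timepoint_label: str = "") -> FrequencyMap:
    """Voxel-wise sum of binary masks across patients (the frequency map)."""
    if not masks:
        raise InsufficientDataError("cannot aggregate an empty mask list")
    grid = require_same_grid(*masks)
    counts = np.zeros(grid.shape, dtype=np.int32)
    for m in masks:
        counts += m.data
    label = timepoint_label or masks[0].timepoint
    return FrequencyMap(counts, n_subjects=len(masks), timepoint_label=label, grid=grid)


def recurrence_specific(initial: LesionMask, recurrent: LesionMask) -> LesionMask:
    """Voxels newly involved at recurrence: ``recurrent AND NOT initial``.

    The result is disjoint from the initial mask and a subset of the
    recurrent mask; it may legitimately be empty (recurrence fully inside
    the initial lesion).
    """
    require_same_grid(initial, recurrent)
    if initial.patient_id != recurrent.patient_id:
        raise ValueError(
            f"masks belong to different patients: {initial.patient_id!r} vs "
            f"{recurrent.patient_id!r}"
        )
    if (initial.timepoint, recurrent.timepoint) != ("initial", "recurrent"):
        raise ValueError("arguments must be (initial, recurrent) masks in that order")
    data = recurrent.data & ~initial.data
    return LesionMask(recurrent.patient_id, "recurrent", data, recurrent.grid,
                      allow_empty=True)


def label_regions(mask: LesionMask, atlas: AtlasVolume, condition: str = "") -> RegionCountTable:
    """Tally lesion voxels per atlas region.

    Proportions are relative to the total lesion voxel count (background
    voxels included in the denominator, reported as ``unlabeled_voxels``).
    """
    require_same_grid(mask, atlas)
    total = mask.voxel_count
    labels_in_mask = atlas.labels[mask.data]
    counts = np.bincount(labels_in_mask, minlength=1)
    unlabeled = int(counts[0]) if counts.size else 0
    rows = []
    for rid in sorted(atlas.lookup):
        c = int(counts[rid]) if rid < counts.size else 0
        rows.append(
            {
                "region_id": rid,
                "region_name": atlas.lookup[rid],
                "voxel_count": c,
                "proportion": c / total if total else 0.0,
            }
        )
    table = pd.DataFrame(rows, columns=["region_id", "region_name", "voxel_count", "proportion"])
    return RegionCountTable(table, total_voxels=total, unlabeled_voxels=unlabeled,
                            condition=condition or mask.timepoint)


def compare_region_distributions(
    table_initial: RegionCountTable,
    table_recurrent: RegionCountTable,
    include_unlabeled: bool = False,
    adjust: str | None = None,
) -> DistributionComparison:
    """Chi-square shift test between two regional lesion distributions.

    Builds the regions x 2-condition contingency table of pooled voxel
    counts and tests for a distribution shift (no continuity correction),
    then runs a two-sided Fisher exact test per region on the 2x2 table
    (this region vs all others) x (initial vs recurrent).  Fisher p-values
    are unadjusted by default; pass ``adjust="holm"`` or ``"bh"`` for a
    corrected column alongside.
    """
    ci = table_initial.region_counts()
    cr = table_recurrent.region_counts()
    if not ci.index.equals(cr.index):
        raise ValueError("the two tables cover different region sets")
    names = table_initial.table.set_index("region_id")["region_name"]

    if include_unlabeled:
        ci = pd.concat([ci, pd.Series({0: table_initial.unlabeled_voxels})])
        cr = pd.concat([cr, pd.Series({0: table_recurrent.unlabeled_voxels})])
        names = pd.concat([names, pd.Series({0: "unlabeled"})])

    # drop regions empty in both conditions (zero-count rows break chi-square)
    keep = (ci + cr) > 0
    ci, cr = ci[keep], cr[keep]
    if len(ci) < 2 or ci.sum() == 0 or cr.sum() == 0:
        raise InsufficientDataError("need >= 2 populated regions in both conditions")

    contingency = np.column_stack([ci.to_numpy(), cr.to_numpy()])
    chi2, p, df, _ = stats.chi2_contingency(contingency, correction=False)

    ti, tr = int(ci.sum()), int(cr.sum())
    rows = []
    for rid in ci.index:
        a, b = int(ci[rid]), int(cr[rid])
        odds, fp = fisher_exact_2x2([[a, b], [ti - a, tr - b]])
        rows.append(
            {
                "region_id": int(rid),
                "region_name": names[rid],
                "odds_ratio": float(odds),
                "fisher_p": float(fp),
            }
        )
    per_region = pd.DataFrame(rows)
    if adjust is not None:
        from statsmodels.stats.multitest import multipletests

        method = {"holm": "holm", "bh": "fdr_bh"}[adjust]
        per_region["fisher_p_adj"] = multipletests(per_region["fisher_p"], method=method)[1]
    return DistributionComparison(float(chi2), int(df), float(p), per_region, adjust=adjust)
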