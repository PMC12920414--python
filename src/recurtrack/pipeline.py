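"""End-to-end pipeline: simulate -> map lesions -> track -> MACC -> test -> report.

A single :class:`RunConfig` drives every stage; all randomness is pinned by
explicit seeds recorded in the emitted provenance, so rerunning a config
reproduces identical numeric outputs.  Products are written as NIfTI
(frequency maps), CSV (region tables, MACC matrix) and JSON (test results,
report).
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .directional import (
    MACCMatrix,
    connectome_level,
    one_sample_test,
    patient_level,
)
from .directional import build_macc_matrix
from .errors import ConfigurationError, InsufficientDataError
from .grid import VolumeGrid
from .lesion_mapping import (
    AtlasVolume,
    RegionCountTable,
    aggregate,
    compare_region_distributions,
    flip_to_right,
    label_regions,
    recurrence_specific,
)
from .synthetic import SyntheticCohort, SyntheticCohortConfig, generate_cohort
from .tractography import TrackingParams
from .volumes import LesionMask

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline", "render_outputs", "toy_atlas",
           "pooled_region_table"]


def toy_atlas(grid: VolumeGrid, n_regions: int = 4, axis: int = 0) -> AtlasVolume:
    """Slab parcellation of the grid into ``n_regions`` equal regions.

    A synthetic stand-in for an anatomical label volume: regions are
    contiguous slabs along ``axis``, named ``region_1 .. region_n``.
    """
    labels = np.zeros(grid.shape, dtype=np.int32)
    edges = np.linspace(0, grid.shape[axis], n_regions + 1).astype(int)
    for r in range(n_regions):
        sl = [slice(None)] * 3
        sl[axis] = slice(edges[r], edges[r + 1])
        labels[tuple(sl)] = r + 1
    lookup = {r + 1: f"region_{r + 1}" for r in range(n_regions)}
    return AtlasVolume(labels, lookup, grid)


def pooled_region_table(masks: list[LesionMask], atlas: AtlasVolume,
                        condition: str) -> RegionCountTable:
    """Region table of voxels pooled across patients (group-level proportions)."""
    tables = [label_regions(m, atlas, condition) for m in masks]
    pooled = tables[0].table.copy()
    pooled["voxel_count"] = sum(t.table["voxel_count"] for t in tables)
    total = sum(t.total_voxels for t in tables)
    unlabeled = sum(t.unlabeled_voxels for t in tables)
    pooled["proportion"] = pooled["voxel_count"] / total if total else 0.0
    return RegionCountTable(pooled, total_voxels=total, unlabeled_voxels=unlabeled,
                            condition=condition)


@dataclass
class RunConfig:
    """Everything one end-to-end run needs, with all seeds explicit."""

    cohort: SyntheticCohortConfig = dc_field(default_factory=SyntheticCohortConfig)
    tracking: TrackingParams = dc_field(default_factory=TrackingParams)
    metric: str = "abs_pearson"
    null_mean: float = 0.0
    flip: bool = False
    atlas_regions: int = 4
    atlas_path: str | None = None
    lookup_path: str | None = None
    out_dir: str = "recurtrack_out"
    save_volumes: bool = False
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        kwargs = dict(raw)
        if "cohort" in kwargs:
            c = dict(kwargs["cohort"])
            for key in ("displacement_mm", "radii_mm", "grid_shape", "voxel_size_mm"):
                if key in c:
                    c[key] = tuple(c[key])
            kwargs["cohort"] = SyntheticCohortConfig(**c)
        if "tracking" in kwargs:
            kwargs["tracking"] = TrackingParams(**kwargs["tracking"])
        unknown = set(kwargs) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass
class RunReport:
    """Manifest + summary counts + test results for a completed run."""

    config: dict
    counts: dict
    alignment_test: dict | None
    distribution_test: dict | None
    manifest: dict[str, str]
    version: str = __version__
    stage_seconds: dict[str, float] = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute all stages on a synthetic cohort and write every product.

    Stage order: simulate, lesion mapping (frequency + recurrence-specific
    maps, region tables, distribution test), tracking + MACC matrix,
    patient/connectome-level aggregation, one-sample alignment test,
    report.  Any stage failure aborts with the stage named; products written
    so far are retained.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, str] = {}
    timings: dict[str, float] = {}

    def _stage(name):
        logger.info("stage: %s", name)
        return time.perf_counter()

    # -- simulate ------------------------------------------------------------
    t0 = _stage("simulate")
    cohort = generate_cohort(config.cohort)
    timings["simulate"] = time.perf_counter() - t0
    if config.save_volumes:
        vol_dir = out / "volumes"
        vol_dir.mkdir(exist_ok=True)
        for pid, ini, rec in cohort.patients:
            ini.save(vol_dir / f"{pid}_initial.nii.gz")
            rec.save(vol_dir / f"{pid}_recurrent.nii.gz")
        for cid, fld in cohort.connectomes:
            fld.save(vol_dir / f"{cid}_field.nii.gz")
        manifest["volumes_dir"] = str(vol_dir)

    # -- lesion mapping ------------------------------------------------------
    t0 = _stage("map-lesions")
    initials = [p[1] for p in cohort.patients]
    recurrents = [p[2] for p in cohort.patients]
    if config.flip:
        initials = [flip_to_right(m) for m in initials]
        recurrents = [flip_to_right(m) for m in recurrents]
    freq_initial = aggregate(initials, "initial")
    freq_recurrent = aggregate(recurrents, "recurrent")
    rec_specific = [
        recurrence_specific(i, r) for i, r in zip(initials, recurrents)
    ]
    nonempty_spec = [m for m in rec_specific if m.voxel_count > 0]
    freq_spec = aggregate(nonempty_spec, "recurrence_specific") if nonempty_spec else None

    if config.atlas_path and config.lookup_path:
        atlas = AtlasVolume.load(config.atlas_path, config.lookup_path)
    elif config.atlas_path or config.lookup_path:
        raise ConfigurationError(
            "atlas_path and lookup_path must be provided together"
        )
    else:
        atlas = toy_atlas(config.cohort.grid, config.atlas_regions)
    table_initial = pooled_region_table(initials, atlas, "initial")
    table_recurrent = pooled_region_table(recurrents, atlas, "recurrent")
    try:
        dist_test = compare_region_distributions(table_initial, table_recurrent)
        dist_dict = {
            "chi2_stat": dist_test.chi2_stat,
            "df": dist_test.df,
            "p_value": dist_test.p_value,
            "per_region": dist_test.per_region.to_dict(orient="records"),
        }
    except InsufficientDataError as exc:
        logger.warning("distribution test skipped: %s", exc)
        dist_dict = None
    timings["map-lesions"] = time.perf_counter() - t0

    for name, fm in (("frequency_initial", freq_initial),
                     ("frequency_recurrent", freq_recurrent),
                     ("frequency_recurrence_specific", freq_spec)):
        if fm is None:
            continue
        p = out / f"{name}.nii.gz"
        fm.save(p)
        manifest[name] = str(p)
    for name, tbl in (("regions_initial", table_initial),
                      ("regions_recurrent", table_recurrent)):
        p = out / f"{name}.csv"
        tbl.save_csv(p)
        manifest[name] = str(p)
    if dist_dict is not None:
        p = out / "distribution_test.json"
        with open(p, "w") as fh:
            json.dump(dist_dict, fh, indent=2)
        manifest["distribution_test"] = str(p)

    # -- tracking + MACC -----------------------------------------------------
    t0 = _stage("track+macc")
    matrix = build_macc_matrix(
        cohort.patients, cohort.connectomes, config.tracking, config.metric
    )
    timings["track+macc"] = time.perf_counter() - t0
    p = out / "macc_matrix.csv"
    matrix.save_csv(p)
    manifest["macc_matrix"] = str(p)
    sidecar = {
        "metric": matrix.metric,
        "remote_ids": sorted(matrix.remote_ids),
        "excluded_ids": sorted(matrix.excluded_ids),
        "streamline_counts": matrix.streamline_counts.to_dict(),
    }
    p = out / "macc_sidecar.json"
    with open(p, "w") as fh:
        json.dump(sidecar, fh, indent=2, sort_keys=True)
    manifest["macc_sidecar"] = str(p)

    # -- aggregation + test --------------------------------------------------
    t0 = _stage("test")
    pl = patient_level(matrix)
    cl_means, cl_grand, cl_sd = connectome_level(matrix)
    test = one_sample_test(pl.to_numpy(), null_mean=config.null_mean)
    timings["test"] = time.perf_counter() - t0

    p = out / "patient_level_macc.csv"
    pl.rename("macc").to_csv(p, index_label="patient_id")
    manifest["patient_level_macc"] = str(p)
    p = out / "alignment_test.json"
    test_dict = test.to_dict()
    test_dict["connectome_level"] = {"grand_mean": cl_grand, "sd": cl_sd}
    with open(p, "w") as fh:
        json.dump(test_dict, fh, indent=2, sort_keys=True)
    manifest["alignment_test"] = str(p)

    n_analyzed = len(pl)
    counts = {
        "patients": len(cohort.patients),
        "connectomes": len(cohort.connectomes),
        "remote_patients": len(matrix.remote_ids),
        "excluded_patients": len(matrix.excluded_ids),
        "analyzed_patients": n_analyzed,
        "macc_entries": matrix.n_entries,
    }
    report = RunReport(
        config=config.to_dict(),
        counts=counts,
        alignment_test=test_dict,
        distribution_test=dist_dict,
        manifest=manifest,
        stage_seconds=timings,
    )
    p = out / "report.json"
    report.manifest["report"] = str(p)
    report.save(p)
    return report


def render_outputs(report: RunReport) -> list[str]:
    """Verify and list the product files a completed run wrote.

    All rendering happens inside :func:`run_pipeline`; this checks the
    manifest references only files that exist and returns their paths.
    """
    missing = [p for p in report.manifest.values() if not Path(p).exists()]
    if missing:
        raise FileNotFoundError(f"manifest references missing files: {missing}")
    return sorted(report.manifest.values())
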