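"""Directional statistics: progression vectors, MACC, and the cohort test.

The core statistic is the **mean absolute correlation coefficient (MACC)**:
for one patient and one white-matter orientation dataset ("connectome"), the
absolute Pearson correlation between the patient's tumor progression vector
(the unit centroid-to-centroid vector from initial to recurrent lesion,
treated as 3 paired observations) and each connecting streamline's
representative direction vector is averaged over streamlines.  Absolute
values are used because streamline vectors carry orientation, not polarity:
``v`` and ``-v`` are equivalent.  An alternative sign-invariant metric,
absolute cosine similarity ``|u . v|``, is provided for robustness checks.

Aggregation follows the patients x connectomes design: per-(patient,
connectome) MACC entries form a matrix; row means give patient-level MACCs
(one per patient), which feed a one-sample t-test against a null mean with
Cohen's d; column means give connectome-level MACCs as a robustness
descriptive.  Patients whose recurrence is remote (no connecting streamlines
on any connectome) receive MACC = 0 entries for display but are excluded
from the patient-level list and the test by default.

Note on the null: the chance expectation of |Pearson r| between independent
random unit 3-vectors is 2/pi (about 0.64), not 0, and of |cos| is 1/2.
:func:`chance_level` estimates these by Monte Carlo so users can test
against chance rather than zero; the default null mean remains 0, which
reproduces the conventional analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import (
    EmptyMaskError,
    InsufficientDataError,
    UndefinedCorrelationError,
    UndefinedVectorError,
)
from .tractography import StreamlineSet, TrackingParams, track
from .volumes import LesionMask, OrientationField, require_same_grid

__all__ = [
    "ProgressionVector",
    "MACCEntry",
    "MACCMatrix",
    "AlignmentTestResult",
    "centroid",
    "progression_vector",
    "abs_pearson",
    "abs_cosine",
    "compute_macc",
    "build_macc_matrix",
    "patient_level",
    "connectome_level",
    "one_sample_test",
    "chance_level",
]

METRICS = ("abs_pearson", "abs_cosine")


def centroid(mask: LesionMask) -> np.ndarray:
    """Unweighted mean world coordinate (mm) of all lesion voxel centers."""
    coords = mask.world_coords()
    if coords.shape[0] == 0:
        raise EmptyMaskError(f"mask {mask.patient_id}/{mask.timepoint} is empty")
    return coords.mean(axis=0)


@dataclass(frozen=True)
class ProgressionVector:
    """Unit vector of tumor progression, initial centroid -> recurrent centroid."""

    patient_id: str
    centroid_initial_mm: tuple[float, float, float]
    centroid_recurrent_mm: tuple[float, float, float]
    direction: tuple[float, float, float]


def progression_vector(initial: LesionMask, recurrent: LesionMask) -> ProgressionVector:
    """Compute the unit centroid-to-centroid progression vector.

    Raises :class:`UndefinedVectorError` when the two centroids coincide
    (separation < 1e-6 mm); such patients are handled by exclusion rules
    downstream.
    """
    require_same_grid(initial, recurrent)
    c0 = centroid(initial)
    c1 = centroid(recurrent)
    d = c1 - c0
    n = np.linalg.norm(d)
    if n < 1e-6:
        raise UndefinedVectorError(
            f"patient {initial.patient_id}: lesion centroids coincide; "
            "progression direction undefined"
        )
    return ProgressionVector(
        initial.patient_id, tuple(c0), tuple(c1), tuple(d / n)
    )


def abs_pearson(u, v) -> float:
    """|Pearson r| between the 3 components of two vectors, in [0, 1].

    The two vectors' components are treated as 3 paired observations.
    Invariant under scaling (either sign) and constant shifts of either
    argument, and symmetric.  Undefined when a vector has zero variance
    across its components (proportional to (1, 1, 1)).
    """
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    uc = u - u.mean()
    vc = v - v.mean()
    su = np.linalg.norm(uc)
    sv = np.linalg.norm(vc)
    if su < 1e-12 or sv < 1e-12:
        raise UndefinedCorrelationError(
            "zero component variance: Pearson correlation undefined"
        )
    r = float(np.dot(uc, vc) / (su * sv))
    return min(abs(r), 1.0)


def abs_cosine(u, v) -> float:
    """|cos| of the angle between two vectors, in [0, 1].

    Inputs are normalized internally (with a warning if they deviate from
    unit norm by more than 1e-6): 1 iff (anti)parallel, 0 iff orthogonal.
    """
    import logging

    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    nu = np.linalg.norm(u)
    nv = np.linalg.norm(v)
    if nu < 1e-12 or nv < 1e-12:
        raise UndefinedVectorError("zero vector has no direction")
    if abs(nu - 1) > 1e-6 or abs(nv - 1) > 1e-6:
        logging.getLogger(__name__).warning("non-unit input normalized in abs_cosine")
    return min(abs(float(np.dot(u, v))) / (nu * nv), 1.0)


_METRIC_FN = {"abs_pearson": abs_pearson, "abs_cosine": abs_cosine}


@dataclass(frozen=True)
class MACCEntry:
    """One patient x connectome MACC value with its provenance counts."""

    value: float
    n_streamlines: int
    n_excluded: int = 0
    remote: bool = False

    def __float__(self) -> float:
        return self.value


def compute_macc(
    pv: ProgressionVector,
    fibers: StreamlineSet,
    metric: str = "abs_pearson",
) -> MACCEntry:
    """Mean absolute similarity between a progression vector and fiber vectors.

    An empty streamline set (no connection between the lesions) yields
    MACC = 0 flagged as remote.  Streamlines whose similarity is undefined
    (degenerate direction, zero component variance under Pearson) are
    excluded from the mean rather than coerced to 0.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if len(fibers) == 0:
        return MACCEntry(0.0, 0, 0, remote=True)
    fn = _METRIC_FN[metric]
    direction = np.asarray(pv.direction, dtype=float)
    vals = []
    n_excluded = 0
    vecs = fibers.representative_vectors()
    n_excluded += len(fibers) - len(vecs)
    for v in vecs:
        try:
            vals.append(fn(direction, v))
        except (UndefinedCorrelationError, UndefinedVectorError):
            n_excluded += 1
    if not vals:
        return MACCEntry(0.0, len(fibers), n_excluded, remote=True)
    return MACCEntry(float(np.mean(vals)), len(fibers), n_excluded, remote=False)


@dataclass
class MACCMatrix:
    """Patients x connectomes grid of MACC values and streamline counts."""

    values: pd.DataFrame            # index: patient_id, columns: connectome_id
    streamline_counts: pd.DataFrame
    metric: str
    remote_ids: frozenset[str] = frozenset()    # zero streamlines on every connectome
    excluded_ids: frozenset[str] = frozenset()  # undefined progression vector

    @property
    def n_entries(self) -> int:
        """Entries for analyzed (connected) patients."""
        connected = [p for p in self.values.index
                     if p not in self.remote_ids and p not in self.excluded_ids]
        return len(connected) * self.values.shape[1]

    def connected_values(self) -> pd.DataFrame:
        keep = [p for p in self.values.index
                if p not in self.remote_ids and p not in self.excluded_ids]
        return self.values.loc[keep]

    def save_csv(self, path) -> None:
        self.values.to_csv(path, index_label="patient_id")


def build_macc_matrix(
    patients: list[tuple[str, LesionMask, LesionMask]],
    connectomes: list[tuple[str, OrientationField]],
    params: TrackingParams | None = None,
    metric: str = "abs_pearson",
) -> MACCMatrix:
    """Track every patient pair on every connectome and assemble the MACC grid.

    One entry per (patient, connectome): streamlines are tracked between the
    patient's initial (seed) and recurrent (endpoint) lesions on that
    connectome's orientation field and reduced by :func:`compute_macc`.
    Deterministic: the per-pair tracking seed is derived from
    ``params.rng_seed`` and the (patient, connectome) position.  Patients
    with an undefined progression vector are flagged excluded and carry no
    entries (NaN row).
    """
    if not patients or not connectomes:
        raise InsufficientDataError("need at least one patient and one connectome")
    params = params or TrackingParams()
    pids = [p[0] for p in patients]
    cids = [c[0] for c in connectomes]
    values = pd.DataFrame(np.nan, index=pids, columns=cids)
    counts = pd.DataFrame(0, index=pids, columns=cids, dtype=int)
    remote: set[str] = set()
    excluded: set[str] = set()

    root = np.random.SeedSequence(params.rng_seed)
    pair_seeds = root.spawn(len(patients) * len(connectomes))

    for i, (pid, initial, recurrent) in enumerate(patients):
        try:
            pv = progression_vector(initial, recurrent)
        except UndefinedVectorError:
            excluded.add(pid)
            continue
        any_streamlines = False
        for j, (cid, field) in enumerate(connectomes):
            pair_params = dataclasses.replace(
                params, rng_seed=pair_seeds[i * len(connectomes) + j]
            )
            sset = track(field, initial, recurrent, pair_params)
            entry = compute_macc(pv, sset, metric)
            values.loc[pid, cid] = entry.value
            counts.loc[pid, cid] = entry.n_streamlines
            any_streamlines = any_streamlines or entry.n_streamlines > 0
        if not any_streamlines:
            remote.add(pid)
    return MACCMatrix(values, counts, metric,
                      remote_ids=frozenset(remote), excluded_ids=frozenset(excluded))


def patient_level(matrix: MACCMatrix, include_remote: bool = False) -> pd.Series:
    """Patient-level MACCs: row means across connectomes.

    Remote-flagged patients are dropped by default (the cohort-test n counts
    connected patients only); pass ``include_remote=True`` to keep their
    all-zero rows.
    """
    if matrix.values.empty:
        raise InsufficientDataError("empty MACC matrix")
    vals = matrix.values.drop(index=list(matrix.excluded_ids), errors="ignore")
    if not include_remote:
        vals = vals.drop(index=list(matrix.remote_ids), errors="ignore")
    return vals.mean(axis=1)


def connectome_level(matrix: MACCMatrix) -> tuple[pd.Series, float, float]:
    """Connectome-level MACCs: column means across connected patients.

    Returns ``(per-connectome means, grand mean, sample SD)`` — a
    descriptive of robustness to the choice of normative dataset.
    """
    vals = matrix.connected_values()
    if vals.empty:
        raise InsufficientDataError("no connected patients in MACC matrix")
    means = vals.mean(axis=0)
    grand = float(means.mean())
    sd = float(means.std(ddof=1)) if len(means) > 1 else 0.0
    return means, grand, sd


@dataclass(frozen=True)
class AlignmentTestResult:
    """One-sample t-test summary for patient-level MACC values."""

    n: int
    mean: float
    sd: float
    null_mean: float
    t_stat: float
    df: int
    p_two_sided: float
    ci95_low: float
    ci95_high: float
    cohens_d: float

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def one_sample_test(values, null_mean: float = 0.0) -> AlignmentTestResult:
    """Two-sided one-sample t-test with 95% CI and Cohen's d.

    t = (mean - null) / (sd / sqrt(n)) with df = n - 1; sample SD uses the
    n - 1 denominator; CI = mean +/- t_{0.975, df} * sd / sqrt(n);
    d = (mean - null) / sd.
    """
    x = np.asarray(list(values), dtype=float)
    n = x.size
    if n < 2:
        raise InsufficientDataError("one-sample t-test needs n >= 2")
    mean = float(x.mean())
    sd = float(x.std(ddof=1))
    if sd <= 0:
        # a constant sample equal to the null carries no information; a
        # constant sample away from it is the decisive limit t -> +/-inf
        if abs(mean - null_mean) < 1e-15:
            raise InsufficientDataError(
                "zero sample SD at the null mean: t statistic undefined"
            )
        sign = 1.0 if mean > null_mean else -1.0
        return AlignmentTestResult(
            n=n, mean=mean, sd=0.0, null_mean=float(null_mean),
            t_stat=sign * float("inf"), df=n - 1, p_two_sided=0.0,
            ci95_low=mean, ci95_high=mean, cohens_d=sign * float("inf"),
        )
    se = sd / np.sqrt(n)
    t_stat = (mean - null_mean) / se
    df = n - 1
    p = 2.0 * float(stats.t.sf(abs(t_stat), df))
    tcrit = float(stats.t.ppf(0.975, df))
    return AlignmentTestResult(
        n=n,
        mean=mean,
        sd=sd,
        null_mean=float(null_mean),
        t_stat=float(t_stat),
        df=df,
        p_two_sided=p,
        ci95_low=float(mean - tcrit * se),
        ci95_high=float(mean + tcrit * se),
        cohens_d=float((mean - null_mean) / sd),
    )


def chance_level(metric: str = "abs_pearson", n_draws: int = 1_000_000,
                 rng_seed: int = 0) -> tuple[float, float]:
    """Monte-Carlo chance expectation of the absolute similarity metric.

    Mean and SD of the metric between independent uniformly random unit
    3-vectors.  Analytic references: E|cos| = 1/2 (cos of the angle between
    uniform directions is uniform on [-1, 1]); E|r| = 2/pi for the
    component-wise Pearson correlation of random 3-vectors.
    """
    if metric not in METRICS:
        raise ValueError(f"metric must be one of {METRICS}, got {metric!r}")
    if n_draws < 1000:
        raise ValueError("n_draws must be >= 1000 for a stable estimate")
    rng = np.random.default_rng(rng_seed)
    u = rng.normal(size=(n_draws, 3))
    v = rng.normal(size=(n_draws, 3))
    if metric == "abs_cosine":
        u /= np.linalg.norm(u, axis=1, keepdims=True)
        v /= np.linalg.norm(v, axis=1, keepdims=True)
        vals = np.abs(np.einsum("ij,ij->i", u, v))
    else:
        uc = u - u.mean(axis=1, keepdims=True)
        vc = v - v.mean(axis=1, keepdims=True)
        num = np.einsum("ij,ij->i", uc, vc)
        den = np.linalg.norm(uc, axis=1) * np.linalg.norm(vc, axis=1)
        vals = np.abs(num / den)
    return float(vals.mean()), float(vals.std(ddof=1))
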