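"""Directional statistics: centroids, progression vectors, the sign-invariant
similarity metrics, MACC aggregation and the cohort-level test."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from recurtrack import (
    LesionMask,
    MACCMatrix,
    ProgressionVector,
    StreamlineSet,
    TrackingParams,
    VolumeGrid,
    abs_cosine,
    abs_pearson,
    build_macc_matrix,
    centroid,
    chance_level,
    compute_macc,
    connectome_level,
    generate_lesion_pair,
    generate_orientation_field,
    one_sample_test,
    patient_level,
    progression_vector,
    track,
)
from recurtrack.errors import (
    EmptyMaskError,
    InsufficientDataError,
    UndefinedCorrelationError,
    UndefinedVectorError,
)

unit_vec = st.tuples(*[st.floats(-1, 1) for _ in range(3)]).filter(
    lambda v: 0.1 < np.linalg.norm(v)
).map(lambda v: tuple(np.asarray(v) / np.linalg.norm(v)))


def single_voxel_mask(world_point, timepoint="initial", pid="P"):
    grid = VolumeGrid((16, 16, 16), origin_mm=(0, 0, 0))
    data = np.zeros(grid.shape, dtype=bool)
    idx = grid.world_to_nearest_index(world_point)
    data[tuple(idx)] = True
    return LesionMask(pid, timepoint, data, grid)


class TestCentroid:
    def test_single_voxel(self):
        m = single_voxel_mask((3, 4, 5))
        assert np.allclose(centroid(m), (3, 4, 5))

    def test_symmetric_sphere(self):
        grid = VolumeGrid((64, 64, 64), origin_mm=(-20, -40, 0))
        ini, _ = generate_lesion_pair(grid, (10, -20, 30), (6, 6, 6), (0, 0, 0))
        assert np.all(np.abs(centroid(ini) - (10, -20, 30)) <= 0.5)

    def test_matches_brute_force_average(self, grid):
        rng = np.random.default_rng(1)
        data = np.zeros(grid.shape, dtype=bool)
        flat = rng.choice(np.prod(grid.shape), size=100, replace=False)
        data.flat[flat] = True
        m = LesionMask("P", "initial", data, grid)
        acc = np.zeros(3)
        n = 0
        for i in range(grid.shape[0]):
            for j in range(grid.shape[1]):
                for k in range(grid.shape[2]):
                    if data[i, j, k]:
                        acc += grid.index_to_world((i, j, k))
                        n += 1
        assert np.allclose(centroid(m), acc / n, atol=1e-12)

    def test_empty_mask_rejected(self, grid):
        m = LesionMask("P", "initial", np.zeros(grid.shape, bool), grid,
                       allow_empty=True)
        with pytest.raises(EmptyMaskError):
            centroid(m)


class TestProgressionVector:
    def test_axis_aligned(self):
        pv = progression_vector(single_voxel_mask((0, 0, 0)),
                                single_voxel_mask((10, 0, 0), "recurrent"))
        assert np.allclose(pv.direction, (1, 0, 0))

    def test_hand_normalization(self):
        pv = progression_vector(single_voxel_mask((0, 0, 0)),
                                single_voxel_mask((3, 4, 0), "recurrent"))
        assert np.allclose(pv.direction, (0.6, 0.8, 0))
        assert np.linalg.norm(pv.direction) == pytest.approx(1.0, abs=1e-9)

    def test_identical_masks_undefined(self):
        with pytest.raises(UndefinedVectorError):
            progression_vector(single_voxel_mask((5, 5, 5)),
                               single_voxel_mask((5, 5, 5), "recurrent"))


class TestSimilarityMetrics:
    def test_abs_pearson_self_correlation(self):
        assert abs_pearson((1, 0, 0), (1, 0, 0)) == pytest.approx(1.0)

    def test_abs_pearson_hand_value_orthogonal_axes(self):
        # centered vectors (2/3,-1/3,-1/3).(-1/3,2/3,-1/3) -> r = -1/2
        assert abs_pearson((1, 0, 0), (0, 1, 0)) == pytest.approx(0.5, abs=1e-12)

    def test_abs_pearson_affine_relative(self):
        # v = 1*u + constant -> perfectly correlated
        assert abs_pearson((1, 0, 0), (2, 1, 1)) == pytest.approx(1.0, abs=1e-12)

    def test_abs_pearson_zero_variance_undefined(self):
        with pytest.raises(UndefinedCorrelationError):
            abs_pearson((1, 0, 0), (1, 1, 1))

    @settings(derandomize=True, max_examples=200)
    @given(u=unit_vec, v=unit_vec)
    def test_metrics_symmetric_and_sign_invariant(self, u, v):
        nu = tuple(-x for x in u)
        for f in (abs_cosine,):
            assert f(u, v) == pytest.approx(f(v, u), abs=1e-12)
            assert f(nu, v) == pytest.approx(f(u, v), abs=1e-12)
        try:
            r = abs_pearson(u, v)
        except UndefinedCorrelationError:
            return
        assert r == pytest.approx(abs_pearson(v, u), abs=1e-12)
        assert r == pytest.approx(abs_pearson(nu, v), abs=1e-12)
        assert 0.0 <= r <= 1.0

    @settings(derandomize=True, max_examples=200)
    @given(u=unit_vec, v=unit_vec,
           a=st.floats(-5, 5).filter(lambda a: abs(a) > 1e-3),
           b=st.floats(-5, 5))
    def test_abs_pearson_affine_invariance(self, u, v, a, b):
        try:
            r = abs_pearson(u, v)
        except UndefinedCorrelationError:
            return
        w = tuple(a * x + b for x in v)
        assert abs_pearson(u, w) == pytest.approx(r, abs=1e-9)

    def test_abs_cosine_values(self):
        assert abs_cosine((1, 0, 0), (1, 0, 0)) == 1.0
        assert abs_cosine((1, 0, 0), (-1, 0, 0)) == 1.0
        assert abs_cosine((1, 0, 0), (0, 1, 0)) == 0.0
        assert abs_cosine((1, 0, 0), (1 / np.sqrt(2), 1 / np.sqrt(2), 0)) == \
            pytest.approx(0.7071, abs=1e-4)


def straight_streamline(direction, length=10.0, origin=(0.0, 0.0, 0.0)):
    d = np.asarray(direction, float)
    d = d / np.linalg.norm(d)
    return np.asarray(origin) + np.outer(np.linspace(0, length, 11), d)


class TestMACC:
    pv = ProgressionVector("P", (0, 0, 0), (10, 0, 0), (1.0, 0.0, 0.0))

    def test_parallel_fibers_give_one(self):
        fibers = StreamlineSet([straight_streamline((1, 0, 0)),
                                straight_streamline((-1, 0, 0))])
        for metric in ("abs_pearson", "abs_cosine"):
            assert compute_macc(self.pv, fibers, metric).value == pytest.approx(1.0)

    def test_empty_set_is_zero_with_remote_flag(self):
        entry = compute_macc(self.pv, StreamlineSet([]))
        assert entry.value == 0.0
        assert entry.remote

    def test_mean_of_known_cosines(self):
        # fibers at 0, 60 and 90 degrees to the progression axis:
        # |cos| = 1.0, 0.5, 0.0 -> MACC 0.5
        fibers = StreamlineSet([
            straight_streamline((1, 0, 0)),
            straight_streamline((0.5, np.sqrt(3) / 2, 0)),
            straight_streamline((0, 1, 0)),
        ])
        entry = compute_macc(self.pv, fibers, "abs_cosine")
        assert entry.value == pytest.approx(0.5, abs=1e-9)

    def test_degenerate_streamlines_excluded_not_coerced(self):
        loop = np.array([[0, 0, 0], [1, 0, 0], [0, 0, 0]], float)
        fibers = StreamlineSet([straight_streamline((1, 0, 0)), loop])
        entry = compute_macc(self.pv, fibers, "abs_cosine")
        assert entry.value == pytest.approx(1.0)
        assert entry.n_excluded == 1


def matrix_from(values: dict, metric="abs_cosine", remote=(), excluded=()):
    df = pd.DataFrame(values).T
    counts = (df.notna() & (df > 0)).astype(int)
    return MACCMatrix(df, counts, metric, frozenset(remote), frozenset(excluded))


class TestAggregation:
    def test_patient_level_row_means_and_remote_exclusion(self):
        m = matrix_from({
            "P1": {"C1": 0.7, "C2": 0.7},
            "P2": {"C1": 0.4, "C2": 0.6},
            "P3": {"C1": 0.0, "C2": 0.0},
        }, remote={"P3"})
        pl = patient_level(m)
        assert list(pl.index) == ["P1", "P2"]
        assert pl["P1"] == pytest.approx(0.7)
        assert pl["P2"] == pytest.approx(0.5)
        assert len(patient_level(m, include_remote=True)) == 3

    def test_connectome_level_grand_mean_and_sd(self):
        m = matrix_from({
            "P1": {"C1": 0.4, "C2": 0.6},
            "P2": {"C1": 0.6, "C2": 0.8},
        })
        means, grand, sd = connectome_level(m)
        assert means["C1"] == pytest.approx(0.5)
        assert means["C2"] == pytest.approx(0.7)
        assert grand == pytest.approx(0.6)
        assert sd == pytest.approx(np.sqrt(((0.5 - 0.6) ** 2 + (0.7 - 0.6) ** 2)),
                                   abs=1e-9)  # sample SD of {0.5, 0.7} = 0.1414

    def test_build_matrix_equals_brute_force_double_loop(self, grid):
        patients = []
        for i, disp in enumerate([(6, 0, 0), (0, 6, 0)]):
            ini, rec = generate_lesion_pair(grid, (0.5, 0.5, 0.5), (5, 5, 5),
                                            disp, 1.1, patient_id=f"P{i}")
            patients.append((f"P{i}", ini, rec))
        connectomes = [
            ("C0", generate_orientation_field(grid, (1, 0, 0), 0, 0.8, 0)),
            ("C1", generate_orientation_field(grid, (0, 1, 0), 0, 0.8, 1)),
        ]
        params = TrackingParams(target_count=30, max_seed_attempts=2000, rng_seed=5)
        m = build_macc_matrix(patients, connectomes, params, "abs_cosine")

        root = np.random.SeedSequence(params.rng_seed)
        pair_seeds = root.spawn(4)
        import dataclasses
        for i, (pid, ini, rec) in enumerate(patients):
            pv = progression_vector(ini, rec)
            for j, (cid, field) in enumerate(connectomes):
                pp = dataclasses.replace(params, rng_seed=pair_seeds[i * 2 + j])
                expected = compute_macc(pv, track(field, ini, rec, pp), "abs_cosine")
                assert m.values.loc[pid, cid] == expected.value
                assert m.streamline_counts.loc[pid, cid] == expected.n_streamlines


class TestOneSampleTest:
    def test_derived_three_value_example(self):
        res = one_sample_test([0.5, 0.6, 0.7], null_mean=0.0)
        assert res.t_stat == pytest.approx(10.3923, abs=1e-4)
        assert res.df == 2
        # closed form for df = 2: p = 1 - t / sqrt(2 + t^2)
        assert res.p_two_sided == pytest.approx(
            1 - res.t_stat / np.sqrt(2 + res.t_stat**2), abs=1e-9)
        assert res.p_two_sided == pytest.approx(0.0091326, abs=5e-6)
        assert (res.ci95_low, res.ci95_high) == (
            pytest.approx(0.3516, abs=1e-4), pytest.approx(0.8484, abs=1e-4))
        assert res.cohens_d == pytest.approx(6.0, abs=1e-9)

    def test_symmetric_sample_about_null(self):
        res = one_sample_test([0.4, 0.6], null_mean=0.5)
        assert res.t_stat == pytest.approx(0.0, abs=1e-12)
        assert res.p_two_sided == pytest.approx(1.0, abs=1e-12)

    def test_matches_scipy_on_random_samples(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n = int(rng.integers(3, 40))
            x = rng.normal(rng.uniform(-1, 1), rng.uniform(0.1, 2), size=n)
            null = float(rng.uniform(-0.5, 0.5))
            res = one_sample_test(x, null_mean=null)
            t_ref, p_ref = sps.ttest_1samp(x, null)
            assert res.t_stat == pytest.approx(float(t_ref), abs=1e-9)
            assert res.p_two_sided == pytest.approx(float(p_ref), abs=1e-9)
            lo, hi = sps.t.interval(0.95, n - 1, loc=x.mean(),
                                    scale=x.std(ddof=1) / np.sqrt(n))
            assert res.ci95_low == pytest.approx(float(lo), abs=1e-9)
            assert res.ci95_high == pytest.approx(float(hi), abs=1e-9)

    def test_insufficient_data_rejected(self):
        with pytest.raises(InsufficientDataError):
            one_sample_test([0.5])
        with pytest.raises(InsufficientDataError):
            one_sample_test([0.5, 0.5, 0.5], null_mean=0.5)

    def test_constant_sample_away_from_null_is_decisive(self):
        res = one_sample_test([1.0, 1.0, 1.0], null_mean=0.0)
        assert res.t_stat == np.inf
        assert res.p_two_sided == 0.0


class TestChanceLevel:
    def test_abs_cosine_expectation_half(self):
        mean, sd = chance_level("abs_cosine", n_draws=200_000, rng_seed=0)
        assert mean == pytest.approx(0.5, abs=0.005)

    def test_abs_pearson_expectation_two_over_pi(self):
        mean, sd = chance_level("abs_pearson", n_draws=200_000, rng_seed=0)
        assert mean == pytest.approx(2 / np.pi, abs=0.005)

    def test_deterministic(self):
        assert chance_level("abs_cosine", 10_000, 7) == \
            chance_level("abs_cosine", 10_000, 7)
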