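import numpy as np
import pytest
from scipy import stats

from dynmesh import preprocessing as prep
from dynmesh.io_core import LabeledVoxelSeries, Parcellation, ValidationError
from oracles import bf_pearson


def voxel_series(data, labels, puzzle_ids=None):
    data = np.asarray(data, dtype=float)
    vs = LabeledVoxelSeries(data=data, grid_shape=(data.shape[0], 1, 1))
    vs.labels = np.asarray(labels, dtype=object)
    vs.puzzle_ids = (
        np.asarray(puzzle_ids) if puzzle_ids is not None else np.zeros(data.shape[1], int)
    )
    return vs


def region_series(values, labels, puzzle_ids=None):
    values = np.asarray(values, dtype=float)
    T = values.shape[1]
    return prep.RegionSeries(
        values=values,
        labels=np.asarray(labels, dtype=object),
        puzzle_ids=np.asarray(puzzle_ids) if puzzle_ids is not None else np.zeros(T, int),
        measured_mask=np.ones(T, bool),
        z=0,
        active_regions=np.ones(values.shape[0], bool),
        selected_sets=[np.array([j]) for j in range(values.shape[0])],
        region_ids=np.arange(1, values.shape[0] + 1),
    )


LABELS_2x2 = np.array(["planning"] * 2 + ["execution"] * 2, dtype=object)
LABELS_3x3 = np.array(["planning"] * 3 + ["execution"] * 3, dtype=object)


class TestFScores:
    def test_equal_group_means_score_zero(self):
        t = prep.compute_f_scores(voxel_series([[1, 2, 2, 1]], LABELS_2x2))
        assert t.f_score[0] == 0.0

    def test_separated_groups_match_hand_evaluation(self):
        t = prep.compute_f_scores(voxel_series([[1, 2, 3, 4, 5, 6]], LABELS_3x3))
        assert t.f_score[0] == pytest.approx(13.5)
        assert (t.df_between, t.df_within) == (1, 4)

    def test_rest_volumes_excluded(self):
        labels = np.array(["planning"] * 3 + ["execution"] * 3 + ["rest"] * 4, dtype=object)
        data = [[1, 2, 3, 4, 5, 6, 100, -100, 100, -100]]
        t = prep.compute_f_scores(voxel_series(data, labels))
        assert t.f_score[0] == pytest.approx(13.5)

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_textbook_anova(self, seed):
        """The ratio-of-mean-squares computation equals a standard one-way
        ANOVA F statistic on random fixtures."""
        rng = np.random.default_rng(seed)
        n_p, n_e = rng.integers(3, 30, size=2)
        labels = np.array(["planning"] * n_p + ["execution"] * n_e, dtype=object)
        data = rng.normal(size=(15, n_p + n_e))
        t = prep.compute_f_scores(voxel_series(data, labels))
        for v in range(data.shape[0]):
            f_ref = stats.f_oneway(data[v, :n_p], data[v, n_p:]).statistic
            assert t.f_score[v] == pytest.approx(f_ref, rel=1e-10)

    def test_tiny_group_rejected(self):
        labels = np.array(["planning", "execution", "execution"], dtype=object)
        with pytest.raises(ValidationError):
            prep.compute_f_scores(voxel_series([[1, 2, 3]], labels))

    def test_constant_voxel_flagged_infinite(self):
        t = prep.compute_f_scores(voxel_series([[1, 1, 2, 2]], LABELS_2x2))
        assert np.isinf(t.f_score[0]) and t.flagged[0]


class TestVoxelSelection:
    def _scores(self, values):
        values = np.asarray(values, dtype=float)
        return prep.VoxelScoreTable(
            f_score=values, msb=values, msw=np.ones_like(values),
            df_between=1, df_within=4, flagged=np.zeros(values.size, bool),
        )

    def test_keep_all_selects_everything(self):
        mask = prep.select_voxels(self._scores([3.0, 1.0, 2.0]), n_keep=None)
        assert mask.all()

    def test_top_two_of_forced_ordering(self):
        mask = prep.select_voxels(self._scores([10, 9, 1, 0.5]), n_keep=2)
        np.testing.assert_array_equal(mask, [True, True, False, False])

    def test_elbow_finds_breakpoint_of_joined_segments(self):
        steep = np.linspace(100, 10, 21)
        flat = np.linspace(10, 9, 80)[1:]
        curve = np.concatenate([steep, flat])
        assert prep.elbow_index(curve) == 20
        mask = prep.select_voxels(self._scores(curve), mode="elbow")
        assert mask.sum() == 21

    def test_selection_monotone_in_n_keep(self):
        rng = np.random.default_rng(0)
        scores = rng.random(200)
        prev = np.zeros(200, bool)
        for n in (10, 50, 120, 200):
            mask = prep.select_voxels(self._scores(scores.copy()), n_keep=n)
            assert np.all(mask[prev])  # previously selected voxels stay selected
            prev = mask

    def test_cerebellar_voxels_never_selected(self):
        parc = Parcellation(
            region_ids=np.array([1, 2]), names=["a", "cereb"],
            cerebellum_flags=np.array([False, True]),
            voxel_labels=np.array([1, 2, 2, 1]),
        )
        mask = prep.select_voxels(self._scores([1.0, 99.0, 99.0, 2.0]), n_keep=2, parcellation=parc)
        np.testing.assert_array_equal(mask, [True, False, False, True])

    def test_oversized_request_keeps_all_and_warns(self):
        with pytest.warns(UserWarning):
            mask = prep.select_voxels(self._scores([1.0, 2.0]), n_keep=10)
        assert mask.all()


class TestRegionAveraging:
    def _parc(self):
        return Parcellation(
            region_ids=np.array([1, 2, 3]), names=["r1", "r2", "r3"],
            cerebellum_flags=np.zeros(3, bool),
            voxel_labels=np.array([1, 2, 2, 3]),
        )

    def test_single_voxel_region_copies_series(self):
        vs = voxel_series([[1, 2, 3, 4]] * 4, LABELS_2x2)
        mask = np.array([True, True, True, False])
        series = prep.average_regions(vs, mask, self._parc())
        np.testing.assert_array_equal(series.values[0], [1, 2, 3, 4])

    def test_two_voxel_mean(self):
        vs = voxel_series([[0, 0, 0, 0], [1, 3, 1, 3], [3, 5, 3, 5], [0, 0, 0, 0]], LABELS_2x2)
        series = prep.average_regions(vs, np.ones(4, bool), self._parc())
        np.testing.assert_array_equal(series.values[1], [2, 4, 2, 4])

    def test_empty_region_zero_row_inactive(self):
        vs = voxel_series([[1, 1, 1, 1]] * 4, LABELS_2x2)
        mask = np.array([True, True, True, False])  # region 3 contributes nothing
        series = prep.average_regions(vs, mask, self._parc())
        assert not series.active_regions[2]
        np.testing.assert_array_equal(series.values[2], 0)


class TestRegionSummary:
    def test_one_subject_zero_variance(self):
        s = region_series([[1.0, 3.0]], ["planning", "execution"])
        table = prep.region_summary([s])
        assert table["var_activation"].iloc[0] == 0.0

    def test_two_subject_population_moments(self):
        a = region_series([[1.0, 1.0]], LABELS_2x2[:2])
        b = region_series([[3.0, 3.0]], LABELS_2x2[:2])
        table = prep.region_summary([a, b])
        assert table["mean_activation"].iloc[0] == pytest.approx(2.0)
        assert table["var_activation"].iloc[0] == pytest.approx(1.0)

    def test_matches_direct_recomputation(self, small_study, small_parcellation):
        voxels, events, _ = small_study
        runs = []
        for key, vox in voxels.items():
            vox.attach_events(events[key])
            scores = prep.compute_f_scores(vox)
            mask = prep.select_voxels(scores, n_keep=40, parcellation=small_parcellation)
            runs.append(prep.average_regions(vox, mask, small_parcellation))
        table = prep.region_summary(runs, small_parcellation)
        means = np.stack([r.values.mean(axis=1) for r in runs])
        np.testing.assert_allclose(table["mean_activation"], means.mean(axis=0))
        np.testing.assert_allclose(table["var_activation"], means.var(axis=0))


class TestInterpolation:
    def test_segment_length_and_knot_fidelity(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(2, 3))
        s = region_series(vals, ["planning", "planning", "execution"])
        out = prep.interpolate(s, z=8)
        assert out.n_columns == 3 + 8 * 2  # n + z*(n-1) = 19
        np.testing.assert_allclose(out.values[:, out.measured_mask], vals, rtol=0, atol=1e-12)

    def test_splines_do_not_cross_rest_gaps(self):
        labels = ["planning", "execution", "rest", "planning", "execution"]
        pids = [0, 0, -1, 1, 1]
        vals = np.arange(10, dtype=float).reshape(2, 5)
        out = prep.interpolate(region_series(vals, labels, pids), z=2)
        # two 2-column segments -> 4 columns each, one untouched rest column
        assert out.n_columns == 4 + 1 + 4
        assert out.labels[4] == "rest" and out.measured_mask[4]

    def test_single_volume_segment_passes_through_with_warning(self):
        labels = ["planning", "rest"]
        with pytest.warns(UserWarning):
            out = prep.interpolate(region_series([[1.0, 9.0]], labels, [0, -1]), z=4)
        assert out.n_columns == 2

    def test_sinusoid_dominant_frequency_preserved(self):
        """Upsampling must not move the dominant bin of the amplitude spectrum."""
        t = np.arange(64, dtype=float)
        sig = np.sin(2 * np.pi * 0.1 * t)
        s = region_series(sig[None, :], ["planning"] * 32 + ["execution"] * 32)
        f0 = prep.dominant_frequency(sig, fs=1.0)
        out = prep.interpolate(s, z=8)
        f1 = prep.dominant_frequency(out.values[0], fs=9.0)
        assert f1 == pytest.approx(f0, abs=0.01)

    def test_spectrum_survives_default_noise(self):
        t = np.arange(64, dtype=float)
        sig = np.sin(2 * np.pi * 0.1 * t)
        s = region_series(sig[None, :], ["planning"] * 32 + ["execution"] * 32)
        out = prep.interpolate(s, z=8)
        out = prep.assign_interpolated_labels(out)
        out = prep.inject_noise(out, prep.NoiseConfig(seed=0))
        assert prep.dominant_frequency(out.values[0], fs=9.0) == pytest.approx(0.1, abs=0.01)


class TestLabelAssignment:
    def test_nearest_neighbor_offsets(self):
        labels = ["planning", "execution"]
        s = prep.interpolate(region_series([[0.0, 1.0]], labels), z=8)
        s = prep.assign_interpolated_labels(s)
        # offsets 1-4 inherit the left (planning) label, 5-8 the right
        assert list(s.labels[1:5]) == ["planning"] * 4
        assert list(s.labels[5:9]) == ["execution"] * 4

    def test_counts_match_exhaustive_enumeration(self):
        labels = ["planning", "planning", "execution", "rest", "planning", "execution", "execution"]
        pids = [0, 0, 0, -1, 1, 1, 1]
        vals = np.arange(7, dtype=float)[None, :]
        z = 8
        s = prep.assign_interpolated_labels(prep.interpolate(region_series(vals, labels, pids), z))
        expected = {"planning": 0, "execution": 0, "rest": 0}
        for seg in ([0, 0, 1], [0, 1, 1]):  # 0=planning, 1=execution per measured volume
            names = ["planning", "execution"]
            for i in range(len(seg) - 1):
                expected[names[seg[i]]] += 1 + z // 2  # knot + left-inheriting offsets
                expected[names[seg[i + 1]]] += z // 2
            expected[names[seg[-1]]] += 1
        expected["rest"] += 1
        counts = {k: int((s.labels == k).sum()) for k in expected}
        assert counts == expected


class TestNoise:
    def test_zero_factors_leave_series_unchanged(self):
        s = region_series([[1.0, 2.0, 3.0, 4.0]], LABELS_2x2)
        before = s.values.copy()
        prep.inject_noise(s, prep.NoiseConfig(alpha_noise=0, beta_noise=0, seed=0))
        np.testing.assert_array_equal(s.values, before)

    def test_moments_match_region_statistics(self):
        """Across 1e5 noise samples the empirical mean is within 3 standard
        errors of alpha * mu_j under the default scaling factors."""
        rng = np.random.default_rng(2)
        T = 100_000
        vals = rng.normal(loc=10.0, scale=2.0, size=(1, T))
        labels = np.array(["planning"] * (T // 2) + ["execution"] * (T - T // 2), dtype=object)
        s = region_series(vals, labels)
        cfg = prep.NoiseConfig(seed=3)  # alpha 0.025, beta 0.075
        mu, var = vals.mean(), vals.var()
        before = vals.copy()
        prep.inject_noise(s, cfg)
        noise = s.values - before
        se = np.sqrt(cfg.beta_noise * var / T)
        assert abs(noise.mean() - cfg.alpha_noise * mu) < 3 * se
        assert noise.var() == pytest.approx(cfg.beta_noise * var, rel=0.05)

    def test_inactive_regions_untouched(self):
        s = region_series([[1.0, 2, 3, 4], [0, 0, 0, 0]], LABELS_2x2)
        s.active_regions[1] = False
        prep.inject_noise(s, prep.NoiseConfig(seed=0))
        np.testing.assert_array_equal(s.values[1], 0)


class TestWindowCorrelationOracle:
    def test_pearson_helper_matches_covariance_formula(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 50))
        assert bf_pearson(x, y) == pytest.approx(np.corrcoef(x, y)[0, 1], rel=1e-12)
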