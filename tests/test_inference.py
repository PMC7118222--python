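"""Group GLM, smoothness/resels, GRF cluster correction, permutation null,
cluster features and the small descriptive statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats
from scipy.ndimage import gaussian_filter

from nethom import inference as inf


def smooth_maps(n, mask, fwhm_vox=2.0, seed=0):
    sigma = fwhm_vox / np.sqrt(8 * np.log(2))
    vols = gaussian_filter(
        np.random.default_rng(seed).standard_normal((n,) + mask.shape),
        (0, sigma, sigma, sigma))
    return vols[:, mask]


@pytest.fixture(scope="module")
def box_mask():
    mask = np.zeros((16, 18, 16), bool)
    mask[2:14, 3:15, 2:14] = True
    return mask


class TestGLM:
    def test_matches_per_voxel_regression_oracle(self):
        rng = np.random.default_rng(0)
        n, v = 25, 40
        x = np.column_stack([np.ones(n), rng.integers(0, 2, n),
                             rng.standard_normal(n)])
        c = np.array([0.0, 1.0, 0.0])
        y = rng.standard_normal((n, v))
        t, resid, dof = inf.fit_voxelwise_glm(y, x, c)
        assert dof == n - 3
        xtx_inv = np.linalg.inv(x.T @ x)
        for j in range(v):
            beta = np.linalg.lstsq(x, y[:, j], rcond=None)[0]
            rj = y[:, j] - x @ beta
            se = np.sqrt(rj @ rj / dof * (c @ xtx_inv @ c))
            assert abs(t[j] - (c @ beta) / se) < 1e-8

    def test_identical_groups_t_near_zero(self):
        rng = np.random.default_rng(1)
        half = rng.standard_normal((10, 30))
        y = np.vstack([half, half])
        x = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        t, _, _ = inf.fit_voxelwise_glm(y, x, np.array([0.0, 1.0]))
        assert np.abs(t).max() < 1e-6

    def test_covariate_absorbs_confounded_group_difference(self):
        """When a covariate fully explains the group shift, T collapses."""
        rng = np.random.default_rng(2)
        n = 30
        group = np.r_[np.zeros(n // 2), np.ones(n // 2)]
        cov = 2.0 * group + 0.3 * rng.standard_normal(n)
        # the signal follows the covariate, not the group label itself
        y = cov[:, None] * 0.75 + 0.1 * rng.standard_normal((n, 20))
        x_plain = np.column_stack([np.ones(n), group])
        x_adj = np.column_stack([np.ones(n), group, cov - cov.mean()])
        t_plain, _, _ = inf.fit_voxelwise_glm(y, x_plain, np.array([0, 1.0]))
        t_adj, _, _ = inf.fit_voxelwise_glm(y, x_adj, np.array([0, 1.0, 0]))
        assert np.abs(t_plain).min() > 10
        assert np.abs(t_adj).max() < np.abs(t_plain).min()

    def test_no_residual_dof_errors(self):
        with pytest.raises(ValueError):
            inf.fit_voxelwise_glm(np.zeros((2, 5)), np.eye(2), np.array([1.0, 0]))


class TestInteraction:
    def test_f_equals_t_squared_and_matches_ttest(self):
        rng = np.random.default_rng(3)
        diff = rng.standard_normal((24, 15))
        arm = np.r_[np.zeros(12), np.ones(12)]
        x = np.column_stack([np.ones(24), arm])
        f, t, _, dof = inf.interaction_f(diff, x, np.array([0.0, 1.0]))
        assert np.allclose(f, t**2)
        t_sp = stats.ttest_ind(diff[12:], diff[:12], axis=0)
        assert np.allclose(np.abs(t), np.abs(t_sp.statistic), atol=1e-10)

    def test_equal_arm_effects_give_null_f(self):
        """When both arms share the same within-subject change, the
        interaction F stays in its null range."""
        rng = np.random.default_rng(4)
        shared_effect = rng.standard_normal(15)
        diff = np.tile(shared_effect, (20, 1)) + 0.2 * rng.standard_normal((20, 15))
        x = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        f, _, _, dof = inf.interaction_f(diff, x, np.array([0.0, 1.0]))
        assert f.max() < stats.f.isf(1e-4, 1, dof)


class TestSmoothness:
    def test_white_noise_fwhm_near_voxel_size(self, box_mask):
        ests = []
        for seed in range(20):
            y = np.random.default_rng(seed).standard_normal((15, box_mask.sum()))
            sm = inf.estimate_smoothness(y, box_mask, voxel_size_mm=3.0)
            ests.append(sm.fwhm_mm.mean())
        assert abs(np.mean(ests) - 3.0) / 3.0 < 0.2

    def test_smoothed_noise_fwhm_recovered(self, box_mask):
        ests = []
        for seed in range(10):
            y = smooth_maps(15, box_mask, fwhm_vox=2.0, seed=seed)
            sm = inf.estimate_smoothness(y, box_mask, voxel_size_mm=3.0)
            ests.append(sm.fwhm_mm.mean())
        assert abs(np.mean(ests) - 6.0) / 6.0 < 0.2

    def test_scale_invariance(self, box_mask):
        y = smooth_maps(12, box_mask, seed=5)
        a = inf.estimate_smoothness(y, box_mask)
        b = inf.estimate_smoothness(2.0 * y, box_mask)
        assert np.allclose(a.fwhm_voxels, b.fwhm_voxels)

    def test_preconditions(self, box_mask):
        with pytest.raises(ValueError, match="residual maps"):
            inf.estimate_smoothness(np.zeros((5, box_mask.sum())), box_mask)
        small = np.zeros((4, 4, 4), bool)
        small[:2, :2, :2] = True
        with pytest.raises(ValueError, match="mask"):
            inf.estimate_smoothness(np.zeros((12, 8)), small)


class TestResels:
    def test_cuboid_counts_analytic(self):
        """For a full a x b x c box at FWHM 1 voxel the counting scheme gives
        the Adler resel polynomial of the cuboid."""
        mask = np.zeros((10, 11, 12), bool)
        mask[1:5, 2:7, 3:9] = True  # 4 x 5 x 6 box
        r = inf.resel_counts(mask, np.ones(3))
        a, b, c = 3, 4, 5  # box side lengths in edge units
        assert r[3] == a * b * c
        assert r[2] == a * b + a * c + b * c
        assert r[1] == a + b + c
        assert r[0] == 1

    def test_fwhm_scaling(self):
        mask = np.zeros((8, 8, 8), bool)
        mask[1:7, 1:7, 1:7] = True
        r1 = inf.resel_counts(mask, np.ones(3))
        r2 = inf.resel_counts(mask, np.full(3, 2.0))
        assert np.isclose(r2[3], r1[3] / 8)
        assert np.isclose(r2[1], r1[1] / 2)


def flood_fill_sizes(binary):
    """Exhaustive BFS 26-connectivity labelling oracle."""
    binary = np.asarray(binary, bool)
    seen = np.zeros_like(binary)
    sizes = []
    coords = list(zip(*np.nonzero(binary)))
    coordset = set(coords)
    for start in coords:
        if seen[start]:
            continue
        stack, size = [start], 0
        seen[start] = True
        while stack:
            cur = stack.pop()
            size += 1
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for dz in (-1, 0, 1):
                        nb = (cur[0] + dx, cur[1] + dy, cur[2] + dz)
                        if nb in coordset and not seen[nb]:
                            seen[nb] = True
                            stack.append(nb)
        sizes.append(size)
    return sorted(sizes)


class TestClusterLabeling:
    @pytest.mark.parametrize("seed", range(5))
    def test_agrees_with_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        binary = rng.random((8, 9, 7)) < 0.25
        labels, n = inf.label_clusters(binary)
        sizes = sorted(np.bincount(labels.ravel())[1:].tolist())
        assert sizes == flood_fill_sizes(binary)
        assert n == len(sizes)


class TestGRF:
    def _fit(self, y, mask, seed=0, signal=None):
        n = y.shape[0]
        rng = np.random.default_rng(seed)
        x = np.column_stack([np.ones(n), np.r_[np.zeros(n // 2), np.ones(n // 2)],
                             rng.standard_normal(n)])
        c = np.array([0.0, 1.0, 0.0])
        t, resid, dof = inf.fit_voxelwise_glm(y, x, c)
        sm = inf.estimate_smoothness(resid, mask)
        return inf.StatMap(t, mask, "T", dof), sm, (y, x, c)

    def test_planted_effect_detected_with_overlap(self, box_mask):
        rng = np.random.default_rng(10)
        y = smooth_maps(40, box_mask, seed=11)
        effect = np.zeros(box_mask.shape)
        blob = np.zeros_like(box_mask)
        blob[6:9, 7:10, 6:9] = True  # 27-voxel planted effect
        effect[blob] = 1.5
        y[20:] += effect[box_mask]
        stat, sm, _ = self._fit(y, box_mask)
        table, labels = inf.grf_cluster_correct(stat, sm)
        assert len(table) >= 1
        from nethom.ica import dice
        assert dice(labels > 0, blob) >= 0.5

    def test_cluster_count_monotone_in_voxel_p(self, box_mask):
        y = smooth_maps(40, box_mask, seed=12)
        y[20:] += 0.8  # diffuse shift creates several clusters
        stat, sm, _ = self._fit(y, box_mask)
        counts = [len(inf.grf_cluster_correct(stat, sm, voxel_p=p,
                                              cluster_p=1.0)[0])
                  for p in (0.01, 0.001, 0.0001)]
        assert counts[0] >= counts[1] >= counts[2]

    def test_corrected_p_below_cluster_p_for_reported_rows(self, box_mask):
        y = smooth_maps(40, box_mask, seed=13)
        y[20:, :50] += 2.0
        stat, sm, _ = self._fit(y, box_mask)
        table, _ = inf.grf_cluster_correct(stat, sm)
        assert (table.corrected_p < 0.05).all()

    def test_resels_positive_required(self, box_mask):
        stat = inf.StatMap(np.zeros(box_mask.sum()), box_mask, "T", 30)
        bad = inf.SmoothnessEstimate(np.ones(3), np.full(3, 3.0), 0.0)
        with pytest.raises(ValueError, match="resel"):
            inf.grf_cluster_correct(stat, bad)


class TestPermutationNull:
    def test_seed_determinism(self, box_mask):
        y = smooth_maps(20, box_mask, seed=20)
        x = np.column_stack([np.ones(20), np.r_[np.zeros(10), np.ones(10)]])
        c = np.array([0.0, 1.0])
        a, _ = inf.permutation_cluster_null(y, x, c, box_mask, n_perm=60, seed=4)
        b, _ = inf.permutation_cluster_null(y, x, c, box_mask, n_perm=60, seed=4)
        assert np.array_equal(a, b)

    def test_planted_signal_beats_null_percentile(self, box_mask):
        y = smooth_maps(30, box_mask, seed=21)
        y[15:, :60] += 1.5
        x = np.column_stack([np.ones(30), np.r_[np.zeros(15), np.ones(15)]])
        c = np.array([0.0, 1.0])
        t, _, dof = inf.fit_voxelwise_glm(y, x, c)
        thr = stats.t.isf(0.001, dof)
        vol = np.zeros(box_mask.shape)
        vol[box_mask] = t
        labels, n = inf.label_clusters((vol > thr) & box_mask)
        observed = np.bincount(labels.ravel())[1:].max()
        _, p95 = inf.permutation_cluster_null(y, x, c, box_mask,
                                              n_perm=200, seed=5)
        assert observed > p95


class TestClusterMeans:
    def _maps(self):
        from nethom.homogeneity import NHMap
        mask = np.ones((3, 3, 3), bool)
        rng = np.random.default_rng(6)
        return mask, [NHMap(rng.standard_normal(27), mask, f"s{i}", "baseline",
                            np.eye(4)) for i in range(3)]

    def test_single_voxel_cluster_equals_voxel_value(self):
        mask, maps = self._maps()
        labels = np.zeros((3, 3, 3), int)
        labels[1, 1, 1] = 1
        out = inf.extract_cluster_means(maps, labels)
        for m, row in zip(maps, out.itertuples()):
            assert np.isclose(row.mean_nh, m.to_volume()[1, 1, 1])

    def test_uniform_map_gives_constant_feature(self):
        from nethom.homogeneity import NHMap
        mask = np.ones((3, 3, 3), bool)
        m = NHMap(np.full(27, 0.37), mask, "s", "baseline", np.eye(4))
        labels = np.zeros((3, 3, 3), int)
        labels[0, :, :] = 1
        labels[2, :, :] = 2
        out = inf.extract_cluster_means([m], labels)
        assert np.allclose(out.mean_nh, 0.37)

    def test_empty_label_volume_errors(self):
        _, maps = self._maps()
        with pytest.raises(ValueError, match="cluster"):
            inf.extract_cluster_means(maps, np.zeros((3, 3, 3), int))


class TestPearson:
    def test_exact_linear_relation(self):
        x = np.arange(10.0)
        r, p = inf.pearson_corr(x, 2 * x + 1)
        assert np.isclose(r, 1.0)
        assert p < 1e-12

    def test_reported_correlation_shape_consistent(self):
        """r = -0.503 at n = 19 gives p ~= 0.028 under the t-transform —
        the formula reproduces the printed significance."""
        r = -0.503
        n = 19
        t = r * np.sqrt((n - 2) / (1 - r**2))
        p = 2 * stats.t.sf(abs(t), n - 2)
        assert round(p, 3) == 0.028
        assert p < 0.05

    def test_null_rejection_rate_near_alpha(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(20)
        hits = 0
        reps = 1000
        for _ in range(reps):
            _, p = inf.pearson_corr(x, rng.permutation(x))
            hits += p < 0.05
        assert 0.03 < hits / reps < 0.07

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError, match="variance"):
            inf.pearson_corr(np.ones(10), np.arange(10.0))


class TestChiSquare:
    def test_printed_sex_table(self):
        stat, dof, p = inf.chi_square_contingency([[12, 15, 14], [7, 5, 6]])
        assert round(stat, 3) == 0.648
        assert dof == 2
        assert round(p, 3) == 0.723

    def test_identical_proportions_zero(self):
        stat, _, _ = inf.chi_square_contingency([[10, 20, 30], [5, 10, 15]])
        assert np.isclose(stat, 0.0)

    def test_perfect_association_2x2(self):
        """Hand computation: all four expected cells are 5, so
        chi2 = 4 * (10-5)^2/5 ... summed = 20."""
        stat, dof, _ = inf.chi_square_contingency([[10, 0], [0, 10]])
        assert np.isclose(stat, 20.0)
        assert dof == 1

    def test_zero_marginal_errors(self):
        with pytest.raises(ValueError, match="marginal"):
            inf.chi_square_contingency([[0, 0], [5, 5]])


def test_make_design_centres_covariates():
    frame = pd.DataFrame({"grp": ["a", "a", "b", "b"],
                          "age": [20.0, 30, 25, 45],
                          "mean_fd": [0.1, 0.2, 0.15, 0.3]})
    x, c, levels = inf.make_design(frame, "grp")
    assert np.allclose(x[:, 2].sum(), 0)
    assert np.allclose(x[:, 3].sum(), 0)
    assert c.tolist() == [0, 1, 0, 0]
    assert levels == ["a", "b"]
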