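"""Two-block PLS, permutation z-scores and major-axis slopes."""

import numpy as np
import pytest

from cardiomorph.covariation import (
    IndeterminateSlopeError,
    individual_covariation,
    major_axis_slope,
    pls_effect_size,
    trajectory_covariation,
    two_block_pls,
)


class TestTwoBlockPls:
    def test_identical_blocks(self, rng):
        a = rng.normal(size=(10, 5))
        res = two_block_pls(a, a)
        assert res.r_pls == pytest.approx(1.0)
        np.testing.assert_allclose(np.abs(res.singular_vectors_A[:, 0]),
                                   np.abs(res.singular_vectors_B[:, 0]),
                                   atol=1e-10)

    def test_rank_one_response_recovery(self, rng):
        """B = t w^T with t the first principal scores of A: the first
        singular pair recovers w and the matching A direction."""
        a = rng.normal(size=(20, 8))
        ac = a - a.mean(axis=0)
        u, s, vt = np.linalg.svd(ac, full_matrices=False)
        t = u[:, 0] * s[0]
        w = rng.normal(size=6)
        w /= np.linalg.norm(w)
        b = np.outer(t, w)
        res = two_block_pls(a, b)
        assert abs(np.dot(res.singular_vectors_B[:, 0], w)) == pytest.approx(1.0)
        assert abs(np.dot(res.singular_vectors_A[:, 0], vt[0])) == pytest.approx(1.0)
        assert res.r_pls == pytest.approx(1.0)
        assert res.pct_covariance == pytest.approx(1.0)

    def test_block_swap_symmetry(self, rng):
        a, b = rng.normal(size=(12, 5)), rng.normal(size=(12, 7))
        r1 = two_block_pls(a, b)
        r2 = two_block_pls(b, a)
        np.testing.assert_allclose(r1.singular_values, r2.singular_values,
                                   atol=1e-10)
        np.testing.assert_allclose(np.abs(r1.singular_vectors_A),
                                   np.abs(r2.singular_vectors_B), atol=1e-8)

    def test_frobenius_conservation(self, rng):
        """Squared singular values sum to the total squared cross-
        covariance (dense cross-covariance oracle)."""
        a, b = rng.normal(size=(15, 6)), rng.normal(size=(15, 9))
        res = two_block_pls(a, b)
        ac = a - a.mean(axis=0)
        bc = b - b.mean(axis=0)
        c = ac.T @ bc / 14
        assert np.sum(res.singular_values ** 2) == pytest.approx(
            np.sum(c ** 2))
        # and the paired-score covariances equal the singular values
        for j in range(min(3, len(res.singular_values))):
            cov = np.cov(res.scores_A[:, j], res.scores_B[:, j], ddof=1)[0, 1]
            assert cov == pytest.approx(res.singular_values[j], abs=1e-10)

    def test_avoids_materializing_large_cross_matrix(self, rng):
        """Shape-sized blocks (p, q >> n) are handled; singular values
        checked against a small-n identity."""
        a = rng.normal(size=(16, 3891))
        b = rng.normal(size=(16, 3891))
        res = two_block_pls(a, b)
        assert res.singular_values.size <= 15
        assert np.all(np.diff(res.singular_values) <= 1e-12)

    def test_too_few_rows(self, rng):
        with pytest.raises(ValueError):
            two_block_pls(rng.normal(size=(2, 4)), rng.normal(size=(2, 4)))


class TestEffectSize:
    def test_signal_gives_large_z(self, rng):
        a = rng.normal(size=(16, 30))
        b = a + 0.1 * rng.normal(size=a.shape)
        z = pls_effect_size(a, b, n_perm=199, seed=1)
        assert z > 3

    def test_null_mean_near_zero(self, rng):
        zs = [pls_effect_size(rng.normal(size=(16, 50)),
                              rng.normal(size=(16, 50)),
                              n_perm=99, seed=i)
              for i in range(40)]
        assert abs(np.mean(zs)) < 0.3

    def test_column_scaling_invariance(self, rng):
        a = rng.normal(size=(14, 6))
        b = a @ rng.normal(size=(6, 6)) + 0.2 * rng.normal(size=(14, 6))
        z1 = pls_effect_size(a, b, n_perm=99, seed=3)
        z2 = pls_effect_size(a * 7.0, b * 0.3, n_perm=99, seed=3)
        assert z1 == pytest.approx(z2, abs=1e-10)

    def test_reproducible(self, rng):
        a, b = rng.normal(size=(12, 5)), rng.normal(size=(12, 5))
        assert pls_effect_size(a, b, 99, 7) == pls_effect_size(a, b, 99, 7)


class TestMajorAxis:
    def test_identity_line(self):
        assert major_axis_slope([0, 1, 2], [0, 1, 2]) == pytest.approx(1.0)

    def test_eigen_decomposition_oracle(self):
        """Sample with exact covariance [[2, 1], [1, 1]]: MA slope equals
        the first-eigenvector slope (sqrt(5) - 1) / 2."""
        # construct a 4-point sample with that exact sample covariance
        chol = np.linalg.cholesky(np.array([[2.0, 1.0], [1.0, 1.0]]))
        zs = np.array([[1.0, 1.0], [1.0, -1.0], [-1.0, 1.0], [-1.0, -1.0]])
        zs /= zs.std(axis=0, ddof=1)
        xy = zs @ chol.T
        slope = major_axis_slope(xy[:, 0], xy[:, 1])
        assert slope == pytest.approx((np.sqrt(5) - 1) / 2)
        # independent eigen oracle
        w, v = np.linalg.eigh(np.cov(xy.T, ddof=1))
        assert slope == pytest.approx(v[1, -1] / v[0, -1])

    def test_reciprocal_symmetry(self, rng):
        x = rng.normal(size=50)
        y = 0.7 * x + 0.3 * rng.normal(size=50)
        assert major_axis_slope(x, y) * major_axis_slope(y, x) == \
            pytest.approx(1.0)

    def test_isotropic_raises(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        with pytest.raises(IndeterminateSlopeError):
            major_axis_slope(x, y)


class TestIndividualCovariation:
    def test_isometric_subject_has_unit_slope(self, small_transport):
        """Generator cohorts plant LA score sequences proportional to the
        LV sequences; here the planted rate is 1.25."""
        zs, slopes = zip(*[
            individual_covariation(small_transport, i, n_perm=99, seed=i)
            for i in range(small_transport.n_subjects)])
        assert np.mean(slopes) == pytest.approx(1.25, abs=0.1)
        assert min(zs) > 2.0

    def test_group_slope_recovery(self, two_group_transport):
        """Planted rates 1.25 (Control-like) and 0.89 (HCM-like) are
        recovered by the per-subject PLS + MA pipeline."""
        ts = two_group_transport
        slopes = {g: [] for g in ("Control", "HCM")}
        for i in range(ts.n_subjects):
            _, sl = individual_covariation(ts, i, compute_z=False)
            slopes[ts.groups[i]].append(sl)
        assert np.mean(slopes["Control"]) == pytest.approx(1.25, abs=0.1)
        assert np.mean(slopes["HCM"]) == pytest.approx(0.89, abs=0.1)

    def test_time_order_invariance(self, small_transport, rng):
        """Jointly permuting the 16 time points of both blocks changes
        neither the z-score nor the MA slope."""
        ts = small_transport
        z1, s1 = individual_covariation(ts, 0, n_perm=499, seed=5)
        perm = rng.permutation(16)
        shuffled = ts.residuals.copy()
        shuffled[0] = shuffled[0][perm]
        from dataclasses import replace
        ts2 = replace(ts, residuals=shuffled)
        z2, s2 = individual_covariation(ts2, 0, n_perm=499, seed=5)
        assert s1 == pytest.approx(s2, abs=1e-10)
        # the observed r is exactly invariant; the permutation null is
        # invariant in law, so z agrees up to its Monte-Carlo error
        assert z1 == pytest.approx(z2, abs=0.75)


def synthetic_trajectories(rng, n, slope=1.0, noise=0.05):
    """Paired LV/LA trajectory shapes from one covariation model."""
    base = np.column_stack([3 * np.cos(2 * np.pi * np.arange(16) / 16),
                            np.sin(2 * np.pi * np.arange(16) / 16),
                            np.zeros(16)])
    lv, la = [], []
    for _ in range(n):
        morph = rng.normal()
        lv.append(base + morph * 0.3 * np.eye(16, 3)
                  + noise * rng.normal(size=(16, 3)))
        la.append(base + slope * morph * 0.3 * np.eye(16, 3)
                  + noise * rng.normal(size=(16, 3)))
    return lv, la


class TestTrajectoryCovariation:
    def test_equal_trajectories(self, rng):
        lv, la = synthetic_trajectories(rng, 12, noise=0.02)
        la = [x.copy() for x in lv]
        groups = ["A"] * 6 + ["B"] * 6
        res = trajectory_covariation(lv, la, groups, n_perm=49,
                                     inner_perm=49, seed=0)
        for g in ("A", "B"):
            assert res.z_by_group[g] > 2
            assert res.slope_by_group[g] == pytest.approx(1.0, abs=1e-6)

    def test_rank_one_model_has_high_pct_covariance(self, rng):
        lv, la = synthetic_trajectories(rng, 12, noise=0.001)
        groups = ["A"] * 6 + ["B"] * 6
        res = trajectory_covariation(lv, la, groups, n_perm=19,
                                     inner_perm=19, seed=0)
        assert min(res.pct_covariance_by_group.values()) >= 0.9

    def test_null_slope_difference_rarely_significant(self, rng):
        """Both groups from one covariation model: the slope-difference
        permutation p exceeds 0.05 in at least 90% of seeded runs."""
        hits = 0
        n_runs = 40
        for run in range(n_runs):
            r = np.random.default_rng(1000 + run)
            lv, la = synthetic_trajectories(r, 14, slope=1.1, noise=0.05)
            groups = ["A"] * 7 + ["B"] * 7
            res = trajectory_covariation(lv, la, groups, n_perm=99,
                                         inner_perm=0 or 19, seed=run,
                                         test_z=False)
            if res.slope_difference_p > 0.05:
                hits += 1
        assert hits >= 0.9 * n_runs

    def test_small_group_rejected(self, rng):
        lv, la = synthetic_trajectories(rng, 5)
        with pytest.raises(ValueError):
            trajectory_covariation(lv, la, ["A"] * 2 + ["B"] * 3, 9, 0)
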