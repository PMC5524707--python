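"""Procrustes primitives: centroid size, OPA, GPA, distances, tangent maps."""

import numpy as np
import pytest

from cardiomorph.core import (
    DegenerateConfigurationError,
    ShapeMismatchError,
    centroid_size,
    gpa,
    opa_align,
    preshape,
    procrustes_distance,
    tangent_project,
    tangent_unproject,
)


def rotation_z(theta):
    c, s = np.cos(theta), np.sin(theta)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


def random_config(rng, k=10, m=3):
    return rng.normal(size=(k, m))


EQUILATERAL = np.array([[0.0, 1.0], [np.sqrt(3) / 2, -0.5],
                        [-np.sqrt(3) / 2, -0.5]])


class TestCentroidSize:
    def test_four_planar_points(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8))

    def test_homogeneous_under_scaling(self, rng):
        x = random_config(rng)
        assert centroid_size(3 * x) == pytest.approx(3 * centroid_size(x))

    def test_unit_after_normalization(self, rng):
        x = random_config(rng, 20)
        assert centroid_size(preshape(x)) == pytest.approx(1.0)

    def test_degenerate_raises(self):
        with pytest.raises(DegenerateConfigurationError):
            centroid_size(np.ones((5, 3)))


class TestOPA:
    def test_exact_rotation_recovery(self, rng):
        target = random_config(rng)
        rot = rotation_z(np.pi / 2)
        source = target @ rot.T
        res = opa_align(source, target)
        assert res.residual == pytest.approx(0, abs=1e-10)
        # recovered rotation undoes the applied one
        np.testing.assert_allclose(res.rotation, rot, atol=1e-10)
        np.testing.assert_allclose(res.aligned, target, atol=1e-10)

    def test_scale_recovery(self, rng):
        target = random_config(rng)
        res = opa_align(2 * target, target, allow_scaling=True)
        assert res.scale == pytest.approx(0.5)
        assert res.residual == pytest.approx(0, abs=1e-10)

    def test_residual_matches_rotation_grid_search(self, rng):
        """OPA residual equals the minimum over a dense grid of rotations."""
        x = random_config(rng)
        y = random_config(rng)
        res = opa_align(x, y)
        xc = x - x.mean(axis=0)
        yc = y - y.mean(axis=0)
        # brute force over ZYZ Euler angles
        n = 40
        best = np.inf
        alphas = np.linspace(0, 2 * np.pi, n, endpoint=False)
        betas = np.linspace(0, np.pi, n)
        for a in alphas:
            for b in betas:
                rab = rotation_z(a) @ np.array(
                    [[np.cos(b), 0, np.sin(b)], [0, 1, 0],
                     [-np.sin(b), 0, np.cos(b)]])
                for g in alphas:
                    r = rab @ rotation_z(g)
                    d = np.sqrt(np.sum((xc @ r - yc) ** 2))
                    if d < best:
                        best = d
        assert res.residual <= best + 1e-9
        assert res.residual == pytest.approx(best, rel=1e-2)

    def test_mismatched_k_raises(self, rng):
        with pytest.raises(ShapeMismatchError):
            opa_align(random_config(rng, 5), random_config(rng, 6))


class TestGPA:
    def test_rigid_copies_collapse(self, rng):
        x = random_config(rng)
        configs = [x @ rotation_z(t) + rng.normal(size=3)
                   for t in rng.uniform(0, 2 * np.pi, 5)]
        res = gpa(configs, space="size_and_shape")
        for al in res.aligned:
            np.testing.assert_allclose(al, res.aligned[0], atol=1e-7)
        assert procrustes_distance(res.consensus, x) < 1e-7

    def test_consensus_equidistant_for_two_shapes(self, rng):
        a, b = random_config(rng), random_config(rng)
        res = gpa([a, b], space="shape")
        da = procrustes_distance(res.consensus, a)
        db = procrustes_distance(res.consensus, b)
        assert da == pytest.approx(db, abs=1e-6)

    def test_consensus_is_least_squares_optimal(self, rng):
        """Summed squared residuals about the consensus do not exceed those
        about any single input shape (pairwise OPA oracle)."""
        configs = [preshape(random_config(rng)) for _ in range(5)]
        res = gpa(configs, space="shape")

        def total_ss(target):
            return sum(opa_align(preshape(c), preshape(target)).residual ** 2
                       for c in configs)

        ss_consensus = total_ss(res.consensus)
        for c in configs:
            assert ss_consensus <= total_ss(c) + 1e-9

    def test_order_invariance(self, rng):
        configs = [random_config(rng) for _ in range(6)]
        res1 = gpa(configs, space="shape", tol=1e-12)
        order = rng.permutation(6)
        res2 = gpa([configs[i] for i in order], space="shape", tol=1e-12)
        np.testing.assert_allclose(res1.consensus, res2.consensus, atol=1e-8)

    def test_sizes_preserved_by_space(self, rng):
        configs = [random_config(rng) for _ in range(4)]
        shape_res = gpa(configs, space="shape")
        sss_res = gpa(configs, space="size_and_shape")
        for i, c in enumerate(configs):
            assert centroid_size(shape_res.aligned[i]) == pytest.approx(1.0)
            assert centroid_size(sss_res.aligned[i]) == pytest.approx(
                centroid_size(c))


class TestProcrustesDistance:
    def test_similarity_invariance(self, rng):
        x = random_config(rng)
        y = 2.5 * x @ rotation_z(1.0) + np.array([3, -1, 2])
        assert procrustes_distance(x, y) == pytest.approx(0, abs=1e-7)

    def test_equilateral_mirror_is_maximal(self):
        """Planar equilateral triangle vs its mirror image under SO(2)
        rotations only: the distance attains the pi/2 maximum."""
        mirror = EQUILATERAL * np.array([-1.0, 1.0])
        d = procrustes_distance(EQUILATERAL, mirror)
        assert d == pytest.approx(np.pi / 2, abs=1e-6)
        # brute-force confirmation over a dense SO(2) grid
        za = preshape(EQUILATERAL)
        zb = preshape(mirror)
        thetas = np.linspace(0, 2 * np.pi, 100_000, endpoint=False)
        cosines = np.cos(thetas)
        sines = np.sin(thetas)
        # tr(R^T zb^T za) over all rotation angles
        m = zb.T @ za
        traces = cosines * (m[0, 0] + m[1, 1]) + sines * (m[0, 1] - m[1, 0])
        assert np.arccos(traces.max()) == pytest.approx(np.pi / 2, abs=1e-6)

    def test_small_perturbation_matches_tangent_norm(self, rng):
        x = preshape(random_config(rng))
        eps = 1e-5 * rng.normal(size=x.shape)
        y = preshape(x + eps)
        d = procrustes_distance(x, y)
        y_aligned = opa_align(y, x).aligned
        v = tangent_project(preshape(y_aligned), x)
        # to first order the arc length equals the tangent residual norm
        assert d == pytest.approx(np.linalg.norm(v), rel=1e-3)

    def test_metric_properties_on_random_triples(self, rng):
        for _ in range(10):
            a, b, c = (random_config(rng, 8) for _ in range(3))
            dab = procrustes_distance(a, b)
            assert dab == pytest.approx(procrustes_distance(b, a), abs=1e-10)
            assert dab <= np.pi / 2 + 1e-12
            assert dab <= procrustes_distance(a, c) + procrustes_distance(c, b) + 1e-9


class TestTangentMaps:
    def test_pole_maps_to_zero(self, rng):
        p = random_config(rng)
        v = tangent_project(preshape(p), p)
        np.testing.assert_allclose(v, 0, atol=1e-12)

    def test_round_trip(self, rng):
        pole = random_config(rng)
        x = preshape(pole) + 0.01 * rng.normal(size=pole.shape)
        x = preshape(x)
        v = tangent_project(x, pole)
        np.testing.assert_allclose(tangent_unproject(v, pole), x, atol=1e-8)

    def test_projection_norm_approximates_distance(self, rng):
        pole = random_config(rng)
        x = preshape(preshape(pole) + 0.002 * rng.normal(size=pole.shape))
        x = preshape(opa_align(x, preshape(pole)).aligned)
        d = procrustes_distance(pole, x)
        v = tangent_project(x, pole)
        assert np.linalg.norm(v) == pytest.approx(d, rel=1e-3)
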