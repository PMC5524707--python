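"""Linear-shift parallel transport: local/common templates and residuals."""

import numpy as np
import pytest

from cardiomorph.core import gpa, preshape, procrustes_distance, \
    optimal_rotation, tangent_project
from cardiomorph.synthetic import GeneratorParams, generate_left_heart, \
    _horizontal_project
from cardiomorph.temporal import HomologousCycle, STRICT_INDICES
from cardiomorph.transport import linear_shift, local_template

PARAMS = GeneratorParams(n_circles=6, n_per_circle=6, subject_shape_sd=0.0)
K = 2 * PARAMS.layout.n_landmarks
LABELS = np.array(["LV"] * (K // 2) + ["LA"] * (K // 2))


def make_hcycle(shapes, subject_id="S0", group="Control"):
    return HomologousCycle(
        shapes=np.asarray(shapes, dtype=float),
        homologous_times_ms=np.arange(16) * 50.0,
        strict_indices=STRICT_INDICES,
        subject_id=subject_id,
        group=group,
        chamber_labels=LABELS,
        layout=PARAMS.layout,
    )


def deformed_cycle(rng, base, amp=0.01, n_modes=2, phases=None):
    """16 shapes = base + sum of horizontal modes with smooth periodic
    weights; returns (hcycle, per-time deformation fields)."""
    fields = _horizontal_project(rng.normal(size=(n_modes,) + base.shape), base)
    fields /= np.sqrt((fields ** 2).sum(axis=(1, 2)))[:, None, None]
    t = np.arange(16) / 16
    weights = np.stack([np.sin(2 * np.pi * (j + 1) * t) for j in range(n_modes)])
    deform = amp * np.einsum("jt,jkm->tkm", weights, fields)
    return np.stack([base + d for d in deform]), deform


@pytest.fixture
def base(rng):
    b = generate_left_heart(PARAMS, rng=None)
    return preshape(b)


class TestLocalTemplate:
    def test_motionless_cycle(self, base):
        lt = local_template(make_hcycle(np.repeat(base[None], 16, axis=0)))
        assert procrustes_distance(lt, base) < 1e-6

    def test_two_state_cycle_equidistant(self, rng, base):
        shapes, _ = deformed_cycle(rng, base, amp=0.02, n_modes=1)
        two_state = np.where((np.arange(16) % 2 == 0)[:, None, None],
                             shapes[0], shapes[4])
        lt = local_template(make_hcycle(two_state))
        d0 = procrustes_distance(lt, shapes[0])
        d4 = procrustes_distance(lt, shapes[4])
        assert d0 == pytest.approx(d4, abs=1e-7)

    def test_matches_mean_of_aligned_shapes(self, rng, base):
        """The LT equals the per-landmark average of the GPA-aligned
        shapes (direct averaging oracle), up to renormalization."""
        shapes, _ = deformed_cycle(rng, base)
        h = make_hcycle(shapes)
        lt = local_template(h)
        res = gpa(list(shapes), space="shape")
        mean = res.aligned.mean(axis=0)
        assert procrustes_distance(lt, preshape(mean)) < 1e-6


class TestLinearShift:
    def test_mean_residual_is_zero(self, rng, base):
        hcs = [make_hcycle(deformed_cycle(rng, base, amp=0.02)[0], f"S{i}")
               for i in range(4)]
        ts = linear_shift(hcs)
        means = ts.residuals.mean(axis=1)
        assert np.abs(means).max() < 1e-8

    def test_zero_shift_subject(self, rng, base):
        """For identical subjects (LT = CT) the transported shapes equal
        the subject's own aligned shapes."""
        shapes, _ = deformed_cycle(rng, base, amp=0.02)
        hcs = [make_hcycle(shapes, f"S{i}") for i in range(2)]
        ts = linear_shift(hcs)
        np.testing.assert_allclose(ts.residuals[0], ts.residuals[1], atol=1e-12)
        own = gpa(list(shapes), space="shape", canonical=False)
        rot = optimal_rotation(own.consensus, ts.common_template)
        proj = np.stack([tangent_project(s @ rot, ts.common_template)
                         for s in own.aligned])
        np.testing.assert_allclose(ts.residuals[0], proj - proj.mean(axis=0),
                                   atol=1e-8)

    def test_filters_inter_individual_differences(self, rng, base):
        """Two subjects with identical within-cycle deformations but
        different mean shapes yield identical residual sequences."""
        bump = _horizontal_project(rng.normal(size=base.shape), base)
        bump *= 1e-3 / np.linalg.norm(bump)
        base2 = preshape(base + bump)
        fields = _horizontal_project(rng.normal(size=(2,) + base.shape), base)
        fields /= np.sqrt((fields ** 2).sum(axis=(1, 2)))[:, None, None]
        t = np.arange(16) / 16
        w = np.stack([np.sin(2 * np.pi * t), np.cos(4 * np.pi * t)])
        deform = 1e-4 * np.einsum("jt,jkm->tkm", w, fields)
        h1 = make_hcycle(base[None] + deform, "S1")
        h2 = make_hcycle(base2[None] + deform, "S2")
        ts = linear_shift([h1, h2])
        diff = np.linalg.norm(ts.residuals[0] - ts.residuals[1])
        assert diff < 1e-6

    def test_recentering_oracle(self, rng, base):
        """Residuals match a direct no-projection oracle: rotate each
        subject's aligned shapes by its LT->CT rotation, subtract the
        rotated local template, re-center."""
        hcs = []
        for i in range(5):
            bump = _horizontal_project(rng.normal(size=base.shape), base)
            bump *= 5e-4 / np.linalg.norm(bump)
            shapes, _ = deformed_cycle(rng, preshape(base + bump), amp=1e-4)
            hcs.append(make_hcycle(shapes, f"S{i}"))
        ts = linear_shift(hcs)
        for i, h in enumerate(hcs):
            own = gpa(list(h.shapes), space="shape", canonical=False)
            rot = optimal_rotation(own.consensus, ts.common_template)
            rotated = own.aligned @ rot
            oracle = rotated - own.consensus @ rot
            oracle = oracle - oracle.mean(axis=0)
            err = np.linalg.norm(ts.residuals[i] - oracle)
            assert err / np.linalg.norm(oracle) < 1e-4

    def test_norm_preservation(self, rng, base):
        """The shift is plain tangent-plane subtraction/addition: each
        residual's norm equals the norm of the subject's own re-centered
        tangent deformation."""
        hcs = [make_hcycle(deformed_cycle(rng, base, amp=0.01)[0], f"S{i}")
               for i in range(3)]
        ts = linear_shift(hcs)
        shifted = ts.transported_shapes() - ts.common_template[None, None]
        np.testing.assert_allclose(
            np.linalg.norm(shifted, axis=(2, 3)),
            np.linalg.norm(ts.residuals, axis=(2, 3)), atol=1e-12)

    def test_grand_mean_of_transported_is_ct(self, rng, base):
        hcs = [make_hcycle(deformed_cycle(rng, base, amp=0.02)[0], f"S{i}")
               for i in range(4)]
        ts = linear_shift(hcs)
        grand = ts.transported_shapes().mean(axis=(0, 1))
        assert np.linalg.norm(grand - ts.common_template) < 1e-6

    def test_idempotence(self, rng, base):
        """Re-running the shift on the transported shapes reproduces the
        same residuals (CT as both source and destination)."""
        hcs = [make_hcycle(deformed_cycle(rng, base, amp=5e-3)[0], f"S{i}")
               for i in range(3)]
        ts = linear_shift(hcs)
        hcs2 = [make_hcycle(ts.transported_shapes()[i], f"S{i}")
                for i in range(3)]
        ts2 = linear_shift(hcs2)
        rot = optimal_rotation(ts.common_template, ts2.common_template)
        moved = ts.residuals @ rot
        err = np.linalg.norm(moved - ts2.residuals)
        assert err / np.linalg.norm(ts.residuals) < 1e-3

    def test_rejects_wrong_shape_count(self, base):
        good = make_hcycle(np.repeat(base[None], 16, axis=0))
        with pytest.raises(ValueError):
            linear_shift([good])
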