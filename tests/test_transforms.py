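import math

import numpy as np
import pytest

from icksim import (
    DoseGrid,
    GridSpec,
    Transform6DOF,
    apply_setup_error,
    build_matrix,
    error_vector,
    inverse,
)
from icksim.transforms import resample_mask, transform_points


def random_transform(rng, pivot=(0.0, 0.0, 0.0)):
    return Transform6DOF(
        dx=rng.uniform(-3, 3), dy=rng.uniform(-3, 3), dz=rng.uniform(-3, 3),
        pitch=rng.uniform(-2, 2), roll=rng.uniform(-2, 2), yaw=rng.uniform(-2, 2),
        pivot=pivot,
    )


class TestMatrix:
    def test_zero_transform_is_identity(self):
        assert np.allclose(build_matrix(Transform6DOF()), np.eye(4))

    def test_pure_yaw_chord_length(self):
        # a point 50 mm from the pivot moves along a chord 2 R sin(theta/2)
        t = Transform6DOF(yaw=2.0)
        p = transform_points(t, np.array([50.0, 0.0, 0.0]))
        displacement = np.linalg.norm(p - np.array([50.0, 0.0, 0.0]))
        assert displacement == pytest.approx(2 * 50 * math.sin(math.radians(1.0)), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_inverse_composes_to_identity(self, seed):
        rng = np.random.default_rng(seed)
        t = random_transform(rng, pivot=(5.0, -3.0, 2.0))
        assert np.allclose(build_matrix(t) @ build_matrix(inverse(t)), np.eye(4), atol=1e-9)

    @pytest.mark.parametrize("seed", range(5))
    def test_rotation_preserves_distance_to_pivot(self, seed):
        rng = np.random.default_rng(seed)
        pivot = np.array([1.0, 2.0, 3.0])
        t = Transform6DOF(
            pitch=rng.uniform(-2, 2), roll=rng.uniform(-2, 2), yaw=rng.uniform(-2, 2),
            pivot=tuple(pivot),
        )
        pts = rng.uniform(-60, 60, size=(20, 3))
        moved = transform_points(t, pts)
        r0 = np.linalg.norm(pts - pivot, axis=1)
        r1 = np.linalg.norm(moved - pivot, axis=1)
        assert np.allclose(r0, r1, atol=1e-6)

    def test_rotation_displacement_grows_linearly_with_lever_arm(self):
        t = Transform6DOF(yaw=2.0)
        theta = math.radians(2.0)
        for r in (10.0, 40.0, 80.0):
            p = transform_points(t, np.array([r, 0.0, 0.0]))
            chord = np.linalg.norm(p - np.array([r, 0.0, 0.0]))
            assert chord == pytest.approx(2 * r * math.sin(theta / 2), abs=1e-6)

    def test_opposite_signs_give_mirror_symmetric_displacements(self):
        # pure translations mirror exactly; composed Euler rotations mirror
        # only to second order in the angle, so bound the residual by R*theta^2
        t_plus = error_vector(1.5, 0.0, signs=[1, 1, 1, 1, 1, 1])
        t_minus = error_vector(1.5, 0.0, signs=[-1, -1, -1, -1, -1, -1])
        assert np.allclose(t_plus.translation, -t_minus.translation)
        plus = error_vector(1.5, 1.5, signs=[1, 1, 1, 1, 1, 1])
        minus = error_vector(1.5, 1.5, signs=[-1, -1, -1, -1, -1, -1])
        pts = np.array([[30.0, -10.0, 20.0], [-50.0, 5.0, 0.0]])
        d_plus = np.linalg.norm(transform_points(plus, pts) - pts, axis=1)
        d_minus = np.linalg.norm(transform_points(minus, pts) - pts, axis=1)
        theta = math.radians(1.5)
        bound = np.linalg.norm(pts, axis=1) * theta**2
        assert (np.abs(d_plus - d_minus) <= bound).all()

    def test_angle_guard_rejects_large_rotations(self):
        with pytest.raises(ValueError, match="guard"):
            Transform6DOF(pitch=15.0)


class TestApplySetupError:
    def test_identity_returns_exact_copy(self, sphere_phantom):
        out = apply_setup_error(sphere_phantom.dose, Transform6DOF())
        assert np.array_equal(out.values, sphere_phantom.dose.values)

    def test_pure_translation_shifts_linear_field(self):
        # d(x) = x + 40 sampled after dx=+2 becomes d(x + 2) in the interior
        g = GridSpec.centered_cube(20.0, spacing_mm=1.0)
        x = g.voxel_centers()[0]
        dose = DoseGrid(np.broadcast_to(x + 40.0, g.shape).copy(), g)
        out = apply_setup_error(dose, Transform6DOF(dx=2.0), warn_clip_fraction=1.0)
        interior = (slice(3, -3),) * 3
        assert np.allclose(out.values[interior], dose.values[interior] + 2.0, atol=1e-9)

    def test_two_mm_translation_drops_min_ptv_dose_by_falloff(self, sphere_phantom):
        # kernel geometry: min PTV dose falls ~ falloff_gradient * shift
        t = sphere_phantom.targets[0]
        ptv = sphere_phantom.ptv_masks[0]
        out = apply_setup_error(
            sphere_phantom.dose, Transform6DOF(dx=2.0), warn_clip_fraction=1.0
        )
        drop = (
            sphere_phantom.dose.values[ptv.voxels].min() - out.values[ptv.voxels].min()
        )
        # half-voxel sampling slack on each side of the 2 mm estimate
        assert drop == pytest.approx(t.falloff_gradient * 2.0, abs=t.falloff_gradient * 1.25)

    def test_round_trip_error_within_analytic_interpolation_bound(self, sphere_phantom):
        t = Transform6DOF(dx=1.0, dy=-0.7, dz=0.4, pitch=1.0, roll=-1.0, yaw=1.0)
        once = apply_setup_error(sphere_phantom.dose, t, warn_clip_fraction=1.0)
        back = apply_setup_error(once, inverse(t), warn_clip_fraction=1.0)
        interior = (slice(4, -4),) * 3
        diff = np.abs(back.values[interior] - sphere_phantom.dose.values[interior])
        # two trilinear resamples across a slope kink of at most
        # (d_max-19.2)/1mm + 3.3 ~ 10.8 Gy/mm err by <= 2 * jump * h / 4 each
        spec = sphere_phantom.targets[0]
        jump = (spec.d_max - spec.boundary_min_dose) / spec.ptv_margin + spec.falloff_gradient
        assert diff.max() <= 2 * jump * 1.25 / 4
        assert diff.mean() <= 0.5  # kinks occupy a thin shell; bulk is exact

    def test_large_shift_reports_clipping_and_warns(self, sphere_phantom):
        t = Transform6DOF(dx=25.0)
        with pytest.warns(UserWarning, match="clipped"):
            out = apply_setup_error(
                sphere_phantom.dose, t, stat_mask=sphere_phantom.brain_mask,
                warn_clip_fraction=0.001,
            )
        assert out.clip_fraction > 0

    def test_move_structures_mode_matches_moving_dose(self, sphere_phantom):
        # moving the dose by t equals moving the PTV by the inverse transform
        t = Transform6DOF(dx=2.5, dy=-1.25, dz=1.25)  # whole-voxel shifts: exact
        ptv = sphere_phantom.ptv_masks[0]
        dose_moved = apply_setup_error(sphere_phantom.dose, t, warn_clip_fraction=1.0)
        mask_moved = resample_mask(ptv, inverse(t))
        a = dose_moved.values[ptv.voxels].min()
        b = sphere_phantom.dose.values[mask_moved.voxels].min()
        assert a == pytest.approx(b, abs=1e-9)


class TestErrorVector:
    def test_all_positive_component_convention_matches_nominal(self):
        t = error_vector(2.0, 2.0, convention="component")
        assert (t.dx, t.dy, t.dz) == (2.0, 2.0, 2.0)
        assert (t.pitch, t.roll, t.yaw) == (2.0, 2.0, 2.0)

    def test_norm_convention_translation_norm_equals_magnitude(self):
        t = error_vector(2.0, 0.0)
        assert np.linalg.norm(t.translation) == pytest.approx(2.0)
        t2 = error_vector(1.0, 1.0, signs=[1, -1, 1, -1, 1, -1])
        assert np.linalg.norm(t2.translation) == pytest.approx(1.0)

    def test_zero_magnitudes_give_identity(self):
        assert error_vector(0.0, 0.0).is_identity

    def test_random_signs_reproducible_from_seed(self):
        a = error_vector(1.0, 1.0, signs="random", seed=3)
        b = error_vector(1.0, 1.0, signs="random", seed=3)
        assert a == b

    def test_json_round_trip(self):
        t = error_vector(1.0, 2.0, signs=[1, -1, 1, 1, -1, 1], pivot=(1.0, 2.0, 3.0))
        assert Transform6DOF.from_json(t.to_json()) == t
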