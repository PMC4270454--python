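import numpy as np
import pytest
from scipy.spatial.transform import Rotation

import polywear as pw
from conftest import pure_axis_cycle


class TestEulerRotation:
    def test_zero_angles_identity(self):
        np.testing.assert_allclose(pw.euler_rotation(0, 0, 0), np.eye(3), atol=1e-15)

    def test_single_axis_quarter_turn(self):
        r = pw.euler_rotation(90, 0, 0)
        np.testing.assert_allclose(r @ [0, 0, 1], [0, -1, 0], atol=1e-12)
        np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)

    @pytest.mark.parametrize("angles", [(30, 20, 10), (-15, 5, -8), (170, -80, 45)])
    def test_matches_fixed_axis_composition_oracle(self, angles):
        """Extrinsic x-y-z composition, checked element-wise against both an
        explicit single-axis matrix product and scipy's Rotation."""
        fe, aa, ier = angles
        rx = Rotation.from_euler("x", fe, degrees=True).as_matrix()
        ry = Rotation.from_euler("y", aa, degrees=True).as_matrix()
        rz = Rotation.from_euler("z", ier, degrees=True).as_matrix()
        ours = pw.euler_rotation(fe, aa, ier)
        np.testing.assert_allclose(ours, rz @ ry @ rx, atol=1e-12)
        np.testing.assert_allclose(
            ours, Rotation.from_euler("xyz", angles, degrees=True).as_matrix(), atol=1e-12
        )
        assert np.linalg.det(ours) == pytest.approx(1.0, abs=1e-12)

    def test_intrinsic_variant(self):
        angles = (30, 20, 10)
        np.testing.assert_allclose(
            pw.euler_rotation(*angles, intrinsic=True),
            Rotation.from_euler("XYZ", angles, degrees=True).as_matrix(),
            atol=1e-12,
        )


class TestRelativeMotion:
    def test_zero_angles_identity(self):
        cycle = pure_axis_cycle("fe", 0.0, 0.0)
        np.testing.assert_allclose(pw.relative_motion(cycle, 0), np.eye(3), atol=1e-15)

    def test_head_vs_negated_cup_equivalent(self):
        on_head = pure_axis_cycle("fe", 10.0, 10.0, carrier="head")
        on_cup = pure_axis_cycle("fe", -10.0, -10.0, carrier="cup")
        np.testing.assert_allclose(
            pw.relative_motion(on_head, 0), pw.relative_motion(on_cup, 0), atol=1e-12
        )

    def test_proper_orthogonal_for_all_protocols(self, any_cycle):
        for j in range(any_cycle.n_samples):
            r = pw.relative_motion(any_cycle, j)
            np.testing.assert_allclose(r @ r.T, np.eye(3), atol=1e-12)
            assert np.linalg.det(r) == pytest.approx(1.0, abs=1e-12)


class TestSliding:
    def test_single_axis_distance_is_path_times_lever_arm(self, spec, mesh):
        """Pure FE +-15 deg: per-node sliding over a cycle equals the total
        angular path (2 x 30 deg) times the node's distance to the x-axis,
        whatever the waveform shape."""
        cycle = pure_axis_cycle("fe", 15.0, -15.0, n_samples=64)
        field = pw.compute_sliding(mesh, cycle)
        theta = np.deg2rad(2 * 30.0)
        lever = mesh.radius * np.linalg.norm(mesh.directions[:, 1:], axis=1)
        keep = lever > 0.5  # skip near-axis nodes where both sides -> 0
        np.testing.assert_allclose(
            field.cycle_distance[keep], theta * lever[keep], rtol=5e-3
        )

    def test_node_on_axis_does_not_slide(self, spec):
        cycle = pure_axis_cycle("fe", 15.0, -15.0)
        mesh = pw.build_cup_mesh(spec, 1.0)
        mesh.directions[0] = [1.0, 0.0, 0.0]  # place a node on the FE axis
        field = pw.compute_sliding(mesh, cycle)
        assert field.cycle_distance[0] == pytest.approx(0.0, abs=1e-9)

    def test_single_axis_increments_collinear(self, spec, coarse_mesh):
        cycle = pure_axis_cycle("ier", 10.0, -10.0)
        field = pw.compute_sliding(coarse_mesh, cycle)
        u = field.increments
        cross = u[:, :, None, 0] * u[:, None, :, 1] - u[:, :, None, 1] * u[:, None, :, 0]
        scale = np.maximum(field.cycle_distance, 1e-12) ** 2
        assert np.max(np.abs(cross) / scale[:, None, None]) < 1e-9

    def test_surface_average_lever_arm(self, spec, mesh):
        """For single-axis motion the hemisphere-average lever arm is
        (pi/4) R, so mean(L) = path * (pi/4) R."""
        cycle = pure_axis_cycle("fe", 15.0, -15.0, n_samples=64)
        field = pw.compute_sliding(mesh, cycle)
        theta = np.deg2rad(60.0)
        expected = theta * (np.pi / 4.0) * mesh.radius
        assert pw.average_cycle_distance(field, mesh) == pytest.approx(expected, rel=0.01)

    def test_distances_match_increment_norms(self, mesh, any_cycle):
        field = pw.compute_sliding(mesh, any_cycle)
        np.testing.assert_allclose(
            np.linalg.norm(field.increments, axis=2), field.distances, atol=1e-12
        )

    def test_time_reversal_preserves_total_distance(self, coarse_mesh, any_cycle):
        import dataclasses

        rev = dataclasses.replace(
            any_cycle,
            fe_angle=np.roll(any_cycle.fe_angle[::-1], 1),
            aa_angle=np.roll(any_cycle.aa_angle[::-1], 1),
            ier_angle=np.roll(any_cycle.ier_angle[::-1], 1),
            load_magnitude=np.roll(any_cycle.load_magnitude[::-1], 1),
        )
        fwd = pw.compute_sliding(coarse_mesh, any_cycle)
        bwd = pw.compute_sliding(coarse_mesh, rev)
        np.testing.assert_allclose(bwd.cycle_distance, fwd.cycle_distance, rtol=1e-9)

    def test_benchmark_surface_averages(self, spec, mesh):
        """Whole-surface average per-cycle sliding distances are about
        20 / 18 / 21 mm for walking / ISO / ProSim on the 28 mm bearing."""
        mount = pw.inclination_matrix(spec.inclination_deg)
        for gen, target in [
            (pw.make_walking_cycle, 20.0),
            (pw.make_iso_cycle, 18.0),
            (pw.make_prosim_cycle, 21.0),
        ]:
            field = pw.compute_sliding(mesh, gen(), mount=mount)
            assert pw.average_cycle_distance(field, mesh) == pytest.approx(target, rel=0.15)


class TestTracks:
    def test_tracks_close_over_one_cycle(self, mesh, any_cycle):
        mount = pw.inclination_matrix(35.0)
        for node in (0, mesh.n_nodes // 2, mesh.n_nodes - 1):
            for convention in ("cup_on_head", "head_on_cup"):
                pts = pw.slide_track(mesh, any_cycle, node, mount=mount, convention=convention)
                np.testing.assert_allclose(pts[-1], pts[0], atol=1e-9)

    def test_unknown_convention_rejected(self, mesh):
        with pytest.raises(ValueError):
            pw.slide_track(mesh, pw.make_walking_cycle(), 0, convention="sideways")


class TestFlatten:
    def test_equator_maps_to_flattened_radius(self):
        """A 14.04 mm bearing flattens to a disc of radius pi R / 2 = 22 mm."""
        radius = 14.04
        flat = pw.flatten_track(np.array([[radius, 0.0, 0.0]]))
        assert np.linalg.norm(flat[0]) == pytest.approx(np.pi * radius / 2, abs=1e-9)
        assert np.linalg.norm(flat[0]) == pytest.approx(22.05, abs=0.01)

    def test_pole_maps_to_origin(self):
        flat = pw.flatten_track(np.array([[0.0, 0.0, 14.04]]))
        np.testing.assert_allclose(flat[0], [0.0, 0.0], atol=1e-12)

    def test_meridian_arc_length_preserved(self):
        radius = 14.04
        polar = np.linspace(0, np.pi / 2, 50)
        pts = radius * np.column_stack(
            [np.sin(polar), np.zeros_like(polar), np.cos(polar)]
        )
        flat = pw.flatten_track(pts)
        np.testing.assert_allclose(
            np.linalg.norm(flat, axis=1), radius * polar, atol=1e-12
        )
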