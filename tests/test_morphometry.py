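"""Anatomical axes, FTA and medial-plateau coronal inclination."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from cortmap import (compute_fta, compute_section_centroids, fit_anatomical_axis,
                     fit_mct_plane, mct_coronal_angle)
from cortmap.anatomy import TibialCS
from cortmap.morphometry import AnatomicalAxis, FTAResult, MCTPlane
from cortmap.phantom import (PhantomSpec, _tube_mesh, generate_alignment_meshes,
                             generate_mct_points)

from helpers_oracles import (angle_between, grid_search_line_direction,
                             grid_search_plane_normal)

IDENT = TibialCS.identity()


def fta_for_varus(varus, side="right"):
    spec = PhantomSpec(varus_angle=varus, side=side)
    femur, tibia, frame = generate_alignment_meshes(spec)
    fa = fit_anatomical_axis(compute_section_centroids(femur, frame, "femur"))
    ta = fit_anatomical_axis(compute_section_centroids(tibia, frame, "tibia"))
    return compute_fta(fa, ta, frame, side=side)


class TestSectionCentroids:
    def test_counts_per_bone(self):
        spec = PhantomSpec()
        femur, tibia, frame = generate_alignment_meshes(spec)
        assert len(compute_section_centroids(femur, frame, "femur")) == 10
        assert len(compute_section_centroids(tibia, frame, "tibia")) == 12

    def test_straight_prism_centroids_on_axis(self):
        mesh = _tube_mesh([0, 0, 0], [0, 0, 1], 300.0, lambda f: 12.0)
        cents = compute_section_centroids(mesh, IDENT, "tibia")
        assert np.allclose(cents[:, :2], 0.0, atol=1e-6)

    def test_bowed_prism_centroids_offset(self):
        """2 mm lateral bow at mid-shaft shifts the mid centroids by ~2 mm."""
        mesh = _tube_mesh([0, 0, 0], [0, 0, 1], 300.0, lambda f: 12.0,
                          n_rings=60)
        z = mesh.vertices[:, 2]
        bow = 2.0 * np.sin(np.pi * z / 300.0)
        mesh.vertices[:, 0] += bow
        cents = compute_section_centroids(mesh, IDENT, "tibia")
        mid = np.argmin(np.abs(cents[:, 2] - 150.0))
        assert cents[mid, 0] == pytest.approx(
            2.0 * np.sin(np.pi * cents[mid, 2] / 300.0), abs=0.1)


class TestAnatomicalAxis:
    def test_collinear_centroids_zero_residual(self):
        pts = np.outer(np.linspace(0, 10, 12), [0.2, 0.3, 1.0])
        ax = fit_anatomical_axis(pts)
        assert ax.rms_residual < 1e-12
        assert angle_between(ax.direction, [0.2, 0.3, 1.0]) < 1e-12

    def test_noisy_axis_matches_grid_oracle(self, rng):
        pts = np.outer(np.linspace(0, 120, 12), [0.05, -0.02, 1.0])
        pts += rng.normal(0, 0.8, pts.shape)
        ax = fit_anatomical_axis(pts)
        oracle = grid_search_line_direction(pts)
        assert angle_between(ax.direction, oracle) < 1e-6

    def test_single_centroid_rejected(self):
        with pytest.raises(ValueError):
            fit_anatomical_axis(np.array([[1.0, 2.0, 3.0]]))
        with pytest.raises(ValueError, match="coincide"):
            fit_anatomical_axis(np.tile([1.0, 2.0, 3.0], (5, 1)))


class TestFTA:
    def test_straight_limb_is_180(self):
        res = fta_for_varus(0.0)
        assert res.fta == pytest.approx(180.0, abs=1e-6)

    def test_seven_degree_varus(self):
        assert fta_for_varus(7.0).fta == pytest.approx(187.0, abs=0.1)

    def test_valgus_matches_healthy_female_scale(self):
        assert fta_for_varus(-4.6).fta == pytest.approx(175.4, abs=0.1)

    def test_left_side_sign_convention(self):
        assert fta_for_varus(7.0, side="left").fta == pytest.approx(187.0, abs=0.1)

    @pytest.mark.parametrize("lo,hi", [(0.0, 2.0), (2.0, 5.0), (5.0, 9.0)])
    def test_monotone_in_varus(self, lo, hi):
        assert fta_for_varus(hi).fta > fta_for_varus(lo).fta

    def test_axis_orthogonal_to_coronal_plane_rejected(self):
        fa = AnatomicalAxis(np.zeros(3), np.array([0, 0, -1.0]), 0.0, 10)
        ta = AnatomicalAxis(np.zeros(3), np.array([0, 1.0, 0]), 0.0, 12)
        with pytest.raises(ValueError, match="coronal"):
            compute_fta(fa, ta, IDENT)

    def test_implausible_fta_rejected(self):
        with pytest.raises(ValueError):
            FTAResult(fta=80.0)


class TestMCTPlane:
    def test_coplanar_points_exact(self):
        pts = generate_mct_points(0.2, 0.1, n=8, seed=0)
        plane = fit_mct_plane(pts)
        assert plane.fit_rms < 1e-9
        ref = np.array([-0.2, -0.1, 1.0])
        assert angle_between(plane.normal, ref) < 1e-9

    def test_noisy_plane_matches_grid_oracle(self, rng):
        pts = generate_mct_points(0.2, 0.05, n=30, noise_sd=0.4, seed=4)
        plane = fit_mct_plane(pts)
        oracle = grid_search_plane_normal(pts)
        assert angle_between(plane.normal, oracle) < 1e-6

    def test_collinear_rejected(self):
        pts = np.outer(np.linspace(0, 1, 5), [1.0, 2.0, 0.5])
        with pytest.raises(ValueError, match="collinear"):
            fit_mct_plane(pts)


class TestMCTCoronalAngle:
    def _plane(self, b, a=0.0):
        n = np.array([-b, -a, 1.0])
        n /= np.linalg.norm(n)
        return MCTPlane(normal=n, offset=0.0, fit_rms=0.0, centroid=np.zeros(3))

    def test_horizontal_plateau_is_zero(self):
        assert mct_coronal_angle(self._plane(0.0), IDENT) == pytest.approx(0.0)

    def test_known_slope_recovered_exactly(self):
        b = np.tan(np.radians(12.2))
        assert mct_coronal_angle(self._plane(b), IDENT) == pytest.approx(
            12.2, abs=1e-9)

    def test_sagittal_tilt_leaves_coronal_angle_unchanged(self):
        b = np.tan(np.radians(9.3))
        for a in (0.0, 0.1, -0.25):
            assert mct_coronal_angle(self._plane(b, a), IDENT) == pytest.approx(
                9.3, abs=1e-9)

    def test_degenerate_plane_rejected(self):
        plane = MCTPlane(normal=np.array([0.0, 1.0, 0.0]), offset=0.0,
                         fit_rms=0.0, centroid=np.zeros(3))
        with pytest.raises(ValueError):
            mct_coronal_angle(plane, IDENT)


class TestRigidEquivariance:
    def test_fta_and_mct_invariant_under_rigid_motion(self):
        """Moving meshes and frames together leaves both angles unchanged."""
        spec = PhantomSpec(varus_angle=5.0)
        femur, tibia, frame = generate_alignment_meshes(spec)
        R = Rotation.from_euler("xyz", [11, -27, 42], degrees=True).as_matrix()
        t = np.array([30.0, -12.0, 55.0])
        femur2, tibia2 = femur.copy(), tibia.copy()
        femur2.vertices = femur.vertices @ R.T + t
        tibia2.vertices = tibia.vertices @ R.T + t
        frame2 = TibialCS(R @ frame.origin + t, R @ frame.x_axis,
                          R @ frame.y_axis, R @ frame.z_axis)
        fta1 = compute_fta(
            fit_anatomical_axis(compute_section_centroids(femur, frame, "femur")),
            fit_anatomical_axis(compute_section_centroids(tibia, frame, "tibia")),
            frame).fta
        fta2 = compute_fta(
            fit_anatomical_axis(compute_section_centroids(femur2, frame2, "femur")),
            fit_anatomical_axis(compute_section_centroids(tibia2, frame2, "tibia")),
            frame2).fta
        assert fta2 == pytest.approx(fta1, abs=1e-6)

        pts = generate_mct_points(0.2, 0.05, n=8, seed=2)
        a1 = mct_coronal_angle(fit_mct_plane(pts), IDENT)
        frame3 = TibialCS(t, R[:, 0], R[:, 1], R[:, 2])
        a2 = mct_coronal_angle(fit_mct_plane(pts @ R.T + t), frame3)
        assert a2 == pytest.approx(a1, abs=1e-6)
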